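"""Filtering of score tables and export of visualization-ready artifacts.

Two static export formats are produced per condition: a Sankey structure
(gene nodes in their pathway roles, links weighted by the number of
surviving pathways traversing each adjacent gene pair) and a cell-group
interaction graph (directed sender-to-receiver edges weighted by surviving
pathway counts, node sizes from cell counts).  Both are plain JSON validated
against the schema files shipped in ``incytr/schemas``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any, Mapping

import pandas as pd

from .expression import CellAnnotation

ROLES = ("ligand", "receptor", "em", "target")


def filter_scores(
    records: pd.DataFrame,
    min_probability: float | None = None,
    max_padj: float | None = None,
    min_abs_pds: float | None = None,
    min_abs_t_pds: float | None = None,
    genes: list[str] | None = None,
    sender_groups: list[str] | None = None,
    receiver_groups: list[str] | None = None,
) -> tuple[pd.DataFrame, dict[str, Any]]:
    """AND-combine optional thresholds over a score table.

    ``min_probability`` and ``max_padj`` pass a record when met in at least
    one condition; gene selection keeps pathways containing any listed gene.
    Returns the surviving records and a provenance dict of the thresholds
    applied.
    """
    keep = pd.Series(True, index=records.index)
    applied: dict[str, Any] = {}
    if min_probability is not None:
        keep &= (records["P_cond1"] >= min_probability) | (
            records["P_cond2"] >= min_probability
        )
        applied["min_probability"] = min_probability
    if max_padj is not None:
        keep &= (records["padj_cond1"] <= max_padj) | (records["padj_cond2"] <= max_padj)
        applied["max_padj"] = max_padj
    if min_abs_pds is not None:
        keep &= records["PDS"].abs() >= min_abs_pds
        applied["min_abs_pds"] = min_abs_pds
    if min_abs_t_pds is not None:
        keep &= records["T_PDS"].abs() >= min_abs_t_pds
        applied["min_abs_t_pds"] = min_abs_t_pds
    if genes is not None:
        gset = set(genes)
        keep &= records[list(ROLES)].isin(gset).any(axis=1)
        applied["genes"] = sorted(gset)
    if sender_groups is not None:
        keep &= records["sender_group"].isin(sender_groups)
        applied["sender_groups"] = sorted(sender_groups)
    if receiver_groups is not None:
        keep &= records["receiver_group"].isin(receiver_groups)
        applied["receiver_groups"] = sorted(receiver_groups)
    return records[keep].reset_index(drop=True), applied


def export_sankey(
    filtered: pd.DataFrame, condition: str, filters_applied: Mapping[str, Any] | None = None
) -> dict:
    """Sankey structure of the surviving pathways for one condition panel.

    Nodes are (gene, role) pairs; a link's weight is the count of pathways
    traversing that gene pair at adjacent roles.
    """
    nodes: list[dict] = []
    node_id: dict[tuple[str, str], int] = {}

    def _node(gene: str, role: str, sender_group: str) -> int:
        key = (gene, role)
        if key not in node_id:
            node_id[key] = len(nodes)
            nodes.append(
                {"id": len(nodes), "label": gene, "role": role, "sender_group": sender_group}
            )
        return node_id[key]

    link_weight: dict[tuple[int, int], int] = {}
    for row in filtered.to_dict("records"):
        ids = [
            _node(row[role], role, row["sender_group"]) for role in ROLES
        ]
        for a, b in zip(ids, ids[1:]):
            link_weight[(a, b)] = link_weight.get((a, b), 0) + 1

    return {
        "condition": condition,
        "sign_convention": "positive scores mean condition-1 dominant",
        "nodes": nodes,
        "links": [
            {"source": a, "target": b, "weight": w}
            for (a, b), w in sorted(link_weight.items())
        ],
        "filters_applied": dict(filters_applied or {}),
    }


def export_interaction_graph(
    filtered: pd.DataFrame, ann: CellAnnotation, condition: str
) -> dict:
    """Directed cell-group graph: edge weight = surviving pathway count."""
    counts = (
        filtered.groupby(["sender_group", "receiver_group"]).size().reset_index(name="n")
    )
    sizes = ann.group_sizes(condition=condition)
    return {
        "condition": condition,
        "nodes": [
            {"group": g, "n_cells": int(n)} for g, n in sorted(sizes.items())
        ],
        "edges": [
            {
                "sender_group": r.sender_group,
                "receiver_group": r.receiver_group,
                "n_pathways": int(r.n),
            }
            for r in counts.itertuples(index=False)
            if r.n >= 1
        ],
    }


def export_corpus(records: pd.DataFrame) -> str:
    """One 'L R EM T' sentence per pathway (hook for text-embedding tools)."""
    return "\n".join(
        " ".join(row[r] for r in ROLES) for row in records.to_dict("records")
    )


def interaction_graph_edges(graph: dict) -> pd.DataFrame:
    """Edge list CSV form of an interaction-graph export."""
    return pd.DataFrame(graph["edges"], columns=["sender_group", "receiver_group", "n_pathways"])


# ---------------------------------------------------------------------------
# schema validation (minimal, for the schema dialect used by the shipped files)


def _load_schema(name: str) -> dict:
    with resources.files("incytr").joinpath("schemas", name).open() as fh:
        return json.load(fh)


_TYPES = {
    "object": dict,
    "array": list,
    "string": str,
    "integer": int,
    "number": (int, float),
    "boolean": bool,
}


def _check(instance: Any, schema: Mapping[str, Any], where: str) -> None:
    typ = schema.get("type")
    if typ and not isinstance(instance, _TYPES[typ]):
        raise ValueError(f"{where}: expected {typ}, got {type(instance).__name__}")
    if typ == "object":
        for req in schema.get("required", []):
            if req not in instance:
                raise ValueError(f"{where}: missing required key {req!r}")
        for key, sub in schema.get("properties", {}).items():
            if key in instance:
                _check(instance[key], sub, f"{where}.{key}")
    elif typ == "array" and "items" in schema:
        for i, item in enumerate(instance):
            _check(item, schema["items"], f"{where}[{i}]")


def validate_export(document: dict, kind: str) -> None:
    """Validate an export document against its shipped JSON schema.

    ``kind`` is 'sankey' or 'interaction_graph'; raises ValueError on
    violation.
    """
    schema = _load_schema(f"{kind}.schema.json")
    _check(document, schema, kind)


def write_json(document: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(document, indent=2) + "\n")
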
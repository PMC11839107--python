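"""Enumeration of admissible ligand-receptor-EM-target signaling pathways.

A pathway L-R-EM-T between a sender and a receiver cell group is admissible
when the ligand is a sender gene, the receptor, effector molecule and target
are receiver genes, each consecutive pair is documented in the corresponding
database layer, and R, EM, T are pairwise distinct.  The ligand may by
default coincide with a downstream component (distinctness is required only
among R, EM and T); ``exclude_ligand_overlap`` additionally forbids
L ∈ {R, EM, T}.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .db import InteractionDB

logger = logging.getLogger(__name__)

PATHWAY_COLUMNS = ["sender_group", "receiver_group", "ligand", "receptor", "em", "target"]


@dataclass
class PathwayTable:
    """A deduplicated, lexicographically ordered table of pathways."""

    table: pd.DataFrame = field(repr=False)
    sender_genes: list[str] = field(default_factory=list)
    receiver_genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        df = self.table
        missing = [c for c in PATHWAY_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"pathway table missing columns: {missing}")
        if df.duplicated(subset=PATHWAY_COLUMNS).any():
            raise ValueError("duplicate pathway rows")
        self.table = df[PATHWAY_COLUMNS].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    def genes(self) -> set[str]:
        """All gene symbols occurring in any pathway component."""
        out: set[str] = set()
        for col in ("ligand", "receptor", "em", "target"):
            out |= set(self.table[col])
        return out

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "PathwayTable":
        return cls(table=pd.read_csv(path, dtype=str))


def infer_pathways(
    db: InteractionDB,
    sender_genes: Iterable[str],
    receiver_genes: Iterable[str],
    sender_group: str,
    receiver_group: str,
    exclude_ligand_overlap: bool = False,
) -> PathwayTable:
    """Enumerate all admissible pathways for one sender/receiver group pair.

    The result is exactly the set of tuples (L, R, EM, T) with L a sender
    gene, {R, EM, T} receiver genes, L->R, R->EM and EM->T present in the
    corresponding layers, and R, EM, T pairwise distinct; ordered
    lexicographically on (L, R, EM, T).
    """
    senders = set(sender_genes)
    receivers = set(receiver_genes)
    if not senders or not receivers:
        raise ValueError("sender and receiver gene lists must be nonempty")

    lr = db.layer("LR")
    re_ = db.layer("RE")
    et = db.layer("ET")

    # index each layer by source for the chained join
    re_by_src: dict[str, list[str]] = {}
    for s, t in zip(re_["source"], re_["target"]):
        if t in receivers:
            re_by_src.setdefault(s, []).append(t)
    et_by_src: dict[str, list[str]] = {}
    for s, t in zip(et["source"], et["target"]):
        if t in receivers:
            et_by_src.setdefault(s, []).append(t)

    rows = []
    for lig, rec in zip(lr["source"], lr["target"]):
        if lig not in senders or rec not in receivers:
            continue
        for em in re_by_src.get(rec, ()):
            if em == rec:
                continue
            for tgt in et_by_src.get(em, ()):
                if tgt == rec or tgt == em:
                    continue
                if exclude_ligand_overlap and lig in (rec, em, tgt):
                    continue
                rows.append((sender_group, receiver_group, lig, rec, em, tgt))

    df = pd.DataFrame(rows, columns=PATHWAY_COLUMNS).drop_duplicates()
    df = df.sort_values(["ligand", "receptor", "em", "target"]).reset_index(drop=True)
    if df.empty:
        logger.warning(
            "no pathways found for %s -> %s", sender_group, receiver_group
        )
    return PathwayTable(
        table=df, sender_genes=sorted(senders), receiver_genes=sorted(receivers)
    )


def enumerate_group_pairs(
    db: InteractionDB,
    sender_map: Mapping[str, Iterable[str]],
    receiver_map: Mapping[str, Iterable[str]],
    exclude_ligand_overlap: bool = False,
) -> PathwayTable:
    """Union of :func:`infer_pathways` over every (sender, receiver) group pair.

    Autocrine pairs (sender group == receiver group) are included.
    """
    if not sender_map or not receiver_map:
        raise ValueError("sender and receiver maps must be nonempty")
    parts = []
    all_senders: set[str] = set()
    all_receivers: set[str] = set()
    for sg in sorted(sender_map):
        for rg in sorted(receiver_map):
            pt = infer_pathways(
                db,
                sender_map[sg],
                receiver_map[rg],
                sender_group=sg,
                receiver_group=rg,
                exclude_ligand_overlap=exclude_ligand_overlap,
            )
            parts.append(pt.table)
            all_senders |= set(sender_map[sg])
            all_receivers |= set(receiver_map[rg])
    df = pd.concat(parts, ignore_index=True).drop_duplicates()
    df = df.sort_values(PATHWAY_COLUMNS).reset_index(drop=True)
    return PathwayTable(
        table=df,
        sender_genes=sorted(all_senders),
        receiver_genes=sorted(all_receivers),
    )
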
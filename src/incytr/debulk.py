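"""Allocation of bulk (phospho)proteomic signal to cell groups.

Mass-spectrometry measurements are typically bulk: one value per feature per
sample, with no cell-type resolution.  Debulking distributes each bulk value
across cell groups proportionally to the groups' share of the gene's raw
single-cell transcript counts in the matching condition, so the allocations
of a feature in a sample always sum exactly to the bulk value.

Phosphosite features ("GENE_S473") are allocated using the transcript
proportions of the whole gene; the gene symbol is taken as the part of the
identifier before the first underscore (configurable regex).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .expression import CellAnnotation, ExpressionMatrix

logger = logging.getLogger(__name__)

MODALITIES = ("protein", "phospho_ST", "phospho_Y")

#: default phosphosite identifier dialect: gene symbol before first underscore
SITE_REGEX = r"^(?P<gene>[^_]+)(_.*)?$"


@dataclass
class BulkOmicsMatrix:
    """Features-by-samples matrix of strictly positive bulk measurements."""

    features: list[str]
    samples: list[str]
    values: np.ndarray  # (n_features, n_samples), strictly positive
    sample_condition: dict[str, str]
    modality: str = "protein"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.features), len(self.samples)):
            raise ValueError("bulk matrix shape mismatch")
        if (self.values <= 0).any() or not np.isfinite(self.values).all():
            raise ValueError("bulk values must be strictly positive and finite")
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        missing = [s for s in self.samples if s not in self.sample_condition]
        if missing:
            raise ValueError(f"samples without condition mapping: {missing}")

    def feature_gene(self, feature: str, site_regex: str = SITE_REGEX) -> str:
        m = re.match(site_regex, feature)
        if m is None:
            raise ValueError(f"feature id {feature!r} does not match site regex")
        return m.group("gene")


@dataclass
class DebulkedOmics:
    """Per-group allocations and condition-level averages of one modality.

    ``allocations`` is long-format (feature, gene, sample, condition, group,
    value); for every (feature, sample) the values over groups sum to the
    bulk value.  ``levels`` averages allocations over each condition's
    samples: (feature, gene, group, condition, level).
    """

    modality: str
    allocations: pd.DataFrame = field(repr=False)
    levels: pd.DataFrame = field(repr=False)
    skipped_features: list[str] = field(default_factory=list)

    def level(self, gene: str, group: str, condition: str, default: float | None = None) -> float:
        """Condition-level value for a gene (summing over a gene's features).

        Phospho matrices can carry several sites per gene; their levels are
        summed so one number per (gene, group, condition) feeds scoring.
        """
        sub = self.levels[
            (self.levels["gene"] == gene)
            & (self.levels["group"] == group)
            & (self.levels["condition"] == condition)
        ]
        if sub.empty:
            if default is not None:
                return default
            raise KeyError((gene, group, condition))
        return float(sub["level"].sum())

    def genes(self) -> set[str]:
        return set(self.levels["gene"])


def transcript_proportions(
    raw_counts: ExpressionMatrix, ann: CellAnnotation
) -> pd.DataFrame:
    """Per-gene share of raw transcript counts held by each group.

    Counts are aggregated per (gene, group, condition); an aggregate of
    exactly zero is imputed to 1 before proportioning so every group gets a
    positive share and later divisions cannot hit zero.  Returns a long
    DataFrame (gene, group, condition, proportion) whose proportions sum to
    1 within each (gene, condition).
    """
    if raw_counts.normalized:
        raise ValueError("transcript proportions are computed on raw counts")
    col_of = {c: j for j, c in enumerate(raw_counts.cells)}
    rows = []
    for condition in ann.conditions:
        groups = [g for g in ann.groups if ann.cells_of(group=g, condition=condition)]
        agg = np.zeros((len(raw_counts.genes), len(groups)))
        for k, group in enumerate(groups):
            cols = [col_of[c] for c in ann.cells_of(group=group, condition=condition) if c in col_of]
            agg[:, k] = raw_counts.values[:, cols].sum(axis=1)
        agg[agg == 0] = 1.0  # zero aggregates imputed to one pseudo-count
        props = agg / agg.sum(axis=1, keepdims=True)
        for i, gene in enumerate(raw_counts.genes):
            for k, group in enumerate(groups):
                rows.append((gene, group, condition, props[i, k]))
    return pd.DataFrame(rows, columns=["gene", "group", "condition", "proportion"])


def debulk(
    bulk: BulkOmicsMatrix,
    props: pd.DataFrame,
    site_regex: str = SITE_REGEX,
) -> DebulkedOmics:
    """Allocate bulk values to groups and average them per condition.

    ``allocated[feature, group, sample] = bulk[feature, sample] *
    proportion[gene(feature), group, condition(sample)]``; the
    (group, condition) level is the arithmetic mean over that condition's
    samples.  Features whose gene has no transcript proportions are skipped
    and reported.
    """
    prop_lookup: dict[tuple[str, str], pd.DataFrame] = {
        (g, c): sub.set_index("group")["proportion"]
        for (g, c), sub in props.groupby(["gene", "condition"])
    }
    alloc_rows = []
    skipped: list[str] = []
    for i, feature in enumerate(bulk.features):
        gene = bulk.feature_gene(feature, site_regex)
        covered = False
        for j, sample in enumerate(bulk.samples):
            condition = bulk.sample_condition[sample]
            key = (gene, condition)
            if key not in prop_lookup:
                continue
            covered = True
            shares = prop_lookup[key]
            for group, share in shares.items():
                alloc_rows.append(
                    (feature, gene, sample, condition, group, bulk.values[i, j] * share)
                )
        if not covered:
            skipped.append(feature)
    if skipped:
        logger.info(
            "%d %s features skipped (gene absent from transcript proportions)",
            len(skipped),
            bulk.modality,
        )
    allocations = pd.DataFrame(
        alloc_rows,
        columns=["feature", "gene", "sample", "condition", "group", "value"],
    )
    if allocations.empty:
        levels = pd.DataFrame(columns=["feature", "gene", "group", "condition", "level"])
    else:
        levels = (
            allocations.groupby(["feature", "gene", "group", "condition"], sort=True)["value"]
            .mean()
            .reset_index()
            .rename(columns={"value": "level"})
        )
    return DebulkedOmics(
        modality=bulk.modality,
        allocations=allocations,
        levels=levels,
        skipped_features=skipped,
    )


def read_bulk_matrix(
    matrix_path: str | Path,
    sample_map_path: str | Path,
    modality: str = "protein",
) -> BulkOmicsMatrix:
    """Read a bulk matrix CSV (first column feature id) plus a sample map CSV."""
    df = pd.read_csv(matrix_path, index_col=0)
    smap = pd.read_csv(sample_map_path, dtype=str)
    for col in ("sample", "condition"):
        if col not in smap.columns:
            raise ValueError(f"sample map missing column {col!r}")
    return BulkOmicsMatrix(
        features=[str(f) for f in df.index],
        samples=[str(s) for s in df.columns],
        values=df.to_numpy(dtype=float),
        sample_condition=dict(zip(smap["sample"], smap["condition"])),
        modality=modality,
    )
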
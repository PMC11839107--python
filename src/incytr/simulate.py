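"""Self-contained synthetic inputs with planted ground-truth pathways.

The generator emulates the full input set of a differential signaling
analysis: a negative-binomial single-cell count matrix over two conditions,
a three-layer interaction database containing the planted chains plus decoy
chains, bulk (phospho)proteomics matrices derived from pseudo-bulk sums with
lognormal noise, and a kinase-substrate prediction table.

Planted pathways have the expression of their components multiplied by
``effect_size`` (on the raw count mean, pre-normalization) in the designated
condition — the ligand in the sender group, receptor/EM/target in the
receiver group.  Signal genes are kept at low mean counts while dedicated
high-abundance "filler" genes carry the bulk of each cell's library size, so
that after library-size normalization the average expression of signal genes
lands in the dynamic range of the Hill factors (products around the
half-saturation constant) rather than in saturation, as in real data where
most signaling genes are sparsely detected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .db import InteractionDB, KinasePrediction, _dedupe
from .debulk import BulkOmicsMatrix
from .expression import CellAnnotation, ExpressionMatrix
from .pathways import PATHWAY_COLUMNS, PathwayTable

CONDITIONS = ("cond1", "cond2")


@dataclass
class PlantedPathway:
    """One ground-truth differential pathway."""

    ligand: str
    receptor: str
    em: str
    target: str
    sender_group: str
    receiver_group: str
    direction: str = "cond1_up"  # which condition carries the elevated expression
    effect_size: float = 4.0

    def __post_init__(self) -> None:
        if self.effect_size <= 1:
            raise ValueError("effect_size must exceed 1")
        if self.direction not in ("cond1_up", "cond2_up"):
            raise ValueError("direction must be 'cond1_up' or 'cond2_up'")

    @property
    def up_condition(self) -> str:
        return "cond1" if self.direction == "cond1_up" else "cond2"

    def genes(self) -> tuple[str, str, str, str]:
        return (self.ligand, self.receptor, self.em, self.target)


def _default_planted() -> list[PlantedPathway]:
    return [
        PlantedPathway("LIGA", "RECA", "EMA", "TGTA", "g1", "g2", "cond1_up", 4.0),
        PlantedPathway("LIGB", "RECB", "EMB", "TGTB", "g1", "g2", "cond2_up", 4.0),
    ]


@dataclass
class SyntheticDesign:
    """Parameters of the synthetic study.

    Defaults describe a two-condition comparison of 3 cell groups with 500
    cells per group per condition, two planted pathways (one up in each
    condition, four-fold effect), 8 decoy chains among background genes,
    triplicate bulk samples per condition with 10% lognormal noise, and a
    negative-binomial count model (signal genes at mean 0.5 counts/cell,
    constant dispersion).
    """

    n_groups: int = 3
    n_cells_per_group_per_condition: int = 500
    n_background_genes: int = 48
    n_filler_genes: int = 20
    planted_pathways: list[PlantedPathway] = field(default_factory=_default_planted)
    n_decoy_chains: int = 8
    n_decoy_kinases: int = 2
    signal_mean: float = 0.5
    filler_mean: float = 50.0
    dispersion: float = 2.0
    bulk_noise_cv: float = 0.1
    n_bulk_samples_per_condition: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_groups < 2:
            raise ValueError("at least two groups are required")
        needed = 4 * self.n_decoy_chains + self.n_decoy_kinases
        if needed > self.n_background_genes:
            raise ValueError(
                f"{self.n_background_genes} background genes cannot host "
                f"{self.n_decoy_chains} decoy chains + {self.n_decoy_kinases} kinases"
            )
        planted = [g for p in self.planted_pathways for g in p.genes()]
        if len(set(planted)) != len(planted):
            raise ValueError("planted pathways must use distinct genes")

    @property
    def groups(self) -> list[str]:
        return [f"g{i + 1}" for i in range(self.n_groups)]

    @property
    def planted_genes(self) -> list[str]:
        return [g for p in self.planted_pathways for g in p.genes()]

    @property
    def background_genes(self) -> list[str]:
        return [f"BG{i + 1:03d}" for i in range(self.n_background_genes)]

    @property
    def filler_genes(self) -> list[str]:
        return [f"FILL{i + 1:02d}" for i in range(self.n_filler_genes)]

    @property
    def genes(self) -> list[str]:
        return self.planted_genes + self.background_genes + self.filler_genes

    def decoy_chains(self) -> list[tuple[str, str, str, str]]:
        """Decoy L-R-EM-T chains over disjoint background genes.

        Decoys never touch planted genes, so no decoy edge can complete a
        planted chain with swapped members.
        """
        bg = self.background_genes
        return [
            (bg[4 * i], bg[4 * i + 1], bg[4 * i + 2], bg[4 * i + 3])
            for i in range(self.n_decoy_chains)
        ]

    def decoy_kinase_genes(self) -> list[str]:
        start = 4 * self.n_decoy_chains
        return self.background_genes[start : start + self.n_decoy_kinases]

    def truth_table(self) -> PathwayTable:
        rows = [
            (p.sender_group, p.receiver_group, *p.genes())
            for p in self.planted_pathways
        ]
        return PathwayTable(table=pd.DataFrame(rows, columns=PATHWAY_COLUMNS))


def simulate_counts(design: SyntheticDesign) -> tuple[ExpressionMatrix, CellAnnotation]:
    """Negative-binomial counts with the planted effects applied to means."""
    rng = np.random.default_rng(design.seed)
    genes = design.genes
    gene_idx = {g: i for i, g in enumerate(genes)}

    base = np.empty(len(genes))
    jitter = rng.lognormal(mean=0.0, sigma=0.3, size=len(genes))
    for g in genes:
        i = gene_idx[g]
        base[i] = (design.filler_mean if g.startswith("FILL") else design.signal_mean)
        base[i] *= jitter[i]

    cells, groups_col, conds_col = [], [], []
    for cond in CONDITIONS:
        for grp in design.groups:
            for j in range(design.n_cells_per_group_per_condition):
                cells.append(f"{cond}_{grp}_c{j:04d}")
                groups_col.append(grp)
                conds_col.append(cond)

    n_cells = len(cells)
    counts = np.zeros((len(genes), n_cells))
    r = design.dispersion
    # per (condition, group) block: same mean vector for all its cells
    start = 0
    for cond in CONDITIONS:
        for grp in design.groups:
            n = design.n_cells_per_group_per_condition
            mu = base.copy()
            for p in design.planted_pathways:
                if cond != p.up_condition:
                    continue
                if grp == p.sender_group:
                    mu[gene_idx[p.ligand]] *= p.effect_size
                if grp == p.receiver_group:
                    for g in (p.receptor, p.em, p.target):
                        mu[gene_idx[g]] *= p.effect_size
            prob = r / (r + mu)
            counts[:, start : start + n] = rng.negative_binomial(
                r, prob[:, None], size=(len(genes), n)
            )
            start += n

    expr = ExpressionMatrix(genes=genes, cells=cells, values=counts, normalized=False)
    ann = CellAnnotation(
        table=pd.DataFrame(
            {"cell_id": cells, "group": groups_col, "condition": conds_col}
        )
    )
    return expr, ann


def simulate_db(design: SyntheticDesign, species: str = "human") -> InteractionDB:
    """Interaction DB containing every planted chain plus the decoy chains."""
    rows = []
    for chain, prov in [(p.genes(), "planted") for p in design.planted_pathways] + [
        (c, "decoy") for c in design.decoy_chains()
    ]:
        lig, rec, em, tgt = chain
        rows.append({"layer": "LR", "source": lig, "target": rec, "provenance": prov, "direct": True})
        rows.append({"layer": "RE", "source": rec, "target": em, "provenance": prov, "direct": False})
        rows.append({"layer": "ET", "source": em, "target": tgt, "provenance": prov, "direct": False})
    return InteractionDB(species=species, records=_dedupe(pd.DataFrame(rows)))


def sender_receiver_maps(
    design: SyntheticDesign, db: InteractionDB
) -> tuple[dict[str, list[str]], dict[str, list[str]]]:
    """Gene lists per group: all DB ligands as sender genes for every group,
    all DB receptor/EM/target genes as receiver genes."""
    senders = sorted(set(db.layer("LR")["source"]))
    receivers = sorted(
        db.endpoint_genes("LR") | db.endpoint_genes("RE") | db.endpoint_genes("ET")
    )
    return (
        {g: senders for g in design.groups},
        {g: receivers for g in design.groups},
    )


def simulate_bulk(
    design: SyntheticDesign,
    counts: ExpressionMatrix,
    ann: CellAnnotation,
    modality: str = "protein",
    feature_genes: list[str] | None = None,
) -> BulkOmicsMatrix:
    """Bulk matrix: per-condition pseudo-bulk gene sums with lognormal noise.

    Each sample of a condition observes the gene-level sum of that
    condition's counts multiplied by a unit-mean lognormal factor with
    coefficient of variation ``bulk_noise_cv``.  Exact zeros (a gene with no
    counts in a condition) are nudged to half a count to keep the matrix
    strictly positive.  Phospho modalities use site-style feature ids
    ("GENE_S1") over the supplied gene subset.
    """
    rng = np.random.default_rng([design.seed, {"protein": 1, "phospho_ST": 2, "phospho_Y": 3}[modality]])
    if feature_genes is None:
        if modality == "protein":
            feature_genes = [g for g in counts.genes if not g.startswith("FILL")]
        else:
            feature_genes = design.planted_genes
    col_of = {c: j for j, c in enumerate(counts.cells)}

    samples, sample_condition = [], {}
    for cond in CONDITIONS:
        for s in range(design.n_bulk_samples_per_condition):
            name = f"{cond}_s{s + 1}"
            samples.append(name)
            sample_condition[name] = cond

    cv = design.bulk_noise_cv
    sigma = float(np.sqrt(np.log1p(cv * cv)))
    values = np.zeros((len(feature_genes), len(samples)))
    for j, sample in enumerate(samples):
        cond = sample_condition[sample]
        cols = [col_of[c] for c in ann.cells_of(condition=cond)]
        sums = np.array(
            [counts.gene_row(g)[cols].sum() if g in counts else 0.0 for g in feature_genes]
        )
        noise = (
            rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=len(feature_genes))
            if cv > 0
            else np.ones(len(feature_genes))
        )
        values[:, j] = sums * noise
    values[values == 0] = 0.5  # keep strictly positive

    features = (
        list(feature_genes)
        if modality == "protein"
        else [f"{g}_S1" for g in feature_genes]
    )
    return BulkOmicsMatrix(
        features=features,
        samples=samples,
        values=values,
        sample_condition=sample_condition,
        modality=modality,
    )


def simulate_kinase_preds(
    design: SyntheticDesign, sik_pathway_indices: list[int] | None = None
) -> list[KinasePrediction]:
    """Kinase-substrate predictions: the EM of designated planted pathways
    predicted to phosphorylate its target (a signaling-involved kinase),
    plus decoy kinases (background genes outside every chain) predicted to
    phosphorylate planted receptors (signaling-related kinases)."""
    if sik_pathway_indices is None:
        sik_pathway_indices = list(range(len(design.planted_pathways)))
    preds = []
    for i in sik_pathway_indices:
        p = design.planted_pathways[i]
        preds.append(KinasePrediction(kinase=p.em, substrate=p.target, site="S1"))
    for kin in design.decoy_kinase_genes():
        for p in design.planted_pathways:
            preds.append(KinasePrediction(kinase=kin, substrate=p.receptor, site="S2"))
    return preds


@dataclass
class SyntheticData:
    """Everything one run of the generator produced."""

    design: SyntheticDesign
    counts: ExpressionMatrix
    annotation: CellAnnotation
    db: InteractionDB
    bulk: dict[str, BulkOmicsMatrix]
    kinase_preds: list[KinasePrediction]


def simulate_all(design: SyntheticDesign, modalities: tuple[str, ...] = ("protein",)) -> SyntheticData:
    """Run every generator with one design."""
    counts, ann = simulate_counts(design)
    db = simulate_db(design)
    bulk = {m: simulate_bulk(design, counts, ann, modality=m) for m in modalities}
    return SyntheticData(
        design=design,
        counts=counts,
        annotation=ann,
        db=db,
        bulk=bulk,
        kinase_preds=simulate_kinase_preds(design),
    )


def write_inputs(data: SyntheticData, outdir: str | Path) -> None:
    """Write every synthetic input in the file formats the CLI consumes."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    counts_df = pd.DataFrame(
        data.counts.values, index=data.counts.genes, columns=data.counts.cells
    )
    counts_df.to_csv(out / "counts.csv")
    data.annotation.table.to_csv(out / "cells.csv", index=False)

    for layer, fname in (("LR", "lr.tsv"), ("RE", "re.tsv"), ("ET", "et.tsv")):
        data.db.layer(layer)[["source", "target", "provenance", "direct"]].to_csv(
            out / fname, sep="\t", index=False
        )

    smap, rmap = sender_receiver_maps(data.design, data.db)
    any_group = data.design.groups[0]
    (out / "senders.txt").write_text("\n".join(smap[any_group]) + "\n")
    (out / "receivers.txt").write_text("\n".join(rmap[any_group]) + "\n")

    for mod, bulk in data.bulk.items():
        pd.DataFrame(bulk.values, index=bulk.features, columns=bulk.samples).to_csv(
            out / f"bulk_{mod}.csv"
        )
        pd.DataFrame(
            {"sample": bulk.samples, "condition": [bulk.sample_condition[s] for s in bulk.samples]}
        ).to_csv(out / f"bulk_{mod}_samples.csv", index=False)

    pd.DataFrame(
        [
            {"kinase": p.kinase, "substrate": p.substrate, "site": p.site or ""}
            for p in data.kinase_preds
        ]
    ).to_csv(out / "kinase_preds.csv", index=False)

    data.design.truth_table().to_csv(out / "truth_pathways.csv")
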
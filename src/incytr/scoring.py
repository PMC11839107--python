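"""Per-pathway statistics: signaling probability, significance, and the
pathway differential score family.

For a pathway L-R-EM-T from sender group *i* to receiver group *j*, the
signaling probability is a product of three Hill factors over the
consecutive expression products,

    P = h(AE_L * AE_R) * h(AE_R * AE_EM) * h(AE_EM * AE_T),
    h(x) = x^N / (x^N + Kh^N),

with half-saturation constant Kh (0.5) and Hill coefficient N (2).
Cross-condition change is quantified by the adjusted log2 fold change

    aFC(x, y) = log2(x/y) * min{2 max(x,y)^2 / (max(x,y)^2 + a^2), 1},

which shrinks fold changes between two values that are both small relative
to the threshold ``a``, and by its logistic transform

    2 / (1 + exp(-k * aFC)) - 1  in (-1, 1).

Statistical significance comes from a permutation test that reshuffles the
group labels of a condition's cells and recomputes the probability;
Benjamini-Hochberg correction is applied across all tested pathways per
condition.  Kinase-substrate predictions contribute the SiK-score (mean
over the six ordered component pairs of kinase-EI times an in-prediction
indicator) and, weighted, the final pathway differential score PDS.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from statsmodels.stats.multitest import multipletests

from .db import KinasePrediction
from .debulk import DebulkedOmics
from .expression import (
    CellAnnotation,
    ExpressionMatrix,
    GroupExpression,
    _trimean_rows,
    group_average_expression,
)
from .pathways import PathwayTable

logger = logging.getLogger(__name__)

#: fixed order of the six candidate kinase->substrate role pairs
SIK_PAIR_ROLES: tuple[tuple[str, str], ...] = (
    ("receptor", "em"),
    ("receptor", "target"),
    ("em", "target"),
    ("em", "receptor"),
    ("target", "receptor"),
    ("target", "em"),
)

SCORE_COLUMNS = [
    "sender_group", "receiver_group", "ligand", "receptor", "em", "target",
    "P_cond1", "P_cond2", "pval_cond1", "pval_cond2", "padj_cond1", "padj_cond2",
    "afc_P", "T_PDS", "P_PDS", "Ph_PDS_pS", "Ph_PDS_pY", "DS_multimodal",
    "SiK_cond1", "SiK_cond2", "K_PDS", "PDS", "modality_coverage",
    "significant_cond1", "significant_cond2", "srk_top",
    "naive_fc_L", "naive_fc_R", "naive_fc_EM", "naive_fc_T",
]


@dataclass
class ScoringConfig:
    """All tunable constants of the scoring pipeline.

    Attributes
    ----------
    kh : Hill half-saturation constant (0.5). Rescaling Kh changes absolute
        probabilities but not their ordering across pathways.
    hill_n : Hill coefficient (2).
    k : logistic sensitivity of the differential scores (2); changes the
        scale but not the ranking of the scores.
    a : smallness threshold for the adjusted fold change.  ``None`` (the
        default) computes it per comparison context as the 75th percentile
        of the pooled positive values being compared.
    alpha : fold-change threshold of the exclusiveness index (10).
    m_permutations : permutation count M for the significance test (100).
    w1, w2, w3 : weights of the proteomics / phospho-S|T / phospho-Y
        differential scores in the multi-modal score (0.5 each).
    w4 : weight of the kinase score in the final PDS (0.5).
    fdr : BH-adjusted significance cutoff (0.05).
    seed : RNG seed governing the permutations.
    pds_literal : if True, the kinase term is always added with a plus sign;
        by default it is multiplied by sign(DS) so kinase evidence
        reinforces whichever condition dominates.
    pseudo_count_factor : zeros entering a fold change are replaced by the
        smallest positive value observed for that quantity times this factor.
    conditions : optional explicit (condition1, condition2) ordering;
        defaults to sorted label order.
    """

    kh: float = 0.5
    hill_n: float = 2.0
    k: float = 2.0
    a: float | None = None
    alpha: float = 10.0
    m_permutations: int = 100
    w1: float = 0.5
    w2: float = 0.5
    w3: float = 0.5
    w4: float = 0.5
    fdr: float = 0.05
    seed: int = 0
    pds_literal: bool = False
    pseudo_count_factor: float = 1e-3
    quantile_method: str = "linear"
    conditions: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        if self.kh <= 0 or self.hill_n <= 0 or self.k <= 0:
            raise ValueError("kh, hill_n and k must be positive")
        if self.a is not None and self.a < 0:
            raise ValueError("a must be nonnegative")
        if self.alpha <= 1:
            raise ValueError("alpha must exceed 1")
        if self.m_permutations < 1:
            raise ValueError("at least one permutation is required")
        if min(self.w1, self.w2, self.w3, self.w4) < 0:
            raise ValueError("weights must be nonnegative")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScoringConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "conditions" in data and data["conditions"] is not None:
            data["conditions"] = tuple(data["conditions"])
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# elementary scores


def hill_probability(
    ae_ligand: float, ae_receptor: float, ae_em: float, ae_target: float,
    cfg: ScoringConfig | None = None,
) -> float:
    """Signaling probability: product of three Hill factors in [0, 1)."""
    cfg = cfg or ScoringConfig()
    products = np.array(
        [ae_ligand * ae_receptor, ae_receptor * ae_em, ae_em * ae_target]
    )
    if (products < 0).any():
        raise ValueError("average expression levels must be nonnegative")
    return float(np.prod(_hill_factor(products, cfg)))


def _hill_factor(x: np.ndarray, cfg: ScoringConfig) -> np.ndarray:
    xn = np.asarray(x, dtype=float) ** cfg.hill_n
    return xn / (xn + cfg.kh ** cfg.hill_n)


def afc(x: float, y: float, a: float) -> float:
    """Adjusted log2 fold change of two positive values.

    The shrink factor min{2 max^2 / (max^2 + a^2), 1} saturates at 1 as soon
    as max(x, y) >= a, leaving ordinary fold changes untouched.
    """
    if x <= 0 or y <= 0:
        raise ValueError(
            "afc requires positive inputs; apply the pseudo-count policy "
            "(replace zeros by the smallest positive observed value times "
            "pseudo_count_factor) before calling"
        )
    top = max(x, y) ** 2
    factor = min(2.0 * top / (top + a * a), 1.0)
    return math.log2(x / y) * factor


def pds_transform(afc_value: float, k: float = 2.0) -> float:
    """Odd, strictly increasing logistic map of an aFC onto (-1, 1)."""
    return 2.0 / (1.0 + math.exp(-k * afc_value)) - 1.0


def adjust_bh(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving).

    NaN entries (untestable pathways) pass through unchanged.
    """
    arr = np.asarray(pvals, dtype=float)
    out = np.full(arr.shape, np.nan)
    mask = ~np.isnan(arr)
    if mask.any():
        out[mask] = multipletests(arr[mask], method="fdr_bh")[1]
    return out


def exclusiveness_index(
    ae_by_group: Mapping[str, float], focal_group: str, alpha: float = 10.0
) -> float:
    """Exclusiveness index of a gene in one group, in [0, 1].

    0 when expression is flat across groups; 1 when the focal group exceeds
    alpha times the second-highest group; otherwise a min-max rescaling of
    the focal AE, capped at 0.99.
    """
    if focal_group not in ae_by_group:
        raise KeyError(f"group {focal_group!r} not in AE map")
    vals = np.array(list(ae_by_group.values()), dtype=float)
    hi, lo = vals.max(), vals.min()
    if hi == lo:
        return 0.0
    focal = ae_by_group[focal_group]
    second = np.sort(vals)[-2]  # second order statistic; ties with max allowed
    if focal > alpha * second:
        return 1.0
    return 0.99 * (focal - lo) / (hi - lo)


# ---------------------------------------------------------------------------
# permutation significance


def _condition_submatrix(
    expr: ExpressionMatrix, ann: CellAnnotation, genes: Sequence[str], condition: str
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Values (genes x condition cells, zero rows for absent genes), the
    cells' group labels, and the sorted group list of the condition."""
    cond_cells = ann.table[ann.table["condition"] == condition]
    col_of = {c: j for j, c in enumerate(expr.cells)}
    cols, labels = [], []
    for cid, grp in zip(cond_cells["cell_id"], cond_cells["group"]):
        if cid in col_of:
            cols.append(col_of[cid])
            labels.append(grp)
    mat = np.zeros((len(genes), len(cols)))
    for i, g in enumerate(genes):
        if g in expr:
            mat[i] = expr.gene_row(g)[cols]
    return mat, np.asarray(labels, dtype=object), sorted(set(labels))


def _group_ae(
    mat: np.ndarray, labels: np.ndarray, groups: Sequence[str], method: str
) -> np.ndarray:
    """AE per gene per group: shape (n_groups, n_genes)."""
    out = np.zeros((len(groups), mat.shape[0]))
    for k, g in enumerate(groups):
        cols = labels == g
        if cols.any():
            out[k] = _trimean_rows(mat[:, cols], method=method)
    return out


def _pathway_probs(
    ae: np.ndarray,
    gene_idx: Mapping[str, int],
    group_idx: Mapping[str, int],
    paths: pd.DataFrame,
    cfg: ScoringConfig,
) -> np.ndarray:
    """Hill probability per pathway from an AE array (..., group, gene)."""
    gi = lambda col: np.array([gene_idx[g] for g in paths[col]])
    sg = np.array([group_idx.get(g, -1) for g in paths["sender_group"]])
    rg = np.array([group_idx.get(g, -1) for g in paths["receiver_group"]])
    valid = (sg >= 0) & (rg >= 0)
    l_i, r_i, e_i, t_i = gi("ligand"), gi("receptor"), gi("em"), gi("target")
    ael = np.where(valid, ae[..., np.clip(sg, 0, None), l_i], 0.0)
    aer = np.where(valid, ae[..., np.clip(rg, 0, None), r_i], 0.0)
    aee = np.where(valid, ae[..., np.clip(rg, 0, None), e_i], 0.0)
    aet = np.where(valid, ae[..., np.clip(rg, 0, None), t_i], 0.0)
    return (
        _hill_factor(ael * aer, cfg)
        * _hill_factor(aer * aee, cfg)
        * _hill_factor(aee * aet, cfg)
    )


def permutation_test(
    expr: ExpressionMatrix,
    ann: CellAnnotation,
    pathway_table: PathwayTable,
    condition: str,
    cfg: ScoringConfig,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Permutation p-values of all pathways in one condition.

    Group labels of the condition's cells are permuted M times; one shared
    permutation set serves every pathway (the marginal null distribution is
    identical and the cost drops by the pathway count).  The p-value is the
    fraction of permuted probabilities strictly greater than the observed
    one, exactly #{m : P(m) > P_obs} / M — without the (M+1) correction, so
    p = 0 is attainable.

    Returns (observed probabilities, p-values, permuted probability matrix
    of shape (M, n_pathways)).  With fewer than two groups in the condition
    the p-values are NaN.
    """
    paths = pathway_table.table
    genes = sorted(pathway_table.genes())
    gene_idx = {g: i for i, g in enumerate(genes)}
    mat, labels, groups = _condition_submatrix(expr, ann, genes, condition)
    group_idx = {g: i for i, g in enumerate(groups)}

    ae_obs = _group_ae(mat, labels, groups, cfg.quantile_method)
    p_obs = _pathway_probs(ae_obs, gene_idx, group_idx, paths, cfg)

    if len(groups) < 2:
        logger.warning("condition %r has fewer than two groups; p undefined", condition)
        nan = np.full(len(paths), np.nan)
        return p_obs, nan, np.zeros((0, len(paths)))

    rng = rng or np.random.default_rng(cfg.seed)
    m = cfg.m_permutations
    p_perm = np.zeros((m, len(paths)))
    for it in range(m):
        perm_labels = rng.permutation(labels)
        ae = _group_ae(mat, perm_labels, groups, cfg.quantile_method)
        p_perm[it] = _pathway_probs(ae, gene_idx, group_idx, paths, cfg)
    pvals = (p_perm > p_obs[None, :]).mean(axis=0)
    return p_obs, pvals, p_perm


def permutation_pvalue(
    expr: ExpressionMatrix,
    ann: CellAnnotation,
    pathway: Mapping[str, str],
    condition: str,
    cfg: ScoringConfig,
) -> tuple[float, list[float]]:
    """Permutation p-value of a single pathway (mapping with the six
    pathway fields); returns (p, permuted probabilities)."""
    pt = PathwayTable(table=pd.DataFrame([pathway]))
    _, pvals, p_perm = permutation_test(expr, ann, pt, condition, cfg)
    return float(pvals[0]), [float(v) for v in p_perm[:, 0]]


# ---------------------------------------------------------------------------
# fold-change helpers


def smallness_threshold(values: Iterable[float], cfg: ScoringConfig) -> float:
    """The aFC threshold ``a``: the configured constant, or the 75th
    percentile of the pooled positive values being compared."""
    if cfg.a is not None:
        return cfg.a
    pos = np.asarray([v for v in values if v > 0], dtype=float)
    return float(np.percentile(pos, 75)) if pos.size else 0.0


def apply_pseudo_count(values: np.ndarray, cfg: ScoringConfig) -> np.ndarray:
    """Replace zeros by the smallest positive observed value times
    ``pseudo_count_factor`` so fold changes stay defined."""
    vals = np.asarray(values, dtype=float).copy()
    pos = vals[vals > 0]
    if pos.size == 0:
        return vals
    vals[vals == 0] = pos.min() * cfg.pseudo_count_factor
    return vals


def t_pds(p1: float, p2: float, a: float, cfg: ScoringConfig) -> float:
    """Transcriptomics pathway differential score of one pathway."""
    if p1 == 0 and p2 == 0:
        return 0.0
    return pds_transform(afc(p1, p2, a), cfg.k)


def modality_pds(
    debulked: DebulkedOmics,
    pathway: Mapping[str, str],
    cond1: str,
    cond2: str,
    a: float,
    cfg: ScoringConfig,
) -> tuple[float, int]:
    """Proteomics/phospho differential score of one pathway.

    Averages the logistic-transformed aFC of the four components; the
    ligand level is read in the sender group, receptor/EM/target in the
    receiver group.  A component missing from the modality in either
    condition contributes 0; the count of measured components (of 4) is
    returned alongside.
    """
    comps = [
        (pathway["ligand"], pathway["sender_group"]),
        (pathway["receptor"], pathway["receiver_group"]),
        (pathway["em"], pathway["receiver_group"]),
        (pathway["target"], pathway["receiver_group"]),
    ]
    total, measured = 0.0, 0
    for gene, group in comps:
        v1 = debulked.level(gene, group, cond1, default=0.0)
        v2 = debulked.level(gene, group, cond2, default=0.0)
        if v1 <= 0 or v2 <= 0:
            continue
        measured += 1
        total += pds_transform(afc(v1, v2, a), cfg.k)
    if measured == 0:
        logger.debug("pathway %s: no components measured in %s", pathway, debulked.modality)
    return total / 4.0, measured


def ds_multimodal(
    t: float,
    p: float | None,
    ph_s: float | None,
    ph_y: float | None,
    cfg: ScoringConfig,
) -> float:
    """Multi-modal differential score; absent modalities (None) drop out."""
    ds = t
    for score, w in ((p, cfg.w1), (ph_s, cfg.w2), (ph_y, cfg.w3)):
        if score is not None:
            ds += w * score
    return ds


def k_pds(ds: float, sik1: float, sik2: float) -> float:
    """Kinase differential score: the SiK-score of the dominant condition."""
    if ds > 0:
        return sik1
    if ds < 0:
        return sik2
    return 0.5 * (sik1 + sik2)


def pds(ds: float, k_pds_value: float, cfg: ScoringConfig) -> float:
    """Final pathway differential score.

    By default the kinase term carries the sign of the multi-modal score
    (sign(0) = +1), so kinase evidence pushes the score further in the
    dominant condition's direction; ``pds_literal`` always adds it.
    """
    if cfg.pds_literal:
        return ds + cfg.w4 * k_pds_value
    sign = -1.0 if ds < 0 else 1.0
    return ds + cfg.w4 * k_pds_value * sign


# ---------------------------------------------------------------------------
# kinase analysis


def sik_score(pairs: Sequence[tuple[int, float]]) -> float:
    """Mean over the six ordered role pairs of (indicator x kinase EI)."""
    if len(pairs) != 6:
        raise ValueError("expected exactly six kinase-substrate role pairs")
    return sum(chi * ei for chi, ei in pairs) / 6.0


def identify_kinases(
    pathway: Mapping[str, str],
    pred_pairs: frozenset[tuple[str, str]],
    pred_by_substrate: Mapping[str, set[str]],
    ei_of: Mapping[str, Mapping[str, float]],
) -> tuple[dict[str, list[tuple[int, float]]], str]:
    """Signaling-involved and signaling-related kinases of one pathway.

    For each condition, the six ordered role pairs (R->EM, R->T, EM->T,
    EM->R, T->R, T->EM) get an indicator chi = 1 iff the (kinase gene,
    substrate gene) pair is predicted, paired with the kinase gene's EI in
    the receiver group.  Predicted kinases of any component that are not
    themselves pathway components are signaling-related kinases (SrKs); the
    one with the highest EI per component is annotated (and excluded from
    scoring).

    ``ei_of`` maps condition -> gene -> EI in the receiver group.  Returns
    ({condition: six (chi, ei) pairs}, srk annotation string).
    """
    comp_gene = {r: pathway[r] for r in ("receptor", "em", "target")}
    members = {pathway[r] for r in ("ligand", "receptor", "em", "target")}

    pairs_by_cond: dict[str, list[tuple[int, float]]] = {}
    for cond, ei_map in ei_of.items():
        pairs = []
        for kin_role, sub_role in SIK_PAIR_ROLES:
            kin_gene = comp_gene[kin_role]
            chi = int((kin_gene, comp_gene[sub_role]) in pred_pairs)
            pairs.append((chi, ei_map.get(kin_gene, 0.0)))
        pairs_by_cond[cond] = pairs

    srk_parts = []
    for role in ("receptor", "em", "target"):
        cands = pred_by_substrate.get(comp_gene[role], set()) - members
        if not cands:
            continue
        best, best_ei = None, -1.0
        for kin in sorted(cands):
            ei = max(ei_map.get(kin, 0.0) for ei_map in ei_of.values()) if ei_of else 0.0
            if ei > best_ei:
                best, best_ei = kin, ei
        srk_parts.append(f"{role}:{best}({best_ei:.3f})")
    return pairs_by_cond, ";".join(srk_parts)


# ---------------------------------------------------------------------------
# orchestration


def score_all(
    pathway_table: PathwayTable,
    expr: ExpressionMatrix,
    ann: CellAnnotation,
    cfg: ScoringConfig,
    raw_counts: ExpressionMatrix | None = None,
    debulked: Mapping[str, DebulkedOmics] | None = None,
    preds: Sequence[KinasePrediction] | None = None,
) -> pd.DataFrame:
    """Score every pathway and assemble the full result table.

    Requires exactly two conditions in the annotation.  Per-record failures
    (untestable permutation, missing modality components) surface as NaN /
    zero-contribution flags rather than aborting the batch.  The run is
    deterministic given (inputs, config, seed).
    """
    conditions = ann.conditions
    if cfg.conditions is not None:
        cond1, cond2 = cfg.conditions
        if set((cond1, cond2)) != set(conditions):
            raise ValueError("configured conditions do not match the annotation")
    else:
        if len(conditions) != 2:
            raise ValueError(
                f"differential scoring requires exactly 2 conditions, got {conditions}"
            )
        cond1, cond2 = conditions

    paths = pathway_table.table
    if paths.empty:
        return pd.DataFrame(columns=SCORE_COLUMNS)

    debulked = debulked or {}
    preds = list(preds or [])

    # --- signaling probabilities + permutation significance, per condition
    p_obs: dict[str, np.ndarray] = {}
    pvals: dict[str, np.ndarray] = {}
    padj: dict[str, np.ndarray] = {}
    for ci, cond in enumerate((cond1, cond2)):
        rng = np.random.default_rng([cfg.seed, ci])
        obs, pv, _ = permutation_test(expr, ann, pathway_table, cond, cfg, rng=rng)
        p_obs[cond], pvals[cond] = obs, pv
        padj[cond] = adjust_bh(pv)

    # --- transcriptomic differential score
    pooled = np.concatenate([p_obs[cond1], p_obs[cond2]])
    a_t = smallness_threshold(pooled, cfg)
    p1_adj = apply_pseudo_count(p_obs[cond1], cfg)
    p2_adj = apply_pseudo_count(p_obs[cond2], cfg)
    afc_p = np.zeros(len(paths))
    t_scores = np.zeros(len(paths))
    for i in range(len(paths)):
        if p1_adj[i] > 0 and p2_adj[i] > 0:
            afc_p[i] = afc(p1_adj[i], p2_adj[i], a_t)
            t_scores[i] = pds_transform(afc_p[i], cfg.k)

    # --- modality differential scores
    mod_scores: dict[str, np.ndarray] = {}
    mod_measured: dict[str, np.ndarray] = {}
    pathway_genes = pathway_table.genes()
    for mod, deb in debulked.items():
        lv = deb.levels.loc[deb.levels["gene"].isin(pathway_genes), "level"]
        a_mod = smallness_threshold(lv, cfg)
        scores = np.zeros(len(paths))
        measured = np.zeros(len(paths), dtype=int)
        for i, row in enumerate(paths.to_dict("records")):
            scores[i], measured[i] = modality_pds(deb, row, cond1, cond2, a_mod, cfg)
        mod_scores[mod] = scores
        mod_measured[mod] = measured

    # --- kinase analysis
    pred_pairs = frozenset((p.kinase, p.substrate) for p in preds)
    pred_by_substrate: dict[str, set[str]] = {}
    for p in preds:
        pred_by_substrate.setdefault(p.substrate, set()).add(p.kinase)

    kinase_genes = sorted({p.kinase for p in preds} & set(expr.genes))
    ei_genes = sorted(pathway_table.genes() | set(kinase_genes))
    ge = group_average_expression(expr, ann, genes=ei_genes, method=cfg.quantile_method)
    # EI per (condition, receiver group, gene), computed lazily per group
    ei_cache: dict[tuple[str, str], dict[str, float]] = {}

    def _ei_map(cond: str, group: str) -> dict[str, float]:
        key = (cond, group)
        if key not in ei_cache:
            out = {}
            for g in ei_genes:
                by_group = ge.ae_by_group(g, cond)
                out[g] = (
                    exclusiveness_index(by_group, group, cfg.alpha)
                    if group in by_group
                    else 0.0
                )
            ei_cache[key] = out
        return ei_cache[key]

    # --- naive pseudo-bulk fold change annotation
    naive_fc: dict[str, float] = {}
    if raw_counts is not None:
        col_of = {c: j for j, c in enumerate(raw_counts.cells)}
        cells1 = [col_of[c] for c in ann.cells_of(condition=cond1) if c in col_of]
        cells2 = [col_of[c] for c in ann.cells_of(condition=cond2) if c in col_of]
        for g in pathway_table.genes():
            if g in raw_counts:
                row = raw_counts.gene_row(g)
                m1 = row[cells1].mean() if cells1 else 0.0
                m2 = row[cells2].mean() if cells2 else 0.0
                naive_fc[g] = math.log2((m1 + 1.0) / (m2 + 1.0))

    # --- assemble
    records = []
    for i, row in enumerate(paths.to_dict("records")):
        ei_of = {
            cond1: _ei_map(cond1, row["receiver_group"]),
            cond2: _ei_map(cond2, row["receiver_group"]),
        }
        pairs_by_cond, srk_top = identify_kinases(
            row, pred_pairs, pred_by_substrate, ei_of
        )
        sik1 = sik_score(pairs_by_cond[cond1])
        sik2 = sik_score(pairs_by_cond[cond2])

        p_score = mod_scores.get("protein")
        ph_s = mod_scores.get("phospho_ST")
        ph_y = mod_scores.get("phospho_Y")
        ds = ds_multimodal(
            t_scores[i],
            p_score[i] if p_score is not None else None,
            ph_s[i] if ph_s is not None else None,
            ph_y[i] if ph_y is not None else None,
            cfg,
        )
        kp = k_pds(ds, sik1, sik2)
        coverage = ";".join(
            f"{mod}:{mod_measured[mod][i]}/4" for mod in sorted(mod_scores)
        )
        records.append(
            {
                **{c: row[c] for c in paths.columns},
                "P_cond1": p_obs[cond1][i],
                "P_cond2": p_obs[cond2][i],
                "pval_cond1": pvals[cond1][i],
                "pval_cond2": pvals[cond2][i],
                "padj_cond1": padj[cond1][i],
                "padj_cond2": padj[cond2][i],
                "afc_P": afc_p[i],
                "T_PDS": t_scores[i],
                "P_PDS": p_score[i] if p_score is not None else np.nan,
                "Ph_PDS_pS": ph_s[i] if ph_s is not None else np.nan,
                "Ph_PDS_pY": ph_y[i] if ph_y is not None else np.nan,
                "DS_multimodal": ds,
                "SiK_cond1": sik1,
                "SiK_cond2": sik2,
                "K_PDS": kp,
                "PDS": pds(ds, kp, cfg),
                "modality_coverage": coverage,
                "significant_cond1": bool(padj[cond1][i] < cfg.fdr)
                if not np.isnan(padj[cond1][i])
                else False,
                "significant_cond2": bool(padj[cond2][i] < cfg.fdr)
                if not np.isnan(padj[cond2][i])
                else False,
                "srk_top": srk_top,
                "naive_fc_L": naive_fc.get(row["ligand"], np.nan),
                "naive_fc_R": naive_fc.get(row["receptor"], np.nan),
                "naive_fc_EM": naive_fc.get(row["em"], np.nan),
                "naive_fc_T": naive_fc.get(row["target"], np.nan),
            }
        )
    return pd.DataFrame.from_records(records, columns=SCORE_COLUMNS)
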
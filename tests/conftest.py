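import numpy as np
import pandas as pd
import pytest

from incytr import (
    CellAnnotation,
    ExpressionMatrix,
    InteractionDB,
    SyntheticDesign,
    normalize_counts,
    simulate_all,
)


def make_db(edges, species="human"):
    """Build an InteractionDB from (layer, source, target) triples."""
    rows = [
        {
            "layer": lay,
            "source": s,
            "target": t,
            "provenance": "test",
            "direct": lay == "LR",
        }
        for lay, s, t in edges
    ]
    cols = ["layer", "source", "target", "provenance", "direct"]
    return InteractionDB(species=species, records=pd.DataFrame(rows, columns=cols))


@pytest.fixture
def chain_db():
    """One complete L1-R1-E1-T1 chain."""
    return make_db([("LR", "L1", "R1"), ("RE", "R1", "E1"), ("ET", "E1", "T1")])


def random_db(rng, n_per_layer=8, pool_size=10):
    """A random DB over a small shared gene pool (chains arise by chance)."""
    pool = [f"G{i}" for i in range(pool_size)]
    edges = set()
    for lay in ("LR", "RE", "ET"):
        while sum(1 for e in edges if e[0] == lay) < n_per_layer:
            s, t = rng.choice(pool, size=2, replace=True)
            edges.add((lay, str(s), str(t)))
    return make_db(sorted(edges)), pool


def brute_force_pathways(db, senders, receivers, sender_group, receiver_group):
    """Independent oracle: scan every (L, R, EM, T) tuple over the gene
    universe and apply each admissibility constraint directly."""
    lr, re_, et = db.edge_set("LR"), db.edge_set("RE"), db.edge_set("ET")
    genes = {g for pair in lr | re_ | et for g in pair}
    out = set()
    for lig in genes:
        for rec in genes:
            for em in genes:
                for tgt in genes:
                    if lig not in senders:
                        continue
                    if not {rec, em, tgt} <= set(receivers):
                        continue
                    if (lig, rec) not in lr or (rec, em) not in re_ or (em, tgt) not in et:
                        continue
                    if rec == em or rec == tgt or em == tgt:
                        continue
                    out.add((sender_group, receiver_group, lig, rec, em, tgt))
    return out


def small_design(**overrides):
    """A fast variant of the default synthetic study for unit tests."""
    params = dict(n_cells_per_group_per_condition=80, seed=7)
    params.update(overrides)
    return SyntheticDesign(**params)


@pytest.fixture(scope="session")
def small_synth():
    design = SyntheticDesign(n_cells_per_group_per_condition=80, seed=7)
    return simulate_all(design, modalities=("protein", "phospho_ST"))


@pytest.fixture(scope="session")
def small_normalized(small_synth):
    return normalize_counts(small_synth.counts)


def tiny_expression(values, groups, conditions):
    """Matrix with one gene per row of ``values`` and one cell per column."""
    values = np.asarray(values, dtype=float)
    n_genes, n_cells = values.shape
    genes = [f"g{i}" for i in range(n_genes)]
    cells = [f"c{j}" for j in range(n_cells)]
    expr = ExpressionMatrix(genes=genes, cells=cells, values=values, normalized=True)
    ann = CellAnnotation(
        table=pd.DataFrame(
            {"cell_id": cells, "group": groups, "condition": conditions}
        )
    )
    return expr, ann
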
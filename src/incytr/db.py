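"""Three-layer interaction database (ligand-receptor, receptor-EM, EM-target).

The database is the substrate for four-step pathway enumeration: a directed
edge set split into three layers, ``LR`` (ligand to receptor), ``RE``
(receptor to effector molecule) and ``ET`` (effector molecule to target).
LR edges must represent direct physical interactions; RE and ET edges may
also encode indirect associations (e.g. co-expression within a pathway).

Databases from several sources can be merged, filtered to genes of interest,
and augmented with externally predicted kinase-substrate relations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

LAYERS = ("LR", "RE", "ET")

#: canonical record columns, in storage order
_COLUMNS = ["layer", "source", "target", "provenance", "direct"]


class FormatError(ValueError):
    """An input table does not conform to the expected schema."""


def canonical_symbol(symbol: str, species: str) -> str:
    """Normalize a gene symbol to the species' casing convention.

    Human symbols are upper-cased (HGNC style); mouse symbols keep only the
    first letter capitalized (MGI style).
    """
    s = str(symbol).strip()
    if species == "human":
        return s.upper()
    if species == "mouse":
        return s[:1].upper() + s[1:].lower()
    raise ValueError(f"unknown species {species!r}; expected 'human' or 'mouse'")


@dataclass
class KinasePrediction:
    """One predicted kinase -> substrate phosphorylation relation."""

    kinase: str
    substrate: str
    site: str | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if not self.kinase or not self.substrate:
            raise ValueError("kinase and substrate symbols must be non-empty")


@dataclass
class InteractionDB:
    """A deduplicated set of directed interactions in three layers.

    ``records`` is a DataFrame with columns layer, source, target,
    provenance, direct; one row per unique (layer, source, target) triple.
    """

    species: str = "human"
    records: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=_COLUMNS)
    )

    def __post_init__(self) -> None:
        df = self.records
        missing = [c for c in _COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"records missing columns: {missing}")
        bad = set(df["layer"]) - set(LAYERS)
        if bad:
            raise FormatError(f"unknown layers: {sorted(bad)}")
        if ((df["source"] == "") | (df["target"] == "")).any():
            raise ValueError("empty gene symbols are not allowed")
        if not df.loc[df["layer"] == "LR", "direct"].astype(bool).all():
            raise ValueError("every LR record must be a direct interaction")
        if df.duplicated(subset=["layer", "source", "target"]).any():
            raise ValueError("duplicate (layer, source, target) triples")
        self.records = df[_COLUMNS].reset_index(drop=True)

    def layer(self, name: str) -> pd.DataFrame:
        """Return the records of one layer."""
        if name not in LAYERS:
            raise ValueError(f"unknown layer {name!r}")
        return self.records[self.records["layer"] == name]

    def edge_set(self, name: str) -> set[tuple[str, str]]:
        sub = self.layer(name)
        return set(zip(sub["source"], sub["target"]))

    def endpoint_genes(self, name: str) -> set[str]:
        """Genes occurring as the *target* endpoint of a layer.

        Targets of LR are receptors, of RE effector molecules, of ET targets.
        """
        return set(self.layer(name)["target"])

    def __len__(self) -> int:
        return len(self.records)

    def counts(self) -> dict[str, int]:
        return {lay: int((self.records["layer"] == lay).sum()) for lay in LAYERS}


def _dedupe(df: pd.DataFrame) -> pd.DataFrame:
    """Collapse duplicate triples: provenance tags concatenated, direct OR-ed."""
    if df.empty:
        return df[_COLUMNS]

    def _collapse(group: pd.DataFrame) -> pd.Series:
        tags: list[str] = []
        for tag in group["provenance"]:
            for part in str(tag).split(";"):
                if part and part not in tags:
                    tags.append(part)
        return pd.Series(
            {"provenance": ";".join(tags), "direct": bool(group["direct"].any())}
        )

    out = (
        df.groupby(["layer", "source", "target"], sort=False)
        .apply(_collapse, include_groups=False)
        .reset_index()
    )
    return out[_COLUMNS]


def load_interaction_tables(
    lr_path: str | Path,
    re_path: str | Path,
    et_path: str | Path,
    species: str = "human",
    sep: str = "\t",
) -> InteractionDB:
    """Parse one table per layer into an :class:`InteractionDB`.

    Each file needs at least ``source`` and ``target`` columns; optional
    ``provenance`` (defaults to the file name) and ``direct`` (defaults to
    true for the LR layer, false for RE/ET, which may hold indirect
    associations).
    """
    frames = []
    for layer, path in (("LR", lr_path), ("RE", re_path), ("ET", et_path)):
        path = Path(path)
        df = pd.read_csv(path, sep=sep, dtype=str)
        for col in ("source", "target"):
            if col not in df.columns:
                raise FormatError(f"{path.name}: missing required column {col!r}")
        if df.empty:
            logger.warning("%s: empty %s table", path.name, layer)
        df = df.copy()
        df["layer"] = layer
        if "provenance" not in df.columns:
            df["provenance"] = path.name
        else:
            df["provenance"] = df["provenance"].fillna(path.name)
        if "direct" not in df.columns:
            df["direct"] = layer == "LR"
        else:
            df["direct"] = (
                df["direct"].astype(str).str.lower().isin(("true", "1", "yes"))
            )
        if layer == "LR":
            df["direct"] = True  # LR interactions are direct by definition
        for col in ("source", "target"):
            df[col] = [canonical_symbol(s, species) for s in df[col]]
        frames.append(df[_COLUMNS])
    records = _dedupe(pd.concat(frames, ignore_index=True))
    db = InteractionDB(species=species, records=records)
    logger.info("loaded interaction DB: %s", db.counts())
    return db


def merge_dbs(dbs: Sequence[InteractionDB]) -> InteractionDB:
    """Union of several databases of the same species.

    When the same (layer, source, target) triple occurs in several inputs,
    provenance tags are concatenated and ``direct=True`` wins.
    """
    if not dbs:
        return InteractionDB()
    species = {db.species for db in dbs}
    if len(species) > 1:
        raise ValueError(f"cannot merge DBs of different species: {sorted(species)}")
    combined = pd.concat([db.records for db in dbs], ignore_index=True)
    return InteractionDB(species=dbs[0].species, records=_dedupe(combined))


def append_kinase_predictions(
    db: InteractionDB,
    preds: Iterable[KinasePrediction],
    em_rule_literal: bool = False,
) -> tuple[InteractionDB, int]:
    """Augment a database with predicted kinase-substrate edges.

    Role membership (receptor / effector molecule / target) of each substrate
    is decided against the *unmodified* snapshot ``db``; a substrate holding
    several roles triggers every matching rule.  For a prediction K -> S:

    * S is a receptor: add RE edge S -> K (the receptor phosphorylated by K
      can relay to it as an effector);
    * S is an effector molecule: add RE edge K -> S and ET edge S -> K;
    * S is a target: add ET edge K -> S.

    With ``em_rule_literal=True`` the fourth rule is instead read as a second
    effector-molecule rule (EM-role substrates additionally gain ET edge
    K -> S) and target-role substrates trigger nothing.

    Predictions whose substrate occurs in no role are skipped and counted.
    Returns the augmented DB and the skip count.
    """
    receptors = db.endpoint_genes("LR")
    ems = db.endpoint_genes("RE")
    targets = db.endpoint_genes("ET")

    new_rows: list[dict] = []

    def _add(layer: str, source: str, target: str) -> None:
        new_rows.append(
            {
                "layer": layer,
                "source": source,
                "target": target,
                "provenance": "kinase_prediction",
                "direct": True,
            }
        )

    skipped = 0
    for p in preds:
        kin = canonical_symbol(p.kinase, db.species)
        sub = canonical_symbol(p.substrate, db.species)
        hit = False
        if sub in receptors:
            _add("RE", sub, kin)
            hit = True
        if sub in ems:
            _add("RE", kin, sub)
            _add("ET", sub, kin)
            if em_rule_literal:
                _add("ET", kin, sub)
            hit = True
        if sub in targets and not em_rule_literal:
            _add("ET", kin, sub)
            hit = True
        if not hit:
            skipped += 1
    if skipped:
        logger.info("kinase predictions skipped (substrate not in DB): %d", skipped)
    if not new_rows:
        return db, skipped
    combined = pd.concat(
        [db.records, pd.DataFrame(new_rows)], ignore_index=True
    )
    return InteractionDB(species=db.species, records=_dedupe(combined)), skipped


def filter_db(
    db: InteractionDB,
    ligands: Iterable[str] | None = None,
    receptors: Iterable[str] | None = None,
    ems: Iterable[str] | None = None,
    targets: Iterable[str] | None = None,
) -> InteractionDB:
    """Restrict the database to interactions touching the supplied genes.

    Each argument constrains one pathway role; ``None`` means unconstrained.
    An *empty* list is honoured (emptying the corresponding layer) with a
    warning.
    """
    df = db.records
    keep = pd.Series(True, index=df.index)

    def _role(layer: str, endpoint: str, genes: Iterable[str] | None) -> None:
        nonlocal keep
        if genes is None:
            return
        genes = {canonical_symbol(g, db.species) for g in genes}
        if not genes:
            logger.warning("empty %s filter removes the whole %s layer", endpoint, layer)
        mask = (df["layer"] != layer) | df[endpoint].isin(genes)
        keep &= mask

    _role("LR", "source", ligands)
    _role("LR", "target", receptors)
    _role("RE", "source", receptors)
    _role("RE", "target", ems)
    _role("ET", "source", ems)
    _role("ET", "target", targets)
    return InteractionDB(species=db.species, records=df[keep].reset_index(drop=True))


def load_kinase_predictions(
    path: str | Path, species: str = "human"
) -> list[KinasePrediction]:
    """Read a kinase-substrate prediction table (CSV: kinase, substrate[, site, score])."""
    df = pd.read_csv(path)
    for col in ("kinase", "substrate"):
        if col not in df.columns:
            raise FormatError(f"{Path(path).name}: missing required column {col!r}")
    preds = []
    for row in df.itertuples(index=False):
        preds.append(
            KinasePrediction(
                kinase=canonical_symbol(row.kinase, species),
                substrate=canonical_symbol(row.substrate, species),
                site=str(getattr(row, "site")) if hasattr(row, "site") else None,
                score=float(getattr(row, "score")) if hasattr(row, "score") else None,
            )
        )
    return preds


def write_db(db: InteractionDB, path: str | Path) -> None:
    """Write the combined database as a single TSV with the layer column."""
    db.records.to_csv(path, sep="\t", index=False)


def read_db(path: str | Path, species: str = "human") -> InteractionDB:
    """Read back a combined TSV written by :func:`write_db`."""
    df = pd.read_csv(path, sep="\t", dtype={"layer": str, "source": str, "target": str})
    df["direct"] = df["direct"].astype(str).str.lower().isin(("true", "1", "yes"))
    return InteractionDB(species=species, records=df)
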
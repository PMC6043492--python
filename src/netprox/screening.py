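"""Batch drug x disease proximity screening and its evaluation.

Curation follows the binding-affinity rule used for the drug-target
network: a physical drug-target interaction requires a reported Ki, Kd,
IC50 or EC50 of at most 10 uM. Disease modules enter the screen only if at
least 10 of their genes are present in the interactome. High-confidence
predictions are the pairs with z < -4.0, and ranking quality against a set
of known indications is summarised by the ROC AUC using -z as the score.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd
from sklearn.metrics import roc_auc_score

from .interactome import (
    DegreeBins,
    GeneSet,
    build_degree_bins,
    restrict_to_network,
)
from .proximity import ProximityResult, proximity_z

__all__ = [
    "AFFINITY_TYPES",
    "DrugTargetRecord",
    "ScreenTable",
    "load_drug_target_table",
    "curate_targets",
    "filter_disease_modules",
    "screen",
    "filter_high_confidence",
    "roc_auc",
    "atc_class",
]

logger = logging.getLogger(__name__)

AFFINITY_TYPES = ("Ki", "Kd", "IC50", "EC50")

TABLE_COLUMNS = [
    "drug", "disease", "measure", "d", "z", "null_mean", "null_sd",
    "replicates", "n_targets_used", "n_disease_used", "seed",
]


@dataclass(frozen=True)
class DrugTargetRecord:
    """One reported drug-target binding measurement (affinity in uM)."""

    drug: str
    target: str
    affinity_value: float
    affinity_type: str
    atc_codes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.affinity_value <= 0:
            raise ValueError(f"affinity must be positive, got {self.affinity_value}")
        if self.affinity_type not in AFFINITY_TYPES:
            raise ValueError(
                f"affinity_type {self.affinity_type!r} not one of {AFFINITY_TYPES}"
            )


@dataclass
class ScreenTable:
    """Results of a drug x disease screen plus skip reasons and metadata."""

    df: pd.DataFrame
    skipped: list[tuple[str, str, str]] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.df)

    def to_csv(self, target: str | Path | IO[str]) -> None:
        self.df.to_csv(target, index=False)

    @classmethod
    def from_csv(cls, source: str | Path | IO[str]) -> "ScreenTable":
        df = pd.read_csv(source, dtype={"drug": str, "disease": str})
        missing = [c for c in TABLE_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"screen table missing columns: {missing}")
        return cls(df=df)


_UNIT_FACTORS_TO_UM = {"uM": 1.0, "µM": 1.0, "um": 1.0, "nM": 1e-3, "nm": 1e-3, "mM": 1e3}


def load_drug_target_table(source: str | Path | IO[str]) -> list[DrugTargetRecord]:
    """Read a drug-target TSV: drug, atc, target, affinity_value, affinity_type, affinity_units.

    The ``atc`` column holds comma-separated ATC codes (may be empty).
    Affinities are converted to uM; an unrecognised unit is an error.
    """
    df = pd.read_csv(source, sep="\t", dtype=str)
    required = {"drug", "target", "affinity_value", "affinity_type"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"drug-target table missing columns: {sorted(missing)}")
    records: list[DrugTargetRecord] = []
    for row in df.itertuples(index=False):
        units = getattr(row, "affinity_units", "uM") or "uM"
        if units not in _UNIT_FACTORS_TO_UM:
            raise ValueError(f"unknown affinity units {units!r} for drug {row.drug!r}")
        atc_raw = getattr(row, "atc", "") or ""
        atc = tuple(code.strip() for code in str(atc_raw).split(",") if code.strip()) \
            if atc_raw and str(atc_raw) != "nan" else ()
        records.append(
            DrugTargetRecord(
                drug=str(row.drug),
                target=str(row.target),
                affinity_value=float(row.affinity_value) * _UNIT_FACTORS_TO_UM[units],
                affinity_type=str(row.affinity_type),
                atc_codes=atc,
            )
        )
    return records


def curate_targets(
    records: Iterable[DrugTargetRecord], cutoff_uM: float = 10.0
) -> tuple[dict[str, GeneSet], dict[str, int]]:
    """Keep measurements with affinity <= cutoff (boundary included) and group by drug.

    Returns the drug -> target-set mapping and a report counting, per drug,
    the records discarded by the affinity cutoff; drugs left with no
    targets appear in the report but not in the mapping.
    """
    kept: dict[str, set[str]] = {}
    dropped: dict[str, int] = {}
    for rec in records:
        if rec.affinity_value <= cutoff_uM:
            kept.setdefault(rec.drug, set()).add(rec.target)
        else:
            dropped[rec.drug] = dropped.get(rec.drug, 0) + 1
            kept.setdefault(rec.drug, set())
    mapping = {
        drug: GeneSet(name=drug, members=frozenset(targets))
        for drug, targets in kept.items()
        if targets
    }
    for drug, targets in kept.items():
        if not targets:
            logger.warning("drug %s has no targets passing the %.3g uM cutoff", drug, cutoff_uM)
    report = {d: n for d, n in dropped.items()}
    return mapping, report


def atc_class(records: Iterable[DrugTargetRecord]) -> dict[str, str]:
    """Class each drug as cardiovascular ('CV', any first-level ATC code C),
    'non-CV' (has ATC codes, none starting with C) or 'unknown' (no codes)."""
    codes: dict[str, set[str]] = {}
    for rec in records:
        codes.setdefault(rec.drug, set()).update(rec.atc_codes)
    out = {}
    for drug, cs in codes.items():
        if not cs:
            out[drug] = "unknown"
        elif any(c.upper().startswith("C") for c in cs):
            out[drug] = "CV"
        else:
            out[drug] = "non-CV"
    return out


def filter_disease_modules(
    modules: Sequence[GeneSet], g: nx.Graph, min_genes: int = 10
) -> list[GeneSet]:
    """Keep disease modules with at least ``min_genes`` genes inside the network.

    Genes outside the interactome do not count toward the threshold; the
    returned sets keep their full membership (restriction happens at
    screening time).
    """
    kept = []
    for m in modules:
        in_network = sum(1 for gene in m.members if gene in g)
        if in_network >= min_genes:
            kept.append(m)
        else:
            logger.warning(
                "disease module %s dropped: %d in-network genes < %d",
                m.name, in_network, min_genes,
            )
    return kept


def _pair_seed(seed: int, drug: str, disease: str) -> int:
    # order-independent deterministic seed per pair; < 2**31 for portability
    digest = hashlib.sha256(f"{seed}|{drug}|{disease}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def screen(
    g: nx.Graph,
    drugs: Mapping[str, GeneSet],
    diseases: Sequence[GeneSet],
    measure: str = "closest",
    replicates: int = 1000,
    seed: int = 0,
    min_bin_size: int = 100,
    bins: DegreeBins | None = None,
    randomize: str = "both",
) -> ScreenTable:
    """Proximity z-score for every drug x disease pair.

    Deterministic given ``seed``: each pair derives its own substream seed
    from (seed, drug, disease), so results do not depend on evaluation
    order. Pairs whose drug targets or disease genes all fall outside the
    network are skipped with a recorded reason. Rows are ordered by
    (disease, ascending z) for stable diffs.
    """
    if not drugs or not diseases:
        raise ValueError("screen needs at least one drug and one disease module")
    if bins is None:
        bins = build_degree_bins(g, min_bin_size=min_bin_size)
    rows: list[dict] = []
    skipped: list[tuple[str, str, str]] = []
    for disease in diseases:
        disease_in, _ = restrict_to_network(disease, g)
        for drug_name, targets in drugs.items():
            targets_in, _ = restrict_to_network(targets, g)
            if not disease_in.members:
                skipped.append((drug_name, disease.name, "no disease genes in network"))
                continue
            if not targets_in.members:
                skipped.append((drug_name, disease.name, "no targets in network"))
                continue
            pair_seed = _pair_seed(seed, drug_name, disease.name)
            logger.info("screening %s x %s (seed %d)", drug_name, disease.name, pair_seed)
            res: ProximityResult = proximity_z(
                g, bins, disease_in, targets_in,
                measure=measure, replicates=replicates, seed=pair_seed,
                randomize=randomize, drug=drug_name, disease=disease.name,
            )
            rows.append(
                {
                    "drug": drug_name,
                    "disease": disease.name,
                    "measure": measure,
                    "d": res.observed,
                    "z": res.z,
                    "null_mean": res.null.mean,
                    "null_sd": res.null.sd,
                    "replicates": replicates,
                    "n_targets_used": res.n_targets_used,
                    "n_disease_used": res.n_disease_used,
                    "seed": pair_seed,
                }
            )
    for drug_name, disease_name, reason in skipped:
        logger.warning("skipped %s x %s: %s", drug_name, disease_name, reason)
    df = pd.DataFrame(rows, columns=TABLE_COLUMNS)
    if len(df):
        df = df.sort_values(["disease", "z"], kind="mergesort").reset_index(drop=True)
    metadata = {
        "seed": seed,
        "replicates": replicates,
        "measure": measure,
        "min_bin_size": bins.min_bin_size,
        "randomize": randomize,
    }
    return ScreenTable(df=df, skipped=skipped, metadata=metadata)


def filter_high_confidence(table: ScreenTable, z_cutoff: float = -4.0) -> ScreenTable:
    """Pairs with z strictly below the cutoff (default z < -4.0). Idempotent."""
    df = table.df[table.df["z"] < z_cutoff].reset_index(drop=True)
    return ScreenTable(df=df, skipped=list(table.skipped), metadata=dict(table.metadata))


def roc_auc(table: ScreenTable, known_pairs: set[tuple[str, str]]) -> float:
    """ROC AUC for recovering known drug-disease pairs, scoring by -z.

    Negatives are all screened pairs not in ``known_pairs``. Equals the
    Mann-Whitney pair-counting statistic with ties counted 0.5.
    """
    screened = set(zip(table.df["drug"], table.df["disease"]))
    unknown = known_pairs - screened
    if unknown:
        raise ValueError(f"known pairs not present in the screen: {sorted(unknown)[:5]}")
    labels = [
        1 if (d, dis) in known_pairs else 0
        for d, dis in zip(table.df["drug"], table.df["disease"])
    ]
    if sum(labels) == 0 or sum(labels) == len(labels):
        raise ValueError("ROC needs at least one positive and one negative pair")
    scores = (-table.df["z"]).to_numpy()
    return float(roc_auc_score(labels, scores))
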
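"""Tissue-specific expression calls, z-scores and interactome subnetworks.

A gene counts as expressed in a tissue when its RPKM is at least 1 in more
than 80% of that tissue's samples. The significance of a gene's expression
in tissue t is

    z_E(i, t) = (E(i, t) - <E(i)>) / delta_E(i)

with E(i, t) the mean RPKM of gene i over the tissue's samples, and
<E(i)>, delta_E(i) the mean and standard deviation of those tissue-level
means across all tissues. Tissue-specific subnetworks are the interactome
induced on the tissue's expressed genes; mechanism paths enumerate all
shortest paths from drug targets to disease proteins inside such a
subnetwork.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import IO, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .interactome import GeneSet

__all__ = [
    "ExpressionMatrix",
    "MechanismPath",
    "load_expression",
    "expressed_genes",
    "expression_zscores",
    "tissue_subnetwork",
    "mechanism_paths",
]


@dataclass
class ExpressionMatrix:
    """Genes x samples RPKM table with a sample -> tissue label mapping."""

    values: pd.DataFrame
    tissues: pd.Series

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < 0).any():
            raise ValueError("RPKM values must be non-negative")
        unlabeled = set(self.values.columns) - set(self.tissues.index)
        if unlabeled:
            raise ValueError(f"samples without tissue labels: {sorted(unlabeled)[:5]}")
        self.tissues = self.tissues.loc[list(self.values.columns)]

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def tissue_names(self) -> list[str]:
        return sorted(self.tissues.unique())

    def samples_of(self, tissue: str) -> list[str]:
        samples = [s for s, t in self.tissues.items() if t == tissue]
        if not samples:
            raise KeyError(f"unknown tissue {tissue!r}")
        return samples

    def tissue_means(self) -> pd.DataFrame:
        """E(i, t): per-gene mean RPKM over each tissue's samples."""
        return self.values.T.groupby(self.tissues).mean().T

    def write(self, values_path: str | Path, labels_path: str | Path) -> None:
        self.values.to_csv(values_path, sep="\t", index_label="gene")
        self.tissues.rename("tissue").to_csv(labels_path, sep="\t", index_label="sample")


def load_expression(
    values_source: str | Path | IO[str], labels_source: str | Path | IO[str]
) -> ExpressionMatrix:
    """Read an expression TSV (first column gene id) and a sample->tissue TSV."""
    values = pd.read_csv(values_source, sep="\t", index_col=0)
    values.index = values.index.astype(str)
    labels = pd.read_csv(labels_source, sep="\t", index_col=0)
    return ExpressionMatrix(values=values, tissues=labels.iloc[:, 0].astype(str))


def expressed_genes(
    m: ExpressionMatrix,
    tissue: str,
    rpkm_threshold: float = 1.0,
    fraction: float = 0.8,
) -> GeneSet:
    """Genes with RPKM >= threshold in strictly more than ``fraction`` of the tissue's samples.

    The comparisons mirror the calling rule exactly: the per-sample test is
    ``>=`` the RPKM threshold, the across-sample test is ``>`` the fraction
    (so 8 of 10 samples does not qualify at fraction 0.8, 9 of 10 does).
    """
    samples = m.samples_of(tissue)
    sub = m.values[samples]
    frac_passing = (sub >= rpkm_threshold).sum(axis=1) / len(samples)
    members = frozenset(frac_passing.index[frac_passing > fraction].astype(str))
    return GeneSet(name=f"{tissue}_expressed", members=members)


def expression_zscores(m: ExpressionMatrix) -> pd.DataFrame:
    """Tidy table of tissue expression z-scores, one row per gene x tissue.

    Columns: gene, tissue, mean_expression E(i,t), across_mean <E(i)>,
    across_sd delta_E(i) (sample sd over tissue means, ddof=1), z, and
    ``constant`` flagging genes whose expression does not vary across
    tissues (their z is set to 0 rather than NaN). Requires >= 2 tissues.
    """
    means = m.tissue_means()
    if means.shape[1] < 2:
        raise ValueError("z-scores need at least 2 tissues")
    grand = means.mean(axis=1)
    sd = means.std(axis=1, ddof=1)
    constant = sd == 0
    z = means.sub(grand, axis=0).div(sd.where(~constant, 1.0), axis=0)
    z[constant] = 0.0
    tidy = (
        z.stack()
        .rename("z")
        .reset_index()
        .rename(columns={"level_0": "gene", "level_1": "tissue"})
    )
    tidy.columns = ["gene", "tissue", "z"]
    tidy["mean_expression"] = [
        means.at[g, t] for g, t in zip(tidy["gene"], tidy["tissue"])
    ]
    tidy["across_mean"] = grand.loc[tidy["gene"]].to_numpy()
    tidy["across_sd"] = sd.loc[tidy["gene"]].to_numpy()
    tidy["constant"] = constant.loc[tidy["gene"]].to_numpy()
    return tidy[
        ["gene", "tissue", "mean_expression", "across_mean", "across_sd", "z", "constant"]
    ]


def tissue_subnetwork(g: nx.Graph, expressed: GeneSet) -> nx.Graph:
    """Interactome induced on the tissue's expressed genes (a copy)."""
    return g.subgraph(n for n in g if n in expressed.members).copy()


@dataclass(frozen=True)
class MechanismPath:
    """One shortest path from a drug target to a disease protein."""

    target: str
    disease_gene: str
    length: int
    nodes: tuple[str, ...]


def mechanism_paths(
    g_tissue: nx.Graph,
    targets: GeneSet,
    disease: GeneSet,
    max_len: int,
    zscores: pd.DataFrame | None = None,
    tissue: str | None = None,
) -> tuple[list[MechanismPath], list[tuple[str, str]]]:
    """All shortest target-to-disease paths of hop length <= ``max_len``.

    Genes absent from the tissue subnetwork are skipped and reported as
    (gene, role) tuples. When a z-score table (from
    :func:`expression_zscores`) and a tissue are given, each path node
    gains an expression annotation usable for node sizing; annotations are
    attached as graph-independent metadata via :func:`annotate_expression`.
    """
    skipped: list[tuple[str, str]] = []
    targets_in = sorted(t for t in targets.members if t in g_tissue)
    disease_in = sorted(d for d in disease.members if d in g_tissue)
    skipped.extend((t, "target") for t in sorted(targets.members) if t not in g_tissue)
    skipped.extend((d, "disease") for d in sorted(disease.members) if d not in g_tissue)
    paths: list[MechanismPath] = []
    for t in targets_in:
        lengths = nx.single_source_shortest_path_length(g_tissue, t, cutoff=max_len)
        for d in disease_in:
            if d not in lengths:
                continue
            for p in nx.all_shortest_paths(g_tissue, t, d):
                paths.append(
                    MechanismPath(target=t, disease_gene=d, length=len(p) - 1, nodes=tuple(p))
                )
    return paths, skipped


def annotate_expression(
    paths: Sequence[MechanismPath], zscores: pd.DataFrame, tissue: str
) -> pd.DataFrame:
    """Per-node expression z in the given tissue for every path node (for node sizing)."""
    ztab = zscores[zscores["tissue"] == tissue].set_index("gene")["z"]
    nodes = sorted({n for p in paths for n in p.nodes})
    return pd.DataFrame(
        {
            "node": nodes,
            "z_expression": [float(ztab.get(n, np.nan)) for n in nodes],
            "tissue": tissue,
        }
    )
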
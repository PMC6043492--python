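"""Synthetic-data generators with known ground truth.

Everything the other modules consume — interactomes, disease modules,
drug-target sets, expression matrices, study-estimate pairs — can be
generated here, deterministically from a seed. The synthetic interactome
uses preferential attachment, because the degree-matched null model is
only meaningfully exercised on graphs with heterogeneous degrees; disease
modules are grown as connected neighborhoods, emulating the tendency of
disease proteins to cluster in the same network region; "proximal" drugs
draw their targets from the module and its immediate neighbors, so their
closest distance is at most 1 by construction.

The generators write the same on-disk formats the loaders read, so
end-to-end (including CLI) tests need no special casing.
"""

from __future__ import annotations

import json
from collections import deque
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .epimeta import StudyEstimate
from .interactome import GeneSet, build_degree_bins, write_edge_list, write_gene_sets
from .proximity import sample_degree_matched
from .tissue import ExpressionMatrix

__all__ = [
    "make_interactome",
    "plant_disease_module",
    "make_drug",
    "make_expression",
    "make_study_pair",
    "SyntheticScenario",
    "make_screen_scenario",
    "write_scenario",
]


def make_interactome(n_nodes: int = 500, attach_m: int = 2, seed: int = 0) -> nx.Graph:
    """Connected scale-free-like graph via preferential attachment.

    Nodes are relabeled to string gene identifiers "1".."n". The standard
    construction yields exactly attach_m * (n_nodes - attach_m) edges.
    Deterministic per seed.
    """
    g = nx.barabasi_albert_graph(n_nodes, attach_m, seed=seed)
    return nx.relabel_nodes(g, {i: str(i + 1) for i in g.nodes()})


def plant_disease_module(g: nx.Graph, size: int, seed: int = 0) -> GeneSet:
    """Grow a connected neighborhood of ``size`` nodes as a disease module.

    Breadth-first growth from a random seed node, expanding the frontier
    in random order, so the module induces a connected subgraph and sits
    closer together than a degree-matched random set of the same size.
    """
    if size > g.number_of_nodes():
        raise ValueError(f"module size {size} exceeds graph size {g.number_of_nodes()}")
    rng = np.random.default_rng(seed)
    nodes = sorted(g.nodes())
    start = nodes[rng.integers(len(nodes))]
    module = {start}
    frontier = deque([start])
    while len(module) < size:
        if not frontier:
            raise ValueError("component exhausted before reaching requested module size")
        u = frontier.popleft()
        neighbors = sorted(v for v in g[u] if v not in module)
        rng.shuffle(neighbors)
        for v in neighbors:
            if len(module) >= size:
                break
            module.add(v)
            frontier.append(v)
    return GeneSet(name=f"module_{seed}", members=frozenset(module))


def make_drug(
    g: nx.Graph,
    module: GeneSet,
    mode: str,
    k_targets: int = 3,
    seed: int = 0,
    min_bin_size: int = 25,
) -> GeneSet:
    """Synthetic drug target set: ``proximal`` to the module or degree-matched ``random``.

    Proximal drugs sample targets from the module and its first neighbors
    (closest distance <= 1 by construction). Random drugs take a uniform
    template of the same size and replace it by a degree-matched draw, so
    the two classes differ in placement, not in connectivity profile.
    """
    rng = np.random.default_rng(seed)
    if mode == "proximal":
        pool = set(module.members)
        for m in module.members:
            pool.update(g[m])
        pool = sorted(pool)
        if k_targets > len(pool):
            raise ValueError("k_targets exceeds module neighborhood size")
        picked = rng.choice(len(pool), size=k_targets, replace=False)
        members = frozenset(pool[i] for i in picked)
    elif mode == "random":
        nodes = sorted(g.nodes())
        template = [nodes[i] for i in rng.choice(len(nodes), size=k_targets, replace=False)]
        bins = build_degree_bins(g, min_bin_size=min_bin_size)
        members = frozenset(sample_degree_matched(g, bins, template, rng))
    else:
        raise ValueError(f"mode must be 'proximal' or 'random', got {mode!r}")
    return GeneSet(name=f"{mode}_drug_{seed}", members=members)


def make_expression(
    genes: Sequence[str],
    tissues: Sequence[str],
    n_samples_per_tissue: int = 10,
    effect_genes: Sequence[str] = (),
    effect_size: float = 5.0,
    effect_tissue: str | None = None,
    seed: int = 0,
) -> ExpressionMatrix:
    """Log-normal RPKM matrix with an optional planted tissue effect.

    Every gene gets a log-normal baseline (median RPKM ~ e^mu with mu drawn
    N(0.5, 1), sample noise sigma = 0.5 on the log scale); ``effect_genes``
    additionally get ``effect_size`` added to their mean RPKM in
    ``effect_tissue`` (the first tissue by default). Values are
    non-negative by construction.
    """
    if len(tissues) < 2:
        raise ValueError("need at least 2 tissues")
    rng = np.random.default_rng(seed)
    effect_tissue = effect_tissue or tissues[0]
    if effect_tissue not in tissues:
        raise ValueError(f"effect tissue {effect_tissue!r} not in tissue list")
    gene_mu = rng.normal(0.5, 1.0, size=len(genes))
    columns, labels, data = [], [], []
    for tissue in tissues:
        for j in range(n_samples_per_tissue):
            columns.append(f"{tissue}_s{j}")
            labels.append(tissue)
    values = np.empty((len(genes), len(columns)))
    effect = np.isin(np.asarray(genes, dtype=object), np.asarray(effect_genes, dtype=object))
    col = 0
    for tissue in tissues:
        block = rng.lognormal(
            mean=gene_mu[:, None], sigma=0.5, size=(len(genes), n_samples_per_tissue)
        )
        if tissue == effect_tissue:
            block = block + effect[:, None] * effect_size
        values[:, col : col + n_samples_per_tissue] = block
        col += n_samples_per_tissue
    df = pd.DataFrame(values, index=[str(g) for g in genes], columns=columns)
    return ExpressionMatrix(values=df, tissues=pd.Series(labels, index=columns))


def make_study_pair(
    true_log_hr: float,
    variances: tuple[float, float] = (0.04, 0.06),
    ns: tuple[int, int] = (50000, 15000),
    seed: int = 0,
) -> list[StudyEstimate]:
    """Two per-database estimates drawn Normal(true_log_hr, variance_i)."""
    rng = np.random.default_rng(seed)
    return [
        StudyEstimate(
            database=f"db{i + 1}",
            log_hr=float(rng.normal(true_log_hr, np.sqrt(v))),
            variance=float(v),
            n=int(n),
        )
        for i, (v, n) in enumerate(zip(variances, ns))
    ]


@dataclass
class SyntheticScenario:
    """A reproducible bundle of inputs with ground-truth labels."""

    seed: int
    interactome: nx.Graph
    disease_modules: list[GeneSet]
    drugs: dict[str, GeneSet]
    drug_labels: dict[str, str]
    expression: ExpressionMatrix | None = None
    study_estimates: list[StudyEstimate] | None = None
    true_log_hr: float | None = None


def make_screen_scenario(
    seed: int = 0,
    n_nodes: int = 500,
    attach_m: int = 2,
    module_size: int = 25,
    n_proximal: int = 10,
    n_random: int = 10,
    k_targets: int = 3,
) -> SyntheticScenario:
    """Interactome + planted disease module + proximal/random drug panels."""
    g = make_interactome(n_nodes=n_nodes, attach_m=attach_m, seed=seed)
    module = plant_disease_module(g, size=module_size, seed=seed + 1)
    drugs: dict[str, GeneSet] = {}
    labels: dict[str, str] = {}
    for i in range(n_proximal):
        name = f"proximal_{i}"
        drugs[name] = GeneSet(
            name=name,
            members=make_drug(g, module, "proximal", k_targets, seed=seed * 100003 + i).members,
        )
        labels[name] = "proximal"
    for i in range(n_random):
        name = f"random_{i}"
        drugs[name] = GeneSet(
            name=name,
            members=make_drug(
                g, module, "random", k_targets, seed=seed * 100003 + 50021 + i
            ).members,
        )
        labels[name] = "random"
    return SyntheticScenario(
        seed=seed,
        interactome=g,
        disease_modules=[module],
        drugs=drugs,
        drug_labels=labels,
    )


def write_scenario(scenario: SyntheticScenario, out_dir: str | Path) -> dict[str, str]:
    """Write a scenario in the on-disk formats the loaders read.

    Produces edge list, disease GMT, drug-target TSV (affinity columns
    filled with a passing placeholder value), optional expression TSVs and
    estimates CSV, plus ground_truth.json. Returns the path map.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    edge_path = out / "interactome.tsv"
    write_edge_list(scenario.interactome, edge_path)
    paths["interactome"] = str(edge_path)

    gmt_path = out / "diseases.gmt"
    write_gene_sets(scenario.disease_modules, gmt_path)
    paths["diseases"] = str(gmt_path)

    targets_path = out / "drug_targets.tsv"
    rows = []
    for drug, targets in scenario.drugs.items():
        for target in sorted(targets.members):
            rows.append(
                {
                    "drug": drug,
                    "atc": "",
                    "target": target,
                    "affinity_value": 1.0,
                    "affinity_type": "Ki",
                    "affinity_units": "uM",
                }
            )
    pd.DataFrame(rows).to_csv(targets_path, sep="\t", index=False)
    paths["drug_targets"] = str(targets_path)

    if scenario.expression is not None:
        vals, labs = out / "expression.tsv", out / "sample_tissues.tsv"
        scenario.expression.write(vals, labs)
        paths["expression"], paths["sample_tissues"] = str(vals), str(labs)

    if scenario.study_estimates is not None:
        est_path = out / "estimates.csv"
        pd.DataFrame(
            [
                {"database": e.database, "log_hr": e.log_hr, "variance": e.variance, "n": e.n}
                for e in scenario.study_estimates
            ]
        ).to_csv(est_path, index=False)
        paths["estimates"] = str(est_path)

    truth = {
        "seed": scenario.seed,
        "drug_labels": scenario.drug_labels,
        "disease_modules": {m.name: sorted(m.members) for m in scenario.disease_modules},
        "true_log_hr": scenario.true_log_hr,
    }
    truth_path = out / "ground_truth.json"
    truth_path.write_text(json.dumps(truth, indent=2))
    paths["ground_truth"] = str(truth_path)
    return paths
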
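"""Tissue-specific subnetworks by personalized PageRank.

Seed genes are the constituents of co-existing pairs whose tissue
double-mutant fraction exceeds a tissue-specific threshold.  Scores are
propagated over a directed gene interaction network by random walk with
restart (personalized PageRank, damping 0.85, at most 100 power
iterations); nodes above a score threshold induce the tissue subnetwork.
Robustness is assessed two ways: damping-factor sensitivity (Spearman rank
correlation of scores across alternative alpha values) and pathway
enrichment frequency across degree-preserving randomized networks.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import spearmanr

from .annotate import GeneSetCollection, geneset_enrichment, tissue_fractions
from .cohort import BinaryCohortMatrix, DataError, SampleMeta
from .pairs import CO_EXISTING, PairResult

logger = logging.getLogger("comutnet")

DEFAULT_ALPHA = 0.85
DEFAULT_MAX_ITER = 100
DEFAULT_TOL = 1e-10
DEFAULT_SCORE_THRESHOLD = 0.001        # original subnetwork extraction
DEFAULT_ROBUSTNESS_THRESHOLD = 0.002   # randomization analysis
SENSITIVITY_ALPHAS = (0.70, 0.75, 0.80, 0.90, 0.95)


@dataclass
class PageRankConfig:
    """Power-iteration settings for personalized PageRank."""

    alpha: float = DEFAULT_ALPHA
    max_iterations: int = DEFAULT_MAX_ITER
    tolerance: float = DEFAULT_TOL
    personalization: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        if any(w < 0 for w in self.personalization.values()):
            raise ValueError("personalization weights must be nonnegative")


# ---------------------------------------------------------------------------
# Network I/O


def load_network(path) -> nx.DiGraph:
    """Load a directed network from edge-list TSV or SIF; self-loops dropped."""
    path = str(path)
    g = nx.DiGraph()
    is_sif = path.endswith(".sif")
    with open(path) as fh:
        for lineno, line in enumerate(fh):
            parts = line.rstrip("\n").split("\t")
            if lineno == 0 and not is_sif and parts[:2] == ["source", "target"]:
                continue  # edge-list header
            if len(parts) < 2:
                if parts[0]:
                    g.add_node(parts[0])  # isolated node line (SIF)
                continue
            if is_sif and len(parts) >= 3:
                _maybe_add_edge(g, parts[0], parts[2])
            else:
                _maybe_add_edge(g, parts[0], parts[1])
    return g


def _maybe_add_edge(g: nx.DiGraph, u: str, v: str) -> None:
    if u == v:
        logger.info("dropping self-loop on %s", u)
        return
    g.add_edge(u, v)


def write_sif(g: nx.DiGraph, path, interaction: str = "interacts") -> None:
    with open(path, "w") as fh:
        for u, v in sorted(g.edges()):
            fh.write(f"{u}\t{interaction}\t{v}\n")
    isolated = [n for n in g.nodes() if g.degree(n) == 0]
    if isolated:
        with open(path, "a") as fh:
            for n in sorted(isolated):
                fh.write(f"{n}\n")


def write_graphml(g: nx.DiGraph, path) -> None:
    nx.write_graphml(g, path)


# ---------------------------------------------------------------------------
# Seed selection


def select_seeds(
    pairs: Sequence[PairResult],
    matrix: BinaryCohortMatrix,
    metadata: Mapping[str, SampleMeta],
    tissue: str,
    fraction_threshold: float,
    mode: str = "all_tumors",
) -> set[str]:
    """Genes of co-existing pairs whose tissue double-mutant fraction
    strictly exceeds ``fraction_threshold`` (a fraction in [0, 1])."""
    co_pairs = [r for r in pairs if r.pair_class == CO_EXISTING]
    fractions = tissue_fractions(co_pairs, matrix, metadata, mode=mode)
    in_tissue = fractions[fractions["tissue"] == tissue]
    seeds: set[str] = set()
    for row in in_tissue.itertuples(index=False):
        if not math.isnan(row.fraction) and row.fraction > fraction_threshold:
            seeds.add(row.key_a.split(":")[0])
            seeds.add(row.key_b.split(":")[0])
    if not seeds:
        raise DataError(
            f"no seed genes for tissue {tissue!r} at threshold {fraction_threshold};"
            " lower the threshold"
        )
    return seeds


# ---------------------------------------------------------------------------
# Personalized PageRank (sparse power iteration)


def personalized_pagerank(network: nx.DiGraph, config: PageRankConfig) -> dict[str, float]:
    """Random walk with restart to the personalization vector.

    Power iteration on the column form x <- alpha*(x P + dangling_mass * p)
    + (1-alpha) p, where P is the row-stochastic transition matrix and
    dangling nodes redistribute their mass to the personalization vector
    p.  Stops when the L1 change drops below tolerance or after
    ``max_iterations``.  Scores are nonnegative and sum to 1.
    """
    if network.number_of_nodes() == 0:
        raise DataError("empty network")
    nodes = sorted(network.nodes())
    index = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)

    pers = np.zeros(n)
    missing = [s for s in config.personalization if s not in index]
    if missing:
        logger.info("dropping %d personalization seeds absent from network", len(missing))
    for s, w in config.personalization.items():
        if s in index:
            pers[index[s]] = w
    if pers.sum() == 0:
        if config.personalization:
            raise DataError("no personalization seed present in the network")
        pers[:] = 1.0
    p = pers / pers.sum()

    rows, cols = [], []
    for u, v in network.edges():
        rows.append(index[u])
        cols.append(index[v])
    A = sp.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n, n), dtype=float
    )
    out_deg = np.asarray(A.sum(axis=1)).ravel()
    dangling = out_deg == 0
    inv_deg = np.where(dangling, 0.0, 1.0 / np.maximum(out_deg, 1e-300))
    P = sp.diags(inv_deg) @ A

    alpha = config.alpha
    x = p.copy()
    for _ in range(config.max_iterations):
        x_new = alpha * (x @ P + x[dangling].sum() * p) + (1.0 - alpha) * p
        if np.abs(x_new - x).sum() < config.tolerance:
            x = x_new
            break
        x = x_new
    x = np.maximum(x, 0.0)
    x = x / x.sum()
    return {node: float(x[index[node]]) for node in nodes}


def extract_subnetwork(
    network: nx.DiGraph,
    scores: Mapping[str, float],
    score_threshold: float = DEFAULT_SCORE_THRESHOLD,
    include_seeds: bool = True,
    seeds: Sequence[str] = (),
) -> nx.DiGraph:
    """Induced subgraph over nodes with score strictly above the threshold
    (optionally forcing the seed nodes in)."""
    keep = {node for node, s in scores.items() if s > score_threshold}
    if include_seeds:
        keep |= {s for s in seeds if s in network}
    sub = network.subgraph(keep).copy()
    if sub.number_of_nodes() == 0:
        logger.warning("subnetwork empty at threshold %g", score_threshold)
    return sub


def alpha_sensitivity(
    network: nx.DiGraph,
    seeds: Sequence[str],
    alphas: Sequence[float] = SENSITIVITY_ALPHAS,
    reference_alpha: float = DEFAULT_ALPHA,
    max_iterations: int = DEFAULT_MAX_ITER,
    tolerance: float = DEFAULT_TOL,
) -> pd.DataFrame:
    """Spearman rank correlation of scores at each alpha vs the reference.

    Undefined correlations (constant rankings) are emitted as missing.
    """
    pers = {s: 1.0 for s in seeds}

    def _run(alpha: float) -> np.ndarray:
        cfg = PageRankConfig(
            alpha=alpha, max_iterations=max_iterations,
            tolerance=tolerance, personalization=dict(pers),
        )
        scores = personalized_pagerank(network, cfg)
        return np.array([scores[n] for n in sorted(network.nodes())])

    ref = _run(reference_alpha)
    rows = []
    for alpha in alphas:
        vec = ref if alpha == reference_alpha else _run(alpha)
        if np.all(vec == vec[0]) or np.all(ref == ref[0]):
            rho = math.nan
        else:
            rho = float(spearmanr(ref, vec).statistic)
        rows.append({"alpha": alpha, "spearman_rho": rho})
    return pd.DataFrame(rows, columns=["alpha", "spearman_rho"])


# ---------------------------------------------------------------------------
# Degree-preserving randomization


def randomize_network(
    network: nx.DiGraph, swap_multiplier: float = 10.0, seed: int = 0
) -> nx.DiGraph:
    """Degree-preserving randomization by attempted two-edge swaps.

    Attempts ``swap_multiplier * |E|`` swaps (a,b),(c,d) -> (a,d),(c,b),
    rejecting any that would create a self-loop or duplicate edge.  In- and
    out-degrees of every node are preserved exactly.  Returns the input
    unchanged (with a warning) when no swap could be applied.
    """
    edges = sorted(network.edges())
    m = len(edges)
    if m < 2:
        logger.warning("network too small to randomize; returned unchanged")
        return network.copy()
    edge_set = set(edges)
    rng = np.random.default_rng(seed)
    attempts = int(swap_multiplier * m)
    accepted = 0
    pick = rng.integers(0, m, size=(attempts, 2))
    for i, j in pick:
        if i == j:
            continue
        a, b = edges[i]
        c, d = edges[j]
        if a == d or c == b or b == d or a == c:
            continue
        if (a, d) in edge_set or (c, b) in edge_set:
            continue
        edge_set.remove((a, b))
        edge_set.remove((c, d))
        edge_set.add((a, d))
        edge_set.add((c, b))
        edges[i] = (a, d)
        edges[j] = (c, b)
        accepted += 1
    if accepted == 0:
        logger.warning("no degree-preserving swap applied; network unchanged")
        return network.copy()
    logger.info("randomize_network: %d/%d swap attempts accepted", accepted, attempts)
    g = nx.DiGraph()
    g.add_nodes_from(network.nodes())
    g.add_edges_from(edge_set)
    return g


def tabulate_robustness(
    original_enriched: Sequence[str],
    random_enriched: Sequence[set[str] | Sequence[str]],
) -> pd.DataFrame:
    """Frequency (%) with which each originally enriched pathway recurs
    across randomized replicates."""
    n = len(random_enriched)
    rows = []
    for name in sorted(original_enriched):
        count = sum(1 for rep in random_enriched if name in set(rep))
        rows.append(
            {
                "pathway": name,
                "original_enriched": True,
                "random_frequency_percent": (100.0 * count / n) if n else math.nan,
            }
        )
    return pd.DataFrame(rows, columns=["pathway", "original_enriched", "random_frequency_percent"])


def enrichment_robustness(
    network: nx.DiGraph,
    seeds: Sequence[str],
    collection: GeneSetCollection,
    n_random: int = 100,
    score_threshold: float = DEFAULT_ROBUSTNESS_THRESHOLD,
    q_cutoff: float = 0.05,
    swap_multiplier: float = 10.0,
    alpha: float = DEFAULT_ALPHA,
    seed: int = 0,
) -> pd.DataFrame:
    """Pathway-enrichment robustness against degree-preserving nulls.

    Extracts the original subnetwork (scores > ``score_threshold``), finds
    pathways enriched at BH q < ``q_cutoff``, then repeats the propagation
    and enrichment on ``n_random`` randomized networks with the same
    personalization, reporting the recurrence percentage per pathway.
    """
    def _enriched(g: nx.DiGraph) -> set[str]:
        cfg = PageRankConfig(alpha=alpha, personalization={s: 1.0 for s in seeds})
        scores = personalized_pagerank(g, cfg)
        sub = extract_subnetwork(g, scores, score_threshold, seeds=seeds)
        table = geneset_enrichment(sub.nodes(), collection, universe=set(network.nodes()))
        if table.empty:
            return set()
        return set(table.loc[table["q"] < q_cutoff, "set"])

    original = sorted(_enriched(network))
    if n_random == 0:
        return pd.DataFrame(
            {
                "pathway": original,
                "original_enriched": True,
                "random_frequency_percent": math.nan,
            }
        )
    rng = np.random.default_rng(seed)
    replicate_sets = []
    for _ in range(n_random):
        g_rand = randomize_network(network, swap_multiplier, seed=int(rng.integers(2**31 - 1)))
        replicate_sets.append(_enriched(g_rand))
    return tabulate_robustness(original, replicate_sets)
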
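"""Synthetic cohorts, networks and expression matrices with planted truth.

Every generator is a pure function of (configuration, seed) and emits the
exact file dialects the analysis stages consume, together with a
:class:`TruthLedger` recording what was planted so that recovery can be
scored.

Planted pairwise dependence between two mutations is parameterized by the
pair's marginal carrier frequencies and a target odds ratio theta, using
the exact odds-ratio-parameterized 2x2 joint (the Plackett construction):
the joint-carrier cell p11 is the root of

    p11 * p00 = theta * p10 * p01

inside the Frechet interval, so the planted theta is directly comparable
to the pipeline's odds-ratio estimator.

Metastatic markers are planted by multiplying an itemset's joint-carrier
probability by an enrichment factor in metastatic samples and
renormalizing the primary-sample rate so the cohort-wide marginal stays at
the base rate; the expected propensity statistic of the marker then equals
the enrichment factor.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .cohort import MutationKey, parse_key


class InfeasibleSpecError(ValueError):
    """Raised when a planted specification admits no valid joint distribution."""


# ---------------------------------------------------------------------------
# Planted-structure specifications


@dataclass(frozen=True)
class PairSpec:
    """A planted mutation pair with marginals and target odds ratio."""

    key_a: MutationKey
    key_b: MutationKey
    marginal_a: float
    marginal_b: float
    target_or: float
    tissue_restriction: str | None = None

    def __post_init__(self) -> None:
        if not (0 < self.marginal_a < 1 and 0 < self.marginal_b < 1):
            raise InfeasibleSpecError("marginals must lie in (0, 1)")
        if self.target_or <= 0:
            raise InfeasibleSpecError("target odds ratio must be positive")
        if self.key_a.gene == self.key_b.gene:
            raise InfeasibleSpecError("planted pair must span two genes")


@dataclass(frozen=True)
class MarkerSpec:
    """A planted metastatic marker itemset.

    ``base_p`` is the cohort-wide joint-carrier probability; in metastatic
    samples the rate is ``enrichment * base_p`` with the primary rate
    renormalized down so the overall marginal stays ``base_p``.
    """

    items: tuple[MutationKey, ...]
    base_p: float
    enrichment: float

    def __post_init__(self) -> None:
        if not (0 < self.base_p < 1):
            raise InfeasibleSpecError("base_p must lie in (0, 1)")
        if self.enrichment <= 0:
            raise InfeasibleSpecError("enrichment must be positive")


@dataclass
class TruthLedger:
    """Everything planted into a synthetic dataset, for recovery scoring."""

    seed: int
    planted_pairs: list[dict] = field(default_factory=list)
    planted_metastatic_markers: list[dict] = field(default_factory=list)
    planted_degs: list[dict] = field(default_factory=list)
    driver_keys: list[str] = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "TruthLedger":
        with open(path) as fh:
            return cls(**json.load(fh))


# ---------------------------------------------------------------------------
# OR-parameterized 2x2 joint


def solve_joint_cell(pa: float, pb: float, theta: float) -> float:
    """Joint-carrier probability p11 with given marginals and odds ratio.

    Solves ``p11*p00 = theta*p10*p01`` (Plackett) with p10 = pa-p11,
    p01 = pb-p11, p00 = 1-pa-pb+p11.  theta=1 gives independence pa*pb.
    """
    if not (0 < pa < 1 and 0 < pb < 1):
        raise InfeasibleSpecError("marginals must lie in (0, 1)")
    if theta <= 0:
        raise InfeasibleSpecError("theta must be positive")
    if theta == 1.0:
        return pa * pb
    s = 1.0 + (theta - 1.0) * (pa + pb)
    disc = s * s - 4.0 * theta * (theta - 1.0) * pa * pb
    if disc < 0:
        raise InfeasibleSpecError("no admissible joint cell for these parameters")
    # rationalized root of (1-theta) x^2 + s x - theta*pa*pb = 0: stable as
    # theta -> 1 where the textbook quadratic formula cancels catastrophically
    p11 = 2.0 * theta * pa * pb / (s + math.sqrt(disc))
    lo = max(0.0, pa + pb - 1.0)
    hi = min(pa, pb)
    if not (lo - 1e-12 <= p11 <= hi + 1e-12):
        raise InfeasibleSpecError(
            f"solved p11={p11:.6g} outside Frechet interval [{lo:.6g}, {hi:.6g}]"
        )
    return float(min(max(p11, lo), hi))


def _pair_cell_probs(spec: PairSpec) -> np.ndarray:
    p11 = solve_joint_cell(spec.marginal_a, spec.marginal_b, spec.target_or)
    p10 = spec.marginal_a - p11
    p01 = spec.marginal_b - p11
    p00 = 1.0 - p11 - p10 - p01
    probs = np.array([p11, p10, p01, p00])
    if np.any(probs < -1e-12):
        raise InfeasibleSpecError("negative cell probability")
    probs = np.clip(probs, 0.0, 1.0)
    return probs / probs.sum()


# ---------------------------------------------------------------------------
# Cohort generator


DEFAULT_TISSUE_MIX = {"breast": 0.4, "pancreas": 0.3, "lung": 0.3}


def generate_cohort(
    n_samples: int,
    background_mutations: int,
    pair_specs: Sequence[PairSpec] = (),
    marker_specs: Sequence[MarkerSpec] = (),
    tissue_mix: Mapping[str, float] | None = None,
    metastatic_fraction: float = 0.2,
    background_marginal_range: tuple[float, float] = (0.02, 0.15),
    vaf_range: tuple[float, float] = (0.15, 0.6),
    driver_fraction: float = 0.3,
    seed: int = 0,
    out_dir=None,
) -> tuple[pd.DataFrame, pd.DataFrame, TruthLedger]:
    """Simulate a mutation cohort with planted pairs and metastatic markers.

    Returns (mutation table, sample metadata, truth ledger); when
    ``out_dir`` is given, also writes ``mutations.tsv``, ``samples.tsv``,
    ``driver_catalog.txt`` and ``truth.json`` there.

    Background mutations are independent Bernoulli columns with marginals
    drawn uniformly from ``background_marginal_range``; planted pairs are
    drawn from their OR-parameterized joint (restricted to one tissue when
    the pair spec says so, independent elsewhere); marker itemsets are carried
    jointly at an enriched rate in metastatic samples.  VAF values are
    drawn uniformly from ``vaf_range`` (the cohort emulates calls that
    already passed VAF-based QC).
    """
    if tissue_mix is None:
        tissue_mix = DEFAULT_TISSUE_MIX
    for spec in pair_specs:
        _pair_cell_probs(spec)  # raise before writing anything
    for mk in marker_specs:
        if mk.enrichment * metastatic_fraction >= 1.0:
            raise InfeasibleSpecError(
                "enrichment * metastatic_fraction must be < 1 for renormalization"
            )

    ss = np.random.SeedSequence(seed)
    rng_meta, rng_bg, rng_pairs, rng_markers, rng_vaf = (
        np.random.default_rng(s) for s in ss.spawn(5)
    )

    sample_ids = [f"S{i:05d}" for i in range(n_samples)]
    tissues = list(tissue_mix)
    tprobs = np.array([tissue_mix[t] for t in tissues], dtype=float)
    tprobs = tprobs / tprobs.sum()
    tissue_of = rng_meta.choice(tissues, size=n_samples, p=tprobs)
    metastatic = rng_meta.random(n_samples) < metastatic_fraction

    columns: dict[MutationKey, np.ndarray] = {}

    # background: independent Bernoulli columns
    lo, hi = background_marginal_range
    bg_marginals = rng_bg.uniform(lo, hi, size=background_mutations)
    for j in range(background_mutations):
        key = MutationKey(f"BG{j:04d}", f"A{j % 700 + 1}V")
        columns[key] = (rng_bg.random(n_samples) < bg_marginals[j]).astype(np.uint8)

    # planted pairs: joint 2x2 draws
    for spec in pair_specs:
        probs = _pair_cell_probs(spec)
        draw = rng_pairs.choice(4, size=n_samples, p=probs)
        col_a = np.isin(draw, (0, 1)).astype(np.uint8)
        col_b = np.isin(draw, (0, 2)).astype(np.uint8)
        if spec.tissue_restriction is not None:
            outside = tissue_of != spec.tissue_restriction
            n_out = int(outside.sum())
            col_a[outside] = rng_pairs.random(n_out) < spec.marginal_a
            col_b[outside] = rng_pairs.random(n_out) < spec.marginal_b
        columns[spec.key_a] = np.maximum(columns.get(spec.key_a, 0), col_a)
        columns[spec.key_b] = np.maximum(columns.get(spec.key_b, 0), col_b)

    # planted metastatic markers: joint itemset carriage, enriched in mets
    for mk in marker_specs:
        p_met = mk.enrichment * mk.base_p
        p_pri = mk.base_p * (1.0 - mk.enrichment * metastatic_fraction) / (
            1.0 - metastatic_fraction
        )
        if p_met >= 1.0:
            raise InfeasibleSpecError("enriched marker probability exceeds 1")
        u = rng_markers.random(n_samples)
        carried = np.where(metastatic, u < p_met, u < p_pri)
        for item in mk.items:
            columns[item] = np.maximum(
                columns.get(item, np.zeros(n_samples, dtype=np.uint8)),
                carried.astype(np.uint8),
            )

    keys = sorted(columns)
    cells = np.column_stack([columns[k] for k in keys]) if keys else np.zeros((n_samples, 0), np.uint8)

    rows = []
    samp_arr, key_arr = np.nonzero(cells)
    vafs = rng_vaf.uniform(vaf_range[0], vaf_range[1], size=len(samp_arr))
    for (i, j, v) in zip(samp_arr, key_arr, vafs):
        k = keys[j]
        rows.append((sample_ids[i], k.gene, k.change, round(float(v), 4)))
    mutations = pd.DataFrame(
        rows, columns=["sample_id", "gene", "protein_change", "vaf"]
    )
    burden = cells.sum(axis=1)
    metadata = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "tissue": tissue_of,
            "sample_type": np.where(metastatic, "metastatic", "primary"),
            "mutation_count": burden.astype(int),
        }
    )

    # drivers: planted pair constituents plus a deterministic slice of background
    driver_keys = sorted(
        {spec.key_a.render() for spec in pair_specs}
        | {spec.key_b.render() for spec in pair_specs}
        | {
            k.render()
            for i, k in enumerate(keys)
            if k.gene.startswith("BG") and (i % max(1, round(1 / max(driver_fraction, 1e-9)))) == 0
        }
    )

    ledger = TruthLedger(
        seed=seed,
        planted_pairs=[
            {
                "key_a": s.key_a.render(),
                "key_b": s.key_b.render(),
                "marginal_a": s.marginal_a,
                "marginal_b": s.marginal_b,
                "target_or": s.target_or,
                "tissue_restriction": s.tissue_restriction,
            }
            for s in pair_specs
        ],
        planted_metastatic_markers=[
            {
                "items": [k.render() for k in mk.items],
                "base_p": mk.base_p,
                "enrichment": mk.enrichment,
            }
            for mk in marker_specs
        ],
        driver_keys=driver_keys,
    )

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        mutations.to_csv(out / "mutations.tsv", sep="\t", index=False)
        metadata.to_csv(out / "samples.tsv", sep="\t", index=False)
        (out / "driver_catalog.txt").write_text("\n".join(driver_keys) + "\n")
        ledger.to_json(out / "truth.json")
    return mutations, metadata, ledger


def to_cohort_matrix(
    mutations: pd.DataFrame,
    metadata: pd.DataFrame,
    recurrence_min: int = 1,
):
    """Binarize a generated mutation table directly (no file round trip).

    Equivalent to loading the emitted TSVs through the cohort loader when
    every VAF already passes the filter (as generated cohorts do); rows
    cover every sample in ``metadata``, columns are mutations recurring in
    at least ``recurrence_min`` samples.
    """
    from .cohort import BinaryCohortMatrix

    samples = list(metadata["sample_id"])
    key_text = mutations["gene"] + ":" + mutations["protein_change"]
    wide = pd.crosstab(mutations["sample_id"], key_text).clip(upper=1)
    wide = wide.reindex(index=samples, fill_value=0)
    wide = wide.loc[:, wide.sum(axis=0) >= recurrence_min]
    keys = sorted(parse_key(k) for k in wide.columns)
    cells = wide[[k.render() for k in keys]].to_numpy(dtype=np.uint8)
    return BinaryCohortMatrix(samples=samples, mutations=keys, cells=cells)


# ---------------------------------------------------------------------------
# Network generator


def generate_network(
    n_genes: int,
    attachment_parameter: float = 0.41,
    pathway_count: int = 10,
    seed: int = 0,
    out_dir=None,
) -> tuple[nx.DiGraph, dict[str, set[str]]]:
    """Directed scale-free gene network plus overlapping pathway gene sets.

    The graph is a simplified (no self-loops / multi-edges) scale-free
    digraph, patched to be weakly connected.  Pathways are gene sets biased
    toward graph neighborhoods (a seed node plus nearby nodes), so that
    pathway membership correlates with topology as it does for curated
    pathway databases.  Writes ``network.tsv`` (edge list) and
    ``pathways.gmt`` when ``out_dir`` is given.
    """
    if n_genes < 10:
        raise ValueError("need at least 10 genes")
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    raw = nx.scale_free_graph(
        n_genes,
        alpha=attachment_parameter,
        beta=max(1.0 - attachment_parameter - 0.05, 0.05),
        gamma=1.0 - attachment_parameter - max(1.0 - attachment_parameter - 0.05, 0.05),
        seed=int(rng.integers(2**31 - 1)),
    )
    g = nx.DiGraph()
    g.add_nodes_from(raw.nodes())
    g.add_edges_from((u, v) for u, v in raw.edges() if u != v)
    # patch weak connectivity
    comps = sorted(nx.weakly_connected_components(g), key=len, reverse=True)
    hub = max(comps[0], key=lambda n: g.degree(n))
    for comp in comps[1:]:
        g.add_edge(hub, min(comp))
    mapping = {n: f"G{n:05d}" for n in g.nodes()}
    g = nx.relabel_nodes(g, mapping)

    nodes = sorted(g.nodes())
    undirected = g.to_undirected()
    pathways: dict[str, set[str]] = {}
    for p in range(pathway_count):
        center = nodes[int(rng.integers(len(nodes)))]
        size = int(rng.integers(10, 41))
        members = [center]
        frontier = [center]
        seen = {center}
        while frontier and len(members) < size:
            nxt = []
            for node in frontier:
                for nb in sorted(undirected.neighbors(node)):
                    if nb not in seen and rng.random() < 0.8:
                        seen.add(nb)
                        members.append(nb)
                        nxt.append(nb)
                        if len(members) >= size:
                            break
                if len(members) >= size:
                    break
            frontier = nxt
        while len(members) < size:  # top up from random nodes
            cand = nodes[int(rng.integers(len(nodes)))]
            if cand not in seen:
                seen.add(cand)
                members.append(cand)
        pathways[f"PATHWAY_{p:02d}"] = set(members)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "network.tsv", "w") as fh:
            fh.write("source\ttarget\n")
            for u, v in sorted(g.edges()):
                fh.write(f"{u}\t{v}\n")
        with open(out / "pathways.gmt", "w") as fh:
            for name in sorted(pathways):
                genes = "\t".join(sorted(pathways[name]))
                fh.write(f"{name}\tsynthetic\t{genes}\n")
    return g, pathways


# ---------------------------------------------------------------------------
# Expression generator


def generate_expression(
    group1_ids: Sequence[str],
    group2_ids: Sequence[str],
    n_genes: int,
    planted: Mapping[str, float] | None = None,
    base_log2_mean: float = 5.0,
    sigma_log2: float = 0.5,
    seed: int = 0,
    out_dir=None,
) -> tuple[pd.DataFrame, TruthLedger]:
    """Gene x sample TPM matrix with planted log2 fold changes.

    Non-planted genes share one log-normal distribution (log2-space normal
    with mean ``base_log2_mean`` and sd ``sigma_log2``) across both groups;
    planted genes have their group-1 log2 mean shifted by the stated
    effect.  TPM values are 2**x, hence nonnegative.
    """
    g1 = list(group1_ids)
    g2 = list(group2_ids)
    if set(g1) & set(g2):
        raise ValueError("expression groups must be disjoint")
    planted = dict(planted or {})
    genes = [f"GENE{i:04d}" for i in range(n_genes)]
    for gname in planted:
        if gname not in genes:
            raise ValueError(f"planted gene {gname!r} outside generated gene list")
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    samples = g1 + g2
    log2x = rng.normal(base_log2_mean, sigma_log2, size=(n_genes, len(samples)))
    for gname, effect in planted.items():
        i = genes.index(gname)
        log2x[i, : len(g1)] += effect
    tpm = pd.DataFrame(np.power(2.0, log2x), index=genes, columns=samples)
    tpm.index.name = "gene"
    ledger = TruthLedger(
        seed=seed,
        planted_degs=[{"gene": g, "log2_effect": e} for g, e in sorted(planted.items())],
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        tpm.to_csv(out / "expression.tsv", sep="\t", float_format="%.6g")
        ledger.to_json(out / "expression_truth.json")
    return tpm, ledger
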
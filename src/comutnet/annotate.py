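"""Pathway, tissue and synthetic-lethality annotation of mutation pairs.

Pair annotation answers three questions for each significant pair: do the
two genes share a signaling pathway (by gene-set intersection, never by
pathway-name matching); in which tissues are double-mutant tumors
concentrated; and do mutually exclusive gene pairs overlap known
synthetic-lethality interactions more than expected.  A generic
hypergeometric gene-set over-representation test over GMT collections is
provided for subnetwork and DEG enrichment.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .cohort import BinaryCohortMatrix, MutationKey, SampleMeta
from .pairs import ContingencyTable, PairResult, bh_adjust, fisher_exact_two_sided

logger = logging.getLogger("comutnet")

UNANNOTATED = "unannotated"
SHARED = "shared"
NOT_SHARED = "not_shared"


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. KEGG pathways) with an optional universe."""

    sets: dict[str, set[str]]
    universe: set[str] | None = None

    def __post_init__(self) -> None:
        if self.universe is not None:
            for name, genes in self.sets.items():
                extra = genes - self.universe
                if extra:
                    raise ValueError(
                        f"gene set {name!r} has genes outside the universe: {sorted(extra)[:5]}"
                    )

    @property
    def annotated_genes(self) -> set[str]:
        out: set[str] = set()
        for genes in self.sets.values():
            out |= genes
        return out

    @classmethod
    def from_gmt(cls, path, universe: set[str] | None = None) -> "GeneSetCollection":
        sets = {}
        with open(path) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 3:
                    continue
                sets[parts[0]] = {g for g in parts[2:] if g}
        return cls(sets=sets, universe=universe)

    def to_gmt(self, path) -> None:
        with open(path, "w") as fh:
            for name in sorted(self.sets):
                fh.write(f"{name}\tna\t" + "\t".join(sorted(self.sets[name])) + "\n")


@dataclass(frozen=True)
class SLReference:
    """Known synthetic-lethality interactions as unordered gene pairs."""

    pairs: frozenset[frozenset[str]]

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "SLReference":
        out = set()
        for a, b in pairs:
            if a == b:
                raise ValueError(f"self-pair {a!r} in SL reference")
            out.add(frozenset((a, b)))
        return cls(pairs=frozenset(out))

    @classmethod
    def from_tsv(cls, path) -> "SLReference":
        frame = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
        return cls.from_pairs(zip(frame.iloc[:, 0], frame.iloc[:, 1]))

    def __contains__(self, pair: tuple[str, str] | frozenset) -> bool:
        return frozenset(pair) in self.pairs

    def __len__(self) -> int:
        return len(self.pairs)


# ---------------------------------------------------------------------------
# Pathway sharing


def shared_pathway(
    gene_a: str, gene_b: str, collection: GeneSetCollection
) -> tuple[str, list[str]]:
    """Pathways containing both genes, by set intersection.

    Returns (status, pathway names): status is ``"shared"`` when at least
    one pathway holds both genes, ``"not_shared"`` when both genes are
    annotated somewhere but never together, and ``"unannotated"`` when
    either gene is absent from every set (such pairs are excluded from
    shared/not-shared tallies).
    """
    annotated = collection.annotated_genes
    if gene_a not in annotated or gene_b not in annotated:
        return UNANNOTATED, []
    hits = sorted(
        name for name, genes in collection.sets.items()
        if gene_a in genes and gene_b in genes
    )
    return (SHARED if hits else NOT_SHARED), hits


def pathway_sharing_table(
    pairs: Sequence[PairResult], collection: GeneSetCollection
) -> pd.DataFrame:
    """Per-pair pathway-sharing status; statuses partition the pair list."""
    rows = []
    for r in pairs:
        status, hits = shared_pathway(r.key_a.gene, r.key_b.gene, collection)
        rows.append(
            {
                "key_a": r.key_a.render(),
                "key_b": r.key_b.render(),
                "composition": r.composition,
                "status": status,
                "shared_pathways": ";".join(hits),
            }
        )
    return pd.DataFrame(rows, columns=["key_a", "key_b", "composition", "status", "shared_pathways"])


# ---------------------------------------------------------------------------
# Tissue fractions


def tissue_fractions(
    pairs: Sequence[PairResult],
    matrix: BinaryCohortMatrix,
    metadata: Mapping[str, SampleMeta],
    mode: str = "all_tumors",
) -> pd.DataFrame:
    """Double-mutant fraction of each pair per tissue.

    Numerator: tumors in the tissue carrying both constituents.
    Denominator: all tumors in the tissue (``mode="all_tumors"``) or tumors
    carrying either constituent (``mode="either_carrier"``).  Tissues with
    a zero denominator yield a missing fraction.
    """
    if mode not in ("all_tumors", "either_carrier"):
        raise ValueError(f"unknown mode {mode!r}")
    tissue_of = np.array([metadata[s].tissue for s in matrix.samples])
    tissues = sorted(set(tissue_of))
    rows = []
    for r in pairs:
        ca = matrix.carriers(r.key_a)
        cb = matrix.carriers(r.key_b)
        both = ca & cb
        either = ca | cb
        for t in tissues:
            in_t = tissue_of == t
            num = int(np.sum(both & in_t))
            denom = int(np.sum(in_t)) if mode == "all_tumors" else int(np.sum(either & in_t))
            rows.append(
                {
                    "key_a": r.key_a.render(),
                    "key_b": r.key_b.render(),
                    "tissue": t,
                    "double_mutant": num,
                    "denominator": denom,
                    "fraction": (num / denom) if denom > 0 else math.nan,
                }
            )
    return pd.DataFrame(
        rows, columns=["key_a", "key_b", "tissue", "double_mutant", "denominator", "fraction"]
    )


def pathway_tissue_bubble(
    pairs: Sequence[PairResult],
    matrix: BinaryCohortMatrix,
    metadata: Mapping[str, SampleMeta],
    collection: GeneSetCollection,
) -> pd.DataFrame:
    """Double-mutant tumors per (pathway, tissue) bubble-plot table.

    A pair contributes to a pathway when at least one constituent gene
    belongs to it; the pathway's double-mutant tumors in a tissue are the
    union over contributing pairs.
    """
    tissue_of = np.array([metadata[s].tissue for s in matrix.samples])
    tissues = sorted(set(tissue_of))
    tissue_size = {t: int(np.sum(tissue_of == t)) for t in tissues}
    rows = []
    for name, genes in sorted(collection.sets.items()):
        union = np.zeros(matrix.n_samples, dtype=bool)
        contributing = 0
        for r in pairs:
            if r.key_a.gene in genes or r.key_b.gene in genes:
                union |= matrix.carriers(r.key_a) & matrix.carriers(r.key_b)
                contributing += 1
        if contributing == 0:
            continue
        for t in tissues:
            n_double = int(np.sum(union & (tissue_of == t)))
            rows.append(
                {
                    "pathway": name,
                    "tissue": t,
                    "double_mutant_tumors": n_double,
                    "tissue_tumors": tissue_size[t],
                    "rate": n_double / tissue_size[t] if tissue_size[t] else math.nan,
                    "n_pairs": contributing,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["pathway", "tissue", "double_mutant_tumors", "tissue_tumors", "rate", "n_pairs"],
    )


def pathway_tissue_filter(
    bubble_table: pd.DataFrame, min_tumors: int = 80, min_rate: float = 0.10
) -> pd.DataFrame:
    """Drop (pathway, tissue) rows with too few double mutants or too low a rate.

    Thresholds are read as "less than" cutoffs, so rows at exactly
    ``min_tumors`` / ``min_rate`` are retained.
    """
    keep = (bubble_table["double_mutant_tumors"] >= min_tumors) & (
        bubble_table["rate"] >= min_rate
    )
    return bubble_table[keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Synthetic-lethality overlap enrichment


def sl_enrichment(pairs: Sequence[PairResult], sl_reference: SLReference) -> pd.DataFrame:
    """Per-class enrichment of gene pairs in the SL reference.

    Mutation pairs are projected to unordered, deduplicated gene pairs;
    the universe is every gene pair appearing in the input.  For each pair
    class a 2x2 table {class vs rest} x {in reference vs not} gives an
    odds ratio and two-sided Fisher p.  The rounded overlap percentage is
    reported alongside the raw fraction.
    """
    gene_pairs: dict[frozenset[str], set[str]] = {}
    for r in pairs:
        gp = frozenset((r.key_a.gene, r.key_b.gene))
        gene_pairs.setdefault(gp, set()).add(r.pair_class)
    classes = sorted({c for cls_set in gene_pairs.values() for c in cls_set})
    rows = []
    for cls in classes:
        in_cls = [gp for gp, cset in gene_pairs.items() if cls in cset]
        rest = [gp for gp, cset in gene_pairs.items() if cls not in cset]
        if not in_cls:
            logger.warning("pair class %r empty in sl_enrichment", cls)
            continue
        a = sum(1 for gp in in_cls if gp in sl_reference.pairs)
        b = len(in_cls) - a
        c = sum(1 for gp in rest if gp in sl_reference.pairs)
        d = len(rest) - c
        orr, p = fisher_exact_two_sided(ContingencyTable(a, b, c, d))
        rows.append(
            {
                "pair_class": cls,
                "n_gene_pairs": len(in_cls),
                "overlap": a,
                "overlap_fraction": a / len(in_cls),
                "overlap_percent": round(100.0 * a / len(in_cls)),
                "odds_ratio": orr,
                "p": p,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["pair_class", "n_gene_pairs", "overlap", "overlap_fraction",
                 "overlap_percent", "odds_ratio", "p"],
    )


# ---------------------------------------------------------------------------
# Hypergeometric gene-set over-representation


def geneset_enrichment(
    query_genes: Iterable[str],
    collection: GeneSetCollection,
    universe: set[str] | None = None,
) -> pd.DataFrame:
    """Hypergeometric over-representation of a query against each gene set.

    p = P[overlap >= observed] drawing |query| genes from the universe
    (default: union of all set members); BH q across sets; sorted by q
    then p then set name.  Query genes outside the universe are dropped
    and logged.
    """
    if universe is None:
        universe = collection.universe or collection.annotated_genes
    query = set(query_genes)
    dropped = query - universe
    if dropped:
        logger.info("dropping %d query genes outside universe", len(dropped))
    query &= universe
    if not query:
        return pd.DataFrame(columns=["set", "set_size", "overlap", "p", "q"])
    M, n_query = len(universe), len(query)
    rows = []
    for name in sorted(collection.sets):
        members = collection.sets[name] & universe
        k = len(members & query)
        p = float(hypergeom.sf(k - 1, M, len(members), n_query))
        rows.append({"set": name, "set_size": len(members), "overlap": k, "p": p})
    frame = pd.DataFrame(rows)
    frame["q"] = bh_adjust(frame["p"].to_numpy())
    return frame.sort_values(["q", "p", "set"]).reset_index(drop=True)
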
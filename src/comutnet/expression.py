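"""Double- vs single-mutant differential expression.

Tumors carrying a significant co-existing mutation pair (e.g. a KRAS G12
hotspot together with any TP53 mutation) form the double-mutant group;
tumors carrying exactly one side form the single-mutant group.  Per gene:
log2 fold change of mean TPM between the groups, two-sided Mann-Whitney U
p-value, BH q across all tested genes, and up/down status at
|log2FC| > 0.5 and q < 0.05.  For heatmap-style output, z-scores are
computed per gene across the union of both groups with the population
(divide-by-n) standard deviation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .cohort import BinaryCohortMatrix, DataError, MutationKey, SampleMeta
from .pairs import CO_EXISTING, PairResult, bh_adjust

logger = logging.getLogger("comutnet")

DEFAULT_FC_CUT = 0.5
DEFAULT_Q_CUT = 0.05
DEFAULT_PSEUDOCOUNT = 0.01

UP = "up"
DOWN = "down"
NS = "ns"


def read_expression(path) -> pd.DataFrame:
    """Read a gene x sample TPM matrix (TSV, genes as rows)."""
    matrix = pd.read_csv(path, sep="\t", index_col=0)
    if (matrix.to_numpy() < 0).any():
        raise DataError("TPM values must be nonnegative")
    if matrix.columns.duplicated().any():
        raise DataError("duplicate sample ids in expression matrix")
    return matrix


@dataclass(frozen=True)
class PairPattern:
    """Anchor mutations plus a partner gene defining the double-mutant group.

    e.g. anchor = {KRAS:G12D, KRAS:G12V, KRAS:G12C}, partner gene TP53.
    """

    anchor: frozenset[MutationKey]
    partner_gene: str


def assign_groups(
    pairs: Sequence[PairResult],
    matrix: BinaryCohortMatrix,
    pattern: PairPattern,
) -> tuple[list[str], list[str]]:
    """Split tumors into double-mutant (group 1) and single-mutant (group 2).

    Group 1: tumors carrying an anchor mutation and a partner-gene mutation
    that together form a reported significant co-existing pair.  Group 2:
    tumors carrying exactly one side, or an anchor + partner combination
    that was not reported significant.  Tumors with neither are excluded.
    """
    anchors = [k for k in pattern.anchor if k in matrix]
    partner_keys = [k for k in matrix.mutations if k.gene == pattern.partner_gene]
    if not anchors or not partner_keys:
        raise DataError("pattern mutations absent from cohort matrix")
    significant = {
        frozenset((r.key_a, r.key_b))
        for r in pairs
        if r.pair_class == CO_EXISTING
    }
    any_anchor = np.zeros(matrix.n_samples, dtype=bool)
    for k in anchors:
        any_anchor |= matrix.carriers(k)
    any_partner = np.zeros(matrix.n_samples, dtype=bool)
    for k in partner_keys:
        any_partner |= matrix.carriers(k)
    double = np.zeros(matrix.n_samples, dtype=bool)
    for ka in anchors:
        for kb in partner_keys:
            if frozenset((ka, kb)) in significant:
                double |= matrix.carriers(ka) & matrix.carriers(kb)
    single = (any_anchor ^ any_partner) | (any_anchor & any_partner & ~double)
    group1 = [s for s, m in zip(matrix.samples, double) if m]
    group2 = [s for s, m in zip(matrix.samples, single) if m]
    if not group1 or not group2:
        raise DataError("empty double- or single-mutant group")
    return group1, group2


def log2_fold_change(
    matrix: pd.DataFrame,
    group1: Sequence[str],
    group2: Sequence[str],
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.Series:
    """Per-gene log2(mean TPM in group1 / mean TPM in group2).

    The pseudocount is added to both means only when either is zero; with
    pseudocount 0 and both means zero the value is missing.
    """
    g1 = list(group1)
    g2 = list(group2)
    if not g1 or not g2:
        raise DataError("groups must be nonempty")
    if set(g1) & set(g2):
        raise DataError("groups must be disjoint")
    m1 = matrix[g1].mean(axis=1).to_numpy(dtype=float)
    m2 = matrix[g2].mean(axis=1).to_numpy(dtype=float)
    zeroish = (m1 == 0) | (m2 == 0)
    num = np.where(zeroish, m1 + pseudocount, m1)
    den = np.where(zeroish, m2 + pseudocount, m2)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = np.log2(num / den)
    fc = np.where((num == 0) & (den == 0), np.nan, fc)
    return pd.Series(fc, index=matrix.index, name="log2fc")


def differential_expression(
    matrix: pd.DataFrame,
    group1: Sequence[str],
    group2: Sequence[str],
    fc_cut: float = DEFAULT_FC_CUT,
    q_cut: float = DEFAULT_Q_CUT,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    min_group_size: int = 3,
) -> pd.DataFrame:
    """Mann-Whitney + BH differential expression between two tumor groups.

    Returns one row per gene: means, log2fc, p, q and status (``up`` iff
    log2fc > fc_cut and q < q_cut, ``down`` symmetric, else ``ns``).
    Genes constant across all samples get p = 1 and a flag.
    """
    g1 = list(group1)
    g2 = list(group2)
    if len(g1) < min_group_size or len(g2) < min_group_size:
        raise DataError(f"each group needs >= {min_group_size} samples")
    x1 = matrix[g1].to_numpy(dtype=float)
    x2 = matrix[g2].to_numpy(dtype=float)
    constant = np.array([
        np.unique(np.concatenate([a, b])).size == 1 for a, b in zip(x1, x2)
    ])
    pvals = np.ones(len(matrix))
    if (~constant).any():
        res = mannwhitneyu(
            x1[~constant], x2[~constant], alternative="two-sided", axis=1,
            method="auto",
        )
        pvals[~constant] = res.pvalue
    if constant.any():
        logger.info("%d constant genes given p = 1", int(constant.sum()))
    qvals = bh_adjust(pvals)
    fc = log2_fold_change(matrix, g1, g2, pseudocount=pseudocount)
    status = np.where(
        (fc > fc_cut) & (qvals < q_cut), UP,
        np.where((fc < -fc_cut) & (qvals < q_cut), DOWN, NS),
    )
    return pd.DataFrame(
        {
            "gene": matrix.index,
            "mean_group1": x1.mean(axis=1),
            "mean_group2": x2.mean(axis=1),
            "log2fc": fc.to_numpy(),
            "p": pvals,
            "q": qvals,
            "status": status,
            "constant": constant,
        }
    ).set_index("gene")


def zscore_matrix(
    matrix: pd.DataFrame,
    genes: Sequence[str],
    group1: Sequence[str],
    group2: Sequence[str],
) -> pd.DataFrame:
    """Per-gene z-scores across the union of both groups.

    z = (TPM - mu) / sigma with the population (divide-by-n) standard
    deviation over group1 + group2; zero-variance genes are dropped and
    logged.  Output metadata: rows mean 0, sd 1 by construction.
    """
    samples = list(group1) + list(group2)
    sub = matrix.loc[list(genes), samples].to_numpy(dtype=float)
    mu = sub.mean(axis=1, keepdims=True)
    sigma = sub.std(axis=1, ddof=0, keepdims=True)
    keep = sigma.ravel() > 0
    if (~keep).any():
        logger.info("dropping %d zero-variance genes from z-score output", int((~keep).sum()))
    z = (sub[keep] - mu[keep]) / sigma[keep]
    return pd.DataFrame(z, index=np.asarray(genes)[keep], columns=samples)
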
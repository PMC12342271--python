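"""Mining of co-existing and mutually exclusive mutation pairs.

Every unordered cross-gene pair of recurrent mutations is tested on a 2x2
contingency table (both / only first / only second / neither) with a
two-sided Fisher exact test; p-values are Benjamini-Hochberg adjusted
across all tested pairs; significant pairs (q below a threshold, default
0.3) are classified as co-existing (odds ratio > 1, with at least three
joint carriers) or excluded (odds ratio < 1 — pairs with zero joint
carriers are deliberately retained and tested).  Pair constituents are
labelled driver (D) or passenger (P) against a catalog of validated
oncogenic mutations, giving the pair a composition D+D, D+P or P+P.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .cohort import BinaryCohortMatrix, DriverCatalog, MutationKey, label_driver

DEFAULT_Q_THRESHOLD = 0.3
DEFAULT_MIN_JOINT = 3

CO_EXISTING = "co-existing"
EXCLUDED = "excluded"
NEUTRAL = "neutral"


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 joint-presence counts for a mutation pair.

    a: tumors with both mutations; b: only the first; c: only the second;
    d: neither.  ``n_total`` is the cohort size (a+b+c+d).
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be nonnegative")

    @property
    def n_total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)


def odds_ratio(table: ContingencyTable) -> float:
    """Sample odds ratio a*d/(b*c); +inf if b*c=0 with a*d>0, NaN if both 0."""
    ad = table.a * table.d
    bc = table.b * table.c
    if bc == 0:
        return math.inf if ad > 0 else math.nan
    return ad / bc


# ---------------------------------------------------------------------------
# Fisher's exact test (two-sided)
#
# Implemented via the log hypergeometric pmf so that hundreds of thousands
# of tables per cohort can be tested quickly; the two-sided p-value sums
# all outcomes (at fixed margins) whose probability does not exceed the
# observed one, with the conventional 1+1e-7 relative gate.

_REL_GATE = 1.0 + 1e-7


def _support_log_pmf(r1: int, r2: int, c1: int) -> tuple[np.ndarray, np.ndarray]:
    n = r1 + r2
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    ks = np.arange(lo, hi + 1)
    lp = (
        gammaln(r1 + 1) - gammaln(ks + 1) - gammaln(r1 - ks + 1)
        + gammaln(r2 + 1) - gammaln(c1 - ks + 1) - gammaln(r2 - c1 + ks + 1)
        - (gammaln(n + 1) - gammaln(c1 + 1) - gammaln(n - c1 + 1))
    )
    return ks, lp


def fisher_exact_two_sided(table: ContingencyTable) -> tuple[float, float]:
    """Two-sided Fisher exact test; returns (odds_ratio, p_value).

    The p-value is the sum of hypergeometric probabilities, at the observed
    margins, of every table at least as extreme (probability <= observed).
    """
    ks, lp = _support_log_pmf(table.a + table.b, table.c + table.d, table.a + table.c)
    obs = lp[ks == table.a][0]
    p = float(np.exp(lp[np.exp(lp) <= np.exp(obs) * _REL_GATE]).sum())
    return odds_ratio(table), min(p, 1.0)


def fisher_exact_batch(tables: np.ndarray) -> np.ndarray:
    """Vectorized two-sided Fisher p-values for an (n, 4) array of a,b,c,d."""
    tables = np.asarray(tables, dtype=np.int64)
    out = np.empty(len(tables))
    for i, (a, b, c, d) in enumerate(tables):
        ks, lp = _support_log_pmf(a + b, c + d, a + c)
        obs = lp[ks == a][0]
        pm = np.exp(lp)
        out[i] = min(float(pm[pm <= math.exp(obs) * _REL_GATE].sum()), 1.0)
    return out


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving with input."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


# ---------------------------------------------------------------------------
# Pair enumeration and results


@dataclass(frozen=True)
class PairResult:
    """One tested mutation pair with its statistics and classification."""

    key_a: MutationKey
    key_b: MutationKey
    table: ContingencyTable
    odds_ratio: float
    p_value: float
    q_value: float = math.nan
    pair_class: str = NEUTRAL
    composition: str = ""

    def __post_init__(self) -> None:
        if self.key_a.gene == self.key_b.gene:
            raise ValueError("pair constituents must be in different genes")

    def constituents_by_frequency(self) -> tuple[MutationKey, MutationKey]:
        """(lower-frequency constituent, higher-frequency constituent)."""
        fa = self.table.a + self.table.b
        fb = self.table.a + self.table.c
        return (self.key_a, self.key_b) if fa <= fb else (self.key_b, self.key_a)


def enumerate_candidates(matrix: BinaryCohortMatrix) -> list[tuple[MutationKey, MutationKey]]:
    """All unordered cross-gene mutation pairs, lexicographically canonical."""
    keys = sorted(matrix.mutations)
    pairs = []
    for i in range(len(keys)):
        for j in range(i + 1, len(keys)):
            if keys[i].gene != keys[j].gene:
                pairs.append((keys[i], keys[j]))
    return pairs


def build_table(
    matrix: BinaryCohortMatrix, key_a: MutationKey, key_b: MutationKey
) -> ContingencyTable:
    """Joint-presence 2x2 table for one pair over the whole cohort."""
    ca = matrix.carriers(key_a)
    cb = matrix.carriers(key_b)
    a = int(np.sum(ca & cb))
    b = int(np.sum(ca & ~cb))
    c = int(np.sum(~ca & cb))
    d = matrix.n_samples - (a + b + c)
    return ContingencyTable(a, b, c, d)


def classify_pair(
    result: PairResult,
    q_threshold: float = DEFAULT_Q_THRESHOLD,
    min_joint: int = DEFAULT_MIN_JOINT,
) -> str:
    """Classify a tested pair: co-existing, excluded, or neutral.

    Significance requires q < q_threshold.  Among significant pairs,
    co-existing needs OR > 1 and at least ``min_joint`` joint carriers;
    excluded needs OR < 1 (zero joint carriers allowed); OR exactly 1 (or
    undefined) is neutral.  Non-significant pairs are neutral and not
    reported downstream.
    """
    if not (result.q_value < q_threshold):
        return NEUTRAL
    orr = result.odds_ratio
    if math.isnan(orr) or orr == 1.0:
        return NEUTRAL
    if orr > 1.0:
        return CO_EXISTING if result.table.a >= min_joint else NEUTRAL
    return EXCLUDED


def composition(key_a: MutationKey, key_b: MutationKey, catalog: DriverCatalog) -> str:
    """Unordered driver/passenger composition: D+D, D+P or P+P."""
    labels = sorted((label_driver(key_a, catalog), label_driver(key_b, catalog)))
    return f"{labels[0]}+{labels[1]}"


def mine_pairs(
    matrix: BinaryCohortMatrix,
    catalog: DriverCatalog | None = None,
    q_threshold: float = DEFAULT_Q_THRESHOLD,
    min_joint: int = DEFAULT_MIN_JOINT,
    significant_only: bool = True,
) -> list[PairResult]:
    """Full pair-mining pass over a filtered cohort matrix.

    Enumerates cross-gene pairs, tests each table, BH-adjusts across all
    tested pairs, classifies, and (by default) returns only significant
    pairs, sorted by (q, p, keys).
    """
    cands = enumerate_candidates(matrix)
    if not cands:
        return []
    X = matrix.cells.astype(np.int64)
    counts = X.sum(axis=0)
    joint = X.T @ X  # co-occurrence counts per key pair
    n = matrix.n_samples
    kidx = {k: j for j, k in enumerate(matrix.mutations)}

    tables = np.empty((len(cands), 4), dtype=np.int64)
    for i, (ka, kb) in enumerate(cands):
        ja, jb = kidx[ka], kidx[kb]
        a = joint[ja, jb]
        b = counts[ja] - a
        c = counts[jb] - a
        tables[i] = (a, b, c, n - a - b - c)
    pvals = fisher_exact_batch(tables)
    qvals = bh_adjust(pvals)

    results = []
    for i, (ka, kb) in enumerate(cands):
        tab = ContingencyTable(*map(int, tables[i]))
        res = PairResult(
            key_a=ka,
            key_b=kb,
            table=tab,
            odds_ratio=odds_ratio(tab),
            p_value=float(pvals[i]),
            q_value=float(qvals[i]),
        )
        cls = classify_pair(res, q_threshold=q_threshold, min_joint=min_joint)
        comp = composition(ka, kb, catalog) if catalog is not None else ""
        res = replace(res, pair_class=cls, composition=comp)
        if significant_only and cls == NEUTRAL:
            continue
        results.append(res)
    results.sort(key=lambda r: (r.q_value, r.p_value, r.key_a, r.key_b))
    return results


def summarize_pairs(results: Iterable[PairResult]) -> pd.DataFrame:
    """Tally pair counts by class and composition (Fig-2-style summary).

    Returns a table with one row per (pair_class, composition) plus row,
    column and grand totals under the label ``"total"``.
    """
    rows = [(r.pair_class, r.composition or "unlabelled") for r in results]
    frame = pd.DataFrame(rows, columns=["pair_class", "composition"])
    tally = (
        frame.groupby(["pair_class", "composition"]).size().rename("n").reset_index()
    )
    by_class = frame.groupby("pair_class").size().rename("n").reset_index()
    by_class["composition"] = "total"
    by_comp = frame.groupby("composition").size().rename("n").reset_index()
    by_comp["pair_class"] = "total"
    grand = pd.DataFrame(
        [{"pair_class": "total", "composition": "total", "n": len(frame)}]
    )
    out = pd.concat([tally, by_class, by_comp, grand], ignore_index=True)
    return out[["pair_class", "composition", "n"]]


def results_to_frame(results: Iterable[PairResult]) -> pd.DataFrame:
    """Flatten results to the output-table schema (one pair per row)."""
    rows = []
    for r in results:
        lo, hi = r.constituents_by_frequency()
        rows.append(
            {
                "key_a": r.key_a.render(),
                "key_b": r.key_b.render(),
                "a": r.table.a,
                "b": r.table.b,
                "c": r.table.c,
                "d": r.table.d,
                "odds_ratio": r.odds_ratio,
                "p": r.p_value,
                "q": r.q_value,
                "pair_class": r.pair_class,
                "composition": r.composition,
                "constituent1": lo.render(),
                "constituent2": hi.render(),
                "freq1": r.table.a + (r.table.b if lo == r.key_a else r.table.c),
                "freq2": r.table.a + (r.table.c if lo == r.key_a else r.table.b),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "key_a", "key_b", "a", "b", "c", "d", "odds_ratio", "p", "q",
            "pair_class", "composition", "constituent1", "constituent2",
            "freq1", "freq2",
        ],
    )


def write_pairs_tsv(results: Iterable[PairResult], path) -> None:
    results_to_frame(results).to_csv(path, sep="\t", index=False, float_format="%.8g")
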
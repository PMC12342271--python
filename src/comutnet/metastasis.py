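"""Metastatic marker discovery by frequent-pattern mining.

Each tumor is a transaction whose items are its (position-level) mutation
keys.  FP-growth enumerates itemsets above a support threshold without
candidate generation; association rules above a confidence threshold are
assembled into a marker tree rooted at a null node, where every root-to-
node path is a set of mutually associated alterations.  Each marker's
tendency to occur in metastatic tumors is quantified by the propensity
statistic

    propensity(i) = (x_i / N_i) / (X / N)

(the marker's metastatic fraction over the cohort's metastatic fraction),
and each alteration pair in a cohort gets a 2x2 odds ratio, Fisher exact p
and continuity-corrected chi-square for volcano/bubble outputs.
"""

from __future__ import annotations

import itertools
import json
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .cohort import BinaryCohortMatrix, MutationKey, SampleMeta
from .pairs import ContingencyTable, fisher_exact_batch, odds_ratio

logger = logging.getLogger("comutnet")

NULL_ROOT = "null"

STRONG_COOCCURRING = "strong_cooccurring"
STRONG_EXCLUSIVE = "strong_exclusive"
WEAK = "weak"

DEFAULT_OR_LOG_THRESHOLD = 0.75
DEFAULT_P_LOG_THRESHOLD = 1.65


@dataclass
class TransactionDB:
    """Per-tumor alteration itemsets with cohort labels."""

    transactions: dict[str, frozenset[str]]
    metadata: Mapping[str, SampleMeta] | None = None

    def __post_init__(self) -> None:
        if self.metadata is not None:
            missing = [t for t in self.transactions if t not in self.metadata]
            if missing:
                raise ValueError(f"tumors missing from metadata: {missing[:5]}")

    def __len__(self) -> int:
        return len(self.transactions)

    @classmethod
    def from_matrix(
        cls,
        matrix: BinaryCohortMatrix,
        metadata: Mapping[str, SampleMeta] | None = None,
        drop_empty: bool = False,
    ) -> "TransactionDB":
        items = [k.render() for k in matrix.mutations]
        transactions = {}
        for i, sid in enumerate(matrix.samples):
            carried = frozenset(
                items[j] for j in np.nonzero(matrix.cells[i])[0]
            )
            if carried or not drop_empty:
                transactions[sid] = carried
        return cls(transactions=transactions, metadata=metadata)


@dataclass(frozen=True)
class AssociationRule:
    """antecedent => consequent with support (of the union) and confidence."""

    antecedent: frozenset[str]
    consequent: frozenset[str]
    support: float
    confidence: float

    def __post_init__(self) -> None:
        if self.antecedent & self.consequent:
            raise ValueError("antecedent and consequent must be disjoint")
        if not (0 <= self.support <= 1 and 0 <= self.confidence <= 1):
            raise ValueError("support and confidence must lie in [0, 1]")


# ---------------------------------------------------------------------------
# FP-growth


class _FPNode:
    __slots__ = ("item", "count", "parent", "children")

    def __init__(self, item: str | None, parent: "_FPNode | None"):
        self.item = item
        self.count = 0
        self.parent = parent
        self.children: dict[str, _FPNode] = {}


def _build_fp_tree(
    transactions: Iterable[tuple[tuple[str, ...], int]],
    min_count: int,
) -> tuple[_FPNode, dict[str, list[_FPNode]], dict[str, int]]:
    counts: dict[str, int] = {}
    cached = []
    for items, weight in transactions:
        cached.append((items, weight))
        for it in items:
            counts[it] = counts.get(it, 0) + weight
    frequent = {it: c for it, c in counts.items() if c >= min_count}
    # insertion order: count desc, then item asc — canonical and deterministic
    order = {it: rank for rank, it in enumerate(
        sorted(frequent, key=lambda it: (-frequent[it], it))
    )}
    root = _FPNode(None, None)
    links: dict[str, list[_FPNode]] = {it: [] for it in frequent}
    for items, weight in cached:
        path = sorted((it for it in items if it in frequent), key=order.__getitem__)
        node = root
        for it in path:
            child = node.children.get(it)
            if child is None:
                child = _FPNode(it, node)
                node.children[it] = child
                links[it].append(child)
            child.count += weight
            node = child
    return root, links, frequent


def _mine_fp_tree(
    links: dict[str, list[_FPNode]],
    frequent: dict[str, int],
    suffix: frozenset[str],
    min_count: int,
    out: dict[frozenset[str], int],
) -> None:
    for item in sorted(frequent, key=lambda it: (frequent[it], it)):
        itemset = suffix | {item}
        out[itemset] = frequent[item]
        # conditional pattern base: prefix paths of every node carrying `item`
        conditional = []
        for node in links[item]:
            path = []
            parent = node.parent
            while parent is not None and parent.item is not None:
                path.append(parent.item)
                parent = parent.parent
            if path:
                conditional.append((tuple(reversed(path)), node.count))
        if conditional:
            _, sub_links, sub_frequent = _build_fp_tree(conditional, min_count)
            if sub_frequent:
                _mine_fp_tree(sub_links, sub_frequent, itemset, min_count, out)


def fp_growth(db: TransactionDB, min_support: float) -> list[tuple[frozenset[str], float]]:
    """All itemsets with support >= ``min_support`` and their exact supports.

    Output is deterministic: support descending, then the lexicographically
    sorted itemset.
    """
    if not (0 < min_support <= 1):
        raise ValueError("min_support must lie in (0, 1]")
    n = len(db)
    if n == 0:
        return []
    min_count = max(1, math.ceil(min_support * n - 1e-9))
    transactions = [(tuple(sorted(t)), 1) for t in db.transactions.values()]
    _, links, frequent = _build_fp_tree(transactions, min_count)
    mined: dict[frozenset[str], int] = {}
    if frequent:
        _mine_fp_tree(links, frequent, frozenset(), min_count, mined)
    out = [(s, c / n) for s, c in mined.items()]
    out.sort(key=lambda pair: (-pair[1], tuple(sorted(pair[0]))))
    return out


# ---------------------------------------------------------------------------
# Association rules


def association_rules(
    itemsets: Sequence[tuple[frozenset[str], float]],
    db: TransactionDB,
    min_confidence: float,
) -> list[AssociationRule]:
    """Rules A => C from frequent itemsets with confidence >= threshold.

    confidence(A => C) = support(A u C) / support(A); antecedent supports
    come from the frequent-itemset list (every subset of a frequent set is
    frequent, so they are always available).
    """
    support = {s: sup for s, sup in itemsets}
    rules = []
    for itemset, sup in itemsets:
        if len(itemset) < 2:
            continue
        items = sorted(itemset)
        for r in range(1, len(items)):
            for ante in itertools.combinations(items, r):
                ante_set = frozenset(ante)
                ante_sup = support.get(ante_set)
                if ante_sup is None or ante_sup == 0:
                    continue
                conf = sup / ante_sup
                if conf >= min_confidence:
                    rules.append(
                        AssociationRule(
                            antecedent=ante_set,
                            consequent=itemset - ante_set,
                            support=sup,
                            confidence=min(conf, 1.0),
                        )
                    )
    rules.sort(
        key=lambda r: (-r.confidence, -r.support, tuple(sorted(r.antecedent)),
                       tuple(sorted(r.consequent)))
    )
    return rules


# ---------------------------------------------------------------------------
# Marker tree


@dataclass
class MarkerTree:
    """Prefix tree of associated alterations rooted at a null node.

    ``nodes`` maps a node id (path-joined item names) to its item and
    frequency; ``edges`` carry the confidence of the prefix rule that
    justified the extension.  Acyclic by construction.
    """

    nodes: dict[str, dict] = field(default_factory=dict)
    edges: list[dict] = field(default_factory=list)
    root: str = NULL_ROOT

    def children(self, node_id: str) -> list[str]:
        return [e["target"] for e in self.edges if e["source"] == node_id]

    def depth(self, node_id: str) -> int:
        if node_id == self.root:
            return 0
        return len(node_id.split("|"))

    def paths(self) -> list[tuple[str, ...]]:
        """All root-to-leaf item paths."""
        out = []
        children = {}
        for e in self.edges:
            children.setdefault(e["source"], []).append(e["target"])

        def walk(node_id: str, acc: tuple[str, ...]):
            kids = children.get(node_id, [])
            if not kids:
                if acc:
                    out.append(acc)
                return
            for kid in sorted(kids):
                walk(kid, acc + (self.nodes[kid]["item"],))

        walk(self.root, ())
        return out

    def to_json(self, path) -> None:
        payload = {
            "root": self.root,
            "nodes": [
                {"id": nid, **info} for nid, info in sorted(self.nodes.items())
            ],
            "edges": self.edges,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)

    def to_dot(self, path=None) -> str:
        lines = ["digraph marker_tree {", f'  "{self.root}" [shape=point];']
        for nid, info in sorted(self.nodes.items()):
            lines.append(
                f'  "{nid}" [label="{info["item"]}\\n{info["frequency"]:.4g}"];'
            )
        for e in self.edges:
            lines.append(
                f'  "{e["source"]}" -> "{e["target"]}" [label="{e["confidence"]:.3g}"];'
            )
        lines.append("}")
        text = "\n".join(lines) + "\n"
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def build_marker_tree(
    rules: Sequence[AssociationRule],
    itemsets: Sequence[tuple[frozenset[str], float]] | None = None,
    min_confidence: float = 0.0,
    prune_root_pairs: bool = True,
) -> MarkerTree:
    """Assemble associated-alteration chains into a prefix tree.

    A path root-A-B-C exists only when every prefix rule ({A} => B,
    {A,B} => C, ...) meets the confidence threshold; within a path, items
    are ordered by support (ancestral = more frequent).  With
    ``prune_root_pairs``, branches that contain only direct pairs hanging
    off the null root (depth <= 2 subtrees) are removed, as are childless
    depth-1 nodes.

    Rules are consumed highest-confidence first, which also breaks any
    directionality conflicts deterministically.
    """
    support: dict[frozenset[str], float] = {}
    if itemsets:
        support.update({s: sup for s, sup in itemsets})
    for r in rules:
        support.setdefault(r.antecedent | r.consequent, r.support)

    # index rules by (antecedent, single consequent item) keeping best confidence
    conf_of: dict[tuple[frozenset[str], str], float] = {}
    for r in sorted(rules, key=lambda r: -r.confidence):
        for item in r.consequent:
            key = (r.antecedent, item)
            if key not in conf_of:
                conf_of[key] = r.confidence

    def item_support(item: str) -> float:
        sup = support.get(frozenset((item,)), math.nan)
        return 0.0 if math.isnan(sup) else sup

    tree = MarkerTree()
    full_sets = sorted(
        {r.antecedent | r.consequent for r in rules},
        key=lambda s: (len(s), tuple(sorted(s))),
    )
    for itemset in full_sets:
        # order by item support desc (then name) -> ancestral first
        chain = sorted(itemset, key=lambda it: (-item_support(it), it))
        ok = True
        confs = []
        for k in range(1, len(chain)):
            prefix = frozenset(chain[:k])
            conf = conf_of.get((prefix, chain[k]))
            if conf is None or conf < min_confidence:
                ok = False
                break
            confs.append(conf)
        if not ok:
            continue
        parent_id = tree.root
        for k, item in enumerate(chain):
            node_id = "|".join(chain[: k + 1])
            if node_id not in tree.nodes:
                tree.nodes[node_id] = {
                    "item": item,
                    "frequency": item_support(item),
                }
                tree.edges.append(
                    {
                        "source": parent_id,
                        "target": node_id,
                        "confidence": confs[k - 1] if k > 0 else 1.0,
                    }
                )
            parent_id = node_id

    if prune_root_pairs:
        _prune_root_pairs(tree)
    return tree


def _prune_root_pairs(tree: MarkerTree) -> None:
    """Drop root-attached branches whose subtree holds only direct pairs."""
    children: dict[str, list[str]] = {}
    for e in tree.edges:
        children.setdefault(e["source"], []).append(e["target"])

    def subtree_depth(node_id: str) -> int:
        kids = children.get(node_id, [])
        if not kids:
            return 1
        return 1 + max(subtree_depth(k) for k in kids)

    doomed: set[str] = set()

    def collect(node_id: str) -> None:
        doomed.add(node_id)
        for k in children.get(node_id, []):
            collect(k)

    for top in children.get(tree.root, []):
        if subtree_depth(top) <= 2:
            collect(top)
    if doomed:
        tree.nodes = {nid: v for nid, v in tree.nodes.items() if nid not in doomed}
        tree.edges = [
            e for e in tree.edges
            if e["source"] not in doomed and e["target"] not in doomed
        ]
        logger.info("pruned %d nodes in root-pair-only branches", len(doomed))


# ---------------------------------------------------------------------------
# Propensity and cohort statistics


def propensity(x_i: int, n_i: int, x_total: int, n_total: int) -> float:
    """Metastatic propensity (x_i/N_i)/(X/N) of an alteration (set)."""
    if not (0 <= x_i <= n_i <= n_total and x_i <= x_total <= n_total):
        raise ValueError("invalid propensity counts")
    if n_i == 0 or x_total == 0:
        raise ValueError("propensity undefined for N_i = 0 or X = 0")
    return (x_i / n_i) / (x_total / n_total)


def cohort_pair_stats(
    matrix_subset: BinaryCohortMatrix,
    min_joint_for_plot: int = 3,
    continuity_correction: bool = True,
) -> pd.DataFrame:
    """Pairwise 2x2 statistics over all unique alterations of a cohort.

    For each unordered alteration pair: joint-state counts a,b,c,d, odds
    ratio (ad/bc with the usual zero-cell conventions), two-sided Fisher
    p, and continuity-corrected chi-square (missing for degenerate
    margins).  ``in_plot`` flags pairs with at least ``min_joint_for_plot``
    joint carriers for volcano/bubble outputs.
    """
    keys = list(matrix_subset.mutations)
    n = matrix_subset.n_samples
    X = matrix_subset.cells.astype(np.int64)
    counts = X.sum(axis=0)
    joint = X.T @ X
    combos = list(itertools.combinations(range(len(keys)), 2))
    tables = np.empty((len(combos), 4), dtype=np.int64)
    for idx, (i, j) in enumerate(combos):
        a = joint[i, j]
        tables[idx] = (a, counts[i] - a, counts[j] - a, n - counts[i] - counts[j] + a)
    pvals = fisher_exact_batch(tables) if len(combos) else np.empty(0)
    rows = []
    for idx, (i, j) in enumerate(combos):
        a, b, c, d = map(int, tables[idx])
        tab = ContingencyTable(a, b, c, d)
        arr = tab.as_array()
        if arr.sum(axis=0).min() == 0 or arr.sum(axis=1).min() == 0:
            chi2_stat, chi2_p = math.nan, math.nan
        else:
            chi2_stat, chi2_p, _, _ = chi2_contingency(
                arr, correction=continuity_correction
            )
        rows.append(
            {
                "key_a": keys[i].render(),
                "key_b": keys[j].render(),
                "a": a, "b": b, "c": c, "d": d,
                "odds_ratio": odds_ratio(tab),
                "fisher_p": float(pvals[idx]),
                "chi2": chi2_stat,
                "chi2_p": chi2_p,
                "in_plot": a >= min_joint_for_plot,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["key_a", "key_b", "a", "b", "c", "d", "odds_ratio",
                 "fisher_p", "chi2", "chi2_p", "in_plot"],
    )


def volcano_classify(
    odds_ratio_value: float,
    p_value: float,
    or_log_threshold: float = DEFAULT_OR_LOG_THRESHOLD,
    p_log_threshold: float = DEFAULT_P_LOG_THRESHOLD,
    table: ContingencyTable | None = None,
) -> tuple[str, bool]:
    """Volcano-plot class of a pair: strong co-occurring / exclusive / weak.

    Strong requires both |log10(OR)| > ``or_log_threshold`` and
    -log10(p) > ``p_log_threshold``; the sign of log10(OR) picks the
    direction.  A zero or infinite OR is replaced by the Haldane 0.5
    continuity-corrected OR computed from ``table`` (flagged in the second
    return value); without a table such pairs are classified weak.
    """
    corrected = False
    orr = odds_ratio_value
    if not (math.isfinite(orr) and orr > 0):
        if table is None:
            return WEAK, False
        orr = ((table.a + 0.5) * (table.d + 0.5)) / ((table.b + 0.5) * (table.c + 0.5))
        corrected = True
    log_or = math.log10(orr)
    neg_log_p = -math.log10(p_value) if p_value > 0 else math.inf
    if abs(log_or) > or_log_threshold and neg_log_p > p_log_threshold:
        return (STRONG_COOCCURRING if log_or > 0 else STRONG_EXCLUSIVE), corrected
    return WEAK, corrected


def pair_frequency_comparison(
    matrix: BinaryCohortMatrix,
    metadata: Mapping[str, SampleMeta],
    pairs: Sequence[tuple[MutationKey, MutationKey]] | None = None,
) -> pd.DataFrame:
    """Primary vs metastatic occurrence of each alteration pair.

    Per pair: carrier counts and fractions in primary and metastatic
    tumors, plus the metastatic propensity of the pair.  Pairs with no
    carriers get a missing propensity.
    """
    met_mask = np.array(
        [metadata[s].sample_type == "metastatic" for s in matrix.samples]
    )
    n_total = matrix.n_samples
    x_total = int(met_mask.sum())
    if pairs is None:
        keys = list(matrix.mutations)
        pairs = [
            (keys[i], keys[j])
            for i, j in itertools.combinations(range(len(keys)), 2)
        ]
    rows = []
    for ka, kb in pairs:
        both = matrix.carriers(ka) & matrix.carriers(kb)
        n_i = int(both.sum())
        x_i = int(np.sum(both & met_mask))
        prim = n_i - x_i
        n_primary = n_total - x_total
        rows.append(
            {
                "key_a": ka.render(),
                "key_b": kb.render(),
                "n_carriers": n_i,
                "metastatic_carriers": x_i,
                "primary_carriers": prim,
                "metastatic_fraction": x_i / x_total if x_total else math.nan,
                "primary_fraction": prim / n_primary if n_primary else math.nan,
                "propensity": (
                    propensity(x_i, n_i, x_total, n_total)
                    if n_i > 0 and x_total > 0
                    else math.nan
                ),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["key_a", "key_b", "n_carriers", "metastatic_carriers",
                 "primary_carriers", "metastatic_fraction", "primary_fraction",
                 "propensity"],
    )
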
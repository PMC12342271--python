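"""Mutation-cohort data model and I/O.

A cohort is a set of tumor samples, each carrying protein-level somatic
mutations identified by ``GENE:change`` keys (e.g. ``KRAS:G12D``).  The
module parses MAF-like tab-separated tables, applies the standard quality
filters (variant allele frequency, recurrence among non-hypermutated
samples), and binarizes the result into a sample x mutation presence
matrix that every downstream stage consumes.

Mutation identity is exact-level (``KRAS:G12D``) by default; collapsing to
residue-position level (``KRAS:G12``) is an explicit transformation used by
the metastasis-marker stage, where hotspot positions rather than specific
substitutions are the unit of interest.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("comutnet")

# Defaults shared across the pipeline.
DEFAULT_VAF_MIN = 0.125          # strict: vaf must exceed this
DEFAULT_RECURRENCE_MIN = 3       # mutation seen in >= this many non-hypermutated samples
DEFAULT_HYPERMUT_CUTOFF = 500    # per-sample mutation count above which a sample is hypermutated


class ConfigurationError(ValueError):
    """Raised when an input file does not match the configured dialect."""


class DataError(ValueError):
    """Raised when input data is structurally invalid or degenerate."""


_POSITION_RE = re.compile(r"(\d+)")


@dataclass(frozen=True, order=True)
class MutationKey:
    """Identity of a mutation: gene symbol plus protein change.

    ``level`` is ``"exact"`` (``KRAS:G12D``) or ``"position"`` (``KRAS:G12``);
    two keys are equal iff gene, level and rendered change all match.
    """

    gene: str
    change: str
    level: str = "exact"

    def __post_init__(self) -> None:
        if self.level not in ("exact", "position"):
            raise ValueError(f"invalid key level {self.level!r}")
        if not self.gene:
            raise ValueError("gene symbol must be nonempty")

    def render(self) -> str:
        return f"{self.gene}:{self.change}"

    def position(self) -> int | None:
        """First integer in the protein-change string, or None."""
        m = _POSITION_RE.search(self.change)
        return int(m.group(1)) if m else None

    def to_position_level(self) -> "MutationKey":
        pos = self.position()
        if pos is None:
            raise DataError(f"no parseable protein position in {self.render()!r}")
        ref = self.change[: _POSITION_RE.search(self.change).start()]
        return MutationKey(self.gene, f"{ref}{pos}", level="position")

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.render()


def parse_key(text: str, level: str = "exact") -> MutationKey:
    """Parse ``GENE:CHANGE`` into a :class:`MutationKey`."""
    gene, sep, change = text.strip().partition(":")
    if not sep or not gene or not change:
        raise DataError(f"cannot parse mutation key {text!r}")
    return MutationKey(gene, change, level=level)


@dataclass(frozen=True)
class MutationRecord:
    """One observed protein-level mutation in one tumor sample."""

    sample_id: str
    gene: str
    protein_change: str
    vaf: float

    def __post_init__(self) -> None:
        if not self.gene:
            raise ValueError("gene symbol must be nonempty")
        if not (0.0 <= self.vaf <= 1.0):
            raise ValueError(f"VAF {self.vaf} outside [0, 1]")

    @property
    def key(self) -> MutationKey:
        return MutationKey(self.gene, self.protein_change)

    @property
    def protein_position(self) -> int | None:
        return self.key.position()


@dataclass(frozen=True)
class SampleMeta:
    """Tumor-level annotations: tissue, primary/metastatic, mutation burden."""

    sample_id: str
    tissue: str
    sample_type: str  # "primary" | "metastatic"
    mutation_count: int = 0
    hypermut_cutoff: int = DEFAULT_HYPERMUT_CUTOFF

    def __post_init__(self) -> None:
        if self.sample_type not in ("primary", "metastatic"):
            raise ValueError(f"invalid sample_type {self.sample_type!r}")
        if self.mutation_count < 0:
            raise ValueError("mutation_count must be nonnegative")

    @property
    def hypermutated(self) -> bool:
        return self.mutation_count > self.hypermut_cutoff


@dataclass(frozen=True)
class DriverCatalog:
    """Set of validated oncogenic mutations at exact-change level."""

    entries: frozenset[MutationKey]

    @classmethod
    def from_keys(cls, keys: Iterable[MutationKey | str]) -> "DriverCatalog":
        parsed = frozenset(
            k if isinstance(k, MutationKey) else parse_key(k) for k in keys
        )
        return cls(entries=parsed)

    @classmethod
    def from_file(cls, path) -> "DriverCatalog":
        with open(path) as fh:
            keys = [line.strip() for line in fh if line.strip()]
        return cls.from_keys(keys)

    def __contains__(self, key: MutationKey) -> bool:
        return key in self.entries

    def __len__(self) -> int:
        return len(self.entries)


def label_driver(key: MutationKey, catalog: DriverCatalog) -> str:
    """Label a mutation ``"D"`` (driver) if in the catalog, else ``"P"``.

    Driver status is defined at exact-change level only.
    """
    if key.level != "exact":
        raise DataError(f"driver status undefined for {key.level}-level key {key.render()!r}")
    return "D" if key in catalog else "P"


@dataclass
class BinaryCohortMatrix:
    """Sample x mutation presence matrix (0/1 cells).

    ``cells[i, j]`` is 1 iff sample ``samples[i]`` carries ``mutations[j]``.
    """

    samples: list[str]
    mutations: list[MutationKey]
    cells: np.ndarray  # uint8, shape (n_samples, n_mutations)

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells, dtype=np.uint8)
        if self.cells.shape != (len(self.samples), len(self.mutations)):
            raise ValueError("cells shape does not match samples/mutations")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample ids")
        if len(set(self.mutations)) != len(self.mutations):
            raise ValueError("duplicate mutation keys")
        self._sample_index = {s: i for i, s in enumerate(self.samples)}
        self._key_index = {k: j for j, k in enumerate(self.mutations)}

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def recurrence(self, key: MutationKey | None = None):
        """Column sums: number of samples carrying each mutation."""
        counts = self.cells.sum(axis=0)
        if key is None:
            return counts
        return int(counts[self.column(key)])

    def __contains__(self, key: MutationKey) -> bool:
        return key in self._key_index

    def column(self, key: MutationKey) -> int:
        try:
            return self._key_index[key]
        except KeyError:
            raise DataError(f"mutation {key.render()!r} not in matrix") from None

    def carriers(self, key: MutationKey) -> np.ndarray:
        """Boolean carrier vector over samples for one mutation."""
        return self.cells[:, self.column(key)].astype(bool)

    def subset_samples(self, sample_ids: Sequence[str]) -> "BinaryCohortMatrix":
        idx = [self._sample_index[s] for s in sample_ids if s in self._sample_index]
        return BinaryCohortMatrix(
            samples=[self.samples[i] for i in idx],
            mutations=list(self.mutations),
            cells=self.cells[idx, :].copy(),
        )

    def to_long_frame(self) -> pd.DataFrame:
        rows, cols = np.nonzero(self.cells)
        return pd.DataFrame(
            {
                "sample_id": [self.samples[i] for i in rows],
                "key": [self.mutations[j].render() for j in cols],
                "level": [self.mutations[j].level for j in cols],
            }
        )

    def to_tsv(self, path) -> None:
        self.to_long_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_long_frame(
        cls, frame: pd.DataFrame, samples: Sequence[str] | None = None
    ) -> "BinaryCohortMatrix":
        keys = sorted(
            {parse_key(k, level=lv) for k, lv in zip(frame["key"], frame["level"])}
        )
        if samples is None:
            samples = sorted(set(frame["sample_id"]))
        samples = list(samples)
        sidx = {s: i for i, s in enumerate(samples)}
        kidx = {k: j for j, k in enumerate(keys)}
        cells = np.zeros((len(samples), len(keys)), dtype=np.uint8)
        for sid, k, lv in zip(frame["sample_id"], frame["key"], frame["level"]):
            if sid in sidx:
                cells[sidx[sid], kidx[parse_key(k, level=lv)]] = 1
        return cls(samples=samples, mutations=list(keys), cells=cells)

    @classmethod
    def from_tsv(cls, path, samples: Sequence[str] | None = None) -> "BinaryCohortMatrix":
        return cls.from_long_frame(pd.read_csv(path, sep="\t"), samples=samples)


# ---------------------------------------------------------------------------
# Loading


DEFAULT_COLUMN_MAP = {
    "sample": "sample_id",
    "gene": "gene",
    "protein_change": "protein_change",
    "vaf": "vaf",
}


@dataclass
class LoadReport:
    """Run-provenance counters for a mutation-table load."""

    n_rows: int = 0
    n_records: int = 0
    n_dropped_vaf: int = 0
    n_dropped_gene: int = 0
    n_dropped_classification: int = 0

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def load_mutation_table(
    path,
    column_map: Mapping[str, str] | None = None,
    missense_only: bool = False,
    classification_column: str = "variant_classification",
    report: LoadReport | None = None,
) -> list[MutationRecord]:
    """Read a MAF-like TSV into :class:`MutationRecord` objects.

    Rows with unparseable VAF or an empty gene symbol are dropped and
    counted in ``report``.  With ``missense_only`` and a variant
    classification column present, non-missense rows are dropped; if the
    column is absent no filter is applied (logged).
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    table = pd.read_csv(path, sep="\t", dtype=str)
    if table.empty and table.columns.size == 0:
        logger.warning("mutation table %s is empty", path)
        return []
    for logical in ("sample", "gene", "protein_change", "vaf"):
        if cmap[logical] not in table.columns:
            raise ConfigurationError(
                f"required column {cmap[logical]!r} (for {logical}) missing from {path}"
            )
    rep = report if report is not None else LoadReport()
    rep.n_rows = len(table)

    if missense_only:
        if classification_column in table.columns:
            keep = table[classification_column].str.lower().str.contains(
                "missense", na=False
            )
            rep.n_dropped_classification = int((~keep).sum())
            table = table[keep]
        else:
            logger.info(
                "missense_only requested but column %r absent; no filter applied",
                classification_column,
            )

    records: list[MutationRecord] = []
    for sid, gene, change, vaf in zip(
        table[cmap["sample"]],
        table[cmap["gene"]],
        table[cmap["protein_change"]],
        table[cmap["vaf"]],
    ):
        if not isinstance(gene, str) or not gene.strip():
            rep.n_dropped_gene += 1
            continue
        try:
            v = float(vaf)
        except (TypeError, ValueError):
            rep.n_dropped_vaf += 1
            continue
        if not np.isfinite(v) or not (0.0 <= v <= 1.0):
            rep.n_dropped_vaf += 1
            continue
        records.append(
            MutationRecord(
                sample_id=str(sid),
                gene=gene.strip(),
                protein_change=str(change).strip(),
                vaf=v,
            )
        )
    rep.n_records = len(records)
    if rep.n_dropped_vaf or rep.n_dropped_gene:
        logger.info(
            "dropped %d rows with bad VAF, %d with empty gene",
            rep.n_dropped_vaf,
            rep.n_dropped_gene,
        )
    return records


def load_sample_metadata(path, hypermut_cutoff: int = DEFAULT_HYPERMUT_CUTOFF) -> dict[str, SampleMeta]:
    """Read sample metadata TSV (sample_id, tissue, sample_type[, mutation_count])."""
    table = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    for col in ("sample_id", "tissue", "sample_type"):
        if col not in table.columns:
            raise ConfigurationError(f"required column {col!r} missing from {path}")
    metas = {}
    for row in table.itertuples(index=False):
        count = int(getattr(row, "mutation_count", 0) or 0)
        metas[row.sample_id] = SampleMeta(
            sample_id=row.sample_id,
            tissue=row.tissue,
            sample_type=row.sample_type,
            mutation_count=count,
            hypermut_cutoff=hypermut_cutoff,
        )
    return metas


# ---------------------------------------------------------------------------
# Filtering & binarization


def filter_cohort(
    records: Iterable[MutationRecord],
    samples: Mapping[str, SampleMeta] | Sequence[str],
    vaf_min: float = DEFAULT_VAF_MIN,
    recurrence_min: int = DEFAULT_RECURRENCE_MIN,
    hypermut_cutoff: int = DEFAULT_HYPERMUT_CUTOFF,
) -> BinaryCohortMatrix:
    """Binarize a cohort after VAF / hypermutation / recurrence filtering.

    Keeps records with ``vaf > vaf_min`` (strict), drops hypermutated
    samples entirely, then keeps only mutations recurring in at least
    ``recurrence_min`` of the remaining samples.  The matrix rows cover
    every non-hypermutated sample (including mutation-free ones), so column
    sums are recurrence counts and ``n_samples`` is the contingency-table
    total.
    """
    if isinstance(samples, Mapping):
        metas = samples
        all_ids = list(metas.keys())
        kept_ids = [
            s for s in all_ids
            if not _is_hypermutated(metas[s], hypermut_cutoff)
        ]
    else:
        all_ids = list(samples)
        kept_ids = all_ids
    if all_ids and not kept_ids:
        raise DataError("all samples are hypermutated; empty cohort")
    kept = set(kept_ids)

    by_key: dict[MutationKey, set[str]] = {}
    for rec in records:
        if rec.vaf <= vaf_min:
            continue
        if rec.sample_id not in kept:
            continue
        by_key.setdefault(rec.key, set()).add(rec.sample_id)

    keys = sorted(k for k, carriers in by_key.items() if len(carriers) >= recurrence_min)
    sidx = {s: i for i, s in enumerate(kept_ids)}
    cells = np.zeros((len(kept_ids), len(keys)), dtype=np.uint8)
    for j, k in enumerate(keys):
        for s in by_key[k]:
            cells[sidx[s], j] = 1
    return BinaryCohortMatrix(samples=kept_ids, mutations=keys, cells=cells)


def _is_hypermutated(meta: SampleMeta, cutoff: int) -> bool:
    return meta.mutation_count > cutoff


def collapse_to_position(matrix: BinaryCohortMatrix) -> BinaryCohortMatrix:
    """Collapse exact-level keys to residue positions (``PIK3CA:E545``).

    A sample carries ``GENE:pos`` iff it carried any exact change at that
    position; recurrence is recomputed from the union.
    """
    bad = [k.render() for k in matrix.mutations if k.position() is None]
    if bad:
        raise DataError(f"keys without parseable position: {bad}")
    if any(k.level != "exact" for k in matrix.mutations):
        raise DataError("collapse_to_position expects exact-level keys")
    groups: dict[MutationKey, list[int]] = {}
    for j, k in enumerate(matrix.mutations):
        groups.setdefault(k.to_position_level(), []).append(j)
    pos_keys = sorted(groups)
    cells = np.zeros((matrix.n_samples, len(pos_keys)), dtype=np.uint8)
    for jj, pk in enumerate(pos_keys):
        cells[:, jj] = matrix.cells[:, groups[pk]].max(axis=1)
    return BinaryCohortMatrix(samples=list(matrix.samples), mutations=pos_keys, cells=cells)


def write_provenance(path, *, filters: Mapping, report: LoadReport | None = None) -> None:
    """Serialize run-provenance (filter settings, drop counts) as JSON."""
    payload = {"filters": dict(filters)}
    if report is not None:
        payload["load_report"] = report.to_dict()
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
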
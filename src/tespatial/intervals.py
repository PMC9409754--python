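"""Genomic interval data model and interval-set algebra.

Everything downstream — the spatial statistics, the TE pipeline, the genic
feature assembly — operates on :class:`IntervalSet` objects: chromosome-anchored
collections of 0-based half-open intervals (BED convention) tied to a
:class:`GenomeLayout`. GTF input (1-based, closed) is converted on read so a
single coordinate convention holds everywhere.

Interval sets are stored per chromosome as sorted NumPy start/end arrays, which
keeps merge, coverage and nearest-neighbour queries vectorized; the permutation
engine calls these thousands of times per analysis.
"""

from __future__ import annotations

import warnings
from collections.abc import Iterable, Iterator, Mapping
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "GenomeLayout",
    "IntervalSet",
    "merge",
    "intersection_length",
    "union_length",
    "nearest_distance",
    "nearest_distances",
    "read_bed",
    "write_bed",
    "read_chrom_sizes",
    "read_gtf_features",
    "GTF_FEATURE_KINDS",
]

_STRANDS = frozenset({"+", "-", "."})

GTF_FEATURE_KINDS = ("transcript", "CDS", "start_codon")


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open interval on a named chromosome.

    ``start`` is inclusive, ``end`` exclusive; ``length = end - start >= 1``.
    Strand is carried for provenance but ignored by every spatial statistic.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in _STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}; expected one of + - .")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)


class GenomeLayout:
    """Ordered chromosome names and lengths; the coordinate frame of a genome.

    All intervals in any associated :class:`IntervalSet` must lie within
    ``[0, chrom_length)`` of a chromosome listed here.
    """

    def __init__(self, chrom_lengths: Mapping[str, int] | Iterable[tuple[str, int]]):
        items = list(chrom_lengths.items()) if isinstance(chrom_lengths, Mapping) else list(chrom_lengths)
        lengths: dict[str, int] = {}
        for name, length in items:
            name = str(name)
            if name in lengths:
                raise ValueError(f"duplicate chromosome name {name!r}")
            length = int(length)
            if length < 1:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")
            lengths[name] = length
        if not lengths:
            raise ValueError("layout must contain at least one chromosome")
        self._lengths = lengths

    @classmethod
    def from_chrom_sizes(cls, path) -> "GenomeLayout":
        return read_chrom_sizes(path)

    @property
    def chrom_names(self) -> tuple[str, ...]:
        return tuple(self._lengths)

    def __contains__(self, name: str) -> bool:
        return name in self._lengths

    def __getitem__(self, name: str) -> int:
        return self._lengths[name]

    def __eq__(self, other) -> bool:
        return isinstance(other, GenomeLayout) and self._lengths == other._lengths

    def __hash__(self):
        return hash(tuple(self._lengths.items()))

    def __repr__(self) -> str:
        return f"GenomeLayout({len(self._lengths)} chromosomes, {self.total_bp:,} bp)"

    @property
    def total_bp(self) -> int:
        return sum(self._lengths.values())

    def items(self):
        return self._lengths.items()

    def to_chrom_sizes(self, path) -> None:
        with open(path, "w") as fh:
            for name, length in self._lengths.items():
                fh.write(f"{name}\t{length}\n")


def read_chrom_sizes(path) -> GenomeLayout:
    """Read a two-column (name, length) chromosome-sizes table."""
    pairs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 2:
                raise ValueError(f"{path}: line {lineno}: expected 'name<TAB>length'")
            try:
                pairs.append((fields[0], int(fields[1])))
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: bad length {fields[1]!r}") from exc
    return GenomeLayout(pairs)


class IntervalSet:
    """A sorted collection of intervals on a :class:`GenomeLayout`.

    Internally one ``(starts, ends)`` pair of int64 arrays per chromosome,
    sorted by start. A *merged* set has no two overlapping or bookended
    intervals on the same chromosome; the statistics that require merged
    input check the ``is_merged`` flag.
    """

    def __init__(self, layout: GenomeLayout, intervals: Iterable[GenomicInterval] = ()):
        self.layout = layout
        per_chrom: dict[str, list[tuple[int, int, str]]] = {}
        for iv in intervals:
            if iv.chrom not in layout:
                raise ValueError(f"interval on chromosome {iv.chrom!r} absent from layout")
            if iv.end > layout[iv.chrom]:
                raise ValueError(
                    f"interval {iv.chrom}:{iv.start}-{iv.end} exceeds chromosome "
                    f"length {layout[iv.chrom]}"
                )
            per_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end, iv.strand))
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        self._strands: dict[str, np.ndarray] = {}
        for chrom, rows in per_chrom.items():
            starts = np.array([r[0] for r in rows], dtype=np.int64)
            ends = np.array([r[1] for r in rows], dtype=np.int64)
            strands = np.array([r[2] for r in rows], dtype="<U1")
            order = np.argsort(starts, kind="stable")
            self._starts[chrom] = starts[order]
            self._ends[chrom] = ends[order]
            self._strands[chrom] = strands[order]

    @classmethod
    def from_arrays(
        cls,
        layout: GenomeLayout,
        arrays: Mapping[str, tuple[np.ndarray, np.ndarray]],
        *,
        validate: bool = True,
    ) -> "IntervalSet":
        """Build from per-chromosome (starts, ends) arrays (need not be sorted)."""
        obj = cls.__new__(cls)
        obj.layout = layout
        obj._starts, obj._ends, obj._strands = {}, {}, {}
        for chrom, (starts, ends) in arrays.items():
            starts = np.asarray(starts, dtype=np.int64)
            ends = np.asarray(ends, dtype=np.int64)
            if starts.size == 0:
                continue
            if validate:
                if chrom not in layout:
                    raise ValueError(f"chromosome {chrom!r} absent from layout")
                if np.any(starts < 0) or np.any(starts >= ends):
                    raise ValueError(f"invalid intervals on {chrom}: require 0 <= start < end")
                if np.any(ends > layout[chrom]):
                    raise ValueError(f"intervals exceed chromosome {chrom} bounds")
            order = np.argsort(starts, kind="stable")
            obj._starts[chrom] = starts[order]
            obj._ends[chrom] = ends[order]
            obj._strands[chrom] = np.full(starts.size, ".", dtype="<U1")
        return obj

    # -- basic accessors ---------------------------------------------------

    def __len__(self) -> int:
        return sum(a.size for a in self._starts.values())

    def __iter__(self) -> Iterator[GenomicInterval]:
        for chrom in self.chroms:
            starts, ends, strands = self._starts[chrom], self._ends[chrom], self._strands[chrom]
            for s, e, st in zip(starts.tolist(), ends.tolist(), strands.tolist()):
                yield GenomicInterval(chrom, s, e, st)

    def __eq__(self, other) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        if self.layout != other.layout or set(self._starts) != set(other._starts):
            return False
        return all(
            np.array_equal(self._starts[c], other._starts[c])
            and np.array_equal(self._ends[c], other._ends[c])
            for c in self._starts
        )

    @property
    def chroms(self) -> tuple[str, ...]:
        """Chromosomes (in layout order) that carry at least one interval."""
        return tuple(c for c in self.layout.chrom_names if c in self._starts)

    def arrays(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        """Sorted (starts, ends) on one chromosome; empty arrays if none."""
        if chrom not in self._starts:
            empty = np.empty(0, dtype=np.int64)
            return empty, empty
        return self._starts[chrom], self._ends[chrom]

    @property
    def total_length(self) -> int:
        """Total covered bases; on a merged set, the footprint in bp."""
        m = self if self.is_merged else self.merge()
        return int(sum((m._ends[c] - m._starts[c]).sum() for c in m._starts))

    @property
    def is_merged(self) -> bool:
        for chrom in self._starts:
            starts, ends = self._starts[chrom], self._ends[chrom]
            if starts.size > 1 and not np.all(starts[1:] > ends[:-1]):
                return False
        return True

    # -- algebra -----------------------------------------------------------

    def merge(self) -> "IntervalSet":
        """Minimal equivalent set of disjoint intervals (strand dropped)."""
        out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom in self._starts:
            starts, ends = self._starts[chrom], self._ends[chrom]
            if starts.size == 1:
                out[chrom] = (starts, ends)
                continue
            run_max = np.maximum.accumulate(ends)
            # a new block begins wherever the start clears every prior end
            new_block = np.empty(starts.size, dtype=bool)
            new_block[0] = True
            new_block[1:] = starts[1:] > run_max[:-1]
            idx = np.flatnonzero(new_block)
            block_ends = np.append(idx[1:], starts.size) - 1
            out[chrom] = (starts[idx], run_max[block_ends])
        return IntervalSet.from_arrays(self.layout, out, validate=False)

    def restricted_to(self, chroms: Iterable[str]) -> "IntervalSet":
        keep = set(chroms)
        return IntervalSet.from_arrays(
            self.layout,
            {c: (self._starts[c], self._ends[c]) for c in self._starts if c in keep},
            validate=False,
        )


def merge(s: IntervalSet) -> IntervalSet:
    return s.merge()


def _coverage_before(starts: np.ndarray, ends: np.ndarray, cumcov: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Covered bases of a merged interval list in [0, x) for each x (vectorized)."""
    k = np.searchsorted(starts, x, side="left")
    over = np.zeros(x.shape, dtype=np.int64)
    nz = k > 0
    if np.any(nz):
        over[nz] = np.maximum(ends[k[nz] - 1] - x[nz], 0)
    return cumcov[k] - over


def intersection_length(a: IntervalSet, b: IntervalSet) -> int:
    """Total bases covered by both merged sets; symmetric."""
    if a.layout != b.layout:
        raise ValueError("interval sets live on different genome layouts")
    if not a.is_merged or not b.is_merged:
        raise ValueError("intersection_length requires merged interval sets")
    total = 0
    for chrom in a.chroms:
        bs, be = b.arrays(chrom)
        if bs.size == 0:
            continue
        as_, ae = a.arrays(chrom)
        cumcov = np.concatenate(([0], np.cumsum(be - bs)))
        total += int((_coverage_before(bs, be, cumcov, ae) - _coverage_before(bs, be, cumcov, as_)).sum())
    return total


def union_length(a: IntervalSet, b: IntervalSet) -> int:
    """Total bases covered by either merged set: |A| + |B| - |A∩B|."""
    return a.total_length + b.total_length - intersection_length(a, b)


def nearest_distance(query: GenomicInterval, refs: IntervalSet) -> int | None:
    """Gap in bp from ``query`` to the nearest reference on its chromosome.

    0 if the query overlaps (or abuts) a reference; ``None`` if the chromosome
    carries no reference interval.
    """
    if not refs.is_merged:
        raise ValueError("nearest_distance requires a merged reference set")
    rs, re_ = refs.arrays(query.chrom)
    if rs.size == 0:
        return None
    d = _nearest_gaps(np.array([query.start]), np.array([query.end]), rs, re_)
    return int(d[0])


def _nearest_gaps(qs: np.ndarray, qe: np.ndarray, rs: np.ndarray, re_: np.ndarray) -> np.ndarray:
    i = np.searchsorted(rs, qe, side="left")
    left = np.full(qs.shape, np.inf)
    nz = i > 0
    left[nz] = qs[nz] - re_[i[nz] - 1]
    right = np.full(qs.shape, np.inf)
    lt = i < rs.size
    right[lt] = rs[i[lt]] - qe[lt]
    return np.maximum(np.minimum(left, right), 0.0)


def nearest_distances(queries: IntervalSet, refs: IntervalSet) -> np.ndarray:
    """Per-query nearest gaps, skipping queries on chromosomes without refs."""
    if not refs.is_merged:
        refs = refs.merge()
    chunks = []
    for chrom in queries.chroms:
        rs, re_ = refs.arrays(chrom)
        if rs.size == 0:
            continue
        qs, qe = queries.arrays(chrom)
        chunks.append(_nearest_gaps(qs, qe, rs, re_))
    if not chunks:
        return np.empty(0)
    return np.concatenate(chunks)


# -- file formats ----------------------------------------------------------


def read_bed(path, layout: GenomeLayout) -> IntervalSet:
    """Read a BED3+ file (0-based half-open) into a sorted IntervalSet."""
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno}: expected >= 3 tab-separated BED columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: non-integer coordinates") from exc
            if start >= end or start < 0:
                raise ValueError(f"{path}: line {lineno}: invalid interval {start}-{end}")
            strand = fields[5] if len(fields) >= 6 and fields[5] in _STRANDS else "."
            intervals.append(GenomicInterval(chrom, start, end, strand))
    return IntervalSet(layout, intervals)


def write_bed(s: IntervalSet, path) -> None:
    """Write BED3 sorted by (chromosome, start); round-trips through read_bed."""
    with open(path, "w") as fh:
        for iv in s:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


_GTF_COLUMNS = ["seqname", "source", "feature", "start", "end", "score", "strand", "frame", "attribute"]


def read_gtf_features(path, layout: GenomeLayout, feature_kind: str) -> IntervalSet:
    """Extract one feature kind from a GTF as a merged IntervalSet.

    GTF coordinates (1-based, closed) are converted to 0-based half-open.
    Overlapping records of the same kind (isoforms, per-exon CDS lines) are
    merged so overlap statistics never double-count bases.
    """
    if feature_kind not in GTF_FEATURE_KINDS:
        raise ValueError(
            f"unknown feature_kind {feature_kind!r}; expected one of {GTF_FEATURE_KINDS}"
        )
    try:
        df = pd.read_csv(
            path, sep="\t", comment="#", header=None, names=_GTF_COLUMNS,
            dtype={"seqname": str, "feature": str, "strand": str}, quoting=3,
        )
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=_GTF_COLUMNS)
    sel = df[df["feature"] == feature_kind]
    if sel.empty:
        warnings.warn(f"no {feature_kind!r} records in {path}", stacklevel=2)
        return IntervalSet(layout)
    intervals = [
        GenomicInterval(row.seqname, int(row.start) - 1, int(row.end),
                        row.strand if row.strand in _STRANDS else ".")
        for row in sel.itertuples()
    ]
    return IntervalSet(layout, intervals).merge()
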
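"""Genomic interval algebra: the data model and BED plumbing under every analysis.

Coordinates are 0-based half-open (BED convention) throughout the package;
1-based sources (VCF, fixedStep wiggle) are converted at ingestion. Strand is
ignored: all analyses here are strand-agnostic.

The three algebraic operations — ``merge`` (coalesce overlapping and
book-ended intervals), ``overlap_count`` (per-base membership of single
positions in a feature set) and ``shuffle`` (length-preserving random
re-placement on a genome, the permutation-null generator) — are the
primitives the conservation and enrichment modules are built on.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

from .errors import BedParseError, DataError

logger = logging.getLogger(__name__)

__all__ = [
    "GenomicInterval",
    "IntervalSet",
    "PositionList",
    "merge",
    "overlap_count",
    "shuffle",
    "read_bed",
    "write_bed",
    "read_genome",
    "write_genome",
    "sample_positions",
]


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic range [start, end) on one chromosome."""

    chrom: str
    start: int
    end: int
    name: str | None = None

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise DataError(
                f"malformed interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


class IntervalSet:
    """An ordered collection of :class:`GenomicInterval` plus an optional genome.

    ``genome`` maps chromosome name to length and is required only by
    operations that need to know the placement space (``shuffle``,
    position sampling).
    """

    def __init__(
        self,
        intervals: Iterable[GenomicInterval] = (),
        genome: Mapping[str, int] | None = None,
    ) -> None:
        self.intervals: list[GenomicInterval] = list(intervals)
        self.genome: dict[str, int] | None = dict(genome) if genome is not None else None
        self._index: dict[str, tuple[np.ndarray, np.ndarray]] | None = None

    # -- basic container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return self.intervals == other.intervals

    def __repr__(self) -> str:
        return f"IntervalSet(n={len(self)}, total_length={self.total_length})"

    @property
    def total_length(self) -> int:
        return sum(iv.length for iv in self.intervals)

    @property
    def chroms(self) -> list[str]:
        seen: dict[str, None] = {}
        for iv in self.intervals:
            seen.setdefault(iv.chrom, None)
        return list(seen)

    # -- algebra -------------------------------------------------------------------
    def merge(self) -> "IntervalSet":
        return merge(self)

    def merged_index(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Per-chromosome (starts, ends) arrays of the merged set, cached."""
        if self._index is None:
            by_chrom: dict[str, list[GenomicInterval]] = {}
            for iv in merge(self).intervals:
                by_chrom.setdefault(iv.chrom, []).append(iv)
            self._index = {
                c: (
                    np.array([iv.start for iv in ivs], dtype=np.int64),
                    np.array([iv.end for iv in ivs], dtype=np.int64),
                )
                for c, ivs in by_chrom.items()
            }
        return self._index

    def positions(self) -> "PositionList":
        """Enumerate every base position covered by the (merged) set."""
        chroms: list[np.ndarray] = []
        pos: list[np.ndarray] = []
        for iv in merge(self).intervals:
            pos.append(np.arange(iv.start, iv.end, dtype=np.int64))
            chroms.append(np.full(iv.length, iv.chrom, dtype=object))
        if not pos:
            return PositionList.empty()
        return PositionList(np.concatenate(chroms), np.concatenate(pos))


class PositionList:
    """Ordered list of single-base genomic positions (parallel chrom/pos arrays)."""

    __slots__ = ("chroms", "pos")

    def __init__(self, chroms: np.ndarray, pos: np.ndarray) -> None:
        self.chroms = np.asarray(chroms, dtype=object)
        self.pos = np.asarray(pos, dtype=np.int64)
        if self.chroms.shape != self.pos.shape:
            raise ValueError("chroms and pos must have equal length")

    @classmethod
    def empty(cls) -> "PositionList":
        return cls(np.empty(0, dtype=object), np.empty(0, dtype=np.int64))

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, int]]) -> "PositionList":
        pairs = list(pairs)
        if not pairs:
            return cls.empty()
        chroms = np.array([c for c, _ in pairs], dtype=object)
        pos = np.array([p for _, p in pairs], dtype=np.int64)
        return cls(chroms, pos)

    def __len__(self) -> int:
        return len(self.pos)

    def __iter__(self) -> Iterator[tuple[str, int]]:
        return zip(self.chroms, (int(p) for p in self.pos))

    def subset(self, idx: np.ndarray) -> "PositionList":
        return PositionList(self.chroms[idx], self.pos[idx])

    def concat(self, other: "PositionList") -> "PositionList":
        return PositionList(
            np.concatenate([self.chroms, other.chroms]),
            np.concatenate([self.pos, other.pos]),
        )

    def group_indices(self) -> dict[str, np.ndarray]:
        """Map chromosome -> indices into this list, preserving order within groups."""
        if len(self.chroms) == 0:
            return {}
        uniq, inverse = np.unique(self.chroms.astype(str), return_inverse=True)
        if len(uniq) == 1:
            return {str(uniq[0]): np.arange(len(self.chroms), dtype=np.intp)}
        return {str(c): np.flatnonzero(inverse == k) for k, c in enumerate(uniq)}


def as_position_list(positions) -> PositionList:
    """Coerce an iterable of (chrom, pos) pairs — or a PositionList — to a PositionList."""
    if isinstance(positions, PositionList):
        return positions
    return PositionList.from_pairs(positions)


# ---------------------------------------------------------------------------
# merge
# ---------------------------------------------------------------------------

def merge(intervals: IntervalSet | Iterable[GenomicInterval]) -> IntervalSet:
    """Coalesce overlapping and book-ended intervals into a sorted disjoint set.

    Book-ended inputs ([100,200) and [200,300)) are merged, matching the
    behaviour of the common interval-merge tools. Union coverage is preserved;
    names are dropped on coalesced output.
    """
    genome = intervals.genome if isinstance(intervals, IntervalSet) else None
    ivs = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    out: list[GenomicInterval] = []
    for iv in ivs:
        if out and out[-1].chrom == iv.chrom and iv.start <= out[-1].end:
            if iv.end > out[-1].end:
                out[-1] = GenomicInterval(iv.chrom, out[-1].start, iv.end)
        else:
            out.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return IntervalSet(out, genome=genome)


# ---------------------------------------------------------------------------
# overlap_count
# ---------------------------------------------------------------------------

def overlap_count(
    query, features: IntervalSet
) -> tuple[int, np.ndarray]:
    """Count query positions falling inside ``features``.

    A position overlaps iff ``start <= pos < end`` of some feature interval.
    Returns the total count and a per-position boolean vector in input order.
    Positions on chromosomes absent from the feature set count as
    non-overlapping (logged at debug level).
    """
    q = as_position_list(query)
    flags = np.zeros(len(q), dtype=bool)
    index = features.merged_index()
    for chrom, idx in q.group_indices().items():
        if chrom not in index:
            logger.debug("chromosome %s absent from feature set; %d positions "
                         "counted as non-overlapping", chrom, len(idx))
            continue
        starts, ends = index[chrom]
        p = q.pos[idx]
        j = np.searchsorted(starts, p, side="right") - 1
        ok = j >= 0
        hit = np.zeros(len(p), dtype=bool)
        hit[ok] = p[ok] < ends[j[ok]]
        flags[idx] = hit
    return int(flags.sum()), flags


# ---------------------------------------------------------------------------
# shuffle
# ---------------------------------------------------------------------------

def shuffle(
    intervals: IntervalSet,
    genome: Mapping[str, int] | None = None,
    excluded: IntervalSet | None = None,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    same_chrom: bool = True,
    max_retries: int = 1000,
) -> IntervalSet:
    """Re-place each interval uniformly at random on the genome.

    The output preserves the per-interval length multiset (hence total
    length). Placements are uniform over the allowed space, must not
    intersect ``excluded``, and are reproducible under a fixed seed.
    By default each interval stays on its own chromosome; with
    ``same_chrom=False`` the target chromosome is drawn with probability
    proportional to the number of valid start positions on it.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    genome = dict(genome) if genome is not None else intervals.genome
    if genome is None:
        raise DataError("shuffle requires chromosome lengths (genome)")
    excl_index = excluded.merged_index() if excluded is not None else {}

    def intersects_excluded(chrom: str, s: int, e: int) -> bool:
        if chrom not in excl_index:
            return False
        starts, ends = excl_index[chrom]
        j = int(np.searchsorted(starts, e, side="left")) - 1
        return j >= 0 and ends[j] > s

    out: list[GenomicInterval] = []
    for iv in intervals:
        length = iv.length
        if same_chrom:
            if iv.chrom not in genome:
                raise DataError(f"chromosome {iv.chrom} not in genome")
            allowed = [iv.chrom]
        else:
            allowed = [c for c, L in genome.items() if L >= length]
        spans = np.array([genome[c] - length + 1 for c in allowed], dtype=np.int64)
        if len(allowed) == 0 or (spans <= 0).all():
            raise DataError(f"interval of length {length} fits on no allowed chromosome")
        weights = np.clip(spans, 0, None).astype(float)
        weights /= weights.sum()
        placed = False
        for _ in range(max_retries):
            chrom = allowed[int(rng.choice(len(allowed), p=weights))]
            start = int(rng.integers(0, genome[chrom] - length + 1))
            if not intersects_excluded(chrom, start, start + length):
                out.append(GenomicInterval(chrom, start, start + length, iv.name))
                placed = True
                break
        if not placed:
            raise DataError(
                f"could not place interval of length {length} after "
                f"{max_retries} retries (exclusion too dense?)"
            )
    return IntervalSet(out, genome=genome)


# ---------------------------------------------------------------------------
# position sampling
# ---------------------------------------------------------------------------

def sample_positions(
    universe: IntervalSet,
    n: int,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    replace: bool = False,
) -> PositionList:
    """Sample ``n`` single-base positions uniformly from the universe's coverage."""
    if rng is None:
        rng = np.random.default_rng(seed)
    merged = merge(universe)
    total = merged.total_length
    if total == 0:
        raise DataError("cannot sample positions from an empty universe")
    if not replace and n > total:
        raise DataError(f"requested {n} positions without replacement from {total} bases")
    offsets = rng.choice(total, size=n, replace=replace)
    offsets.sort()
    bounds = np.cumsum([iv.length for iv in merged.intervals])
    which = np.searchsorted(bounds, offsets, side="right")
    chroms = np.empty(n, dtype=object)
    pos = np.empty(n, dtype=np.int64)
    prev = np.concatenate([[0], bounds[:-1]])
    for i, (o, w) in enumerate(zip(offsets, which)):
        iv = merged.intervals[int(w)]
        chroms[i] = iv.chrom
        pos[i] = iv.start + (o - prev[int(w)])
    perm = rng.permutation(n)
    return PositionList(chroms[perm], pos[perm])


# ---------------------------------------------------------------------------
# BED / genome-file I/O
# ---------------------------------------------------------------------------

def read_bed(path: str | Path, genome: Mapping[str, int] | None = None) -> IntervalSet:
    """Read BED3+ (tab-separated, half-open). ``track``/``browser``/# lines skipped."""
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(f"{path}:{lineno}: expected >=3 tab-separated fields")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            try:
                intervals.append(GenomicInterval(fields[0], start, end, name))
            except DataError as exc:
                raise BedParseError(f"{path}:{lineno}: {exc}") from exc
    return IntervalSet(intervals, genome=genome)


def write_bed(intervals: IntervalSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            if iv.name is not None:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_genome(path: str | Path) -> dict[str, int]:
    """Read a two-column 'chrom<TAB>length' genome file."""
    genome: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise BedParseError(f"{path}:{lineno}: expected 'chrom\\tlength'")
            try:
                genome[fields[0]] = int(fields[1])
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: non-integer length") from exc
    return genome


def write_genome(genome: Mapping[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, length in genome.items():
            fh.write(f"{chrom}\t{length}\n")
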
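"""Per-base conservation-score analysis.

A :class:`ScoreTrack` holds phyloP-style per-base scores (positive =
conserved, negative = accelerated) over the analysis universe only —
memory is bounded by the universe, not the genome. Missing positions are
explicit, never silently zero.

On top of the track: G/C-composition-matched null position sampling
(exact stratified sampling on the binary reference-base class {G,C} vs
{A,T}), empirical CDFs with pointwise bootstrap confidence envelopes,
two-sided Kolmogorov–Smirnov comparisons, within-element relative
positions (element start = 0%, end = 100%, flanks of one element length
mapped to [-100,0) and [100,200)), and pooled flanking-window score
samples around variant sites.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError
from .intervals import GenomicInterval, IntervalSet, PositionList, as_position_list, merge
from .variants import VariantSet

logger = logging.getLogger(__name__)

__all__ = [
    "ScoreTrack",
    "BaseComposition",
    "EcdfBand",
    "KsResult",
    "extract_scores",
    "gc_matched_sample",
    "ecdf_band",
    "ks_compare",
    "relative_positions",
    "flank_scores",
]

GC_BASES = frozenset(b"GCgc")


# ---------------------------------------------------------------------------
# Score track
# ---------------------------------------------------------------------------

class ScoreTrack:
    """Per-base score lookup backed by sorted position/value arrays per chromosome."""

    def __init__(self, data: Mapping[str, tuple[np.ndarray, np.ndarray]]) -> None:
        self._data: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, (pos, vals) in data.items():
            pos = np.asarray(pos, dtype=np.int64)
            vals = np.asarray(vals, dtype=np.float64)
            order = np.argsort(pos, kind="stable")
            pos, vals = pos[order], vals[order]
            # deduplicate: last value wins
            keep = np.concatenate([pos[1:] != pos[:-1], [True]]) if len(pos) else \
                np.zeros(0, dtype=bool)
            self._data[chrom] = (pos[keep], vals[keep])

    def __len__(self) -> int:
        return sum(len(p) for p, _ in self._data.values())

    @property
    def chroms(self) -> list[str]:
        return list(self._data)

    @classmethod
    def from_segments(
        cls, segments: Iterable[tuple[str, int, np.ndarray]]
    ) -> "ScoreTrack":
        """Build from (chrom, start, per-base values) segments (0-based starts)."""
        acc: dict[str, list[tuple[np.ndarray, np.ndarray]]] = {}
        for chrom, start, values in segments:
            values = np.asarray(values, dtype=np.float64)
            pos = np.arange(start, start + len(values), dtype=np.int64)
            acc.setdefault(chrom, []).append((pos, values))
        return cls(
            {
                c: (
                    np.concatenate([p for p, _ in parts]),
                    np.concatenate([v for _, v in parts]),
                )
                for c, parts in acc.items()
            }
        )

    @classmethod
    def from_bedgraph(cls, path: str | Path) -> "ScoreTrack":
        """Read a bedGraph (chrom, start, end, value; 0-based half-open)."""
        segments = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith(("track", "browser", "#")):
                    continue
                fields = line.split("\t")
                if len(fields) < 4:
                    raise DataError(f"{path}:{lineno}: expected 4 bedGraph fields")
                chrom, start, end, value = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
                segments.append((chrom, start, np.full(end - start, value)))
        return cls.from_segments(segments)

    @classmethod
    def from_wiggle(cls, path: str | Path) -> "ScoreTrack":
        """Read a fixedStep wiggle (1-based starts converted to 0-based)."""
        segments: list[tuple[str, int, list[float]]] = []
        chrom, pos, step = None, 0, 1
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith(("track", "browser", "#")):
                    continue
                if line.startswith("fixedStep"):
                    attrs = dict(kv.split("=") for kv in line.split()[1:])
                    chrom = attrs["chrom"]
                    pos = int(attrs["start"]) - 1
                    step = int(attrs.get("step", 1))
                    if int(attrs.get("span", 1)) != 1:
                        raise DataError(f"{path}:{lineno}: only span=1 supported")
                    segments.append((chrom, pos, []))
                else:
                    if chrom is None:
                        raise DataError(f"{path}:{lineno}: value before fixedStep header")
                    segments[-1][2].append(float(line))
        out: list[tuple[str, int, np.ndarray]] = []
        for chrom_, start_, vals in segments:
            vals_arr = np.asarray(vals)
            if step == 1:
                out.append((chrom_, start_, vals_arr))
            else:
                for i, v in enumerate(vals_arr):
                    out.append((chrom_, start_ + i * step, np.array([v])))
        return cls.from_segments(out)

    def write_bedgraph(self, path: str | Path) -> None:
        """Write as bedGraph, run-length collapsing consecutive equal-valued bases."""
        with open(path, "w") as fh:
            for chrom in self._data:
                pos, vals = self._data[chrom]
                if len(pos) == 0:
                    continue
                run_start = 0
                for i in range(1, len(pos) + 1):
                    if (
                        i == len(pos)
                        or pos[i] != pos[i - 1] + 1
                        or vals[i] != vals[run_start]
                    ):
                        fh.write(
                            f"{chrom}\t{pos[run_start]}\t{pos[i - 1] + 1}"
                            f"\t{vals[run_start]:.6g}\n"
                        )
                        run_start = i

    def lookup(self, positions) -> tuple[np.ndarray, np.ndarray]:
        """Scores at positions (NaN where undefined) and a found-mask, input order."""
        q = as_position_list(positions)
        out = np.full(len(q), np.nan)
        found = np.zeros(len(q), dtype=bool)
        for chrom, idx in q.group_indices().items():
            if chrom not in self._data:
                continue
            pos, vals = self._data[chrom]
            p = q.pos[idx]
            j = np.searchsorted(pos, p)
            ok = (j < len(pos)) & (pos[np.clip(j, 0, len(pos) - 1)] == p)
            out[idx[ok]] = vals[j[ok]]
            found[idx[ok]] = True
        return out, found


def extract_scores(
    positions, track: ScoreTrack
) -> tuple[np.ndarray, PositionList]:
    """Score per position, order-preserving; missing positions reported separately.

    Returns (scores aligned to input, NaN at missing; PositionList of missing
    positions). More than 5% missing logs a warning; all missing (for a
    non-empty query) raises.
    """
    q = as_position_list(positions)
    scores, found = track.lookup(q)
    missing = q.subset(np.flatnonzero(~found))
    if len(q) > 0 and len(missing) == len(q):
        raise DataError("no query position has a defined score")
    if len(q) > 0 and len(missing) / len(q) > 0.05:
        logger.warning(
            "%d of %d positions (%.1f%%) missing from score track",
            len(missing), len(q), 100 * len(missing) / len(q),
        )
    return scores, missing


# ---------------------------------------------------------------------------
# Base composition and G/C-matched sampling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BaseComposition:
    """Binary reference-base composition: fraction G/C (A/T is the complement)."""

    gc: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.gc <= 1.0:
            raise DataError(f"G/C fraction {self.gc} outside [0, 1]")

    @property
    def at(self) -> float:
        return 1.0 - self.gc

    @classmethod
    def from_bases(cls, bases: np.ndarray) -> "BaseComposition":
        b = np.asarray(bases)
        if b.size == 0:
            raise DataError("cannot compute composition of zero bases")
        is_gc = np.isin(b, np.array([b"G", b"C", b"g", b"c"], dtype="S1"))
        return cls(float(is_gc.mean()))

    @classmethod
    def from_positions(
        cls, reference: Mapping[str, np.ndarray], positions
    ) -> "BaseComposition":
        return cls.from_bases(_bases_at(reference, as_position_list(positions)))


def _bases_at(reference: Mapping[str, np.ndarray], q: PositionList) -> np.ndarray:
    out = np.empty(len(q), dtype="S1")
    for chrom, idx in q.group_indices().items():
        if chrom not in reference:
            raise DataError(f"chromosome {chrom} absent from reference")
        out[idx] = np.asarray(reference[chrom], dtype="S1")[q.pos[idx]]
    return out


def gc_matched_sample(
    universe: IntervalSet,
    reference: Mapping[str, np.ndarray],
    target: BaseComposition,
    n: int,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> PositionList:
    """Draw n positions from the universe, composition-matched to ``target``.

    Exact stratified sampling without replacement on the binary base class
    {G,C} vs {A,T}: per-stratum counts come from largest-remainder
    apportionment of ``n`` (so they are deterministic given target and n),
    positions are uniform within each stratum, and the draw is reproducible
    under a seed.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if n == 0:
        return PositionList.empty()
    all_pos = universe.positions()
    bases = _bases_at(reference, all_pos)
    is_gc = np.isin(bases, np.array([b"G", b"C", b"g", b"c"], dtype="S1"))
    strata = {"G/C": np.flatnonzero(is_gc), "A/T": np.flatnonzero(~is_gc)}
    # largest-remainder apportionment over the two strata
    ideal = {"G/C": n * target.gc, "A/T": n * target.at}
    counts = {k: int(np.floor(v)) for k, v in ideal.items()}
    leftover = n - sum(counts.values())
    for k in sorted(ideal, key=lambda k: (ideal[k] - counts[k], k == "G/C"), reverse=True):
        if leftover == 0:
            break
        counts[k] += 1
        leftover -= 1
    picks = []
    for name, idx in strata.items():
        need = counts[name]
        if need > len(idx):
            raise DataError(
                f"stratum {name}: need {need} positions but universe has {len(idx)}"
            )
        if need:
            picks.append(rng.choice(idx, size=need, replace=False))
    chosen = np.concatenate(picks) if picks else np.empty(0, dtype=np.intp)
    chosen = chosen[rng.permutation(len(chosen))]
    return all_pos.subset(chosen)


# ---------------------------------------------------------------------------
# ECDF with bootstrap band
# ---------------------------------------------------------------------------

@dataclass
class EcdfBand:
    """Empirical CDF of a score sample with a pointwise 95% bootstrap envelope."""

    sample: np.ndarray  # sorted
    grid: np.ndarray
    ecdf: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    n_boot: int

    def evaluate(self, x: np.ndarray | float) -> np.ndarray:
        """Right-continuous ECDF value(s) at arbitrary points."""
        return np.searchsorted(self.sample, np.asarray(x), side="right") / len(self.sample)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"x": self.grid, "ecdf": self.ecdf, "lower": self.lower, "upper": self.upper}
        )


def _ecdf_on_grid(sorted_sample: np.ndarray, grid: np.ndarray) -> np.ndarray:
    return np.searchsorted(sorted_sample, grid, side="right") / len(sorted_sample)


def ecdf_band(
    sample: Sequence[float] | np.ndarray,
    B: int = 1000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    grid: np.ndarray | None = None,
) -> EcdfBand:
    """Point ECDF plus pointwise 2.5/97.5-percentile envelope of B bootstrap ECDFs.

    The default evaluation grid is the sorted unique sample values (exact).
    Pass ``grid`` (e.g. 512 evenly spaced points) for plotting. The envelope
    is clipped to contain the point ECDF, preserving lower <= point <= upper.
    """
    x = np.sort(np.asarray(sample, dtype=float))
    if len(x) < 2:
        raise DataError("ecdf_band needs a sample of size >= 2")
    if B < 100:
        raise DataError("ecdf_band needs B >= 100 bootstrap replicates")
    if rng is None:
        rng = np.random.default_rng(seed)
    if grid is None:
        grid = np.unique(x)
    point = _ecdf_on_grid(x, grid)
    boot = np.empty((B, len(grid)))
    n = len(x)
    for b in range(B):
        res = np.sort(x[rng.integers(0, n, size=n)])
        boot[b] = _ecdf_on_grid(res, grid)
    lower = np.percentile(boot, 2.5, axis=0)
    upper = np.percentile(boot, 97.5, axis=0)
    lower = np.minimum(lower, point)
    upper = np.maximum(upper, point)
    return EcdfBand(sample=x, grid=grid, ecdf=point, lower=lower, upper=upper, n_boot=B)


# ---------------------------------------------------------------------------
# Kolmogorov–Smirnov comparison
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KsResult:
    statistic: float
    pvalue: float


def ks_compare(sample_a, sample_b) -> KsResult:
    """Two-sided two-sample KS test: D = sup |ECDF_a - ECDF_b|, asymptotic p."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise DataError("ks_compare needs non-empty samples")
    res = stats.ks_2samp(a, b, alternative="two-sided", method="asymp")
    return KsResult(float(res.statistic), float(res.pvalue))


# ---------------------------------------------------------------------------
# Relative positions within host elements
# ---------------------------------------------------------------------------

def relative_positions(
    variants: VariantSet | PositionList,
    elements: IntervalSet,
) -> pd.DataFrame:
    """Express variant positions as a percentage along their host element.

    Inside an element maps to [0, 100) (start = 0%, end = 100%); flanks of
    one element length map to [-100, 0) upstream and [100, 200) downstream
    by the same scaling. A position ambiguous between two elements' flanks is
    assigned to the nearer one; a tie goes to the upstream (leftward)
    element (logged). A position farther than one element length from every
    element is an error.
    """
    q = variants.positions() if isinstance(variants, VariantSet) else as_position_list(variants)
    merged = merge(elements)
    index = merged.merged_index()
    rows = []
    n_ties = 0
    for chrom, pos in q:
        if chrom not in index:
            raise DataError(f"position {chrom}:{pos} has no element on its chromosome")
        starts, ends = index[chrom]
        j = int(np.searchsorted(starts, pos, side="right")) - 1
        host = None
        if j >= 0 and pos < ends[j]:
            host = j
            region = "inside"
        else:
            # candidate flanks: element to the left (downstream flank) and right (upstream flank)
            cand = []
            if j >= 0:  # left element ends at ends[j] <= pos
                L = int(ends[j] - starts[j])
                if pos < ends[j] + L:
                    cand.append((int(pos - ends[j]) + 1, j, "downstream"))
            if j + 1 < len(starts):  # right element begins after pos
                L = int(ends[j + 1] - starts[j + 1])
                if pos >= starts[j + 1] - L:
                    cand.append((int(starts[j + 1] - pos), j + 1, "upstream"))
            if not cand:
                raise DataError(
                    f"position {chrom}:{pos} is farther than one element length "
                    "from every element"
                )
            if len(cand) == 2 and cand[0][0] == cand[1][0]:
                n_ties += 1
                cand = [c for c in cand if c[2] == "downstream"]  # upstream *element*
            cand.sort()
            _, host, region = cand[0]
        s, e = int(starts[host]), int(ends[host])
        percent = (pos - s) / (e - s) * 100.0
        rows.append(
            {
                "chrom": chrom,
                "pos": pos,
                "percent": percent,
                "host_start": s,
                "host_end": e,
                "region": region,
            }
        )
    if n_ties:
        logger.info("%d flank positions tied between two elements; assigned upstream", n_ties)
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "percent", "host_start", "host_end", "region"]
    )


# ---------------------------------------------------------------------------
# Flanking-window scores
# ---------------------------------------------------------------------------

@dataclass
class FlankScores:
    """Pooled score samples for the bases flanking each variant site."""

    upstream: np.ndarray
    downstream: np.ndarray
    n_missing_upstream: int
    n_missing_downstream: int


def flank_scores(
    variants: VariantSet | PositionList,
    track: ScoreTrack,
    window: int = 3,
) -> FlankScores:
    """Scores of the ``window`` bases immediately 5' and 3' of each variant.

    The variant base itself is excluded; for a variant at position p the
    upstream window is [p-window, p) and the downstream window is
    (p, p+window]. Scores are pooled across variants into one sample per
    side; bases falling outside the track domain are dropped and counted.
    """
    if window < 1:
        raise DataError("flank window must be >= 1")
    q = variants.positions() if isinstance(variants, VariantSet) else as_position_list(variants)
    offs = np.arange(1, window + 1)
    sides = {}
    for name, sign in (("upstream", -1), ("downstream", +1)):
        chroms = np.repeat(q.chroms, window)
        pos = (q.pos[:, None] + sign * offs[None, :]).ravel()
        keep = pos >= 0
        pl = PositionList(chroms[keep], pos[keep])
        vals, found = track.lookup(pl)
        sides[name] = (vals[found], int((~found).sum()) + int((~keep).sum()))
    return FlankScores(
        upstream=sides["upstream"][0],
        downstream=sides["downstream"][0],
        n_missing_upstream=sides["upstream"][1],
        n_missing_downstream=sides["downstream"][1],
    )
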
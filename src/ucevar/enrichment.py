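"""Feature-overlap enrichment and depletion tests.

Two complementary designs, mirroring how regulatory-feature overlap of
variant classes is usually tested:

* a 2x2 Pearson chi-squared test (no continuity correction) of query
  positions vs an equal-size composition-matched null set, reporting the
  relative overlap (query rate / null rate; 1.0 = no difference);
* a resampling summary — repeated fixed-size position sets drawn from a
  pool, per-set overlap counts, mean and percentile 95% CI — with a
  two-tailed Mann–Whitney rank test between two such summaries.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError, DegenerateStatisticsWarning
from .conservation import BaseComposition, gc_matched_sample
from .intervals import IntervalSet, PositionList, as_position_list, overlap_count

logger = logging.getLogger(__name__)

__all__ = [
    "OverlapTestResult",
    "ResampleResult",
    "overlap_chi2",
    "resample_overlap",
    "compare_resamples",
    "class_depletion_report",
]


@dataclass
class OverlapTestResult:
    """2x2 overlap test of a query position set against a null position set."""

    query_overlap: int
    query_total: int
    null_overlap: int
    null_total: int
    chi2: float
    pvalue: float
    relative_overlap: float
    low_expected: bool = False
    degenerate: bool = False

    @property
    def query_rate(self) -> float:
        return self.query_overlap / self.query_total if self.query_total else float("nan")

    @property
    def null_rate(self) -> float:
        return self.null_overlap / self.null_total if self.null_total else float("nan")


def overlap_chi2(
    query_positions, null_positions, features: IntervalSet
) -> OverlapTestResult:
    """Pearson chi-squared (no continuity correction) on the 2x2 overlap table.

    Rows are query/null, columns overlap/non-overlap. Relative overlap is
    the query overlap rate divided by the null overlap rate. An expected
    cell below 5 sets ``low_expected`` (test still computed); a zero margin
    (e.g. empty feature set: nobody overlaps) yields a degenerate result
    with NaN statistic and a warning.
    """
    q = as_position_list(query_positions)
    nl = as_position_list(null_positions)
    if len(q) == 0 or len(nl) == 0:
        raise DataError("overlap_chi2 needs non-empty query and null position sets")
    qo, _ = overlap_count(q, features)
    no, _ = overlap_count(nl, features)
    table = np.array([[qo, len(q) - qo], [no, len(nl) - no]], dtype=float)
    rel = (
        (qo / len(q)) / (no / len(nl)) if no > 0 else float("inf") if qo > 0 else float("nan")
    )
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        warnings.warn(
            "degenerate 2x2 overlap table (zero margin); chi-squared undefined",
            DegenerateStatisticsWarning,
            stacklevel=2,
        )
        return OverlapTestResult(qo, len(q), no, len(nl), float("nan"), float("nan"),
                                 rel, degenerate=True)
    chi2, p, _, expected = stats.chi2_contingency(table, correction=False)
    return OverlapTestResult(
        qo, len(q), no, len(nl), float(chi2), float(p), float(rel),
        low_expected=bool(expected.min() < 5),
    )


@dataclass
class ResampleResult:
    """Per-set overlap counts from repeated fixed-size draws out of a position pool."""

    counts: np.ndarray
    set_size: int
    n_sets: int
    label: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.n_sets < 2:
            raise DataError("need at least 2 resampled sets")
        if ((self.counts < 0) | (self.counts > self.set_size)).any():
            raise DataError("per-set counts must lie in [0, set_size]")

    @property
    def mean(self) -> float:
        return float(self.counts.mean())

    @property
    def ci(self) -> tuple[float, float]:
        """Percentile 95% interval of the per-set counts."""
        return (
            float(np.percentile(self.counts, 2.5)),
            float(np.percentile(self.counts, 97.5)),
        )


def resample_overlap(
    position_pool,
    features: IntervalSet,
    n_sets: int = 100,
    set_size: int = 1000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    label: str = "",
) -> ResampleResult:
    """Draw ``n_sets`` sets of ``set_size`` positions from the pool; count overlaps.

    Each set is sampled without replacement within itself; sets are drawn
    independently of each other (a position may recur across sets), keeping
    per-set counts i.i.d. for rank comparisons. Reproducible under a seed.
    """
    pool = as_position_list(position_pool)
    if len(pool) < set_size:
        raise DataError(f"pool of {len(pool)} positions smaller than set size {set_size}")
    if rng is None:
        rng = np.random.default_rng(seed)
    _, flags = overlap_count(pool, features)
    counts = np.empty(n_sets, dtype=np.int64)
    for s in range(n_sets):
        idx = rng.choice(len(pool), size=set_size, replace=False)
        counts[s] = int(flags[idx].sum())
    return ResampleResult(counts=counts, set_size=set_size, n_sets=n_sets, label=label)


@dataclass(frozen=True)
class MannWhitneyResult:
    statistic: float
    pvalue: float
    higher: str  # label of the side with the higher median, or "tie"


def compare_resamples(a: ResampleResult, b: ResampleResult) -> MannWhitneyResult:
    """Two-tailed Mann–Whitney rank test on the two per-set count vectors.

    Exact enumeration when both vectors are shorter than 20 and tie-free;
    otherwise the normal approximation with tie correction. All counts tied
    across both vectors gives p = 1.
    """
    x, y = a.counts, b.counts
    if np.all(x == x[0]) and np.all(y == y[0]) and x[0] == y[0]:
        return MannWhitneyResult(len(x) * len(y) / 2.0, 1.0, "tie")
    ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (len(x) < 20 and len(y) < 20 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    med_a, med_b = float(np.median(x)), float(np.median(y))
    if med_a > med_b:
        higher = a.label or "a"
    elif med_b > med_a:
        higher = b.label or "b"
    else:
        higher = "tie"
    return MannWhitneyResult(float(res.statistic), float(res.pvalue), higher)


def class_depletion_report(
    class_positions: Mapping[str, PositionList],
    universe: IntervalSet,
    reference: Mapping[str, np.ndarray],
    features: IntervalSet,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> dict[str, OverlapTestResult]:
    """Per-frequency-class feature overlap vs an equal-size G/C-matched null.

    For each class, a random position set of equal size is drawn from the
    element universe, composition-matched to the class's variant positions,
    and the 2x2 chi-squared overlap test is computed. Relative overlap below
    1.0 means the class is depleted in the features relative to matched
    random element positions.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    out: dict[str, OverlapTestResult] = {}
    for name, positions in class_positions.items():
        pl = as_position_list(positions)
        if len(pl) == 0:
            raise DataError(f"frequency class {name!r} has no positions")
        target = BaseComposition.from_positions(reference, pl)
        null = gc_matched_sample(universe, reference, target, n=len(pl), rng=rng)
        out[name] = overlap_chi2(pl, null, features)
    return out


def depletion_report_frame(
    report: Mapping[str, OverlapTestResult], bonferroni: bool = False
) -> pd.DataFrame:
    """Tabulate a class depletion report (one row per class) for TSV export.

    Per-class tests are reported uncorrected by default, matching the
    per-set testing design; ``bonferroni=True`` adds a column with p-values
    multiplied by the number of classes (capped at 1).
    """
    df = pd.DataFrame(
        [
            {
                "class": name,
                "n_positions": r.query_total,
                "overlap": r.query_overlap,
                "null_overlap": r.null_overlap,
                "relative_overlap": r.relative_overlap,
                "chi2": r.chi2,
                "pvalue": r.pvalue,
                "low_expected": r.low_expected,
                "degenerate": r.degenerate,
            }
            for name, r in report.items()
        ]
    )
    if bonferroni and len(df):
        df["pvalue_bonferroni"] = np.minimum(df["pvalue"] * len(df), 1.0)
    return df
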
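"""Synthetic data with the statistical structure the analysis assumes.

The generator emulates, on a small genome, the features the pipeline
consumes: an AT-rich set of conserved elements embedded in a background
sequence; a phyloP-like score track elevated inside elements except at a
fraction of "relaxed" positions; frequency-stratified variant sets whose
placement depends on score (prevalent variants preferentially land on
low-score positions, via rejection sampling with a logistic acceptance in
-beta * score, while rare variants are uniform); a sparse
transcription-factor-binding feature track whose per-base cover probability
rises with conservation score inside elements; and a separate dense
feature cover over non-conserved super-enhancer-like regions.

Scores are Gaussian mixtures rather than alignment-derived — the analyses
consume only score ranks and ECDFs, so the distributional family is
immaterial. Feature tracks are merged runs of independent per-base
Bernoulli draws, which makes realized coverage exactly binomial (handy for
oracle checks) at the cost of unrealistically short intervals; the
analyses only ever ask per-base overlap questions, so interval length does
not enter. MAFs are drawn from class-consistent uniform ranges, not
evolved under any demographic model.

Everything is deterministic under the configured seed: each stage draws
from a named substream derived from it.
"""
from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import DataError
from .conservation import ScoreTrack
from .intervals import (
    GenomicInterval,
    IntervalSet,
    PositionList,
    merge,
    write_bed,
    write_genome,
)
from .variants import VariantRecord, VariantSet, write_vcf

__all__ = [
    "SyntheticConfig",
    "SyntheticFeatures",
    "SyntheticDataset",
    "derived_rng",
    "simulate_genome",
    "simulate_scores",
    "simulate_variants",
    "simulate_features",
    "simulate_dataset",
    "write_dataset",
]

_BASES = np.array([b"A", b"C", b"G", b"T"], dtype="S1")


def derived_rng(seed: int, name: str) -> np.random.Generator:
    """A named, reproducible substream of the top-level seed."""
    return np.random.default_rng(
        np.random.SeedSequence([seed & 0x7FFFFFFF, zlib.crc32(name.encode())])
    )


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic scenario (defaults = the study conditions).

    Sizes are chosen so a full end-to-end run completes in a couple of
    seconds: a 10 Mb genome carrying 300 conserved elements of 200–600 bp
    (the 200 bp floor matches the element definition) and 2000 variants per
    frequency class. Scores are in phyloP-like units; ``beta`` is the
    log-odds decrease in prevalent-variant placement probability per unit
    score.
    """

    chrom_sizes: Mapping[str, int] = field(default_factory=lambda: {"chrS": 10_000_000})
    n_elements: int = 300
    element_length_range: tuple[int, int] = (200, 600)
    element_min_gap: int = 2000

    background_gc: float = 0.41  # genome-wide G+C fraction of the background
    element_at_fraction: float = 0.62  # conserved elements are AT-rich

    score_mu_element: float = 3.0
    score_sd_element: float = 0.7
    relaxed_fraction: float = 0.15  # fraction of element bases under relaxed constraint
    score_mu_relaxed: float = 0.0
    score_sd_relaxed: float = 0.7
    score_mu_background: float = 0.0
    score_sd_background: float = 0.8

    n_rare: int = 2000
    n_intermediate: int = 2000
    n_prevalent: int = 2000
    beta: float = 1.5
    beta_intermediate: float = 0.75

    tfbs_in_element_density: float = 0.40
    tfbs_background_density: float = 0.02
    tfbs_score_coupling: float = 2.0  # logistic slope of cover prob in score

    n_se_regions: int = 60
    se_length_range: tuple[int, int] = (2000, 10000)
    se_tfbs_density: float = 0.70

    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_elements", "n_rare", "n_intermediate", "n_prevalent",
                     "n_se_regions"):
            if getattr(self, name) < 0:
                raise DataError(f"{name} must be >= 0")
        for name in ("background_gc", "element_at_fraction", "relaxed_fraction",
                     "tfbs_in_element_density", "tfbs_background_density",
                     "se_tfbs_density"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise DataError(f"{name}={v} outside [0, 1]")
        if self.element_length_range[0] < 200:
            raise DataError("element lengths must be >= 200 bp")
        if self.element_length_range[0] > self.element_length_range[1]:
            raise DataError("element length range inverted")

    def with_(self, **kwargs) -> "SyntheticConfig":
        return replace(self, **kwargs)


# ---------------------------------------------------------------------------
# placement helpers
# ---------------------------------------------------------------------------

def _apportion(n: int, weights: np.ndarray) -> np.ndarray:
    """Largest-remainder apportionment of n into len(weights) integer parts."""
    ideal = n * weights / weights.sum()
    base = np.floor(ideal).astype(int)
    rem = ideal - base
    for i in np.argsort(-rem)[: n - base.sum()]:
        base[i] += 1
    return base


def _place_nonoverlapping(
    lengths: np.ndarray, chrom_len: int, min_gap: int, margin: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Uniform non-overlapping starts for the given lengths within one chromosome."""
    n = len(lengths)
    if n == 0:
        return np.empty(0, dtype=np.int64)
    order = rng.permutation(n)
    shuffled = lengths[order]
    slack = chrom_len - 2 * margin - int(shuffled.sum()) - (n - 1) * min_gap
    if slack < 0:
        raise DataError("element total length (plus gaps) exceeds chromosome")
    gaps = np.sort(rng.integers(0, slack + 1, size=n))
    starts = margin + gaps + np.concatenate([[0], np.cumsum(shuffled[:-1] + min_gap)])
    out = np.empty(n, dtype=np.int64)
    out[order] = starts
    return out


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

def simulate_genome(
    config: SyntheticConfig, rng: np.random.Generator | None = None
) -> tuple[dict[str, np.ndarray], IntervalSet]:
    """Reference bases plus embedded conserved elements.

    Background bases are i.i.d. at the configured G/C fraction; element
    interiors are resampled at the element A/T enrichment.
    """
    if rng is None:
        rng = derived_rng(config.seed, "genome")
    chroms = list(config.chrom_sizes)
    sizes = np.array([config.chrom_sizes[c] for c in chroms], dtype=float)
    counts = _apportion(config.n_elements, sizes)
    gc = config.background_gc
    p_bg = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    at = config.element_at_fraction
    p_el = np.array([at / 2, (1 - at) / 2, (1 - at) / 2, at / 2])
    reference: dict[str, np.ndarray] = {}
    elements: list[GenomicInterval] = []
    lo, hi = config.element_length_range
    margin = hi  # keep one element length of flank inside the chromosome
    for chrom, n_el in zip(chroms, counts):
        L = config.chrom_sizes[chrom]
        seq = _BASES[rng.choice(4, size=L, p=p_bg)]
        lengths = rng.integers(lo, hi + 1, size=int(n_el)).astype(np.int64)
        starts = _place_nonoverlapping(lengths, L, config.element_min_gap, margin, rng)
        order = np.argsort(starts)
        for k, (s, ln) in enumerate(zip(starts[order], lengths[order])):
            seq[s : s + ln] = _BASES[rng.choice(4, size=int(ln), p=p_el)]
            elements.append(GenomicInterval(chrom, int(s), int(s + ln), f"{chrom}_el{k}"))
        reference[chrom] = seq
    return reference, IntervalSet(elements, genome=dict(config.chrom_sizes))


def place_se_regions(
    config: SyntheticConfig,
    elements: IntervalSet,
    rng: np.random.Generator | None = None,
    max_retries: int = 1000,
) -> IntervalSet:
    """Place non-conserved super-enhancer-like regions avoiding the elements."""
    if rng is None:
        rng = derived_rng(config.seed, "se")
    excl = merge(elements)
    excl_index = excl.merged_index()
    chroms = list(config.chrom_sizes)
    sizes = np.array([config.chrom_sizes[c] for c in chroms], dtype=float)
    counts = _apportion(config.n_se_regions, sizes)
    lo, hi = config.se_length_range
    out: list[GenomicInterval] = []
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    for chrom, n_se in zip(chroms, counts):
        L = config.chrom_sizes[chrom]
        for k in range(int(n_se)):
            ln = int(rng.integers(lo, hi + 1))
            for _ in range(max_retries):
                s = int(rng.integers(0, L - ln + 1))
                e = s + ln
                if chrom in excl_index:
                    starts, ends = excl_index[chrom]
                    j = int(np.searchsorted(starts, e, side="left")) - 1
                    if j >= 0 and ends[j] > s:
                        continue
                if any(ps < e and pe > s for ps, pe in placed[chrom]):
                    continue
                placed[chrom].append((s, e))
                out.append(GenomicInterval(chrom, s, e, f"{chrom}_se{k}"))
                break
            else:
                raise DataError("could not place a super-enhancer-like region")
    return IntervalSet(sorted(out, key=lambda iv: (iv.chrom, iv.start)),
                       genome=dict(config.chrom_sizes))


# ---------------------------------------------------------------------------
# scores
# ---------------------------------------------------------------------------

def analysis_universe(config: SyntheticConfig, elements: IntervalSet,
                      extra: IntervalSet | None = None) -> IntervalSet:
    """Elements extended by one element length each side, plus any extra regions."""
    ivs = []
    for iv in merge(elements):
        L = iv.length
        lo = max(0, iv.start - L)
        hi = min(config.chrom_sizes[iv.chrom], iv.end + L)
        ivs.append(GenomicInterval(iv.chrom, lo, hi))
    if extra is not None:
        ivs.extend(extra)
    return merge(IntervalSet(ivs, genome=dict(config.chrom_sizes)))


def simulate_scores(
    config: SyntheticConfig,
    elements: IntervalSet,
    extra: IntervalSet | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[ScoreTrack, PositionList]:
    """Score track over the analysis universe, plus the relaxed ground truth.

    Element bases score Normal(mu_element, sd_element) except a configured
    fraction of relaxed positions at Normal(mu_relaxed, sd_relaxed);
    everything else in the universe (flanks, extra regions) scores
    Normal(mu_background, sd_background). The track covers only the
    universe — memory is bounded by it, not the genome.
    """
    if rng is None:
        rng = derived_rng(config.seed, "scores")
    universe = analysis_universe(config, elements, extra)
    segments = []
    relaxed_chroms: list[np.ndarray] = []
    relaxed_pos: list[np.ndarray] = []
    el_index = merge(elements).merged_index()
    for iv in universe:
        n = iv.length
        vals = rng.normal(config.score_mu_background, config.score_sd_background, size=n)
        if iv.chrom in el_index:
            starts, ends = el_index[iv.chrom]
            j0 = np.searchsorted(ends, iv.start, side="right")
            for j in range(j0, len(starts)):
                if starts[j] >= iv.end:
                    break
                s = max(int(starts[j]), iv.start) - iv.start
                e = min(int(ends[j]), iv.end) - iv.start
                m = e - s
                inside = rng.normal(config.score_mu_element, config.score_sd_element, size=m)
                relax = rng.random(m) < config.relaxed_fraction
                inside[relax] = rng.normal(
                    config.score_mu_relaxed, config.score_sd_relaxed, size=int(relax.sum())
                )
                vals[s:e] = inside
                rp = np.flatnonzero(relax) + iv.start + s
                relaxed_pos.append(rp)
                relaxed_chroms.append(np.full(len(rp), iv.chrom, dtype=object))
        segments.append((iv.chrom, iv.start, vals))
    track = ScoreTrack.from_segments(segments)
    relaxed = (
        PositionList(np.concatenate(relaxed_chroms), np.concatenate(relaxed_pos))
        if relaxed_pos
        else PositionList.empty()
    )
    return track, relaxed


# ---------------------------------------------------------------------------
# variants
# ---------------------------------------------------------------------------

_MAF_RANGES = {
    "rare": (0.0005, 0.005),
    "intermediate": (0.005, 0.05),
    "prevalent": (0.05, 0.5),
}


def simulate_variants(
    config: SyntheticConfig,
    elements: IntervalSet,
    track: ScoreTrack,
    reference: Mapping[str, np.ndarray],
    rng: np.random.Generator | None = None,
) -> tuple[VariantSet, pd.DataFrame]:
    """Frequency-stratified SNVs over element positions, with ground truth.

    Rare variants are placed uniformly; intermediate and prevalent variants
    by rejection sampling with acceptance probability logistic in
    ``-beta * score`` (beta_intermediate / beta respectively). Positions are
    distinct across the whole set; MAFs are uniform in class-consistent
    ranges; the alternate base is drawn uniformly from the three non-
    reference bases. Ground truth records class and placement score.
    """
    if rng is None:
        rng = derived_rng(config.seed, "variants")
    all_pos = merge(elements).positions()
    scores, found = track.lookup(all_pos)
    if not found.all():
        raise DataError("score track does not cover every element position")
    n_avail = len(all_pos)
    wanted = [
        ("rare", config.n_rare, 0.0),
        ("intermediate", config.n_intermediate, config.beta_intermediate),
        ("prevalent", config.n_prevalent, config.beta),
    ]
    if sum(n for _, n, _ in wanted) > n_avail:
        raise DataError(
            f"requested {sum(n for _, n, _ in wanted)} variants but only "
            f"{n_avail} element positions available"
        )
    used = np.zeros(n_avail, dtype=bool)
    records: list[VariantRecord] = []
    truth_rows = []
    for cls, n_want, beta in wanted:
        chosen: list[int] = []
        if beta == 0.0:
            free = np.flatnonzero(~used)
            chosen = list(rng.choice(free, size=n_want, replace=False)) if n_want else []
        else:
            max_batches = 2000
            for _ in range(max_batches):
                if len(chosen) >= n_want:
                    break
                cand = rng.integers(0, n_avail, size=max(256, 2 * (n_want - len(chosen))))
                accept = rng.random(len(cand)) < 1.0 / (1.0 + np.exp(beta * scores[cand]))
                for i in cand[accept]:
                    if not used[i]:
                        used[i] = True
                        chosen.append(int(i))
                        if len(chosen) >= n_want:
                            break
            if len(chosen) < n_want:
                raise DataError(
                    f"could not place {n_want} {cls} variants (placement too constrained)"
                )
        used[chosen] = True
        lo, hi = _MAF_RANGES[cls]
        mafs = rng.uniform(np.nextafter(lo, 1.0), hi, size=len(chosen))
        for i, maf in zip(chosen, mafs):
            chrom, pos = all_pos.chroms[i], int(all_pos.pos[i])
            ref = reference[chrom][pos].decode()
            alts = [b for b in "ACGT" if b != ref]
            alt = alts[int(rng.integers(0, 3))]
            records.append(VariantRecord(chrom, pos, ref, alt, float(maf), "SIM"))
            truth_rows.append(
                {"chrom": chrom, "pos": pos, "class": cls, "score": float(scores[i]),
                 "maf": float(maf)}
            )
    truth = pd.DataFrame(truth_rows, columns=["chrom", "pos", "class", "score", "maf"])
    return VariantSet(records, provenance="SIM"), truth


# ---------------------------------------------------------------------------
# features
# ---------------------------------------------------------------------------

@dataclass
class SyntheticFeatures:
    """Feature tracks: sparse element-coupled, dense SE cover, and their union."""

    sparse: IntervalSet  # element-coupled TFBS analog + genomic background
    dense: IntervalSet  # dense cover of the SE-like regions
    union: IntervalSet
    realized: dict[str, float]  # realized coverage fractions per compartment


def _scaled_probabilities(weights: np.ndarray, target_mean: float) -> np.ndarray:
    """Scale weights into per-base probabilities min(s*w, 1) with mean = target.

    The clipped mean is monotone in s, so s is found by bisection; a target
    of 1 (or one unreachable because every weight would need clipping) gives
    all-ones.
    """
    if target_mean <= 0.0:
        return np.zeros_like(weights)
    if target_mean >= 1.0:
        return np.ones_like(weights)
    lo, hi = 0.0, 1.0
    while np.minimum(hi * weights, 1.0).mean() < target_mean:
        hi *= 2.0
        if hi > 1e12:
            return np.ones_like(weights)
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if np.minimum(mid * weights, 1.0).mean() < target_mean:
            lo = mid
        else:
            hi = mid
    return np.minimum(hi * weights, 1.0)


def _mask_to_intervals(chrom: str, offset: int, mask: np.ndarray) -> list[GenomicInterval]:
    edges = np.flatnonzero(np.diff(np.concatenate([[0], mask.view(np.int8), [0]])))
    return [
        GenomicInterval(chrom, offset + int(s), offset + int(e))
        for s, e in zip(edges[::2], edges[1::2])
    ]


def simulate_features(
    config: SyntheticConfig,
    elements: IntervalSet,
    track: ScoreTrack,
    se_regions: IntervalSet | None = None,
    rng: np.random.Generator | None = None,
) -> SyntheticFeatures:
    """Per-base Bernoulli feature cover, score-coupled inside elements.

    Inside elements the cover probability is proportional to a logistic
    function of the conservation score (slope ``tfbs_score_coupling``,
    centred between the relaxed and conserved means) and scaled so the mean
    equals ``tfbs_in_element_density``: conserved bases are bound, relaxed
    bases mostly are not. The remaining genome gets a uniform background
    density, and SE-like regions a uniform dense cover. Realized coverage
    fractions are reported per compartment.
    """
    if rng is None:
        rng = derived_rng(config.seed, "features")
    merged_el = merge(elements)
    sparse: list[GenomicInterval] = []
    realized: dict[str, float] = {}

    # -- element-coupled cover
    el_pos = merged_el.positions()
    if len(el_pos):
        scores, found = track.lookup(el_pos)
        if not found.all():
            raise DataError("score track does not cover every element position")
        mid = 0.5 * (config.score_mu_element + config.score_mu_relaxed)
        w = 1.0 / (1.0 + np.exp(-config.tfbs_score_coupling * (scores - mid)))
        p = _scaled_probabilities(w, config.tfbs_in_element_density)
        covered = rng.random(len(el_pos)) < p
        realized["in_element"] = float(covered.mean())
        i = 0
        for iv in merged_el:
            m = covered[i : i + iv.length]
            sparse.extend(_mask_to_intervals(iv.chrom, iv.start, m))
            i += iv.length

    # -- uniform genomic background outside elements (and outside SE regions)
    bg_total = 0
    bg_covered = 0
    excl = merge(IntervalSet(
        list(merged_el) + (list(se_regions) if se_regions is not None else []),
        genome=dict(config.chrom_sizes),
    ))
    excl_index = excl.merged_index()
    for chrom, L in config.chrom_sizes.items():
        bounds = [0]
        if chrom in excl_index:
            starts, ends = excl_index[chrom]
            for s, e in zip(starts, ends):
                bounds.extend([int(s), int(e)])
        bounds.append(L)
        for s, e in zip(bounds[::2], bounds[1::2]):
            if e <= s:
                continue
            m = rng.random(e - s) < config.tfbs_background_density
            bg_total += e - s
            bg_covered += int(m.sum())
            sparse.extend(_mask_to_intervals(chrom, s, m))
    realized["background"] = bg_covered / bg_total if bg_total else 0.0

    # -- dense cover of SE-like regions
    dense: list[GenomicInterval] = []
    se_total = 0
    se_covered = 0
    if se_regions is not None:
        for iv in merge(se_regions):
            m = rng.random(iv.length) < config.se_tfbs_density
            se_total += iv.length
            se_covered += int(m.sum())
            dense.extend(_mask_to_intervals(iv.chrom, iv.start, m))
    realized["se"] = se_covered / se_total if se_total else 0.0

    # masks already yield disjoint maximal runs per compartment, and the
    # compartments (elements / background / SE) partition the genome, so no
    # further merging is needed; IntervalSet sorts lazily where required.
    genome = dict(config.chrom_sizes)
    sparse_set = IntervalSet(sparse, genome=genome)
    dense_set = IntervalSet(dense, genome=genome)
    union = IntervalSet(sparse + dense, genome=genome)
    return SyntheticFeatures(sparse=sparse_set, dense=dense_set, union=union,
                             realized=realized)


# ---------------------------------------------------------------------------
# full dataset
# ---------------------------------------------------------------------------

@dataclass
class SyntheticDataset:
    """Everything one end-to-end run needs, generated from one seed."""

    config: SyntheticConfig
    genome: dict[str, int]
    reference: dict[str, np.ndarray]
    elements: IntervalSet
    se_regions: IntervalSet
    track: ScoreTrack
    relaxed: PositionList
    variants: VariantSet
    ground_truth: pd.DataFrame
    features: SyntheticFeatures


def simulate_dataset(config: SyntheticConfig | None = None, seed: int | None = None) -> SyntheticDataset:
    """Run every generator stage off named substreams of one seed."""
    if config is None:
        config = SyntheticConfig()
    if seed is not None:
        config = config.with_(seed=seed)
    reference, elements = simulate_genome(config)
    se_regions = place_se_regions(config, elements)
    track, relaxed = simulate_scores(config, elements, extra=se_regions)
    variants, truth = simulate_variants(config, elements, track, reference)
    features = simulate_features(config, elements, track, se_regions)
    return SyntheticDataset(
        config=config,
        genome=dict(config.chrom_sizes),
        reference=reference,
        elements=elements,
        se_regions=se_regions,
        track=track,
        relaxed=relaxed,
        variants=variants,
        ground_truth=truth,
        features=features,
    )


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write the dataset in the exact formats the pipeline ingests."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "reference": outdir / "reference.fa",
        "genome": outdir / "genome.txt",
        "elements": outdir / "elements.bed",
        "se_regions": outdir / "se_regions.bed",
        "tfbs": outdir / "tfbs.bed",
        "scores": outdir / "scores.bedGraph",
        "variants": outdir / "variants.vcf",
        "ground_truth": outdir / "ground_truth.tsv",
    }
    with open(paths["reference"], "w") as fh:
        for chrom, seq in ds.reference.items():
            fh.write(f">{chrom}\n")
            raw = seq.tobytes().decode()
            for i in range(0, len(raw), 80):
                fh.write(raw[i : i + 80] + "\n")
    write_genome(ds.genome, paths["genome"])
    write_bed(ds.elements, paths["elements"])
    write_bed(ds.se_regions, paths["se_regions"])
    write_bed(ds.features.union, paths["tfbs"])
    ds.track.write_bedgraph(paths["scores"])
    write_vcf(ds.variants, paths["variants"], contigs=ds.genome)
    ds.ground_truth.to_csv(paths["ground_truth"], sep="\t", index=False)
    return paths
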
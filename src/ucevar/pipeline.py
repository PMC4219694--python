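"""End-to-end orchestration: load tracks, run the three analyses, write reports.

Every run is driven by a :class:`RunConfig` (YAML/JSON on disk) and one
top-level seed; each stage draws from a named substream so stages are
individually reproducible. Outputs are TSV tables plus a ``manifest.json``
(config hash, seed, package version) sufficient to reproduce them
bit-for-bit; a re-run with the same config and seed writes byte-identical
files. Filtering counts are logged at every step.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigError, DataError
from .conservation import (
    BaseComposition,
    ScoreTrack,
    ecdf_band,
    extract_scores,
    flank_scores,
    gc_matched_sample,
    ks_compare,
    relative_positions,
)
from .enrichment import (
    class_depletion_report,
    compare_resamples,
    depletion_report_frame,
    resample_overlap,
)
from .intervals import (
    GenomicInterval,
    IntervalSet,
    PositionList,
    merge,
    read_bed,
    read_genome,
    sample_positions,
)
from .simulate import derived_rng
from .variants import FrequencyClass, VariantSet, read_vcf_snvs, sharing_table, snv_rate

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.6g"


@dataclass
class RunConfig:
    """Paths and parameters of one pipeline run."""

    elements_bed: str
    genome_file: str
    variant_vcfs: dict[str, str] = field(default_factory=dict)  # population -> path
    samples: dict[str, int] = field(default_factory=dict)  # population -> n samples
    score_track: str | None = None  # bedGraph (.bedGraph) or fixedStep wiggle (.wig)
    tfbs_bed: str | None = None
    se_bed: str | None = None
    reference_fasta: str | None = None
    af_field: str = "AF"
    rare_below: float = 0.005
    prevalent_above: float = 0.05
    bootstrap_B: int = 1000
    n_sets: int = 100
    set_size: int = 1000
    random_pool_size: int = 20000  # random-genomic position pool for resampling
    seed: int = 0
    outdir: str = "results"
    force: bool = False

    def validate(self, require: tuple[str, ...] = ()) -> None:
        if not (0.0 < self.rare_below < self.prevalent_above < 0.5):
            raise ConfigError(
                "need 0 < rare_below < prevalent_above < 0.5 "
                f"(got {self.rare_below}, {self.prevalent_above})"
            )
        paths = {"elements_bed": self.elements_bed, "genome_file": self.genome_file}
        for pop, p in self.variant_vcfs.items():
            paths[f"variant_vcfs[{pop}]"] = p
        for name in ("score_track", "tfbs_bed", "se_bed", "reference_fasta"):
            if getattr(self, name) is not None or name in require:
                paths[name] = getattr(self, name)
        for name, p in paths.items():
            if p is None:
                raise ConfigError(f"{name} is required for this step")
            if not Path(p).exists():
                raise ConfigError(f"{name}: path does not exist: {p}")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: expected a mapping at top level")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**raw)


def _read_fasta(path: str | Path) -> dict[str, np.ndarray]:
    from pyfaidx import Fasta

    out: dict[str, np.ndarray] = {}
    with Fasta(str(path)) as fa:
        for name in fa.keys():
            out[name] = np.frombuffer(str(fa[name][:]).upper().encode(), dtype="S1")
    return out


def _read_score_track(path: str) -> ScoreTrack:
    if path.endswith((".wig", ".wiggle")):
        return ScoreTrack.from_wiggle(path)
    return ScoreTrack.from_bedgraph(path)


def _out(cfg: RunConfig, name: str) -> Path:
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / name
    if path.exists() and not cfg.force:
        raise ConfigError(f"output file {path} exists (use force to overwrite)")
    return path


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def _write_manifest(cfg: RunConfig, step: str) -> None:
    blob = json.dumps(asdict(cfg), sort_keys=True).encode()
    manifest = {
        "step": step,
        "seed": cfg.seed,
        "config": asdict(cfg),
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "package_version": __version__,
    }
    path = Path(cfg.outdir) / f"manifest_{step}.json"
    path.write_text(json.dumps(manifest, sort_keys=True, indent=2) + "\n")


def _load_variants(cfg: RunConfig, elements: IntervalSet) -> dict[str, VariantSet]:
    out = {}
    for pop, path in cfg.variant_vcfs.items():
        vs = read_vcf_snvs(path, region_filter=elements, af_field=cfg.af_field,
                           population=pop)
        logger.info("population %s: %d SNVs inside elements", pop, len(vs))
        out[pop] = vs
    if not out:
        raise ConfigError("at least one variant VCF is required")
    return out


def _class_positions(vs: VariantSet) -> dict[str, PositionList]:
    return {
        c.value: sub.positions()
        for c, sub in vs.by_class().items()
        if len(sub) > 0
    }


# ---------------------------------------------------------------------------
# characterization: rates and sharing (Venn) tables
# ---------------------------------------------------------------------------

def run_characterization(cfg: RunConfig) -> dict[str, pd.DataFrame]:
    """Per-population, per-class SNV rates plus cross-dataset sharing tables."""
    cfg.validate()
    genome = read_genome(cfg.genome_file)
    elements = merge(read_bed(cfg.elements_bed, genome=genome))
    target_bp = elements.total_length
    variant_sets = _load_variants(cfg, elements)

    rows = []
    for pop, vs in variant_sets.items():
        n_samples = cfg.samples.get(pop)
        by_class = vs.by_class()
        for cls in [None, *FrequencyClass]:
            sub = vs if cls is None else by_class[cls]
            rows.append(
                {
                    "population": pop,
                    "class": "all" if cls is None else cls.value,
                    "n_snvs": len(sub),
                    "target_mb": target_bp / 1e6,
                    "n_samples": n_samples if n_samples else "",
                    "snvs_per_mb_per_sample": (
                        snv_rate(len(sub), target_bp, n_samples) if n_samples else float("nan")
                    ),
                }
            )
    rates = pd.DataFrame(rows)
    tables = {"rates": rates}
    _write_tsv(rates, _out(cfg, "rates.tsv"))

    pops = list(variant_sets)
    if len(pops) >= 2:
        for label, selector in (
            ("all", None),
            ("prevalent", FrequencyClass.PREVALENT),
            ("rare", FrequencyClass.RARE),
        ):
            sets = [
                variant_sets[p] if selector is None else variant_sets[p].subset_class(selector)
                for p in pops
            ]
            tab = sharing_table(sets, names=pops)
            tables[f"sharing_{label}"] = tab
            _write_tsv(tab, _out(cfg, f"sharing_{label}.tsv"))
    else:
        # single population: sharing degenerates to per-class counts
        only = variant_sets[pops[0]]
        tab = pd.DataFrame(
            [{"class": c.value, "count": len(s)} for c, s in only.by_class().items()]
        )
        tables["sharing_all"] = tab
        _write_tsv(tab, _out(cfg, "sharing_all.tsv"))

    _write_manifest(cfg, "characterize")
    return tables


# ---------------------------------------------------------------------------
# conservation: ECDFs + null band, KS, relative positions, flank windows
# ---------------------------------------------------------------------------

def run_conservation(cfg: RunConfig) -> dict[str, pd.DataFrame]:
    """Per-class score ECDFs with a G/C-matched null band, KS tests, positions."""
    cfg.validate(require=("score_track", "reference_fasta"))
    genome = read_genome(cfg.genome_file)
    elements = merge(read_bed(cfg.elements_bed, genome=genome))
    track = _read_score_track(cfg.score_track)
    reference = _read_fasta(cfg.reference_fasta)
    variant_sets = _load_variants(cfg, elements)
    rng = derived_rng(cfg.seed, "conserve")

    ecdf_rows, ks_rows, flank_rows, rel_frames = [], [], [], []
    for pop, vs in variant_sets.items():
        class_pos = _class_positions(vs)
        class_scores: dict[str, np.ndarray] = {}
        for cls, pos in class_pos.items():
            scores, missing = extract_scores(pos, track)
            logger.info("%s/%s: %d positions, %d missing scores",
                        pop, cls, len(pos), len(missing))
            class_scores[cls] = scores[~np.isnan(scores)]

        # G/C-matched null of equal size to the full SNV set, with bootstrap band
        all_pos = vs.positions()
        target = BaseComposition.from_positions(reference, all_pos)
        null_pos = gc_matched_sample(elements, reference, target, n=len(all_pos), rng=rng)
        null_scores, _ = extract_scores(null_pos, track)
        null_scores = null_scores[~np.isnan(null_scores)]
        lo = min(s.min() for s in [*class_scores.values(), null_scores])
        hi = max(s.max() for s in [*class_scores.values(), null_scores])
        grid = np.linspace(lo, hi, 512)
        band = ecdf_band(null_scores, B=cfg.bootstrap_B, rng=rng, grid=grid)
        bdf = band.to_dataframe()
        bdf.insert(0, "sample", "gc_matched_null")
        bdf.insert(0, "population", pop)
        ecdf_rows.append(bdf)
        for cls, scores in class_scores.items():
            e = pd.DataFrame({"x": grid,
                              "ecdf": np.searchsorted(np.sort(scores), grid, side="right")
                              / len(scores)})
            e["lower"] = np.nan
            e["upper"] = np.nan
            e.insert(0, "sample", cls)
            e.insert(0, "population", pop)
            ecdf_rows.append(e)

        # KS comparisons
        pairs = []
        if "prevalent" in class_scores and "rare" in class_scores:
            pairs.append(("prevalent", "rare", class_scores["prevalent"], class_scores["rare"]))
        for cls, scores in class_scores.items():
            pairs.append((cls, "gc_matched_null", scores, null_scores))
        for name_a, name_b, sa, sb in pairs:
            res = ks_compare(sa, sb)
            ks_rows.append(
                {"population": pop, "sample_a": name_a, "sample_b": name_b,
                 "n_a": len(sa), "n_b": len(sb),
                 "D": res.statistic, "pvalue": res.pvalue,
                 "a_median": float(np.median(sa)), "b_median": float(np.median(sb))}
            )

        # relative positions within host elements
        rel = relative_positions(vs, elements)
        rel.insert(0, "population", pop)
        rel["class"] = [r.frequency_class.value for r in vs]
        rel_frames.append(rel)

        # 3-bp flank windows
        for cls, sub in vs.by_class().items():
            if len(sub) == 0:
                continue
            fl = flank_scores(sub, track, window=3)
            site = class_scores[cls.value]
            for side, sample in (("upstream", fl.upstream), ("downstream", fl.downstream)):
                res = ks_compare(site, sample)
                flank_rows.append(
                    {"population": pop, "class": cls.value, "side": side,
                     "n_site": len(site), "n_flank": len(sample),
                     "D": res.statistic, "pvalue": res.pvalue,
                     "site_median": float(np.median(site)),
                     "flank_median": float(np.median(sample))}
                )

    tables = {
        "ecdf": pd.concat(ecdf_rows, ignore_index=True),
        "ks": pd.DataFrame(ks_rows),
        "relative_positions": pd.concat(rel_frames, ignore_index=True),
        "flank_ks": pd.DataFrame(flank_rows),
    }
    for name, df in tables.items():
        _write_tsv(df, _out(cfg, f"{name}.tsv"))
    _write_manifest(cfg, "conserve")
    return tables


# ---------------------------------------------------------------------------
# enrichment: per-class TFBS overlap, resampling comparisons
# ---------------------------------------------------------------------------

def run_enrichment(cfg: RunConfig) -> dict[str, pd.DataFrame]:
    """Class depletion report plus per-1000-position resampling comparisons."""
    cfg.validate(require=("tfbs_bed", "reference_fasta"))
    genome = read_genome(cfg.genome_file)
    elements = merge(read_bed(cfg.elements_bed, genome=genome))
    features = merge(read_bed(cfg.tfbs_bed, genome=genome))
    reference = _read_fasta(cfg.reference_fasta)
    variant_sets = _load_variants(cfg, elements)
    rng = derived_rng(cfg.seed, "enrich")

    dep_frames = []
    for pop, vs in variant_sets.items():
        report = class_depletion_report(
            _class_positions(vs), elements, reference, features, rng=rng
        )
        df = depletion_report_frame(report)
        df.insert(0, "population", pop)
        dep_frames.append(df)
    depletion = pd.concat(dep_frames, ignore_index=True)

    # per-1000 resampling: element universe vs random genomic, and vs SE if given
    genome_universe = IntervalSet(
        [GenomicInterval(c, 0, L) for c, L in genome.items()], genome=genome
    )
    pools = {
        "elements": elements.positions(),
        "random_genomic": sample_positions(genome_universe, cfg.random_pool_size, rng=rng),
    }
    if cfg.se_bed is not None:
        pools["super_enhancers"] = merge(read_bed(cfg.se_bed, genome=genome)).positions()
    else:
        logger.info("no super-enhancer track given; SE comparison skipped")

    results = {
        name: resample_overlap(pool, features, n_sets=cfg.n_sets,
                               set_size=cfg.set_size, rng=rng, label=name)
        for name, pool in pools.items()
    }
    res_rows = [
        {"pool": name, "n_sets": r.n_sets, "set_size": r.set_size,
         "mean_overlap": r.mean, "ci_low": r.ci[0], "ci_high": r.ci[1]}
        for name, r in results.items()
    ]
    mw_rows = []
    comparisons = [("elements", "random_genomic")]
    if "super_enhancers" in results:
        comparisons.append(("super_enhancers", "elements"))
    for a, b in comparisons:
        res = compare_resamples(results[a], results[b])
        mw_rows.append(
            {"pool_a": a, "pool_b": b, "U": res.statistic,
             "pvalue": res.pvalue, "higher": res.higher}
        )

    tables = {
        "class_overlap": depletion,
        "resample_summary": pd.DataFrame(res_rows),
        "resample_mw": pd.DataFrame(mw_rows),
    }
    for name, df in tables.items():
        _write_tsv(df, _out(cfg, f"{name}.tsv"))
    _write_manifest(cfg, "enrich")
    return tables


def run_all(cfg: RunConfig) -> dict[str, pd.DataFrame]:
    out = {}
    out.update(run_characterization(cfg))
    out.update(run_conservation(cfg))
    out.update(run_enrichment(cfg))
    return out
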
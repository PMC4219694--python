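"""Variant ingestion and minor-allele-frequency stratification.

SNVs carry a folded minor allele frequency (MAF, in [0, 0.5]) and are
stratified into three classes with the thresholds used throughout the
analysis: rare (MAF < 0.5%), prevalent (MAF > 5%), intermediate otherwise.
Boundary values fall in the intermediate class (the strict inequalities
leave them open; keeping rare/prevalent conservative).

Variant identity is the key (chrom, pos, alt); positions are 0-based.
Also here: consensus intersection of two caller outputs, cross-dataset
sharing (Venn) tables, SNVs/Mb/sample rate summaries, and the pooled-design
per-allele coverage arithmetic.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataError
from .intervals import IntervalSet, PositionList, overlap_count

logger = logging.getLogger(__name__)

__all__ = [
    "VariantRecord",
    "VariantSet",
    "FrequencyClass",
    "PoolDesign",
    "classify_maf",
    "read_vcf_snvs",
    "write_vcf",
    "intersect_callsets",
    "sharing_table",
    "snv_rate",
    "per_allele_coverage",
]

NUCLEOTIDES = frozenset("ACGT")

# Stratification thresholds: rare below 0.5%, prevalent above 5%.
RARE_BELOW = 0.005
PREVALENT_ABOVE = 0.05


class FrequencyClass(str, Enum):
    RARE = "rare"
    INTERMEDIATE = "intermediate"
    PREVALENT = "prevalent"

    def __str__(self) -> str:  # tidy TSV output
        return self.value


def classify_maf(
    maf: float,
    rare_below: float = RARE_BELOW,
    prevalent_above: float = PREVALENT_ABOVE,
) -> FrequencyClass:
    """Assign a folded MAF to its frequency class (strict thresholds).

    Boundary values (exactly ``rare_below`` or ``prevalent_above``) are
    intermediate.
    """
    if not 0.0 <= maf <= 0.5:
        raise DataError(f"MAF {maf} outside [0, 0.5]")
    if maf < rare_below:
        return FrequencyClass.RARE
    if maf > prevalent_above:
        return FrequencyClass.PREVALENT
    return FrequencyClass.INTERMEDIATE


@dataclass(frozen=True)
class VariantRecord:
    """A single-nucleotide variant with folded minor allele frequency."""

    chrom: str
    pos: int  # 0-based
    ref: str
    alt: str
    maf: float
    population: str = ""

    def __post_init__(self) -> None:
        if self.ref not in NUCLEOTIDES or self.alt not in NUCLEOTIDES:
            raise DataError(f"non-SNV alleles {self.ref}->{self.alt} at {self.chrom}:{self.pos}")
        if self.ref == self.alt:
            raise DataError(f"ref == alt at {self.chrom}:{self.pos}")
        if not 0.0 <= self.maf <= 0.5:
            raise DataError(f"MAF {self.maf} outside [0, 0.5] at {self.chrom}:{self.pos}")

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chrom, self.pos, self.alt)

    @property
    def frequency_class(self) -> FrequencyClass:
        return classify_maf(self.maf)


class VariantSet:
    """A keyed collection of :class:`VariantRecord` from one dataset.

    Keys (chrom, pos, alt) are unique; two records at the same (chrom, pos)
    must agree on the reference base — a mismatch raises rather than
    silently merging.
    """

    def __init__(self, records: Iterable[VariantRecord] = (), provenance: str = "") -> None:
        self.provenance = provenance
        self._records: dict[tuple[str, int, str], VariantRecord] = {}
        refs: dict[tuple[str, int], str] = {}
        for rec in records:
            site = (rec.chrom, rec.pos)
            if site in refs and refs[site] != rec.ref:
                raise DataError(
                    f"reference mismatch at {rec.chrom}:{rec.pos}: "
                    f"{refs[site]} vs {rec.ref}"
                )
            refs[site] = rec.ref
            if rec.key in self._records:
                raise DataError(f"duplicate variant key {rec.key}")
            self._records[rec.key] = rec

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[VariantRecord]:
        return iter(self._records.values())

    def __contains__(self, key: tuple[str, int, str]) -> bool:
        return key in self._records

    def __repr__(self) -> str:
        return f"VariantSet({self.provenance!r}, n={len(self)})"

    def keys(self) -> set[tuple[str, int, str]]:
        return set(self._records)

    def get(self, key: tuple[str, int, str]) -> VariantRecord:
        return self._records[key]

    def positions(self) -> PositionList:
        """Variant site positions in insertion order (one per record)."""
        recs = list(self)
        return PositionList(
            np.array([r.chrom for r in recs], dtype=object),
            np.array([r.pos for r in recs], dtype=np.int64),
        )

    def by_class(self) -> dict[FrequencyClass, "VariantSet"]:
        groups: dict[FrequencyClass, list[VariantRecord]] = {c: [] for c in FrequencyClass}
        for rec in self:
            groups[rec.frequency_class].append(rec)
        return {
            c: VariantSet(rs, provenance=f"{self.provenance}:{c.value}")
            for c, rs in groups.items()
        }

    def subset_class(self, cls: FrequencyClass) -> "VariantSet":
        return self.by_class()[cls]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "chrom": r.chrom,
                    "pos": r.pos,
                    "ref": r.ref,
                    "alt": r.alt,
                    "maf": r.maf,
                    "population": r.population,
                    "class": r.frequency_class.value,
                }
                for r in self
            ],
            columns=["chrom", "pos", "ref", "alt", "maf", "population", "class"],
        )


# ---------------------------------------------------------------------------
# VCF I/O (pysam)
# ---------------------------------------------------------------------------

def read_vcf_snvs(
    path: str | Path,
    region_filter: IntervalSet | None = None,
    af_field: str = "AF",
    population: str = "",
) -> VariantSet:
    """Read biallelic-decomposed SNVs from a VCF, folding allele frequency to MAF.

    Multiallelic records are decomposed into one record per ALT allele, each
    with its own frequency from the Number=A INFO field ``af_field``; a
    frequency above 0.5 is folded (MAF = 1 - f). Indels/MNVs are excluded and
    counted; records lacking the AF field are skipped with a warning count.
    Positions are converted to 0-based; an optional region filter keeps only
    variants inside the given intervals.
    """
    import pysam

    records: list[VariantRecord] = []
    n_non_snv = 0
    n_missing_af = 0
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            alts = rec.alts or ()
            afs = rec.info.get(af_field, None)
            if afs is None:
                n_missing_af += 1
                continue
            if not isinstance(afs, (tuple, list)):
                afs = (afs,)
            for alt, af in zip(alts, afs):
                if len(rec.ref) != 1 or len(alt) != 1 or rec.ref not in NUCLEOTIDES \
                        or alt not in NUCLEOTIDES:
                    n_non_snv += 1
                    continue
                if af is None:
                    n_missing_af += 1
                    continue
                af = float(af)
                maf = af if af <= 0.5 else 1.0 - af
                records.append(
                    VariantRecord(rec.chrom, rec.start, rec.ref, alt, maf, population)
                )
    if n_non_snv:
        logger.info("%s: excluded %d non-SNV alleles", path, n_non_snv)
    if n_missing_af:
        logger.warning("%s: skipped %d alleles lacking INFO/%s", path, n_missing_af, af_field)
    if region_filter is not None and records:
        pl = PositionList(
            np.array([r.chrom for r in records], dtype=object),
            np.array([r.pos for r in records], dtype=np.int64),
        )
        _, flags = overlap_count(pl, region_filter)
        records = [r for r, keep in zip(records, flags) if keep]
    logger.info("%s: retained %d SNVs", path, len(records))
    return VariantSet(records, provenance=population or str(path))


def write_vcf(
    variants: VariantSet,
    path: str | Path,
    contigs: Mapping[str, int],
    af_field: str = "AF",
) -> None:
    """Write a VariantSet as a minimal VCF 4.2 with allele frequency in INFO."""
    import pysam

    header = pysam.VariantHeader()
    for chrom, length in contigs.items():
        header.contigs.add(chrom, length=length)
    header.info.add(af_field, "A", "Float", "Alternate allele frequency")
    recs = sorted(variants, key=lambda r: (r.chrom, r.pos, r.alt))
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for r in recs:
            rec = out.new_record(
                contig=r.chrom, start=r.pos, stop=r.pos + 1,
                alleles=(r.ref, r.alt),
            )
            rec.info[af_field] = (r.maf,)
            out.write(rec)


# ---------------------------------------------------------------------------
# Set operations
# ---------------------------------------------------------------------------

def intersect_callsets(a: VariantSet, b: VariantSet) -> tuple[VariantSet, int, int]:
    """Consensus of two caller outputs: key intersection, MAF taken from ``a``.

    Returns (consensus, n exclusive to a, n exclusive to b). The first
    argument plays the role of the frequency-authoritative caller.
    """
    shared = a.keys() & b.keys()
    consensus = VariantSet(
        (a.get(k) for k in sorted(shared)),
        provenance=f"{a.provenance}&{b.provenance}",
    )
    return consensus, len(a) - len(shared), len(b) - len(shared)


def sharing_table(
    sets: Sequence[VariantSet], names: Sequence[str] | None = None
) -> pd.DataFrame:
    """Membership (Venn-cell) counts of variant keys across >= 2 datasets.

    One row per non-empty membership pattern, with a boolean column per
    dataset and a ``count`` column; counts sum to the union size.
    """
    if len(sets) < 2:
        raise DataError("sharing_table needs at least two variant sets")
    if names is None:
        names = [s.provenance or f"set{i}" for i, s in enumerate(sets)]
    keysets = [s.keys() for s in sets]
    union = set().union(*keysets)
    cells: dict[tuple[bool, ...], int] = {}
    for k in union:
        pattern = tuple(k in ks for ks in keysets)
        cells[pattern] = cells.get(pattern, 0) + 1
    rows = [
        {**{n: m for n, m in zip(names, pattern)}, "count": c}
        for pattern, c in sorted(cells.items(), reverse=True)
    ]
    return pd.DataFrame(rows, columns=[*names, "count"])


# ---------------------------------------------------------------------------
# Rate / pooled-design arithmetic
# ---------------------------------------------------------------------------

def snv_rate(set_size: int, target_length_bp: float, n_samples: int) -> float:
    """SNVs per Mb of target per sample."""
    if target_length_bp <= 0:
        raise DataError("target length must be positive")
    if n_samples <= 0:
        raise DataError("sample count must be positive")
    if set_size < 0:
        raise DataError("set size must be non-negative")
    return set_size / (target_length_bp / 1e6) / n_samples


@dataclass(frozen=True)
class PoolDesign:
    """A pooled-sequencing design: samples distributed over pools at a mean depth."""

    n_samples: int
    n_pools: int
    mean_pool_coverage: float

    def __post_init__(self) -> None:
        if self.n_pools < 1 or self.n_samples < self.n_pools:
            raise DataError("need n_samples >= n_pools >= 1")
        if self.mean_pool_coverage < 0:
            raise DataError("coverage must be non-negative")


def per_allele_coverage(design: PoolDesign) -> float:
    """Mean fold-coverage attributable to one sequenced allele in a pool.

    pool depth / (2 x samples per pool); the factor 2 is diploidy. Reported
    at full precision.
    """
    samples_per_pool = design.n_samples / design.n_pools
    return design.mean_pool_coverage / (2.0 * samples_per_pool)
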
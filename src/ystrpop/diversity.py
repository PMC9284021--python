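"""Intra-population diversity statistics for Y-STR data.

Forensic summary statistics over a haplotype table:

* per-locus allele frequency spectra and allele counts;
* gene diversity ``GD = 1 - sum(p_i^2)`` over a locus's allele frequencies
  (optionally Nei's unbiased form with the ``n/(n-1)`` correction);
* haplotype-level statistics — Nei's haplotype diversity
  ``HD = (1 - sum(p_i^2)) * n/(n-1)``, match probability ``MP = sum(p_i^2)``
  and discrimination capacity ``DC = (#distinct haplotypes)/n`` — where a
  haplotype is the full ordered allele vector across all loci.

Samples missing any allele are excluded from haplotype-level statistics
(only complete haplotypes are comparable) but still contribute to per-locus
spectra at the loci where they are called.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .data_io import HaplotypeTable

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AlleleFrequencySpectrum:
    """Observed allele -> relative frequency map for one locus."""

    locus: str
    frequencies: dict[float, float]
    n: int  #: number of non-missing observations

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("spectrum requires >=1 observation")
        total = sum(self.frequencies.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"frequencies sum to {total}, expected 1")
        if any(p <= 0 for p in self.frequencies.values()):
            raise ValueError("zero/negative frequency in spectrum")

    @property
    def alleles(self) -> list[float]:
        return sorted(self.frequencies)

    def homozygosity(self) -> float:
        return sum(p * p for p in self.frequencies.values())


def allele_frequencies(table: HaplotypeTable, locus: str) -> AlleleFrequencySpectrum:
    """Empirical allele frequencies at ``locus``, over non-missing calls."""
    if locus not in table.alleles.columns:
        raise KeyError(f"locus {locus!r} not in table")
    col = table.alleles[locus].dropna()
    if col.empty:
        raise ValueError(f"locus {locus!r} has no non-missing observations")
    counts = col.value_counts()
    n = int(counts.sum())
    return AlleleFrequencySpectrum(
        locus=locus,
        frequencies={float(a): c / n for a, c in counts.items()},
        n=n,
    )


def gene_diversity(spectrum: AlleleFrequencySpectrum, *, unbiased: bool = False) -> float:
    """Gene diversity ``1 - sum(p_i^2)`` at one locus.

    With ``unbiased=True`` applies Nei's small-sample correction
    ``n/(n-1)``; this matches the value reported by STRAF-style software.
    """
    gd = 1.0 - spectrum.homozygosity()
    if unbiased:
        if spectrum.n < 2:
            raise ValueError("unbiased gene diversity requires n >= 2")
        gd *= spectrum.n / (spectrum.n - 1)
    return gd


def allele_count(table: HaplotypeTable, locus: str) -> int:
    """Number of distinct observed alleles at ``locus``."""
    return len(allele_frequencies(table, locus).frequencies)


@dataclass(frozen=True)
class DiversityReport:
    """Haplotype-level diversity summary plus per-locus gene diversities."""

    n: int  #: complete haplotypes used
    n_excluded: int  #: samples dropped for missing data
    n_distinct: int
    multiplicity_spectrum: dict[int, int]  #: multiplicity k -> number of haplotypes seen k times
    haplotype_diversity: float
    haplotype_diversity_sd: float  #: Nei's variance estimator, for reference
    match_probability: float
    discrimination_capacity: float
    gene_diversity_per_locus: dict[str, float] = field(default_factory=dict)
    total_distinct_alleles: int = 0

    def summary(self) -> str:
        lines = [
            "Haplotype-level diversity",
            f"  samples (complete haplotypes): {self.n}",
            f"  samples excluded (missing data): {self.n_excluded}",
            f"  distinct haplotypes: {self.n_distinct}",
            "  multiplicity spectrum (k: haplotypes seen k times): "
            + ", ".join(f"{k}: {v}" for k, v in sorted(self.multiplicity_spectrum.items())),
            f"  haplotype diversity (Nei): {self.haplotype_diversity:.4f}"
            f" (sd {self.haplotype_diversity_sd:.4f})",
            f"  match probability: {self.match_probability:.6f}",
            f"  discrimination capacity: {self.discrimination_capacity:.4f}",
            "",
            "Per-locus gene diversity (1 - sum p^2)",
        ]
        for locus, gd in self.gene_diversity_per_locus.items():
            lines.append(f"  {locus}: {gd:.4f}")
        lines.append(f"  total distinct alleles across loci: {self.total_distinct_alleles}")
        return "\n".join(lines) + "\n"


def nei_diversity_sd(freqs: np.ndarray, n: int) -> float:
    """Standard error of Nei's diversity from frequencies ``freqs`` (Nei 1987)."""
    j2 = float(np.sum(freqs**2))
    j3 = float(np.sum(freqs**3))
    var = 2.0 / (n * (n - 1)) * (2.0 * (n - 2) * (j3 - j2 * j2) + j2 - j2 * j2)
    return math.sqrt(max(var, 0.0))


def diversity_from_multiplicities(multiplicity_spectrum: dict[int, int]) -> "DiversityReport":
    """Haplotype statistics from a multiplicity spectrum alone.

    ``multiplicity_spectrum`` maps multiplicity ``k`` to the number of
    distinct haplotypes observed exactly ``k`` times.  Useful when only the
    published multiplicity structure of a sample is available.
    """
    n = sum(k * c for k, c in multiplicity_spectrum.items())
    if n < 2:
        raise ValueError("haplotype diversity requires n >= 2")
    counts = np.array([k for k, c in multiplicity_spectrum.items() for _ in range(c)], dtype=float)
    freqs = counts / n
    mp = float(np.sum(freqs**2))
    hd = (1.0 - mp) * n / (n - 1)
    n_distinct = int(sum(multiplicity_spectrum.values()))
    return DiversityReport(
        n=n,
        n_excluded=0,
        n_distinct=n_distinct,
        multiplicity_spectrum=dict(multiplicity_spectrum),
        haplotype_diversity=hd,
        haplotype_diversity_sd=nei_diversity_sd(freqs, n),
        match_probability=mp,
        discrimination_capacity=n_distinct / n,
    )


def haplotype_statistics(table: HaplotypeTable) -> DiversityReport:
    """Full diversity report for a haplotype table.

    Haplotype-level statistics use complete cases only; per-locus gene
    diversities use every sample called at the locus.
    """
    complete = table.complete_cases()
    n_excluded = table.n_samples - complete.n_samples
    if n_excluded:
        dropped = sorted(set(table.sample_ids) - set(complete.sample_ids))
        logger.info("excluding %d samples with missing alleles: %s", n_excluded, dropped)
    if complete.n_samples < 2:
        raise ValueError("haplotype diversity requires >= 2 complete haplotypes")

    haplos = [tuple(row) for row in complete.alleles.to_numpy()]
    counts: dict[tuple, int] = {}
    for h in haplos:
        counts[h] = counts.get(h, 0) + 1
    mult: dict[int, int] = {}
    for c in counts.values():
        mult[c] = mult.get(c, 0) + 1
    base = diversity_from_multiplicities(mult)

    gd_per_locus: dict[str, float] = {}
    total_alleles = 0
    for locus in table.loci:
        spec = allele_frequencies(table, locus)
        gd_per_locus[locus] = gene_diversity(spec)
        total_alleles += len(spec.frequencies)

    return DiversityReport(
        n=base.n,
        n_excluded=n_excluded,
        n_distinct=base.n_distinct,
        multiplicity_spectrum=base.multiplicity_spectrum,
        haplotype_diversity=base.haplotype_diversity,
        haplotype_diversity_sd=base.haplotype_diversity_sd,
        match_probability=base.match_probability,
        discrimination_capacity=base.discrimination_capacity,
        gene_diversity_per_locus=gd_per_locus,
        total_distinct_alleles=total_alleles,
    )
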
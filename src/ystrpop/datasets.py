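"""Bundled reference data for the Croatian Y-STR population study.

Small published summary tables shipped with the package:

* 27-locus allele-frequency spectra for the pooled Croatian sample
  (n = 518), and the allele registry derived from them;
* haplogroup counts for the five regional subpopulations (n = 518);
* the published pairwise regional Rst matrix with permutation p-values
  (p-values reported as "< 0.0001" are stored as 0.0001).

Raw per-sample haplotypes are deposited in YHRD and are not redistributed;
use :mod:`ystrpop.simulate` for per-sample test data.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .data_io import AlleleRegistry
from .diversity import AlleleFrequencySpectrum
from .rst import DistanceMatrix

CROATIA_N = 518  #: pooled sample size behind the allele-frequency table
REGION_SIZES = {"Hvar": 104, "Osijek": 110, "Pula": 99, "Split": 105, "Varazdin": 100}


def _data(name: str):
    return resources.files("ystrpop.data").joinpath(name)


def croatia_allele_frequencies() -> dict[str, AlleleFrequencySpectrum]:
    """Published 27-locus allele-frequency spectra (pooled, n = 518).

    Printed frequencies are rounded to 3 decimals, so each spectrum is
    renormalized to sum exactly to one; the rounding error is < 0.001 per
    column.
    """
    df = pd.read_csv(_data("croatia_allele_frequencies.csv"))
    out: dict[str, AlleleFrequencySpectrum] = {}
    for locus, grp in df.groupby("locus", sort=False):
        freqs = dict(zip(grp["allele"].astype(float), grp["frequency"].astype(float)))
        total = sum(freqs.values())
        out[str(locus)] = AlleleFrequencySpectrum(
            locus=str(locus),
            frequencies={a: p / total for a, p in freqs.items()},
            n=CROATIA_N,
        )
    return out


def croatia_allele_registry() -> AlleleRegistry:
    """Registry of all alleles observed in the published frequency table."""
    return AlleleRegistry.read_csv(_data("croatia_allele_registry.csv"))


def croatia_haplogroup_counts() -> pd.DataFrame:
    """Predicted haplogroup counts per Croatian region (rows sum to region n)."""
    return pd.read_csv(_data("croatia_haplogroup_counts.csv"), index_col="region")


def croatia_regional_rst() -> DistanceMatrix:
    """Published pairwise Rst between the five Croatian regions."""
    r = pd.read_csv(_data("croatia_regional_rst.csv"), index_col=0)
    p = pd.read_csv(_data("croatia_regional_rst_pvalues.csv"), index_col=0)
    return DistanceMatrix(r, p, permutations=10_000)
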
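"""Pairwise Rst genetic distances via AMOVA on repeat counts.

Rst is the microsatellite analogue of Fst: allelic distance is the squared
difference in repeat number, which under stepwise mutation accumulates
linearly in divergence time.  For each locus a one-way random-effects ANOVA
on raw repeat counts yields among- and within-population variance
components; variance components are summed across loci before forming

    Rst = sigma_among / (sigma_among + sigma_within)

(the Arlequin/YHRD convention — summing keeps the estimator defined when
individual loci are monomorphic).  Significance is assessed by permuting
individuals between the two populations, preserving group sizes, with the
add-one p-value estimator ``p = (b + 1)/(m + 1)``.

Negative Rst estimates (sampling noise around zero) are reported raw;
:meth:`DistanceMatrix.clamped` provides the non-negative view used for
embeddings and trees.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import HaplotypeTable

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class VarianceComponents:
    """One-locus one-way AMOVA decomposition."""

    locus: str
    ss_among: float
    ss_within: float
    df_among: int
    df_within: int
    sigma_among: float  #: may be negative (unbiased moment estimator)
    sigma_within: float

    @property
    def usable(self) -> bool:
        return self.df_within > 0 and np.isfinite(self.sigma_among)


def locus_variance_components(
    values_by_population: dict[str, np.ndarray], locus: str = ""
) -> VarianceComponents:
    """One-way random-effects variance components for a single locus.

    ``values_by_population`` maps population label to a 1-D array of repeat
    counts (missing values already removed).  Uses the standard unequal
    sample size coefficient ``n0 = (N - sum(n_g^2)/N)/(k-1)``.
    """
    groups = {k: np.asarray(v, dtype=float) for k, v in values_by_population.items()}
    if len(groups) < 2:
        raise ValueError("need >= 2 populations")
    if any(g.size < 1 for g in groups.values()):
        raise ValueError("every population needs >= 1 observation")
    sizes = np.array([g.size for g in groups.values()], dtype=float)
    k = len(groups)
    N = sizes.sum()
    grand = sum(g.sum() for g in groups.values()) / N
    ss_among = float(sum(g.size * (g.mean() - grand) ** 2 for g in groups.values()))
    ss_within = float(sum(((g - g.mean()) ** 2).sum() for g in groups.values()))
    df_among = k - 1
    df_within = int(N) - k
    n0 = (N - (sizes**2).sum() / N) / (k - 1)
    ms_within = ss_within / df_within if df_within > 0 else np.nan
    ms_among = ss_among / df_among
    sigma_within = ms_within
    sigma_among = (ms_among - ms_within) / n0 if df_within > 0 else np.nan
    return VarianceComponents(
        locus=locus,
        ss_among=ss_among,
        ss_within=ss_within,
        df_among=df_among,
        df_within=df_within,
        sigma_among=float(sigma_among),
        sigma_within=float(sigma_within),
    )


# -- vectorized two-group engine --------------------------------------------


def _two_group_sigmas(
    values: np.ndarray, in_a: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Variance components per locus for many two-group assignments at once.

    Parameters
    ----------
    values
        ``(n, L)`` repeat counts, NaN for missing.
    in_a
        ``(m, n)`` boolean matrix; each row assigns samples to group A
        (True) or B (False).

    Returns
    -------
    sigma_among, sigma_within : ``(m, L)`` arrays
    usable : ``(m, L)`` boolean — both groups have >= 2 observations
    """
    values = np.atleast_2d(np.asarray(values, dtype=float))
    in_a = np.atleast_2d(np.asarray(in_a, dtype=float))
    mask = np.isfinite(values)
    v0 = np.where(mask, values, 0.0)
    maskf = mask.astype(float)

    na = in_a @ maskf  # (m, L) group-A counts per locus
    sa = in_a @ v0
    qa = in_a @ (v0 * v0)
    ntot = maskf.sum(axis=0)  # (L,)
    stot = v0.sum(axis=0)
    qtot = (v0 * v0).sum(axis=0)
    nb = ntot - na
    sb = stot - sa
    qb = qtot - qa

    usable = (na >= 2) & (nb >= 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        ss_within = (qa - sa**2 / na) + (qb - sb**2 / nb)
        ss_among = sa**2 / na + sb**2 / nb - stot**2 / ntot
        n_used = na + nb
        df_within = n_used - 2
        ms_within = ss_within / df_within
        ms_among = ss_among  # df_among = 1
        n0 = (n_used - (na**2 + nb**2) / n_used)  # / (k-1) with k=2
        sigma_among = (ms_among - ms_within) / n0
    sigma_within = ms_within
    return sigma_among, sigma_within, usable


def _rst_from_sigmas(
    sigma_among: np.ndarray, sigma_within: np.ndarray, usable: np.ndarray
) -> np.ndarray:
    """Multi-locus Rst per assignment row; rows with no usable locus -> NaN."""
    sa = np.where(usable, sigma_among, 0.0).sum(axis=1)
    sw = np.where(usable, sigma_within, 0.0).sum(axis=1)
    any_usable = usable.any(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        rst = np.where(any_usable & (sa + sw != 0), sa / (sa + sw), np.nan)
    rst = np.where(any_usable & (sa + sw == 0), 0.0, rst)
    return rst


def _pair_values(
    table: HaplotypeTable, pop_a: str, pop_b: str, loci: list[str] | None
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    labels = set(table.populations)
    for p in (pop_a, pop_b):
        if p not in labels:
            raise KeyError(f"population {p!r} not in table")
    loci = list(loci) if loci is not None else table.loci
    sub = table.select_populations([pop_a, pop_b]).select_loci(loci)
    values = sub.alleles.to_numpy(dtype=float)
    in_a = (sub.populations == pop_a).to_numpy()
    return values, in_a, loci


def pairwise_rst(
    table: HaplotypeTable,
    pop_a: str,
    pop_b: str,
    loci: list[str] | None = None,
) -> tuple[float, list[VarianceComponents]]:
    """Multi-locus Rst between two populations, plus per-locus components.

    Loci where either population has fewer than two called samples are
    skipped (and logged).  The raw, possibly negative estimate is returned.
    """
    values, in_a, loci = _pair_values(table, pop_a, pop_b, loci)
    sa, sw, usable = _two_group_sigmas(values, in_a[None, :])
    comps = []
    for j, locus in enumerate(loci):
        if not usable[0, j]:
            logger.info("locus %s skipped for pair (%s, %s): <2 observations in a group",
                        locus, pop_a, pop_b)
            continue
        col = values[:, j]
        ok = np.isfinite(col)
        comps.append(
            locus_variance_components(
                {pop_a: col[ok & in_a], pop_b: col[ok & ~in_a]}, locus=locus
            )
        )
    rst = _rst_from_sigmas(sa, sw, usable)[0]
    if np.isnan(rst):
        raise ValueError(f"no usable loci for pair ({pop_a!r}, {pop_b!r})")
    return float(rst), comps


def permutation_p(
    table: HaplotypeTable,
    pop_a: str,
    pop_b: str,
    loci: list[str] | None = None,
    m: int = 10_000,
    seed: int | np.random.Generator = 0,
) -> float:
    """Permutation p-value for Rst(pop_a, pop_b).

    Individuals are shuffled between the two groups preserving group sizes;
    ``p = (b + 1)/(m + 1)`` where ``b`` counts permuted Rst >= observed.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    values, in_a, loci = _pair_values(table, pop_a, pop_b, loci)
    observed = _rst_from_sigmas(*_two_group_sigmas(values, in_a[None, :]))[0]
    if np.isnan(observed):
        raise ValueError(f"no usable loci for pair ({pop_a!r}, {pop_b!r})")
    assignments = rng.permuted(np.tile(in_a, (m, 1)), axis=1)
    perm = _rst_from_sigmas(*_two_group_sigmas(values, assignments))
    b = int(np.sum(perm[np.isfinite(perm)] >= observed - 1e-12))
    return (b + 1) / (m + 1)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise Rst matrix with permutation p-values."""

    rst: pd.DataFrame
    pvalues: pd.DataFrame
    permutations: int
    seed: int | None = None

    def __post_init__(self) -> None:
        labels = list(self.rst.index)
        if list(self.rst.columns) != labels or list(self.pvalues.index) != labels:
            raise ValueError("labels of rst/pvalue matrices disagree")
        a = self.rst.to_numpy(dtype=float)
        if not np.allclose(a, a.T, atol=1e-12, equal_nan=True):
            raise ValueError("rst matrix not symmetric")
        if not np.allclose(np.diag(a), 0.0):
            raise ValueError("rst diagonal must be zero")

    @property
    def labels(self) -> list[str]:
        return list(self.rst.index)

    def clamped(self) -> pd.DataFrame:
        """Non-negative view ``max(Rst, 0)`` for embeddings and trees."""
        return self.rst.clip(lower=0.0)

    @classmethod
    def from_condensed(
        cls,
        labels: list[str],
        pairs: dict[tuple[str, str], tuple[float, float]],
        permutations: int = 0,
        seed: int | None = None,
    ) -> "DistanceMatrix":
        r = pd.DataFrame(0.0, index=labels, columns=labels)
        p = pd.DataFrame(1.0, index=labels, columns=labels)
        for (a, b), (rv, pv) in pairs.items():
            r.loc[a, b] = r.loc[b, a] = rv
            p.loc[a, b] = p.loc[b, a] = pv
        return cls(r, p, permutations, seed)


def rst_matrix(
    table: HaplotypeTable,
    populations: list[str] | None = None,
    loci: list[str] | None = None,
    m: int = 10_000,
    seed: int = 0,
) -> DistanceMatrix:
    """All pairwise Rst values and permutation p-values.

    Populations with fewer than two samples are excluded with a warning.
    Deterministic given ``seed``: each unordered pair gets an independent
    child seed, so results do not depend on pair evaluation order.
    """
    if populations is None:
        populations = sorted(set(table.populations))
    sizes = table.population_sizes()
    usable = [p for p in populations if sizes.get(p, 0) >= 2]
    dropped = sorted(set(populations) - set(usable))
    if dropped:
        logger.warning("populations excluded (<2 samples): %s", dropped)
    if len(usable) < 2:
        raise ValueError("need >= 2 populations with >= 2 samples")
    r = pd.DataFrame(0.0, index=usable, columns=usable)
    p = pd.DataFrame(1.0, index=usable, columns=usable)
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(usable) * (len(usable) - 1) // 2)
    idx = 0
    for i, a in enumerate(usable):
        for b in usable[i + 1 :]:
            rng = np.random.default_rng(children[idx])
            idx += 1
            rst, _ = pairwise_rst(table, a, b, loci)
            pval = permutation_p(table, a, b, loci, m=m, seed=rng)
            r.loc[a, b] = r.loc[b, a] = rst
            p.loc[a, b] = p.loc[b, a] = pval
    return DistanceMatrix(r, p, permutations=m, seed=seed)
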
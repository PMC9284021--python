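"""Synthetic Y-STR panels under a stepwise mutation model (SMM).

The generators produce the statistical structure the analysis stack
consumes, without any external data:

* multi-population panels diverged under SMM drift — each population's
  ancestral haplotype drifts for half the pairwise divergence time from a
  shared root (star topology), and each sampled lineage adds its own
  within-population drift;
* haplogroup-labeled panels built from well-separated modal haplotypes
  plus per-locus SMM noise, with matched train/test splits;
* tables with planted novel microvariants (+0.2 repeat shifts).

Mutation counts per lineage are binomial over generations (per-generation
mutation probability ``mu``, around 0.2% per generation for Y-STRs) and
every mutation is a +-1 repeat step; only the *net* displacement is
sampled, which is sufficient for the variance structure Rst measures.
Repeat counts are floored at 5 to avoid non-physical alleles.  All
generators are pure functions of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .data_io import HaplotypeTable
from .haplogroups import HaplogroupReferencePanel, train_panel

MIN_REPEAT = 5
DEFAULT_ANCESTRAL_REPEAT = 14


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of an SMM population-split simulation.

    ``divergence_time`` is the *pairwise* separation between populations in
    generations (each population sits ``t/2`` from the shared root);
    ``within_time`` is the drift depth of each sampled lineage within its
    population, emulating within-population coalescent depth.
    """

    n_populations: int = 2
    samples_per_population: int = 50
    loci: Sequence[str] = field(default_factory=lambda: tuple(f"L{i + 1}" for i in range(17)))
    mu: float = 0.002  #: per-locus per-generation mutation probability
    divergence_time: int = 200
    within_time: int = 200
    seed: int | None = None
    ancestral_haplotype: Sequence[float] | None = None
    population_names: Sequence[str] | None = None

    def validate(self) -> None:
        errors = []
        if self.n_populations < 1:
            errors.append("n_populations must be >= 1")
        if self.samples_per_population < 2:
            errors.append("samples_per_population must be >= 2")
        if not 0 <= self.mu <= 0.01:
            errors.append("mu must be in [0, 0.01]")
        if self.divergence_time < 0:
            errors.append("divergence_time must be >= 0")
        if self.within_time < 0:
            errors.append("within_time must be >= 0")
        if self.seed is None:
            errors.append("seed is mandatory (simulations must be reproducible)")
        if len(self.loci) < 1:
            errors.append("need >= 1 locus")
        if self.ancestral_haplotype is not None and len(self.ancestral_haplotype) != len(self.loci):
            errors.append("ancestral_haplotype length must match loci")
        if self.population_names is not None and len(self.population_names) != self.n_populations:
            errors.append("population_names length must match n_populations")
        if errors:
            raise ValueError("invalid SimulationConfig: " + "; ".join(errors))


def _net_displacement(rng: np.random.Generator, t: int, mu: float, shape) -> np.ndarray:
    """Net SMM displacement after ``t`` generations at rate ``mu``."""
    k = rng.binomial(t, mu, size=shape)
    up = rng.binomial(k, 0.5)
    return 2 * up - k


def simulate_split_populations(config: SimulationConfig) -> HaplotypeTable:
    """Multi-population panel diverged under SMM in star topology."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    L = len(config.loci)
    root = (
        np.asarray(config.ancestral_haplotype, dtype=float)
        if config.ancestral_haplotype is not None
        else np.full(L, float(DEFAULT_ANCESTRAL_REPEAT))
    )
    names = (
        list(config.population_names)
        if config.population_names is not None
        else [f"pop{i + 1}" for i in range(config.n_populations)]
    )
    half_t = config.divergence_time // 2 + config.divergence_time % 2
    blocks, pops, ids = [], [], []
    for p, name in enumerate(names):
        anc = root + _net_displacement(rng, half_t, config.mu, L)
        drift = _net_displacement(
            rng, config.within_time, config.mu, (config.samples_per_population, L)
        )
        vals = np.maximum(anc[None, :] + drift, MIN_REPEAT)
        blocks.append(vals)
        pops += [name] * config.samples_per_population
        ids += [f"{name}_s{i + 1}" for i in range(config.samples_per_population)]
    alleles = pd.DataFrame(
        np.vstack(blocks), index=pd.Index(ids, name="SampleID"), columns=list(config.loci)
    )
    return HaplotypeTable(alleles, pd.Series(pops, index=alleles.index, name="Population"))


# -- haplogroup panels -------------------------------------------------------


@dataclass(frozen=True)
class HaplogroupPanelSim:
    """Matched train/test haplogroup panels plus the trained reference."""

    train_table: HaplotypeTable
    train_labels: pd.Series
    test_table: HaplotypeTable
    test_labels: pd.Series
    panel: HaplogroupReferencePanel
    modal_haplotypes: pd.DataFrame  #: haplogroup x locus


def _spread_modals(
    rng: np.random.Generator, n_groups: int, n_loci: int, min_steps: int, tries: int = 200
) -> np.ndarray:
    """Random modal haplotypes with pairwise L1 distance >= min_steps."""
    for _ in range(tries):
        modals = DEFAULT_ANCESTRAL_REPEAT + rng.integers(-4, 5, size=(n_groups, n_loci))
        dist = np.abs(modals[:, None, :] - modals[None, :, :]).sum(axis=2)
        np.fill_diagonal(dist, min_steps)
        if (dist >= min_steps).all():
            return modals.astype(float)
    raise RuntimeError("could not place modal haplotypes at the requested separation")


def simulate_haplogroup_panel(
    haplogroup_sizes: dict[str, int],
    loci: Sequence[str],
    *,
    noise: float = 0.05,
    train_per_haplogroup: int = 50,
    min_step_distance: int = 6,
    modal_haplotypes: pd.DataFrame | None = None,
    epsilon: float = 1e-4,
    seed: int,
) -> HaplogroupPanelSim:
    """Labeled train/test haplotype panels around modal haplotypes.

    ``haplogroup_sizes`` gives the held-out test count per haplogroup
    (label counts match it exactly); ``noise`` is the per-locus probability
    that a sampled haplotype deviates one SMM step from its modal value.
    Modal haplotypes are drawn to be pairwise at least ``min_step_distance``
    mutational steps apart, or validated if supplied.
    """
    if not haplogroup_sizes:
        raise ValueError("need >= 1 haplogroup")
    if not 0 <= noise <= 1:
        raise ValueError("noise must be a probability")
    rng = np.random.default_rng(seed)
    hgs = sorted(haplogroup_sizes)
    L = len(loci)
    if modal_haplotypes is None:
        modals = pd.DataFrame(
            _spread_modals(rng, len(hgs), L, min_step_distance), index=hgs, columns=list(loci)
        )
    else:
        modals = modal_haplotypes.loc[hgs, list(loci)].astype(float)
        d = np.abs(modals.to_numpy()[:, None, :] - modals.to_numpy()[None, :, :]).sum(axis=2)
        np.fill_diagonal(d, np.inf)
        if (d < min_step_distance).any():
            raise ValueError(
                f"modal haplotypes closer than min_step_distance={min_step_distance}"
            )

    def draw(prefix: str, sizes: dict[str, int]) -> tuple[HaplotypeTable, pd.Series]:
        rows, labels, ids = [], [], []
        for hg in hgs:
            n = sizes[hg]
            base = modals.loc[hg].to_numpy()
            mutate = rng.random((n, L)) < noise
            step = rng.choice([-1.0, 1.0], size=(n, L))
            vals = np.maximum(base[None, :] + mutate * step, MIN_REPEAT)
            rows.append(vals)
            labels += [hg] * n
            ids += [f"{prefix}_{hg}_{i + 1}" for i in range(n)]
        alleles = pd.DataFrame(
            np.vstack(rows), index=pd.Index(ids, name="SampleID"), columns=list(loci)
        )
        table = HaplotypeTable(
            alleles, pd.Series(["panel"] * len(ids), index=alleles.index, name="Population")
        )
        return table, pd.Series(labels, index=alleles.index, name="Haplogroup")

    train_table, train_labels = draw("train", {hg: train_per_haplogroup for hg in hgs})
    test_table, test_labels = draw("test", haplogroup_sizes)
    panel = train_panel(train_table, train_labels, epsilon=epsilon)
    return HaplogroupPanelSim(train_table, train_labels, test_table, test_labels, panel, modals)


def plant_microvariants(table: HaplotypeTable, k: int, seed: int) -> HaplotypeTable:
    """Shift one allele of ``k`` distinct samples by +0.2 (novel microvariants)."""
    if k > table.n_samples:
        raise ValueError(f"k={k} exceeds sample count {table.n_samples}")
    if k < 0:
        raise ValueError("k must be >= 0")
    rng = np.random.default_rng(seed)
    alleles = table.alleles.copy()
    chosen = rng.choice(table.n_samples, size=k, replace=False)
    for i in chosen:
        called = np.flatnonzero(np.isfinite(alleles.iloc[i].to_numpy()))
        if called.size == 0:
            raise ValueError(f"sample {table.sample_ids[i]!r} has no called alleles")
        j = int(rng.choice(called))
        alleles.iloc[i, j] = alleles.iloc[i, j] + 0.2
    return HaplotypeTable(alleles, table.populations.copy())
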
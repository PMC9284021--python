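"""Bayesian allele-frequency prediction of Y haplogroups from STR profiles.

In the style of Athey's haplogroup predictor: each candidate haplogroup h
has a per-locus allele-frequency table f_h; a query haplotype is scored

    score(h) = prior(h) * prod_over_scored_loci max(f_h(allele), epsilon)

and posteriors are the normalized scores.  ``epsilon`` is the smoothing mass
given to alleles never observed in a haplogroup's reference sample, so one
novel allele penalizes rather than zeroes a likelihood.  Scoring is done in
log space; multi-copy locus pairs are compared order-insensitively.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data_io import DEFAULT_MULTICOPY_POLICY, HaplotypeTable, MultiCopyLocusPolicy

logger = logging.getLogger(__name__)

_ALLELE_DECIMALS = 1  # alleles compared at 0.1-repeat resolution


def _key(allele: float) -> float:
    return round(float(allele), _ALLELE_DECIMALS)


@dataclass
class HaplogroupReferencePanel:
    """Per-haplogroup, per-locus allele-frequency tables with priors."""

    frequencies: dict[str, dict[str, dict[float, float]]]  #: hg -> locus -> allele -> freq
    priors: dict[str, float]
    epsilon: float = 1e-4

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")
        total = sum(self.priors.values())
        if total <= 0:
            raise ValueError("priors must have positive mass")
        self.priors = {h: w / total for h, w in self.priors.items()}
        if set(self.priors) != set(self.frequencies):
            raise ValueError("priors and frequency tables name different haplogroups")
        for hg, table in self.frequencies.items():
            for locus, freqs in table.items():
                s = sum(freqs.values())
                if s > 1 + 1e-9 or any(p <= 0 for p in freqs.values()):
                    raise ValueError(f"bad frequencies for {hg}/{locus} (sum {s})")

    @property
    def haplogroups(self) -> list[str]:
        return sorted(self.frequencies)

    @property
    def loci(self) -> list[str]:
        out: set[str] = set()
        for table in self.frequencies.values():
            out.update(table)
        return sorted(out)

    def frequency(self, hg: str, locus: str, allele: float) -> float:
        f = self.frequencies[hg].get(locus, {}).get(_key(allele), 0.0)
        return max(f, self.epsilon)

    def to_csv(self, path: str | Path) -> None:
        rows = [
            {"haplogroup": hg, "locus": locus, "allele": a, "frequency": f}
            for hg in self.haplogroups
            for locus in sorted(self.frequencies[hg])
            for a, f in sorted(self.frequencies[hg][locus].items())
        ]
        pd.DataFrame(rows).to_csv(path, index=False)

    @classmethod
    def read_csv(
        cls,
        path: str | Path,
        priors: dict[str, float] | None = None,
        epsilon: float = 1e-4,
    ) -> "HaplogroupReferencePanel":
        df = pd.read_csv(path)
        need = {"haplogroup", "locus", "allele", "frequency"}
        if not need.issubset(df.columns):
            raise ValueError(f"{path}: expected columns {sorted(need)}")
        freqs: dict[str, dict[str, dict[float, float]]] = {}
        for row in df.itertuples(index=False):
            freqs.setdefault(str(row.haplogroup), {}).setdefault(str(row.locus), {})[
                _key(row.allele)
            ] = float(row.frequency)
        if priors is None:
            priors = {h: 1.0 for h in freqs}
        return cls(freqs, priors, epsilon)


def train_panel(
    table: HaplotypeTable,
    haplogroup_labels: pd.Series,
    epsilon: float = 1e-4,
    priors: dict[str, float] | None = None,
) -> HaplogroupReferencePanel:
    """Empirical per-haplogroup allele frequencies from a labeled table.

    Haplogroups present in ``priors`` but absent from the data are dropped
    with a warning.
    """
    labels = haplogroup_labels.reindex(table.alleles.index)
    if labels.isna().any():
        raise ValueError("every sample needs a haplogroup label")
    freqs: dict[str, dict[str, dict[float, float]]] = {}
    for hg, idx in labels.groupby(labels).groups.items():
        sub = table.alleles.loc[idx]
        freqs[str(hg)] = {}
        for locus in table.loci:
            col = sub[locus].dropna()
            if col.empty:
                continue
            counts = col.round(_ALLELE_DECIMALS).value_counts()
            n = counts.sum()
            freqs[str(hg)][locus] = {float(a): c / n for a, c in counts.items()}
    if priors is None:
        priors = {h: 1.0 for h in freqs}
    else:
        dropped = sorted(set(priors) - set(freqs))
        if dropped:
            logger.warning("haplogroups with zero training samples dropped: %s", dropped)
        priors = {h: w for h, w in priors.items() if h in freqs}
    return HaplogroupReferencePanel(freqs, priors, epsilon)


@dataclass(frozen=True)
class Prediction:
    """Posterior haplogroup assignment for one sample."""

    sample_id: str
    posteriors: dict[str, float]
    haplogroup: str  #: argmax posterior (alphabetical tie-break)
    fitness: float  #: mean per-locus log10 likelihood of the winning haplogroup
    n_loci_scored: int


def predict_haplogroup(
    haplotype: dict[str, float] | pd.Series,
    panel: HaplogroupReferencePanel,
    priors: dict[str, float] | None = None,
    *,
    sample_id: str = "",
    policy: MultiCopyLocusPolicy = DEFAULT_MULTICOPY_POLICY,
) -> Prediction:
    """Posterior haplogroup probabilities for a single haplotype.

    Loci missing from either the haplotype or the panel are skipped;
    multi-copy pairs are sorted before scoring so copy order never matters.
    """
    if isinstance(haplotype, pd.Series):
        haplotype = {str(k): v for k, v in haplotype.items()}
    observed = {k: float(v) for k, v in haplotype.items() if v is not None and np.isfinite(v)}
    # order-insensitive multi-copy scoring: sort each complete pair
    for a, b in policy.pairs.values():
        if a in observed and b in observed and observed[a] > observed[b]:
            observed[a], observed[b] = observed[b], observed[a]
    panel_loci = set(panel.loci)
    scored = [l for l in observed if l in panel_loci]
    if not scored:
        raise ValueError("haplotype shares no loci with the panel")
    weights = priors if priors is not None else panel.priors
    hgs = panel.haplogroups
    loglik = {}
    for hg in hgs:
        ll = sum(math.log10(panel.frequency(hg, l, observed[l])) for l in scored)
        loglik[hg] = ll
    logscore = {hg: math.log10(weights.get(hg, 0.0)) + loglik[hg] if weights.get(hg, 0.0) > 0 else -math.inf for hg in hgs}
    top = max(logscore.values())
    raw = {hg: 10.0 ** (s - top) if np.isfinite(s) else 0.0 for hg, s in logscore.items()}
    z = sum(raw.values())
    posteriors = {hg: v / z for hg, v in raw.items()}
    best = max(posteriors.values())
    winner = min(hg for hg, p in posteriors.items() if p >= best - 1e-15)
    return Prediction(
        sample_id=sample_id,
        posteriors=posteriors,
        haplogroup=winner,
        fitness=loglik[winner] / len(scored),
        n_loci_scored=len(scored),
    )


def predict_table(
    table: HaplotypeTable,
    panel: HaplogroupReferencePanel,
    priors: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Predict every sample in a table; one row per sample."""
    rows = []
    for sid in table.sample_ids:
        pred = predict_haplogroup(table.alleles.loc[sid], panel, priors, sample_id=sid)
        row = {
            "sample_id": sid,
            "population": table.populations.loc[sid],
            "haplogroup": pred.haplogroup,
            "posterior_max": pred.posteriors[pred.haplogroup],
            "fitness": pred.fitness,
            "n_loci_scored": pred.n_loci_scored,
        }
        for hg in panel.haplogroups:
            row[f"p_{hg}"] = pred.posteriors[hg]
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class HaplogroupFrequencyTable:
    """Haplogroup counts and percentages per group, plus an overall row."""

    counts: pd.DataFrame  #: groups x haplogroups, with a "Total" row
    percentages: pd.DataFrame  #: same shape, 100 * count / group size

    def to_frame(self) -> pd.DataFrame:
        pct = self.percentages.add_suffix(" (%)")
        return pd.concat([self.counts, pct.round(2)], axis=1)


def haplogroup_frequency_table(
    haplogroups: pd.Series, groups: pd.Series
) -> HaplogroupFrequencyTable:
    """Cross-tabulate haplogroup assignments by group.

    Percentages are relative to group size (rows sum to 100).
    """
    haplogroups = haplogroups.astype(str)
    groups = groups.reindex(haplogroups.index)
    if groups.isna().any() or len(haplogroups) == 0:
        raise ValueError("every sample needs a group label and >=1 sample required")
    counts = pd.crosstab(groups, haplogroups)
    if (counts.sum(axis=1) == 0).any():
        raise ValueError("empty group")
    counts.loc["Total"] = counts.sum(axis=0)
    pct = counts.div(counts.sum(axis=1), axis=0) * 100.0
    counts.index.name = "group"
    pct.index.name = "group"
    return HaplogroupFrequencyTable(counts, pct)
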
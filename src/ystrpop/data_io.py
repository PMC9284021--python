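"""Reading, validation, filtering and serialization of Y-STR data.

The universal input is a *haplotype table*: one row per sampled man, one
column per Y-STR locus, cells holding numeric repeat counts.  Microvariant
alleles (partial repeats) are stored as exact decimals, e.g. ``13.2`` for
13 full repeats plus 2 bases; they are distinct allelic categories and are
never rounded.

File format: wide CSV/TSV whose first two columns are ``SampleID`` and
``Population``, followed by one column per locus; missing calls use the
token ``NA``.
"""

from __future__ import annotations

import dataclasses
import json
import math
import os
import shutil
import tempfile
import warnings
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode

from . import markers

MISSING_TOKEN = "NA"

#: Fractional parts a Y-STR allele may carry (full repeats plus 0-3 bases).
_VALID_FRACTIONS = frozenset({0, 1, 2, 3})


def _valid_allele(v: float) -> bool:
    if not math.isfinite(v) or not 0 < v < 100:
        return False
    tenths = v * 10
    return abs(tenths - round(tenths)) < 1e-6 and round(tenths) % 10 in _VALID_FRACTIONS


@dataclass(frozen=True)
class MultiCopyLocusPolicy:
    """How the two unphased alleles of a multi-copy marker map to columns.

    ``sorted_ascending`` (the convention used by YHRD and most forensic
    reports) puts the smaller allele in the ``a`` column; ``as_reported``
    leaves the columns untouched.
    """

    pairs: Mapping[str, tuple[str, str]] = field(
        default_factory=lambda: {
            "DYS385": ("DYS385a", "DYS385b"),
            "DYF387S1": ("DYF387S1a", "DYF387S1b"),
        }
    )
    rule: str = "sorted_ascending"

    def __post_init__(self) -> None:
        if self.rule not in ("sorted_ascending", "as_reported"):
            raise ValueError(f"unknown assignment rule {self.rule!r}")

    def normalize(self, alleles: pd.DataFrame) -> pd.DataFrame:
        """Return a copy with each present column pair in canonical order.

        Sorting is idempotent; cells where either copy is missing are left
        as reported (order is then meaningless).
        """
        if self.rule == "as_reported":
            return alleles.copy()
        out = alleles.copy()
        for a, b in self.pairs.values():
            if a in out.columns and b in out.columns:
                pair = out[[a, b]].to_numpy(dtype=float)
                both = ~np.isnan(pair).any(axis=1)
                pair[both] = np.sort(pair[both], axis=1)
                out[a] = pair[:, 0]
                out[b] = pair[:, 1]
        return out


DEFAULT_MULTICOPY_POLICY = MultiCopyLocusPolicy()


@dataclass
class HaplotypeTable:
    """Samples x loci matrix of repeat counts with population labels.

    Parameters
    ----------
    alleles
        DataFrame indexed by unique sample IDs, one float column per locus;
        ``NaN`` marks a missing call.
    populations
        Population label per sample, aligned with ``alleles.index``.
    """

    alleles: pd.DataFrame
    populations: pd.Series

    def __post_init__(self) -> None:
        self.alleles = self.alleles.astype(float)
        if not self.alleles.index.is_unique:
            dups = self.alleles.index[self.alleles.index.duplicated()].unique()
            raise ValueError(f"duplicate sample IDs: {list(dups)}")
        self.populations = self.populations.reindex(self.alleles.index)
        if self.populations.isna().any():
            missing = list(self.populations.index[self.populations.isna()])
            raise ValueError(f"samples without a population label: {missing}")
        vals = self.alleles.to_numpy()
        bad = np.zeros(vals.shape, dtype=bool)
        with np.errstate(invalid="ignore"):
            finite = np.isfinite(vals)
            bad[finite] = ~np.vectorize(_valid_allele)(vals[finite]) if finite.any() else False
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise ValueError(
                f"invalid allele {vals[r, c]!r} for sample "
                f"{self.alleles.index[r]!r} at locus {self.alleles.columns[c]!r} "
                "(alleles must be in (0, 100) with fractional part .0/.1/.2/.3)"
            )

    # -- basic accessors -------------------------------------------------

    @property
    def sample_ids(self) -> list[str]:
        return list(self.alleles.index)

    @property
    def loci(self) -> list[str]:
        return list(self.alleles.columns)

    @property
    def n_samples(self) -> int:
        return len(self.alleles)

    def population_sizes(self) -> pd.Series:
        return self.populations.value_counts()

    # -- views -----------------------------------------------------------

    def select_loci(self, loci: Iterable[str]) -> "HaplotypeTable":
        loci = list(loci)
        missing = [l for l in loci if l not in self.alleles.columns]
        if missing:
            raise KeyError(f"loci not in table: {missing}")
        return HaplotypeTable(self.alleles[loci].copy(), self.populations.copy())

    def select_samples(self, sample_ids: Iterable[str]) -> "HaplotypeTable":
        ids = list(sample_ids)
        return HaplotypeTable(self.alleles.loc[ids].copy(), self.populations.loc[ids].copy())

    def select_populations(self, labels: Iterable[str]) -> "HaplotypeTable":
        keep = self.populations.isin(set(labels))
        return HaplotypeTable(self.alleles[keep].copy(), self.populations[keep].copy())

    def complete_cases(self) -> "HaplotypeTable":
        """Samples fully genotyped at every locus in the table."""
        keep = self.alleles.notna().all(axis=1)
        return HaplotypeTable(self.alleles[keep].copy(), self.populations[keep].copy())

    def equals(self, other: "HaplotypeTable", tol: float = 1e-9) -> bool:
        if self.sample_ids != other.sample_ids or self.loci != other.loci:
            return False
        if not self.populations.equals(other.populations):
            return False
        a, b = self.alleles.to_numpy(), other.alleles.to_numpy()
        both_nan = np.isnan(a) & np.isnan(b)
        return bool(np.all(both_nan | (np.abs(a - b) <= tol)))


def read_haplotype_table(
    path: str | Path,
    *,
    delimiter: str | None = None,
    missing: str = MISSING_TOKEN,
    policy: MultiCopyLocusPolicy = DEFAULT_MULTICOPY_POLICY,
    known_loci: Iterable[str] | None = markers.YFILER_PLUS27,
) -> HaplotypeTable:
    """Read and validate a wide haplotype CSV/TSV.

    Loci columns not in ``known_loci`` trigger a warning but are retained
    (pass ``known_loci=None`` to silence).  Non-numeric cells other than the
    missing token are a hard error naming the offending sample and locus.
    """
    path = Path(path)
    if delimiter is None:
        delimiter = "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","
    raw = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    if raw.shape[1] < 3:
        raise ValueError(f"{path}: expected SampleID, Population and >=1 locus column")
    id_col, pop_col = raw.columns[:2]
    loci = list(raw.columns[2:])
    if known_loci is not None:
        unknown = sorted(set(loci) - set(known_loci))
        if unknown:
            warnings.warn(f"{path.name}: unknown locus columns retained: {unknown}", stacklevel=2)
    ids = raw[id_col].astype(str)
    if ids.duplicated().any():
        raise ValueError(f"{path}: duplicate sample IDs: {sorted(ids[ids.duplicated()])}")
    values = np.full((len(raw), len(loci)), np.nan)
    for j, locus in enumerate(loci):
        for i, tok in enumerate(raw[locus]):
            tok = tok.strip()
            if tok == missing or tok == "":
                continue
            try:
                values[i, j] = float(tok)
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric allele {tok!r} for sample "
                    f"{ids.iloc[i]!r} at locus {locus!r}"
                ) from None
    alleles = pd.DataFrame(values, index=pd.Index(ids, name="SampleID"), columns=loci)
    table = HaplotypeTable(policy.normalize(alleles), pd.Series(raw[pop_col].values, index=alleles.index, name="Population"))
    return table


def write_haplotype_table(table: HaplotypeTable, path: str | Path, *, delimiter: str = ",") -> None:
    path = Path(path)

    def fmt(v: float) -> str:
        if np.isnan(v):
            return MISSING_TOKEN
        return f"{v:.1f}".rstrip("0").rstrip(".") if v % 1 else str(int(v))

    out = table.alleles.map(fmt)
    out.insert(0, "Population", table.populations)
    out.index.name = "SampleID"
    out.to_csv(path, sep=delimiter)


# -- allele registry ---------------------------------------------------------


@dataclass(frozen=True)
class AlleleRegistry:
    """Per-locus sets of known allele values.

    A haplotype carrying any allele absent from the registry at its locus is
    a candidate novel microvariant.  Membership is tested at 0.1-repeat
    resolution, the resolution at which alleles are called.
    """

    alleles: Mapping[str, frozenset[float]]

    def __post_init__(self) -> None:
        for locus, vals in self.alleles.items():
            for v in vals:
                if not _valid_allele(v):
                    raise ValueError(f"invalid registry allele {v!r} at {locus!r}")

    def known(self, locus: str, allele: float) -> bool:
        vals = self.alleles.get(locus)
        if vals is None:
            return False
        key = round(allele * 10) / 10
        return any(abs(key - v) < 1e-6 for v in vals)

    def covers(self, loci: Iterable[str]) -> bool:
        return all(l in self.alleles for l in loci)

    @classmethod
    def from_table(cls, table: HaplotypeTable) -> "AlleleRegistry":
        return cls(
            {
                locus: frozenset(round(v * 10) / 10 for v in col.dropna().unique())
                for locus, col in table.alleles.items()
            }
        )

    @classmethod
    def read_csv(cls, path: str | Path) -> "AlleleRegistry":
        df = pd.read_csv(path)
        if list(df.columns[:2]) != ["locus", "allele"]:
            raise ValueError(f"{path}: expected columns locus,allele")
        grouped: dict[str, set[float]] = {}
        for locus, allele in zip(df["locus"], df["allele"].astype(float)):
            grouped.setdefault(str(locus), set()).add(round(allele * 10) / 10)
        return cls({k: frozenset(v) for k, v in grouped.items()})

    def to_csv(self, path: str | Path) -> None:
        rows = [
            {"locus": locus, "allele": allele}
            for locus in self.alleles
            for allele in sorted(self.alleles[locus])
        ]
        pd.DataFrame(rows).to_csv(path, index=False)


def filter_by_registry(
    table: HaplotypeTable, registry: AlleleRegistry
) -> tuple[HaplotypeTable, HaplotypeTable]:
    """Partition samples into (retained, flagged) against a registry.

    A sample is flagged iff at least one of its non-missing alleles is
    unknown to the registry at that locus; row order is preserved on both
    sides of the partition.
    """
    if not registry.covers(table.loci):
        missing = [l for l in table.loci if l not in registry.alleles]
        raise ValueError(f"registry does not cover loci: {missing}")
    flagged_mask = np.zeros(table.n_samples, dtype=bool)
    for j, locus in enumerate(table.loci):
        col = table.alleles[locus].to_numpy()
        for i, v in enumerate(col):
            if not np.isnan(v) and not registry.known(locus, v):
                flagged_mask[i] = True
    keep_ids = [s for s, f in zip(table.sample_ids, flagged_mask) if not f]
    flag_ids = [s for s, f in zip(table.sample_ids, flagged_mask) if f]
    return table.select_samples(keep_ids), table.select_samples(flag_ids)


# -- trees -------------------------------------------------------------------


def write_newick(tree: TreeNode, path: str | Path) -> None:
    """Serialize a tree to Newick with branch lengths.

    Every tip must carry a label; quoting of labels containing whitespace is
    handled by the Newick writer.
    """
    for tip in tree.tips():
        if tip.name is None or str(tip.name).strip() == "":
            raise ValueError("tree has an unlabeled leaf")
    tree.write(str(path), format="newick")


def read_newick(path: str | Path) -> TreeNode:
    return TreeNode.read(str(path), format="newick")


# -- report bundle -----------------------------------------------------------

BUNDLE_FILES = (
    "allele_frequencies.csv",
    "diversity_summary.txt",
    "rst_matrix.csv",
    "rst_pvalues.csv",
    "mds_coordinates.csv",
    "nj_tree.nwk",
    "haplogroup_predictions.csv",
    "haplogroup_frequencies.csv",
    "manifest.json",
)


def write_report_bundle(results: Mapping[str, object], out_dir: str | Path) -> list[Path]:
    """Write all stage outputs atomically into ``out_dir``.

    ``results`` maps stage names to result objects (any subset of:
    ``allele_frequencies`` - list of spectra, ``diversity`` - DiversityReport,
    ``rst`` - DistanceMatrix, ``mds`` - EmbeddingResult, ``tree`` - TreeNode,
    ``predictions`` - DataFrame, ``haplogroup_frequencies`` -
    HaplogroupFrequencyTable, ``manifest`` - JSON-serializable dict).
    Files are first written to a temporary sibling directory and moved into
    place only after every write succeeded, so a failure leaves no partial
    bundle behind.
    """
    if not results:
        raise ValueError("empty results: nothing to write")
    out_dir = Path(out_dir)
    out_dir.parent.mkdir(parents=True, exist_ok=True)
    tmp = Path(tempfile.mkdtemp(prefix=out_dir.name + ".partial-", dir=out_dir.parent))
    written: list[Path] = []
    try:
        if "allele_frequencies" in results:
            rows = [
                {"locus": s.locus, "allele": a, "frequency": round(f, 6), "n": s.n}
                for s in results["allele_frequencies"]
                for a, f in sorted(s.frequencies.items())
            ]
            pd.DataFrame(rows).to_csv(tmp / "allele_frequencies.csv", index=False)
            written.append(out_dir / "allele_frequencies.csv")
        if "diversity" in results:
            (tmp / "diversity_summary.txt").write_text(results["diversity"].summary())
            written.append(out_dir / "diversity_summary.txt")
        if "rst" in results:
            dm = results["rst"]
            dm.rst.to_csv(tmp / "rst_matrix.csv")
            dm.pvalues.to_csv(tmp / "rst_pvalues.csv")
            written += [out_dir / "rst_matrix.csv", out_dir / "rst_pvalues.csv"]
        if "mds" in results:
            results["mds"].to_frame().to_csv(tmp / "mds_coordinates.csv", index=False)
            written.append(out_dir / "mds_coordinates.csv")
        if "tree" in results:
            write_newick(results["tree"], tmp / "nj_tree.nwk")
            written.append(out_dir / "nj_tree.nwk")
        if "predictions" in results:
            results["predictions"].to_csv(tmp / "haplogroup_predictions.csv", index=False)
            written.append(out_dir / "haplogroup_predictions.csv")
        if "haplogroup_frequencies" in results:
            results["haplogroup_frequencies"].to_frame().to_csv(tmp / "haplogroup_frequencies.csv")
            written.append(out_dir / "haplogroup_frequencies.csv")
        if "manifest" in results:
            (tmp / "manifest.json").write_text(json.dumps(results["manifest"], indent=2, sort_keys=True))
            written.append(out_dir / "manifest.json")
        out_dir.mkdir(exist_ok=True)
        for dest in written:
            os.replace(tmp / dest.name, dest)
    finally:
        shutil.rmtree(tmp, ignore_errors=True)
    return written
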
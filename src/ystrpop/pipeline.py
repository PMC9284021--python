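"""Config-driven end-to-end analysis pipeline.

Stage order mirrors the study design: samples carrying alleles unknown to
the registry (candidate novel microvariants) are set aside before any STR
statistic is computed, but haplogroup prediction runs on the *unfiltered*
table — microvariants do not impede Bayesian scoring, so every sample gets
a haplogroup call while diversity/Rst use only validated haplotypes.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__, markers
from .data_io import (
    AlleleRegistry,
    HaplotypeTable,
    filter_by_registry,
    read_haplotype_table,
    write_report_bundle,
)
from .diversity import allele_frequencies, haplotype_statistics
from .embedding import classical_mds, neighbor_joining
from .haplogroups import (
    HaplogroupReferencePanel,
    haplogroup_frequency_table,
    predict_table,
)
from .rst import rst_matrix

logger = logging.getLogger(__name__)

STAGES = ("diversity", "rst", "mds", "njtree", "predict")


@dataclass
class PipelineConfig:
    """Fully resolved pipeline configuration."""

    table: Path
    seed: int
    registry: Path | None = None
    panel: Path | None = None
    markers: str | list[str] = "yfilerplus27"
    permutations: int = 10_000
    out_dir: Path = Path("ystrpop_out")
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    frequency_decimals: int = 6

    def validate(self) -> None:
        errors = []
        if not Path(self.table).exists():
            errors.append(f"input table not found: {self.table}")
        for name in ("registry", "panel"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                errors.append(f"{name} file not found: {p}")
        if self.permutations < 99:
            errors.append("permutations must be >= 99")
        if self.seed is None:
            errors.append("seed is mandatory")
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            errors.append(f"unknown stages: {sorted(unknown)} (valid: {list(STAGES)})")
        if "predict" in self.stages and self.panel is None:
            errors.append("prediction stage enabled but no reference panel configured")
        try:
            markers.resolve_marker_set(self.markers)
        except ValueError as e:
            errors.append(str(e))
        if errors:
            raise ValueError("invalid pipeline config:\n  " + "\n  ".join(errors))

    @property
    def loci(self) -> list[str]:
        return list(markers.resolve_marker_set(self.markers))


def validate_config(path: str | Path, **overrides) -> PipelineConfig:
    """Load a YAML config file, apply defaults and overrides, validate."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    raw.update({k: v for k, v in overrides.items() if v is not None})
    known = {f.name for f in PipelineConfig.__dataclass_fields__.values()}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"{path}: unknown config keys: {sorted(unknown)}")
    if "table" not in raw:
        raise ValueError(f"{path}: 'table' is required")
    if "seed" not in raw:
        raise ValueError(f"{path}: 'seed' is required")
    for key in ("table", "registry", "panel", "out_dir"):
        if key in raw and raw[key] is not None:
            raw[key] = Path(raw[key])
    cfg = PipelineConfig(**raw)
    cfg.validate()
    return cfg


def run_pipeline(config: PipelineConfig) -> dict[str, object]:
    """Run all enabled stages and write the report bundle.

    Returns the results mapping that was written (see
    :func:`ystrpop.data_io.write_report_bundle`).
    """
    config.validate()
    t0 = time.time()
    table = read_haplotype_table(config.table, known_loci=config.loci)
    loci = [l for l in config.loci if l in table.loci]
    if not loci:
        raise RuntimeError("stage 'input': no configured marker present in the table")
    table = table.select_loci(loci)
    logger.info("input: %d samples, %d loci", table.n_samples, len(loci))

    if config.registry is not None:
        registry = AlleleRegistry.read_csv(config.registry)
    else:
        registry = AlleleRegistry.from_table(table)
    str_table, flagged = filter_by_registry(table, registry)
    logger.info(
        "microvariant filter: %d retained for STR statistics, %d flagged",
        str_table.n_samples,
        flagged.n_samples,
    )

    results: dict[str, object] = {}
    timings: dict[str, float] = {}

    def stage(name):
        return name in config.stages

    try:
        if stage("diversity"):
            t = time.time()
            results["allele_frequencies"] = [
                allele_frequencies(str_table, l) for l in str_table.loci
            ]
            results["diversity"] = haplotype_statistics(str_table)
            timings["diversity"] = time.time() - t
        dm = None
        if stage("rst") or stage("mds") or stage("njtree"):
            t = time.time()
            dm = rst_matrix(str_table, m=config.permutations, seed=config.seed)
            results["rst"] = dm
            timings["rst"] = time.time() - t
        if stage("mds") and dm is not None:
            t = time.time()
            results["mds"] = classical_mds(dm)
            timings["mds"] = time.time() - t
        if stage("njtree") and dm is not None and len(dm.labels) >= 3:
            t = time.time()
            results["tree"] = neighbor_joining(dm)
            timings["njtree"] = time.time() - t
        if stage("predict"):
            t = time.time()
            panel = HaplogroupReferencePanel.read_csv(config.panel)
            # prediction runs on the unfiltered table: every sample is scored
            preds = predict_table(table, panel)
            results["predictions"] = preds
            results["haplogroup_frequencies"] = haplogroup_frequency_table(
                preds.set_index("sample_id")["haplogroup"],
                table.populations.rename(index=str),
            )
            timings["predict"] = time.time() - t
    except Exception as e:
        raise RuntimeError(f"stage failure: {e}") from e

    config_text = json.dumps(
        {k: str(v) for k, v in vars(config).items()}, sort_keys=True
    )
    results["manifest"] = {
        "package": "ystrpop",
        "version": __version__,
        "seed": config.seed,
        "markers": config.markers if isinstance(config.markers, str) else list(config.markers),
        "permutations": config.permutations,
        "config_sha256": hashlib.sha256(config_text.encode()).hexdigest(),
        "n_samples_input": table.n_samples,
        "n_samples_str_statistics": str_table.n_samples,
        "n_samples_flagged_microvariant": flagged.n_samples,
        "stages": list(config.stages),
        "stage_seconds": {k: round(v, 3) for k, v in timings.items()},
        "total_seconds": round(time.time() - t0, 3),
    }
    write_report_bundle(results, config.out_dir)
    return results
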
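"""End-to-end pipeline: simulate (optional) -> features -> select (train
only) -> fit (train) -> evaluate (test) -> GC bias, with one config, an
explicit seed, and a self-describing run directory.

Interchange between stages is plain files (BED / TSV / JSON) so each stage
is independently runnable and testable; rerunning with the same config and
seed reproduces the outputs bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import classify, features, gcbias, selection, simulate
from .core import CohortManifest, GenomicRegion, ValidationError, resolve_fragments_path
from .io import (
    read_fragment_arrays,
    read_manifest,
    write_feature_matrix,
    write_manifest,
)

logger = logging.getLogger(__name__)


@dataclass
class SimulateConfig:
    enabled: bool = True
    region_chrom: str = "chr18s"
    region_start: int = 0
    region_end: int = 10_000_000
    genome_bin_width: int = 5000
    chemistry: str = "WGES"
    tumor_fraction: float = 0.2
    cnv_copy_ratio: float = 3.0
    n_fragments: int = 50_000
    n_train_cancer: int = 24
    n_train_control: int = 24
    n_test_cancer: int = 12
    n_test_control: int = 12


@dataclass
class FeatureConfig:
    bin_width: int = 5000
    short_lo: int = 100
    short_hi: int = 150
    medium_lo: int = 151
    medium_hi: int = 220
    normalization: str = "cpm"
    layout: str = "combined"


@dataclass
class SelectionConfig:
    batch_size: int = 1000
    threshold: float = 0.7
    differential_test: bool = False
    differential_alpha: float = 0.05


@dataclass
class LdaConfig:
    shrinkage: float | str = "auto"
    threshold: float = 0.5


@dataclass
class GcBiasConfig:
    enabled: bool = True
    window_width: int = 150
    n_total: int = 3000
    gate_lo: float = 0.15
    gate_hi: float = 0.65
    gate_step: float = 0.05


@dataclass
class PipelineConfig:
    """Single configuration object for a full run."""

    seed: int = 0
    manifest_path: str | None = None  # required unless simulate.enabled
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    lda: LdaConfig = field(default_factory=LdaConfig)
    gc_bias: GcBiasConfig = field(default_factory=GcBiasConfig)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        for key, sub in (
            ("simulate", SimulateConfig),
            ("features", FeatureConfig),
            ("selection", SelectionConfig),
            ("lda", LdaConfig),
            ("gc_bias", GcBiasConfig),
        ):
            if key in d and isinstance(d[key], dict):
                d[key] = sub(**d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
        return path

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class RunResult:
    outdir: Path
    manifest: CohortManifest
    metrics: classify.MetricsReport
    selection: selection.SelectionResult
    gc_results: dict[str, gcbias.GcRegressionResult]
    genome: simulate.SyntheticGenome | None


def _check_no_leakage(manifest: CohortManifest) -> None:
    train = set(manifest.subset(split="train").sample_ids())
    test = set(manifest.subset(split="test").sample_ids())
    overlap = train & test
    if overlap:
        raise ValidationError(f"sample(s) in both train and test: {sorted(overlap)}")


def run(config: PipelineConfig, outdir: str | Path) -> RunResult:
    """Execute all stages in order and write a self-describing run directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    log: dict = {"config_hash": config.config_hash(), "seed": config.seed, "stages": {}}

    # --- simulate (optional) ------------------------------------------------
    genome = None
    if config.simulate.enabled:
        sim = config.simulate
        region = GenomicRegion(sim.region_chrom, sim.region_start, sim.region_end)
        genome = simulate.build_genome(
            region, bin_width=sim.genome_bin_width, seed=config.seed
        )
        cohort = simulate.CohortSpec(
            n_train_cancer=sim.n_train_cancer,
            n_train_control=sim.n_train_control,
            n_test_cancer=sim.n_test_cancer,
            n_test_control=sim.n_test_control,
            chemistry=sim.chemistry,
            tumor_fraction=sim.tumor_fraction,
            cnv_copy_ratio=sim.cnv_copy_ratio,
            n_fragments=sim.n_fragments,
        )
        manifest, manifest_path = simulate.simulate_cohort(
            genome, outdir / "cohort", cohort, seed=config.seed
        )
        manifest_dir = manifest_path.parent
        target_region = region
        log["stages"]["simulate"] = {
            "n_samples": len(manifest),
            "chemistry": sim.chemistry,
        }
    else:
        if not config.manifest_path:
            raise ValidationError("manifest_path required when simulation is disabled")
        manifest = read_manifest(config.manifest_path)
        manifest_dir = Path(config.manifest_path).parent
        # target region defaults to the configured simulate region bounds
        sim = config.simulate
        target_region = GenomicRegion(sim.region_chrom, sim.region_start, sim.region_end)

    _check_no_leakage(manifest)
    manifest.require_both_labels("train")
    manifest.require_both_labels("test")

    # --- features -----------------------------------------------------------
    fc = config.features
    bins = features.make_bins(target_region, fc.bin_width)
    classes = features.SizeClassScheme(
        short=(fc.short_lo, fc.short_hi), medium=(fc.medium_lo, fc.medium_hi)
    )
    matrix = features.build_feature_matrix(
        manifest,
        bins,
        classes,
        normalization=fc.normalization,
        layout=fc.layout,
        manifest_dir=manifest_dir,
    )
    write_feature_matrix(matrix, outdir / "features.tsv")
    log["stages"]["features"] = {"n_bins": bins.n_bins, "n_features": matrix.shape[1]}

    # --- selection (train rows only) ----------------------------------------
    train_manifest = manifest.subset(split="train")
    test_manifest = manifest.subset(split="test")
    train_matrix = matrix.loc[train_manifest.sample_ids()]
    sel = selection.correlation_filter(
        train_matrix,
        batch_size=config.selection.batch_size,
        threshold=config.selection.threshold,
    )
    kept = sel.kept_feature_ids
    if config.selection.differential_test:
        diff = selection.differential_test(
            train_matrix[kept], train_manifest.labels()
        )
        kept = [f for f in kept if diff.loc[f, "pvalue"] < config.selection.differential_alpha]
        diff.to_csv(outdir / "differential.tsv", sep="\t")
    sel.to_frame().to_csv(outdir / "selection.tsv", sep="\t", index=False)
    if len(kept) < 2:
        raise ValidationError("fewer than 2 features survive selection")
    log["stages"]["select"] = {
        "n_input": matrix.shape[1],
        "n_kept": len(kept),
        "n_removed": matrix.shape[1] - len(sel.kept_feature_ids),
    }

    # --- fit + evaluate -----------------------------------------------------
    model = classify.fit_lda(
        train_matrix[kept], train_manifest.labels(), shrinkage=config.lda.shrinkage
    )
    model.to_frame().to_csv(outdir / "model.tsv", sep="\t", index=False)
    test_scores = classify.score(model, matrix.loc[test_manifest.sample_ids()])
    test_scores.to_csv(outdir / "scores.tsv", sep="\t")
    metrics = classify.evaluate(test_scores, test_manifest, threshold=config.lda.threshold)
    (outdir / "metrics.json").write_text(metrics.to_json(), encoding="utf-8")
    roc = classify.roc_points(test_scores, test_manifest.labels())
    roc.to_csv(outdir / "roc.csv", index=False)
    log["stages"]["evaluate"] = {
        "sensitivity_pct": metrics.sensitivity_pct,
        "specificity_pct": metrics.specificity_pct,
        "auc": metrics.auc,
        "shrinkage": model.shrinkage,
    }

    # --- GC bias ------------------------------------------------------------
    gc_results: dict[str, gcbias.GcRegressionResult] = {}
    if config.gc_bias.enabled and genome is not None:
        gcfg = config.gc_bias
        windows = gcbias.gc_windows(genome, target_region, width=gcfg.window_width)
        subset = gcbias.stratified_sample(
            windows,
            n_total=gcfg.n_total,
            seed=config.seed,
            lo=gcfg.gate_lo,
            hi=gcfg.gate_hi,
            step=gcfg.gate_step,
        )
        # pool each split+label's first sample per chemistry == use the first
        # test control sample as the representative fragment pool
        rep = test_manifest.subset(label="control").samples[0]
        frags = read_fragment_arrays(resolve_fragments_path(rep, manifest_dir))
        gc_results[rep.chemistry] = gcbias.coverage_vs_gc(frags, subset)
        (outdir / "gc_bias.json").write_text(
            json.dumps(
                {k: json.loads(v.to_json()) for k, v in gc_results.items()}, indent=2
            ),
            encoding="utf-8",
        )
        log["stages"]["gc_bias"] = {
            k: {"slope": v.slope, "pearson_r": v.pearson_r} for k, v in gc_results.items()
        }

    (outdir / "run_log.json").write_text(json.dumps(log, indent=2), encoding="utf-8")
    return RunResult(
        outdir=outdir,
        manifest=manifest,
        metrics=metrics,
        selection=sel,
        gc_results=gc_results,
        genome=genome,
    )
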
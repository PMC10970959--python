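"""Synthetic cfDNA cohort generator.

Emits post-alignment fragment intervals with the statistical structure the
downstream analysis assumes:

* nucleosome-periodic fragment lengths — a Gaussian mixture laddering at
  ~167 bp multiples (1-4 nucleosomes) with geometrically decaying weights;
* tumor-fraction-scaled regional copy-number alteration — in CNV bins the
  expected fragment emission is scaled by
  ``(1 - tumor_fraction) + tumor_fraction * cnv_copy_ratio``;
* conversion-chemistry degradation — each candidate fragment survives with
  probability ``exp(-(lambda_len * max(0, length - 250) + lambda_gc * gc))``,
  so bisulfite chemistry both strips long fragments and depletes GC-rich
  windows, while enzymatic conversion is near-lossless and untreated WGS
  is lossless. Bisulfite degradation rates additionally jitter per sample
  (lognormal), modelling batch-to-batch conversion variability.

Reads, base qualities, methylation states and alignment artifacts are out
of scope: the simulator emits fragments as they would appear after
alignment and deduplication.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .core import CohortManifest, FragmentRecord, GenomicRegion, SampleMeta, ValidationError
from .io import write_manifest

_TRAIN_STAGES = ["0"] * 3 + ["I"] * 10 + ["IIA"] * 5 + ["III"] * 3 + ["IIIA"] * 2 + ["IIIB"]
_TEST_STAGES = ["I"] * 4 + ["IIA"] * 4 + ["III"] * 4
_LOCATIONS = [
    "cecum",
    "ileocecal valve",
    "hepatic flexure",
    "transverse colon",
    "descending colon",
    "sigmoid colon",
    "rectosigmoid",
    "rectum",
]


@dataclass(frozen=True)
class ChemistryModel:
    """Fragment-length mixture and survival model for one conversion chemistry.

    ``survival(length, gc)`` is the per-fragment retention probability;
    identically 1 for untreated WGS, mildly below 1 for enzymatic
    conversion, and strongly length/GC-dependent for bisulfite.
    """

    name: str
    peak_centers: tuple[float, ...] = (167.0, 334.0, 501.0, 668.0)
    peak_weights: tuple[float, ...] = ()
    peak_sd: float = 25.0
    tumor_length_shift: float = -20.0
    lambda_len: float = 0.0       # per-bp decay beyond len_knee
    lambda_gc: float = 0.0        # decay per unit GC fraction
    len_knee: float = 250.0
    sample_jitter_sd: float = 0.0  # lognormal sd on per-sample lambdas
    overdispersion_sd: float = 0.0  # lognormal sd on per-sample per-bin emission

    def __post_init__(self) -> None:
        if not self.peak_weights:
            # geometric decay across nucleosome peaks, ratio 1/4
            w = np.array([0.25**k for k in range(len(self.peak_centers))])
            object.__setattr__(self, "peak_weights", tuple(w / w.sum()))
        if len(self.peak_weights) != len(self.peak_centers):
            raise ValidationError("peak_weights and peak_centers must match")
        if abs(sum(self.peak_weights) - 1.0) > 1e-9:
            raise ValidationError("peak_weights must sum to 1")
        if self.lambda_len < 0 or self.lambda_gc < 0:
            raise ValidationError("survival rates must be non-negative")

    def survival(
        self, lengths: np.ndarray, gc: np.ndarray,
        lambda_len: float | None = None, lambda_gc: float | None = None,
    ) -> np.ndarray:
        ll = self.lambda_len if lambda_len is None else lambda_len
        lg = self.lambda_gc if lambda_gc is None else lambda_gc
        excess = np.maximum(0.0, np.asarray(lengths, dtype=float) - self.len_knee)
        return np.exp(-(ll * excess + lg * np.asarray(gc, dtype=float)))


_CHEMISTRY_PRESETS = {
    "WGS": ChemistryModel(name="WGS"),
    "WGES": ChemistryModel(
        name="WGES",
        lambda_len=0.0005,
        lambda_gc=0.3,
        sample_jitter_sd=0.1,
        overdispersion_sd=0.05,
    ),
    "WGBS": ChemistryModel(
        name="WGBS",
        lambda_len=0.01,
        lambda_gc=1.5,
        sample_jitter_sd=0.5,
        overdispersion_sd=0.5,
    ),
}


def chemistry_model(chemistry: str | ChemistryModel) -> ChemistryModel:
    """Preset lookup: WGS (lossless), WGES (near-lossless enzymatic),
    WGBS (bisulfite, length- and GC-dependent loss with per-sample jitter)."""
    if isinstance(chemistry, ChemistryModel):
        return chemistry
    try:
        return _CHEMISTRY_PRESETS[chemistry]
    except KeyError:
        raise ValidationError(
            f"unknown chemistry {chemistry!r}; presets: {sorted(_CHEMISTRY_PRESETS)}"
        ) from None


@dataclass(frozen=True)
class SyntheticGenome:
    """Single-chromosome synthetic target region with per-bin fragment
    emission weights and GC fractions.

    Baseline weights are positively coupled to GC (log-linear), emulating
    the empirically GC-increasing coverage of untreated cfDNA libraries;
    conversion chemistry then modulates it.
    """

    region: GenomicRegion
    bin_width: int
    weights: np.ndarray
    gc: np.ndarray

    def __post_init__(self) -> None:
        n = math.ceil(len(self.region) / self.bin_width)
        if len(self.weights) != n or len(self.gc) != n:
            raise ValidationError("weights/gc length must equal the bin count")
        if (self.weights <= 0).any():
            raise ValidationError("bin weights must be strictly positive")
        if ((self.gc < 0) | (self.gc > 1)).any():
            raise ValidationError("GC fractions must lie in [0, 1]")

    @property
    def n_bins(self) -> int:
        return len(self.weights)

    @property
    def bin_starts(self) -> np.ndarray:
        return self.region.start + self.bin_width * np.arange(self.n_bins)

    def bin_sizes(self) -> np.ndarray:
        sizes = np.full(self.n_bins, self.bin_width, dtype=np.int64)
        sizes[-1] = self.region.end - self.bin_starts[-1]
        return sizes


def build_genome(
    region: GenomicRegion,
    bin_width: int = 5000,
    gc_period_bp: float = 1_000_000.0,
    gc_noise_sd: float = 0.01,
    gc_weight_coupling: float = 2.0,
    weight_noise_sd: float = 0.2,
    seed: int = 0,
) -> SyntheticGenome:
    """Deterministic synthetic genome given a seed.

    The GC track is a smooth sinusoid (period ``gc_period_bp``, amplitude
    0.26 around 0.40) with small Gaussian roughness, spanning [0.15, 0.65]
    and beyond so every 5% GC gate between 15% and 65% is populated.
    Baseline weights are ``exp(coupling * (gc - mean_gc) + noise)``.
    """
    if bin_width < 150:
        raise ValidationError("bin_width must be at least 150 bp")
    if len(region) < bin_width:
        raise ValidationError("region shorter than one bin")
    rng = np.random.default_rng(seed)
    n = math.ceil(len(region) / bin_width)
    centers = region.start + bin_width * (np.arange(n) + 0.5)
    gc = 0.40 + 0.26 * np.sin(2 * np.pi * centers / gc_period_bp)
    gc = np.clip(gc + rng.normal(0.0, gc_noise_sd, n), 0.05, 0.95)
    log_w = gc_weight_coupling * (gc - gc.mean()) + rng.normal(0.0, weight_noise_sd, n)
    weights = np.exp(log_w)
    return SyntheticGenome(region=region, bin_width=bin_width, weights=weights, gc=gc)


@dataclass(frozen=True)
class SampleSpec:
    """Generation parameters for one synthetic sample."""

    label: str
    tumor_fraction: float
    chemistry: str | ChemistryModel
    n_fragments: int
    seed: int
    cnv_bins: tuple[int, ...] = ()
    cnv_copy_ratio: float = 3.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.tumor_fraction <= 1.0:
            raise ValidationError("tumor_fraction must lie in [0, 1]")
        if self.label == "control" and self.tumor_fraction != 0.0:
            raise ValidationError("control samples must have tumor_fraction 0")
        if self.cnv_copy_ratio <= 0:
            raise ValidationError("cnv_copy_ratio must be positive")
        if self.n_fragments <= 0:
            raise ValidationError("n_fragments must be positive")


def copy_number_factor(spec: SampleSpec, n_bins: int) -> np.ndarray:
    """Per-bin expected-count scaling from the copy-number alteration:
    ``(1 - tf) + tf * ratio`` in CNV bins, 1 elsewhere."""
    cn = np.ones(n_bins)
    if spec.cnv_bins:
        idx = np.asarray(spec.cnv_bins, dtype=np.int64)
        if (idx < 0).any() or (idx >= n_bins).any():
            raise ValidationError("cnv_bins outside the genome")
        cn[idx] = (1.0 - spec.tumor_fraction) + spec.tumor_fraction * spec.cnv_copy_ratio
    return cn


def simulate_fragment_arrays(
    genome: SyntheticGenome, spec: SampleSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate one sample; returns (starts, ends) arrays of length
    ``spec.n_fragments``, deterministic given ``spec.seed``.

    Rejection sampling: candidates draw a bin (propensity weight x copy
    number), a length from the chemistry mixture (tumor component shifted),
    a uniform position within the bin, and survive conversion with
    probability ``survival(length, gc_bin)``; draws repeat until enough
    fragments are retained.
    """
    chem = chemistry_model(spec.chemistry)
    rng = np.random.default_rng(spec.seed)
    n_bins = genome.n_bins
    cn = copy_number_factor(spec, n_bins)
    p_bin = genome.weights * cn

    # per-sample chemistry jitter (batch variability of conversion)
    if chem.sample_jitter_sd > 0:
        ll = chem.lambda_len * float(np.exp(rng.normal(0.0, chem.sample_jitter_sd)))
        lg = chem.lambda_gc * float(np.exp(rng.normal(0.0, chem.sample_jitter_sd)))
    else:
        ll, lg = chem.lambda_len, chem.lambda_gc
    # locus-level degradation variability: overdispersed coverage, iid per
    # (sample, bin) — the high-rank noise component of harsh conversion
    if chem.overdispersion_sd > 0:
        p_bin = p_bin * np.exp(rng.normal(0.0, chem.overdispersion_sd, n_bins))
    p_bin = p_bin / p_bin.sum()

    # mean survival over the length mixture, per bin, to detect degeneracy
    probe_len = np.array(chem.peak_centers)
    mean_surv = (
        chem.survival(probe_len[:, None], genome.gc[None, :], ll, lg)
        * np.asarray(chem.peak_weights)[:, None]
    ).sum(axis=0)
    if float((p_bin * mean_surv).sum()) < 1e-12:
        raise ValidationError("degenerate chemistry: survival ~ 0 over the genome")

    bin_starts = genome.bin_starts
    bin_sizes = genome.bin_sizes()
    starts_out: list[np.ndarray] = []
    ends_out: list[np.ndarray] = []
    remaining = spec.n_fragments
    acc_rate = max(float((p_bin * mean_surv).sum()), 1e-6)
    peak_w = np.asarray(chem.peak_weights)
    centers = np.asarray(chem.peak_centers)
    while remaining > 0:
        m = int(min(4_000_000, max(1000, remaining / acc_rate * 1.2)))
        bins = rng.choice(n_bins, size=m, p=p_bin)
        tumor = rng.random(m) < spec.tumor_fraction
        peaks = rng.choice(len(centers), size=m, p=peak_w)
        lengths = rng.normal(centers[peaks], chem.peak_sd)
        lengths = lengths + np.where(tumor, chem.tumor_length_shift, 0.0)
        lengths = np.maximum(50, np.rint(lengths)).astype(np.int64)
        surv = chem.survival(lengths, genome.gc[bins], ll, lg)
        keep = rng.random(m) < surv
        bins, lengths = bins[keep], lengths[keep]
        if bins.size == 0:
            continue
        offs = rng.integers(0, bin_sizes[bins])
        starts = bin_starts[bins] + offs
        # keep fragments inside the genome region
        starts = np.minimum(starts, genome.region.end - lengths)
        starts = np.maximum(starts, genome.region.start)
        take = min(remaining, bins.size)
        starts_out.append(starts[:take])
        ends_out.append(starts[:take] + lengths[:take])
        remaining -= take
    return np.concatenate(starts_out), np.concatenate(ends_out)


def simulate_sample(genome: SyntheticGenome, spec: SampleSpec) -> list[FragmentRecord]:
    """Simulate one sample as an ordered list of fragment records."""
    starts, ends = simulate_fragment_arrays(genome, spec)
    chrom = genome.region.chrom
    return [FragmentRecord(chrom, int(s), int(e)) for s, e in zip(starts, ends)]


#: Stage-relative tumor-fraction multipliers: circulating tumor DNA burden
#: rises steeply with clinical stage, so the per-sample tumor fraction is
#: the cohort's reference ``tumor_fraction`` scaled by its stage.
DEFAULT_STAGE_TF_MULTIPLIER = {
    "0": 0.2,
    "I": 0.45,
    "IIA": 0.75,
    "III": 1.25,
    "IIIA": 1.25,
    "IIIB": 1.5,
    "IV": 2.0,
}


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions for a simulated cohort.

    Defaults mirror the reference study design: 24 cancer + 24 control
    training samples, 12 + 12 held-out test samples, single conversion
    chemistry, a contiguous CNV block, and a stage-graded tumor fraction
    (``tumor_fraction`` is the stage-III reference; earlier stages carry
    proportionally less circulating tumor DNA).
    """

    n_train_cancer: int = 24
    n_train_control: int = 24
    n_test_cancer: int = 12
    n_test_control: int = 12
    chemistry: str | ChemistryModel = "WGES"
    tumor_fraction: float = 0.2
    cnv_copy_ratio: float = 3.0
    cnv_bins: tuple[int, ...] = ()
    n_fragments: int = 50_000
    stages_train: tuple[str, ...] = tuple(_TRAIN_STAGES)
    stages_test: tuple[str, ...] = tuple(_TEST_STAGES)
    locations: tuple[str, ...] = tuple(_LOCATIONS)
    stage_tf_multiplier: dict[str, float] | None = None

    def sample_tumor_fraction(self, stage: str) -> float:
        mult = self.stage_tf_multiplier or DEFAULT_STAGE_TF_MULTIPLIER
        return float(min(1.0, self.tumor_fraction * mult.get(stage, 1.0)))

    def __post_init__(self) -> None:
        for n in (
            self.n_train_cancer,
            self.n_train_control,
            self.n_test_cancer,
            self.n_test_control,
        ):
            if n <= 0:
                raise ValidationError("every split/class needs at least one sample")


def default_cnv_bins(genome: SyntheticGenome, fraction: float = 0.05, start_frac: float = 0.3) -> tuple[int, ...]:
    """A contiguous CNV block covering ``fraction`` of the genome's bins."""
    n = max(1, int(genome.n_bins * fraction))
    lo = int(genome.n_bins * start_frac)
    return tuple(range(lo, min(lo + n, genome.n_bins)))


def simulate_cohort(
    genome: SyntheticGenome,
    outdir: str | Path,
    cohort: CohortSpec = CohortSpec(),
    seed: int = 0,
) -> tuple[CohortManifest, Path]:
    """Simulate a cohort to disk: one BED per sample plus ``manifest.tsv``.

    Stages and locations are assigned to cancer samples by deterministic
    round-robin over the configured composition lists, so per-stage and
    per-location reporting is exercisable and output is byte-identical for
    a given seed. Returns the manifest and the manifest path.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chem = chemistry_model(cohort.chemistry)
    cnv_bins = cohort.cnv_bins or default_cnv_bins(genome)
    ss = np.random.SeedSequence(seed)
    sample_seeds = [int(s) for s in ss.generate_state(
        2 * (cohort.n_train_cancer + cohort.n_train_control
             + cohort.n_test_cancer + cohort.n_test_control)
    ) >> np.uint32(1)]
    seed_iter = iter(sample_seeds)

    samples: list[SampleMeta] = []
    plan = [
        ("train", "cancer", cohort.n_train_cancer, cohort.stages_train),
        ("train", "control", cohort.n_train_control, None),
        ("test", "cancer", cohort.n_test_cancer, cohort.stages_test),
        ("test", "control", cohort.n_test_control, None),
    ]
    for split, label, n, stages in plan:
        for i in range(n):
            sid = f"{split}_{label}_{i:03d}"
            stage = stages[i % len(stages)] if stages else "NA"
            location = cohort.locations[i % len(cohort.locations)] if label == "cancer" else "NA"
            tf = cohort.sample_tumor_fraction(stage) if label == "cancer" else 0.0
            spec = SampleSpec(
                label=label,
                tumor_fraction=tf,
                chemistry=chem,
                n_fragments=cohort.n_fragments,
                seed=next(seed_iter),
                cnv_bins=cnv_bins if label == "cancer" else (),
                cnv_copy_ratio=cohort.cnv_copy_ratio,
            )
            starts, ends = simulate_fragment_arrays(genome, spec)
            bed = outdir / f"{sid}.bed"
            with open(bed, "w", encoding="utf-8", newline="") as fh:
                chromname = genome.region.chrom
                fh.write(
                    "".join(
                        f"{chromname}\t{s}\t{e}\n" for s, e in zip(starts, ends)
                    )
                )
            samples.append(
                SampleMeta(
                    sample_id=sid,
                    label=label,
                    stage=stage,
                    location=location,
                    chemistry=chem.name,
                    split=split,
                    fragments_path=bed.name,
                )
            )
    manifest = CohortManifest(samples)
    manifest_path = write_manifest(manifest, outdir / "manifest.tsv")
    return manifest, manifest_path
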
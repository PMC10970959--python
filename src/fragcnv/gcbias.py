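"""Conversion-chemistry GC bias: coverage-vs-GC regression over
GC-stratified 150 bp windows.

Bisulfite conversion preferentially degrades unmethylated-cytosine-rich
fragments, depleting GC-rich windows; enzymatic conversion does not. The
quantification: tile the target region into fixed-width (150 bp) windows,
compute each window's GC fraction, draw a random GC-stratified subset
(equal allocation across 5%-wide GC gates spanning 15-65%), count fragment
midpoints per window, and regress coverage on GC by ordinary least
squares. Both the slope and the Pearson correlation are reported; a lower
correlation under bisulfite chemistry is the depletion signature.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import Iterable

import numpy as np
from scipy import stats

from .core import FragmentRecord, GenomicRegion, ValidationError
from .simulate import SyntheticGenome

logger = logging.getLogger(__name__)

GC_GATE_LO = 0.15
GC_GATE_HI = 0.65
GC_GATE_STEP = 0.05
DEFAULT_WINDOW_WIDTH = 150
DEFAULT_N_TOTAL = 3000


@dataclass(frozen=True)
class GcWindowSet:
    """Non-overlapping fixed-width windows with per-window GC fractions."""

    chrom: str
    starts: np.ndarray
    width: int
    gc: np.ndarray

    def __post_init__(self) -> None:
        if len(self.starts) != len(self.gc):
            raise ValidationError("starts and gc must have equal length")
        if ((self.gc < 0) | (self.gc > 1)).any():
            raise ValidationError("GC fractions must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.starts)

    def take(self, idx: np.ndarray) -> "GcWindowSet":
        return GcWindowSet(self.chrom, self.starts[idx], self.width, self.gc[idx])

    def regions(self) -> list[GenomicRegion]:
        return [
            GenomicRegion(self.chrom, int(s), int(s) + self.width) for s in self.starts
        ]


def gc_gate_index(
    gc: np.ndarray,
    lo: float = GC_GATE_LO,
    hi: float = GC_GATE_HI,
    step: float = GC_GATE_STEP,
) -> np.ndarray:
    """Gate index 0..9 for each GC fraction; -1 outside [lo, hi)."""
    gc = np.asarray(gc, dtype=float)
    idx = np.floor((gc - lo) / step + 1e-12).astype(int)
    n_gates = int(round((hi - lo) / step))
    idx[(gc < lo) | (gc >= hi)] = -1
    idx[idx >= n_gates] = -1
    return idx


def _gc_from_sequence(seq: str) -> float | None:
    up = seq.upper()
    gc = up.count("G") + up.count("C")
    at = up.count("A") + up.count("T")
    denom = gc + at  # ambiguous bases excluded from numerator and denominator
    if denom == 0:
        return None
    return gc / denom


def gc_windows(
    source,
    region: GenomicRegion,
    width: int = DEFAULT_WINDOW_WIDTH,
) -> GcWindowSet:
    """Tile ``region`` into ``width``-bp windows with GC fractions.

    ``source`` is either a FASTA path / ``pyfaidx.Fasta`` (GC computed from
    sequence, ambiguous bases excluded; all-ambiguous windows dropped) or a
    :class:`~fragcnv.simulate.SyntheticGenome` (GC interpolated from its
    per-bin track to the window midpoints). The trailing partial window is
    dropped so all windows share the same width.
    """
    if width <= 0:
        raise ValidationError("window width must be positive")
    n = (len(region) // width)
    if n == 0:
        raise ValidationError("region shorter than one window")
    starts = region.start + width * np.arange(n, dtype=np.int64)

    if isinstance(source, SyntheticGenome):
        if source.region.chrom != region.chrom:
            raise ValidationError("region chromosome does not match genome")
        mids = starts + width / 2.0
        bin_centers = source.bin_starts + source.bin_width / 2.0
        gc = np.interp(mids, bin_centers, source.gc)
        return GcWindowSet(region.chrom, starts, width, gc)

    fasta = _as_fasta(source)
    seq = str(fasta[region.chrom][region.start : region.start + n * width])
    gc_vals = []
    keep = []
    for i in range(n):
        g = _gc_from_sequence(seq[i * width : (i + 1) * width])
        if g is None:
            logger.info("dropping all-ambiguous window at %s:%d", region.chrom, starts[i])
            continue
        keep.append(i)
        gc_vals.append(g)
    return GcWindowSet(region.chrom, starts[keep], width, np.array(gc_vals))


def _as_fasta(source):
    import pyfaidx

    if isinstance(source, (str, bytes)) or hasattr(source, "__fspath__"):
        return pyfaidx.Fasta(str(source))
    return source


def stratified_sample(
    windows: GcWindowSet,
    n_total: int = DEFAULT_N_TOTAL,
    seed: int = 0,
    lo: float = GC_GATE_LO,
    hi: float = GC_GATE_HI,
    step: float = GC_GATE_STEP,
    per_gate: int | None = None,
    strict: bool = True,
) -> GcWindowSet:
    """Random GC-stratified subset, without replacement, deterministic in
    ``seed``.

    Allocation: ``per_gate`` windows from every gate if given; otherwise
    ``n_total`` split equally across the gates with the remainder going to
    the lowest-GC gates. With ``strict`` a gate that cannot fill its
    allocation raises; otherwise it contributes what it has.
    """
    n_gates = int(round((hi - lo) / step))
    gates = gc_gate_index(windows.gc, lo, hi, step)
    if per_gate is not None:
        alloc = np.full(n_gates, per_gate)
    else:
        base, rem = divmod(n_total, n_gates)
        alloc = np.full(n_gates, base)
        alloc[:rem] += 1
    rng = np.random.default_rng(seed)
    chosen: list[np.ndarray] = []
    for g in range(n_gates):
        pool = np.flatnonzero(gates == g)
        want = int(alloc[g])
        if pool.size < want:
            gate_lo, gate_hi = lo + g * step, lo + (g + 1) * step
            if strict:
                raise ValidationError(
                    f"GC gate [{gate_lo:.2f}, {gate_hi:.2f}) has {pool.size} "
                    f"windows, {want} requested"
                )
            want = pool.size
        if want:
            chosen.append(rng.choice(pool, size=want, replace=False))
    idx = np.sort(np.concatenate(chosen)) if chosen else np.array([], dtype=int)
    return windows.take(idx)


@dataclass(frozen=True)
class GcRegressionResult:
    slope: float
    intercept: float
    pearson_r: float
    n_windows: int

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(
            {
                "slope": self.slope,
                "intercept": self.intercept,
                "pearson_r": self.pearson_r,
                "n_windows": self.n_windows,
            },
            indent=indent,
        )


def window_coverage(
    fragments: Iterable[FragmentRecord] | tuple[np.ndarray, np.ndarray, np.ndarray],
    windows: GcWindowSet,
) -> np.ndarray:
    """Per-window coverage: count of fragments whose midpoint lies in the
    window. Windows may be a sparse subset; they must be sorted and
    non-overlapping (guaranteed by construction)."""
    if isinstance(fragments, tuple):
        chroms, starts, ends = fragments
    else:
        recs = list(fragments)
        chroms = np.array([f.chrom for f in recs])
        starts = np.array([f.start for f in recs], dtype=np.int64)
        ends = np.array([f.end for f in recs], dtype=np.int64)
    mids = (starts + ends) // 2
    on_chrom = chroms == windows.chrom
    mids = mids[on_chrom]
    ws = windows.starts
    pos = np.searchsorted(ws, mids, side="right") - 1
    valid = (pos >= 0) & (mids < ws[np.clip(pos, 0, None)] + windows.width)
    return np.bincount(pos[valid], minlength=len(ws))


def coverage_vs_gc(
    fragments: Iterable[FragmentRecord] | tuple[np.ndarray, np.ndarray, np.ndarray],
    windows: GcWindowSet,
    coverage: np.ndarray | None = None,
) -> GcRegressionResult:
    """OLS of per-window fragment coverage on GC fraction.

    Returns slope (coverage units per unit GC fraction), intercept, and
    Pearson r. ``coverage`` may be supplied directly to regress
    pre-computed values.
    """
    if len(windows) < 3:
        raise ValidationError("need at least 3 windows")
    if coverage is None:
        coverage = window_coverage(fragments, windows)
    coverage = np.asarray(coverage, dtype=float)
    if np.ptp(windows.gc) == 0:
        raise ValidationError("degenerate design: zero-variance GC in subset")
    fit = stats.linregress(windows.gc, coverage)
    return GcRegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        pearson_r=float(fit.rvalue),
        n_windows=len(windows),
    )
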
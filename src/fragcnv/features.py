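"""Uniform-window binning and the samples x bins fragment-count matrix.

The target region (by default the long arm of chromosome 18, the arm
recurrently lost in colorectal cancer) is tiled into uniform windows; in
each window the short and medium mono-nucleosomal fragment sub-populations
are counted per sample. Regional copy-number change in the tumor-derived
cfDNA fraction shifts these counts, so the matrix carries both coverage
(CNV) and fragment-size signal.

A fragment is assigned to the bin containing its midpoint and to the size
class containing its length; everything else is excluded (and tallied).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

from .core import CohortManifest, FragmentRecord, GenomicRegion, ValidationError, resolve_fragments_path
from .io import read_fragment_arrays

logger = logging.getLogger(__name__)

NORMALIZATIONS = ("cpm", "raw")
LAYOUTS = ("combined", "separate", "ratio")


@dataclass(frozen=True)
class SizeClassScheme:
    """Inclusive bp ranges for the short and medium fragment classes.

    Defaults (100-150 and 151-220 bp inserts) follow the fragmentomics
    convention of splitting the mono-nucleosomal population into its
    shortened, tumor-enriched tail and the nucleosome-core mode.
    """

    short: tuple[int, int] = (100, 150)
    medium: tuple[int, int] = (151, 220)

    def __post_init__(self) -> None:
        if not (self.short[0] <= self.short[1] < self.medium[0] <= self.medium[1]):
            raise ValidationError(
                "size classes must be ordered and disjoint: short.hi < medium.lo"
            )


@dataclass(frozen=True)
class BinSet:
    """Uniform left-to-right tiling of a region; the last bin may be short."""

    region: GenomicRegion
    bin_width: int

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValidationError(f"non-positive bin width {self.bin_width}")

    @property
    def n_bins(self) -> int:
        return math.ceil(len(self.region) / self.bin_width)

    @property
    def bins(self) -> list[GenomicRegion]:
        r, w = self.region, self.bin_width
        return [
            GenomicRegion(r.chrom, r.start + i * w, min(r.start + (i + 1) * w, r.end))
            for i in range(self.n_bins)
        ]

    def feature_ids(self, suffix: str = "") -> list[str]:
        return [f"{b.chrom}:{b.start}-{b.end}{suffix}" for b in self.bins]

    def bin_index(self, positions: np.ndarray) -> np.ndarray:
        """Bin index for each position; -1 when outside the region."""
        positions = np.asarray(positions, dtype=np.int64)
        idx = (positions - self.region.start) // self.bin_width
        idx[(positions < self.region.start) | (positions >= self.region.end)] = -1
        return idx


def make_bins(region: GenomicRegion, bin_width: int) -> BinSet:
    """Tile ``region`` into uniform ``bin_width`` windows."""
    return BinSet(region=region, bin_width=bin_width)


class ClassCounts(NamedTuple):
    short: np.ndarray
    medium: np.ndarray
    n_out_of_region: int
    n_out_of_class: int

    @property
    def combined(self) -> np.ndarray:
        return self.short + self.medium


def _fragment_arrays(
    fragments: Iterable[FragmentRecord] | tuple[np.ndarray, np.ndarray, np.ndarray],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if isinstance(fragments, tuple):
        return fragments
    recs = list(fragments)
    chroms = np.array([f.chrom for f in recs])
    starts = np.array([f.start for f in recs], dtype=np.int64)
    ends = np.array([f.end for f in recs], dtype=np.int64)
    return chroms, starts, ends


def count_by_class(
    fragments: Iterable[FragmentRecord] | tuple[np.ndarray, np.ndarray, np.ndarray],
    bins: BinSet,
    classes: SizeClassScheme = SizeClassScheme(),
) -> ClassCounts:
    """Per-bin short and medium fragment counts.

    Each fragment contributes to the bin containing its midpoint
    ``(start + end) // 2`` and to the size class containing its length;
    fragments on another chromosome, outside the region, or outside both
    classes contribute nothing (excluded counts are returned and logged).
    """
    chroms, starts, ends = _fragment_arrays(fragments)
    on_chrom = chroms == bins.region.chrom
    lengths = ends - starts
    mids = (starts + ends) // 2
    idx = bins.bin_index(mids)
    in_region = on_chrom & (idx >= 0)

    is_short = (lengths >= classes.short[0]) & (lengths <= classes.short[1])
    is_medium = (lengths >= classes.medium[0]) & (lengths <= classes.medium[1])
    in_class = is_short | is_medium

    n_out_of_region = int((~in_region).sum())
    n_out_of_class = int((in_region & ~in_class).sum())
    if n_out_of_region or n_out_of_class:
        logger.debug(
            "excluded %d out-of-region and %d out-of-class fragments",
            n_out_of_region,
            n_out_of_class,
        )

    short = np.bincount(idx[in_region & is_short], minlength=bins.n_bins)
    medium = np.bincount(idx[in_region & is_medium], minlength=bins.n_bins)
    return ClassCounts(short, medium, n_out_of_region, n_out_of_class)


def _layout_values(counts: ClassCounts, layout: str) -> np.ndarray:
    if layout == "combined":
        return counts.combined.astype(float)
    if layout == "separate":
        return np.concatenate([counts.short, counts.medium]).astype(float)
    if layout == "ratio":
        # add-one smoothing so empty bins stay finite
        return (counts.short + 1.0) / (counts.medium + 1.0)
    raise ValidationError(f"unknown layout {layout!r}; choose from {LAYOUTS}")


def build_feature_matrix(
    manifest: CohortManifest,
    bins: BinSet,
    classes: SizeClassScheme = SizeClassScheme(),
    normalization: str = "cpm",
    layout: str = "combined",
    manifest_dir: str | Path | None = None,
) -> pd.DataFrame:
    """Samples x features matrix of size-class fragment counts.

    Default features are short+medium counts per bin, normalized to
    counts-per-million in-region class-qualifying fragments per sample
    (CPM) so samples are comparable at unequal depth. Layouts: ``combined``
    (one column per bin), ``separate`` (short and medium columns), or
    ``ratio`` (short/medium per bin, add-one smoothed; never CPM-scaled).
    """
    if normalization not in NORMALIZATIONS:
        raise ValidationError(
            f"unknown normalization {normalization!r}; choose from {NORMALIZATIONS}"
        )
    rows = []
    for s in manifest:
        path = resolve_fragments_path(s, manifest_dir)
        if not path.exists():
            raise ValidationError(
                f"fragment file for sample {s.sample_id!r} not found: {path}"
            )
        counts = count_by_class(read_fragment_arrays(path), bins, classes)
        total = int(counts.combined.sum())
        if total == 0:
            raise ValidationError(
                f"sample {s.sample_id!r} has zero in-region class-qualifying fragments"
            )
        values = _layout_values(counts, layout)
        if normalization == "cpm" and layout != "ratio":
            values = values * (1e6 / total)
        rows.append(values)

    if layout == "separate":
        columns = bins.feature_ids(":short") + bins.feature_ids(":medium")
    else:
        columns = bins.feature_ids()
    matrix = pd.DataFrame(rows, index=manifest.sample_ids(), columns=columns)
    matrix.index.name = "sample_id"
    matrix.attrs["normalization"] = normalization
    matrix.attrs["layout"] = layout
    return matrix
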
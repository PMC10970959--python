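"""Readers and writers for fragment BED files and cohort manifest TSVs.

Fragments travel as BED3 (tab-separated, no header, UTF-8); extra columns
are ignored on read. Manifests are TSV with a header row.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import CohortManifest, FragmentRecord, SampleMeta, ValidationError

MANIFEST_COLUMNS = (
    "sample_id",
    "label",
    "stage",
    "location",
    "chemistry",
    "split",
    "fragments_path",
)


class BedParseError(ValueError):
    """A BED line could not be parsed; the message names the line number."""


def read_fragment_arrays(path: str | Path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Read a BED3+ file into (chroms, starts, ends) arrays.

    Fast path used by counting code; :func:`read_fragments` wraps it into
    records. Order is preserved.
    """
    path = Path(path)
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            usecols=[0, 1, 2],
            names=["chrom", "start", "end"],
            dtype={"chrom": str},
            comment=None,
        )
    except pd.errors.EmptyDataError:
        return np.array([], dtype=str), np.array([], dtype=np.int64), np.array([], dtype=np.int64)
    except ValueError as exc:
        raise BedParseError(f"{path}: malformed BED ({exc})") from exc

    for col in ("start", "end"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna().to_numpy() | (coerced.to_numpy(dtype=float) % 1 != 0)
        if bad.any():
            line = int(np.flatnonzero(bad)[0]) + 1
            raise BedParseError(f"{path}: non-integer {col} at line {line}")
        df[col] = coerced.astype(np.int64)

    starts = df["start"].to_numpy()
    ends = df["end"].to_numpy()
    if (starts < 0).any():
        line = int(np.flatnonzero(starts < 0)[0]) + 1
        raise BedParseError(f"{path}: negative start at line {line}")
    if (ends <= starts).any():
        line = int(np.flatnonzero(ends <= starts)[0]) + 1
        raise BedParseError(f"{path}: end <= start at line {line}")
    return df["chrom"].to_numpy(), starts, ends


def read_fragments(path: str | Path) -> list[FragmentRecord]:
    """Read a BED3+ file into an ordered list of :class:`FragmentRecord`."""
    chroms, starts, ends = read_fragment_arrays(path)
    return [
        FragmentRecord(c, int(s), int(e)) for c, s, e in zip(chroms, starts, ends)
    ]


def write_fragments(records: Iterable[FragmentRecord], path: str | Path) -> Path:
    """Write fragments as BED3. Round-trips with :func:`read_fragments`."""
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for rec in records:
            fh.write(f"{rec.chrom}\t{rec.start}\t{rec.end}\n")
    return path


def read_manifest(path: str | Path) -> CohortManifest:
    """Read and validate a cohort manifest TSV.

    Relative ``fragments_path`` entries are kept as written; resolve them
    against the manifest's directory with
    :func:`fragcnv.core.resolve_fragments_path`.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: manifest missing column(s) {missing}")
    samples = [
        SampleMeta(
            sample_id=row.sample_id,
            label=row.label,
            stage=row.stage,
            location=row.location,
            chemistry=row.chemistry,
            split=row.split,
            fragments_path=row.fragments_path,
        )
        for row in df.itertuples()
    ]
    return CohortManifest(samples)


def write_manifest(manifest: CohortManifest, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(MANIFEST_COLUMNS)
        for s in manifest:
            writer.writerow(
                [s.sample_id, s.label, s.stage, s.location, s.chemistry, s.split, s.fragments_path]
            )
    return path


def write_feature_matrix(matrix: pd.DataFrame, path: str | Path) -> Path:
    """Persist a samples x features matrix as TSV (index = sample ids)."""
    path = Path(path)
    matrix.to_csv(path, sep="\t", index_label="sample_id")
    return path


def read_feature_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample_id")


def write_regions_bed(regions: Sequence, path: str | Path, scores: Sequence | None = None) -> Path:
    """Write GenomicRegions (optionally with a 4th column) as BED."""
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for i, r in enumerate(regions):
            extra = f"\t{scores[i]}" if scores is not None else ""
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}{extra}\n")
    return path
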
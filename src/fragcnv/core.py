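"""Core domain types: fragments, genomic regions, cohort samples.

Coordinates are 0-based half-open (BED convention) throughout. Strand is
ignored: cfDNA fragment counting is strand-agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

LABELS = ("cancer", "control")
STAGES = ("0", "I", "IIA", "III", "IIIA", "IIIB", "IV", "NA")
CHEMISTRIES = ("WGES", "WGBS", "WGS")
SPLITS = ("train", "test")


class ValidationError(ValueError):
    """A domain invariant was violated."""


@dataclass(frozen=True, slots=True)
class FragmentRecord:
    """One aligned, deduplicated cfDNA fragment.

    The fragment is the unit of all downstream counting; its length is the
    aligned insert length ``end - start`` (not the adapter-ligated library
    molecule length — see :mod:`fragcnv.gates` for the offset between the
    two axes).
    """

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValidationError(f"negative start {self.start}")
        if self.end <= self.start:
            raise ValidationError(
                f"end <= start for fragment {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True, slots=True)
class GenomicRegion:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValidationError(
                f"end <= start for region {self.chrom}:{self.start}-{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start


#: Long arm of chromosome 18 on an hg38-like build. The genome build is a
#: named preset, not a constant of the method; override freely.
CHR18Q = GenomicRegion("chr18", 18_500_000, 80_373_285)


@dataclass(slots=True)
class SampleMeta:
    """Per-sample cohort metadata plus the path to its fragment file."""

    sample_id: str
    label: str
    stage: str
    location: str
    chemistry: str
    split: str
    fragments_path: str

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValidationError(f"{self.sample_id}: unknown label {self.label!r}")
        if self.stage not in STAGES:
            raise ValidationError(f"{self.sample_id}: unknown stage {self.stage!r}")
        if self.chemistry not in CHEMISTRIES:
            raise ValidationError(
                f"{self.sample_id}: unknown chemistry {self.chemistry!r}"
            )
        if self.split not in SPLITS:
            raise ValidationError(f"{self.sample_id}: unknown split {self.split!r}")
        if self.label == "control" and self.stage != "NA":
            raise ValidationError(
                f"{self.sample_id}: control sample must have stage NA, "
                f"got {self.stage!r}"
            )


@dataclass(slots=True)
class CohortManifest:
    """An ordered collection of samples with unique ids."""

    samples: list[SampleMeta] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for s in self.samples:
            if s.sample_id in seen:
                raise ValidationError(f"duplicate sample_id {s.sample_id!r}")
            seen.add(s.sample_id)

    def __iter__(self) -> Iterator[SampleMeta]:
        return iter(self.samples)

    def __len__(self) -> int:
        return len(self.samples)

    def subset(self, split: str | None = None, label: str | None = None) -> "CohortManifest":
        picked = [
            s
            for s in self.samples
            if (split is None or s.split == split)
            and (label is None or s.label == label)
        ]
        return CohortManifest(picked)

    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def labels(self) -> list[str]:
        return [s.label for s in self.samples]

    def require_both_labels(self, split: str) -> None:
        """Any split used for fitting needs at least one sample per class."""
        sub = self.subset(split=split)
        have = {s.label for s in sub}
        missing = set(LABELS) - have
        if missing:
            raise ValidationError(
                f"split {split!r} lacks {sorted(missing)} samples"
            )


def resolve_fragments_path(meta: SampleMeta, manifest_dir: str | Path | None) -> Path:
    """Fragment paths in a manifest are taken relative to the manifest file."""
    p = Path(meta.fragments_path)
    if not p.is_absolute() and manifest_dir is not None:
        p = Path(manifest_dir) / p
    return p


def fragments_from_arrays(chrom: str, starts: Iterable[int], ends: Iterable[int]) -> list[FragmentRecord]:
    return [FragmentRecord(chrom, int(s), int(e)) for s, e in zip(starts, ends)]
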
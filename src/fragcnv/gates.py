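"""Nucleosome-wrapping size gates and paired chemistry comparison.

cfDNA fragment lengths ladder at multiples of the ~167 bp mono-nucleosome
unit. Four half-open gates capture fragments wrapped around 1, 2, 3, or
more nucleosomes. The canonical gate boundaries (100-400, 400-585,
585-825, 825-5500 bp) are expressed on the adapter-ligated library-molecule
axis as output by capillary electrophoresis; ``adapter_offset`` converts an
aligned insert length onto that axis (insert + offset) before lookup, so
the same scheme serves both electropherogram exports and sequencing-derived
fragments.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import FragmentRecord, ValidationError

#: Library-size gate boundaries in bp: [100,400), [400,585), [585,825), [825,5500).
DEFAULT_BOUNDARIES = (100, 400, 585, 825, 5500)

#: Typical total adapter + index length added per library molecule; preset
#: for emulating electropherogram gates on aligned insert sizes.
ELECTROPHEROGRAM_OFFSET = 130

N_GATES = 4


@dataclass(frozen=True, slots=True)
class GateScheme:
    """Four half-open size gates, lower bound inclusive, upper exclusive."""

    boundaries: tuple[int, ...] = DEFAULT_BOUNDARIES
    adapter_offset: int = 0

    def __post_init__(self) -> None:
        if len(self.boundaries) != N_GATES + 1:
            raise ValidationError(
                f"need {N_GATES + 1} boundaries for {N_GATES} gates, "
                f"got {len(self.boundaries)}"
            )
        if any(b >= a for b, a in zip(self.boundaries, self.boundaries[1:])):
            raise ValidationError("gate boundaries must be strictly increasing")


@dataclass(frozen=True, slots=True)
class GateProfile:
    """Per-sample percentage of fragments in each gate.

    Percentages are relative to all fragments considered, so fragments
    outside every gate make the four percentages sum to less than 100 —
    matching Fragment Analyzer percentage exports.
    """

    sample_id: str
    pct: tuple[float, float, float, float]
    n_total: int

    def __post_init__(self) -> None:
        if any(p < 0 or p > 100 for p in self.pct):
            raise ValidationError("gate percentages must lie in [0, 100]")
        if sum(self.pct) > 100.0 + 1e-9:
            raise ValidationError("gate percentages sum above 100")


def assign_gate(length: int, scheme: GateScheme = GateScheme()) -> int | None:
    """Gate index in 1..4 for a fragment length, or None if out of range.

    The insert length is shifted onto the library-size axis by
    ``adapter_offset`` and looked up in the half-open gates.
    """
    if length <= 0:
        raise ValidationError(f"non-positive fragment length {length}")
    adj = length + scheme.adapter_offset
    b = scheme.boundaries
    if adj < b[0] or adj >= b[-1]:
        return None
    return int(np.searchsorted(b, adj, side="right"))


def assign_gates(lengths: np.ndarray, scheme: GateScheme = GateScheme()) -> np.ndarray:
    """Vectorized gate lookup; 0 marks out-of-range lengths."""
    lengths = np.asarray(lengths)
    if (lengths <= 0).any():
        raise ValidationError("non-positive fragment length")
    adj = lengths + scheme.adapter_offset
    g = np.searchsorted(scheme.boundaries, adj, side="right")
    g[(g == 0) | (g == N_GATES + 1)] = 0
    return g


def _lengths(fragments: Iterable[FragmentRecord] | np.ndarray) -> np.ndarray:
    if isinstance(fragments, np.ndarray):
        return fragments
    return np.array([f.length for f in fragments], dtype=np.int64)


def gate_percentages(
    fragments: Iterable[FragmentRecord] | np.ndarray,
    scheme: GateScheme = GateScheme(),
    sample_id: str = "",
) -> GateProfile:
    """Percentage of fragments in each gate, relative to all fragments.

    ``fragments`` may be records or a plain array of lengths.
    """
    lengths = _lengths(fragments)
    if lengths.size == 0:
        raise ValidationError("no fragments")
    g = assign_gates(lengths, scheme)
    counts = np.bincount(g, minlength=N_GATES + 1)[1:]
    pct = tuple(100.0 * c / lengths.size for c in counts)
    return GateProfile(sample_id=sample_id, pct=pct, n_total=int(lengths.size))


def compare_paired_gates(
    profiles_a: Sequence[GateProfile], profiles_b: Sequence[GateProfile]
) -> pd.DataFrame:
    """Paired per-gate comparison of two chemistry arms, matched by sample.

    For each gate a two-sided Wilcoxon signed-rank test on the paired
    percentage differences (A - B); direction is the sign of the median
    difference. Returns a 4-row DataFrame (gate, median_diff, direction,
    statistic, pvalue).
    """
    ids_a = {p.sample_id for p in profiles_a}
    ids_b = {p.sample_id for p in profiles_b}
    if ids_a != ids_b:
        orphans = sorted(ids_a.symmetric_difference(ids_b))
        raise ValidationError(f"unmatched sample ids between arms: {orphans}")
    if len(profiles_a) < 6:
        raise ValidationError("need at least 6 matched pairs")
    by_id_b = {p.sample_id: p for p in profiles_b}
    rows = []
    for gate in range(N_GATES):
        diffs = np.array(
            [p.pct[gate] - by_id_b[p.sample_id].pct[gate] for p in profiles_a]
        )
        median = float(np.median(diffs))
        if np.allclose(diffs, 0):
            stat, p = float("nan"), 1.0
        else:
            stat, p = stats.wilcoxon(diffs, alternative="two-sided")
        rows.append(
            {
                "gate": gate + 1,
                "median_diff": median,
                "direction": int(np.sign(median)),
                "statistic": float(stat),
                "pvalue": float(p),
            }
        )
    return pd.DataFrame(rows)


def profiles_to_table(profiles: Sequence[GateProfile], scheme: GateScheme = GateScheme()) -> pd.DataFrame:
    """Long-format (Sample, Range, % Total) table of gate percentages."""
    b = scheme.boundaries
    rows = []
    for p in profiles:
        for g in range(N_GATES):
            rows.append(
                {
                    "Sample": p.sample_id,
                    "Range": f"{b[g]} bp to {b[g + 1]} bp",
                    "% Total": round(p.pct[g], 1),
                }
            )
    return pd.DataFrame(rows)
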
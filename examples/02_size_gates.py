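"""Size-gate profiles: bisulfite vs enzymatic conversion.

Simulates 8 matched sample pairs, expresses fragment lengths on the
library-molecule axis (adapter offset 130 bp), computes the percentage of
fragments in the four nucleosome-wrapping gates, and runs the paired
Wilcoxon signed-rank comparison per gate. A positive median difference in
gate 1 with negative differences in gates 2-4 is the signature of
bisulfite degradation of long fragments.
"""

from fragcnv import GateScheme, GenomicRegion, SampleSpec, build_genome, compare_paired_gates
from fragcnv.gates import ELECTROPHEROGRAM_OFFSET, gate_percentages
from fragcnv.simulate import simulate_fragment_arrays

genome = build_genome(GenomicRegion("chr18s", 0, 1_000_000), seed=1)
scheme = GateScheme(adapter_offset=ELECTROPHEROGRAM_OFFSET)

profiles = {}
for chem in ("WGBS", "WGES"):
    profiles[chem] = []
    for i in range(8):
        spec = SampleSpec(label="control", tumor_fraction=0.0, chemistry=chem,
                          n_fragments=50_000, seed=100 + i)
        s, e = simulate_fragment_arrays(genome, spec)
        profiles[chem].append(gate_percentages(e - s, scheme, sample_id=f"p{i}"))

print("mean gate percentages (library-size gates 100-400 / 400-585 / 585-825 / 825-5500 bp):")
for chem, ps in profiles.items():
    means = [sum(p.pct[g] for p in ps) / len(ps) for g in range(4)]
    print(f"  {chem}: " + "  ".join(f"{m:5.1f}%" for m in means))

print("\npaired Wilcoxon signed-rank, WGBS - WGES per gate:")
print(compare_paired_gates(profiles["WGBS"], profiles["WGES"]).to_string(index=False))
print("\ngate 1 enriched and gates 2-4 depleted under bisulfite -> long-fragment loss.")
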
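"""Scan a synthetic genome for [D1,2] stwintrons with the preset search models.

Builds a 50-kb random genome with six planted Model-A stwintrons (both
strands), scans it in greedy and exhaustive modes, and compares the
candidates with the planted truth.
"""

from stwintron import (
    PlantSpec,
    make_gene,
    model_to_pattern,
    plant,
    preset_model,
    random_background,
    scan_genome,
)

model = preset_model("A")
print("Model A is rendered as the degenerate pattern:")
print(model_to_pattern(model)[:80] + "...")
print(f"shortest stwintron it can report: {model.min_length} nt\n")

genes = [
    make_gene(PlantSpec.random("A", seed=100 + i), seed=200 + i,
              strand="+" if i % 2 == 0 else "-")
    for i in range(6)
]
truth = plant(random_background(50_000, gc=0.45, seed=7), genes, seed=8)

report = scan_genome(truth.contigs, [model], strands="both", mode="exhaustive")
print(f"exhaustive scan: {len(report)} candidate(s); "
      f"planted: {len(truth.truth)}")
found = {(c.strand, c.start, c.end) for c in report.candidates}
recovered = sum((t.strand, t.start, t.end) in found for t in truth.truth)
print(f"planted stwintrons recovered at exact coordinates: "
      f"{recovered}/{len(truth.truth)}")
# Every planted stwintron must be recovered; extra candidates, if any, are
# chance motif constellations in the random background — the >30% true-hit
# rate of a real screen comes from exactly this kind of false positive.
for cand in report.candidates[:3]:
    print(f"  {cand.contig_id}:{cand.start}-{cand.end} ({cand.strand}) "
          f"models={','.join(cand.model_names)} len={cand.end - cand.start}")
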
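"""Simulate the excision pathways of a stwintron gene and validate with reads.

A [D1,2] stwintron needs two consecutive splicing reactions: internal-intron
excision first (producing the 'splinter' intermediate with the external
donor reconstituted), then external-intron excision fusing the exons.  The
one-step mis-splice between the distal splice sites leaves the G1 exonic and
shifts the reading frame by +1.
"""

from stwintron import (
    PlantSpec,
    build_queries,
    make_gene,
    simulate_reads,
    splice,
    validate_reads,
)

gene = make_gene(PlantSpec.random("A", seed=5, phase=1), seed=6).context
products = splice(gene)

print(f"pre-mRNA : {len(products.pre_mrna)} nt")
print(f"splinter : {len(products.splinter)} nt "
      f"(internal intron of {len(products.pre_mrna) - len(products.splinter)} nt removed)")
print(f"mature   : {len(products.mature)} nt "
      f"(external intron of {len(products.splinter) - len(products.mature)} nt removed)")
print(f"one-step : {len(products.one_step)} nt, frameshift "
      f"+{products.frameshift_of_one_step} (the G1 stays exonic)\n")

queries = build_queries(gene)  # 60-nt, junction centred at position 30
print("exon-fusion query:", queries.exon_fusion_query)
print("splinter query   :", queries.splinter_query)
print("positions 31-36 of the splinter query are the reconstituted external "
      "donor:", queries.splinter_query[30:36], "\n")

# 100-nt error-free reads from a 50:50 mature/splinter mixture
reads = simulate_reads(gene, {"mature": 0.5, "splinter": 0.5}, n=100, seed=9)
evidence = validate_reads(queries, [(r.id, r.sequence) for r in reads])
print(f"isoform call: {evidence.isoform_call} "
      f"({len(evidence.mature_read_ids)} mature-junction reads, "
      f"{len(evidence.splinter_read_ids)} splinter-junction reads)")
# 'both' means the read set demonstrates the two-step pathway: some reads
# span the final exon/exon fusion, others the transient splinter junction.
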
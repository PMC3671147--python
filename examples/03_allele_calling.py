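"""Assign closest database alleles to reconstructed haplotypes.

Builds a toy two-tier allele database (full genomic sequences + coding
sequences, IMGT/HLA-style names) that contains the sample's two true
haplotypes, phases the sample, and searches: full sequence against the
genomic tier first, exon-merged CDS against the cDNA tier on fallback,
accepting up to 1% mismatch.
"""

import hlaphase as hp

cfg = hp.SimulationConfig(gene_length=2000, n_snv=20, n_indel=2, n_pairs=600,
                          fragment_min=500, fragment_max=1600,
                          fragment_mean=900, fragment_sd=200, seed=1)
ref = hp.simulate_reference(cfg, name="TOYA")
truth = hp.simulate_haplotype_pair(ref, cfg)
pairs = hp.simulate_read_pairs(truth, cfg)

lo, hi = ref.trimmed_interval
th1 = truth.hap1_seq[lo + 5:hi - 5]
th2 = truth.hap2_seq[truth.layout2.ref_to_hap(lo + 5):truth.layout2.ref_to_hap(hi - 5)]
db = hp.simulate_allele_database(
    [ref], n_alleles_per_gene=8, seed=3,
    include_sequences={"TOYA*51:01:01": th1, "TOYA*52:01:01": th2})

res = hp.run_gene_tagging(pairs, ref, hp.PipelineConfig(), allele_db=db,
                          sample="demo")
for hit, cls in zip(res.allele_hits, res.mismatch_classes):
    print(f"{hit.query_id}: {hit.allele} ({hit.tier} tier, "
          f"{hit.mismatches} mismatches, exact={hit.exact}, "
          f"{hit.resolution}-digit resolution)")
    if cls and hit.mismatches:
        print(f"   exonic {cls['exonic']} / intronic {cls['intronic']}")
# Exact genomic-tier hits at 6-digit resolution: each reconstructed
# haplotype is base-identical to its planted database allele.
print(hp.summarize_run([res]).to_string(index=False))
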
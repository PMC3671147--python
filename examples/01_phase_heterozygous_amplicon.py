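"""Phase one heterozygous HLA amplicon from simulated paired-end reads.

Simulates a 4,440 bp amplicon (the HLA-B preset) carrying 50 SNVs and 2
indels between its two chromosomes, sequences it with 2,000 error-free
2 x 250 bp pairs, and runs the gene-tagging pipeline: QC -> alignment ->
pileup -> site calling -> read-backed phasing -> per-haplotype consensus.
"""

import hlaphase as hp

cfg = hp.SimulationConfig(gene_length=hp.GENE_PRESETS["HLA-B"],
                          n_snv=50, n_indel=2, n_pairs=2000, seed=1)
ref = hp.simulate_reference(cfg, name="HLA-B")
truth = hp.simulate_haplotype_pair(ref, cfg)
pairs = hp.simulate_read_pairs(truth, cfg)

res = hp.run_gene_tagging(pairs, ref, hp.PipelineConfig(), sample="demo")
t1, t2 = res.haplotypes

print(f"mapped pairs      : {res.stats['mapped_fraction']:.1%} "
      f"(mean depth {res.stats['mean_depth']:.0f}x)")
print(f"heterozygous sites: {len(res.het_sites)}")
print(f"phase blocks      : {res.phase['n_blocks']} "
      f"(phased fraction {res.phase['phased_fraction']:.2f})")
print(f"coverage          : {t1.covered_fraction}% / {t2.covered_fraction}%")

lo, hi = ref.trimmed_interval
th1 = truth.hap1_seq[lo + 5:hi - 5]
th2 = truth.hap2_seq[truth.layout2.ref_to_hap(lo + 5):truth.layout2.ref_to_hap(hi - 5)]
print(f"haplotypes equal truth (up to label swap): "
      f"{ {t1.sequence, t2.sequence} == {th1, th2} }")
# A phased fraction of 1.0 with 100% coverage means every heterozygous
# site was assigned to a chromosome and no position had to be masked: the
# two printed sequences are complete, phase-defined gene sequences.
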
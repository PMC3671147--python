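# hlaphase

Phase-defined complete HLA gene sequencing from long-amplicon paired-end
reads.

The classical HLA genes (*HLA-A, -C, -B, -DRB1, -DQB1, -DPB1*) are the
most polymorphic loci in the human genome, and clinically meaningful
typing needs the *phase* of their variants — which alleles sit on the
same chromosome — across the full gene, promoter to 3′-UTR.  Short-read
sequencing of a long-range PCR amplicon loses phase unless it is
recovered from the reads themselves.  `hlaphase` implements the
pipeline that does exactly that for 2 × 250 bp paired-end reads from
broad-insert (500–2,000 bp) tagmentation libraries: because a read
*pair* spans up to ~2 kb, a pair whose two mates each cover a
heterozygous SNV links those sites onto one chromosome, and tiling such
links walks phase across the whole amplicon.

It is a library for people building or evaluating amplicon-based HLA
typing workflows; every stage is importable and runs offline on
synthetic data.

## Method

For a heterozygous amplicon (gene-tagging mode):

1. **QC** — adapter removal, 3′ trimming of the <Q30 suffix, pairs kept
   only if both mates stay >200 bp.
2. **Alignment** — each mate placed at its best edit-distance location
   on either strand of the gene's reference segment, allowing up to 80
   mismatches+gap bases per 250 bp read (scaled for trimmed reads).
3. **Site calling** — per-column pileup (bases <Q20 excluded); a
   minor-allele-fraction rule replaces genotype likelihoods: alleles
   below 10 % of depth are discarded as false positives (error or
   paralog cross-amplification), sites with minor fraction ≥ 0.2 and
   ≥ 4 supporting reads are heterozygous, the band in between is
   ambiguous and excluded from phasing.  The 0.2 threshold keeps the
   worst PCR allelic imbalance observed in practice (1:3.4, minor
   fraction 0.227) callable.
4. **Phasing** — *informative pairs* (heterozygous sites on both mates)
   vote on the allele combination at consecutive het sites; greedy
   left-to-right tiling extends a phase block while each link has ≥ 2
   observations, a strict orientation majority, and conflict ≤ 0.2.
5. **Consensus** — reads are assigned to haplotypes by their phased
   alleles; per-haplotype pileups give one full-length sequence per
   chromosome, with positions masked to N when consensus quality ≤ Q20
   or haplotype depth < 2; primer ends are trimmed and coverage (% non-N
   of trimmed length) reported per haplotype.
6. **Allele calling** — the full sequence is searched against a genomic
   allele database (minimum edit distance, N neutral, ≤ 1 % of query
   length); on failure the exons are merged into a coding sequence and
   searched against the cDNA tier.
7. **Trio validation** — child alleles must partition into one paternal
   and one maternal allele per gene; recombination events are counted by
   minimum-switch parsimony over the gene order A–C–B–DRB1–DQB1–DPB1.

Homozygous samples use individual-tagging mode: all six amplicons pooled
under one index, per-pair gene assignment, and a single consensus per
gene (nothing to phase).

A first-class simulator (`hlaphase.simdata`) generates amplicon
references, haplotype pairs and read pairs reproducing the assay's
stated conditions: truncated-normal fragment sizes in [500, 2000]
(mean 1,561 bp), allelic imbalance up to 1:3.4, paralog contamination
below 1.85 %, configurable per-base error.

## Worked example

`examples/01_phase_heterozygous_amplicon.py` simulates a 4,440 bp
heterozygous amplicon (50 SNVs + 2 indels between the chromosomes,
2,000 error-free pairs) and phases it:

```
mapped pairs      : 100.0% (mean depth 225x)
heterozygous sites: 52
phase blocks      : 2 (phased fraction 1.00)
coverage          : 100.0% / 100.0%
haplotypes equal truth (up to label swap): True
```

All 52 heterozygous sites were called and phased; coverage 100 % means
no position of either reconstructed haplotype had to be masked, and both
sequences are base-identical to the simulated chromosomes.  (Two blocks
rather than one: one pair of adjacent het sites sat 268 bp apart, a gap
geometry that read pairs of this library rarely bridge; each block is
still internally phased.)

The other examples cover the pooled homozygous mode
(`02_homozygous_pooled_consensus.py`), allele calling against a toy
two-tier database (`03_allele_calling.py`) and trio validation with a
planted recombination (`04_trio_validation.py`).

## Acceptance script

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the pipeline's headline behavior from scratch: the error-free
and stressed (1 % error, 1:3.4 imbalance, 1.85 % contamination)
heterozygous runs and the pooled six-gene homozygous run, printing
mapping rate, depth, phasing and truth-recovery summaries, then writes
the results JSON.

## Layout

```
src/hlaphase/
  simdata.py     amplicon/haplotype/read simulation, truth SAM/VCF
  qc.py          FASTQ I/O, quality filtering
  align.py       seeded edit-distance aligner, SAM ingestion, stats
  variants.py    pileup, proportion-filter calling, homozygous consensus
  phasing.py     informative pairs, site links, greedy tiling
  consensus.py   haplotype reconstruction, masking, primer trimming
  allelecall.py  two-tier allele database search, mismatch classification
  trio.py        Mendelian checks, recombination parsimony
  pipeline.py    both tagging modes end to end, run summaries
```

See `docs/methods.md` for the model assumptions, parameter rationale and
known limitations.
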
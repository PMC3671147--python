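# Methods

This note documents the models, parameters and numerical choices behind
`hlaphase`, what the synthetic data does and does not emulate, and the
known limitations.

## The phasing problem

A long-range PCR amplicon of one HLA gene (3.4–13.6 kb) carries two
chromosomal copies in a heterozygous sample.  2 × 250 bp paired-end
reads from a broad-insert library (500–2,000 bp after size selection)
observe, per read pair, up to ~500 bases split across two windows as far
as 2 kb apart.  Any pair observing heterozygous sites in both windows is
direct physical evidence that those alleles are *cis*.  The pipeline
turns that evidence into two full-length gene sequences.

## Simulator (`simdata`)

The generator's defaults are the assay's stated operating point, not
free dials:

| parameter | default | unit | rationale |
|---|---|---|---|
| gene_length presets | 3398/4296/4440/11899/7118/13605 | bp | the six amplicon sizes of A/C/B/DRB1/DQB1/DPB1 |
| read_length | 250 | bp | 2 × 250 bp paired-end chemistry |
| fragment_min/max | 500 / 2000 | bp | gel size-selection window |
| fragment_mean | 1561 | bp | measured mean of the selected library |
| fragment_sd | 375 | bp | (max−min)/4; the source only shows an electropherogram, any broad unimodal law in the window is adequate — truncated normal chosen for two parameters and easy moment checks |
| imbalance | 1.0 (stress 1/3.4) | weight | worst observed PCR allelic imbalance |
| contaminant_fraction | 0 (stress 0.0185) | prob. | observed HLA-H cross-amplification ceiling |
| contaminant divergence | 0.02 | per base | single fixed paralog approximating HLA-H |
| base error quality | errors Q10–20, correct Q35–40 | Phred | simple two-level model; no per-cycle profile is published |

Fragment *starts*: tagmentation of an amplicon molecule makes both
molecule ends obligate fragment boundaries, so a fragment is drawn
anchored at an end with probability min(0.5, 2·902/L) — two terminal
fragments among ~L/902 per molecule, 902 bp being the pre-size-selection
library mean — and uniformly in the interior otherwise.  Without the
end anchor, trimmed-edge depth at 157× falls below the caller's minimum
depth for the outermost few bases of the longest amplicon, which
contradicts the complete promoter-to-3′UTR coverage the assay achieves.

Truth indels are placed left-aligned canonical (candidates whose
representation could shift left in a repeat are re-drawn) and separated
by at least indel_max_len + 8 bp, so called positions are comparable to
truth positions without normalization ambiguity.

What the simulator does **not** emulate: PCR chimeras, per-cycle MiSeq
error/quality profiles, adapter read-through, indel sequencing errors,
more than one paralog, coverage biases other than the end anchor.  A
green test on synthetic data therefore establishes algorithmic
correctness at the stated operating point, not robustness to every
artifact of real libraries.

## QC and alignment (`qc`, `align`)

Reads are 3′-trimmed at the longest all-<Q30 suffix (suffix trimming,
not per-base masking, because phasing needs contiguous read
coordinates) and pairs are kept only if both mates stay >200 bp.

Alignment is seed-and-verify: a k-mer index (k=15, stride 7) proposes
diagonals; a clean single diagonal is verified by a vectorized Hamming
count, anything else goes through a windowed gapped alignment with unit
edit costs and a slight gap-open surcharge (1.5 vs 1) so multi-base
indels stay contiguous; indels are then left-normalized.  Reads without
seed hits fall back to an exhaustive Hamming scan, so even a read with
80 substitutions (the budget boundary) finds its origin.  The mismatch
budget of 80 per 250 bp read counts mismatches plus gap bases and scales
proportionally for trimmed reads.  Proper pairs must map
forward–reverse on one gene within the 2 kb fragment ceiling.

Externally aligned SAM is accepted instead (`ingest_sam`); coordinates
convert 1-based → 0-based at the boundary, and all internal coordinates
are 0-based half-open.

## Site calling (`variants`)

Pileup columns exclude bases <Q20.  With depth d and minor-allele count
m (fraction f = m/d):

- d < 10 → `low_depth` (masked downstream);
- f < 0.1 → minor alleles discarded as false positives; verdict from the
  remaining major allele;
- 0.1 ≤ f < 0.2, or m < 4 → `ambiguous`: excluded from phasing rather
  than guessed — such a site would contribute a coin-flip link;
- otherwise `heterozygous`; >2 surviving alleles flag the site
  multi-allelic and it is likewise excluded from phasing.

The thresholds are this package's decisions (no published values exist):
0.2 keeps the worst observed imbalance (minor fraction 1/4.4 = 0.227)
callable at depth, 0.1 rejects the ≤2 % paralog alleles with an order of
magnitude of headroom, and all four are configurable.  Indels are called
from pileup indel alleles with the same fraction rules; the reference
configuration at an indel site is the token `*`.

## Phasing (`phasing`)

Informative pairs (strict mode, the default: ≥1 het site on *each*
mate; general mode accepts ≥2 sites on any mate) are reduced to allele
observations at called het sites.  Counts of allele combinations at
consecutive sites form links; greedy left-to-right tiling extends a
block while a link has ≥2 observations, a strict majority, and conflict
fraction ≤0.2.  Majority is taken over the *orientation* a combination
implies for haplotype 1 — the two cis combinations of one configuration
vote together, so a perfectly consistent link can never be read as a
tie.  Haplotype 1 seeds each block with the reference allele (else the
lexicographically smaller one), which both makes output deterministic
and, when one chromosome matches the reference, makes multi-block
results globally consistent in practice.

Runs of length 1 are reported as unphased sites; a gene with exactly
one het site forms a single 1-site block (trivially phased).  For ≤12
sites and zero-conflict links the greedy result provably reaches the
exhaustive 2^n maximum link agreement (tested).

Greedy tiling was chosen over MEC-style global optimization because the
evidence structure here (deep coverage, consecutive-site links) makes
conflicts local; the exhaustive oracle bounds its adequacy at test
scale.

## Consensus (`consensus`)

Informative pairs are assigned to the haplotype their alleles match at
the strict majority of covered sites within one block (cross-block
majorities are meaningless — phase between blocks is undefined — so
only the block covering most of the pair's sites is used; ties are
unassigned).  Per-haplotype pileups give a majority base per position;
where a haplotype's own depth is below min_hap_depth (default 2) the
unassigned pool backs it up.

Masking: a position becomes N when haplotype depth < 2 or consensus
quality ≤ Q20.  The default quality score is a base-quality sum
(qualities supporting the consensus allele minus qualities opposing,
capped at 93) — with error-free Q35 bases, two agreeing reads already
clear Q20, while any genuinely contested position goes strongly
negative.  A Laplace-smoothed minority-fraction score
(−10·log10((d−m+1)/(d+2))) is available as `quality_model="laplace"`;
note it cannot exceed Q20 below depth 99 even with perfect agreement, so
it only suits very deep runs (the 2,281× regime) and was therefore not
made the default.

Phased het sites take their block allele unconditionally (the phase
evidence is the support; a deletion carrier has no base depth inside
the deletion).  Unphased het sites are masked in both haplotypes:
correctness over coverage, which is also why reported coverage can be
<100 % rather than ever forcing a call.

Primer intervals plus a 5 bp margin are trimmed from both ends; coverage
is the percentage of non-masked positions over the trimmed length.  The
sequence is kept as one emitted string per reference position ('' for
deleted bases, insertion prefixed to the base it precedes), so exon
extraction and mismatch mapping never need indel-shifted coordinates.

## Allele calling (`allelecall`)

Distance is edit distance with N-masked positions neutral, computed as a
unit-cost global alignment (score only) with a length-difference
prefilter and capped at ceil(0.01 × query length).  The 1 % allowance
applies to both tiers; the genomic tier always preempts the cDNA tier.
Equidistant alleles break ties toward more name fields (higher digit
resolution), then lexicographically.  Mismatches of the single best hit
are located by traceback, mapped back to reference coordinates, labeled
exonic/intronic, and exonic substitutions are flagged
synonymous/nonsynonymous by codon translation when the gene model
carries a reading frame.

The shipped database is synthetic (`simulate_allele_database`): per
gene, a reference-identical allele plus substitution-only mutants at 4 %
divergence (pairwise ≥2 %, far beyond the 1 % tolerance) and a few
cDNA-only alleles to exercise the fallback; a real IMGT/HLA-style FASTA
pair loads unmodified via `AlleleDatabase.from_fastas`.

## Trio validation (`trio`)

Transmission at one gene is multiset logic (one allele from each
parent's pair; homozygosity handled).  Recombination counting assigns
each transmitted allele to a parental haplotype jointly across the six
genes in chromosomal order, minimizing label switches by dynamic
programming over the per-gene feasible label sets (parent-homozygous
genes allow both labels and never break a run); ambiguous per-gene
transmission choices are enumerated.  The reported count equals the
2^6-enumeration minimum (tested).  Allele identity is string equality —
names or sequence digests, whichever the caller provides.

## Degenerate inputs and tie-breaks

- 0 het sites: phasing returns an empty assignment (phased fraction
  defined as 1.0); both haplotypes equal the homozygous consensus.
- Base-count ties in consensus resolve to the alphabetically first base;
  block seeding prefers the reference allele; equidistant database
  alleles prefer higher resolution — all outputs are deterministic and
  independent of read input order.
- Heterozygous input in pooled individual-tagging mode is detected by
  residual het sites in ≥2 genes; the run is flagged unreliable with a
  recommendation to re-run gene-tagged, mirroring the known failure of
  pooled phasing.

## Limitations

- Phase between blocks is undefined; when neither chromosome matches the
  reference allele pattern, a multi-block result is correct only
  per-block (comparisons against truth are modulo per-block label swap).
- The aligner's quick-accept of clean diagonals (≤6 mismatches) can
  misrepresent an indel within ~6 bp of a read end as substitutions;
  this appears as a small (<8 %) discordant minority at indel-adjacent
  links, well inside the 0.2 conflict budget.
- No local assembly: regions with no read support stay masked rather
  than gap-filled; no realignment around indels.
- The allele search is a global-distance criterion, appropriate for
  near-full-length queries; it is not a local aligner and will not
  rescue queries missing large chunks of the gene.
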
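"""Synthetic amplicon sequencing data.

Generates everything a desk-scale run of the pipeline needs: a random
amplicon reference with a gene model, a heterozygous haplotype pair with
known SNVs/indels, and paired-end reads emulating the sequencing design
this pipeline targets — 2 x 250 bp reads from 500-2,000 bp size-selected
tagmentation fragments (mean 1,561 bp), optional PCR allelic imbalance
(stress level 1:3.4), paralog cross-amplification (stress level 1.85 %)
and per-base substitution error.

All truth coordinates are 0-based half-open on the reference; conversion
to 1-based happens only in the SAM/VCF writers.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .qc import ReadPair
from .reference import AmpliconReference

__all__ = [
    "GENE_PRESETS", "SimulationConfig", "Variant", "TruthSet", "HaplotypeLayout",
    "simulate_reference", "simulate_haplotype_pair", "simulate_read_pairs",
    "write_truth_sam", "write_truth_vcf", "simulate_allele_database",
    "revcomp",
]

# Amplicon sizes of the six classical HLA genes targeted by the assay.
GENE_PRESETS = {
    "HLA-A": 3398, "HLA-C": 4296, "HLA-B": 4440,
    "HLA-DRB1": 11899, "HLA-DQB1": 7118, "HLA-DPB1": 13605,
}

_COMP = str.maketrans("ACGTN", "TGCAN")
_BASES = np.array(list("ACGT"))


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class SimulationConfig:
    """Stated world of one simulated amplicon experiment.

    ``imbalance`` is the sampling weight of haplotype 2 relative to
    haplotype 1 (1.0 = balanced; 1/3.4 reproduces the worst PCR imbalance
    observed in real amplicons).  ``contaminant_fraction`` is the
    probability that a pair derives from a paralog copy at 2 % fixed
    divergence (HLA-H-like cross-amplification; stress level 0.0185).
    """

    gene_length: int = 4440
    n_snv: int = 50
    n_indel: int = 0
    indel_max_len: int = 3
    read_length: int = 250
    fragment_min: int = 500
    fragment_max: int = 2000
    fragment_mean: int = 1561
    fragment_sd: float = 375.0          # (max - min) / 4; law is truncated normal
    n_pairs: int = 2000
    base_error_rate: float = 0.0
    imbalance: float = 1.0
    contaminant_fraction: float = 0.0
    contaminant_divergence: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.contaminant_fraction < 1.0):
            raise ValueError("contaminant_fraction must be in [0, 1)")
        if not (self.fragment_min <= self.fragment_mean <= self.fragment_max):
            raise ValueError("need fragment_min <= fragment_mean <= fragment_max")
        if self.read_length > self.fragment_min:
            raise ValueError("read_length must not exceed fragment_min")
        if self.imbalance <= 0:
            raise ValueError("imbalance must be positive")


@dataclass
class Variant:
    """One truth difference between the two haplotypes (reference coordinates).

    kind 'snv': ref_allele/alt_allele are single bases at ``position``.
    kind 'ins': alt_allele is '+SEQ', inserted before ``position``.
    kind 'del': alt_allele is '-SEQ', deleting reference[position:position+len].
    The reference-configuration token for indel sites is '*'.
    """

    position: int
    kind: str
    ref_allele: str
    alt_allele: str

    @property
    def indel_seq(self) -> str:
        return self.alt_allele[1:] if self.kind in ("ins", "del") else ""


class HaplotypeLayout:
    """Piecewise alignment of a haplotype to its reference.

    Built from the truth variant list; answers coordinate projections and
    produces per-fragment CIGARs for the truth SAM.  Ops are (op, ref_len,
    hap_len) with op in 'MID'.
    """

    def __init__(self, ref_length: int, variants: list[Variant]):
        ops: list[tuple[str, int, int]] = []
        ref_pos = 0
        for v in sorted(variants, key=lambda v: v.position):
            if v.kind == "snv":
                continue
            if v.position > ref_pos:
                ops.append(("M", v.position - ref_pos, v.position - ref_pos))
                ref_pos = v.position
            if v.kind == "ins":
                ops.append(("I", 0, len(v.indel_seq)))
            else:
                ops.append(("D", len(v.indel_seq), 0))
                ref_pos += len(v.indel_seq)
        if ref_pos < ref_length:
            ops.append(("M", ref_length - ref_pos, ref_length - ref_pos))
        self.ops = ops
        self.ref_length = ref_length
        self.hap_length = sum(h for _, _, h in ops)

    def ref_to_hap(self, ref_pos: int) -> int:
        """Haplotype coordinate of a reference position (deleted bases map
        to the position following the deletion)."""
        r = h = 0
        for op, rl, hl in self.ops:
            if op != "I" and r + rl > ref_pos:
                return h + (ref_pos - r if op == "M" else 0)
            r += rl
            h += hl
        return self.hap_length

    def cigar_for(self, hap_start: int, hap_end: int) -> tuple[int, list[tuple[str, int]]]:
        """Reference start and CIGAR for haplotype interval [hap_start, hap_end).

        Read bases falling inside an insertion at the interval edge are
        soft-clipped ('S') so the CIGAR consumes exactly the read length.
        """
        cigar: list[tuple[str, int]] = []
        ref_start = None
        r = h = 0
        for op, rl, hl in self.ops:
            h2 = h + hl
            if h2 <= hap_start and not (op == "D" and h2 == hap_start):
                r += rl
                h = h2
                continue
            if h >= hap_end:
                break
            if op == "M":
                lo, hi = max(h, hap_start), min(h2, hap_end)
                if ref_start is None:
                    ref_start = r + (lo - h)
                cigar.append(("M", hi - lo))
            elif op == "I":
                lo, hi = max(h, hap_start), min(h2, hap_end)
                if hi > lo:
                    full = (lo == h and hi == h2)
                    cigar.append(("I" if (full and ref_start is not None) else "S", hi - lo))
            elif op == "D":
                if ref_start is not None and h2 < hap_end:
                    cigar.append(("D", rl))
            r += rl
            h = h2
        # merge same-op runs and strip leading/trailing D
        while cigar and cigar[0][0] == "D":
            cigar.pop(0)
        while cigar and cigar[-1][0] == "D":
            cigar.pop()
        merged: list[tuple[str, int]] = []
        for op, ln in cigar:
            if merged and merged[-1][0] == op:
                merged[-1] = (op, merged[-1][1] + ln)
            else:
                merged.append((op, ln))
        return (ref_start if ref_start is not None else 0), merged


@dataclass
class ReadOrigin:
    source: str                    # '1' | '2' | 'contaminant'
    start: int                     # fragment interval on the source sequence
    end: int
    flipped: bool                  # True when mate1 is the right fragment end


@dataclass
class TruthSet:
    """Ground truth for one simulated heterozygous (or homozygous) sample."""

    reference: AmpliconReference
    hap1_seq: str
    hap2_seq: str
    variant_sites: list[Variant]
    layout2: HaplotypeLayout
    read_origins: dict[str, ReadOrigin] = field(default_factory=dict)
    paralog_seq: str | None = None

    def source_sequence(self, source: str) -> str:
        if source == "1":
            return self.hap1_seq
        if source == "2":
            return self.hap2_seq
        return self.paralog_seq  # type: ignore[return-value]


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def simulate_reference(config: SimulationConfig, name: str = "SIMGENE") -> AmpliconReference:
    """Uniform-random amplicon with 30 bp primer intervals at both ends and
    deterministically placed non-overlapping exons (CDS length % 3 == 0)."""
    L = config.gene_length
    if L < 2 * config.read_length:
        raise ValueError(f"gene_length {L} < 2 x read_length")
    rng = np.random.default_rng([config.seed, 0])
    seq = _random_sequence(rng, L)
    n_exons = int(np.clip(L // 800, 2, 8))
    region_start, region_end = 60, L - 60
    slot = (region_end - region_start) // n_exons
    exons = []
    for i in range(n_exons):
        elen = 3 * int(rng.integers(40, min(100, max(41, (slot - 20) // 3))))
        offset = int(rng.integers(0, max(1, slot - elen - 10)))
        a = region_start + i * slot + offset
        exons.append((a, a + elen))
    return AmpliconReference(
        name=name, sequence=seq,
        primer_intervals=[(0, 30), (L - 30, L)],
        exons=exons, coding_frame=0,
    )


def _left_shiftable(ref: str, pos: int, seq: str, kind: str) -> bool:
    """True when the indel representation could be shifted left (ambiguous
    placement in a repeat); such candidates are rejected so that truth
    positions are already left-aligned canonical."""
    if pos == 0:
        return False
    if kind == "del":
        return ref[pos + len(seq) - 1] == ref[pos - 1]
    return seq[-1] == ref[pos - 1]


def simulate_haplotype_pair(reference: AmpliconReference, config: SimulationConfig) -> TruthSet:
    """hap1 = reference; hap2 carries n_snv substitutions and n_indel indels
    at well-separated positions outside the primer intervals."""
    L = len(reference)
    n_var = config.n_snv + config.n_indel
    if n_var > L / 10:
        raise ValueError("cannot place requested variants: too dense")
    rng = np.random.default_rng([config.seed, 1])
    ref = reference.sequence
    lo = max(b for _, b in reference.primer_intervals[:1]) + 5 if reference.primer_intervals else 5
    hi = (min(a for a, _ in reference.primer_intervals[1:]) - 5
          if len(reference.primer_intervals) > 1 else L - 5)
    min_gap = config.indel_max_len + 8
    positions: list[int] = []
    kinds = ["snv"] * config.n_snv + ["indel"] * config.n_indel
    rng.shuffle(kinds)
    variants: list[Variant] = []
    attempts = 0
    for kind in kinds:
        while True:
            attempts += 1
            if attempts > 200 * max(1, n_var):
                raise ValueError("cannot place requested variants without overlap")
            p = int(rng.integers(lo, hi - config.indel_max_len))
            if any(abs(p - q) < min_gap for q in positions):
                continue
            if kind == "snv":
                alt = str(rng.choice([b for b in "ACGT" if b != ref[p]]))
                variants.append(Variant(p, "snv", ref[p], alt))
            else:
                ilen = int(rng.integers(1, config.indel_max_len + 1))
                if rng.random() < 0.5:
                    dseq = ref[p:p + ilen]
                    if _left_shiftable(ref, p, dseq, "del"):
                        continue
                    variants.append(Variant(p, "del", "*", "-" + dseq))
                else:
                    iseq = _random_sequence(rng, ilen)
                    if _left_shiftable(ref, p, iseq, "ins"):
                        continue
                    variants.append(Variant(p, "ins", "*", "+" + iseq))
            positions.append(p)
            break
    variants.sort(key=lambda v: v.position)
    # build hap2
    parts: list[str] = []
    cursor = 0
    for v in variants:
        parts.append(ref[cursor:v.position])
        if v.kind == "snv":
            parts.append(v.alt_allele)
            cursor = v.position + 1
        elif v.kind == "ins":
            parts.append(v.indel_seq)
            cursor = v.position
        else:
            cursor = v.position + len(v.indel_seq)
    parts.append(ref[cursor:])
    hap2 = "".join(parts)
    return TruthSet(
        reference=reference, hap1_seq=ref, hap2_seq=hap2,
        variant_sites=variants,
        layout2=HaplotypeLayout(L, variants),
    )


def _truncated_normal_lengths(rng: np.random.Generator, n: int,
                              config: SimulationConfig) -> np.ndarray:
    """Rejection-sampled truncated normal fragment lengths (vectorized)."""
    out = np.empty(n, dtype=np.int64)
    filled = 0
    while filled < n:
        draw = rng.normal(config.fragment_mean, config.fragment_sd, size=2 * (n - filled))
        ok = draw[(draw >= config.fragment_min) & (draw <= config.fragment_max)]
        take = min(len(ok), n - filled)
        out[filled:filled + take] = ok[:take].astype(np.int64)
        filled += take
    return out


def simulate_read_pairs(truth: TruthSet, config: SimulationConfig) -> list[ReadPair]:
    """Draw n_pairs fragments and emit 2 x read_length paired-end reads.

    Fragment lengths follow a truncated normal on [fragment_min,
    fragment_max]; the source haplotype is drawn with weight 1:imbalance;
    with probability contaminant_fraction the fragment comes from a fixed
    2 %-diverged paralog copy.  Mate 1 reads one fragment end forward,
    mate 2 the other end reverse-complemented (roles swapped with p=0.5).
    Substitution errors are injected at base_error_rate with Q10-20
    qualities; correct bases get Q35-40.
    """
    rng = np.random.default_rng([config.seed, 2])
    if truth.paralog_seq is None and config.contaminant_fraction > 0:
        prng = np.random.default_rng([config.seed, 3])
        ref = truth.reference.sequence
        n_div = int(round(config.contaminant_divergence * len(ref)))
        sites = prng.choice(len(ref), size=n_div, replace=False)
        para = list(ref)
        for p in sites:
            para[p] = str(prng.choice([b for b in "ACGT" if b != ref[p]]))
        truth.paralog_seq = "".join(para)

    n = config.n_pairs
    R = config.read_length
    lengths = _truncated_normal_lengths(rng, n, config)
    u_src = rng.random(n)
    u_contam = rng.random(n)
    u_flip = rng.random(n) < 0.5
    u_anchor = rng.random(n)
    u_side = rng.random(n) < 0.5
    p2 = config.imbalance / (1.0 + config.imbalance)

    pairs: list[ReadPair] = []
    truth.read_origins = {}
    for i in range(n):
        if u_contam[i] < config.contaminant_fraction:
            source = "contaminant"
        else:
            source = "2" if u_src[i] < p2 else "1"
        src_seq = truth.source_sequence(source)
        flen = int(min(lengths[i], len(src_seq)))
        # tagmentation of an amplicon molecule: both molecule ends are
        # obligate fragment boundaries, so a share of fragments is
        # anchored at an end.  With ~L/902 fragments per molecule
        # (pre-size-selection library mean 902 bp), two of them touch
        # ends: p_end = 2*902/L, capped at 0.5 so short molecules keep
        # their interior middle fragments.
        p_end = min(0.5, 1804 / len(src_seq))
        if u_anchor[i] < p_end:
            start = 0 if u_side[i] else len(src_seq) - flen
        else:
            start = int(rng.integers(0, len(src_seq) - flen + 1))
        end = start + flen
        left = src_seq[start:start + R]
        right = revcomp(src_seq[end - R:end])
        if u_flip[i]:
            left, right = right, left
        rid = f"sim:{i}"

        def _noisy(seq: str) -> tuple[str, np.ndarray]:
            qual = rng.integers(35, 41, size=len(seq)).astype(np.int16)
            if config.base_error_rate > 0:
                err = np.nonzero(rng.random(len(seq)) < config.base_error_rate)[0]
                if len(err):
                    s = np.array(list(seq))
                    for j in err:
                        s[j] = str(rng.choice([b for b in "ACGT" if b != s[j]]))
                        qual[j] = int(rng.integers(10, 21))
                    seq = "".join(s)
            return seq, qual

        s1, q1 = _noisy(left)
        s2, q2 = _noisy(right)
        pairs.append(ReadPair(rid, s1, q1, s2, q2))
        truth.read_origins[rid] = ReadOrigin(source, start, end, bool(u_flip[i]))
    return pairs


# ---------------------------------------------------------------------------
# truth emission

def write_truth_sam(truth: TruthSet, pairs: list[ReadPair], path: str,
                    read_length: int | None = None) -> None:
    """Truth alignments as SAM v1 with correct POS/CIGAR (text SAM, via pysam).

    Contaminant-origin pairs are written mapped to the reference (the
    paralog has the same coordinates); error bases are left as sequenced.
    """
    import pysam

    ref = truth.reference
    header = {"HD": {"VN": "1.6", "SO": "unsorted"},
              "SQ": [{"SN": ref.name, "LN": len(ref)}]}
    identity = HaplotypeLayout(len(ref), [])
    with pysam.AlignmentFile(path, "w", header=header) as out:
        for p in pairs:
            o = truth.read_origins[p.id]
            layout = truth.layout2 if o.source == "2" else identity
            R = len(p.seq1)
            lpos, lcig = layout.cigar_for(o.start, o.start + R)
            rpos, rcig = layout.cigar_for(o.end - len(p.seq2), o.end)
            if o.flipped:   # mate1 is the right (reverse) end
                mates = [(p.seq1, p.qual1, rpos, rcig, True, True),
                         (p.seq2, p.qual2, lpos, lcig, False, False)]
            else:
                mates = [(p.seq1, p.qual1, lpos, lcig, False, True),
                         (p.seq2, p.qual2, rpos, rcig, True, False)]
            for which, (seq, qual, pos, cig, is_rev, is_read1) in enumerate(mates):
                a = pysam.AlignedSegment()
                a.query_name = p.id
                a.reference_id = 0
                a.reference_start = pos
                a.query_sequence = revcomp(seq) if is_rev else seq
                a.query_qualities = list(qual[::-1] if is_rev else qual)
                a.cigarstring = "".join(f"{ln}{op}" for op, ln in cig)
                flag = 0x1 | 0x2
                flag |= 0x10 if is_rev else 0x20
                flag |= 0x40 if is_read1 else 0x80
                a.flag = flag
                a.next_reference_id = 0
                a.next_reference_start = mates[1 - which][2]
                a.template_length = (o.end - o.start) * (1 if not is_rev else -1)
                out.write(a)


def write_truth_vcf(truth: TruthSet, path: str) -> None:
    """Truth variants as minimal VCF v4.2 (phased GT 0|1, hap2 carries ALT)."""
    ref = truth.reference.sequence
    name = truth.reference.name
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={name},length={len(ref)}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ttruth\n")
        for v in truth.variant_sites:
            if v.kind == "snv":
                pos, r, a = v.position + 1, v.ref_allele, v.alt_allele
            elif v.kind == "ins":
                pos = v.position            # anchor base before the insertion
                r = ref[v.position - 1]
                a = r + v.indel_seq
            else:
                pos = v.position
                r = ref[v.position - 1] + v.indel_seq
                a = ref[v.position - 1]
            fh.write(f"{name}\t{pos}\t.\t{r}\t{a}\t.\tPASS\t.\tGT\t0|1\n")


# ---------------------------------------------------------------------------
# toy allele database

def simulate_allele_database(references: list[AmpliconReference],
                             n_alleles_per_gene: int = 12,
                             divergence: float = 0.04,
                             n_cdna_only: int = 3,
                             seed: int = 0,
                             include_sequences: dict[str, str] | None = None):
    """Build a toy two-tier allele database from amplicon references.

    Each gene gets ``n_alleles_per_gene`` genomic alleles: allele :01 is
    the reference itself, the rest are substitution-only mutants at
    ``divergence`` (pairwise distances ~2x divergence, comfortably above
    the 1 % search tolerance).  The cDNA tier holds every genomic
    allele's concatenated exons plus ``n_cdna_only`` extra cDNA-only
    alleles per gene.  ``include_sequences`` maps allele names to exact
    sequences to plant in the genomic tier (e.g. truth haplotypes).
    """
    from .allelecall import AlleleDatabase

    genomic: dict[str, str] = {}
    cdna: dict[str, str] = {}
    field_depth = ["01", "01:01", "01:01:01"]
    for ref in references:
        rng = np.random.default_rng([seed, zlib.crc32(ref.name.encode()) % (2**31)])
        gene = ref.name.split("-")[-1]
        seq = ref.sequence
        for i in range(1, n_alleles_per_gene + 1):
            suffix = field_depth[i % 3]
            allele = f"{gene}*{i:02d}:{suffix}"
            if i == 1:
                aseq = seq
            else:
                n_mut = max(1, int(round(divergence * len(seq))))
                sites = rng.choice(len(seq), size=n_mut, replace=False)
                s = list(seq)
                for p in sites:
                    s[p] = str(rng.choice([b for b in "ACGT" if b != s[p]]))
                aseq = "".join(s)
            genomic[allele] = aseq
            cdna[allele] = "".join(aseq[a:b] for a, b in ref.exons)
        for j in range(1, n_cdna_only + 1):
            allele = f"{gene}*{90 + j:02d}:01"
            cds = "".join(seq[a:b] for a, b in ref.exons)
            n_mut = max(1, int(round(divergence * len(cds))))
            sites = rng.choice(len(cds), size=n_mut, replace=False)
            s = list(cds)
            for p in sites:
                s[p] = str(rng.choice([b for b in "ACGT" if b != s[p]]))
            cdna[allele] = "".join(s)
    if include_sequences:
        genomic.update({k: v.upper() for k, v in include_sequences.items()})
    return AlleleDatabase(genomic=genomic, cdna=cdna)
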
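"""Full-length haplotype sequence reconstruction and masking.

Each informative pair is assigned to the haplotype whose phased block
alleles it matches at the majority of its covered sites; per-haplotype
pileups then yield a consensus base per position, with unassigned pairs
backing positions where haplotype-specific depth is insufficient.

Positions are masked to N when the consensus quality does not exceed
``q_min`` (default Q20) or haplotype depth falls below ``min_hap_depth``.
The default quality model is a base-quality sum (Phred qualities
supporting the consensus allele minus those opposing it, capped at 93);
``quality_model="laplace"`` selects the Laplace-smoothed minority
fraction score -10*log10((d-m+1)/(d+2)) instead, which demands depth
>= 99 for Q20 even with perfect agreement and is therefore only
appropriate for very deep runs.

Phased het sites take their block allele; unphased het sites are masked
in both haplotypes (correctness over coverage).  The sequence is kept as
one emitted string per reference position so that indels never corrupt
downstream coordinate mapping (exon extraction, primer trimming).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .phasing import LocalHaplotype, PhasedAssignment
from .reference import AmpliconReference
from .variants import Pileup

__all__ = ["HaplotypeSequence", "assign_reads_to_haplotypes",
           "build_haplotype_sequences", "trim_primers",
           "laplace_consensus_quality", "write_haplotype_fasta"]

logger = logging.getLogger(__name__)

_BASES = "ACGT"


def laplace_consensus_quality(depth: int, majority: int) -> float:
    """Phred-scaled Laplace-smoothed minority fraction: with one read
    (d=1, m=1) this is -10*log10(1/3) ~ 4.8, i.e. masked at Q20."""
    return float(-10.0 * np.log10((depth - majority + 1) / (depth + 2)))


@dataclass
class HaplotypeSequence:
    """One haplotype as an emitted string per reference position.

    ``pieces[i]`` is what the haplotype emits at reference position
    ``ref_offset + i``: a base, 'N' (masked), '' (deleted), or an
    insertion prefixed to the base at that position.
    """

    gene: str
    hap_index: int
    pieces: list[str]
    masked: np.ndarray                     # bool per reference position
    ref_offset: int = 0
    covered_fraction: float | None = None  # % non-masked over trimmed length
    trimmed: bool = False

    @property
    def sequence(self) -> str:
        return "".join(self.pieces)

    @property
    def masked_intervals(self) -> list[tuple[int, int]]:
        out: list[tuple[int, int]] = []
        for i, m in enumerate(self.masked):
            p = self.ref_offset + i
            if m:
                if out and out[-1][1] == p:
                    out[-1] = (out[-1][0], p + 1)
                else:
                    out.append((p, p + 1))
        return out

    def query_to_ref(self) -> np.ndarray:
        """Reference position of every emitted base (inserted bases map to
        the position they precede)."""
        idx = []
        for i, piece in enumerate(self.pieces):
            idx.extend([self.ref_offset + i] * len(piece))
        return np.asarray(idx, dtype=np.int64)


def assign_reads_to_haplotypes(local_haps: list[LocalHaplotype],
                               assignment: PhasedAssignment) -> dict[str, int | None]:
    """pair id -> 1 | 2 | None (ties and contradictions unassigned).

    A pair is compared against the block containing the most of its
    covered sites (cross-block comparisons are meaningless: phase between
    blocks is undefined) and assigned on a strict within-block majority.
    """
    site_block = assignment.block_of_site()
    hap_allele: dict[int, tuple[str, str]] = {}
    for b in assignment.blocks:
        for i, a1, a2 in zip(b.site_indices, b.hap1_alleles, b.hap2_alleles):
            hap_allele[i] = (a1, a2)
    out: dict[str, int | None] = {}
    for lh in local_haps:
        by_block: dict[int, list[tuple[int, str]]] = {}
        for i, a in lh.observations:
            if i in site_block:
                by_block.setdefault(site_block[i], []).append((i, a))
        if not by_block:
            out[lh.pair_id] = None
            continue
        sizes = sorted(((len(v), -bi) for bi, v in by_block.items()), reverse=True)
        if len(sizes) > 1 and sizes[0][0] == sizes[1][0]:
            best = min(bi for bi, v in by_block.items()
                       if len(v) == sizes[0][0])
        else:
            best = -sizes[0][1]
        v1 = sum(1 for i, a in by_block[best] if hap_allele[i][0] == a)
        v2 = sum(1 for i, a in by_block[best] if hap_allele[i][1] == a)
        out[lh.pair_id] = 1 if v1 > v2 else 2 if v2 > v1 else None
    return out


def _consensus_arrays(counts: np.ndarray, qsums: np.ndarray,
                      quality_model: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(major base code, depth, consensus quality) per position."""
    depth = counts.sum(axis=1)
    major = np.argmax(counts, axis=1)          # ties -> smaller code (lexicographic)
    m = counts[np.arange(len(counts)), major]
    if quality_model == "laplace":
        with np.errstate(divide="ignore"):
            qc = -10.0 * np.log10((depth - m + 1) / (depth + 2))
    elif quality_model == "qualsum":
        support = qsums[np.arange(len(qsums)), major]
        qc = np.minimum(support - (qsums.sum(axis=1) - support), 93)
    else:
        raise ValueError(f"unknown quality_model {quality_model!r}")
    return major, depth, qc


def build_haplotype_sequences(reference: AmpliconReference,
                              assignment: PhasedAssignment,
                              pileups: tuple[Pileup, Pileup, Pileup],
                              q_min: float = 20, min_hap_depth: int = 2,
                              quality_model: str = "qualsum",
                              ) -> tuple[HaplotypeSequence, HaplotypeSequence]:
    """Reconstruct both haplotype sequences from per-haplotype pileups.

    ``pileups`` = (haplotype 1, haplotype 2, unassigned).  At positions
    where a haplotype's own depth is below ``min_hap_depth`` the
    unassigned pool is added (homozygous positions may draw on unassigned
    reads); phased het sites take their block allele; unphased het sites
    are masked in both haplotypes.
    """
    L = len(reference)
    p1, p2, pu = pileups
    out: list[HaplotypeSequence] = []
    hap_site_allele: list[dict[int, str]] = [{}, {}]
    for b in assignment.blocks:
        for i, a1, a2 in zip(b.site_indices, b.hap1_alleles, b.hap2_alleles):
            hap_site_allele[0][i] = a1
            hap_site_allele[1][i] = a2
    for h, pile in ((0, p1), (1, p2)):
        own_depth = pile.depth
        use_pool = own_depth < min_hap_depth
        counts = pile.counts + pu.counts * use_pool[:, None]
        qsums = pile.qual_sums + pu.qual_sums * use_pool[:, None]
        major, depth, qc = _consensus_arrays(counts, qsums, quality_model)
        masked = (qc <= q_min) | (depth < min_hap_depth)
        pieces = [("N" if masked[i] else _BASES[major[i]]) for i in range(L)]

        for i, site in enumerate(assignment.sites):
            p = site.position
            if site.verdict != "heterozygous":
                continue
            allele = hap_site_allele[h].get(i)
            if allele is None or site.multi_allelic:
                # unphased heterozygosity: mask in both haplotypes
                span = max((len(a) - 1 for a in site.alleles if a.startswith("-")),
                           default=1)
                for q in range(p, min(p + max(span, 1), L)):
                    pieces[q] = "N"
                    masked[q] = True
                continue
            # phased sites take their block allele: the phase evidence
            # itself is the support (a deletion carrier has no base depth)
            if site.kind == "snv":
                pieces[p] = allele
                masked[p] = False
            elif site.kind == "ins":
                base = pieces[p] if pieces[p] != "N" else _BASES[major[p]]
                if allele.startswith("+"):
                    pieces[p] = allele[1:] + base
                masked[p] = False
            else:  # del
                if allele.startswith("-"):
                    for q in range(p, min(p + len(allele) - 1, L)):
                        pieces[q] = ""
                        masked[q] = False
        # homozygous-alt indels apply to both haplotypes
        for site in assignment.sites:
            if site.verdict != "homozygous_alt" or site.kind == "snv":
                continue
            allele = max(site.alleles, key=site.alleles.get)
            p = site.position
            if allele.startswith("+"):
                base = pieces[p] if pieces[p] not in ("N", "") else _BASES[major[p]]
                pieces[p] = allele[1:] + base
            elif allele.startswith("-"):
                for q in range(p, min(p + len(allele) - 1, L)):
                    pieces[q] = ""
                    masked[q] = False
        out.append(HaplotypeSequence(reference.name, h + 1, pieces, masked))
    return out[0], out[1]


def trim_primers(hseq: HaplotypeSequence, reference: AmpliconReference,
                 margin: int = 5) -> HaplotypeSequence:
    """Remove the primer intervals plus a safety margin from both ends and
    recompute the covered fraction over the trimmed length."""
    t0, t1 = reference.trimmed_interval
    t0, t1 = t0 + margin, t1 - margin
    primer_len = sum(b - a for a, b in reference.primer_intervals)
    if primer_len > len(reference) / 2:
        raise ValueError("primer intervals cover more than half the amplicon")
    lo, hi = t0 - hseq.ref_offset, t1 - hseq.ref_offset
    pieces = hseq.pieces[lo:hi]
    masked = hseq.masked[lo:hi]
    covered = 100.0 * (1.0 - float(masked.mean())) if len(masked) else 0.0
    return HaplotypeSequence(hseq.gene, hseq.hap_index, pieces, masked,
                             ref_offset=t0, covered_fraction=round(covered, 1),
                             trimmed=True)


def write_haplotype_fasta(hseqs: list[HaplotypeSequence], path: str,
                          sample: str = "sample") -> None:
    with open(path, "w") as fh:
        for hs in hseqs:
            cov = "" if hs.covered_fraction is None else f"|cov={hs.covered_fraction}"
            fh.write(f">{sample}|{hs.gene}|hap{hs.hap_index}{cov}\n")
            seq = hs.sequence
            for i in range(0, len(seq), 80):
                fh.write(seq[i:i + 80] + "\n")
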
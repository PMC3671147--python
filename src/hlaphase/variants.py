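"""Pileup construction, SNV/indel calling and the proportion filter.

The caller is deliberately simple: per-column allele counts (bases below
Q20 excluded), then a minor-allele-fraction rule replacing Bayesian
genotype likelihoods.  Alleles below ``fp_max_fraction`` of the column
depth are discarded as false positives (sequencing error or paralog
cross-amplification); sites with a minor fraction of at least
``het_min_fraction`` and at least ``het_min_count`` supporting reads are
heterozygous; the band in between is ambiguous and excluded from
phasing.  Defaults keep the worst PCR allelic imbalance seen in real
amplicons (1:3.4, minor fraction 0.227) callable as heterozygous.

Indel alleles are tokens: ``'+SEQ'`` (insertion before the position),
``'-SEQ'`` (deletion of reference[pos:pos+len]); the reference
configuration at an indel site is ``'*'``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .align import PairAlignment, encode
from .reference import AmpliconReference

__all__ = ["Pileup", "SiteCall", "build_pileup", "call_sites", "call_site",
           "consensus_homozygous", "estimate_allelic_imbalance",
           "write_sites_vcf"]

logger = logging.getLogger(__name__)

_BASES = "ACGT"


@dataclass
class Pileup:
    """Per-position allele tallies over one reference."""

    reference: AmpliconReference
    counts: np.ndarray              # (L, 4) quality-filtered base counts
    qual_sums: np.ndarray           # (L, 4) summed Phred qualities
    insertions: dict[int, dict[str, int]] = field(default_factory=dict)
    deletions: dict[int, dict[str, int]] = field(default_factory=dict)
    n_reads: int = 0

    @property
    def depth(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def column(self, position: int) -> dict:
        """PileupColumn view: allele -> count (bases and indel alleles),
        total depth and mean base quality per base allele."""
        alleles: dict[str, int] = {}
        quals: dict[str, float] = {}
        for b in range(4):
            c = int(self.counts[position, b])
            if c:
                alleles[_BASES[b]] = c
                quals[_BASES[b]] = float(self.qual_sums[position, b]) / c
        for seq, c in self.insertions.get(position, {}).items():
            alleles["+" + seq] = c
        for seq, c in self.deletions.get(position, {}).items():
            alleles["-" + seq] = c
        return {"position": position, "alleles": alleles,
                "depth": int(self.depth[position]), "mean_quality": quals}


def build_pileup(alignments: list[PairAlignment], reference: AmpliconReference,
                 min_base_quality: int = 20) -> Pileup:
    """Tally every aligned base and indel event at its reference position.

    Bases below ``min_base_quality`` are excluded from the counts.
    Raises on alignments outside the reference (corrupt input).
    """
    L = len(reference)
    counts = np.zeros((L, 4), dtype=np.int32)
    qsums = np.zeros((L, 4), dtype=np.int64)
    insertions: dict[int, dict[str, int]] = {}
    deletions: dict[int, dict[str, int]] = {}
    n_reads = 0
    for pa in alignments:
        if not pa.mapped or pa.gene != reference.name:
            continue
        n_reads += 1
        for mate in pa.mates:
            codes = encode(mate.seq)
            qual = np.asarray(mate.qual, dtype=np.int64)
            if mate.start < 0 or mate.end > L:
                raise ValueError(f"alignment of {pa.pair_id} outside reference")
            for op, r, q, ln in mate.walk():
                if op == "M":
                    c = codes[q:q + ln]
                    quals = qual[q:q + ln]
                    keep = (quals >= min_base_quality) & (c < 4)
                    pos = np.arange(r, r + ln)[keep]
                    np.add.at(counts, (pos, c[keep]), 1)
                    np.add.at(qsums, (pos, c[keep]), quals[keep])
                elif op == "I":
                    if 0 < r < L:   # leading/trailing overhangs are not events
                        seq = mate.seq[q:q + ln]
                        d = insertions.setdefault(r, {})
                        d[seq] = d.get(seq, 0) + 1
                elif op == "D":
                    seq = reference.sequence[r:r + ln]
                    d = deletions.setdefault(r, {})
                    d[seq] = d.get(seq, 0) + 1
    return Pileup(reference, counts, qsums, insertions, deletions, n_reads)


@dataclass
class SiteCall:
    """Verdict for one site after the proportion-based filter.

    verdict is one of homozygous_ref, homozygous_alt, heterozygous,
    ambiguous, low_depth.  ``filtered_alleles`` lists alleles discarded
    as false positives (minor fraction < fp_max_fraction); a site is
    counted as filtered_false_positive when that list is non-empty.
    """

    position: int
    kind: str                       # 'snv' | 'ins' | 'del'
    ref_allele: str
    alleles: dict[str, int]
    depth: int
    minor_fraction: float
    verdict: str
    filtered_alleles: list[str] = field(default_factory=list)
    multi_allelic: bool = False

    @property
    def is_het(self) -> bool:
        return self.verdict == "heterozygous" and not self.multi_allelic

    @property
    def allele_pair(self) -> tuple[str, str]:
        """The two called alleles at a heterozygous site, by count (desc)."""
        top = sorted(self.alleles.items(), key=lambda kv: (-kv[1], kv[0]))[:2]
        return top[0][0], top[1][0]

    @property
    def alt_alleles(self) -> list[str]:
        return [a for a in self.alleles if a != self.ref_allele]

    @property
    def sort_key(self) -> tuple[int, str]:
        return (self.position, self.kind)


def _classify(position: int, kind: str, ref_allele: str, observed: dict[str, int],
              depth: int, het_min_fraction: float, fp_max_fraction: float,
              min_depth: int, het_min_count: int) -> SiteCall:
    if depth < min_depth:
        return SiteCall(position, kind, ref_allele, dict(observed), depth,
                        0.0, "low_depth")
    ranked = sorted(observed.items(), key=lambda kv: (-kv[1], kv[0]))
    major, major_n = ranked[0]
    minor_n = ranked[1][1] if len(ranked) > 1 else 0
    minor_fraction = minor_n / depth
    if minor_fraction < fp_max_fraction:
        kept = {major: major_n}
        dropped = [a for a, c in ranked[1:] if c > 0]
        verdict = "homozygous_ref" if major == ref_allele else "homozygous_alt"
        return SiteCall(position, kind, ref_allele, kept, depth,
                        minor_fraction, verdict, filtered_alleles=dropped)
    if minor_fraction < het_min_fraction or minor_n < het_min_count:
        return SiteCall(position, kind, ref_allele, dict(observed), depth,
                        minor_fraction, "ambiguous")
    kept = {a: c for a, c in ranked if c / depth >= fp_max_fraction}
    dropped = [a for a, c in ranked if 0 < c / depth < fp_max_fraction]
    return SiteCall(position, kind, ref_allele, kept, depth, minor_fraction,
                    "heterozygous", filtered_alleles=dropped,
                    multi_allelic=len(kept) > 2)


def call_site(pileup: Pileup, position: int, *, het_min_fraction: float = 0.2,
              fp_max_fraction: float = 0.1, min_depth: int = 10,
              het_min_count: int = 4) -> SiteCall:
    """Classify the base (SNV) column at one position."""
    observed = {b: int(c) for b, c in zip(_BASES, pileup.counts[position]) if c}
    depth = int(pileup.depth[position])
    ref = pileup.reference.sequence[position]
    if not observed:
        observed = {ref: 0}
    return _classify(position, "snv", ref, observed, depth,
                     het_min_fraction, fp_max_fraction, min_depth, het_min_count)


def call_sites(pileup: Pileup, het_min_fraction: float = 0.2,
               fp_max_fraction: float = 0.1, min_depth: int = 10,
               het_min_count: int = 4,
               positions: list[int] | None = None) -> list[SiteCall]:
    """Call every site with non-reference evidence, indel evidence or low
    depth.  Positions absent from the result are homozygous-reference at
    adequate depth.  Sorted by (position, kind)."""
    ref_codes = encode(pileup.reference.sequence)
    depth = pileup.depth
    L = len(ref_codes)
    if positions is None:
        safe = ref_codes.copy()
        safe[safe > 3] = 0
        nonref = (depth - pileup.counts[np.arange(L), safe]) > 0
        interesting = np.nonzero(nonref | (depth < min_depth))[0]
    else:
        interesting = np.asarray(positions, dtype=int)
    kw = dict(het_min_fraction=het_min_fraction, fp_max_fraction=fp_max_fraction,
              min_depth=min_depth, het_min_count=het_min_count)
    calls = [call_site(pileup, int(p), **kw) for p in interesting]

    for pos, byseq in sorted(pileup.insertions.items()):
        seq, c_ins = max(byseq.items(), key=lambda kv: (kv[1], kv[0]))
        d = int(depth[pos])            # reads with the insertion still match at pos
        observed = {"*": max(d - c_ins, 0), "+" + seq: c_ins}
        calls.append(_classify(pos, "ins", "*", observed, d, **kw))
    for pos, byseq in sorted(pileup.deletions.items()):
        seq, c_del = max(byseq.items(), key=lambda kv: (kv[1], kv[0]))
        d = int(depth[pos]) + c_del    # deleted reads carry no base at pos
        observed = {"*": int(depth[pos]), "-" + seq: c_del}
        calls.append(_classify(pos, "del", "*", observed, d, **kw))
    calls.sort(key=lambda c: c.sort_key)
    n_amb = sum(1 for c in calls if c.verdict == "ambiguous")
    if n_amb:
        logger.info("call_sites: %d ambiguous site(s) excluded from phasing", n_amb)
    return calls


def consensus_homozygous(site_calls: list[SiteCall], reference: AmpliconReference) -> dict:
    """Consensus sequence for a homozygous sample.

    Applies homozygous-alt substitutions and indels to the reference,
    emits N over low-depth runs, and reports positions that remained
    heterozygous (they are *not* auto-corrected).
    """
    pieces = list(reference.sequence)
    false_het: list[int] = []
    low_depth: list[int] = []
    for call in site_calls:
        if call.verdict == "low_depth":
            pieces[call.position] = "N"
            low_depth.append(call.position)
        elif call.verdict == "heterozygous":
            false_het.append(call.position)
        elif call.verdict == "homozygous_alt":
            major = max(call.alleles, key=call.alleles.get)
            if call.kind == "snv":
                pieces[call.position] = major
            elif call.kind == "ins":
                pieces[call.position] = major[1:] + pieces[call.position]
            elif call.kind == "del":
                for p in range(call.position, call.position + len(major) - 1):
                    if p < len(pieces):
                        pieces[p] = ""
    return {"sequence": "".join(pieces), "false_het_positions": sorted(set(false_het)),
            "low_depth_positions": low_depth}


def estimate_allelic_imbalance(site_calls: list[SiteCall]) -> dict | None:
    """Mean and max allelic ratio (1-f)/f over heterozygous sites.

    A perfectly balanced site (minor fraction 0.5) has ratio 1.0; the
    worst imbalance observed in real amplicons, minor fraction 0.227,
    gives ratio ~3.4.  Returns None when there is no heterozygous site.
    """
    fracs = [c.minor_fraction for c in site_calls if c.verdict == "heterozygous"]
    if not fracs:
        return None
    ratios = [(1.0 - f) / f for f in fracs]
    return {"mean_ratio": float(np.mean(ratios)), "max_ratio": float(np.max(ratios)),
            "n_sites": len(ratios)}


def write_sites_vcf(site_calls: list[SiteCall], reference: AmpliconReference,
                    path: str, sample: str = "sample") -> None:
    """SiteCalls as VCF v4.2 (1-based; FILTER carries the verdict)."""
    ref = reference.sequence
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={reference.name},length={len(ref)}>\n")
        for v in ("homozygous_alt", "heterozygous", "ambiguous", "low_depth"):
            fh.write(f'##FILTER=<ID={v},Description="{v}">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}\n")
        for c in site_calls:
            if c.verdict in ("homozygous_ref", "low_depth") or not c.alt_alleles:
                continue
            alt = c.alt_alleles[0]
            if c.kind == "snv":
                pos, r, a = c.position + 1, c.ref_allele, alt
            elif c.kind == "ins":
                pos, r = c.position, ref[c.position - 1]
                a = r + alt[1:]
            else:
                pos, r = c.position, ref[c.position - 1] + alt[1:]
                a = ref[c.position - 1]
            gt = "0/1" if c.verdict == "heterozygous" else "1/1"
            fh.write(f"{reference.name}\t{pos}\t.\t{r}\t{a}\t.\t{c.verdict}\t"
                     f"DP={c.depth}\tGT\t{gt}\n")
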
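"""Closest-allele assignment against a two-tier allele database.

The database mirrors the IMGT/HLA layout: a genomic tier of full gene
sequences and a cDNA tier of coding sequences, with colon-delimited
allele names (e.g. ``A*24:02:01:01``).  A haplotype query is first
searched against the genomic tier; only if nothing lies within the
mismatch tolerance (1 % of the query length) are its exons extracted,
merged into a coding sequence and searched against the cDNA tier.

Distance is edit distance with N-masked positions neutral (unit-cost
global alignment score with a wildcard), capped at the tolerance; a
length-difference prefilter skips hopeless entries.  Mismatch positions
for the single best entry come from the same alignment with traceback.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from Bio import Align
from Bio.Seq import Seq

from .consensus import HaplotypeSequence
from .reference import AmpliconReference

__all__ = ["AlleleDatabase", "AlleleHit", "extract_cds", "search_alleles",
           "classify_mismatches", "edit_distance_capped", "name_fields",
           "call_allele"]

logger = logging.getLogger(__name__)


@dataclass
class AlleleDatabase:
    """genomic: allele name -> full gene sequence; cdna: name -> CDS."""

    genomic: dict[str, str] = field(default_factory=dict)
    cdna: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.genomic = {n: s.upper() for n, s in self.genomic.items()}
        self.cdna = {n: s.upper() for n, s in self.cdna.items()}
        for tier in (self.genomic, self.cdna):
            for name, seq in tier.items():
                if not seq:
                    raise ValueError(f"empty sequence for allele {name}")

    @classmethod
    def from_fastas(cls, genomic_path: str | None, cdna_path: str | None) -> "AlleleDatabase":
        """Plain FASTA, allele name = first whitespace-delimited header
        token (an IMGT/HLA-style FASTA works unmodified)."""
        from Bio import SeqIO

        def load(path):
            if path is None:
                return {}
            return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}

        return cls(genomic=load(genomic_path), cdna=load(cdna_path))


def name_fields(allele: str) -> int:
    """Number of colon-delimited fields after the gene separator."""
    return len(allele.split("*")[-1].split(":"))


@dataclass
class AlleleHit:
    query_id: str
    allele: str
    tier: str                       # 'genomic' | 'cdna'
    mismatches: int
    exact: bool
    resolution: int                 # digit resolution = name fields x 2
    query_length: int
    mismatch_positions: list[tuple[int, str, str]] = field(default_factory=list)
    # (query position, entry base, query base); gaps excluded


_distance_aligner = Align.PairwiseAligner()
_distance_aligner.mode = "global"
_distance_aligner.match_score = 0
_distance_aligner.mismatch_score = -1
_distance_aligner.open_gap_score = -1
_distance_aligner.extend_gap_score = -1
_distance_aligner.wildcard = "N"


def edit_distance_capped(a: str, b: str, cap: int) -> int:
    """Edit distance between a and b, capped at cap+1; columns involving
    N are free (mismatch-neutral).  A length-difference prefilter skips
    hopeless entries; the distance itself is a unit-cost global
    alignment score (C implementation)."""
    if abs(len(a) - len(b)) > cap:
        return cap + 1
    d = int(-_distance_aligner.score(a, b))
    return min(d, cap + 1)


def extract_cds(hseq: HaplotypeSequence, reference: AmpliconReference) -> str:
    """Exon subsequences merged into a coding sequence.

    Works on the per-reference-position representation, so upstream
    indels never shift exon coordinates; Ns inside exons propagate.
    """
    parts = []
    for a, b in reference.exons:
        lo, hi = a - hseq.ref_offset, b - hseq.ref_offset
        if lo < 0 or hi > len(hseq.pieces):
            raise ValueError(f"exon ({a},{b}) outside haplotype sequence")
        parts.append("".join(hseq.pieces[lo:hi]))
    return "".join(parts)


def _tier_search(query: str, tier: dict[str, str], cap: int) -> tuple[str, int] | None:
    """Best (allele, distance) within cap; ties broken by most name
    fields, then lexicographic name."""
    best: tuple[str, int] | None = None
    # iteration order implements the tie-break: most name fields first,
    # then lexicographic, so a strict improvement test suffices
    for name in sorted(tier, key=lambda n: (-name_fields(n), n)):
        d = edit_distance_capped(query, tier[name], cap)
        if d <= cap and (best is None or d < best[1]):
            best = (name, d)
    return best


_mismatch_aligner = Align.PairwiseAligner()
_mismatch_aligner.mode = "global"
_mismatch_aligner.match_score = 0
_mismatch_aligner.mismatch_score = -1
_mismatch_aligner.open_gap_score = -1
_mismatch_aligner.extend_gap_score = -1
_mismatch_aligner.wildcard = "N"


def _mismatch_positions(entry: str, query: str) -> list[tuple[int, str, str]]:
    aln = _mismatch_aligner.align(entry, query)[0]
    out = []
    tblocks, qblocks = aln.aligned
    for (ts, te), (qs, qe) in zip(tblocks, qblocks):
        e = np.frombuffer(entry[ts:te].encode(), dtype=np.uint8)
        q = np.frombuffer(query[qs:qe].encode(), dtype=np.uint8)
        diff = np.nonzero((e != q) & (e != ord("N")) & (q != ord("N")))[0]
        for d in diff:
            out.append((int(qs + d), entry[ts + d], query[qs + d]))
    return out


def search_alleles(full_query: str, cds_query: str | None, db: AlleleDatabase,
                   max_mismatch_fraction: float = 0.01,
                   query_id: str = "query") -> AlleleHit | None:
    """Two-stage closest-allele search.

    Stage 1: full query vs the genomic tier, accepted iff the edit
    distance is within ``max_mismatch_fraction`` of the query length.
    Stage 2 (on failure): the coding sequence vs the cDNA tier, same
    rule.  Returns None if both stages fail.
    """
    if not full_query:
        raise ValueError("empty query")
    stages = [("genomic", full_query, db.genomic)]
    if cds_query:
        stages.append(("cdna", cds_query, db.cdna))
    for tier_name, query, tier in stages:
        if not tier:
            logger.warning("allele database %s tier is empty; stage skipped", tier_name)
            continue
        cap = math.ceil(max_mismatch_fraction * len(query))
        hit = _tier_search(query, tier, cap)
        if hit is None:
            continue
        allele, dist = hit
        positions = _mismatch_positions(tier[allele], query) if dist else []
        return AlleleHit(query_id=query_id, allele=allele, tier=tier_name,
                         mismatches=dist, exact=(dist == 0),
                         resolution=2 * name_fields(allele),
                         query_length=len(query), mismatch_positions=positions)
    return None


def classify_mismatches(hit: AlleleHit, hseq: HaplotypeSequence,
                        reference: AmpliconReference) -> dict:
    """Label each mismatch exonic/intronic (reference coordinates) and,
    when the gene model carries a reading frame and the hit is
    genomic-tier, flag exonic substitutions as (non)synonymous."""
    q2r = hseq.query_to_ref()
    per_site = []
    n_ex = n_in = 0
    cds_offsets = {}
    off = 0
    for a, b in reference.exons:
        cds_offsets[(a, b)] = off
        off += b - a
    ref_cds = "".join(reference.sequence[a:b] for a, b in reference.exons)
    for qpos, entry_base, query_base in hit.mismatch_positions:
        if hit.tier == "cdna":
            ref_pos = None
            exonic = True
            cds_off = qpos
        else:
            ref_pos = int(q2r[qpos]) if qpos < len(q2r) else None
            exonic = ref_pos is not None and reference.is_exonic(ref_pos)
            cds_off = None
            if exonic:
                for (a, b), o in cds_offsets.items():
                    if a <= ref_pos < b:
                        cds_off = o + (ref_pos - a)
                        break
        syn = None
        if exonic and cds_off is not None and reference.coding_frame is not None:
            c0 = 3 * ((cds_off - reference.coding_frame) // 3) + reference.coding_frame
            if 0 <= c0 and c0 + 3 <= len(ref_cds):
                codon = list(ref_cds[c0:c0 + 3])
                codon[cds_off - c0] = entry_base
                aa_entry = str(Seq("".join(codon)).translate())
                codon[cds_off - c0] = query_base
                aa_query = str(Seq("".join(codon)).translate())
                syn = aa_entry == aa_query
        n_ex += exonic
        n_in += not exonic
        per_site.append({"query_pos": qpos, "ref_pos": ref_pos, "exonic": bool(exonic),
                         "entry_base": entry_base, "query_base": query_base,
                         "synonymous": syn})
    return {"exonic": int(n_ex), "intronic": int(n_in), "sites": per_site}


def call_allele(hseq: HaplotypeSequence, reference: AmpliconReference,
                db: AlleleDatabase, max_mismatch_fraction: float = 0.01,
                query_id: str | None = None) -> AlleleHit | None:
    """Pipeline-facing wrapper: full sequence first, exon-merged CDS on
    fallback."""
    cds = extract_cds(hseq, reference)
    qid = query_id or f"{hseq.gene}|hap{hseq.hap_index}"
    return search_alleles(hseq.sequence, cds, db, max_mismatch_fraction, qid)
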
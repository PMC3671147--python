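"""Permissive read-pair alignment against amplicon references.

Each mate is placed at its best edit-distance location on either strand
and kept when mismatches + gap bases stay within the per-read budget
(80 for a full 250 bp read, scaled proportionally for trimmed reads).
Placement is k-mer seeded with a numpy Hamming shortcut on clean
diagonals and a windowed gapped alignment (Bio.Align.PairwiseAligner,
unit edit costs) otherwise; seedless reads fall back to an exhaustive
Hamming scan, so even a read with 80 substitutions finds its origin.

Externally produced SAM (e.g. BWA output) can be ingested instead via
:func:`ingest_sam`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from Bio import Align
from numpy.lib.stride_tricks import sliding_window_view

from .qc import ReadPair
from .reference import AmpliconReference
from .simdata import revcomp

__all__ = ["MateAlignment", "PairAlignment", "ReadAligner", "ingest_sam",
           "alignment_stats"]

logger = logging.getLogger(__name__)

_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


def encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


@dataclass
class MateAlignment:
    """One mate placed on a reference; seq/qual are stored in reference
    (forward) orientation, as in SAM."""

    gene: str
    start: int
    strand: str                     # '+' or '-'
    cigar: list[tuple[str, int]]    # ops in 'MIDS', query-consuming order
    edits: int                      # mismatches + gap bases
    seq: str
    qual: np.ndarray

    @property
    def end(self) -> int:
        return self.start + sum(ln for op, ln in self.cigar if op in "MD")

    def walk(self):
        """Yield (op, ref_pos, read_pos, length) for each CIGAR op."""
        r, q = self.start, 0
        for op, ln in self.cigar:
            yield op, r, q, ln
            if op in "MD":
                r += ln
            if op in "MIS":
                q += ln


@dataclass
class PairAlignment:
    pair_id: str
    gene: str | None
    mate1: MateAlignment | None
    mate2: MateAlignment | None
    mapped: bool
    proper: bool
    pair: ReadPair | None = field(default=None, repr=False)

    @property
    def mates(self) -> list[MateAlignment]:
        return [m for m in (self.mate1, self.mate2) if m is not None]


def _make_edit_aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = 0
    a.mismatch_score = -1
    # slight gap-open surcharge keeps multi-base indels contiguous
    # (unit costs would happily split a 3 bp deletion into 1+2)
    a.open_internal_insertion_score = -1.5
    a.extend_internal_insertion_score = -1
    a.open_internal_deletion_score = -1.5
    a.extend_internal_deletion_score = -1
    # free end gaps on the target (window) side: the read floats
    a.open_end_deletion_score = 0
    a.extend_end_deletion_score = 0
    a.open_end_insertion_score = -1
    a.extend_end_insertion_score = -1
    return a


def _cigar_from_blocks(tblocks, qblocks, qlen: int) -> tuple[int, list[tuple[str, int]]]:
    """Convert PairwiseAligner aligned blocks (target=window, query=read)
    into (window_start, cigar)."""
    cigar: list[tuple[str, int]] = []
    t0 = int(tblocks[0][0])
    q_prev = 0
    t_prev = t0
    if int(qblocks[0][0]) > 0:
        cigar.append(("I", int(qblocks[0][0])))
        q_prev = int(qblocks[0][0])
    for (ts, te), (qs, qe) in zip(tblocks, qblocks):
        ts, te, qs, qe = int(ts), int(te), int(qs), int(qe)
        if qs > q_prev:
            cigar.append(("I", qs - q_prev))
        if ts > t_prev:
            cigar.append(("D", ts - t_prev))
        cigar.append(("M", te - ts))
        t_prev, q_prev = te, qe
    if q_prev < qlen:
        cigar.append(("I", qlen - q_prev))
    merged: list[tuple[str, int]] = []
    for op, ln in cigar:
        if merged and merged[-1][0] == op:
            merged[-1] = (op, merged[-1][1] + ln)
        else:
            merged.append((op, ln))
    return t0, merged


def _count_edits(ref_codes: np.ndarray, read_codes: np.ndarray, start: int,
                 cigar: list[tuple[str, int]]) -> int:
    edits = 0
    r, q = start, 0
    for op, ln in cigar:
        if op == "M":
            edits += int(np.count_nonzero(ref_codes[r:r + ln] != read_codes[q:q + ln]))
            r += ln
            q += ln
        elif op == "D":
            edits += ln
            r += ln
        else:  # I / S
            edits += ln
            q += ln
    return edits


def _left_normalize(ref: str, read: str, start: int,
                    cigar: list[tuple[str, int]]) -> list[tuple[str, int]]:
    """Shift indels left across preceding matches while the moved base is
    identical (canonical left-aligned representation in repeats)."""
    cig = list(cigar)
    changed = True
    while changed:
        changed = False
        r, q = start, 0
        pos = []  # (index, ref_pos, read_pos)
        for idx, (op, ln) in enumerate(cig):
            pos.append((idx, r, q))
            if op in "MD":
                r += ln
            if op in "MIS":
                q += ln
        for idx in range(1, len(cig) - 1):
            op, ln = cig[idx]
            if op not in "ID" or cig[idx - 1][0] != "M" or cig[idx - 1][1] == 0:
                continue
            _, rpos, qpos = pos[idx]
            if op == "D":
                movable = ref[rpos + ln - 1] == ref[rpos - 1]
            else:
                movable = read[qpos + ln - 1] == read[qpos - 1]
            if movable and idx + 1 < len(cig) and cig[idx + 1][0] == "M":
                cig[idx - 1] = ("M", cig[idx - 1][1] - 1)
                cig[idx + 1] = ("M", cig[idx + 1][1] + 1)
                changed = True
                break
    return [(op, ln) for op, ln in cig if ln > 0]


class ReadAligner:
    """Edit-distance aligner for read pairs over one or more amplicons."""

    def __init__(self, references: list[AmpliconReference], k: int = 15,
                 max_mismatch: int = 80, fragment_max: int = 2000,
                 seed_stride: int = 7, pad: int = 24):
        self.references = list(references)
        self.k = k
        self.max_mismatch = max_mismatch
        self.fragment_max = fragment_max
        self.seed_stride = seed_stride
        self.pad = pad
        self._seqs = [r.sequence for r in references]
        self._codes = [encode(r.sequence) for r in references]
        self._aligner = _make_edit_aligner()
        self.index: dict[str, list[tuple[int, int]]] = {}
        for gi, seq in enumerate(self._seqs):
            for p in range(0, len(seq) - k + 1):
                self.index.setdefault(seq[p:p + k], []).append((gi, p))

    # -- candidate generation -------------------------------------------------

    def _seed_clusters(self, seq: str, stride: int) -> dict[int, list[list[int]]]:
        """gene index -> diagonal clusters (sorted diag lists)."""
        k = self.k
        hits: dict[int, list[int]] = {}
        for off in range(0, len(seq) - k + 1, stride):
            for gi, p in self.index.get(seq[off:off + k], ()):
                hits.setdefault(gi, []).append(p - off)
        clusters: dict[int, list[list[int]]] = {}
        for gi, diags in hits.items():
            diags.sort()
            cl: list[list[int]] = [[diags[0]]]
            for d in diags[1:]:
                if d - cl[-1][-1] <= self.pad:
                    cl[-1].append(d)
                else:
                    cl.append([d])
            clusters[gi] = sorted(cl, key=len, reverse=True)[:3]
        return clusters

    def _hamming_at(self, gi: int, diag: int, codes: np.ndarray) -> int | None:
        ref = self._codes[gi]
        if diag < 0 or diag + len(codes) > len(ref):
            return None
        return int(np.count_nonzero(ref[diag:diag + len(codes)] != codes))

    def _gapped(self, gi: int, dmin: int, dmax: int, seq: str):
        """Windowed gapped alignment; returns (start, cigar, edits) or None."""
        ref = self._seqs[gi]
        w0 = max(0, dmin - self.pad)
        w1 = min(len(ref), dmax + len(seq) + self.pad)
        window = ref[w0:w1]
        if len(window) < len(seq):
            return None
        aln = self._aligner.align(window, seq)[0]
        tblocks, qblocks = aln.aligned
        if len(tblocks) == 0:
            return None
        wstart, cigar = _cigar_from_blocks(tblocks, qblocks, len(seq))
        start = w0 + wstart
        cigar = _left_normalize(ref, seq, start, cigar)
        edits = _count_edits(self._codes[gi], encode(seq), start, cigar)
        return start, cigar, edits

    def _candidates_oriented(self, seq: str, genes: set[int] | None):
        """Best (edits, gene_idx, start, cigar) per gene for one orientation."""
        codes = encode(seq)
        out: dict[int, tuple[int, int, list[tuple[str, int]]]] = {}
        clusters = self._seed_clusters(seq, self.seed_stride)
        if not clusters:
            clusters = self._seed_clusters(seq, 1)
        for gi, cls in clusters.items():
            if genes is not None and gi not in genes:
                continue
            best = None
            for cl in cls:
                dmin, dmax = cl[0], cl[-1]
                if dmin == dmax:
                    ham = self._hamming_at(gi, dmin, codes)
                    if ham is not None and ham <= 6:
                        cand = (ham, dmin, [("M", len(seq))])
                        if best is None or cand[0] < best[0]:
                            best = cand
                        continue
                g = self._gapped(gi, dmin, dmax, seq)
                if g is not None:
                    cand = (g[2], g[0], g[1])
                    if best is None or cand[0] < best[0]:
                        best = cand
            if best is not None:
                out[gi] = best
        return out

    def _full_scan(self, seq: str, genes: set[int] | None):
        """Exhaustive Hamming scan (seedless fallback), per gene."""
        codes = encode(seq)
        out: dict[int, tuple[int, int, list[tuple[str, int]]]] = {}
        for gi, ref in enumerate(self._codes):
            if genes is not None and gi not in genes:
                continue
            if len(ref) < len(codes):
                logger.warning("reference %s shorter than read", self.references[gi].name)
                continue
            windows = sliding_window_view(ref, len(codes))
            ham = np.count_nonzero(windows != codes, axis=1)
            best_off = int(np.argmin(ham))
            best = (int(ham[best_off]), best_off, [("M", len(seq))])
            g = self._gapped(gi, best_off, best_off, seq)
            if g is not None and g[2] < best[0]:
                best = (g[2], g[0], g[1])
            out[gi] = best
        return out

    # -- public API -----------------------------------------------------------

    def budget(self, read_length: int) -> int:
        """Edit budget, scaled from 80 per 250 bp."""
        return int(self.max_mismatch * read_length / 250)

    def align_mate(self, seq: str, qual: np.ndarray,
                   genes: set[int] | None = None,
                   per_gene: bool = False):
        """Best placement of one mate over both strands.

        Returns a MateAlignment (or None if nothing within budget); with
        ``per_gene=True`` returns a dict gene_idx -> MateAlignment of the
        per-gene best placements within budget.
        """
        budget = self.budget(len(seq))
        results: dict[int, MateAlignment] = {}
        seedless = True
        for strand, s, q in (("+", seq, qual), ("-", revcomp(seq), qual[::-1])):
            cands = self._candidates_oriented(s, genes)
            if cands:
                seedless = False
            for gi, (edits, start, cigar) in cands.items():
                if gi not in results or edits < results[gi].edits:
                    results[gi] = MateAlignment(self.references[gi].name, start,
                                                strand, cigar, edits, s, q)
        if seedless:
            for strand, s, q in (("+", seq, qual), ("-", revcomp(seq), qual[::-1])):
                for gi, (edits, start, cigar) in self._full_scan(s, genes).items():
                    if gi not in results or edits < results[gi].edits:
                        results[gi] = MateAlignment(self.references[gi].name, start,
                                                    strand, cigar, edits, s, q)
        results = {gi: m for gi, m in results.items() if m.edits <= budget}
        if per_gene:
            return results
        if not results:
            return None
        gi = min(results, key=lambda g: (results[g].edits, g))
        return results[gi]

    def _pair_from_mates(self, pair: ReadPair, m1, m2) -> PairAlignment:
        if m1 is None or m2 is None or m1.gene != m2.gene:
            return PairAlignment(pair.id, None, m1, m2, False, False, pair)
        proper = (m1.strand != m2.strand)
        if proper:
            fwd, rev = (m1, m2) if m1.strand == "+" else (m2, m1)
            span = max(m1.end, m2.end) - min(m1.start, m2.start)
            proper = fwd.start <= rev.end and span <= self.fragment_max
        return PairAlignment(pair.id, m1.gene, m1, m2, proper, proper, pair)

    def align_pair(self, pair: ReadPair, genes: set[int] | None = None) -> PairAlignment:
        """Align both mates; pair is mapped iff both mates map to the same
        gene in proper forward-reverse orientation within fragment_max."""
        m1 = self.align_mate(pair.seq1, pair.qual1, genes)
        m2 = self.align_mate(pair.seq2, pair.qual2, genes)
        if (m1 is None or m2 is None or m1.gene != m2.gene):
            # retry constrained to the better mate's gene before giving up
            anchor = m1 or m2
            if anchor is not None:
                gi = {self._gene_index(anchor.gene)}
                m1 = m1 if m1 and m1.gene == anchor.gene else self.align_mate(
                    pair.seq1, pair.qual1, gi)
                m2 = m2 if m2 and m2.gene == anchor.gene else self.align_mate(
                    pair.seq2, pair.qual2, gi)
        return self._pair_from_mates(pair, m1, m2)

    def _gene_index(self, name: str) -> int:
        return next(i for i, r in enumerate(self.references) if r.name == name)

    def assign_gene(self, pair: ReadPair, margin: int = 5) -> str | None:
        """Gene with strictly lowest total pair mismatch count; ``None``
        ('ambiguous') on tie or when the second best is within margin."""
        per1 = self.align_mate(pair.seq1, pair.qual1, per_gene=True)
        per2 = self.align_mate(pair.seq2, pair.qual2, per_gene=True)
        totals = {gi: per1[gi].edits + per2[gi].edits
                  for gi in set(per1) & set(per2)}
        if not totals:
            return None
        ranked = sorted(totals.items(), key=lambda kv: (kv[1], kv[0]))
        if len(ranked) > 1 and ranked[1][1] - ranked[0][1] <= margin:
            return None
        return self.references[ranked[0][0]].name


def ingest_sam(path: str, references: list[AmpliconReference],
               pairs_by_id: dict[str, ReadPair] | None = None) -> tuple[list[PairAlignment], dict]:
    """Ingest externally aligned reads (SAM v1).

    Mates are reunited by query name; unmapped, secondary and
    supplementary records are dropped; 1-based POS becomes 0-based.
    Returns (pair alignments, counters).
    """
    import pysam

    names = {r.name: r for r in references}
    by_query: dict[str, dict[int, MateAlignment]] = {}
    counters = {"records": 0, "dropped_unpaired": 0, "dropped_unmapped": 0}
    opmap = {0: "M", 7: "M", 8: "M", 1: "I", 2: "D", 4: "S"}
    with pysam.AlignmentFile(path, "r", check_sq=False) as fh:
        for rec in fh:
            counters["records"] += 1
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                counters["dropped_unmapped"] += 1
                continue
            gene = rec.reference_name
            if gene not in names:
                raise ValueError(f"unknown reference name in SAM: {gene}")
            cigar = []
            for op, ln in rec.cigartuples or []:
                if op in (5, 6):
                    continue
                if op not in opmap:
                    raise ValueError(f"unsupported CIGAR op {op} in {rec.query_name}")
                cigar.append((opmap[op], ln))
            qual = np.array(rec.query_qualities or [30] * len(rec.query_sequence),
                            dtype=np.int16)
            mate = MateAlignment(
                gene=gene, start=rec.reference_start,
                strand="-" if rec.is_reverse else "+",
                cigar=cigar, edits=int(rec.get_tag("NM")) if rec.has_tag("NM") else 0,
                seq=rec.query_sequence.upper(), qual=qual)
            by_query.setdefault(rec.query_name, {})[2 if rec.is_read2 else 1] = mate
    out: list[PairAlignment] = []
    for qname, mates in by_query.items():
        if len(mates) != 2:
            counters["dropped_unpaired"] += 1
            continue
        m1, m2 = mates[1], mates[2]
        pair = pairs_by_id.get(qname) if pairs_by_id else None
        gene = m1.gene if m1.gene == m2.gene else None
        ok = gene is not None
        out.append(PairAlignment(qname, gene, m1, m2, ok, ok, pair))
    if counters["dropped_unpaired"]:
        logger.info("ingest_sam: dropped %d pairs with a missing mate",
                    counters["dropped_unpaired"])
    return out, counters


def alignment_stats(alignments: list[PairAlignment],
                    reference: AmpliconReference) -> dict:
    """Mapping rate and depth over one reference.

    mean_depth = total aligned (M) bases / reference length; the
    per-position depth profile comes from the alignment intervals.
    """
    L = len(reference)
    depth = np.zeros(L + 1, dtype=np.int64)
    n_mapped = 0
    for pa in alignments:
        if not pa.mapped or pa.gene != reference.name:
            continue
        n_mapped += 1
        for m in pa.mates:
            for op, r, q, ln in m.walk():
                if op == "M":
                    depth[r] += 1
                    depth[min(r + ln, L)] -= 1
    profile = np.cumsum(depth[:-1])
    total = len(alignments)
    return {
        "mapped_fraction": (n_mapped / total) if total else 0.0,
        "mean_depth": float(profile.sum()) / L if L else 0.0,
        "depth": profile,
        "n_pairs": total,
        "n_mapped": n_mapped,
    }
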
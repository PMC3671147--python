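"""Read-backed phasing: informative pairs, site links, greedy tiling.

The phasing evidence unit is the *informative pair*: a paired-end read
observing alleles at two or more heterozygous sites.  In strict mode
(default, faithful to the assay's description) each mate must cover at
least one het site; general mode accepts any pair covering two sites
regardless of which mate carries them.

Observed allele combinations at consecutive het sites are tallied into
links; greedy left-to-right tiling then extends a phase block while each
link has enough support and a consistent majority, seeding haplotype 1
with the reference allele (else the lexicographically smaller one).
Majority at a link is taken over the *orientation* a combination implies
(the two cis combinations of one configuration vote together), so a
perfectly consistent link can never be read as a tie.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

from .align import PairAlignment
from .variants import SiteCall

__all__ = ["LocalHaplotype", "PhaseBlock", "PhasedAssignment",
           "observe_pair_alleles", "extract_informative_pairs", "link_sites",
           "tile_haplotypes", "phase_report"]

logger = logging.getLogger(__name__)


@dataclass
class LocalHaplotype:
    """Alleles observed at >= 2 het sites by one read pair."""

    pair_id: str
    observations: list[tuple[int, str]]     # (site index, allele), sites increasing
    mates_spanned: str                      # 'one' | 'both'


def _mate_site_alleles(mate, sites: list[SiteCall], min_base_quality: int) -> dict[int, str]:
    """Observed allele per site index for one aligned mate.

    SNV sites report the aligned base (quality-filtered); indel sites
    report '+SEQ'/'-SEQ' when the mate carries the event and '*' when it
    aligns contiguously through the site.  Alleles outside the site's
    called allele set are dropped.
    """
    obs: dict[int, str] = {}
    ins_at: dict[int, str] = {}
    del_at: dict[int, tuple[int, str]] = {}
    m_cover: list[tuple[int, int, int]] = []       # (ref_start, ref_end, read_start)
    for op, r, q, ln in mate.walk():
        if op == "M":
            m_cover.append((r, r + ln, q))
        elif op == "I":
            ins_at[r] = mate.seq[q:q + ln]
        elif op == "D":
            del_at[r] = (ln, "")
    for idx, site in enumerate(sites):
        p = site.position
        if site.kind == "snv":
            for r0, r1, q0 in m_cover:
                if r0 <= p < r1:
                    if mate.qual[q0 + (p - r0)] >= min_base_quality:
                        obs[idx] = mate.seq[q0 + (p - r0)]
                    break
        elif site.kind == "ins":
            if p in ins_at:
                obs[idx] = "+" + ins_at[p]
            else:
                covers = any(r0 <= p - 1 and p < r1 for r0, r1, _ in m_cover)
                if covers:
                    obs[idx] = "*"
        else:  # del
            alt = next(a for a in site.alleles if a.startswith("-"))
            dlen = len(alt) - 1
            if p in del_at and del_at[p][0] == dlen:
                obs[idx] = alt
            else:
                covers = any(r0 <= p and p + dlen <= r1 for r0, r1, _ in m_cover)
                if covers and p not in del_at:
                    obs[idx] = "*"
    return {i: a for i, a in obs.items() if a in sites[i].alleles}


def observe_pair_alleles(pa: PairAlignment, sites: list[SiteCall],
                         min_base_quality: int = 20) -> tuple[dict[int, str], list[int]]:
    """Merge both mates' site observations; returns (site->allele,
    per-mate site counts).  Sites where the mates disagree are dropped."""
    per_mate = [(_mate_site_alleles(m, sites, min_base_quality) if m else {})
                for m in (pa.mate1, pa.mate2)]
    merged: dict[int, str] = {}
    for obs in per_mate:
        for i, a in obs.items():
            if i in merged and merged[i] != a:
                merged[i] = ""                  # intra-pair conflict
            elif i not in merged:
                merged[i] = a
    merged = {i: a for i, a in merged.items() if a}
    return merged, [len(o) for o in per_mate]


def extract_informative_pairs(alignments: list[PairAlignment],
                              sites: list[SiteCall], mode: str = "strict",
                              min_base_quality: int = 20) -> list[LocalHaplotype]:
    """Informative pairs over the called heterozygous sites.

    strict: each mate covers >= 1 het site (and the pair >= 2 distinct);
    general: the pair covers >= 2 distinct het sites on any mate.
    """
    if mode not in ("strict", "general"):
        raise ValueError(f"unknown mode {mode!r}")
    out: list[LocalHaplotype] = []
    for pa in alignments:
        if not pa.mapped:
            continue
        merged, mate_counts = observe_pair_alleles(pa, sites, min_base_quality)
        if len(merged) < 2:
            continue
        if mode == "strict" and min(mate_counts) < 1:
            continue
        spanned = "both" if min(mate_counts) >= 1 else "one"
        out.append(LocalHaplotype(pa.pair_id, sorted(merged.items()), spanned))
    return out


def link_sites(local_haps: list[LocalHaplotype]) -> dict[tuple[int, int], Counter]:
    """Counts of observed allele combinations at consecutive het sites.

    For every local haplotype and every *adjacent in the global site
    list* pair of sites it covers, the observed (allele_i, allele_j)
    combination is counted.  Links with zero observations mark phase
    block boundaries downstream.
    """
    links: dict[tuple[int, int], Counter] = {}
    for lh in local_haps:
        obs = dict(lh.observations)
        idxs = sorted(obs)
        for i in idxs:
            j = i + 1
            if j in obs:
                links.setdefault((i, j), Counter())[(obs[i], obs[j])] += 1
    return links


@dataclass
class PhaseBlock:
    site_indices: list[int]
    positions: list[int]
    hap1_alleles: list[str]
    hap2_alleles: list[str]
    link_support: list[int] = field(default_factory=list)
    link_conflict: list[float] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.site_indices)


@dataclass
class PhasedAssignment:
    blocks: list[PhaseBlock]
    unphased_sites: list[int]               # site indices
    sites: list[SiteCall]

    @property
    def phased_fraction(self) -> float:
        total = len(self.sites)
        if total == 0:
            return 1.0
        return sum(len(b) for b in self.blocks) / total

    def block_of_site(self) -> dict[int, int]:
        return {i: bi for bi, b in enumerate(self.blocks) for i in b.site_indices}


def _site_allele_pair(site: SiteCall) -> tuple[str, str]:
    """(hap1 seed allele, other): reference allele first when called,
    else lexicographically smaller."""
    a, b = site.allele_pair
    if site.ref_allele in (a, b):
        first = site.ref_allele
    else:
        first = min(a, b)
    second = b if first == a else a
    return first, second


def tile_haplotypes(links: dict[tuple[int, int], Counter], sites: list[SiteCall],
                    min_link_support: int = 2, max_conflict: float = 0.2) -> PhasedAssignment:
    """Greedy left-to-right tiling of site links into phase blocks.

    A block extends across link (i, i+1) iff the link has at least
    ``min_link_support`` observations, a strict orientation majority,
    and conflict fraction (1 - majority/total) <= ``max_conflict``.
    Otherwise the block is closed and a new one seeded at the next site.
    Runs of length 1 are reported as unphased sites, except in the
    degenerate single-het-site case which forms one 1-site block.
    """
    blocks: list[PhaseBlock] = []
    n = len(sites)
    if n == 0:
        return PhasedAssignment([], [], sites)
    i = 0
    while i < n:
        a1, a2 = _site_allele_pair(sites[i])
        block = PhaseBlock([i], [sites[i].position], [a1], [a2])
        while block.site_indices[-1] + 1 < n:
            j = block.site_indices[-1]
            combos = links.get((j, j + 1))
            if not combos:
                break
            cur1, cur2 = block.hap1_alleles[-1], block.hap2_alleles[-1]
            nxt1, nxt2 = _site_allele_pair(sites[j + 1])
            votes: Counter = Counter()
            for (x, y), c in combos.items():
                if y not in (nxt1, nxt2):
                    continue
                if x == cur1:
                    votes[y] += c
                elif x == cur2:
                    votes[nxt2 if y == nxt1 else nxt1] += c
            total = sum(votes.values())
            if total < min_link_support:
                break
            (best, best_n), = votes.most_common(1)
            if best_n * 2 <= total:            # no strict majority
                break
            conflict = 1.0 - best_n / total
            if conflict > max_conflict:
                break
            block.site_indices.append(j + 1)
            block.positions.append(sites[j + 1].position)
            block.hap1_alleles.append(best)
            block.hap2_alleles.append(nxt2 if best == nxt1 else nxt1)
            block.link_support.append(total)
            block.link_conflict.append(conflict)
        blocks.append(block)
        i = block.site_indices[-1] + 1
    if n > 1:
        unphased = [b.site_indices[0] for b in blocks if len(b) == 1]
        blocks = [b for b in blocks if len(b) > 1]
    else:
        unphased = []
    if unphased:
        logger.info("tile_haplotypes: %d unphased singleton site(s)", len(unphased))
    return PhasedAssignment(blocks, unphased, sites)


def phase_report(assignment: PhasedAssignment) -> dict:
    """Deterministic phasing summary."""
    conflicts = [c for b in assignment.blocks for c in b.link_conflict]
    supports = [s for b in assignment.blocks for s in b.link_support]
    return {
        "n_sites": len(assignment.sites),
        "n_blocks": len(assignment.blocks),
        "n_unphased": len(assignment.unphased_sites),
        "phased_fraction": assignment.phased_fraction,
        "mean_link_support": (sum(supports) / len(supports)) if supports else 0.0,
        "max_link_conflict": max(conflicts, default=0.0),
        "block_spans": [(b.positions[0], b.positions[-1]) for b in assignment.blocks],
    }
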
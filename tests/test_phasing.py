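"""Informative-pair extraction, site links, greedy tiling vs brute force."""

import itertools
from collections import Counter

import numpy as np
import pytest

import hlaphase as hp
from hlaphase.align import MateAlignment, PairAlignment
from hlaphase.phasing import (LocalHaplotype, extract_informative_pairs,
                              link_sites, phase_report, tile_haplotypes)
from hlaphase.variants import SiteCall


def _site(pos, a, b, ref=None, kind="snv"):
    ref_allele = ref if ref is not None else a
    return SiteCall(pos, kind, ref_allele, {a: 50, b: 50}, 100, 0.5, "heterozygous")


def _ref(seq, name="R"):
    return hp.AmpliconReference(name, seq)


def _pair_cov(ref, pid, s1, seq1, s2=None, seq2=None):
    def mk(start, seq):
        return MateAlignment(ref.name, start, "+", [("M", len(seq))], 0, seq,
                             np.full(len(seq), 35, dtype=np.int16))
    m1 = mk(s1, seq1)
    m2 = mk(s2, seq2) if seq2 is not None else None
    return PairAlignment(pid, ref.name, m1, m2, True, True)


class TestExtractInformative:
    def setup_method(self):
        self.ref = _ref("A" * 60)
        self.sites = [_site(10, "A", "G"), _site(30, "A", "T"), _site(50, "A", "C")]

    def test_pair_covering_no_sites_not_informative(self):
        pa = _pair_cov(self.ref, "p", 15, "A" * 10)
        assert extract_informative_pairs([pa], self.sites) == []

    def test_sites_on_both_mates_informative_in_both_modes(self):
        pa = _pair_cov(self.ref, "p", 5, "A" * 10, 25, "A" * 10)
        for mode in ("strict", "general"):
            (lh,) = extract_informative_pairs([pa], self.sites, mode=mode)
            assert [i for i, _ in lh.observations] == [0, 1]
            assert lh.mates_spanned == "both"

    def test_single_mate_multisite_only_general(self):
        pa = _pair_cov(self.ref, "p", 5, "A" * 30, 40, "T" * 5)
        assert extract_informative_pairs([pa], self.sites, mode="strict") == []
        (lh,) = extract_informative_pairs([pa], self.sites, mode="general")
        assert lh.mates_spanned == "one"

    def test_uncalled_allele_dropped(self):
        # mate shows 'C' at site 0 whose called alleles are {A, G}
        seq = "A" * 4 + "C" + "A" * 5
        pa = _pair_cov(self.ref, "p", 6, seq, 25, "A" * 10)
        out = extract_informative_pairs([pa], self.sites)
        assert out == [] or all(i != 0 for lh in out for i, _ in lh.observations)


class TestLinkSites:
    def test_single_local_hap_counts(self):
        lh = LocalHaplotype("p", [(0, "A"), (1, "G")], "both")
        links = link_sites([lh])
        assert links == {(0, 1): Counter({("A", "G"): 1})}

    def test_nonadjacent_sites_not_linked(self):
        lh = LocalHaplotype("p", [(0, "A"), (2, "C")], "both")
        assert link_sites([lh]) == {}

    def test_error_free_sim_only_cis_combinations(self, het_world, het_mapped):
        _, ref, truth, _ = het_world
        pile = hp.build_pileup(het_mapped, ref)
        sites = [c for c in hp.call_sites(pile) if c.is_het]
        lhs = extract_informative_pairs(het_mapped, sites)
        links = link_sites(lhs)
        truth_allele = {}
        for v in truth.variant_sites:
            a2 = v.alt_allele if v.kind == "snv" else v.alt_allele
            truth_allele[(v.position, v.kind)] = (v.ref_allele if v.kind == "snv" else "*", a2)
        for (i, j), combos in links.items():
            t_i = truth_allele[(sites[i].position, sites[i].kind)]
            t_j = truth_allele[(sites[j].position, sites[j].kind)]
            cis = {(t_i[0], t_j[0]), (t_i[1], t_j[1])}
            discordant = sum(c for combo, c in combos.items() if combo not in cis)
            # a read whose end clips an indel can misreport that site at a
            # low rate; every such minority never threatens the 0.2 budget
            assert discordant / sum(combos.values()) < 0.08


class TestTileHaplotypes:
    def test_single_site_seeds_reference_allele(self):
        sites = [_site(10, "G", "A", ref="A")]
        asn = tile_haplotypes({}, sites)
        assert len(asn.blocks) == 1
        assert asn.blocks[0].hap1_alleles == ["A"]
        assert asn.blocks[0].hap2_alleles == ["G"]
        assert asn.phased_fraction == 1.0

    def test_nonreference_seed_lexicographic(self):
        sites = [_site(10, "T", "G", ref="A")]
        asn = tile_haplotypes({}, sites)
        assert asn.blocks[0].hap1_alleles == ["G"]

    def test_three_sites_consistent_links_single_block(self):
        sites = [_site(10, "A", "G"), _site(20, "C", "T", ref="C"),
                 _site(30, "A", "T")]
        links = {(0, 1): Counter({("A", "C"): 5, ("G", "T"): 4}),
                 (1, 2): Counter({("C", "A"): 6, ("T", "T"): 3})}
        asn = tile_haplotypes(links, sites)
        assert len(asn.blocks) == 1
        assert asn.blocks[0].hap1_alleles == ["A", "C", "A"]
        assert asn.blocks[0].hap2_alleles == ["G", "T", "T"]

    def test_conflict_thresholds(self):
        sites = [_site(10, "A", "G"), _site(20, "C", "T", ref="C")]
        ok = {(0, 1): Counter({("A", "C"): 9, ("A", "T"): 1})}
        asn = tile_haplotypes(ok, sites)
        assert len(asn.blocks) == 1
        assert asn.blocks[0].link_conflict == [pytest.approx(0.1)]
        bad = {(0, 1): Counter({("A", "C"): 6, ("A", "T"): 4})}
        asn = tile_haplotypes(bad, sites)
        assert len(asn.blocks) == 0 and len(asn.unphased_sites) == 2

    def test_low_support_breaks_block(self):
        sites = [_site(10, "A", "G"), _site(20, "C", "T", ref="C")]
        weak = {(0, 1): Counter({("A", "C"): 1})}
        asn = tile_haplotypes(weak, sites, min_link_support=2)
        assert len(asn.blocks) == 0
        asn = tile_haplotypes(weak, sites, min_link_support=1)
        assert len(asn.blocks) == 1

    def test_complementarity_invariant(self, het_result):
        for b in het_result.assignment.blocks:
            for a1, a2 in zip(b.hap1_alleles, b.hap2_alleles):
                assert a1 != a2

    def test_order_insensitivity(self, het_world, het_mapped):
        _, ref, _, _ = het_world
        pile = hp.build_pileup(het_mapped, ref)
        sites = [c for c in hp.call_sites(pile) if c.is_het]
        lhs = extract_informative_pairs(het_mapped, sites)
        fwd = tile_haplotypes(link_sites(lhs), sites)
        rev = tile_haplotypes(link_sites(list(reversed(lhs))), sites)
        assert [b.hap1_alleles for b in fwd.blocks] == [b.hap1_alleles for b in rev.blocks]


def _brute_force_max_agreement(links, sites):
    """Exhaustive 2^n maximum link-agreement phasing (n <= 12)."""
    n = len(sites)
    pairs = [s.allele_pair for s in sites]
    best = -1
    for choice in itertools.product((0, 1), repeat=n):
        hap1 = [pairs[i][choice[i]] for i in range(n)]
        hap2 = [pairs[i][1 - choice[i]] for i in range(n)]
        score = 0
        for (i, j), combos in links.items():
            for (x, y), c in combos.items():
                if (x, y) in ((hap1[i], hap1[j]), (hap2[i], hap2[j])):
                    score += c
        best = max(best, score)
    return best


def _greedy_agreement(asn, links):
    hap1 = {}
    hap2 = {}
    for b in asn.blocks:
        for i, a1, a2 in zip(b.site_indices, b.hap1_alleles, b.hap2_alleles):
            hap1[i], hap2[i] = a1, a2
    for i in asn.unphased_sites:
        a, b = asn.sites[i].allele_pair
        hap1[i], hap2[i] = a, b
    score = 0
    for (i, j), combos in links.items():
        for (x, y), c in combos.items():
            if (x, y) in ((hap1[i], hap1[j]), (hap2[i], hap2[j])):
                score += c
    return score


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(12))
    def test_greedy_matches_exhaustive_on_zero_conflict(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 13))
        sites = []
        truth_choice = rng.integers(0, 2, size=n)
        for i in range(n):
            a, b = rng.choice(list("ACGT"), size=2, replace=False)
            sites.append(_site(10 * i, str(a), str(b), ref=str(a)))
        links = {}
        for i in range(n - 1):
            if rng.random() < 0.15:
                continue                     # missing link -> block boundary
            c = int(rng.integers(2, 7))
            pi = sites[i].allele_pair
            pj = sites[i + 1].allele_pair
            x = pi[truth_choice[i]]
            y = pj[truth_choice[i + 1]]
            xc = pi[1 - truth_choice[i]]
            yc = pj[1 - truth_choice[i + 1]]
            split = int(rng.integers(0, c + 1))
            counter = Counter()
            if split:
                counter[(x, y)] = split
            if c - split:
                counter[(xc, yc)] = c - split
            links[(i, i + 1)] = counter
        asn = tile_haplotypes(links, sites)
        assert all(c == 0.0 for b in asn.blocks for c in b.link_conflict)
        assert _greedy_agreement(asn, links) == _brute_force_max_agreement(links, sites)


class TestPhaseReport:
    def test_single_block_summary(self):
        sites = [_site(10, "A", "G"), _site(20, "C", "T", ref="C")]
        links = {(0, 1): Counter({("A", "C"): 5})}
        rep = phase_report(tile_haplotypes(links, sites))
        assert rep["n_blocks"] == 1 and rep["phased_fraction"] == 1.0

    def test_two_blocks_still_fully_phased(self):
        sites = [_site(10 * i, "A", "G") for i in range(1, 11)]
        links = {(i, i + 1): Counter({("A", "A"): 5}) for i in range(9) if i != 4}
        rep = phase_report(tile_haplotypes(links, sites))
        assert rep["n_blocks"] == 2 and rep["phased_fraction"] == 1.0

    def test_gap_splits_block_at_uncovered_link(self, het_world):
        # simulate a fragment-coverage gap by withholding links across it
        sites = [_site(10 * i, "A", "G") for i in range(1, 9)]
        links = {(i, i + 1): Counter({("A", "A"): 5}) for i in range(7) if i != 4}
        asn = tile_haplotypes(links, sites)
        spans = [(b.site_indices[0], b.site_indices[-1]) for b in asn.blocks]
        assert spans == [(0, 4), (5, 7)]
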
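"""Pileup, proportion-filter calling, homozygous consensus, imbalance."""

import numpy as np
import pytest

import hlaphase as hp
from hlaphase.align import MateAlignment, PairAlignment
from hlaphase.variants import (Pileup, build_pileup, call_site, call_sites,
                               consensus_homozygous, estimate_allelic_imbalance)

_BASES = "ACGT"


def _ref(seq, name="R"):
    return hp.AmpliconReference(name, seq)


def _aln(pid, ref, start, seq, qual=35, cigar=None):
    q = np.full(len(seq), qual, dtype=np.int16)
    m = MateAlignment(ref.name, start, "+", cigar or [("M", len(seq))], 0, seq, q)
    return PairAlignment(pid, ref.name, m, None, True, True)


def _pileup_from_counts(ref, count_map):
    """Pileup with explicit counts {pos: {base: n}}; quality 35 per base."""
    L = len(ref)
    counts = np.zeros((L, 4), dtype=np.int32)
    qsums = np.zeros((L, 4), dtype=np.int64)
    for pos, alleles in count_map.items():
        for base, n in alleles.items():
            counts[pos, _BASES.index(base)] = n
            qsums[pos, _BASES.index(base)] = 35 * n
    return Pileup(ref, counts, qsums)


class TestBuildPileup:
    def test_single_read_columns(self):
        ref = _ref("T" * 20)
        pa = _aln("p1", ref, 10, "ACGT")
        pile = build_pileup([pa], ref)
        for i, base in enumerate("ACGT"):
            col = pile.column(10 + i)
            assert col["alleles"] == {base: 1} and col["depth"] == 1

    def test_disagreeing_reads_both_counted(self):
        ref = _ref("A" * 20)
        pas = [_aln("p1", ref, 5, "ACA"), _aln("p2", ref, 5, "AGA")]
        pile = build_pileup(pas, ref)
        assert pile.column(6)["alleles"] == {"C": 1, "G": 1}

    def test_low_quality_bases_excluded(self):
        ref = _ref("A" * 20)
        pa = _aln("p1", ref, 0, "AAAA", qual=10)
        pile = build_pileup([pa], ref)
        assert pile.depth.sum() == 0

    def test_indel_events_tallied(self):
        ref = _ref("ACGTACGTACGTACGTACGT")
        ins = _aln("p1", ref, 0, "ACGTXXACGT",
                   cigar=[("M", 4), ("I", 2), ("M", 4)])
        dele = _aln("p2", ref, 0, "ACGTGTAC",
                    cigar=[("M", 4), ("D", 2), ("M", 4)])
        pile = build_pileup([ins, dele], ref)
        assert pile.insertions[4] == {"XX": 1}
        assert pile.deletions[4] == {"AC": 1}

    def test_out_of_bounds_alignment_raises(self):
        ref = _ref("A" * 10)
        with pytest.raises(ValueError):
            build_pileup([_aln("p1", ref, 5, "A" * 10)], ref)

    def test_het_truth_sites_biallelic(self, het_world, het_mapped):
        # at every truth SNV site only the two truth alleles appear
        _, ref, truth, _ = het_world
        pile = build_pileup(het_mapped, ref)
        for v in truth.variant_sites:
            if v.kind != "snv":
                continue
            col = pile.column(v.position)
            assert set(col["alleles"]) == {v.ref_allele, v.alt_allele}
            assert sum(col["alleles"].values()) == col["depth"]


class TestCallSites:
    def test_pure_reference_column(self):
        ref = _ref("A" * 30)
        pile = _pileup_from_counts(ref, {5: {"A": 100}})
        assert call_site(pile, 5).verdict == "homozygous_ref"

    def test_balanced_het_fraction(self):
        ref = _ref("A" * 30)
        pile = _pileup_from_counts(ref, {5: {"A": 60, "G": 40}})
        c = call_site(pile, 5)
        assert c.verdict == "heterozygous"
        assert c.minor_fraction == pytest.approx(0.40)

    def test_five_percent_allele_filtered(self):
        ref = _ref("A" * 30)
        pile = _pileup_from_counts(ref, {5: {"A": 95, "G": 5}})
        c = call_site(pile, 5)
        assert c.verdict == "homozygous_ref"
        assert c.filtered_alleles == ["G"]
        assert c.minor_fraction < 0.1

    def test_ambiguous_band_excluded_from_phasing(self):
        ref = _ref("A" * 30)
        pile = _pileup_from_counts(ref, {5: {"A": 85, "G": 15}})
        c = call_site(pile, 5)
        assert c.verdict == "ambiguous" and not c.is_het

    def test_low_depth(self):
        ref = _ref("A" * 30)
        pile = _pileup_from_counts(ref, {5: {"A": 6}})
        assert call_site(pile, 5).verdict == "low_depth"

    def test_worst_observed_imbalance_retained(self):
        # minor fraction 0.227 (the 1:3.4 imbalance) at deep coverage stays het
        ref = _ref("A" * 30)
        pile = _pileup_from_counts(ref, {5: {"A": 1763, "G": 518}})
        c = call_site(pile, 5)
        assert c.verdict == "heterozygous"
        assert c.minor_fraction == pytest.approx(518 / 2281, abs=1e-4)

    def test_simulated_het_sites_all_called(self, het_world, het_mapped):
        _, ref, truth, _ = het_world
        pile = build_pileup(het_mapped, ref)
        calls = {(c.position, c.kind): c for c in call_sites(pile)}
        for v in truth.variant_sites:
            c = calls[(v.position, v.kind)]
            assert c.verdict == "heterozygous"


class TestConsensusHomozygous:
    def test_all_ref_returns_reference(self):
        ref = _ref("ACGT" * 10)
        out = consensus_homozygous([], ref)
        assert out["sequence"] == ref.sequence
        assert out["false_het_positions"] == []

    def test_single_substitution_applied(self):
        ref = _ref("A" * 40)
        pile = _pileup_from_counts(ref, {7: {"G": 50}})
        calls = call_sites(pile, positions=[7])
        out = consensus_homozygous(calls, ref)
        assert out["sequence"][7] == "G"
        assert out["sequence"][:7] == ref.sequence[:7]

    def test_residual_het_reported_not_corrected(self):
        ref = _ref("A" * 40)
        pile = _pileup_from_counts(ref, {3: {"A": 50, "T": 30}})
        calls = call_sites(pile, positions=[3])
        out = consensus_homozygous(calls, ref)
        assert out["false_het_positions"] == [3]
        assert out["sequence"][3] == "A"

    def test_deep_homozygous_simulation_clean(self):
        # 157x, 0.5% error: P(any base reaching the het band) is negligible
        cfg = hp.SimulationConfig(gene_length=1500, n_snv=0, n_indel=0,
                                  n_pairs=471, base_error_rate=0.005,
                                  fragment_min=500, fragment_max=1200,
                                  fragment_mean=800, fragment_sd=150, seed=9)
        ref = hp.simulate_reference(cfg, name="HOM")
        truth = hp.simulate_haplotype_pair(ref, cfg)
        pairs = hp.simulate_read_pairs(truth, cfg)
        aligner = hp.ReadAligner([ref])
        alns = [aligner.align_pair(p) for p in pairs]
        pile = build_pileup(alns, ref)
        out = consensus_homozygous(call_sites(pile), ref)
        assert out["false_het_positions"] == []
        lo, hi = ref.trimmed_interval
        assert out["sequence"][lo:hi] == ref.sequence[lo:hi]


class TestAllelicImbalance:
    def test_balanced_site_ratio_one(self):
        ref = _ref("A" * 30)
        pile = _pileup_from_counts(ref, {5: {"A": 50, "G": 50}})
        est = estimate_allelic_imbalance(call_sites(pile, positions=[5]))
        assert est["mean_ratio"] == pytest.approx(1.0)

    def test_worst_observed_imbalance_back_arithmetic(self):
        # f = 1/(1+3.4) = 0.227 -> ratio (1-f)/f = 3.4
        ref = _ref("A" * 30)
        pile = _pileup_from_counts(ref, {5: {"A": 340, "G": 100}})
        est = estimate_allelic_imbalance(call_sites(pile, positions=[5]))
        assert est["max_ratio"] == pytest.approx(3.4)

    def test_no_het_sites_undefined(self):
        assert estimate_allelic_imbalance([]) is None

    def test_parameter_recovery(self):
        # 50 binomial sites, depth 1000, true ratio 2.0 -> mean within 10%
        rng = np.random.default_rng(0)
        ref = _ref("A" * 200)
        counts = {}
        for i in range(50):
            minor = rng.binomial(1000, 1 / 3)
            counts[2 * i] = {"A": 1000 - minor, "G": minor}
        pile = _pileup_from_counts(ref, counts)
        est = estimate_allelic_imbalance(call_sites(pile, positions=list(counts)))
        assert est["n_sites"] == 50
        assert abs(est["mean_ratio"] - 2.0) / 2.0 < 0.10


class TestTypeIControl:
    def test_homozygous_error_data_yields_no_het_calls(self):
        # depth 150, 1% error: expected het calls per 10 kb below 1
        rng = np.random.default_rng(1)
        L = 5000
        ref = _ref("".join(rng.choice(list("ACGT"), L)))
        counts = np.zeros((L, 4), dtype=np.int32)
        ref_codes = hp.align.encode(ref.sequence)
        for p in range(L):
            errs = rng.binomial(150, 0.01)
            counts[p, ref_codes[p]] = 150 - errs
            if errs:
                counts[p, (ref_codes[p] + 1) % 4] = errs
        pile = Pileup(ref, counts, counts.astype(np.int64) * 35)
        calls = call_sites(pile)
        assert sum(c.verdict == "heterozygous" for c in calls) == 0
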
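import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lectinkit.models import GeneModel
from lectinkit.promoter import (
    PWM,
    MotifMatch,
    bh_fdr,
    build_regulon,
    extract_promoters,
    filter_by_functional_regions,
    hypergeom_enrichment,
    hypergeom_pvalue,
    matches_to_frame,
    merge_intervals,
    motif_presence,
    scan_motifs,
)

from _oracles import (
    filter_matches_naive,
    hypergeom_upper_tail_enumerated,
    scan_scores_brute_force,
)


def one_hot_pwm(motif_id, consensus):
    matrix = np.zeros((len(consensus), 4))
    for j, b in enumerate(consensus):
        matrix[j, "ACGT".index(b)] = 1.0
    return PWM(motif_id, matrix)


class TestExtractPromoters:
    def test_plus_strand_window(self):
        genome = {"chr1": "A" * 10_000}
        m = GeneModel("g", "chr1", "+", ((4_900, 6_000),), ((5_000, 5_999),))
        prom = extract_promoters({"g": m}, genome, length=2000)["g"]
        assert (prom.start, prom.end) == (3_000, 5_000)
        assert len(prom.sequence) == 2000 and not prom.clipped

    def test_plus_strand_clipped_at_chromosome_start(self):
        genome = {"chr1": "A" * 10_000}
        m = GeneModel("g", "chr1", "+", ((1_400, 2_200),), ((1_500, 2_100),))
        prom = extract_promoters({"g": m}, genome, length=2000)["g"]
        assert (prom.start, prom.end) == (0, 1_500)
        assert prom.clipped and len(prom.sequence) == 1_500

    def test_minus_strand_reverse_complement(self):
        chrom = "".join(np.random.default_rng(5).choice(list("ACGT"), size=12_000))
        genome = {"chr1": chrom}
        m = GeneModel("g", "chr1", "-", ((7_000, 8_000),), ((7_100, 8_000),))
        prom = extract_promoters({"g": m}, genome, length=2000)["g"]
        assert (prom.start, prom.end) == (8_000, 10_000)
        from lectinkit.models import revcomp
        assert prom.sequence == revcomp(chrom[8_000:10_000])

    def test_gene_without_cds_skipped(self):
        genome = {"chr1": "A" * 100}
        m = GeneModel("g", "chr1", "+", ((10, 50),))
        assert extract_promoters({"g": m}, genome) == {}


class TestScanMotifs:
    def test_background_pwm_scores_zero(self):
        pwm = PWM("flat", np.full((4, 4), 0.25))
        matches = scan_motifs({"p": "ACGTACGTACGT"}, [pwm], score_threshold_bits=0.1)
        assert matches == []

    def test_exact_match_scores_two_bits_per_column(self):
        pwm = one_hot_pwm("m", "ACGT")
        matches = scan_motifs({"p": "TTTACGTTTT"}, [pwm], score_threshold_bits=7.9)
        fwd = [m for m in matches if m.strand == "+"]
        assert len(fwd) == 1
        assert fwd[0].start == 3 and fwd[0].end == 7
        assert fwd[0].score == pytest.approx(8.0)

    def test_reverse_strand_match_coordinates(self):
        pwm = one_hot_pwm("m", "AACC")  # revcomp GGTT on forward
        matches = scan_motifs({"p": "TTGGTTTT"}, [pwm], score_threshold_bits=7.9)
        assert len(matches) == 1
        m = matches[0]
        assert m.strand == "-" and (m.start, m.end) == (2, 6)

    def test_windows_with_n_never_reported(self):
        pwm = one_hot_pwm("m", "ACGT")
        matches = scan_motifs({"p": "ACNTACGT"}, [pwm], score_threshold_bits=-100)
        assert all("N" not in "ACNTACGT"[m.start:m.end] for m in matches)

    def test_scores_equal_brute_force_enumeration(self, rng):
        """Vectorised scores equal per-offset python-loop recomputation on
        random short promoters, both strands."""
        for _ in range(25):
            L = int(rng.integers(10, 50))
            seq = "".join(rng.choice(list("ACGTN"), size=L,
                                     p=[0.24, 0.24, 0.24, 0.24, 0.04]))
            w = int(rng.integers(2, 6))
            counts = rng.random((w, 4)) + 0.05
            pwm = PWM("m", counts / counts.sum(axis=1, keepdims=True))
            matches = scan_motifs({"p": seq}, [pwm], score_threshold_bits=-50.0)
            got = {(m.strand, m.start): m.score for m in matches}
            expected = scan_scores_brute_force(seq, pwm.matrix.tolist())
            finite = {k: v for k, v in expected.items() if v >= -50.0}
            assert set(got) == set(finite)
            for k, v in finite.items():
                assert got[k] == pytest.approx(v, abs=1e-9)

    def test_zero_width_pwm_rejected(self):
        with pytest.raises(ValueError):
            PWM("empty", np.zeros((0, 4)))

    def test_presence_agrees_with_match_scanner(self, rng):
        seqs = {f"g{i}": "".join(rng.choice(list("ACGT"), size=80))
                for i in range(30)}
        counts = rng.random((5, 4)) + 0.05
        pwms = [PWM(f"m{j}", counts / counts.sum(axis=1, keepdims=True))
                for j in range(2)]
        presence = motif_presence(seqs, pwms, 3.0)
        matches = scan_motifs(seqs, pwms, 3.0)
        derived = {p.motif_id: set() for p in pwms}
        for m in matches:
            derived[m.motif_id].add(m.gene_id)
        assert presence == derived


class TestRegionFilter:
    def match(self, start, end, gene="g"):
        return MotifMatch("m", gene, start, end, "+", 10.0)

    def test_half_overlap_retained(self):
        kept = filter_by_functional_regions([self.match(0, 10)], {"g": [(5, 40)]})
        assert len(kept) == 1

    def test_under_half_overlap_dropped(self):
        kept = filter_by_functional_regions([self.match(0, 10)], {"g": [(6, 40)]})
        assert kept == []

    def test_straddling_gap_between_regions_dropped(self):
        # 3 bp + 3 bp across two regions separated by 1 bp: no single merged
        # region reaches 50% of the 10 bp match
        regions = {"g": [(0, 5), (6, 9)]}
        kept = filter_by_functional_regions([self.match(2, 12)], regions)
        assert kept == []

    def test_bookended_regions_merge(self):
        kept = filter_by_functional_regions([self.match(0, 10)],
                                            {"g": [(0, 3), (3, 6)]})
        assert len(kept) == 1
        assert merge_intervals([(0, 3), (3, 6)]) == [(0, 6)]

    def test_matches_naive_per_base_oracle(self, rng):
        for _ in range(300):
            s = int(rng.integers(0, 80))
            e = s + int(rng.integers(4, 15))
            regions = [(int(a), int(a) + int(rng.integers(2, 20)))
                       for a in rng.integers(0, 90, size=int(rng.integers(0, 5)))]
            frac = float(rng.choice([0.25, 0.5, 0.75]))
            kept = filter_by_functional_regions([self.match(s, e)],
                                                {"g": regions}, min_fraction=frac)
            assert bool(kept) == filter_matches_naive((s, e), regions, frac)

    def test_adding_regions_only_grows_retained_set(self, rng):
        matches = [self.match(int(a), int(a) + 10) for a in rng.integers(0, 90, 20)]
        r1 = {"g": [(10, 30)]}
        r2 = {"g": [(10, 30), (50, 70)]}
        k1 = {(m.start, m.end) for m in filter_by_functional_regions(matches, r1)}
        k2 = {(m.start, m.end) for m in filter_by_functional_regions(matches, r2)}
        assert k1 <= k2

    def test_raising_min_fraction_only_shrinks_retained_set(self, rng):
        matches = [self.match(int(a), int(a) + 10) for a in rng.integers(0, 90, 20)]
        regions = {"g": [(int(a), int(a) + 12) for a in rng.integers(0, 90, 4)]}
        k_low = {id(m) for m in filter_by_functional_regions(matches, regions, 0.3)}
        k_high = {id(m) for m in filter_by_functional_regions(matches, regions, 0.8)}
        assert k_high <= k_low


@settings(derandomize=True, max_examples=60)
@given(st.lists(st.tuples(st.integers(0, 200), st.integers(1, 30)), max_size=12))
def test_merge_intervals_is_a_disjoint_cover(raw):
    intervals = [(s, s + w) for s, w in raw]
    merged = merge_intervals(intervals)
    for (s0, e0), (s1, e1) in zip(merged, merged[1:]):
        assert e0 < s1  # disjoint and not book-ended after merging
    covered = {b for s, e in merged for b in range(s, e)}
    assert covered == {b for s, e in intervals for b in range(s, e)}


@settings(derandomize=True, max_examples=60)
@given(st.lists(st.floats(min_value=1e-9, max_value=1.0, exclude_min=False),
                min_size=1, max_size=30))
def test_bh_fdr_bounds_and_order(ps):
    q = bh_fdr(ps)
    assert np.all((q > 0) & (q <= 1))
    order = np.argsort(ps)
    assert np.all(np.diff(q[order]) >= -1e-12)
    # the smallest rescaled p bounds every q from below
    m = len(ps)
    assert q.min() >= min(p * m / (i + 1)
                          for i, p in enumerate(sorted(ps))) - 1e-12


class TestRegulon:
    def test_identical_profile_has_r_one_and_is_selected(self, rng):
        profile = rng.random(10)
        expr = pd.DataFrame(
            {"s%d" % i: [profile[i], profile[i], rng.random()] for i in range(10)},
            index=["focal", "twin", "noise"])
        reg = build_regulon(expr, "focal", top_n=1)
        assert reg.members[0][0] == "twin"
        assert reg.members[0][1] == pytest.approx(1.0)

    def test_unmapped_ids_shrink_regulon(self, rng):
        expr = pd.DataFrame(rng.random((21, 8)),
                            index=[f"g{i}" for i in range(21)])
        id_map = {f"g{i}": f"m{i}" for i in range(11)}  # g0..g10 mapped
        reg = build_regulon(expr, "g0", top_n=20, id_map=id_map)
        assert len(reg.selected) == 20
        assert reg.size == 10  # 10 mapped partners (focal excluded)

    def test_zero_variance_focal_rejected(self):
        expr = pd.DataFrame([[1.0, 1.0, 1.0], [1, 2, 3]], index=["f", "g"])
        with pytest.raises(ValueError):
            build_regulon(expr, "f")

    def test_members_exclude_focal_and_sorted_descending(self, rng):
        expr = pd.DataFrame(rng.random((10, 12)), index=[f"g{i}" for i in range(10)])
        reg = build_regulon(expr, "g0", top_n=9)
        assert "g0" not in reg.genes
        rs = [r for _, r in reg.members]
        assert rs == sorted(rs, reverse=True)


class TestHypergeometric:
    def test_two_of_two_from_small_urn(self):
        assert hypergeom_pvalue(2, 2, 2, 5) == pytest.approx(0.1)

    def test_zero_hits_gives_one(self):
        assert hypergeom_pvalue(0, 3, 4, 10) == 1.0

    def test_matches_full_enumeration_small_n(self, rng):
        for _ in range(60):
            N = int(rng.integers(2, 13))
            K = int(rng.integers(0, N + 1))
            n = int(rng.integers(1, N + 1))
            k = int(rng.integers(0, min(n, K) + 1))
            assert hypergeom_pvalue(k, K, n, N) == pytest.approx(
                hypergeom_upper_tail_enumerated(k, K, n, N), abs=1e-12)


class TestBHFDR:
    def test_single_p_unchanged(self):
        assert bh_fdr([0.03])[0] == pytest.approx(0.03)

    def test_hand_computed_step_up(self):
        q = bh_fdr([0.01, 0.02, 0.03])
        assert np.allclose(q, [0.03, 0.03, 0.03])

    def test_equal_ps_unchanged(self):
        assert np.allclose(bh_fdr([0.2, 0.2, 0.2]), 0.2)

    def test_order_preserving(self, rng):
        p = rng.random(50) * 0.999 + 1e-6
        q = bh_fdr(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_fdr([0.0, 0.5])
        with pytest.raises(ValueError):
            bh_fdr([1.5])


class TestEnrichment:
    def test_counts_and_focal_presence(self):
        background = [f"g{i}" for i in range(10)]
        matches = [MotifMatch("m1", g, 0, 5, "+", 9.0) for g in ["g0", "g1", "g5"]]
        result = hypergeom_enrichment(["g0", "g1", "g2"], matches, background,
                                      focal_gene="g0")
        row = result.iloc[0]
        assert (row["k"], row["n"], row["K"], row["N"]) == (2, 3, 3, 10)
        assert row["present_in_focal"]

    def test_significant_but_absent_from_focal_not_enriched(self):
        background = [f"g{i}" for i in range(40)]
        regulon = [f"g{i}" for i in range(8)]
        matches = [MotifMatch("m1", g, 0, 5, "+", 9.0) for g in regulon[1:]]
        result = hypergeom_enrichment(regulon, matches, background,
                                      focal_gene="g0")
        row = result.iloc[0]
        assert row["q"] < 0.05 and not row["present_in_focal"]
        assert not row["enriched"]

    def test_regulon_outside_background_rejected(self):
        with pytest.raises(ValueError, match="ghost"):
            hypergeom_enrichment(["ghost"], [], ["g0"], focal_gene="g0")

    def test_presence_mapping_input(self):
        result = hypergeom_enrichment(
            ["g0", "g1"], {"m1": {"g0", "g1", "g3"}},
            [f"g{i}" for i in range(6)], focal_gene="g0")
        assert result.iloc[0]["k"] == 2
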
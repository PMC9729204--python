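"""Seed index, binding-site discovery, efficiency and product enumeration."""

import numpy as np
import pytest

from ampliscore.fixtures import FixtureSpec, generate_fixture
from ampliscore.score_model import ModelParams
from ampliscore.specificity import (BindingSite, SeedIndex, SpecificityError,
                                    bound_efficiency, enumerate_products,
                                    find_binding_sites, off_target_sum,
                                    product_geometry)
from ampliscore.thermo import reverse_complement
from conftest import (oracle_bound_efficiency, oracle_find_sites,
                      oracle_products_face_to_face)


def _random_ref(seed, length=1000, name="r"):
    rng = np.random.default_rng(seed)
    return {name: "".join(rng.choice(list("ACGT"), size=length))}


class TestSeedIndex:
    def test_every_word_retrievable(self):
        ref = _random_ref(0)
        idx = SeedIndex(ref, word=7)
        seq = ref["r"]
        for i in range(0, len(seq) - 7, 31):
            word = seq[i:i + 7]
            naive = [("r", j) for j in range(len(seq) - 6)
                     if seq[j:j + 7] == word]
            assert idx.positions(word) == naive

    def test_duplicated_segment_words_hit_twice(self):
        fx = generate_fixture(
            FixtureSpec(length=2000, n_duplications=1, segment_length=500),
            seed=2)
        idx = SeedIndex(fx.reference)
        seq = fx.reference[fx.spec.ref_id]
        start, end, _ = fx.duplicated_segments[0]
        for i in range(start, end - 7, 13):
            assert len(idx.positions(seq[i:i + 7])) >= 2

    def test_word_size_validation(self):
        with pytest.raises(SpecificityError):
            SeedIndex({"r": "ACGTACGT"}, word=3)
        with pytest.raises(SpecificityError):
            SeedIndex({})


class TestBoundEfficiency:
    def test_optimal_site_is_fully_efficient(self):
        assert bound_efficiency(65.0, ()) == 1.0

    def test_btm_at_zero_point_kills_the_site(self):
        assert bound_efficiency(45.0, ()) == 0.0

    def test_distal_mismatch_costs_nothing(self):
        assert bound_efficiency(62.0, (30,)) == 1.0

    def test_terminal_mismatch_factor_just_above_cutoff(self):
        # hand-evaluated f(1) with k = 10/24.05, x0 = 12.975, y0 = e^-5
        eff = bound_efficiency(65.0, (1,))
        assert eff == pytest.approx(1.40581e-4, abs=1e-9)
        assert eff > 1e-4

    def test_matches_closed_form_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            btm = float(rng.uniform(30, 80))
            mms = tuple(int(m) for m in
                        rng.integers(1, 30, size=rng.integers(0, 4)))
            assert bound_efficiency(btm, mms) == pytest.approx(
                oracle_bound_efficiency(btm, mms), abs=1e-12)


class TestFindBindingSites:
    def test_own_locus_is_a_perfect_site(self, thermo):
        ref = _random_ref(7, length=800)
        primer = "GCGTACCGGTTGACGGCATG"  # GC-rich, Tm >= 60
        ref["r"] = ref["r"][:300] + primer + ref["r"][320:]
        idx = SeedIndex(ref)
        sites = find_binding_sites(primer, idx, thermo)
        own = [s for s in sites if s.start == 300 and s.strand == "+"]
        assert len(own) == 1
        assert own[0].mismatch_dist3 == ()
        assert own[0].efficiency == 1.0
        assert own[0].bound_tm >= 60

    def test_minus_strand_site_found(self, thermo):
        ref = _random_ref(8, length=600)
        primer = "GCGTACCGGTTGACGGCATG"
        planted = reverse_complement(primer)
        ref["r"] = ref["r"][:100] + planted + ref["r"][120:]
        idx = SeedIndex(ref)
        sites = find_binding_sites(primer, idx, thermo)
        assert any(s.start == 100 and s.strand == "-"
                   and s.efficiency == 1.0 for s in sites)

    def test_thirty_five_percent_mismatch_site_detected(self, thermo):
        """7 substitutions in a 20-mer (35%) leaving one exact 7-mer: the
        detection layer still reports the site."""
        fx = generate_fixture(
            FixtureSpec(length=10_000, planted_copies=(7,)), seed=13)
        idx = SeedIndex(fx.reference)
        sites = find_binding_sites(fx.planted_primer, idx, thermo,
                                   efficiency_cutoff=0.0)
        planted = fx.planted_sites[0]
        hit = [s for s in sites if s.start == planted.start
               and s.strand == "+"]
        assert len(hit) == 1
        assert len(hit[0].mismatch_dist3) == 7

    def test_oracle_equivalence_on_small_references(self, thermo):
        """Indexed discovery equals the naive slide-and-score search."""
        for seed in (0, 1, 2):
            fx = generate_fixture(
                FixtureSpec(length=1500, n_duplications=1,
                            segment_length=300, divergence=0.1,
                            planted_copies=(0, 2, 4)), seed=seed)
            idx = SeedIndex(fx.reference)
            primer = fx.planted_primer
            sites = find_binding_sites(primer, idx, thermo)
            expected = oracle_find_sites(primer, fx.reference, thermo)
            got = {s.locus: (s.bound_tm, s.mismatch_dist3, s.efficiency)
                   for s in sites}
            assert got.keys() == expected.keys()
            for locus, (btm, mm, eff) in expected.items():
                assert got[locus][0] == pytest.approx(btm, abs=1e-9)
                assert got[locus][1] == mm
                assert got[locus][2] == pytest.approx(eff, abs=1e-12)


def _site(start, strand, length=20, eff=1.0, ref="r"):
    return BindingSite(ref_id=ref, strand=strand, start=start,
                       end=start + length, bound_tm=65.0,
                       mismatch_dist3=(), efficiency=eff)


DIS = ModelParams(120, 160, 100, 180, 80, 200)


class TestProducts:
    def test_face_to_face_optimal_product(self):
        prods = enumerate_products([_site(100, "+")], [_site(220, "-")],
                                   "face-to-face", DIS)
        assert len(prods) == 1
        assert prods[0].bdis == 240 - 100  # minus-site end - plus start
        assert prods[0].efficiency == 1.0

    def test_weak_second_site_scales_product(self):
        weak = _site(220, "-", eff=1.40581e-4)
        prods = enumerate_products([_site(100, "+")], [weak],
                                   "face-to-face", DIS)
        assert len(prods) == 1
        assert prods[0].efficiency == pytest.approx(1.40581e-4, rel=1e-5)

    def test_product_shorter_than_30_is_never_formed(self):
        prods = enumerate_products([_site(100, "+")], [_site(105, "-")],
                                   "face-to-face", DIS)
        assert prods == []

    def test_back_to_back_gap_geometry(self):
        left = _site(100, "-")
        right = _site(128, "+")
        assert product_geometry(left, right, "back-to-back") == 8

    def test_unidirectional_overlap_is_negative(self):
        outer = _site(100, "+")
        nested = _site(107, "+")
        assert product_geometry(outer, nested, "unidirectional") \
            == 107 - 119

    def test_target_flagging_and_off_target_sum(self):
        s1, s2 = _site(100, "+"), _site(220, "-")
        extra = _site(600, "-", eff=0.5)
        prods = enumerate_products([s1], [s2, extra], "face-to-face", DIS,
                                   origin1=s1.locus, origin2=s2.locus)
        targets = [p for p in prods if p.is_target]
        assert len(targets) == 1
        assert targets[0].site2.start == 220
        oeff = off_target_sum(prods)
        # the 600 site is 520 away: f(bdis) far beyond MaxL -> dropped
        assert oeff == 0.0

    def test_duplicated_template_gives_k_squared_products(self, thermo):
        """k copies of a primer-site pair in face-to-face geometry yield
        k^2 candidate products before distance filtering."""
        k = 3
        sites1 = [_site(1000 * i, "+") for i in range(k)]
        sites2 = [_site(1000 * i + 120, "-") for i in range(k)]
        candidates = [product_geometry(a, b, "face-to-face")
                      for a in sites1 for b in sites2]
        assert len(candidates) == k * k
        assert all(bdis is not None for bdis in candidates)
        # the distance window then keeps only the converging pairs
        wide = ModelParams(120, 160, 100, 3000, 80, 4000)
        prods = enumerate_products(sites1, sites2, "face-to-face", wide,
                                   distance_model=wide)
        assert len(prods) == k * (k + 1) // 2
        assert {p.bdis for p in prods} == {140, 1140, 2140}

    def test_oracle_equivalence_for_products(self, thermo):
        fx = generate_fixture(
            FixtureSpec(length=1200, planted_copies=(0, 1)), seed=31)
        idx = SeedIndex(fx.reference)
        p1 = fx.planted_primer
        p2 = reverse_complement(
            fx.reference[fx.spec.ref_id][150:170])
        sites1 = find_binding_sites(p1, idx, thermo)
        sites2 = find_binding_sites(p2, idx, thermo)
        wide = ModelParams(100, 900, 50, 1100, 30, 1200)
        got = enumerate_products(sites1, sites2, "face-to-face", wide,
                                 distance_model=wide)
        o1 = [(s.ref_id, s.strand, s.start, s.end, s.efficiency)
              for s in sites1]
        o2 = [(s.ref_id, s.strand, s.start, s.end, s.efficiency)
              for s in sites2]
        expected = oracle_products_face_to_face(o1, o2, wide.as_tuple())
        got_map = {(p.site1.locus, p.site2.locus): (p.bdis, p.efficiency)
                   for p in got}
        assert got_map.keys() == expected.keys()
        for key, (bdis, eff) in expected.items():
            assert got_map[key][0] == bdis
            assert got_map[key][1] == pytest.approx(eff, abs=1e-12)

    def test_efficiencies_bounded_and_additive(self):
        s1, s2 = _site(0, "+"), _site(130, "-", eff=0.3)
        s3 = _site(260, "-", eff=0.2)
        with_both = enumerate_products([s1], [s2, s3], "face-to-face", DIS)
        without = enumerate_products([s1], [s2], "face-to-face", DIS)
        assert all(0 < p.efficiency <= 1 for p in with_both)
        assert off_target_sum(without) <= off_target_sum(with_both)
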
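"""Pair scoring, task dispatch, selection and cross-dimer screening."""

import numpy as np
import pytest

from ampliscore.candidate import TemplateRegion, mask_reference
from ampliscore.design import (DesignTask, PairRelation, TargetSpot,
                               check_cross_dimers, design,
                               enumerate_and_score_pairs, evaluate_primers,
                               full_coverage_windows, relation_score)
from ampliscore.fixtures import clean_template
from ampliscore.presets import apply_preset
from ampliscore.score_model import DEFAULT_RELATION_WEIGHTS
from ampliscore.specificity import SeedIndex
from ampliscore.thermo import reverse_complement
from ampliscore.candidate import walk_candidates

FAST = dict(pos_step=3, len_step=6)  # coarse grids keep tests quick


@pytest.fixture(scope="module")
def template():
    return clean_template(380, seed=17)


@pytest.fixture(scope="module")
def template_index(template):
    return SeedIndex(template)


class TestRelationScore:
    def test_all_optimal_relation_scores_100(self):
        rel = PairRelation(tmdiff=0.5, lendiff=1, pos=15, dis=140, oeff=0.0)
        total, breakdown = relation_score(rel)
        assert total == 100.0
        assert all(v == 1.0 for v in breakdown.values())

    def test_dis_at_zero_point_contributes_nothing(self):
        rel = PairRelation(tmdiff=0.5, lendiff=1, pos=15, dis=100, oeff=0.0)
        total, _ = relation_score(rel)
        assert total == pytest.approx(
            100.0 - DEFAULT_RELATION_WEIGHTS["Dis"], abs=1e-9)

    def test_heavy_off_target_load_drags_score_negative(self):
        # f(oEff)(0.1) = -19.944 from the right logistic with y0' = e^3
        rel = PairRelation(tmdiff=0.5, lendiff=1, pos=15, dis=140, oeff=0.1)
        total, breakdown = relation_score(rel)
        assert breakdown["oEff"] == pytest.approx(-19.9444, abs=1e-3)
        assert total < 0

    def test_pos_skipped_for_tasks_without_target(self):
        rel = PairRelation(tmdiff=0.5, lendiff=1, pos=None, dis=140,
                           oeff=0.0)
        total, breakdown = relation_score(rel)
        assert "Pos" not in breakdown
        assert total == pytest.approx(100.0)


class TestEnumerateAndScorePairs:
    def test_three_pairs_by_default_and_deterministic(self, template,
                                                      template_index,
                                                      thermo):
        task = DesignTask(opt_tm=60, **FAST)
        region = TemplateRegion("tpl1", 0, 380)
        res1 = design(task, template, regions=[region],
                      specificity_index=template_index, thermo=thermo)
        res2 = design(task, template, regions=[region],
                      specificity_index=template_index, thermo=thermo)
        pairs = res1["tpl1:0-380"]
        assert len(pairs) == 3
        assert [p.rank for p in pairs] == [1, 2, 3]
        assert [p.final_score for p in pairs] == sorted(
            (p.final_score for p in pairs), reverse=True)
        # byte-identical ranked output on identical inputs
        assert [(p.primer1.id, p.primer2.id, p.final_score)
                for p in res1["tpl1:0-380"]] \
            == [(p.primer1.id, p.primer2.id, p.final_score)
                for p in res2["tpl1:0-380"]]

    def test_top_pair_matches_brute_force_maximum(self, template,
                                                  template_index, thermo):
        """Selection optimality: the winner equals the maximum over the
        full pair enumeration."""
        task = DesignTask(opt_tm=60, **FAST)
        region = TemplateRegion("tpl1", 40, 250)
        c1 = walk_candidates(region, template, strands=("+",), **FAST)
        c2 = walk_candidates(region, template, strands=("-",), **FAST)
        ranked = enumerate_and_score_pairs(c1, c2, task, template_index,
                                           thermo)
        assert ranked, "a 210 bp window admits legal pairs"
        brute_best = max(pr.final_score for pr in ranked)
        assert ranked[0].final_score == brute_best

    def test_no_failure_on_poor_template(self, thermo):
        """Even when every candidate is far from optimal, ranked pairs
        come back as long as one legal geometry exists."""
        ref = {"bad": "GC" * 100}  # GC = 1.0 everywhere, polys everywhere
        task = DesignTask(opt_tm=60, **FAST)
        res = design(task, ref, regions=[TemplateRegion("bad", 0, 200)],
                     specificity_index=SeedIndex(ref), thermo=thermo)
        pairs = res["bad:0-200"]
        assert pairs
        assert all(p.final_score < 100 for p in pairs)

    def test_empty_result_when_no_legal_geometry(self, thermo):
        ref = clean_template(60, seed=9)  # too short for an 80+ nt product
        task = DesignTask(opt_tm=60, **FAST)
        res = design(task, ref, regions=[TemplateRegion("tpl1", 0, 60)],
                     specificity_index=SeedIndex(ref), thermo=thermo)
        assert res["tpl1:0-60"] == []

    def test_worsening_one_feature_never_helps(self, template,
                                               template_index, thermo):
        task = DesignTask(opt_tm=60, **FAST)
        region = TemplateRegion("tpl1", 0, 380)
        c1 = walk_candidates(region, template, strands=("+",), **FAST)
        c2 = walk_candidates(region, template, strands=("-",), **FAST)
        ranked = enumerate_and_score_pairs(c1, c2, task, template_index,
                                           thermo)
        top = ranked[0]
        # same pair rescored with primer1 degraded by a 3'-terminal SNP
        from dataclasses import replace
        worse1 = replace(top.primer1,
                         degenerate_seq=top.primer1.degenerate_seq[:-1] + "N")
        worse = enumerate_and_score_pairs([worse1], [top.primer2], task,
                                          template_index, thermo)
        assert worse[0].final_score < top.final_score


class TestTaskDispatch:
    def test_genotyping_primer1_sits_upstream_at_legal_distance(self,
                                                                thermo):
        ref = clean_template(1400, seed=23)
        cfg = apply_preset("sanger_genotyping", opt_tm=60, pos_step=6,
                           len_step=6)
        target = TargetSpot("tpl1", 700)
        res = design(cfg.task, ref, targets=[target],
                     specificity_index=SeedIndex(ref), thermo=thermo)
        pairs = res["tpl1:700"]
        assert pairs
        for pr in pairs:
            assert pr.primer1.strand == "+"
            assert pr.primer2.strand == "-"
            pos = 700 - pr.primer1.three_prime_pos
            assert 70 <= pos <= 300
            assert 500 <= pr.relation.dis <= 600

    def test_arms_primers_carry_each_allele_at_the_target(self, thermo):
        ref = clean_template(600, seed=29)
        base = ref["tpl1"][300]
        alt = "G" if base != "G" else "A"
        masked, _ = mask_reference(ref, [("tpl1", 300, base, (alt,))])
        cfg = apply_preset("arms", opt_tm=60, pos_step=3, len_step=4)
        res = design(cfg.task, ref, targets=[TargetSpot("tpl1", 300)],
                     masked=masked, specificity_index=SeedIndex(ref),
                     thermo=thermo)
        pairs = res["tpl1:300"]
        assert pairs
        seen_alleles = set()
        for pr in pairs:
            assert pr.primer1.three_prime_pos == 300
            assert pr.relation.pos == 0
            seen_alleles.add(pr.primer1.seq[-1])
        assert seen_alleles <= {base, alt}

    def test_inverse_pairs_diverge_with_small_gap(self, thermo):
        ref = clean_template(500, seed=31)
        cfg = apply_preset("inverse", opt_tm=60, pos_step=3, len_step=6)
        res = design(cfg.task, ref, targets=[TargetSpot("tpl1", 250)],
                     specificity_index=SeedIndex(ref), thermo=thermo)
        pairs = res["tpl1:250"]
        assert pairs
        for pr in pairs:
            assert (pr.primer1.strand, pr.primer2.strand) == ("-", "+")
            assert -20 <= pr.relation.dis <= 35

    def test_anchored_pairs_nest_on_the_same_strand(self, thermo):
        ref = clean_template(500, seed=37)
        cfg = apply_preset("anchored", opt_tm=60, pos_step=3, len_step=6)
        res = design(cfg.task, ref, targets=[TargetSpot("tpl1", 300)],
                     specificity_index=SeedIndex(ref), thermo=thermo)
        pairs = res["tpl1:300"]
        assert pairs
        for pr in pairs:
            assert pr.primer1.strand == pr.primer2.strand == "+"
            assert pr.relation.dis < 0  # nested: primer2 starts inside

    def test_full_coverage_partitions_and_designs_each_window(self, thermo):
        ref = clean_template(1000, seed=41)
        task = DesignTask(task="full_covered", tiling_count=4,
                          opt_tm=60, **FAST)
        res = design(task, ref,
                     regions=[TemplateRegion("tpl1", 0, 1000)],
                     specificity_index=SeedIndex(ref), thermo=thermo)
        assert len(res) == 4
        assert all(len(v) >= 1 for v in res.values())

    def test_window_partition_is_exact(self):
        region = TemplateRegion("r", 0, 1000)
        wins = full_coverage_windows(region, count=5)
        assert len(wins) == 5
        assert wins[0].start == 0 and wins[-1].end == 1000
        for a, b in zip(wins, wins[1:]):
            assert a.end == b.start
        by_spacing = full_coverage_windows(region, spacing=300)
        assert len(by_spacing) == 4  # ceil(1000/300)

    def test_target_outside_reference_errors(self, thermo):
        ref = clean_template(100, seed=1)
        task = apply_preset("anchored").task
        with pytest.raises(Exception):
            design(task, ref, targets=[TargetSpot("tpl1", 500)],
                   thermo=thermo)


class TestEvaluate:
    def test_roundtrip_with_design_time_scoring(self, template, thermo):
        """A designed primer re-submitted to the evaluate task reproduces
        its design-time feature scores exactly."""
        task = DesignTask(opt_tm=60, **FAST)
        region = TemplateRegion("tpl1", 0, 380)
        res = design(task, template, regions=[region],
                     specificity_index=SeedIndex(template), thermo=thermo)
        top = res["tpl1:0-380"][0]
        out = evaluate_primers({"p1": top.primer1.seq}, thermo=thermo,
                               opt_tm=60)
        assert out["p1"]["scores"] == top.breakdown1
        assert out["p1"]["total"] == pytest.approx(top.score1)

    def test_degenerate_codes_count_as_snps(self, thermo):
        out = evaluate_primers({"p": "ACGTACGTACGTACGTACGR"},
                               thermo=thermo, opt_tm=60)
        assert len(out["p"]["features"].snps) == 1
        assert out["p"]["features"].snps[0].dist3 == 0


class TestCrossDimers:
    def test_exact_reverse_complements_reported_and_anchored(self, thermo):
        a = "ACCGTTAGCATGACCGGTAA"
        rep = check_cross_dimers({"a": a, "b": reverse_complement(a)},
                                 thermo=thermo)
        pair_hits = [h for h in rep.hits if h.primer_a != h.primer_b]
        assert pair_hits and pair_hits[0].end_anchored

    def test_random_at_rich_panel_stays_silent(self, thermo):
        rng = np.random.default_rng(43)
        panel = {f"p{i}": "".join(rng.choice(list("ACGT"),
                                             p=[0.4, 0.1, 0.1, 0.4],
                                             size=20))
                 for i in range(6)}
        rep = check_cross_dimers(panel, thermo=thermo, threshold_tm=45.0)
        # verified against an exhaustive duplex scan: AT-rich random
        # 20-mers have no 45 C duplex
        assert rep.hits == ()

    def test_comparison_count_contract(self, thermo):
        """m targets x 3 pairs x 2 primers: C(6m, 2) + 6m comparisons."""
        m = 2
        primers = {f"t{j}|{r}|{k}": "ACGTACGTACGTACGTACG" + "TCGA"[j]
                   for j in range(m) for r in (1, 2, 3) for k in (1, 2)}
        assert len(primers) == 6 * m
        rep = check_cross_dimers(primers, thermo=thermo)
        n = 6 * m
        assert rep.n_comparisons == n * (n - 1) // 2 + n
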
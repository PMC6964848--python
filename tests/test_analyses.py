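from dataclasses import replace

import pytest

from fermpipe import fixtures as fx
from fermpipe.analyses import (
    count_knockout_scenarios,
    enumerate_knockout_scenarios,
    gradient_scan,
    knockout_scan,
    plan_campaign,
    sensitivity_scan,
)
from fermpipe.envelope import OxygenPolicy
from fermpipe.serial_pipeline import FermentationSetup, Organism, run_pipeline


class TestSensitivity:
    def test_removing_sole_substrate_zeroes_yield(self, setup_a):
        rows = sensitivity_scan(setup_a)
        (glc,) = rows
        assert glc.compound == "glc"
        assert glc.relative_yield_max_pct == pytest.approx(0.0, abs=1e-6)
        # baseline min yield is 0 -> relative min undefined, not a crash
        assert glc.relative_yield_min_pct is None

    def test_unusable_compound_scores_hundred(self, setup_ab):
        rows = {r.compound: r for r in sensitivity_scan(setup_ab)}
        # removing glucose leaves the xylose-only step-2 yield: < 100%
        assert rows["glc"].relative_yield_max_pct < 100.0
        # removing xylose removes step 2 only
        assert rows["xyl"].relative_yield_max_pct < 100.0
        expected_glc_removed = (
            (500.0 / 150.0 - 0.5) * (5.0 / 3.0) * 46.0 / 10.0
        )  # % of input mass
        base = run_pipeline(setup_ab).yield_max_pct
        assert rows["glc"].relative_yield_max_pct == pytest.approx(
            100.0 * expected_glc_removed / base, rel=1e-3
        )

    def test_passthrough_only_compound_is_neutral(self, toy_a, registry_a):
        from fermpipe.model_core import MediaComposition, MediaEntry

        media = MediaComposition(
            [
                MediaEntry("glc", 500.0, 180.0, True),
                MediaEntry("inert", 400.0, 100.0, True),  # unmapped for TOY-A
            ]
        )
        setup = FermentationSetup(
            organisms=[Organism(toy_a, registry_a)],
            media=media, target="etoh",
            oxygen=[OxygenPolicy.anaerobic()],
            compound_weights=fx.toy_compound_weights(),
        )
        rows = {r.compound: r for r in sensitivity_scan(setup)}
        assert rows["inert"].relative_yield_max_pct == pytest.approx(100.0, rel=1e-9)

    def test_values_above_hundred_not_clamped(self, setup_a):
        # removal shrinking the baseline denominator is simulated directly:
        # relative_yield = 100*new/old must carry >100% untouched
        from fermpipe.analyses import _relative

        assert _relative(1.2, 1.0) == pytest.approx(120.0)

    def test_removal_idempotent(self, setup_ab):
        removed = replace(setup_ab, media=setup_ab.media.without("glc"))
        rows = {r.compound: r for r in sensitivity_scan(removed)}
        # removing an already-removed compound changes nothing
        assert rows["glc"].relative_yield_max_pct == pytest.approx(100.0, rel=1e-9)


class TestGradient:
    def test_glucose_gradient_closed_form(self, setup_a):
        rows = gradient_scan(setup_a, delta_mg=1.0)
        (glc,) = rows
        # marginal glucose ferments at 2·46/180 mg ethanol per mg glucose
        assert glc.gradient_max == pytest.approx(2 * 46.0 / 180.0, rel=1e-3)
        assert glc.gradient_min == pytest.approx(0.0, abs=1e-6)

    def test_unusable_compound_gradient_zero(self, setup_ab):
        # for the A-then-B pipe, adding xylose converts via TOY-B
        rows = {r.compound: r for r in gradient_scan(setup_ab)}
        assert rows["xyl"].gradient_max == pytest.approx(
            (5.0 / 3.0) * 46.0 / 150.0, rel=1e-3
        )
        # an inert compound's gradient vanishes
        from fermpipe.model_core import MediaComposition, MediaEntry

        media = MediaComposition(
            [
                MediaEntry("glc", 500.0, 180.0, True),
                MediaEntry("inert", 100.0, 100.0, True),
            ]
        )
        setup = replace(setup_ab, media=media)
        rows = {r.compound: r for r in gradient_scan(setup)}
        assert rows["inert"].gradient_max == pytest.approx(0.0, abs=1e-6)

    def test_gradient_consistent_with_neutral_sensitivity(self, toy_a, registry_a):
        from fermpipe.model_core import MediaComposition, MediaEntry

        media = MediaComposition(
            [
                MediaEntry("glc", 500.0, 180.0, True),
                MediaEntry("inert", 400.0, 100.0, True),
            ]
        )
        setup = FermentationSetup(
            organisms=[Organism(toy_a, registry_a)],
            media=media, target="etoh",
            oxygen=[OxygenPolicy.anaerobic()],
            compound_weights=fx.toy_compound_weights(),
        )
        sens = {r.compound: r for r in sensitivity_scan(setup)}
        grad = {r.compound: r for r in gradient_scan(setup)}
        assert sens["inert"].relative_yield_max_pct == pytest.approx(100.0, rel=1e-9)
        assert grad["inert"].gradient_max == pytest.approx(0.0, abs=1e-6)

    def test_bad_delta_rejected(self, setup_a):
        with pytest.raises(ValueError):
            gradient_scan(setup_a, delta_mg=0.0)


class TestEnumeration:
    def test_paper_scale_counts(self):
        assert count_knockout_scenarios(2280, 2914) == 6_649_115

    def test_wild_type_only(self):
        assert count_knockout_scenarios(0, 0) == 1

    def test_small_arithmetic(self):
        assert count_knockout_scenarios(2, 3) == 12

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            count_knockout_scenarios(-1, 2)

    def test_iterator_matches_count(self):
        count, it = enumerate_knockout_scenarios(["r1", "r2"], ["s1", "s2", "s3"])
        pairs = list(it)
        assert count == 12
        assert len(pairs) == 12
        assert (None, None) in pairs
        assert ("r1", "s3") in pairs

    def test_integer_arguments(self):
        count, it = enumerate_knockout_scenarios(2280, 2914)
        assert count == 6_649_115
        first = next(it)
        assert first == (None, None)


class TestKnockoutScan:
    def test_full_toy_scan_row_count_and_wild_type(self, setup_ab):
        rows = knockout_scan(setup_ab)
        n1 = len(setup_ab.organisms[0].model.reactions)
        n2 = len(setup_ab.organisms[1].model.reactions)
        assert len(rows) == (n1 + 1) * (n2 + 1)
        (wt,) = [r for r in rows if r.ko1 is None and r.ko2 is None]
        assert wt.yield_min_rel_pct == 100.0
        assert wt.yield_max_rel_pct == 100.0

    def test_ferm_knockout_leaves_step_two_only(self, setup_ab):
        rows = knockout_scan(setup_ab, scope1=["FERM"], scope2=[])
        by_key = {(r.ko1, r.ko2): r for r in rows}
        hit = by_key[("FERM", None)]
        base = run_pipeline(setup_ab)
        step2_only = 100.0 * base.steps[1].product_max_mg / base.input_mass_mg
        assert hit.yield_max_rel_pct == pytest.approx(
            100.0 * step2_only / base.yield_max_pct, rel=1e-3
        )

    def test_scope_excludes_envelope_transporters(self, setup_ab):
        rows = knockout_scan(setup_ab)
        ids = {r.ko1 for r in rows} | {r.ko2 for r in rows}
        assert not any(i and "__" in i for i in ids)

    def test_growth_knockout_reports_zero(self, setup_ab):
        rows = knockout_scan(setup_ab, scope1=["GROW_PRE"], scope2=["GROW_PRE"])
        by_key = {(r.ko1, r.ko2): r for r in rows}
        both = by_key[("GROW_PRE", "GROW_PRE")]
        assert both.yield_max_rel_pct == pytest.approx(0.0, abs=1e-6)

    def test_base_knockouts_merge_into_every_scenario(self, setup_ab):
        from fermpipe.lp_engine import KnockoutSpec

        base = (KnockoutSpec.of("FERM"), KnockoutSpec())
        rows = knockout_scan(setup_ab, scope1=[], scope2=["FERMX"], base_knockouts=base)
        by_key = {(r.ko1, r.ko2): r for r in rows}
        # WT-of-the-nested-screen keeps FERM knocked: relative 100 by definition
        assert by_key[(None, None)].yield_max_rel_pct == 100.0
        # knocking FERMX on top kills everything that was left
        assert by_key[(None, "FERMX")].yield_max_rel_pct == pytest.approx(0.0, abs=1e-6)

    def test_scan_order_independent_of_runner(self, setup_ab):
        from fermpipe.runner_io import pool_runner

        serial = knockout_scan(setup_ab, scope1=["FERM"], scope2=["FERMX"])
        pooled = knockout_scan(
            setup_ab, scope1=["FERM"], scope2=["FERMX"], runner=pool_runner(2)
        )
        assert [(r.ko1, r.ko2) for r in serial] == [(r.ko1, r.ko2) for r in pooled]
        for a, b in zip(serial, pooled):
            if a.yield_max_rel_pct is None:
                assert b.yield_max_rel_pct is None
            else:
                assert a.yield_max_rel_pct == pytest.approx(b.yield_max_rel_pct, rel=1e-9)


class TestCampaign:
    def test_paper_scale_campaign(self):
        campaign = plan_campaign(
            ["m1", "m2", "m3"],
            ["t1", "t2", "t3", "t4", "t5"],
            ["o1", "o2", "o3", "o4"],
            ["aerobic", "anaerobic"],
        )
        assert campaign.n_configurations == 240
        assert campaign.n_tasks == 480

    def test_minimal_campaign(self):
        campaign = plan_campaign(["m"], ["t"], ["o"], ["anaerobic"])
        assert campaign.n_configurations == 1
        assert campaign.n_tasks == 1

    def test_configuration_formula(self):
        campaign = plan_campaign(["m1", "m2"], ["t"], ["a", "b", "c"], ["x"])
        n = 3
        assert campaign.n_configurations == 2 * 1 * (n + n * (n - 1))

    def test_ordered_pairs_are_distinct(self):
        campaign = plan_campaign(["m"], ["t"], ["a", "b"], ["x"])
        pipes = {c[0] for c in campaign.configurations}
        assert ("a", "b") in pipes and ("b", "a") in pipes and ("a",) in pipes

    def test_duplicate_organisms_rejected(self):
        with pytest.raises(ValueError):
            plan_campaign(["m"], ["t"], ["a", "a"], ["x"])

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            plan_campaign([], ["t"], ["a"], ["x"])
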
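from dataclasses import replace

import pytest

from fermpipe import fixtures as fx
from fermpipe.envelope import OxygenPolicy
from fermpipe.lp_engine import KnockoutSpec
from fermpipe.model_core import (
    CompoundRegistry,
    MediaComposition,
    MediaEntry,
    MetabolicModel,
    Metabolite,
    Reaction,
)
from fermpipe.serial_pipeline import (
    FermentationSetup,
    Organism,
    run_pipeline,
    run_single_step,
    run_two_step,
)

GLC_FEED = 1000.0 / 180.0  # mmol fed by 1000 mg glucose


class TestSingleStep:
    def test_toy_a_yield_on_glucose(self, setup_a):
        res = run_single_step(setup_a)
        # max: residual 4.5556 mmol glc -> 9.1111 mmol ethanol = 419.11 mg
        assert res.yield_max_pct == pytest.approx(100 * 46 * 2 * (GLC_FEED - 1) / 1000, rel=1e-4)
        assert res.yield_max_pct == pytest.approx(41.91, abs=0.01)
        assert res.yield_min_pct == pytest.approx(0.0, abs=1e-6)

    def test_step_reporting(self, setup_a):
        res = run_single_step(setup_a)
        (step,) = res.steps
        assert step.bm_max == pytest.approx(1.0, rel=1e-9)
        assert step.product_min_mg <= step.product_max_mg
        assert step.fed_mass_mg == pytest.approx(1000.0)

    def test_empty_media_flags_no_growth(self, toy_a, registry_a):
        setup = FermentationSetup(
            organisms=[Organism(toy_a, registry_a)],
            media=MediaComposition([]),
            target="etoh",
            oxygen=[OxygenPolicy.anaerobic()],
            compound_weights=fx.toy_compound_weights(),
        )
        res = run_single_step(setup)
        assert (res.yield_min_pct, res.yield_max_pct) == (0.0, 0.0)
        assert "no-growth" in res.flags

    def test_growth_outcompetes_fermentation(self, toy_a, media1, registry_a):
        # raise the growth cap so that all glucose goes to biomass at optimum
        greedy = toy_a.copy()
        greedy.reaction("GROW").upper_bound = 100.0
        setup = FermentationSetup(
            organisms=[Organism(greedy, registry_a)],
            media=media1,
            target="etoh",
            oxygen=[OxygenPolicy.anaerobic()],
            compound_weights=fx.toy_compound_weights(),
        )
        res = run_single_step(setup)
        assert res.yield_max_pct == pytest.approx(0.0, abs=1e-4)

    def test_consumed_plus_residual_equals_fed(self, setup_a):
        res = run_single_step(setup_a)
        (step,) = res.steps
        for entry in setup_a.media.entries:
            fed = entry.mass_mg
            consumed = step.consumed.get(entry.compound_id, 0.0)
            residual = 0.0
            for e in step.residual_media.entries:
                if e.compound_id == entry.compound_id:
                    residual = e.mass_mg
            assert consumed + residual == pytest.approx(fed, abs=1e-3)


class TestTransferMedia:
    def test_unusable_compound_passes_through(self, setup_ab):
        res = run_two_step(setup_ab)
        step1 = res.steps[0]
        # xylose is unmapped for TOY-A: passes through untouched
        assert step1.consumed.get("xyl", 0.0) == pytest.approx(0.0, abs=1e-6)
        xyl = [e for e in step1.residual_media.entries if e.compound_id == "xyl"]
        assert xyl and xyl[0].mass_mg == pytest.approx(500.0, abs=1e-3)

    def test_nontransferable_residual_excluded(self, toy_a, toy_b, registry_a, registry_b):
        media = MediaComposition(
            [
                MediaEntry("glc", 500.0, 180.0, True),
                MediaEntry("xyl", 500.0, 150.0, False),  # marked non-transferable
            ]
        )
        setup = FermentationSetup(
            organisms=[Organism(toy_a, registry_a), Organism(toy_b, registry_b)],
            media=media,
            target="etoh",
            oxygen=[OxygenPolicy.anaerobic()] * 2,
            compound_weights=fx.toy_compound_weights(),
        )
        res = run_two_step(setup)
        # step 2 never sees xylose -> contributes nothing
        assert res.steps[1].product_max_mg == pytest.approx(0.0, abs=1e-3)

    def test_co2_is_not_transferred(self, setup_ab):
        res = run_two_step(setup_ab)
        step2 = res.steps[1]
        assert step2.fed_mass_mg < 1000.0
        # step 2's media is residual xylose only (glc fully used, co2 volatile,
        # ethanol harvested)
        assert step2.fed_mass_mg == pytest.approx(500.0, abs=1e-2)


class TestTwoStep:
    def test_toy_pair_max_yield_closed_form(self, setup_ab):
        res = run_two_step(setup_ab)
        expected = (
            (500.0 / 180.0 - 1.0) * 2 * 46.0
            + (500.0 / 150.0 - 0.5) * (5.0 / 3.0) * 46.0
        ) / 1000.0 * 100.0
        assert res.yield_max_pct == pytest.approx(expected, rel=1e-3)
        assert res.yield_min_pct == pytest.approx(0.0, abs=1e-6)

    def test_order_matters(self, toy_a, media1, registry_a):
        # TOY-C competes for glucose but converts it to ethanol poorly
        # (1 etoh per glc instead of 2) and grows faster; whoever goes
        # first eats the glucose, so order changes the total
        toy_c = MetabolicModel(
            id="TOY-C",
            metabolites={
                "glc": Metabolite("glc", molecular_weight=180.0),
                "etoh": Metabolite("etoh", molecular_weight=46.0),
                "wst": Metabolite("wst", molecular_weight=134.0),
                "bmC": Metabolite("bmC"),
            },
            reactions=[
                Reaction("FERM_C", {"glc": -1.0, "etoh": 1.0, "wst": 1.0}, 0.0, 1000.0),
                Reaction("GROW_PRE", {"glc": -1.0, "bmC": 1.0}, 0.0, 1000.0),
                Reaction("GROW", {"bmC": -1.0}, 0.0, 2.0),
            ],
            growth_reaction_id="GROW",
            excretable=frozenset({"etoh", "wst"}),
        )
        registry_c = CompoundRegistry(
            {"glc": {"TOY-C": "glc"}, "etoh": {"TOY-C": "etoh"}, "wst": {"TOY-C": "wst"}}
        )
        weights = dict(fx.toy_compound_weights(), wst=134.0)
        ac = FermentationSetup(
            organisms=[Organism(toy_a, registry_a), Organism(toy_c, registry_c)],
            media=media1, target="etoh",
            oxygen=[OxygenPolicy.anaerobic()] * 2,
            compound_weights=weights,
        )
        ca = FermentationSetup(
            organisms=[Organism(toy_c, registry_c), Organism(toy_a, registry_a)],
            media=media1, target="etoh",
            oxygen=[OxygenPolicy.anaerobic()] * 2,
            compound_weights=weights,
        )
        res_ac, res_ca = run_two_step(ac), run_two_step(ca)
        assert abs(res_ac.yield_max_pct - res_ca.yield_max_pct) > 1.0
        # A first converts at 2 etoh/glc: strictly better
        assert res_ac.yield_max_pct > res_ca.yield_max_pct

    def test_same_organism_twice_cannot_use_xylose(self, toy_b, media2, registry_b):
        setup = FermentationSetup(
            organisms=[Organism(toy_b, registry_b), Organism(toy_b, registry_b)],
            media=media2, target="etoh",
            oxygen=[OxygenPolicy.anaerobic()] * 2,
            compound_weights=fx.toy_compound_weights(),
        )
        res = run_two_step(setup)
        # glucose is never converted; the xylose-only ceiling applies
        xylose_ceiling = (500.0 / 150.0) * (5.0 / 3.0) * 46.0 / 1000.0 * 100.0
        assert res.yield_max_pct <= xylose_ceiling + 1e-6

    def test_inert_second_organism_equals_single_step(self, toy_a, media1, registry_a, setup_a):
        inert = MetabolicModel(
            id="INERT",
            metabolites={"x": Metabolite("x"), "bmX": Metabolite("bmX")},
            reactions=[
                Reaction("NOOP", {"x": -1.0, "bmX": 1.0}, 0.0, 0.0),
                Reaction("GROW", {"bmX": -1.0}, 0.0, 0.0),
            ],
            growth_reaction_id="GROW",
        )
        inert_reg = CompoundRegistry({"etoh": {"INERT": "x"}})
        two = FermentationSetup(
            organisms=[Organism(toy_a, registry_a), Organism(inert, inert_reg)],
            media=media1, target="etoh",
            oxygen=[OxygenPolicy.anaerobic()] * 2,
            compound_weights=fx.toy_compound_weights(),
        )
        res_two, res_one = run_two_step(two), run_single_step(setup_a)
        assert res_two.yield_max_pct == pytest.approx(res_one.yield_max_pct, rel=1e-6)
        assert res_two.yield_min_pct == pytest.approx(res_one.yield_min_pct, abs=1e-9)

    def test_empty_transfer_media_second_step_contributes_zero(
        self, toy_a, toy_b, registry_a, registry_b
    ):
        media = MediaComposition([MediaEntry("glc", 1000.0, 180.0, False)])
        setup = FermentationSetup(
            organisms=[Organism(toy_a, registry_a), Organism(toy_b, registry_b)],
            media=media, target="etoh",
            oxygen=[OxygenPolicy.anaerobic()] * 2,
            compound_weights=fx.toy_compound_weights(),
        )
        res = run_two_step(setup)
        assert res.steps[1].product_max_mg == pytest.approx(0.0, abs=1e-6)
        assert "empty-media" in res.steps[1].flags

    def test_knockouts_flow_into_steps(self, setup_ab):
        ko = replace(setup_ab, knockouts=(KnockoutSpec.of("FERM"), KnockoutSpec()))
        res = run_two_step(ko)
        assert res.steps[0].product_max_mg == pytest.approx(0.0, abs=1e-6)
        assert res.steps[1].product_max_mg > 0.0


class TestMassConservation:
    @pytest.mark.parametrize("fixture_name", ["setup_a", "setup_ab"])
    def test_input_mass_fully_accounted(self, fixture_name, request):
        setup = request.getfixturevalue(fixture_name)
        res = run_pipeline(setup)
        # product + residual + consumed-but-not-product (biomass + waste)
        # never exceeds input; and per-step consumed+residual == fed
        total_product = sum(s.product_max_mg for s in res.steps)
        assert total_product <= res.input_mass_mg * (1 + 1e-6)
        step1 = res.steps[0]
        fed = {e.compound_id: e.mass_mg for e in setup.media.entries}
        for c, mass in fed.items():
            residual = sum(
                e.mass_mg for e in step1.residual_media.entries if e.compound_id == c
            )
            assert step1.consumed.get(c, 0.0) + residual == pytest.approx(mass, abs=1e-3)

    def test_yield_bounded_by_hundred(self, setup_a, setup_ab):
        for setup in (setup_a, setup_ab):
            res = run_pipeline(setup)
            assert 0.0 <= res.yield_min_pct <= res.yield_max_pct <= 100.0
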
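"""Costing arithmetic against independent hand oracles, and accumulation."""

from __future__ import annotations

import numpy as np
import pytest

from psmcea.config import resolve_inputs
from psmcea.engine import EngineConfig, build_trace
from psmcea.synthetic import default_config
from psmcea.valuation import (
    ArmResult,
    DrugSpec,
    PatientProfile,
    accumulate,
    ae_one_off,
    drug_cost_per_cycle,
    first_line_cycle_cost,
    first_line_cost_vector,
    pd_cycle_cost,
    second_line_cycle_cost,
)

PROFILE = PatientProfile(weight_kg=60.0, bsa_m2=1.6)


@pytest.fixture(scope="module")
def inputs():
    """Reference inputs with the assistance program off (list-price costing)."""
    cfg = default_config()
    cfg.assistance.mode = "off"
    return resolve_inputs(cfg)


def expo(rate):
    return lambda t: np.exp(-rate * np.asarray(t, dtype=float))


class TestDrugCost:
    def test_pembrolizumab_flat_dose(self):
        spec = DrugSpec("pembrolizumab", 100, 2495.13, "flat_mg", 200, cap_cycles=35)
        # 200 mg / 100 mg units -> 2 units x 2495.13
        for cycle in (0, 1, 34):
            assert drug_cost_per_cycle(spec, PROFILE, cycle) == pytest.approx(4990.26)

    def test_pembrolizumab_capped_at_35(self):
        spec = DrugSpec("pembrolizumab", 100, 2495.13, "flat_mg", 200, cap_cycles=35)
        assert drug_cost_per_cycle(spec, PROFILE, 35) == 0.0

    def test_trastuzumab_loading_then_maintenance(self):
        spec = DrugSpec("trastuzumab", 1, 1.74, "per_kg", 6, loading_per_kg=8)
        # loading 8 mg/kg x 60 kg = 480 mg; maintenance 360 mg
        assert drug_cost_per_cycle(spec, PROFILE, 0) == pytest.approx(835.20)
        assert drug_cost_per_cycle(spec, PROFILE, 1) == pytest.approx(626.40)

    def test_vial_rounding_flag(self):
        spec = DrugSpec("x", 100, 10.0, "per_kg", 2.5, vial_rounding=True)
        # 150 mg -> 1.5 units -> 2 vials
        assert drug_cost_per_cycle(spec, PROFILE, 1) == pytest.approx(20.0)

    def test_negative_cycle_rejected(self):
        spec = DrugSpec("x", 100, 10.0, "flat_mg", 100)
        with pytest.raises(ValueError):
            drug_cost_per_cycle(spec, PROFILE, -1)


class TestFirstLineCost:
    def test_chemo_component_weighted_mix(self, inputs):
        """Hand oracle from unit prices: FP $130.43, CAPOX $147.03 per cycle,
        weighted 0.15/0.85 -> $144.54."""
        total = first_line_cycle_cost("PEM", inputs, cycle_index=1)
        pem = 2 * 2495.13
        tras = 360 * 1.74
        fp = 6400 / 100 * 1.80 + 128 / 10 * 1.19
        capox = 44800 / 1000 * 0.59 + 208 / 100 * 57.98
        chemo = 0.15 * fp + 0.85 * capox
        assert chemo == pytest.approx(144.54, abs=0.01)
        expected = pem + tras + chemo + 62.40 + 45.01
        assert total == pytest.approx(expected, abs=1e-9)

    def test_comparator_contains_no_pembrolizumab(self, inputs):
        delta = first_line_cycle_cost("PEM", inputs, 1) - first_line_cycle_cost(
            "TRAS", inputs, 1
        )
        fp = 6400 / 100 * 1.80 + 128 / 10 * 1.19
        capox = 44800 / 1000 * 0.59 + 208 / 100 * 57.98
        mix_shift = (0.15 - 0.14) * fp + (0.85 - 0.86) * capox
        assert delta == pytest.approx(4990.26 + mix_shift, abs=1e-9)

    def test_only_follow_up_after_cap(self, inputs):
        assert first_line_cycle_cost("PEM", inputs, 35) == pytest.approx(45.01)
        assert first_line_cycle_cost("TRAS", inputs, 40) == pytest.approx(45.01)

    def test_vector_matches_scalar(self, inputs):
        vec = first_line_cost_vector("PEM", inputs, 40)
        scal = [first_line_cycle_cost("PEM", inputs, i) for i in range(40)]
        assert np.allclose(vec, scal)

    def test_assistance_scheme_zeroes_later_pembrolizumab_cycles(self):
        cfg = default_config()
        cfg.assistance.mode = "free_after_n"
        cfg.assistance.free_after_n = 4
        mi = resolve_inputs(cfg)
        vec = first_line_cost_vector("PEM", mi, 10)
        cfg.assistance.mode = "off"
        vec_off = first_line_cost_vector("PEM", resolve_inputs(cfg), 10)
        assert np.allclose(vec[:4], vec_off[:4])
        assert np.allclose(vec_off[4:] - vec[4:], 4990.26)


class TestPDCost:
    def test_second_line_hand_oracle(self, inputs):
        """Ramucirumab 960 mg x $6.09 + paclitaxel 384 mg -> $5,945.47 per
        28-day cycle; x 21/28 -> $4,459.10 per model cycle."""
        sl = second_line_cycle_cost(inputs)
        assert sl == pytest.approx(5945.47 * 21 / 28, abs=0.01)
        assert sl == pytest.approx(4459.10, abs=0.01)

    def test_rate_zero_is_bsc_plus_follow_up(self, inputs):
        mi = resolve_inputs(default_config(), {"subsequent.PEM": 0.0})
        assert pd_cycle_cost("PEM", mi) == pytest.approx(348.00 + 45.01)

    def test_rate_one_is_treatment_plus_admin_plus_follow_up(self, inputs):
        mi = resolve_inputs(default_config(), {"subsequent.TRAS": 1.0})
        expected = second_line_cycle_cost(mi) + 62.40 + 45.01
        assert pd_cycle_cost("TRAS", mi) == pytest.approx(expected)

    def test_weighting(self, inputs):
        got = pd_cycle_cost("PEM", inputs)
        sl = second_line_cycle_cost(inputs)
        expected = 0.39 * (sl + 62.40) + 0.61 * 348.00 + 45.01
        assert got == pytest.approx(expected, abs=1e-9)


class TestAdverseEvents:
    def test_intervention_arm_hand_oracle(self, inputs):
        cost, _ = ae_one_off(inputs.adverse_events["PEM"], 21 / 365.25)
        expected = (
            0.0629 * 551.40
            + 0.0629 * 1648.55
            + 0.06 * 486.62
            + 0.0886 * 46.01
            + 0.08 * 551.40
        )
        assert cost == pytest.approx(expected, abs=1e-9)
        assert cost == pytest.approx(215.76, abs=0.01)

    def test_comparator_arm_hand_oracle(self, inputs):
        cost, _ = ae_one_off(inputs.adverse_events["TRAS"], 21 / 365.25)
        expected = 0.0665 * 1648.55 + 0.0578 * 486.62 + 0.078 * 46.01 + 0.0867 * 551.40
        assert cost == pytest.approx(expected, abs=1e-9)
        assert cost == pytest.approx(189.16, abs=0.01)

    def test_qaly_loss_scales_with_duration(self, inputs):
        _, loss1 = ae_one_off(inputs.adverse_events["PEM"], 21 / 365.25)
        _, loss2 = ae_one_off(inputs.adverse_events["PEM"], 42 / 365.25)
        assert loss2 == pytest.approx(2 * loss1)

    def test_empty_burden(self):
        assert ae_one_off((), 0.057) == (0.0, 0.0)


class TestAccumulate:
    def _trace(self, mi, rate_pfs=0.1, rate_os=0.06):
        return build_trace(expo(rate_pfs), expo(rate_os), mi.engine)

    def test_utility_one_identity(self):
        """With unit utilities, no AEs and no discounting, total QALYs equal
        undiscounted total LYs."""
        cfg = default_config()
        cfg.engine.discount_rate.base = 0.0
        cfg.utilities.pfs.base = 1.0
        cfg.utilities.pfs.dist = "fixed"
        cfg.utilities.pd.base = 1.0
        cfg.utilities.pd.dist = "fixed"
        for arm in cfg.adverse_events.incidence:
            for p in cfg.adverse_events.incidence[arm].values():
                p.base, p.low, p.high = 1e-12, None, None
                p.dist = "fixed"
        mi = resolve_inputs(cfg)
        tr = self._trace(mi)
        res = accumulate(tr, "PEM", mi)
        from psmcea.engine import life_years

        _, _, ly = life_years(tr, discounted=False)
        assert res.qaly_total == pytest.approx(ly, rel=1e-9)

    def test_immortal_cohort_has_no_death_cost(self, inputs):
        one = lambda t: np.ones_like(np.asarray(t, float))
        tr = build_trace(one, one, inputs.engine)
        res = accumulate(tr, "PEM", inputs)
        assert res.cost_death == 0.0

    def test_end_of_life_cost_linearity(self):
        cfg = default_config()
        mi1 = resolve_inputs(cfg)
        mi2 = resolve_inputs(cfg, {"costs.end_of_life": 2 * 2122.47})
        tr = self._trace(mi1)
        r1, r2 = accumulate(tr, "TRAS", mi1), accumulate(tr, "TRAS", mi2)
        assert r2.cost_death == pytest.approx(2 * r1.cost_death, rel=1e-12)
        assert r2.cost_pfs == pytest.approx(r1.cost_pfs, rel=1e-12)
        assert r2.cost_pd == pytest.approx(r1.cost_pd, rel=1e-12)

    def test_totals_are_component_sums(self, inputs, results_total):
        for res in results_total.values():
            assert res.cost_total == pytest.approx(
                res.cost_pfs + res.cost_pd + res.cost_death, abs=0.005
            )
            assert res.qaly_total == pytest.approx(res.qaly_pfs + res.qaly_pd, abs=1e-9)

    def test_death_cost_bounded_by_end_of_life_cost(self, inputs):
        tr = self._trace(inputs)
        res = accumulate(tr, "PEM", inputs)
        assert 0 < res.cost_death <= inputs.end_of_life

    def test_flat_cost_closed_form_without_discounting(self):
        """With zero discounting the PFS drug spend equals cost/cycle x
        person-cycles, checked in closed form for an exponential curve."""
        cfg = default_config()
        cfg.engine.discount_rate.base = 0.0
        cfg.assistance.mode = "off"
        mi = resolve_inputs(cfg)
        one = lambda t: np.ones_like(np.asarray(t, float))
        rate = 0.2
        tr = build_trace(expo(rate), one, mi.engine)
        res = accumulate(tr, "TRAS", mi)
        vec = first_line_cost_vector("TRAS", mi, tr.n_cycles)
        expected = float(np.sum(tr.occ_pfs * vec))
        ae_cost, _ = ae_one_off(mi.adverse_events["TRAS"], mi.engine.cycle_years)
        assert res.cost_pfs == pytest.approx(expected + ae_cost, rel=1e-12)

    def test_monotone_in_unit_price(self):
        """Every cost component is non-decreasing in each unit price."""
        cfg = default_config()
        base = resolve_inputs(cfg)
        tr = self._trace(base)
        r0 = accumulate(tr, "PEM", base)
        rng = np.random.default_rng(3)
        for name in (
            "drugs.trastuzumab.unit_cost",
            "drugs.oxaliplatin.unit_cost",
            "drugs.ramucirumab.unit_cost",
            "costs.follow_up_per_cycle",
            "costs.end_of_life",
            "ae.costs.anemia",
        ):
            bump = resolve_inputs(cfg, {name: _base_value(cfg, name) * (1 + rng.uniform(0.05, 0.4))})
            r1 = accumulate(tr, "PEM", bump)
            assert r1.cost_total >= r0.cost_total - 1e-9


def _base_value(cfg, name):
    from psmcea.config import parameter_specs

    return {s.name: s.base for s in parameter_specs(cfg)}[name]
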
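"""Core model types, validation, steady state, residence and relaxation."""

import math

import numpy as np
import pytest

from znbox.model import (
    BoxModel,
    Compartment,
    FluxSpec,
    ModelError,
    alpha_to_delta,
    delta_to_alpha,
    load_model,
    model_from_dict,
    relaxation_modes,
    relaxation_times,
    residence_time,
    save_model,
    steady_state,
    validate_mass_balance,
)
from znbox.rat import rat_model

from conftest import make_single_box, make_two_box


class TestValidation:
    def test_rejects_self_loop(self):
        with pytest.raises(ModelError, match="self-loop"):
            FluxSpec("a", "a", 1.0)

    def test_rejects_negative_rate(self):
        with pytest.raises(ModelError, match="negative rate"):
            FluxSpec("a", "b", -1.0)

    def test_rejects_alpha_outside_sanity_band(self):
        with pytest.raises(ModelError, match="sanity band"):
            FluxSpec("a", "b", 1.0, alpha=1.02)

    def test_rejects_unknown_compartment(self):
        comps = [Compartment("diet", role="source", delta0=0.0),
                 Compartment("waste", role="sink")]
        with pytest.raises(ModelError, match="unknown compartment"):
            BoxModel(comps, [FluxSpec("diet", "nowhere", 1.0)])

    def test_rejects_duplicate_edge(self):
        comps = [Compartment("diet", role="source", delta0=0.0),
                 Compartment("a", mass=10.0),
                 Compartment("waste", role="sink")]
        fluxes = [FluxSpec("diet", "a", 1.0), FluxSpec("a", "waste", 1.0),
                  FluxSpec("diet", "a", 2.0)]
        with pytest.raises(ModelError, match="duplicate flux edge"):
            BoxModel(comps, fluxes)

    def test_empty_flux_list_is_disconnected(self):
        comps = [Compartment("diet", role="source", delta0=0.0),
                 Compartment("a", mass=10.0),
                 Compartment("waste", role="sink")]
        with pytest.raises(ModelError, match="source not connected"):
            BoxModel(comps, [])

    def test_accumulator_needs_single_efflux_to_sink(self):
        comps = [Compartment("diet", role="source", delta0=0.0),
                 Compartment("a", mass=10.0),
                 Compartment("exc", mass=5.0, role="accumulator"),
                 Compartment("waste", role="sink")]
        fluxes = [FluxSpec("diet", "a", 2.0), FluxSpec("a", "exc", 2.0),
                  FluxSpec("exc", "a", 2.0)]
        with pytest.raises(ModelError, match="accumulator"):
            BoxModel(comps, fluxes)

    def test_finite_box_requires_positive_mass(self):
        with pytest.raises(ModelError, match="mass > 0"):
            Compartment("a", mass=0.0)

    def test_cap_delta_alpha_consistency_enforced_on_load(self):
        doc = {
            "compartments": [
                {"name": "diet", "mass": "infinite", "role": "source", "delta0": 0.0},
                {"name": "a", "mass": 10.0},
                {"name": "waste", "mass": "infinite", "role": "sink"},
            ],
            "fluxes": [
                {"from": "diet", "to": "a", "rate": 1.0, "alpha": 1.0, "cap_delta": 0.5},
                {"from": "a", "to": "waste", "rate": 1.0, "alpha": 1.0},
            ],
        }
        with pytest.raises(ModelError, match="inconsistent"):
            model_from_dict(doc)


class TestAlphaDelta:
    @pytest.mark.parametrize("delta", [-0.42, -0.05, 0.01, 0.28, 0.44])
    def test_round_trip(self, delta):
        assert alpha_to_delta(delta_to_alpha(delta)) == pytest.approx(delta, abs=1e-12)

    def test_ln_and_linear_conversion_agree_at_printed_precision(self):
        # 1000 ln(alpha) and (alpha-1)*1000 coincide to < 0.005 per mil here
        alpha = 0.99958
        assert abs(alpha_to_delta(alpha) - (alpha - 1.0) * 1000.0) < 0.005


class TestMassBalance:
    def test_single_box_balanced(self, single_box):
        assert validate_mass_balance(single_box).balanced

    def test_printed_rat_model_has_muscle_plasma_imbalance(self):
        report = validate_mass_balance(rat_model("printed"))
        assert report.unbalanced["plasma"] == pytest.approx(673.0)
        assert report.unbalanced["muscle"] == pytest.approx(-673.0)

    def test_balanced_rat_model_is_balanced(self):
        assert validate_mass_balance(rat_model("balanced")).balanced


class TestSteadyState:
    def test_no_fractionation_collapses_to_diet(self, two_box):
        ss = steady_state(two_box, diet_delta=0.37)
        for box in two_box.finite_boxes:
            assert ss[box] == pytest.approx(0.37, abs=1e-12)

    def test_dead_end_exchange_pair_offsets_by_twice_the_amplitude(self, rat_fitted):
        # a box exchanging only with plasma at -D/+D sits 2D below plasma
        ss = steady_state(rat_fitted, diet_delta=0.42)
        assert ss["liver"] - ss["plasma"] == pytest.approx(-0.84, abs=1e-9)
        assert ss["rbc"] - ss["plasma"] == pytest.approx(0.10, abs=1e-9)

    def test_reproduces_observed_liver_and_rbc(self, rat_fitted):
        ss = steady_state(rat_fitted, diet_delta=0.42)
        assert ss["liver"] == pytest.approx(-0.48, abs=0.02)
        assert ss["rbc"] == pytest.approx(0.46, abs=0.02)

    def test_accumulator_inherits_received_mixture(self, rat_fitted):
        ss = steady_state(rat_fitted, diet_delta=0.42)
        assert ss["feces"] == pytest.approx(ss["intestine"], abs=1e-12)

    def test_ratio_bookkeeping_agrees_to_quadratic_order(self, rat_fitted):
        d = steady_state(rat_fitted, 0.42, method="delta")
        r = steady_state(rat_fitted, 0.42, method="ratio")
        for box in rat_fitted.finite_boxes:
            assert d[box] == pytest.approx(r[box], abs=1e-3)

    def test_zero_efflux_box_raises_named_error(self):
        comps = [Compartment("diet", role="source", delta0=0.0),
                 Compartment("trap", mass=10.0),
                 Compartment("waste", role="sink")]
        model = BoxModel(comps, [FluxSpec("diet", "trap", 1.0),
                                 FluxSpec("diet", "waste", 1.0)])
        with pytest.raises(ModelError, match="trap"):
            steady_state(model, 0.0)

    def test_outputs_conserve_diet_composition(self, rat_fitted):
        # flux-weighted mean delta of all flows into sinks equals the diet
        # within the delta-linearisation error
        ss = steady_state(rat_fitted, 0.42)
        total = 0.0
        flux = 0.0
        for f in rat_fitted.fluxes:
            if rat_fitted.compartment(f.target).role == "sink":
                total += f.rate * (ss[f.source] + f.cap_delta)
                flux += f.rate
        assert total / flux == pytest.approx(0.42, abs=0.01)


class TestResidenceTime:
    def test_unit_turnover(self):
        model = make_single_box(mass=50.0, rate=50.0)
        assert residence_time(model, "box") == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "box,expected",
        [("muscle", 8.6), ("rbc", 9.1), ("liver", 0.4), ("intestine", 0.8),
         ("bone", 300.2), ("integument", 696.8)],
    )
    def test_rat_turnover_table(self, rat_fitted, box, expected):
        assert round(residence_time(rat_fitted, box), 1) == expected

    def test_plasma_reports_full_precision(self, rat_fitted):
        # printed as 0.0 after rounding; the engine keeps 32/1588.7 ~ 0.02
        assert residence_time(rat_fitted, "plasma") == pytest.approx(0.0201, abs=1e-3)

    def test_infinite_box_rejected(self, rat_fitted):
        with pytest.raises(ModelError, match="infinite"):
            residence_time(rat_fitted, "diet")


class TestRelaxation:
    def test_single_box_mode_is_mass_over_efflux(self):
        model = make_single_box(mass=120.0, rate=30.0)
        times = relaxation_times(model)
        assert times == pytest.approx([4.0])

    def test_no_return_chain_modes_equal_per_box_turnovers(self):
        # boxes in a pure feed-forward chain: rate matrix is triangular,
        # eigenvalues are the per-box efflux constants
        comps = [Compartment("diet", role="source", delta0=0.0),
                 Compartment("a", mass=10.0), Compartment("b", mass=40.0),
                 Compartment("waste", role="sink")]
        fluxes = [FluxSpec("diet", "a", 5.0), FluxSpec("a", "b", 5.0),
                  FluxSpec("b", "waste", 5.0)]
        model = BoxModel(comps, fluxes)
        assert relaxation_times(model) == pytest.approx([2.0, 8.0])

    def test_flux_scaling_rescales_times_and_preserves_steady_state(self, two_box):
        k = 3.0
        scaled = BoxModel(
            two_box.compartments,
            [FluxSpec(f.source, f.target, f.rate * k, f.alpha) for f in two_box.fluxes],
        )
        assert relaxation_times(scaled) == pytest.approx(relaxation_times(two_box) / k)
        s0, s1 = steady_state(two_box, 0.2), steady_state(scaled, 0.2)
        for box in two_box.finite_boxes:
            assert s0[box] == pytest.approx(s1[box], abs=1e-12)

    def test_rat_modes_are_tagged_with_dominant_boxes(self, rat_fitted):
        modes = relaxation_modes(rat_fitted)
        assert modes[-1].dominant_box == "integument"
        assert modes[-2].dominant_box == "bone"


class TestConfigRoundTrip:
    def test_yaml_round_trip(self, tmp_path, rat_fitted):
        path = tmp_path / "model.yaml"
        save_model(rat_fitted, path)
        loaded = load_model(path)
        assert loaded.finite_boxes == rat_fitted.finite_boxes
        for f, g in zip(rat_fitted.fluxes, loaded.fluxes):
            assert f.edge == g.edge
            assert f.rate == pytest.approx(g.rate)
            assert f.alpha == pytest.approx(g.alpha, abs=1e-12)

    def test_json_round_trip(self, tmp_path, two_box):
        path = tmp_path / "model.json"
        save_model(two_box, path)
        assert load_model(path).finite_boxes == two_box.finite_boxes
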
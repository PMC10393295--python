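"""Laminar rate network: conservation, deposits, surgery operations and the
weight/placement dissociation."""

import numpy as np
import pytest

from lamcsd.config import RunConfig
from lamcsd.core import InvalidArgumentError
from lamcsd.csd_metrics import wd_csd
from lamcsd.icsd import build_forward
from lamcsd.laminar_model import (
    LaminarNetwork,
    PopulationSpec,
    ProjectionSpec,
    ablate,
    build_default_network,
    default_inputs,
    feedback_switch,
    population_csd_contribution,
    scale_weights,
    set_placement,
    simulate,
)
from lamcsd.pipeline import model_csd_pattern


@pytest.fixture(scope="module")
def base_result():
    return simulate(build_default_network("original"))


class TestBuild:
    def test_presets_validate(self):
        for preset in ("original", "intermediate", "final"):
            net = build_default_network(preset)
            net.validate()
            assert set(net.populations) == {
                "E2/3", "E4", "E5", "E6", "I2/3", "I4", "I5", "I6"
            }

    def test_feedback_only_in_final(self):
        for preset, expect in (("original", False), ("intermediate", False),
                               ("final", True)):
            net = build_default_network(preset)
            has_lm = any(p.source == "LM" for p in net.projections)
            assert has_lm == expect

    def test_final_restricts_l6_recurrent_placement(self):
        net = build_default_network("final")
        for p in net.projections:
            if p.target == "E6" and p.source.startswith("E"):
                assert p.max_dist == 150.0

    def test_unknown_preset(self):
        with pytest.raises(InvalidArgumentError):
            build_default_network("v2")

    def test_apical_on_inhibitory_rejected(self):
        net = build_default_network("original")
        net.projections.append(
            ProjectionSpec("LGN", "I4", 0.5, "apical", 0.0, 100.0)
        )
        with pytest.raises(InvalidArgumentError, match="apical"):
            net.validate()


class TestSimulate:
    def test_zero_input_zero_output(self):
        net = build_default_network("original")
        inputs = default_inputs()
        zeroed = {k: (v if k == "t_ms" else np.zeros_like(v))
                  for k, v in inputs.items()}
        res = simulate(net, inputs=zeroed)
        for r in res.rates.values():
            assert not r.any()
        assert not res.csd_total.any()

    def test_current_conservation(self, base_result):
        integral = np.abs(base_result.csd_total.sum(axis=0)).max()
        scale = np.abs(base_result.csd_total).sum()
        assert integral <= 1e-6 * max(scale, 1e-30)

    def test_per_population_conservation(self, base_result):
        for pop, grid in base_result.csd_by_population.items():
            assert np.abs(grid.sum(axis=0)).max() <= 1e-9 * max(
                np.abs(grid).sum(), 1e-30
            )

    def test_lfp_consistent_with_forward_operator(self, base_result):
        op = build_forward(base_result.depth_axis, context="model")
        np.testing.assert_allclose(
            base_result.lfp_total, op.matrix @ base_result.csd_total, rtol=1e-10
        )

    def test_deterministic(self):
        net = build_default_network("final")
        a = simulate(net, seed=1)
        b = simulate(net, seed=1)
        np.testing.assert_array_equal(a.csd_total, b.csd_total)

    def test_basal_pulse_creates_single_dipole(self):
        """Pulse through a basal-only projection deposits one sink below the
        soma and one source at the soma (hand-computable two-kernel layout)."""
        pops = {
            "E4": PopulationSpec("E4", 100, 370.0, 120.0, 180.0, "excitatory"),
        }
        net = LaminarNetwork(
            populations=pops,
            projections=[ProjectionSpec("LGN", "E4", 1.0, "basal", 0.0, 120.0)],
        )
        res = simulate(net)
        contrib = res.csd_by_population["E4"]
        profile = contrib[:, np.abs(contrib).sum(axis=0).argmax()]
        soma_idx = np.argmin(np.abs(net.depth_axis - 370.0))
        # source (positive) at the soma, sink (negative) below it
        assert profile[soma_idx] > 0
        sink_idx = profile.argmin()
        assert net.depth_axis[sink_idx] > 370.0
        # sign changes exactly once between soma and sink region
        sgn = np.sign(profile[np.abs(profile) > 1e-12 * np.abs(profile).max()])
        assert (np.diff(sgn) != 0).sum() == 1


class TestSurgery:
    def test_scale_weights_identity(self, base_result):
        net = build_default_network("original")
        res = simulate(scale_weights(net, {p.name: 1.0 for p in net.projections}))
        np.testing.assert_array_equal(res.csd_total, base_result.csd_total)

    def test_scale_weights_immutable_original(self):
        net = build_default_network("original")
        w0 = [p.weight for p in net.projections]
        scale_weights(net, {net.projections[0].name: 2.0})
        assert [p.weight for p in net.projections] == w0

    def test_e_to_i_reduction_direction(self, base_result):
        """Weakening E->I disinhibits: I rates fall, E rates rise."""
        net = build_default_network("original")
        factors = {p.name: 0.7 for p in net.projections
                   if p.source.startswith("E") and p.target.startswith("I")}
        res = simulate(scale_weights(net, factors))
        for pop in ("I4", "I2/3"):
            assert res.rates[pop].max() < base_result.rates[pop].max()
        for pop in ("E4", "E2/3", "E5"):
            assert res.rates[pop].max() > base_result.rates[pop].max()

    def test_nonpositive_factor_rejected(self):
        net = build_default_network("original")
        with pytest.raises(InvalidArgumentError):
            scale_weights(net, {net.projections[0].name: 0.0})

    def test_unknown_projection_rejected(self):
        net = build_default_network("original")
        with pytest.raises(InvalidArgumentError, match="unknown"):
            scale_weights(net, {"X->Y": 1.5})

    def test_set_placement_identity(self, base_result):
        net = build_default_network("original")
        net2 = set_placement(net, "LGN->I4", "basal")  # basal -> basal
        res = simulate(net2)
        np.testing.assert_array_equal(res.csd_total, base_result.csd_total)

    def test_apical_on_inhibitory_rejected(self):
        net = build_default_network("original")
        with pytest.raises(InvalidArgumentError, match="apical"):
            set_placement(net, "LGN->I4", "apical")

    def test_apical_scheme_reduces_rate_vs_basal(self):
        net = build_default_network("original")
        sel = lambda p: p.target == "E4" and p.source in ("LGN",)
        r_basal = simulate(set_placement(net, sel, "basal")).rates["E4"].max()
        r_apical = simulate(set_placement(net, sel, "apical")).rates["E4"].max()
        assert r_apical < r_basal

    def test_ablate_recurrent_leaves_external_deposits(self):
        net = build_default_network("final")
        cut = ablate(net, "recurrent")
        assert all(p.source not in net.populations for p in cut.projections)
        res = simulate(cut)
        assert np.abs(res.csd_total).sum() > 0

    def test_ablate_inhibitory(self):
        net = build_default_network("original")
        cut = ablate(net, "inhibitory")
        assert not any(p.source.startswith("I") for p in cut.projections)

    def test_ablate_feedback_removes_upper_layer_dipole(self):
        cfg = RunConfig.default()
        net = build_default_network("final")
        with_fb = model_csd_pattern(cfg, simulate(net))
        without = model_csd_pattern(cfg, simulate(ablate(net, "feedback")))
        diff = with_fb.values - without.values
        # feedback deposits: sink above 300 µm, source in the L4 band
        upper = diff[with_fb.depth_axis < 300.0]
        assert upper.min() < -1e-6
        late = diff[:, with_fb.time_axis > 60.0]
        assert np.abs(late).sum() > np.abs(diff[:, with_fb.time_axis < 40.0]).sum()

    def test_ablate_unknown(self):
        with pytest.raises(InvalidArgumentError):
            ablate(build_default_network("original"), "everything")


class TestContributions:
    def test_sum_equals_total(self, base_result):
        total = sum(
            population_csd_contribution(base_result, p)
            for p in base_result.csd_by_population
        )
        np.testing.assert_array_equal(total, base_result.csd_total)

    def test_unconnected_population_zero(self):
        pops = {
            "E4": PopulationSpec("E4", 10, 370.0, 120.0, 180.0, "excitatory"),
            "E5": PopulationSpec("E5", 10, 540.0, 120.0, 460.0, "excitatory"),
        }
        net = LaminarNetwork(
            populations=pops,
            projections=[ProjectionSpec("LGN", "E4", 1.0, "basal", 0.0, 120.0)],
        )
        res = simulate(net)
        assert not population_csd_contribution(res, "E5").any()

    def test_doubling_input_doubles_contribution_only(self):
        pops = {
            "E4": PopulationSpec("E4", 10, 370.0, 120.0, 180.0, "excitatory"),
            "E5": PopulationSpec("E5", 10, 540.0, 120.0, 460.0, "excitatory"),
        }
        projs = [
            ProjectionSpec("LGN", "E4", 1.0, "basal", 0.0, 120.0),
            ProjectionSpec("BKG", "E5", 0.5, "basal", 0.0, 120.0),
        ]
        net = LaminarNetwork(populations=dict(pops), projections=list(projs))
        res1 = simulate(net)
        net2 = scale_weights(net, {"LGN->E4": 2.0})
        res2 = simulate(net2)
        np.testing.assert_allclose(
            population_csd_contribution(res2, "E4"),
            2 * population_csd_contribution(res1, "E4"), rtol=1e-10,
        )
        np.testing.assert_allclose(
            population_csd_contribution(res2, "E5"),
            population_csd_contribution(res1, "E5"), rtol=1e-10,
        )

    def test_unknown_population(self, base_result):
        with pytest.raises(InvalidArgumentError):
            population_csd_contribution(base_result, "E7")


class TestFeedbackSwitch:
    def test_off_at_zero_equals_ablation(self):
        net = build_default_network("final")
        inputs = feedback_switch(default_inputs(), 0.0)
        res_switch = simulate(net, inputs=inputs)
        res_ablate = simulate(ablate(net, "feedback"))
        np.testing.assert_allclose(
            res_switch.csd_total, res_ablate.csd_total, atol=1e-12
        )

    def test_off_after_end_is_noop(self):
        net = build_default_network("final")
        inputs = default_inputs()
        res_a = simulate(net, inputs=feedback_switch(inputs, 149.5))
        res_b = simulate(net, inputs=inputs)
        np.testing.assert_allclose(res_a.csd_total, res_b.csd_total, atol=1e-12)

    def test_deposits_vanish_after_off_time(self):
        net = build_default_network("final")
        res_on = simulate(net)
        res_off = simulate(net, inputs=feedback_switch(default_inputs(), 60.0))
        diff = res_on.csd_total - res_off.csd_total
        t = res_on.time_axis
        # identical before the switch (plus synaptic delay)
        assert np.abs(diff[:, t < 60.0]).max() <= 1e-12
        assert np.abs(diff[:, t > 80.0]).max() > 0

    def test_outside_window_rejected(self):
        with pytest.raises(InvalidArgumentError):
            feedback_switch(default_inputs(), 500.0)


class TestDissociation:
    def test_weight_vs_placement_two_way_dissociation(self):
        """Placement flip moves the normalized CSD pattern (large WD) with
        tiny rate changes; targeted weight scaling moves rates with a smaller
        pattern change."""
        cfg = RunConfig.default()
        net = build_default_network("original")
        base = simulate(net)
        pat0 = model_csd_pattern(cfg, base)

        factors = {p.name: 0.7 for p in net.projections
                   if p.source.startswith("E") and p.target.startswith("I")}
        res_w = simulate(scale_weights(net, factors))
        wd_weight = wd_csd(pat0, model_csd_pattern(cfg, res_w)).wd_total

        sel = lambda p: p.target == "E4" and (
            p.source == "LGN" or p.source.startswith("E")
        )
        res_p = simulate(set_placement(net, sel, "basal"))
        wd_place = wd_csd(pat0, model_csd_pattern(cfg, res_p)).wd_total

        def max_rate_change(res):
            return max(
                abs(res.rates[p].max() - base.rates[p].max())
                / max(base.rates[p].max(), 1e-12)
                for p in base.rates
            )

        assert wd_place > 2.0 * wd_weight
        assert max_rate_change(res_w) > 2.0 * max_rate_change(res_p)


class TestActiveReturn:
    def test_off_by_default_and_conserving_when_on(self):
        net = build_default_network("original")
        off = simulate(net)
        on = simulate(net, somatic_active_gain=0.3)
        assert np.abs(on.csd_total - off.csd_total).max() > 0
        integral = np.abs(on.csd_total.sum(axis=0)).max()
        assert integral <= 1e-6 * np.abs(on.csd_total).sum()

    def test_adds_source_at_l4_somata(self):
        net = build_default_network("original")
        off = simulate(net)
        on = simulate(net, somatic_active_gain=0.3)
        diff = on.csd_by_population["E4"] - off.csd_by_population["E4"]
        soma_idx = np.argmin(np.abs(net.depth_axis - 370.0))
        assert diff[soma_idx].max() > 0  # extra outward current at the soma
        # inhibitory populations untouched
        np.testing.assert_array_equal(
            on.csd_by_population["I4"], off.csd_by_population["I4"]
        )
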
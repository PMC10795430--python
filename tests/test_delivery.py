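import numpy as np
import pytest

from gateqa.breathing import Cos4Spec, eval_cos4
from gateqa.delivery import (
    DeliveryTiming,
    DoseProfile,
    GridSpec,
    MotionModel,
    SpotPlan,
    make_uniform_plan,
    point_dose,
    simulate_delivery,
)
from gateqa.gating import GateSignal
from gateqa.profile_metrics import width_at


def single_spot_plan(weight=1.0):
    return SpotPlan([np.array([[0.0, weight]])])


class TestPlanConstruction:
    def test_uniform_plan_counts(self):
        plan = make_uniform_plan(40.0, 2.0, n_layers=1)
        assert len(plan.layers[0]) == 21
        assert plan.fwhm == 10.0
        plan9 = make_uniform_plan(40.0, 2.0, n_layers=9)
        assert plan9.n_layers == 9
        assert all(np.array_equal(l, plan9.layers[0]) for l in plan9.layers)

    def test_rows_split_weight_but_conserve_total(self):
        a = make_uniform_plan(40.0, 2.0, n_layers=3, weight=2.0)
        b = make_uniform_plan(40.0, 2.0, n_layers=3, weight=2.0, n_rows=8)
        assert b.total_weight == pytest.approx(a.total_weight)
        assert len(b.layers[0]) == 8 * 21

    def test_invalid_spacing_rejected(self):
        with pytest.raises(ValueError):
            make_uniform_plan(10.0, 20.0)

    def test_json_roundtrip(self, tmp_path):
        plan = make_uniform_plan(40.0, 2.0, n_layers=2)
        plan.to_json(tmp_path / "plan.json")
        back = SpotPlan.from_json(tmp_path / "plan.json")
        assert back.fwhm == plan.fwhm
        assert all(np.allclose(a, b)
                   for a, b in zip(back.layers, plan.layers))


class TestStaticDelivery:
    def test_single_spot_is_a_gaussian_of_plan_fwhm(self):
        prof, log = simulate_delivery(single_spot_plan(), None, None,
                                      DeliveryTiming(particle_rate=1.0))
        assert log["status"] == "ok"
        # normalise to the peak: a lone spot has no flat plateau
        fwhm = width_at(prof, 50.0, plateau=prof.dose.max())
        assert fwhm == pytest.approx(10.0, rel=0.02)
        assert prof.integral() == pytest.approx(1.0, rel=1e-6)

    def test_weight_conservation_across_modes(self, cos4_trace,
                                              reference_gate):
        plan = make_uniform_plan(40.0, 2.0, n_layers=2, n_rows=4)
        timing = DeliveryTiming.for_layer_duration(plan, 1.5)
        motion = MotionModel(surrogate=cos4_trace)
        integrals = []
        for mot, beam, start in [(None, None, 0.0),
                                 (motion, None, 0.0),
                                 (motion, reference_gate,
                                  reference_gate.learning_end)]:
            prof, log = simulate_delivery(plan, mot, beam, timing,
                                          GridSpec(-80, 80),
                                          start_time=start)
            assert log["undelivered_weight"] == 0.0
            integrals.append(prof.integral())
        assert np.ptp(integrals) / integrals[0] < 1e-3

    def test_zero_motion_modes_identical(self, cos4_trace, reference_gate):
        # target/surrogate ratio 0: gating pauses change timing only
        plan = make_uniform_plan(30.0, 3.0, n_layers=2)
        timing = DeliveryTiming.for_layer_duration(plan, 1.5)
        frozen = MotionModel(surrogate=cos4_trace, ratios={"IS": 0.0})
        p_static, _ = simulate_delivery(plan, None, None, timing)
        p_nongated, _ = simulate_delivery(plan, frozen, None, timing)
        p_gated, _ = simulate_delivery(plan, frozen, reference_gate, timing,
                                       start_time=reference_gate.learning_end)
        assert np.allclose(p_static.dose, p_nongated.dose, atol=1e-9)
        assert np.allclose(p_static.dose, p_gated.dose, atol=1e-9)


def test_nongated_single_spot_matches_occupancy_convolution(cos4_trace):
    """Long non-gated delivery of one spot: the target-frame profile is the
    spot Gaussian convolved with the position-occupancy density of the
    motion (independent numerical-convolution oracle)."""
    plan = single_spot_plan(weight=40.0)  # 40 s of beam: 10 periods
    motion = MotionModel(surrogate=cos4_trace)
    grid = GridSpec(-40, 25)
    prof, _ = simulate_delivery(plan, motion, None,
                                DeliveryTiming(particle_rate=1.0), grid)

    # oracle: occupancy histogram of -x(t) on a fine independent time grid
    tt = np.arange(0.0, 40.0, 5e-4)
    x = eval_cos4(Cos4Spec(20.0, 4.0, 60.0), tt)
    pos = grid.positions()
    occ, edges = np.histogram(-x, bins=np.append(pos - grid.spacing / 2,
                                                 pos[-1] + grid.spacing / 2))
    occ = occ / occ.sum() * 40.0 / grid.spacing
    sigma = 10.0 / (2 * np.sqrt(2 * np.log(2)))
    half = int(np.ceil(5 * sigma / grid.spacing))
    kern = np.exp(-0.5 * (np.arange(-half, half + 1) * grid.spacing / sigma) ** 2)
    oracle = np.convolve(occ, kern / kern.sum(), mode="same")

    rms = np.sqrt(np.mean((oracle - prof.dose) ** 2)) / prof.dose.max()
    assert rms <= 0.02


def test_empty_beam_yields_no_dose():
    beam = GateSignal(np.empty((0, 2)))
    prof, log = simulate_delivery(single_spot_plan(), None, beam,
                                  DeliveryTiming(particle_rate=1.0))
    assert log["status"] == "no_beam"
    assert np.all(prof.dose == 0)


class TestPointDose:
    def test_node_and_midpoint(self):
        prof = DoseProfile(np.array([0.0, 1.0, 2.0]),
                           np.array([1.0, 3.0, 5.0]))
        assert point_dose(prof, 1.0) == 3.0
        assert point_dose(prof, 0.5) == 2.0  # linear segment midpoint

    def test_symmetric_profile_center_is_max(self):
        p = np.linspace(-20, 20, 401)
        d = np.exp(-0.5 * (p / 5.0) ** 2)
        assert point_dose(DoseProfile(p, d), 0.0) == d.max()

    def test_out_of_grid_rejected(self):
        prof = DoseProfile(np.array([0.0, 1.0]), np.array([1.0, 1.0]))
        with pytest.raises(ValueError):
            point_dose(prof, 5.0)


def test_motion_model_axis_ratios(cos4_trace):
    m = MotionModel(surrogate=cos4_trace,
                    ratios={"AP": 0.625, "LR": 0.625, "IS": 1.0})
    t = np.array([0.0, 1.0, 2.0])
    assert np.allclose(m.target_position(t, "AP"),
                       0.625 * m.target_position(t, "IS"))
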
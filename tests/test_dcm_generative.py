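"""Model space wiring, neural drift, balloon model, and BOLD simulation."""

import numpy as np
import pytest

from precistim.dcm_generative import (
    INPUTS,
    DCMModel,
    DCMParams,
    HemoParams,
    InputSet,
    SimulationError,
    bold_signal,
    build_model_space,
    default_generating_params,
    hemodynamics_step,
    neural_drift,
    simulate_bold,
    stability_check,
)
from precistim.synthetic_data import GroupConfig, build_dcm_inputs, generate_schedule

IDX = {"IPL": 0, "rPFC": 1, "DLPFC": 2, "SFG": 3}


class TestModelSpace:
    def test_exactly_the_seven_motifs(self, model_space):
        assert [m.name for m in model_space] == \
            ["Diamond", "Fork", "Legs1", "Legs2", "Stork1", "Stork2", "Stork3"]

    def test_only_stork_models_have_gates(self, model_space):
        for m in model_space:
            assert m.is_nonlinear == m.name.startswith("Stork")
            if not m.name.startswith("Stork"):
                assert all(not mask.any() for mask in m.D_masks.values())

    def test_common_base_in_every_model(self, model_space):
        for m in model_space:
            assert m.A_mask[IDX["rPFC"], IDX["IPL"]]  # IPL -> rPFC
            assert m.A_mask[IDX["DLPFC"], IDX["IPL"]]  # IPL -> DLPFC
            assert m.A_mask[IDX["IPL"], IDX["DLPFC"]]  # backward DLPFC -> IPL
            assert m.B_masks["regular"][IDX["rPFC"], IDX["IPL"]]
            assert m.B_masks["different"][IDX["DLPFC"], IDX["IPL"]]
            assert m.C_mask[IDX["IPL"], 0]  # stim drives IPL
            assert m.A_mask.diagonal().all()

    def test_stork3_has_both_reciprocal_gates(self, models_by_name):
        m = models_by_name["Stork3"]
        assert m.D_masks["rPFC"][IDX["SFG"], IDX["DLPFC"]]
        assert m.D_masks["DLPFC"][IDX["SFG"], IDX["rPFC"]]


class TestNeuralDrift:
    def test_rest_is_a_fixed_point(self, models_by_name):
        m = models_by_name["Stork3"]
        p = default_generating_params(m)
        dx = neural_drift(np.zeros(4), np.zeros(3), p, m)
        assert np.allclose(dx, 0.0)

    def test_zero_gates_reduce_to_bilinear_form(self, models_by_name):
        m = models_by_name["Stork3"]
        p = default_generating_params(m)
        for g in p.D:
            p.D[g][:] = 0.0
        x = np.array([0.1, -0.2, 0.3, 0.05])
        u = np.array([1.0, 1.0, 0.0])
        A = p.effective_A() * m.A_mask
        M = A + u[1] * p.B["regular"] * m.B_masks["regular"]
        expected = M @ x + np.where(m.C_mask, p.C, 0.0) @ u
        assert np.allclose(neural_drift(x, u, p, m), expected)

    def test_two_node_gate_matches_expanded_expression(self):
        # hand-built 2-node model with node 1 gating its own afferent 0->1
        A_mask = np.eye(2, dtype=bool)
        A_mask[1, 0] = True
        C_mask = np.zeros((2, 3), dtype=bool)
        C_mask[0, 0] = True
        D_mask = np.zeros((2, 2), dtype=bool)
        D_mask[1, 0] = True
        m = DCMModel(name="toy", nodes=("n0", "n1"), A_mask=A_mask,
                     B_masks={}, C_mask=C_mask, D_masks={"n1": D_mask})
        a10, c, d, th = 0.3, 0.7, 0.9, 0.1
        A = np.zeros((2, 2))
        A[1, 0] = a10
        C = np.zeros((2, 3))
        C[0, 0] = c
        D = {"n1": np.array([[0.0, 0.0], [d, 0.0]])}
        p = DCMParams(A=A, B={}, C=C, D=D, theta_self=np.array([th, th]))
        x = np.array([0.4, -0.3])
        u = np.array([1.0, 0.0, 0.0])
        dx = neural_drift(x, u, p, m)
        s = -0.5 * np.exp(th)
        # expansion: dx0 = s x0 + c u;  dx1 = (a10 + x1 d) x0 + s x1
        assert dx[0] == pytest.approx(s * x[0] + c)
        assert dx[1] == pytest.approx((a10 + x[1] * d) * x[0] + s * x[1])

    def test_dimension_mismatch_raises(self, models_by_name):
        m = models_by_name["Diamond"]
        p = default_generating_params(m)
        with pytest.raises(ValueError):
            neural_drift(np.zeros(3), np.zeros(3), p, m)


class TestHemodynamics:
    def test_rest_is_a_fixed_point_with_zero_bold(self):
        dh, bold = hemodynamics_step(np.array([0.0, 1.0, 1.0, 1.0]), 0.0,
                                     HemoParams())
        assert np.allclose(dh, 0.0)
        assert bold == 0.0

    def test_output_constants_at_default_extraction(self):
        p = HemoParams(E0=0.4)
        # k1 = 2.8, k2 = 2, k3 = 0.6 at E0 = 0.4
        assert bold_signal(1.0, 0.5, p) == pytest.approx(
            0.04 * (2.8 * 0.5 + 2.0 * 0.5))
        assert bold_signal(0.5, 0.5, p) == pytest.approx(
            0.04 * (2.8 * 0.5 + 2.0 * 0.0 + 0.6 * 0.5))

    def test_nonpositive_volume_rejected(self):
        with pytest.raises(ValueError):
            hemodynamics_step(np.array([0.0, 1.0, -0.1, 1.0]), 0.0,
                              HemoParams())

    def test_neural_impulse_yields_delayed_positive_transient(self,
                                                              models_by_name):
        # a brief stimulus: BOLD peaks several seconds later, then returns
        m = models_by_name["Diamond"]
        p = default_generating_params(m)
        dt = 0.01
        T = int(30.0 / dt)
        u_stim = np.zeros(T)
        u_stim[:int(0.5 / dt)] = 1.0
        inputs = InputSet(dt=dt, u_stim=u_stim, u_regular=np.zeros(T),
                          u_different=np.zeros(T))
        series = simulate_bold(m, p, HemoParams(), inputs, tr=0.1)
        ipl = series.data[0]
        t_peak = np.argmax(ipl) * 0.1
        assert ipl.max() > 0
        assert 2.0 < t_peak < 8.0
        assert abs(ipl[-1]) < 0.15 * ipl.max()


class TestStability:
    def test_diagonal_case_margin(self, models_by_name):
        m = models_by_name["Diamond"]
        p = default_generating_params(m)
        p.A[:] = 0.0
        res = stability_check(p, m)
        assert res["stable"] and res["margin"] == pytest.approx(0.5)

    def test_positive_eigenvalue_fails(self, models_by_name):
        m = models_by_name["Diamond"]
        p = default_generating_params(m)
        p.theta_self[:] = -10.0  # self-decay ~ 0; strong loop destabilizes
        p.A[IDX["DLPFC"], IDX["IPL"]] = 1.0
        p.A[IDX["IPL"], IDX["DLPFC"]] = 1.0
        res = stability_check(p, m)
        assert not res["stable"]

    def test_rest_jacobian_equals_intrinsic_matrix(self, models_by_name):
        # gating terms vanish at x = 0, so the Jacobian is A itself
        m = models_by_name["Stork3"]
        p = default_generating_params(m)
        res = stability_check(p, m)
        A = p.effective_A() * m.A_mask
        assert np.allclose(sorted(res["eigenvalues"].real),
                           sorted(np.linalg.eigvals(A).real))


@pytest.fixture(scope="module")
def short_inputs():
    sched = generate_schedule(6, GroupConfig(), seed=13)
    return build_dcm_inputs(sched, dt=0.05, duration=80.0)


class TestSimulateBold:
    def test_noise_free_simulation_is_deterministic(self, models_by_name,
                                                    short_inputs):
        m = models_by_name["Stork3"]
        p = default_generating_params(m)
        a = simulate_bold(m, p, HemoParams(), short_inputs, tr=2.0)
        b = simulate_bold(m, p, HemoParams(), short_inputs, tr=2.0)
        assert np.array_equal(a.data, b.data)
        assert a.n_time == int(np.floor(short_inputs.duration / 2.0))

    def test_zero_inputs_give_flat_zero_series(self, models_by_name):
        m = models_by_name["Diamond"]
        p = default_generating_params(m)
        T = int(40.0 / 0.05)
        inputs = InputSet(dt=0.05, u_stim=np.zeros(T), u_regular=np.zeros(T),
                          u_different=np.zeros(T))
        series = simulate_bold(m, p, HemoParams(), inputs, tr=2.0)
        assert np.allclose(series.data, 0.0)

    def test_matches_tenfold_finer_reference(self, models_by_name):
        # same boxcars rendered on both grids; dt/10 is the reference oracle
        m = models_by_name["Stork3"]
        p = default_generating_params(m)
        sched = generate_schedule(6, GroupConfig(), seed=13)
        coarse = build_dcm_inputs(sched, dt=0.04, duration=80.0)
        fine = InputSet(dt=0.004,
                        u_stim=np.repeat(coarse.u_stim, 10),
                        u_regular=np.repeat(coarse.u_regular, 10),
                        u_different=np.repeat(coarse.u_different, 10))
        a = simulate_bold(m, p, HemoParams(), coarse, tr=2.0)
        b = simulate_bold(m, p, HemoParams(), fine, tr=2.0)
        scale = np.abs(b.data).max()
        assert np.abs(a.data - b.data).max() < 1e-3 * scale

    def test_stork_with_zero_gates_equals_bilinear_skeleton(
            self, models_by_name, short_inputs):
        stork = models_by_name["Stork3"]
        diamond = models_by_name["Diamond"]
        p = default_generating_params(stork)
        for g in p.D:
            p.D[g][:] = 0.0
        a = simulate_bold(stork, p, HemoParams(), short_inputs, tr=2.0)
        b = simulate_bold(diamond, p, HemoParams(), short_inputs, tr=2.0)
        assert np.allclose(a.data, b.data)

    def test_gating_produces_interaction_signature(self, models_by_name,
                                                   short_inputs):
        # factorial: (regular drive on/off) x (gates on/off); with gates on,
        # the SFG response to the same DLPFC input depends on rPFC activity
        stork = models_by_name["Stork3"]

        def sfg_response(gated: bool, regular_on: bool) -> float:
            p = default_generating_params(stork)
            if not gated:
                for g in p.D:
                    p.D[g][:] = 0.0
            u_reg = (short_inputs.u_regular if regular_on
                     else np.zeros_like(short_inputs.u_regular))
            inp = InputSet(dt=short_inputs.dt, u_stim=short_inputs.u_stim,
                           u_regular=u_reg,
                           u_different=short_inputs.u_different)
            series = simulate_bold(stork, p, HemoParams(), inp, tr=2.0)
            return float(np.abs(series.data[IDX["SFG"]]).max())

        interaction = ((sfg_response(True, True) - sfg_response(True, False))
                       - (sfg_response(False, True) - sfg_response(False, False)))
        assert abs(interaction) > 1e-4

    def test_small_signal_response_is_first_order_linear(self, models_by_name,
                                                         short_inputs):
        m = models_by_name["Diamond"]
        p1 = default_generating_params(m)
        p1.C *= 1e-3
        p2 = default_generating_params(m)
        p2.C *= 2e-3
        a = simulate_bold(m, p1, HemoParams(), short_inputs, tr=2.0)
        b = simulate_bold(m, p2, HemoParams(), short_inputs, tr=2.0)
        ratio = np.abs(b.data).max() / np.abs(a.data).max()
        assert ratio == pytest.approx(2.0, rel=2e-3)

    def test_unstable_parameters_raise(self, models_by_name, short_inputs):
        m = models_by_name["Diamond"]
        p = default_generating_params(m)
        p.theta_self[:] = -10.0
        p.A[IDX["DLPFC"], IDX["IPL"]] = 1.0
        p.A[IDX["IPL"], IDX["DLPFC"]] = 1.0
        with pytest.raises(SimulationError):
            simulate_bold(m, p, HemoParams(), short_inputs, tr=2.0)

    def test_integrator_error_shrinks_sixteen_fold_when_dt_halves(
            self, models_by_name):
        # boxcar edges aligned to the coarsest grid keep the vector field
        # piecewise-smooth, exposing the integrator's fourth-order accuracy
        m = models_by_name["Diamond"]
        p = default_generating_params(m)

        def run(dt):
            T = int(round(40.0 / dt))
            u = np.zeros(T)
            u[int(round(2.0 / dt)):int(round(4.0 / dt))] = 1.0
            inp = InputSet(dt=dt, u_stim=u, u_regular=np.zeros(T),
                           u_different=np.zeros(T))
            return simulate_bold(m, p, HemoParams(), inp, tr=8.0).data

        ref = run(0.0125)
        e1 = np.abs(run(0.2) - ref).max()
        e2 = np.abs(run(0.1) - ref).max()
        assert e1 / e2 > 8.0  # ~16 for a fourth-order scheme
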
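"""Rate laws, variant enumeration, ODE assembly and integration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from cocoaferm import model_core as mc
from cocoaferm._integrate import dp45_integrate, rhs_full, rk4_fixed


class TestRateLaws:
    @pytest.mark.parametrize(
        "mu, K, S, X, expected",
        [
            (0.8, 5.0, 0.0, 2.0, 0.0),
            (0.8, 5.0, 5.0, 2.0, 0.8),
            (0.4, 2.0, 3.0, 1.5, 0.36),
        ],
    )
    def test_monod(self, mu, K, S, X, expected):
        assert mc.monod_rate(mu, K, S, X) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "mu, K, S, X, expected",
        [
            (0.5, 1.0, 0.0, 3.0, 0.0),
            (0.5, 0.0, 4.0, 3.0, 1.5),
            (0.5, 2.0, 4.0, 1.0, 1.0 / 3.0),
        ],
    )
    def test_contois(self, mu, K, S, X, expected):
        assert mc.contois_rate(mu, K, S, X) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "k, X, P, order, expected",
        [(0.01, 5.0, 0.0, 1, 0.0), (0.01, 5.0, 2.0, 1, 0.1), (0.001, 4.0, 3.0, 2, 0.036)],
    )
    def test_mortality(self, k, X, P, order, expected):
        assert mc.mortality_rate(k, X, P, order) == pytest.approx(expected)

    def test_mortality_rejects_unsupported_order(self):
        with pytest.raises(ValueError, match="order"):
            mc.mortality_rate(0.1, 1.0, 1.0, 3)

    @pytest.mark.parametrize("b, M, expected", [(0.02, 0.0, 0.0), (0.0, 7.0, 0.0), (0.02, 7.0, 0.14)])
    def test_decay(self, b, M, expected):
        assert mc.decay_rate(b, M) == pytest.approx(expected)

    @pytest.mark.parametrize("fn", [mc.monod_rate, mc.contois_rate])
    def test_negative_arguments_rejected(self, fn):
        with pytest.raises(ValueError):
            fn(0.5, 1.0, -0.1, 1.0)

    @given(
        mu=st.floats(0, 2), K=st.floats(0, 5), S=st.floats(0, 10), X=st.floats(0, 5)
    )
    @settings(max_examples=200, deadline=None)
    def test_monod_bounded_by_mu_X(self, mu, K, S, X):
        rate = mc.monod_rate(mu, K, S, X)
        assert 0.0 <= rate <= mu * X + 1e-12


class TestVariants:
    def test_enumeration_has_32_unique_variants(self):
        variants = mc.enumerate_variants()
        labels = [v.label for v in variants]
        assert len(variants) == 32
        assert len(set(labels)) == 32
        assert labels[0] == "MI(0)"

    def test_enumeration_order_baseline_then_size_then_lexicographic(self):
        labels = [v.label for v in mc.enumerate_variants()]
        assert labels[1:6] == ["MI(1)", "MI(2)", "MI(3)", "MI(4)", "MI(5)"]
        assert labels[6] == "MI(1,2)"
        assert labels[-1] == "MI(1,2,3,4,5)"
        singles = [lab for lab in labels if lab.count(",") == 0 and lab != "MI(0)"]
        assert len(singles) == 5

    @pytest.mark.parametrize(
        "label, expected",
        [("MI(0)", 24), ("MI(1,2,3,4,5)", 43), ("MI(2)", 31), ("MI(2,3)", 33)],
    )
    def test_manifest_sizes(self, label, expected):
        assert mc.build_variant(label).n_params == expected

    def test_parameter_count_identity_all_variants(self):
        for ms in mc.enumerate_variants():
            v = mc.build_variant(ms)
            expected = (
                24 + 3 * ms.m1 + 7 * ms.m2 + 2 * ms.m3 + 4 * ms.m4 + 3 * ms.m5
            )
            assert v.n_params == expected == len(v.parameter_names)

    def test_baseline_manifest_breakdown(self):
        v = mc.build_variant("MI(0)")
        kinds = [mc.PARAMETER_TABLE[mc.PARAM_INDEX[n]].kind for n in v.parameter_names]
        assert kinds.count("mu") == 5
        assert kinds.count("K") == 5
        assert kinds.count("k") == 3
        assert kinds.count("yield") == 11

    def test_manifest_follows_table_row_order(self):
        for label in ("MI(0)", "MI(2,4)", "MI(1,2,3,4,5)"):
            v = mc.build_variant(label)
            idx = [mc.PARAM_INDEX[n] for n in v.parameter_names]
            assert idx == sorted(idx)

    def test_label_round_trip(self):
        for ms in mc.enumerate_variants():
            assert mc.MechanismSet.from_label(ms.label) == ms

    def test_bad_labels_rejected(self):
        for bad in ("MI(6)", "MI", "MI(1,1)"[:3], "M(1)"):
            with pytest.raises(ValueError):
                mc.MechanismSet.from_label(bad)


class TestRhs:
    def test_zero_state_gives_zero_derivative(self, full_params):
        out = mc.rhs(np.zeros(8), full_params, "MI(1,2,3,4,5)")
        assert np.all(out == 0.0)

    def test_ethanol_only_baseline_case(self):
        # only AAB growth on EtOH is active: v4 = 0.5 * (1/2) * 1 = 0.25
        params = dict.fromkeys(mc.build_variant("MI(0)").parameter_names, 0.0)
        params.update(
            mu_AAB_EtOH=0.5, K_AAB_EtOH=1.0, Y_EtOH_AAB=2.0, Y_Ac_AAB_EtOH=0.8, k_AAB=0.0
        )
        # remaining K entries zero is fine: their substrates are zero
        params = {k: v for k, v in params.items()}
        state = np.array([0, 0, 1.0, 0, 0, 0, 0, 1.0])
        out = mc.rhs(state, params, "MI(0)")
        expected = np.zeros(8)
        expected[2] = -0.5  # EtOH consumed
        expected[4] = 0.8 * 0.25  # Ac produced
        expected[7] = 0.25  # AAB growth
        np.testing.assert_allclose(out, expected, atol=1e-14)

    def test_decay_mechanism_isolated(self):
        state = np.zeros(8)
        state[4] = 2.0  # Ac only
        base = dict.fromkeys(mc.build_variant("MI(1)").parameter_names, 0.0)
        params = dict(base, b_Ac=0.1)
        with_decay = mc.rhs(state, params, "MI(1)")
        assert with_decay[4] == pytest.approx(-0.2)
        without = mc.rhs(state, {n: v for n, v in params.items() if not n.startswith("b_")}, "MI(0)")
        assert without[4] == 0.0

    def test_missing_mechanism_parameter_raises(self, baseline_params):
        with pytest.raises(KeyError):
            mc.rhs(np.ones(8), baseline_params, "MI(1)")

    def test_jitted_rhs_matches_reference(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            y = rng.uniform(0, 2, 8)
            p = rng.uniform(0, 1, 43)
            np.testing.assert_allclose(
                rhs_full(y, p), mc._rhs_reference(y, p), rtol=1e-12, atol=1e-14
            )


class TestSimulate:
    def test_zero_field_is_constant(self, init_state, times17):
        params = dict.fromkeys(mc.build_variant("MI(0)").parameter_names, 0.0)
        traj = mc.simulate("MI(0)", params, init_state, times17)
        np.testing.assert_allclose(traj, np.tile(init_state, (17, 1)), atol=1e-12)

    @pytest.mark.parametrize("label", ["MI(0)", "MI(1,2,3,4,5)"])
    def test_adaptive_matches_fixed_step_rk4_oracle(self, label, full_params, init_state, times17):
        """Per-state error relative to each trajectory's own scale < 1e-4."""
        variant = mc.build_variant(label)
        params = {n: full_params[n] for n in variant.parameter_names}
        traj = mc.simulate(variant, params, init_state, times17)
        p = mc.full_param_vector(params, variant.mechanisms)
        oracle = rk4_fixed(p, init_state.astype(float), times17, 0.001)
        scale = np.abs(oracle).max(axis=0)
        rel = np.abs(traj - oracle) / scale
        assert rel.max() < 1e-4

    def test_adaptive_matches_scipy_rk45(self, baseline_params, init_state, times17):
        p = mc.full_param_vector(baseline_params, mc.MechanismSet())
        traj = mc.simulate("MI(0)", baseline_params, init_state, times17)
        sol = solve_ivp(
            lambda t, y: rhs_full(y, p), (times17[0], times17[-1]), init_state,
            t_eval=times17, rtol=1e-9, atol=1e-9, method="RK45",
        )
        scale = np.abs(sol.y.T).max(axis=0)
        assert (np.abs(traj - sol.y.T) / scale).max() < 1e-4

    def test_decay_only_removes_mass(self, full_params, init_state, times17):
        """Products under M1 never exceed the baseline trajectory."""
        base_params = {
            n: full_params[n] for n in mc.build_variant("MI(0)").parameter_names
        }
        m1_params = dict(base_params, b_EtOH=0.05, b_LA=0.05, b_Ac=0.05)
        base = mc.simulate("MI(0)", base_params, init_state, times17)
        decayed = mc.simulate("MI(1)", m1_params, init_state, times17)
        for col in (2, 3, 4):  # EtOH, LA, Ac
            assert np.all(decayed[:, col] <= base[:, col] + 1e-9)

    def test_mechanism_nullity_bit_for_bit(self, full_params, init_state, times17):
        """Zeroed mechanism parameters reproduce the reduced variant exactly."""
        for sup, sub, extra in [
            ("MI(1)", "MI(0)", ("b_EtOH", "b_LA", "b_Ac")),
            ("MI(2,3)", "MI(3)", None),
        ]:
            sup_v = mc.build_variant(sup)
            sub_v = mc.build_variant(sub)
            extra = extra or tuple(
                set(sup_v.parameter_names) - set(sub_v.parameter_names)
            )
            params = {n: full_params[n] for n in sup_v.parameter_names}
            for n in extra:
                params[n] = 0.0
            sub_params = {n: full_params[n] for n in sub_v.parameter_names}
            a = mc.simulate(sup_v, params, init_state, times17)
            b = mc.simulate(sub_v, sub_params, init_state, times17)
            np.testing.assert_array_equal(a, b)

    def test_trajectories_remain_nonnegative(self, full_params, init_state):
        times = np.linspace(0, 160, 33)
        for label in ("MI(0)", "MI(2)", "MI(1,3,5)", "MI(1,2,3,4,5)"):
            variant = mc.build_variant(label)
            params = {n: full_params[n] for n in variant.parameter_names}
            traj = mc.simulate(variant, params, init_state, times)
            assert traj.min() >= -1e-6

    def test_input_validation(self, baseline_params, init_state):
        with pytest.raises(ValueError, match="strictly increasing"):
            mc.simulate("MI(0)", baseline_params, init_state, [0.0, 10.0, 10.0])
        with pytest.raises(ValueError, match="non-negative"):
            mc.simulate("MI(0)", baseline_params, -init_state, [0.0, 1.0])

    def test_step_limit_reported_as_simulation_error(self, baseline_params, init_state):
        solver = mc.SolverConfig(max_steps=3)
        with pytest.raises(mc.SimulationError):
            mc.simulate("MI(0)", baseline_params, init_state, [0.0, 160.0], solver)

    def test_integrator_status_structure(self, baseline_params, init_state, times17):
        p = mc.full_param_vector(baseline_params, mc.MechanismSet())
        out, status, _ = dp45_integrate(p, init_state.astype(float), times17, 1e-6, 1e-6, 10000, 100.0)
        assert status == 0
        np.testing.assert_array_equal(out[0], init_state)
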
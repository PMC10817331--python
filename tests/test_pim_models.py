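import numpy as np
import pytest

from vernal.core_data import CONDITIONS, Condition
from vernal.pim_models import (
    HYPOTHESES,
    RegulatorTrajectory,
    count_free_params,
    delayed_value,
    get_hypothesis,
    make_trajectory,
    pim_rhs,
    production_rate,
    simulate_pim,
)

WT_V = Condition("WT", True)


def zero_regulators():
    knots_t = [5.0, 25.0]
    return {
        g: RegulatorTrajectory(g, None, knots_t, [0.0, 0.0])
        for g in ("FTa1", "SOC1a", "SOC1b", "SOC1c")
    }


def constant_regulators(value):
    knots_t = [5.0, 25.0]
    return {
        g: RegulatorTrajectory(g, None, knots_t, [value, value])
        for g in ("FTa1", "SOC1a", "SOC1b", "SOC1c")
    }


FULL_PARAMS = {
    "H1": {"v0": 0.5, "K0": 1.0, "v1": 0.3, "K1": 2.0, "lambda": 0.4, "tau": 3.0},
    "H2": {"v1": 0.3, "K1": 2.0, "lambda": 0.4},
    "H3": {
        "v1": 0.3, "K1": 2.0, "v2": 0.2, "K2": 1.0,
        "v3": 0.1, "K3": 4.0, "lambda": 0.4,
    },
    "H4": {
        "v0": 0.5, "K0": 1.0, "v1": 0.3, "K1": 2.0, "v2": 0.2, "K2": 1.0,
        "v3": 0.1, "K3": 4.0, "lambda": 0.4, "tau": 3.0,
    },
}


class TestSchemas:
    @pytest.mark.parametrize(
        "hyp,expected", [("H1", 6), ("H2", 3), ("H3", 7), ("H4", 10)]
    )
    def test_free_parameter_counts(self, hyp, expected):
        assert count_free_params(hyp) == expected

    def test_schema_structure(self):
        assert HYPOTHESES["H1"].uses_fta1 and HYPOTHESES["H1"].soc1_mode == "summed"
        assert not HYPOTHESES["H2"].uses_fta1
        assert HYPOTHESES["H3"].soc1_mode == "separate"
        assert HYPOTHESES["H4"].uses_fta1 and HYPOTHESES["H4"].soc1_mode == "separate"

    def test_unknown_hypothesis(self):
        with pytest.raises(KeyError):
            get_hypothesis("H5")

    def test_bounds_cover_all_params(self):
        for schema in HYPOTHESES.values():
            assert set(schema.bounds) == set(schema.param_names)


class TestTrajectory:
    def test_linear_interpolation_midpoint(self):
        traj = RegulatorTrajectory("FTa1", None, [5.0, 10.0], [0.0, 2.0])
        assert traj(7.5) == pytest.approx(1.0)

    def test_knot_values_exact(self, default_dataset):
        traj = make_trajectory(default_dataset, "SOC1a", WT_V)
        means = default_dataset.mean("SOC1a", WT_V)
        for day, m in zip(default_dataset.timepoints, means):
            assert traj(day) == m

    def test_clamped_below_first_knot(self):
        traj = RegulatorTrajectory("FTa1", None, [5.0, 10.0], [0.7, 2.0])
        assert traj(1.0) == 0.7

    def test_pchip_matches_knots(self, default_dataset):
        traj = make_trajectory(default_dataset, "PIM", WT_V, kind="pchip")
        means = default_dataset.mean("PIM", WT_V)
        assert np.allclose([traj(d) for d in default_dataset.timepoints], means)

    def test_unknown_gene(self, default_dataset):
        from vernal.core_data import DatasetSchemaError

        with pytest.raises(DatasetSchemaError):
            make_trajectory(default_dataset, "AP1", WT_V)

    def test_decreasing_knots_rejected(self):
        with pytest.raises(ValueError):
            RegulatorTrajectory("FTa1", None, [5.0, 5.0], [0.0, 1.0])


class TestDelay:
    def test_zero_delay_is_identity(self):
        traj = RegulatorTrajectory("FTa1", None, [5.0, 10.0, 15.0], [1.0, 2.0, 3.0])
        for t in (5.0, 7.3, 12.0):
            assert delayed_value(traj, t, 0.0) == traj(t)

    def test_large_delay_clamps_to_first_value(self):
        traj = RegulatorTrajectory("FTa1", None, [5.0, 10.0, 15.0], [1.0, 2.0, 3.0])
        # t - tau = -4.9, far below the first knot
        assert delayed_value(traj, 5.0, 9.9) == 1.0

    def test_exact_knot_shift(self):
        knots_t = [5.0, 10.0, 15.0, 20.0, 25.0]
        traj = RegulatorTrajectory("FTa1", None, knots_t, [1.0, 2.0, 3.0, 4.0, 5.0])
        assert delayed_value(traj, 20.0, 10.0) == 2.0

    def test_negative_delay_rejected(self):
        traj = RegulatorTrajectory("FTa1", None, [5.0, 10.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            traj.delayed(5.0, -1.0)


class TestRhs:
    @pytest.mark.parametrize("hyp", ["H1", "H2", "H3", "H4"])
    def test_zero_regulators_decay_only(self, hyp):
        params = FULL_PARAMS[hyp]
        regs = zero_regulators()
        assert pim_rhs(hyp, params, 10.0, 2.0, regs) == pytest.approx(-params["lambda"] * 2.0)

    def test_h2_saturation_limit(self):
        params = {"v1": 0.3, "K1": 2.0, "lambda": 0.4}
        regs = constant_regulators(1e9)
        assert pim_rhs("H2", params, 10.0, 1.0, regs) == pytest.approx(
            0.3 - 0.4 * 1.0, rel=1e-6
        )

    def test_h1_h4_agree_on_equal_soc1_inputs(self):
        # sum-inside Hill (v, K) over 3s equals sum-outside with (v/3, K/3)
        # per branch only when all SOC1 levels coincide
        regs_eq = constant_regulators(0.8)
        h1 = {"v0": 0.5, "K0": 1.0, "v1": 0.9, "K1": 3.0, "lambda": 0.4, "tau": 2.0}
        h4 = {
            "v0": 0.5, "K0": 1.0, "lambda": 0.4, "tau": 2.0,
            "v1": 0.3, "K1": 1.0, "v2": 0.3, "K2": 1.0, "v3": 0.3, "K3": 1.0,
        }
        assert pim_rhs("H1", h1, 10.0, 1.0, regs_eq) == pytest.approx(
            pim_rhs("H4", h4, 10.0, 1.0, regs_eq)
        )
        # unequal SOC1 inputs break the identity
        regs_neq = constant_regulators(0.8)
        regs_neq["SOC1b"] = RegulatorTrajectory("SOC1b", None, [5.0, 25.0], [0.1, 0.1])
        regs_neq["SOC1c"] = RegulatorTrajectory("SOC1c", None, [5.0, 25.0], [1.5, 1.5])
        assert pim_rhs("H1", h1, 10.0, 1.0, regs_neq) != pytest.approx(
            pim_rhs("H4", h4, 10.0, 1.0, regs_neq)
        )

    def test_missing_parameter_schema_error(self):
        with pytest.raises(KeyError, match="missing parameters"):
            pim_rhs("H1", {"v0": 1.0}, 10.0, 1.0, zero_regulators())

    def test_negative_pim_rejected(self):
        with pytest.raises(ValueError):
            pim_rhs("H2", FULL_PARAMS["H2"], 10.0, -0.5, zero_regulators())


class TestSimulate:
    def test_decay_closed_form(self, noisefree_mech):
        ds = noisefree_mech.dataset
        params = {"v0": 1e-12, "K0": 1.0, "v1": 1e-12, "K1": 1.0,
                  "lambda": 0.5, "tau": 0.0}
        t = np.linspace(5.0, 25.0, 21)
        for cond in CONDITIONS:
            pim = simulate_pim("H1", params, ds, cond, t)
            p0 = ds.value("PIM", cond, 5.0)
            assert np.max(np.abs(pim - p0 * np.exp(-0.5 * (t - 5.0)))) < 1e-7

    def test_h1_reduces_to_h2_when_fta1_off(self, noisefree_mech):
        ds = noisefree_mech.dataset
        shared = {"v1": 0.3, "K1": 2.0, "lambda": 0.4}
        h1 = {**shared, "v0": 0.0, "K0": 1.0, "tau": 3.0}
        t = np.linspace(5.0, 25.0, 41)
        a = simulate_pim("H1", h1, ds, WT_V, t)
        b = simulate_pim("H2", shared, ds, WT_V, t)
        assert np.max(np.abs(a - b)) < 1e-12

    def test_rk4_against_adaptive_solver(self, noisefree_mech):
        ds = noisefree_mech.dataset
        params = FULL_PARAMS["H4"]
        t = np.linspace(5.0, 25.0, 11)
        fast = simulate_pim("H4", params, ds, WT_V, t, n_steps=400)
        ref = simulate_pim("H4", params, ds, WT_V, t, method="lsoda",
                           rtol=1e-10, atol=1e-12)
        assert np.max(np.abs(fast - ref) / np.maximum(np.abs(ref), 1e-6)) < 1e-5

    def test_grid_refinement_converged(self, noisefree_mech):
        ds = noisefree_mech.dataset
        t = np.linspace(5.0, 25.0, 11)
        coarse = simulate_pim("H1", FULL_PARAMS["H1"], ds, WT_V, t, n_steps=200)
        fine = simulate_pim("H1", FULL_PARAMS["H1"], ds, WT_V, t, n_steps=2000)
        assert np.max(np.abs(coarse - fine) / np.maximum(np.abs(fine), 1e-9)) < 1e-5

    def test_nonnegative_and_bounded(self, noisy_mech_dataset):
        rng = np.random.default_rng(3)
        t = np.linspace(5.0, 25.0, 41)
        for _ in range(20):
            params = {
                "v0": rng.uniform(0.01, 5), "K0": rng.uniform(0.1, 100),
                "v1": rng.uniform(0.01, 5), "K1": rng.uniform(0.1, 100),
                "lambda": rng.uniform(0.05, 5), "tau": rng.uniform(0, 15),
            }
            pim = simulate_pim("H1", params, noisy_mech_dataset, WT_V, t)
            assert np.min(pim) >= -1e-9
            bound = max(
                noisy_mech_dataset.value("PIM", WT_V, 5.0),
                (params["v0"] + params["v1"]) / params["lambda"],
            )
            assert np.max(pim) <= bound + 1e-9

    def test_grid_outside_window_rejected(self, noisefree_mech):
        with pytest.raises(ValueError, match="sampled window"):
            simulate_pim("H2", FULL_PARAMS["H2"], noisefree_mech.dataset, WT_V,
                         [4.0, 26.0])

    def test_production_rate_vectorized(self, noisefree_mech):
        from vernal.pim_models import make_regulators

        regs = make_regulators(noisefree_mech.dataset, WT_V)
        t = np.linspace(5, 25, 7)
        vec = production_rate("H1", FULL_PARAMS["H1"], t, regs)
        scalar = [float(production_rate("H1", FULL_PARAMS["H1"], ti, regs)) for ti in t]
        assert np.allclose(vec, scalar)
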
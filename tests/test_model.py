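import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from meristemsim.model import (
    LineageState,
    NumericalFailureError,
    division_multipliers,
    drift,
    em_step,
    leading_lineage,
    simulate_trajectory,
    uninhibited_inner,
    uninhibited_outer,
)
from meristemsim.params import InvalidInputError, ModelParams


def no_inhibition(**kw):
    """Parameters with the inhibition term effectively switched off."""
    return ModelParams(sigma=0.0, K_hill=1e12, alpha=1e9, **kw)


class TestLeadingLineage:
    def test_clear_lead(self):
        assert leading_lineage([10, 3, 2, 4, 1], alpha=5) == 0

    def test_symmetric_counts_have_no_lead(self):
        assert leading_lineage([5, 5, 5, 5, 5], alpha=1) is None

    def test_margin_below_alpha(self):
        assert leading_lineage([8, 6, 2, 2, 2], alpha=3) is None

    def test_alpha_zero_tie_breaks_to_lowest_index(self):
        assert leading_lineage([7, 7, 3], alpha=0) == 0

    def test_fewer_than_two_lineages_rejected(self):
        with pytest.raises(InvalidInputError):
            leading_lineage([4], alpha=1)

    def test_negative_counts_rejected(self):
        with pytest.raises(InvalidInputError):
            leading_lineage([4, -1], alpha=1)

    @given(
        outer=st.lists(st.floats(0, 1e6, allow_nan=False), min_size=2, max_size=8),
        alpha=st.floats(0, 100, allow_nan=False),
    )
    def test_returned_index_satisfies_margin(self, outer, alpha):
        lead = leading_lineage(outer, alpha)
        arr = np.asarray(outer)
        margins = [arr[i] - np.delete(arr, i).max() for i in range(arr.size)]
        if lead is None:
            assert all(m < alpha for m in margins)
        else:
            assert margins[lead] >= alpha


class TestDivisionMultipliers:
    def test_threshold_without_lead_is_identity(self):
        params = ModelParams(version="threshold", alpha=3)
        out = division_multipliers([5, 5, 5, 5, 5], params)
        np.testing.assert_array_equal(out, np.ones(5))

    def test_threshold_half_saturation(self):
        params = ModelParams(version="threshold", alpha=1, K_hill=10, m_hill=2)
        out = division_multipliers([10, 2, 2, 2, 2], params)
        assert out[0] == 1.0
        np.testing.assert_allclose(out[1:], 0.5)

    def test_mutual_forced_arithmetic(self):
        params = ModelParams(version="mutual", K_hill=20, m_hill=2)
        out = division_multipliers([5, 5, 5, 5, 5], params)
        np.testing.assert_allclose(out, 400.0 / (400.0 + 400.0))

    def test_negative_counts_rejected(self):
        with pytest.raises(InvalidInputError):
            division_multipliers([-1, 2, 3, 4, 5], ModelParams())

    @given(
        outer=st.lists(st.floats(0, 1e4, allow_nan=False), min_size=2, max_size=8),
        version=st.sampled_from(["threshold", "mutual"]),
    )
    def test_factors_bounded(self, outer, version):
        params = ModelParams(n_lineages=len(outer), version=version)
        out = division_multipliers(outer, params)
        assert np.all(out > 0) and np.all(out <= 1)

    def test_permutation_equivariance(self):
        params = ModelParams(version="mutual", K_hill=7, m_hill=3)
        outer = np.array([9.0, 1.0, 4.0, 2.5, 6.0])
        perm = np.array([2, 0, 4, 1, 3])
        np.testing.assert_allclose(
            division_multipliers(outer[perm], params),
            division_multipliers(outer, params)[perm],
        )


class TestDrift:
    def test_forced_arithmetic(self):
        params = ModelParams(r=0.08, gamma=0.5)
        state = LineageState(outer=[10.0], inner=[4.0])
        d_outer, d_inner = drift(state, [1.0], params)
        np.testing.assert_allclose(d_outer, [0.4])
        np.testing.assert_allclose(d_inner, [0.56])

    def test_empty_state_is_absorbing(self):
        state = LineageState(outer=[0.0], inner=[0.0])
        d_outer, d_inner = drift(state, [1.0], ModelParams())
        assert d_outer[0] == 0 and d_inner[0] == 0

    def test_suppressed_lineage(self):
        params = ModelParams(r=0.08, gamma=0.5)
        state = LineageState(outer=[2.0], inner=[2.0])
        d_outer, d_inner = drift(state, [0.5], params)
        np.testing.assert_allclose(d_outer, [0.04])
        np.testing.assert_allclose(d_inner, [0.08])

    def test_permutation_equivariance(self):
        params = ModelParams()
        outer = np.array([1.0, 5.0, 2.0, 8.0, 3.0])
        inner = np.array([0.5, 2.0, 1.0, 4.0, 0.0])
        h = division_multipliers(outer, params)
        perm = np.array([3, 1, 4, 0, 2])
        d_o, d_i = drift(LineageState(outer=outer, inner=inner), h, params)
        d_o_p, d_i_p = drift(
            LineageState(outer=outer[perm], inner=inner[perm]),
            division_multipliers(outer[perm], params),
            params,
        )
        np.testing.assert_allclose(d_o_p, d_o[perm])
        np.testing.assert_allclose(d_i_p, d_i[perm])


class TestEmStep:
    def test_noise_free_limit_equals_euler(self):
        params = ModelParams(sigma=0.0)
        state = LineageState(outer=np.full(5, 2.0), inner=np.full(5, 1.0))
        h = division_multipliers(state.outer, params)
        d_outer, d_inner = drift(state, h, params)
        out = em_step(state, params, np.random.default_rng(0).standard_normal((5, 2)))
        np.testing.assert_array_equal(out.outer, state.outer + params.dt * d_outer)
        np.testing.assert_array_equal(out.inner, state.inner + params.dt * d_inner)
        assert out.t == pytest.approx(params.dt)

    def test_clamp_at_zero(self):
        params = ModelParams(sigma=1.0, noise_model="additive")
        state = LineageState(outer=np.full(5, 0.01), inner=np.zeros(5))
        z = np.zeros((5, 2))
        z[0, 0] = -100.0
        out = em_step(state, params, z)
        assert out.outer[0] == 0.0

    def test_determinism(self):
        params = ModelParams()
        state = LineageState(outer=np.ones(5), inner=np.zeros(5))
        z = np.random.default_rng(3).standard_normal((5, 2))
        a = em_step(state, params, z)
        b = em_step(state, params, z)
        np.testing.assert_array_equal(a.outer, b.outer)
        np.testing.assert_array_equal(a.inner, b.inner)

    def test_wrong_noise_shape_rejected(self):
        state = LineageState(outer=np.ones(5), inner=np.zeros(5))
        with pytest.raises(InvalidInputError):
            em_step(state, ModelParams(), np.zeros(10))


class TestSimulateTrajectory:
    def test_initial_condition(self):
        traj = simulate_trajectory(ModelParams(t_end=1.0), seed=0)
        np.testing.assert_array_equal(traj.outer[0], np.ones(5))
        np.testing.assert_array_equal(traj.inner[0], np.zeros(5))
        assert traj.times[0] == 0.0 and traj.times[-1] == pytest.approx(1.0)

    def test_closed_form_accuracy_and_convergence(self):
        # Forward-Euler drift error dominates: ~1.9e-3 relative on O(120) at
        # dt = 0.05, shrinking linearly with dt.
        r = 0.05
        errs = {}
        for dt in (0.05, 0.005):
            traj = simulate_trajectory(no_inhibition(r=r, dt=dt), seed=0)
            o_err = abs(traj.outer[-1, 0] - uninhibited_outer(120.0, r)) / uninhibited_outer(120.0, r)
            i_err = abs(traj.inner[-1, 0] - uninhibited_inner(120.0, r)) / uninhibited_inner(120.0, r)
            errs[dt] = max(o_err, i_err)
        assert errs[0.05] < 5e-3
        assert errs[0.005] < 5e-4
        assert errs[0.005] < errs[0.05] / 5  # at least ~linear convergence

    def test_noise_free_symmetry(self):
        for version in ("threshold", "mutual"):
            traj = simulate_trajectory(ModelParams(sigma=0.0, version=version), seed=1)
            assert np.all(traj.outer == traj.outer[:, [0]])
            assert np.all(traj.inner == traj.inner[:, [0]])

    def test_non_negativity(self):
        traj = simulate_trajectory(ModelParams(sigma=0.3, t_end=60.0), seed=11)
        assert np.all(traj.outer >= 0) and np.all(traj.inner >= 0)

    def test_determinism(self):
        a = simulate_trajectory(ModelParams(t_end=6.0), seed=5)
        b = simulate_trajectory(ModelParams(t_end=6.0), seed=5)
        np.testing.assert_array_equal(a.outer, b.outer)
        np.testing.assert_array_equal(a.inner, b.inner)

    def test_matches_scalar_em_step_replay(self):
        """The vectorized integrator is bit-identical to iterating em_step
        with the same pre-drawn noise block."""
        params = ModelParams(t_end=3.0, sigma=0.1)
        seed = 9
        traj = simulate_trajectory(params, seed)
        z = np.random.default_rng(seed).standard_normal((params.n_steps, 5, 2))
        state = LineageState(outer=np.ones(5), inner=np.zeros(5))
        for s in range(params.n_steps):
            state = em_step(state, params, z[s])
            np.testing.assert_array_equal(state.outer, traj.outer[s + 1])
            np.testing.assert_array_equal(state.inner, traj.inner[s + 1])

    def test_step_size_robustness(self):
        # first-order drift error: halving dt moves O(120) by ~0.09% and the
        # (slightly less accurate) inner component by ~0.16%
        base = simulate_trajectory(ModelParams(sigma=0.0, dt=0.05), seed=0)
        half = simulate_trajectory(ModelParams(sigma=0.0, dt=0.025), seed=0)
        assert abs(half.outer[-1, 0] - base.outer[-1, 0]) / base.outer[-1, 0] < 1e-3
        assert abs(half.total[-1, 0] - base.total[-1, 0]) / base.total[-1, 0] < 2e-3

    def test_numerical_failure_reports_seed(self):
        with pytest.raises(NumericalFailureError, match="seed 4"):
            simulate_trajectory(ModelParams(r=1e5, t_end=10.0, sigma=0.0), seed=4)
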
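"""Censoring rules, design matrices, OLS fitting and the statistics helpers."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import integrate, stats

from mbsim.design import Event, EventSchedule, rapid_er_schedule
from mbsim.glm import (
    CensorMask,
    EyeTrace,
    RunGLM,
    build_design_matrix,
    censor_broken_fixation,
    flag_motion_outliers,
    isolated_event_height,
    percent_signal_change,
    spherical_roi_mask,
    t_to_z,
)
from mbsim.irf import InvalidParameterError, gamma_hrf
from mbsim.sensitivity import SingularDesignError


def trace_with_outside(n_volumes: int, outside_per_volume: list[int]) -> EyeTrace:
    """40 samples/volume; the requested count per volume placed at 8 deg."""
    x = np.zeros(n_volumes * 40)
    for v, n_out in enumerate(outside_per_volume):
        x[v * 40 : v * 40 + n_out] = 8.0
    return EyeTrace(20.0, x, np.zeros_like(x), 5.0)


class TestCensorBrokenFixation:
    def test_forty_samples_per_volume_at_defaults(self):
        trace = trace_with_outside(3, [0, 0, 0])
        assert trace.x.size / 3 == 40  # 20 Hz x 2 s

    def test_all_inside_keeps_volume(self):
        mask = censor_broken_fixation(trace_with_outside(2, [0, 0]), tr=2.0)
        assert mask.keep.all()

    def test_21_of_40_outside_excludes(self):
        mask = censor_broken_fixation(trace_with_outside(1, [21]), tr=2.0)
        assert not mask.keep[0]
        assert mask.reason[0] == "fixation"

    def test_exactly_half_outside_keeps(self):
        mask = censor_broken_fixation(trace_with_outside(1, [20]), tr=2.0)
        assert mask.keep[0]

    def test_boundary_of_window_counts_as_inside(self):
        x = np.full(40, 5.0)  # exactly on the +/-5 deg edge
        mask = censor_broken_fixation(EyeTrace(20.0, x, np.zeros(40), 5.0), tr=2.0)
        assert mask.keep[0]

    def test_trace_shorter_than_volume_rejected(self):
        with pytest.raises(InvalidParameterError):
            censor_broken_fixation(EyeTrace(20.0, np.zeros(10), np.zeros(10)), 2.0)


class TestFlagMotionOutliers:
    def test_constant_series_flags_nothing(self):
        assert flag_motion_outliers(np.ones(50)).keep.all()

    def test_single_spike_flagged(self):
        """Direct-computation oracle for the mean + 2 SD rule."""
        series = np.concatenate([np.ones(100), [10.0]])
        mean, sd = series.mean(), series.std(ddof=1)
        assert mean == pytest.approx(1.089, abs=1e-3)
        assert sd == pytest.approx(0.896, abs=1e-3)
        assert mean + 2 * sd < 10.0
        mask = flag_motion_outliers(series)
        assert list(np.flatnonzero(~mask.keep)) == [100]

    def test_value_exactly_at_threshold_not_flagged(self):
        # constant series: every value sits exactly at mean + 2*sd (sd = 0);
        # the strict > keeps them all
        v = np.array([1.0, 1.0, 1.0, 1.0])
        assert flag_motion_outliers(v).keep.all()

    def test_too_short_series_rejected(self):
        with pytest.raises(InvalidParameterError):
            flag_motion_outliers([1.0, 2.0])


class TestCensorMask:
    def test_combine_is_commutative(self):
        a = CensorMask(np.array([True, False, True]), ("", "fixation", ""))
        b = CensorMask(np.array([False, False, True]), ("motion", "motion", ""))
        ab, ba = a.combine(b), b.combine(a)
        assert np.array_equal(ab.keep, ba.keep)
        assert ab.reason == ba.reason
        assert ab.reason[1] == "fixation+motion"

    def test_counts_by_reason(self):
        a = CensorMask(np.array([False, False, True]), ("fixation", "motion", ""))
        assert a.counts() == {"fixation": 1, "motion": 1}


class TestBuildDesignMatrix:
    def make_schedule(self, n=6):
        return rapid_er_schedule(n_stimuli=n, n_null=2, seed=9)

    def test_one_column_per_condition(self):
        sched = rapid_er_schedule(seed=1)
        design = build_design_matrix(sched, gamma_hrf(dt=0.1), drift_order=1)
        assert len(design.interest) == 48
        assert list(design.interest) == [f"cond_{i}" for i in range(48)]

    def test_motion_columns_are_one_hot(self):
        sched = self.make_schedule()
        n_vol = sched.n_volumes
        keep = np.ones(n_vol, dtype=bool)
        keep[[2, 5]] = False
        motion = CensorMask(keep, tuple("" if k else "motion" for k in keep))
        design = build_design_matrix(sched, gamma_hrf(dt=0.1), motion=motion)
        for v in (2, 5):
            col = design.frame[f"motion_{v}"]
            assert col.sum() == 1.0 and col[v] == 1.0

    def test_censoring_only_event_zeroes_column(self):
        sched = self.make_schedule()
        # censor every volume overlapping condition 3's single presentation
        ev = sched.events_for(3)[0]
        keep = np.ones(sched.n_volumes, dtype=bool)
        first = int(ev.onset // sched.tr)
        keep[first : first + 2] = False
        censor = CensorMask(keep, tuple("" if k else "fixation" for k in keep))
        design = build_design_matrix(sched, gamma_hrf(dt=0.1), censor=censor)
        assert "cond_3" in design.all_zero
        assert not design.frame["cond_3"].any()


class TestRunGLM:
    def setup_problem(self, seed=0, n_vol=60, n_vox=4, p=5):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((n_vol, p))
        B = rng.standard_normal((p, n_vox))
        return X, B

    def test_exact_recovery_at_zero_noise(self):
        X, B = self.setup_problem()
        frame = pd.DataFrame(X, columns=[f"r{i}" for i in range(5)])
        res = RunGLM(X @ B, frame).fit()
        np.testing.assert_allclose(res.params.to_numpy(), B, atol=1e-8)

    def test_dof_equals_volumes_minus_rank(self):
        X, B = self.setup_problem()
        frame = pd.DataFrame(X, columns=[f"r{i}" for i in range(5)])
        res = RunGLM(X @ B, frame).fit()
        assert res.df_resid == 60 - 5

    def test_residuals_orthogonal_to_design(self, rng):
        X, B = self.setup_problem(seed=3)
        Y = X @ B + rng.standard_normal((60, 4))
        frame = pd.DataFrame(X, columns=[f"r{i}" for i in range(5)])
        res = RunGLM(Y, frame).fit()
        assert np.abs(X.T @ res.resid.to_numpy()).max() < 1e-6

    def test_analytic_se_matches_empirical_beta_spread(self):
        """SD of betas across noise draws matches the reported SE within 5%."""
        rng = np.random.default_rng(12)
        X = rng.standard_normal((80, 3))
        B = np.zeros((3, 1))
        frame = pd.DataFrame(X, columns=["a", "b", "c"])
        betas, ses = [], []
        for _ in range(1000):
            Y = X @ B + rng.standard_normal((80, 1))
            res = RunGLM(Y, frame).fit()
            betas.append(res.params.to_numpy()[:, 0])
            ses.append(res.bse.to_numpy()[:, 0])
        emp = np.std(np.array(betas), axis=0)
        np.testing.assert_allclose(emp, np.mean(ses, axis=0), rtol=0.05)

    def test_matches_statsmodels_single_voxel(self, rng):
        import statsmodels.api as sm

        X = rng.standard_normal((50, 3))
        y = X @ np.array([1.0, -2.0, 0.5]) + rng.standard_normal(50)
        frame = pd.DataFrame(X, columns=["a", "b", "c"])
        ours = RunGLM(y[:, None], frame).fit()
        ref = sm.OLS(y, X).fit()
        np.testing.assert_allclose(ours.params.to_numpy()[:, 0], ref.params, atol=1e-10)
        np.testing.assert_allclose(ours.bse.to_numpy()[:, 0], ref.bse, atol=1e-10)
        np.testing.assert_allclose(ours.tvalues.to_numpy()[:, 0], ref.tvalues, atol=1e-8)

    def test_rank_deficient_design_rejected(self, rng):
        X = rng.standard_normal((30, 2))
        frame = pd.DataFrame(
            np.column_stack([X, X[:, 0]]), columns=["a", "b", "c"]
        )
        with pytest.raises(SingularDesignError):
            RunGLM(rng.standard_normal((30, 2)), frame).fit()

    def test_summary_mentions_dof_and_counts(self):
        X, B = self.setup_problem()
        frame = pd.DataFrame(X, columns=[f"r{i}" for i in range(5)])
        text = RunGLM(X @ B, frame).fit().summary()
        assert "residual dof:       55" in text


class TestTtoZ:
    def test_zero_maps_to_zero(self):
        assert t_to_z(0.0, 10) == 0.0

    def test_converges_to_identity_at_large_dof(self):
        assert t_to_z(2.5, 10**6) == pytest.approx(2.5, abs=1e-3)

    def test_against_quadrature_oracle(self):
        """Tail probability from numerical integration of the t density."""
        t_val, dof = 2.0, 10
        tail, _ = integrate.quad(lambda u: stats.t.pdf(u, dof), t_val, np.inf)
        expected = stats.norm.isf(tail)
        assert t_to_z(t_val, dof) == pytest.approx(expected, rel=1e-9)

    def test_sign_preserving(self):
        assert t_to_z(-2.0, 10) == pytest.approx(-t_to_z(2.0, 10))

    def test_extreme_t_stays_finite(self):
        z = t_to_z(40.0, 100)
        assert np.isfinite(z) and z > 10

    @given(st.floats(-6, 6), st.integers(2, 200))
    def test_strictly_increasing_in_t(self, t_val, dof):
        assert t_to_z(t_val + 0.5, dof) > t_to_z(t_val, dof)

    def test_invalid_dof_rejected(self):
        with pytest.raises(InvalidParameterError):
            t_to_z(1.0, 0)


class TestPercentSignalChange:
    def test_linear_in_beta(self):
        a = percent_signal_change(1.0, 2.0, 100.0)
        assert percent_signal_change(2.0, 2.0, 100.0) == pytest.approx(2 * a)
        assert percent_signal_change(0.0, 2.0, 100.0) == 0.0

    def test_inverse_in_baseline(self):
        a = percent_signal_change(1.0, 2.0, 100.0)
        assert percent_signal_change(1.0, 2.0, 200.0) == pytest.approx(a / 2)

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(InvalidParameterError):
            percent_signal_change(1.0, 2.0, 0.0)

    def test_psc_invariant_to_data_rescaling(self):
        """Scaling raw data by a positive constant leaves %-change unchanged."""
        hrf = gamma_hrf(dt=0.1)
        sched = rapid_er_schedule(n_stimuli=4, n_null=2, seed=2)
        rng = np.random.default_rng(0)
        design = build_design_matrix(sched, hrf)
        Y = 100.0 + rng.standard_normal((sched.n_volumes, 3))
        psc = lambda data: (
            RunGLM(data, design).fit().percent_signal_change(hrf).to_numpy()
        )
        np.testing.assert_allclose(psc(Y * 7.0), psc(Y), rtol=1e-8)

    def test_isolated_event_height_positive(self):
        assert isolated_event_height(gamma_hrf(dt=0.1), 0.5) > 0


class TestSphericalRoiMask:
    def test_radius_zero_is_centre_only(self):
        assert spherical_roi_mask((0, 0, 0), 0.0, 1.5) == {(0, 0, 0)}

    def test_2mm_radius_on_1p5mm_grid_gives_7_voxels(self):
        """Centre + 6 face neighbours; diagonals at 1.5*sqrt(2) excluded."""
        mask = spherical_roi_mask((10, 10, 10), 2.0, 1.5)
        assert len(mask) == 7
        assert (10, 10, 10) in mask and (11, 10, 10) in mask
        assert (11, 11, 10) not in mask

    def test_5mm_radius_matches_brute_force_enumeration(self):
        mask = spherical_roi_mask((0, 0, 0), 5.0, 1.5)
        brute = {
            (i, j, k)
            for i in range(-10, 11)
            for j in range(-10, 11)
            for k in range(-10, 11)
            if 1.5 * np.sqrt(i**2 + j**2 + k**2) <= 5.0 + 1e-9
        }
        assert mask == brute
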
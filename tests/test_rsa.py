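"""Crossnobis distances, noise covariance and split-half RDM assembly."""

import numpy as np
import pandas as pd
import pytest

from mbsim.irf import InvalidParameterError
from mbsim.rsa import (
    RDM,
    CrossnobisRSA,
    NoiseCov,
    PatternEstimates,
    SingularCovarianceError,
    average_rdms,
    crossnobis,
    noise_covariance,
    split_half_rdm,
)


class TestNoiseCovariance:
    def test_single_voxel_two_volumes(self):
        cov = noise_covariance(np.array([[1.0], [-1.0]]), shrinkage=0.0)
        np.testing.assert_allclose(cov.matrix, [[1.0]])

    def test_full_shrinkage_is_diagonal_target(self, rng):
        R = rng.standard_normal((50, 4))
        full = noise_covariance(R, shrinkage=0.0).matrix
        shrunk = noise_covariance(R, shrinkage=1.0).matrix
        np.testing.assert_allclose(shrunk, np.diag(np.diag(full)))

    def test_monte_carlo_identity_recovery(self, rng):
        """(1/T) R'R of unit white noise approaches the identity."""
        R = rng.standard_normal((10_000, 5))
        cov = noise_covariance(R, shrinkage=0.0).matrix
        np.testing.assert_allclose(np.diag(cov), 1.0, rtol=0.05)
        off = cov[~np.eye(5, dtype=bool)]
        assert np.abs(off).max() < 0.05

    def test_shrinkage_out_of_range_rejected(self, rng):
        with pytest.raises(InvalidParameterError):
            noise_covariance(rng.standard_normal((10, 2)), shrinkage=1.5)


class TestCrossnobis:
    def test_identity_covariance_is_squared_euclidean(self):
        d = crossnobis([1.0, 2.0], [1.0, 2.0], NoiseCov(np.eye(2)))
        assert d == pytest.approx(5.0)

    def test_covariance_whitening_scales_distance(self):
        d = crossnobis([2.0, 0.0], [2.0, 0.0], NoiseCov(4.0 * np.eye(2)))
        assert d == pytest.approx(1.0)

    def test_symmetric_under_condition_exchange(self, rng):
        cov = NoiseCov(np.eye(3))
        a, b = rng.standard_normal(3), rng.standard_normal(3)
        assert crossnobis(a, b, cov) == pytest.approx(crossnobis(-a, -b, cov))

    def test_singular_covariance_suggests_shrinkage(self):
        with pytest.raises(SingularCovarianceError, match="shrinkage"):
            crossnobis([1.0, 0.0], [1.0, 0.0], NoiseCov(np.zeros((2, 2))))

    def test_unbiased_for_identical_patterns(self, rng):
        """Independent noise in the two halves makes the expectation zero."""
        n, p = 10_000, 8
        da = rng.standard_normal((n, p))
        db = rng.standard_normal((n, p))
        values = np.einsum("ij,ij->i", da, db)  # identity whitening
        se = values.std(ddof=1) / np.sqrt(n)
        assert abs(values.mean()) < 3 * se


def planted_patterns(n_runs=4, C=5, P=6, seed=0, noise=0.0):
    rng = np.random.default_rng(seed)
    truth = rng.standard_normal((C, P))
    betas = truth[None] + noise * rng.standard_normal((n_runs, C, P))
    avail = np.ones((n_runs, C), dtype=bool)
    return PatternEstimates(betas, avail), truth


class TestSplitHalfRDM:
    def test_symmetric_zero_diagonal(self):
        pats, _ = planted_patterns(noise=0.5)
        rdm = split_half_rdm(pats, n_folds=10, seed=1, noise_cov="identity")
        m = rdm.values()
        np.testing.assert_allclose(m, m.T, atol=1e-12)
        np.testing.assert_array_equal(np.diag(m), 0.0)

    def test_fold_count_recorded(self):
        pats, _ = planted_patterns()
        rdm = split_half_rdm(pats, n_folds=50, seed=1, noise_cov="identity")
        assert rdm.n_folds == 50

    def test_noiseless_patterns_give_planted_squared_euclidean(self):
        pats, truth = planted_patterns(noise=0.0)
        rdm = split_half_rdm(pats, n_folds=10, seed=3, noise_cov="identity")
        diffs = truth[:, None] - truth[None, :]
        expected = np.sum(diffs**2, axis=2)
        np.testing.assert_allclose(rdm.values(), expected, atol=1e-8)

    def test_seeded_folds_bit_reproducible(self):
        pats, _ = planted_patterns(noise=0.3)
        a = split_half_rdm(pats, n_folds=20, seed=7, noise_cov="identity")
        b = split_half_rdm(pats, n_folds=20, seed=7, noise_cov="identity")
        assert a.matrix.equals(b.matrix)

    def test_seed_required(self):
        pats, _ = planted_patterns()
        with pytest.raises(InvalidParameterError):
            split_half_rdm(pats, n_folds=10, noise_cov="identity")

    def test_fewer_than_two_runs_rejected(self):
        pats, _ = planted_patterns(n_runs=1)
        with pytest.raises(InvalidParameterError):
            split_half_rdm(pats, n_folds=5, seed=1, noise_cov="identity")

    def test_odd_run_counts_drop_one_run(self):
        pats, truth = planted_patterns(n_runs=5, noise=0.0)
        rdm = split_half_rdm(pats, n_folds=5, seed=2, noise_cov="identity")
        diffs = truth[:, None] - truth[None, :]
        np.testing.assert_allclose(rdm.values(), np.sum(diffs**2, axis=2), atol=1e-8)

    def test_unavailable_condition_skipped_then_nan(self):
        pats, _ = planted_patterns(C=4)
        avail = pats.available.copy()
        avail[:, 2] = False  # condition 2 never estimable
        pats = PatternEstimates(pats.betas, avail)
        rdm = split_half_rdm(pats, n_folds=5, seed=1, noise_cov="identity")
        assert np.isnan(rdm.values()[2, 0])
        assert np.isfinite(rdm.values()[1, 0])

    def test_monotone_in_planted_separation(self):
        """Scaling one condition's pattern away from another grows their entry."""
        rng = np.random.default_rng(5)
        base = rng.standard_normal((3, 6))
        entries = []
        for scale in (1.0, 2.0, 4.0):
            truth = base.copy()
            truth[1] = truth[0] + scale * (truth[1] - truth[0])
            betas = truth[None] + 0.2 * rng.standard_normal((6, 3, 6))
            pats = PatternEstimates(betas, np.ones((6, 3), dtype=bool))
            rdm = split_half_rdm(pats, n_folds=20, seed=9, noise_cov="identity")
            entries.append(rdm.values()[0, 1])
        assert entries[0] < entries[1] < entries[2]

    def test_estimated_covariance_route_runs(self, rng):
        pats, _ = planted_patterns(noise=0.4)
        residuals = [rng.standard_normal((40, 6)) for _ in range(4)]
        rdm = CrossnobisRSA(pats, residuals).fit(n_folds=5, seed=3, shrinkage=0.1)
        assert np.isfinite(rdm.off_diagonal()).all()
        assert rdm.provenance["shrinkage"] == 0.1

    def test_recovery_beats_label_permutation(self):
        """Rank agreement with the planted RDM exceeds label-permuted chance."""
        rng = np.random.default_rng(11)
        pats, truth = planted_patterns(n_runs=8, C=8, P=10, seed=4, noise=0.8)
        rdm = split_half_rdm(pats, n_folds=20, seed=5, noise_cov="identity")
        diffs = truth[:, None] - truth[None, :]
        planted = np.sum(diffs**2, axis=2)
        iu = np.triu_indices(8, 1)

        def rankcorr(a, b):
            ar = pd.Series(a).rank().to_numpy()
            br = pd.Series(b).rank().to_numpy()
            return np.corrcoef(ar, br)[0, 1]

        observed = rankcorr(rdm.values()[iu], planted[iu])
        null = []
        for _ in range(100):
            perm = rng.permutation(8)
            null.append(rankcorr(rdm.values()[perm][:, perm][iu], planted[iu]))
        assert observed > np.quantile(null, 0.95)


class TestAverageRdms:
    def make(self, values):
        labels = list(range(values.shape[0]))
        return RDM(pd.DataFrame(values, index=labels, columns=labels), n_folds=1)

    def test_single_rdm_unchanged(self):
        rdm = self.make(np.array([[0.0, 1.0], [1.0, 0.0]]))
        np.testing.assert_array_equal(average_rdms([rdm]).values(), rdm.values())

    def test_rdm_plus_negation_is_zero(self):
        m = np.array([[0.0, 2.0], [2.0, 0.0]])
        out = average_rdms([self.make(m), self.make(-m)])
        np.testing.assert_array_equal(out.values(), 0.0)

    def test_missing_entries_ignored(self):
        a = np.array([[0.0, 1.0], [1.0, 0.0]])
        b = np.array([[0.0, 3.0], [3.0, 0.0]])
        c = np.array([[0.0, np.nan], [np.nan, 0.0]])
        out = average_rdms([self.make(a), self.make(b), self.make(c)])
        assert out.values()[0, 1] == pytest.approx(2.0)

    def test_label_mismatch_rejected(self):
        a = self.make(np.zeros((2, 2)))
        b = RDM(pd.DataFrame(np.zeros((2, 2)), index=[5, 6], columns=[5, 6]))
        with pytest.raises(InvalidParameterError):
            average_rdms([a, b])

    def test_rdm_csv_round_trip(self, tmp_path):
        rdm = self.make(np.array([[0.0, 1.5], [1.5, 0.0]]))
        rdm.to_csv(tmp_path / "rdm.csv")
        back = RDM.from_csv(tmp_path / "rdm.csv")
        np.testing.assert_allclose(back.values(), rdm.values())
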
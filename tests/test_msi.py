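"""MSI core: joint covariance, whitening, entropy index, classification."""

import numpy as np
import pytest
from scipy.linalg import fractional_matrix_power

import fbtmsi as fb
from fbtmsi.msi import joint_covariance, sync_index, whiten


def _random_pair(rng, n_c=9, n_h=4, m=250):
    X = fb.standardize(rng.standard_normal((n_c, m)))
    Y = fb.standardize(rng.standard_normal((2 * n_h, m)))
    return X, Y


class TestJointCovariance:
    def test_unit_diagonal_for_standardized_rows(self, rng):
        X, Y = _random_pair(rng)
        cov = joint_covariance(X, Y)
        np.testing.assert_allclose(np.diag(cov.c11), 1.0, atol=1e-10)
        np.testing.assert_allclose(np.diag(cov.c22), 1.0, atol=1e-10)

    def test_orthogonal_signals_give_zero_cross_block(self):
        t = np.arange(1, 251) / 250.0
        X = fb.standardize(np.vstack([np.sin(2 * np.pi * 10 * t)]))
        Y = fb.standardize(np.vstack([np.sin(2 * np.pi * 20 * t),
                                      np.cos(2 * np.pi * 30 * t)]))
        cov = joint_covariance(X, Y)
        assert np.abs(cov.c12).max() < 1e-10

    def test_matches_stacked_signal_oracle(self, rng):
        X, Y = _random_pair(rng)
        cov = joint_covariance(X, Y)
        z = np.vstack([X, Y])
        m = z.shape[1]
        # direct loop-computed (1/M) Z Z^T
        expected = np.zeros((z.shape[0], z.shape[0]))
        for t in range(m):
            expected += np.outer(z[:, t], z[:, t])
        expected /= m
        np.testing.assert_allclose(cov.matrix, expected, atol=1e-10)

    def test_sample_count_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="mismatch"):
            joint_covariance(rng.standard_normal((3, 100)),
                             rng.standard_normal((2, 101)))


class TestWhiten:
    def test_zero_cross_block_gives_identity(self, rng):
        X, Y = _random_pair(rng)
        cov = joint_covariance(X, Y)
        cov.c12[:] = 0.0
        np.testing.assert_allclose(whiten(cov), np.eye(cov.p), atol=1e-8)

    def test_unit_trace_per_signal(self, rng):
        X, Y = _random_pair(rng)
        r = whiten(joint_covariance(X, Y))
        assert np.trace(r) == pytest.approx(r.shape[0], abs=1e-8)

    def test_matches_fractional_power_oracle(self, rng):
        X, Y = _random_pair(rng, n_c=5, n_h=3, m=200)
        cov = joint_covariance(X, Y)
        q1 = fractional_matrix_power(cov.c11, -0.5).real
        q2 = fractional_matrix_power(cov.c22, -0.5).real
        q = np.zeros((cov.p, cov.p))
        n1 = cov.c11.shape[0]
        q[:n1, :n1] = q1
        q[n1:, n1:] = q2
        expected = q @ cov.matrix @ q.T
        np.testing.assert_allclose(whiten(cov), expected, atol=1e-8)

    def test_degenerate_block_error_names_block(self):
        cov = fb.JointCovariance(
            c11=np.zeros((3, 3)), c12=np.zeros((3, 4)), c22=np.eye(4)
        )
        with pytest.raises(np.linalg.LinAlgError, match="C11"):
            whiten(cov)


class TestSyncIndex:
    def test_identity_gives_exact_zero(self):
        assert sync_index(np.eye(17)) == 0.0

    def test_rank_one_gives_exact_one(self):
        p = 17
        v = np.full(p, 1.0 / np.sqrt(p))
        assert sync_index(p * np.outer(v, v)) == 1.0

    def test_matches_direct_entropy_evaluation(self, rng):
        a = rng.standard_normal((17, 17))
        r = a @ a.T
        d = np.sqrt(np.diag(r))
        r = r / np.outer(d, d)  # random correlation matrix
        lam = np.linalg.eigvalsh(r)
        lam = np.maximum(lam, 0)
        lamp = lam / lam.sum()
        expected = 1 + sum(l * np.log(l) for l in lamp if l > 0) / np.log(17)
        assert sync_index(r) == pytest.approx(expected, rel=1e-10)

    def test_rejects_asymmetric_input(self, rng):
        r = rng.standard_normal((5, 5))
        with pytest.raises(ValueError, match="symmetric"):
            sync_index(r)


class TestMsi:
    def test_independent_noise_gives_near_zero(self):
        rng = np.random.default_rng(11)
        ref = fb.build_reference(10.0, 4, 5000, 250.0)
        vals = [
            fb.msi(np.random.default_rng(s).standard_normal((9, 5000)), ref)
            for s in range(5)
        ]
        assert max(vals) < 0.05

    def test_synchrony_decreases_with_noise(self):
        # an epoch made of the reference's own rows stays near its
        # noiseless synchrony for tiny noise and degrades monotonically
        ref = fb.build_reference(10.0, 2, 500, 250.0)
        rng = np.random.default_rng(5)
        base = ref.matrix[:2]
        noise = rng.standard_normal(base.shape)
        noiseless = fb.msi(base + 1e-8 * noise, ref)
        vals = [fb.msi(base + s * noise, ref) for s in (0.01, 0.1, 0.5, 2.0)]
        assert vals[0] == pytest.approx(noiseless, abs=0.02)
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_channel_permutation_invariance(self, rng):
        X = rng.standard_normal((9, 250))
        ref = fb.build_reference(12.0, 4, 250, 250.0)
        perm = rng.permutation(9)
        assert fb.msi(X, ref) == pytest.approx(fb.msi(X[perm], ref), abs=1e-10)

    def test_epoch_scaling_invariance(self, rng):
        X = rng.standard_normal((9, 250))
        ref = fb.build_reference(12.0, 4, 250, 250.0)
        assert fb.msi(X, ref) == pytest.approx(fb.msi(3.7 * X, ref), abs=1e-10)


class TestClassify:
    def test_noiseless_epoch_detected(self, bank40, noiseless_epoch):
        ep, cfg = noiseless_epoch
        x = ep.window(1.0, offset=cfg.latency)
        for method, kw in [("msi", {}), ("tmsi", {"tau": 15.0})]:
            res = fb.classify(x, bank40, method=method, **kw)
            assert res.frequency == pytest.approx(12.6)

    def test_profile_matches_single_pair_msi(self, small_bank, rng):
        X = rng.standard_normal((6, 250))
        prof = fb.msi_profile(X, small_bank)
        direct = [fb.msi(X, ref) for ref in small_bank]
        np.testing.assert_allclose(prof, direct, rtol=1e-8)

    def test_single_frequency_bank_always_returned(self, rng):
        bank = fb.build_reference_bank([11.0], 3, 250, 250.0)
        res = fb.classify(rng.standard_normal((4, 250)), bank, method="msi")
        assert res.frequency == 11.0 and res.n == 1

    def test_exact_tie_breaks_to_lower_index(self, small_bank, monkeypatch):
        import importlib

        msi_mod = importlib.import_module("fbtmsi.msi")
        monkeypatch.setattr(
            msi_mod, "msi_profile",
            lambda X, bank: np.array([0.4, 0.4, 0.2, 0.4, 0.1]),
        )
        res = msi_mod.classify(np.zeros((2, 250)), small_bank, method="msi")
        assert res.index == 0 and res.n == 1
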
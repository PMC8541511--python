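import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from valveseg.errors import ValidationError
from valveseg.factorization import (
    FactorizationConfig,
    VideoMatrix,
    bregman_rnmf,
    exclusion_rnmf,
    nmf_multiplicative,
    soft_threshold_nonneg,
)

from .conftest import make_lowrank


class TestSoftThreshold:
    def test_above_threshold(self):
        assert soft_threshold_nonneg(0.5, 0.2) == pytest.approx(0.3)

    def test_below_threshold(self):
        assert soft_threshold_nonneg(0.1, 0.2) == 0.0

    def test_negative_input(self):
        assert soft_threshold_nonneg(-0.3, 0.2) == 0.0

    def test_negative_lam_rejected(self):
        with pytest.raises(ValidationError):
            soft_threshold_nonneg(0.5, -0.1)

    def test_elementwise(self):
        out = soft_threshold_nonneg(np.array([0.5, 0.1, -0.3]), 0.2)
        np.testing.assert_allclose(out, [0.3, 0.0, 0.0])

    @given(
        u=st.floats(-10, 10, allow_nan=False),
        lam=st.floats(0, 5, allow_nan=False),
    )
    @settings(max_examples=200, deadline=None)
    def test_branches(self, u, lam):
        out = soft_threshold_nonneg(u, lam)
        assert out >= 0
        if u > lam:
            assert out == pytest.approx(u - lam)
        else:
            assert out == 0.0


class TestNMF:
    def test_fixed_point_at_exact_factorization(self, rng):
        W0 = rng.random((12, 2)) + 0.1
        H0 = rng.random((2, 8)) + 0.1
        X = W0 @ H0
        W, H = nmf_multiplicative(X, rank=2, n_iters=5, init=(W0, H0))
        np.testing.assert_allclose(W @ H, X, rtol=1e-6)

    def test_rank1_outer_product_converges(self):
        X = np.outer([1.0, 2.0], [1.0, 1.0, 1.0])
        W, H = nmf_multiplicative(X, rank=1, n_iters=500, seed=0)
        rel = np.linalg.norm(X - W @ H) / np.linalg.norm(X)
        assert rel < 1e-3

    def test_zero_input_collapses(self):
        X = np.zeros((6, 4))
        rng = np.random.default_rng(0)
        W0 = 1.0 - rng.random((6, 2))
        H0 = 1.0 - rng.random((2, 4))
        init_norm = np.linalg.norm(W0 @ H0)
        W, H = nmf_multiplicative(X, rank=2, n_iters=50, seed=0)
        assert np.linalg.norm(W @ H) < 1e-6 * init_norm

    def test_objective_nonincreasing(self, rng):
        X = rng.random((30, 12))
        W, H = nmf_multiplicative(X, rank=3, n_iters=0, seed=1)
        prev = np.sum((X - W @ H) ** 2)
        for _ in range(100):
            W, H = nmf_multiplicative(X, rank=3, n_iters=1, init=(W, H))
            err = np.sum((X - W @ H) ** 2)
            assert err <= prev + 1e-8
            prev = err

    def test_rank_too_large_rejected(self, rng):
        X = rng.random((5, 4))
        with pytest.raises(ValidationError):
            nmf_multiplicative(X, rank=4, n_iters=1)

    def test_nonnegative_output(self, rng):
        X = rng.random((20, 10))
        W, H = nmf_multiplicative(X, rank=2, n_iters=30, seed=2)
        assert W.min() >= 0 and H.min() >= 0


def _video(X):
    # wrap a matrix whose row count factors as sx * sy
    s = X.shape[0]
    for sx in range(int(np.sqrt(s)), 0, -1):
        if s % sx == 0:
            return VideoMatrix(X=X, sx=sx, sy=s // sx)
    raise AssertionError


class TestBregmanRNMF:
    def test_zero_input(self):
        X = _video(np.zeros((20, 8)))
        res = bregman_rnmf(X, FactorizationConfig(rank=2, n_outer_iters=20, n_init_nmf_iters=20))
        assert np.max(np.abs(res.W @ res.H)) < 1e-6
        assert np.max(res.S) < 1e-6

    def test_exact_lowrank_no_sparse_part(self, rng):
        X, _, _ = make_lowrank(100, 30, 1, rng)
        res = bregman_rnmf(_video(X), FactorizationConfig(rank=1, lam=0.1, seed=3))
        assert np.max(np.abs(res.S)) < 0.01 * X.max()
        rel = np.linalg.norm(X - res.W @ res.H) / np.linalg.norm(X)
        assert rel < 1e-2

    def test_nonnegativity_and_subgradient_every_iteration(self, rng):
        X, _, _ = make_lowrank(40, 12, 2, rng)
        X[rng.random(X.shape) < 0.05] += 1.0
        checked = []

        def hook(k, W, H, S, p):
            assert W.min() >= 0 and H.min() >= 0 and S.min() >= 0
            pos = S > 0
            if pos.any():
                np.testing.assert_allclose(p[pos], 1.0, atol=1e-9)
            checked.append(k)

        bregman_rnmf(
            _video(X),
            FactorizationConfig(rank=2, lam=0.1, n_outer_iters=30, n_init_nmf_iters=50),
            iter_hook=hook,
        )
        assert len(checked) == 30

    def test_lam_zero_warns(self, rng):
        X, _, _ = make_lowrank(20, 6, 1, rng)
        with pytest.warns(UserWarning, match="unconstrained"):
            bregman_rnmf(
                _video(X),
                FactorizationConfig(rank=1, lam=0.0, n_outer_iters=5, n_init_nmf_iters=10),
            )

    def test_result_invariants(self, rng):
        X, _, _ = make_lowrank(30, 10, 2, rng)
        res = bregman_rnmf(
            _video(X), FactorizationConfig(rank=2, n_outer_iters=40, n_init_nmf_iters=50)
        )
        assert res.r == 2
        assert res.W.min() >= 0 and res.H.min() >= 0 and res.S.min() >= 0
        assert len(res.objective_trace) == 40
        pos = res.S > 0
        if pos.any():
            np.testing.assert_allclose(res.p[pos], 1.0, atol=1e-9)


def _planted_spikes(rng, s=100, t=30, n_spikes=50, amplitude=1.0):
    bg, _, _ = make_lowrank(s, t, 2, rng)
    flat = rng.choice(s * t, size=n_spikes, replace=False)
    X = bg.copy()
    X.ravel()[flat] += amplitude
    return X, flat


@pytest.fixture(scope="module")
def instance():
    rng = np.random.default_rng(99)
    return _planted_spikes(rng)


class TestShrinkageBias:
    """Planted-spike amplitude recovery: debiased vs frozen-subgradient."""

    def _recovered(self, X, flat, lam, freeze_p):
        cfg = FactorizationConfig(rank=2, lam=lam, seed=5)
        res = bregman_rnmf(_video(X), cfg, freeze_p=freeze_p)
        return res.S.ravel()[flat]

    def test_debiased_amplitude_near_truth(self, instance):
        X, flat = instance
        amp = self._recovered(X, flat, lam=0.1, freeze_p=False)
        assert abs(amp.mean() - 1.0) < 0.05

    def test_frozen_p_shrinks_by_lam(self, instance):
        X, flat = instance
        amp = self._recovered(X, flat, lam=0.1, freeze_p=True)
        assert abs(amp.mean() - 0.9) < 0.05

    @pytest.mark.parametrize("lam", [0.05, 0.1, 0.2])
    def test_bias_ordering(self, instance, lam):
        X, flat = instance
        err_debiased = np.abs(self._recovered(X, flat, lam, False) - 1.0).mean()
        err_frozen = np.abs(self._recovered(X, flat, lam, True) - 1.0).mean()
        assert err_debiased < err_frozen


class TestExclusionRNMF:
    def test_mu2_zero_matches_bregman(self, rng):
        X, _, _ = make_lowrank(30, 10, 2, rng)
        X[rng.random(X.shape) < 0.1] += 0.8
        cfg = FactorizationConfig(rank=2, lam=0.25, mu1=0.25, mu2=0.0, seed=4,
                                  n_outer_iters=50, n_init_nmf_iters=50)
        a = bregman_rnmf(_video(X), cfg)
        b = exclusion_rnmf(_video(X), cfg)
        for x, y in ((a.W, b.W), (a.H, b.H), (a.S, b.S), (a.p, b.p)):
            np.testing.assert_allclose(x, y, atol=1e-10)

    def test_zero_input(self):
        X = _video(np.zeros((20, 8)))
        res = exclusion_rnmf(X, FactorizationConfig(rank=2, n_outer_iters=10, n_init_nmf_iters=10))
        assert np.max(np.abs(res.W @ res.H)) < 1e-6
        assert np.max(res.S) < 1e-6

    def test_mu1_zero_rejected(self, rng):
        X, _, _ = make_lowrank(20, 6, 1, rng)
        with pytest.raises(ValidationError):
            exclusion_rnmf(_video(X), FactorizationConfig(rank=1, mu1=0.0))

    def test_exclusion_reduces_overlap(self, easy_phantom):
        v = easy_phantom.video
        X = VideoMatrix(X=v.matrix, sx=v.sx, sy=v.sy)
        overlaps = {}
        for mu2 in (0.4, 0.0):
            cfg = FactorizationConfig(rank=5, mu1=1.0, mu2=mu2, seed=0)
            res = exclusion_rnmf(X, cfg)
            overlaps[mu2] = np.mean(res.WH * res.S)
        assert overlaps[0.4] < overlaps[0.0]

    def test_subgradient_consistency(self, rng):
        X, _, _ = make_lowrank(30, 10, 2, rng)
        X[rng.random(X.shape) < 0.1] += 1.0
        cfg = FactorizationConfig(rank=2, mu1=0.3, mu2=0.2, seed=1,
                                  n_outer_iters=40, n_init_nmf_iters=40)
        res = exclusion_rnmf(_video(X), cfg)
        pos = res.S > 0
        assert pos.any()
        np.testing.assert_allclose(res.p[pos], 1.0, atol=1e-9)


class TestResultSerialization:
    def test_roundtrip(self, rng, tmp_path):
        from valveseg.factorization import FactorizationResult

        X, _, _ = make_lowrank(30, 10, 2, rng)
        cfg = FactorizationConfig(rank=2, n_outer_iters=10, n_init_nmf_iters=20)
        res = bregman_rnmf(_video(X), cfg)
        res.save(tmp_path / "fact.npz", config=cfg)
        back = FactorizationResult.load(tmp_path / "fact.npz")
        np.testing.assert_array_equal(back.W, res.W)
        np.testing.assert_array_equal(back.S, res.S)
        np.testing.assert_array_equal(back.p, res.p)
        assert back.r == res.r
        np.testing.assert_allclose(back.objective_trace, res.objective_trace)

    def test_numerical_failure_names_iteration(self):
        import warnings

        from valveseg.errors import NumericalError

        X = VideoMatrix(np.full((4, 4), 1e200), 2, 2)
        cfg = FactorizationConfig(rank=1, n_outer_iters=5, n_init_nmf_iters=2)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            with pytest.raises(NumericalError) as err:
                bregman_rnmf(X, cfg)
        assert err.value.iteration is not None


class TestConservation:
    def test_noise_free_residual_small(self, small_spec):
        import dataclasses

        from valveseg.phantom import generate_phantom

        spec = dataclasses.replace(small_spec, noise_sigma=0.0)
        out = generate_phantom(spec)
        v = out.video
        X = VideoMatrix(X=v.matrix, sx=v.sx, sy=v.sy)
        res = bregman_rnmf(X, FactorizationConfig(rank=spec.bg_rank, lam=0.1, seed=0))
        rel = np.linalg.norm(X.X - res.W @ res.H - res.S) / np.linalg.norm(X.X)
        assert rel < 0.05
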
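"""Fast filter path against brute-force window solves and hand bilinear math."""

import numpy as np
import pytest

from csag.attention import AttentionFusion
from csag.csfag import (
    CSFAGConfig,
    aggregate_coefficients,
    csfag_bruteforce_oracle,
    csfag_filter,
    csfag_forward,
    solve_coefficients,
    subsample_guide,
    upsample_coefficients,
    weighted_box_stats,
)


def _hand_bilinear(x, th, tw):
    """Independent half-pixel-center bilinear formula (test-local)."""
    c, h, w = x.shape
    out = np.empty((c, th, tw))
    for i in range(th):
        sy = np.clip((i + 0.5) * h / th - 0.5, 0, h - 1)
        y0, fy = int(np.floor(sy)), sy - int(np.floor(sy))
        y1 = min(y0 + 1, h - 1)
        for j in range(tw):
            sx = np.clip((j + 0.5) * w / tw - 0.5, 0, w - 1)
            x0, fx = int(np.floor(sx)), sx - int(np.floor(sx))
            x1 = min(x0 + 1, w - 1)
            out[:, i, j] = ((1 - fy) * (1 - fx) * x[:, y0, x0] + (1 - fy) * fx * x[:, y0, x1]
                            + fy * (1 - fx) * x[:, y1, x0] + fy * fx * x[:, y1, x1])
    return out


class TestConfig:
    def test_defaults_match_published_settings(self):
        cfg = CSFAGConfig()
        assert cfg.r == 4
        assert cfg.lam == pytest.approx(1e-3)

    @pytest.mark.parametrize("kwargs", [dict(r=0), dict(lam=0.0), dict(lam=-1.0),
                                        dict(subsample_factor=0)])
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            CSFAGConfig(**kwargs)


class TestSubsample:
    def test_constant_preserved(self):
        const = np.full((2, 8, 8), 1.75)
        np.testing.assert_allclose(subsample_guide(const, 2), 1.75)

    def test_factor_one_identity(self, rng):
        g = rng.standard_normal((1, 5, 5))
        np.testing.assert_array_equal(subsample_guide(g, 1), g)

    def test_ramp_matches_hand_bilinear(self):
        g = np.arange(16, dtype=float).reshape(1, 4, 4)
        np.testing.assert_allclose(subsample_guide(g, 2), _hand_bilinear(g, 2, 2), atol=1e-12)

    def test_factor_exceeding_extent_rejected(self):
        with pytest.raises(ValueError):
            subsample_guide(np.zeros((1, 4, 4)), 5)


class TestStats:
    def test_constant_inputs(self):
        c = 2.5
        cfg = CSFAGConfig(r=2)
        a = np.full((1, 6, 6), 0.7)
        stats = weighted_box_stats(np.full((1, 6, 6), c), np.full((1, 6, 6), c), a, cfg)
        np.testing.assert_allclose(stats.mu, c, atol=1e-12)
        np.testing.assert_allclose(stats.fbar, c, atol=1e-12)
        np.testing.assert_allclose(stats.sigma2, 0.0, atol=1e-12)
        np.testing.assert_allclose(stats.cross, c * c, atol=1e-12)

    def test_uniform_weights_equal_unweighted(self, rng):
        cfg = CSFAGConfig(r=2)
        gl = rng.standard_normal((1, 8, 8))
        f = rng.standard_normal((1, 8, 8))
        weighted = weighted_box_stats(gl, f, np.ones((1, 8, 8)), cfg)
        plain = weighted_box_stats(gl, f, None, cfg, weighted=False)
        for name in ("mu", "sigma2", "fbar", "cross"):
            np.testing.assert_allclose(getattr(weighted, name), getattr(plain, name), atol=1e-10)

    def test_matches_double_loop(self):
        rng = np.random.default_rng(3)
        gl = rng.standard_normal((1, 10, 10))
        f = rng.standard_normal((1, 10, 10))
        a = rng.uniform(0.2, 1.0, (1, 10, 10))
        cfg = CSFAGConfig(r=2)
        stats = weighted_box_stats(gl, f, a, cfg)
        for i in range(10):
            for j in range(10):
                ys, xs = slice(max(i - 2, 0), i + 3), slice(max(j - 2, 0), j + 3)
                wts = a[0, ys, xs] ** 2
                gw, fw = gl[0, ys, xs], f[0, ys, xs]
                assert stats.mu[0, i, j] == pytest.approx((wts * gw).sum() / wts.sum(), abs=1e-10)
                assert stats.fbar[0, i, j] == pytest.approx((wts * fw).sum() / wts.sum(), abs=1e-10)
                var = (wts * gw * gw).sum() / wts.sum() - ((wts * gw).sum() / wts.sum()) ** 2
                assert stats.sigma2[0, i, j] == pytest.approx(max(var, 0), abs=1e-10)

    def test_zero_weight_mass_rejected(self):
        cfg = CSFAGConfig(r=1)
        with pytest.raises(ValueError):
            weighted_box_stats(np.ones((1, 6, 6)), np.ones((1, 6, 6)),
                               np.zeros((1, 6, 6)), cfg)

    def test_border_window_counts_exact(self):
        cfg = CSFAGConfig(r=1)
        stats = weighted_box_stats(np.zeros((1, 4, 4)), np.zeros((1, 4, 4)), None, cfg,
                                   weighted=False)
        np.testing.assert_array_equal(
            stats.count,
            [[4, 6, 6, 4], [6, 9, 9, 6], [6, 9, 9, 6], [4, 6, 6, 4]])


class TestSolve:
    def test_constant_f_zero_slope(self, rng):
        cfg = CSFAGConfig(r=2)
        gl = rng.standard_normal((1, 8, 8))
        f = np.full((1, 8, 8), 4.25)
        a = rng.uniform(0.3, 1.0, (1, 8, 8))
        wk, bk = solve_coefficients(weighted_box_stats(gl, f, a, cfg), cfg)
        np.testing.assert_allclose(wk, 0.0, atol=1e-9)
        np.testing.assert_allclose(bk, 4.25, atol=1e-9)

    def test_self_guidance_limit(self, rng):
        cfg = CSFAGConfig(r=2, lam=1e-12)
        gl = rng.standard_normal((1, 8, 8))
        wk, bk = solve_coefficients(weighted_box_stats(gl, gl, None, cfg, weighted=False), cfg)
        np.testing.assert_allclose(wk, 1.0, atol=1e-6)
        np.testing.assert_allclose(bk, 0.0, atol=1e-6)

    def test_matches_normal_equations(self):
        rng = np.random.default_rng(4)
        gl = rng.standard_normal((1, 10, 10))
        f = rng.standard_normal((1, 10, 10))
        a = rng.uniform(0.1, 1.0, (1, 10, 10))
        cfg = CSFAGConfig(r=2, lam=1e-3)
        wk, bk = solve_coefficients(weighted_box_stats(gl, f, a, cfg), cfg)
        for i in range(10):
            for j in range(10):
                ys, xs = slice(max(i - 2, 0), i + 3), slice(max(j - 2, 0), j + 3)
                av = (a[0, ys, xs] ** 2).ravel()
                gv, fv = gl[0, ys, xs].ravel(), f[0, ys, xs].ravel()
                m = np.array([[ (av * gv * gv).sum() + cfg.lam * av.sum(), (av * gv).sum()],
                              [ (av * gv).sum(), av.sum()]])
                sol = np.linalg.solve(m, [ (av * gv * fv).sum(), (av * fv).sum()])
                assert wk[0, i, j] == pytest.approx(sol[0], abs=1e-8)
                assert bk[0, i, j] == pytest.approx(sol[1], abs=1e-8)

    def test_slope_magnitude_monotone_in_lambda(self, rng):
        gl = rng.standard_normal((1, 8, 8))
        f = rng.standard_normal((1, 8, 8))
        prev = None
        for lam in (1e-4, 1e-2, 1.0, 100.0):
            cfg = CSFAGConfig(r=2, lam=lam)
            wk, _ = solve_coefficients(weighted_box_stats(gl, f, None, cfg, weighted=False), cfg)
            if prev is not None:
                assert np.all(np.abs(wk) <= prev + 1e-12)
            prev = np.abs(wk)


class TestAggregate:
    def test_constant(self):
        cfg = CSFAGConfig(r=3)
        wl, _ = aggregate_coefficients(np.full((1, 9, 9), 0.6), np.zeros((1, 9, 9)), cfg)
        np.testing.assert_allclose(wl, 0.6, atol=1e-12)

    def test_impulse_response(self):
        cfg = CSFAGConfig(r=1)
        wk = np.zeros((1, 7, 7))
        wk[0, 3, 3] = 1.0
        wl, _ = aggregate_coefficients(wk, wk, cfg)
        np.testing.assert_allclose(wl[0, 2:5, 2:5], 1.0 / 9.0, atol=1e-12)
        assert wl[0, 0, 0] == 0.0

    def test_matches_double_loop(self, rng):
        cfg = CSFAGConfig(r=3)
        wk = rng.standard_normal((1, 10, 10))
        bk = rng.standard_normal((1, 10, 10))
        wl, bl = aggregate_coefficients(wk, bk, cfg)
        for i in range(10):
            for j in range(10):
                ys, xs = slice(max(i - 3, 0), i + 4), slice(max(j - 3, 0), j + 4)
                assert wl[0, i, j] == pytest.approx(wk[0, ys, xs].mean(), abs=1e-10)
                assert bl[0, i, j] == pytest.approx(bk[0, ys, xs].mean(), abs=1e-10)


class TestUpsample:
    def test_constant_and_identity(self, rng):
        wl = np.full((1, 3, 3), 2.0)
        wh, _ = upsample_coefficients(wl, wl, (6, 6))
        np.testing.assert_allclose(wh, 2.0)
        x = rng.standard_normal((1, 4, 4))
        wh, _ = upsample_coefficients(x, x, (4, 4))
        np.testing.assert_allclose(wh, x)

    def test_ramp_matches_hand_bilinear(self):
        x = np.arange(9, dtype=float).reshape(1, 3, 3)
        wh, _ = upsample_coefficients(x, x, (6, 6))
        np.testing.assert_allclose(wh, _hand_bilinear(x, 6, 6), atol=1e-12)


class TestForward:
    def test_constant_f_conservation(self, rng):
        g = rng.standard_normal((1, 16, 16))
        f = np.full((1, 8, 8), 3.0)
        a = rng.uniform(0.2, 0.9, (1, 8, 8))
        cfg = CSFAGConfig(r=2, subsample_factor=2)
        o = csfag_filter(g, f, a, cfg)
        np.testing.assert_allclose(o, 3.0, atol=1e-9)

    def test_self_guidance_limit(self, rng):
        g = rng.standard_normal((1, 12, 12))
        cfg = CSFAGConfig(r=2, lam=1e-8, subsample_factor=1)
        o = csfag_filter(g, g, np.ones((1, 12, 12)), cfg)
        assert np.abs(o - g).max() < 1e-3

    def test_matches_oracle_with_attention_module(self):
        rng = np.random.default_rng(5)
        g = rng.standard_normal((1, 16, 16))
        f = rng.standard_normal((1, 8, 8))
        cfg = CSFAGConfig(r=2, subsample_factor=2)
        fusion = AttentionFusion(1, ratio=1, kernel_size=3,
                                 rng=np.random.default_rng(5), dtype=np.float64)
        from csag.csfag import subsample_guide
        from csag.nn import Tensor

        gl = subsample_guide(g, 2)
        a = fusion(Tensor(f[None]), Tensor(gl[None])).data[0]
        o_fast = csfag_forward(g, f, cfg, attention=fusion)
        o_slow = csfag_bruteforce_oracle(g, f, a, cfg)
        np.testing.assert_allclose(o_fast, o_slow, atol=1e-6)

    def test_shape_contract_and_channel_mismatch(self, rng):
        g = rng.standard_normal((3, 16, 16))
        f = rng.standard_normal((3, 8, 8))
        o = csfag_forward(g, f, CSFAGConfig(r=1, subsample_factor=2))
        assert o.shape == g.shape
        with pytest.raises(ValueError):
            csfag_filter(g, rng.standard_normal((2, 8, 8)), None, CSFAGConfig(subsample_factor=2))

    def test_oracle_equivalence_random_instances(self):
        rng = np.random.default_rng(123)
        for trial in range(12):
            h = int(rng.integers(6, 17)) * 2
            factor = int(rng.choice([1, 2]))
            r = int(rng.integers(1, 4))
            g = rng.standard_normal((1, h, h))
            f = rng.standard_normal((1, h // factor, h // factor))
            a = rng.uniform(0.05, 1.0, (1, h // factor, h // factor))
            cfg = CSFAGConfig(r=r, lam=10.0 ** rng.uniform(-4, 0), subsample_factor=factor)
            np.testing.assert_allclose(
                csfag_filter(g, f, a, cfg), csfag_bruteforce_oracle(g, f, a, cfg),
                atol=1e-6, err_msg=f"trial {trial}")

    def test_uniform_attention_reduces_to_plain_guided_filter(self):
        rng = np.random.default_rng(9)
        g = rng.standard_normal((1, 12, 12))
        f = rng.standard_normal((1, 12, 12))
        cfg = CSFAGConfig(r=2, lam=1e-2, subsample_factor=1)
        o_uniform = csfag_filter(g, f, np.ones((1, 12, 12)), cfg)
        # plain unweighted fast guided filter written out longhand
        wk = np.empty((12, 12))
        bk = np.empty((12, 12))
        for i in range(12):
            for j in range(12):
                ys, xs = slice(max(i - 2, 0), i + 3), slice(max(j - 2, 0), j + 3)
                gv, fv = g[0, ys, xs], f[0, ys, xs]
                mu, fb = gv.mean(), fv.mean()
                wk[i, j] = ((gv * fv).mean() - mu * fb) / (gv.var() + cfg.lam)
                bk[i, j] = fb - wk[i, j] * mu
        o_plain = np.empty((12, 12))
        for i in range(12):
            for j in range(12):
                ys, xs = slice(max(i - 2, 0), i + 3), slice(max(j - 2, 0), j + 3)
                o_plain[i, j] = wk[ys, xs].mean() * g[0, i, j] + bk[ys, xs].mean()
        np.testing.assert_allclose(o_uniform[0], o_plain, atol=1e-6)

    def test_as_printed_mode_ignores_attention(self, rng):
        g = rng.standard_normal((1, 10, 10))
        f = rng.standard_normal((1, 10, 10))
        cfg = CSFAGConfig(r=2, subsample_factor=1, weighted=False)
        o1 = csfag_filter(g, f, rng.uniform(0.1, 1.0, (1, 10, 10)), cfg)
        o2 = csfag_filter(g, f, np.ones((1, 10, 10)), cfg)
        np.testing.assert_allclose(o1, o2, atol=1e-12)
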
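"""Attention-guided fast filter.

Per channel, the filter fits a local linear model ``O = W*Gl + B`` on every
border-clipped box window of the low-resolution guide by ridge-regularised
weighted least squares, where each pixel's residual is weighted by the
squared attention value ``A_i**2``.  Per-window coefficients are averaged
over all windows covering a pixel, bilinearly upsampled, and applied to the
full-resolution guide.

Two independent computation paths are provided: the production path based
on running box sums (O(N) per channel, autodiff-capable), and a brute-force
oracle that solves every window's 2x2 normal equations explicitly.  Tests
cross-check one against the other.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor, as_tensor

__all__ = [
    "CSFAGConfig",
    "WindowStats",
    "FilterCoefficients",
    "subsample_guide",
    "weighted_box_stats",
    "solve_coefficients",
    "aggregate_coefficients",
    "upsample_coefficients",
    "csfag_filter",
    "csfag_forward",
    "csfag_bruteforce_oracle",
]


@dataclass
class CSFAGConfig:
    """r and lam default to the published configuration (r=4, lam=1e-3)."""

    r: int = 4
    lam: float = 1e-3
    subsample_factor: int = 1
    weighted: bool = True  # False = as-printed mode: attention ignored in the solve

    def __post_init__(self):
        if self.r < 1:
            raise ValueError("window radius r must be >= 1")
        if self.lam <= 0:
            raise ValueError("regularizer lam must be > 0")
        if self.subsample_factor < 1:
            raise ValueError("subsample_factor must be >= 1")


@dataclass
class WindowStats:
    mu: np.ndarray       # weighted mean of Gl per window
    sigma2: np.ndarray   # weighted variance of Gl (clamped at 0)
    fbar: np.ndarray     # weighted mean of F
    cross: np.ndarray    # weighted mean of Gl*F
    mass: np.ndarray     # sum of window weights (|w| or sum A_i^2)
    count: np.ndarray    # plain border-clipped window pixel counts


@dataclass
class FilterCoefficients:
    wk: np.ndarray
    bk: np.ndarray
    wl: np.ndarray
    bl: np.ndarray
    wh: np.ndarray
    bh: np.ndarray


def _as_chw(x) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    if x.ndim == 2:
        x = x[None]
    if x.ndim != 3:
        raise ValueError(f"expected (C,H,W) or (H,W), got shape {x.shape}")
    return x


# ---------------------------------------------------------------------------
# tensor-level building blocks (shared by numpy wrappers and the nn module)
# ---------------------------------------------------------------------------

def _stats_t(gl: Tensor, f: Tensor, a: Tensor | None, r: int, weighted: bool):
    """Weighted window statistics on (...,H,W) tensors; a broadcasts to them."""
    h, w = gl.shape[-2], gl.shape[-1]
    ones = np.ones((h, w))
    count = nn.box_sum_numpy(ones, r)
    if weighted and a is not None:
        wgt = a * a
        mass = nn.box_sum(wgt, r)
        mu = nn.box_sum(wgt * gl, r) / mass
        fbar = nn.box_sum(wgt * f, r) / mass
        cross = nn.box_sum(wgt * gl * f, r) / mass
        sq = nn.box_sum(wgt * gl * gl, r) / mass
    else:
        cnt = Tensor(count)
        mass = cnt
        mu = nn.box_sum(gl, r) / cnt
        fbar = nn.box_sum(f, r) / cnt
        cross = nn.box_sum(gl * f, r) / cnt
        sq = nn.box_sum(gl * gl, r) / cnt
    sigma2 = (sq - mu * mu).clip_min(0.0)
    return mu, sigma2, fbar, cross, mass, count


def _filter_t(g: Tensor, f: Tensor, a: Tensor | None, cfg: CSFAGConfig,
              gl: Tensor | None = None) -> Tensor:
    """Full filter on tensors: stats -> solve -> aggregate -> upsample -> apply."""
    hh, wh_ = g.shape[-2], g.shape[-1]
    if gl is None:
        gl = nn.bilinear_resize(g, f.shape[-2], f.shape[-1])
    mu, sigma2, fbar, cross, mass, count = _stats_t(gl, f, a, cfg.r, cfg.weighted)
    wk = (cross - mu * fbar) / (sigma2 + cfg.lam)
    bk = fbar - wk * mu
    cnt = Tensor(count)
    wl = nn.box_sum(wk, cfg.r) / cnt
    bl = nn.box_sum(bk, cfg.r) / cnt
    wh = nn.bilinear_resize(wl, hh, wh_)
    bh = nn.bilinear_resize(bl, hh, wh_)
    return wh * g + bh


# ---------------------------------------------------------------------------
# numpy-facing operations
# ---------------------------------------------------------------------------

def subsample_guide(g: np.ndarray, factor: int) -> np.ndarray:
    """Bilinear down-scaling of a (C,H,W) guide by an integer factor."""
    g = _as_chw(g)
    if factor < 1:
        raise ValueError("factor must be >= 1")
    h, w = g.shape[-2:]
    if factor > h or factor > w:
        raise ValueError(f"factor {factor} exceeds spatial extent {(h, w)}")
    if factor == 1:
        return g.copy()
    return nn.bilinear_resize_numpy(g, h // factor, w // factor)


def weighted_box_stats(gl: np.ndarray, f: np.ndarray, a: np.ndarray | None,
                       cfg: CSFAGConfig, weighted: bool | None = None) -> WindowStats:
    gl, f = _as_chw(gl), _as_chw(f)
    if gl.shape != f.shape:
        raise ValueError("Gl and F must share a shape")
    weighted = cfg.weighted if weighted is None else weighted
    at = None
    if a is not None:
        a = np.asarray(a, dtype=np.float64)
        if a.ndim == 2:
            a = a[None]
        np.broadcast_shapes(a.shape, gl.shape)
        at = Tensor(a)
        if weighted:
            mass_check = nn.box_sum_numpy(np.broadcast_to(a * a, gl.shape).copy(), cfg.r)
            if np.any(mass_check <= 0):
                raise ValueError("window weight mass is zero in at least one window")
    elif weighted:
        raise ValueError("weighted statistics require an attention map")
    mu, sigma2, fbar, cross, mass, count = _stats_t(Tensor(gl), Tensor(f), at, cfg.r, weighted)
    return WindowStats(mu.data, sigma2.data, fbar.data, cross.data,
                       np.broadcast_to(mass.data, gl.shape).copy(), count)


def solve_coefficients(stats: WindowStats, cfg: CSFAGConfig):
    """Ridge solution: Wk = (cross - mu*fbar)/(sigma2 + lam); Bk = fbar - Wk*mu."""
    for name in ("mu", "sigma2", "fbar", "cross"):
        if not np.all(np.isfinite(getattr(stats, name))):
            raise ValueError(f"non-finite window statistics in {name}")
    wk = (stats.cross - stats.mu * stats.fbar) / (stats.sigma2 + cfg.lam)
    bk = stats.fbar - wk * stats.mu
    return wk, bk


def aggregate_coefficients(wk: np.ndarray, bk: np.ndarray, cfg: CSFAGConfig):
    """Unweighted box mean of per-window coefficients with clipped counts."""
    wk, bk = _as_chw(wk), _as_chw(bk)
    if wk.shape != bk.shape:
        raise ValueError("Wk and Bk must share a shape")
    count = nn.box_sum_numpy(np.ones(wk.shape[-2:]), cfg.r)
    wl = nn.box_sum_numpy(wk, cfg.r) / count
    bl = nn.box_sum_numpy(bk, cfg.r) / count
    return wl, bl


def upsample_coefficients(wl: np.ndarray, bl: np.ndarray, target_shape):
    th, tw = target_shape[-2], target_shape[-1]
    wl, bl = _as_chw(wl), _as_chw(bl)
    if th < wl.shape[-2] or tw < wl.shape[-1]:
        raise ValueError("target shape smaller than coefficient maps")
    return (nn.bilinear_resize_numpy(wl, th, tw),
            nn.bilinear_resize_numpy(bl, th, tw))


def csfag_filter(g: np.ndarray, f: np.ndarray, a: np.ndarray | None,
                 cfg: CSFAGConfig, return_coefficients: bool = False):
    """Filter with an externally supplied attention map (None = uniform)."""
    g, f = _as_chw(g), _as_chw(f)
    gl = subsample_guide(g, cfg.subsample_factor)
    if gl.shape[-2:] != f.shape[-2:]:
        raise ValueError(
            f"F spatial shape {f.shape[-2:]} does not match subsampled guide {gl.shape[-2:]}")
    if f.shape[0] != g.shape[0]:
        raise ValueError("G and F channel counts differ")
    if a is not None:
        a = np.asarray(a, dtype=np.float64)
        if a.ndim == 2:
            a = a[None]
    # a = None means uniform attention, identical to unweighted statistics
    stats = weighted_box_stats(gl, f, a, cfg,
                               weighted=cfg.weighted and a is not None)
    wk, bk = solve_coefficients(stats, cfg)
    wl, bl = aggregate_coefficients(wk, bk, cfg)
    wh, bh = upsample_coefficients(wl, bl, g.shape)
    o = wh * g + bh
    if return_coefficients:
        return o, FilterCoefficients(wk, bk, wl, bl, wh, bh)
    return o


def csfag_forward(g: np.ndarray, f: np.ndarray, cfg: CSFAGConfig,
                  attention=None) -> np.ndarray:
    """Subsample the guide, derive the attention map, run the filter.

    ``attention`` is an :class:`~csag.attention.AttentionFusion` with channel
    count matching G/F; ``None`` runs with uniform attention (A = 1).
    """
    g, f = _as_chw(g), _as_chw(f)
    gl = subsample_guide(g, cfg.subsample_factor)
    if attention is None:
        a = np.ones((1,) + f.shape[-2:])
    else:
        a = attention(Tensor(f[None]), Tensor(gl[None])).data[0]
    return csfag_filter(g, f, a, cfg)


# ---------------------------------------------------------------------------
# brute-force oracle: no shared code with the production path
# ---------------------------------------------------------------------------

def _bilinear_loop(x: np.ndarray, th: int, tw: int) -> np.ndarray:
    """Per-pixel bilinear interpolation (half-pixel centers, edge clamp)."""
    c, h, w = x.shape
    out = np.empty((c, th, tw))
    for yy in range(th):
        sy = min(max((yy + 0.5) * h / th - 0.5, 0.0), h - 1.0)
        y0 = int(np.floor(sy))
        y1 = min(y0 + 1, h - 1)
        fy = sy - y0
        for xx in range(tw):
            sx = min(max((xx + 0.5) * w / tw - 0.5, 0.0), w - 1.0)
            x0 = int(np.floor(sx))
            x1 = min(x0 + 1, w - 1)
            fx = sx - x0
            out[:, yy, xx] = (
                x[:, y0, x0] * (1 - fy) * (1 - fx)
                + x[:, y0, x1] * (1 - fy) * fx
                + x[:, y1, x0] * fy * (1 - fx)
                + x[:, y1, x1] * fy * fx
            )
    return out


def csfag_bruteforce_oracle(g: np.ndarray, f: np.ndarray, a: np.ndarray | None,
                            cfg: CSFAGConfig) -> np.ndarray:
    """Slow reference: explicit per-window 2x2 weighted normal equations,
    explicit overlap averaging, explicit bilinear resampling loops."""
    g, f = _as_chw(g), _as_chw(f)
    if max(g.shape[-2:]) > 64:
        raise ValueError("oracle is restricted to small inputs (<= 64x64)")
    if cfg.subsample_factor == 1:
        gl = g.copy()
    else:
        gl = _bilinear_loop(g, g.shape[-2] // cfg.subsample_factor,
                            g.shape[-1] // cfg.subsample_factor)
    c, h, w = gl.shape
    if a is None or not cfg.weighted:
        amap = np.ones((h, w))
    else:
        amap = np.broadcast_to(np.asarray(a, dtype=np.float64).reshape(-1, h, w)[0], (h, w))
    r, lam = cfg.r, cfg.lam
    wk = np.empty_like(gl)
    bk = np.empty_like(gl)
    for ch in range(c):
        for ky in range(h):
            for kx in range(w):
                ys = slice(max(ky - r, 0), min(ky + r + 1, h))
                xs = slice(max(kx - r, 0), min(kx + r + 1, w))
                gv = gl[ch, ys, xs].ravel()
                fv = f[ch, ys, xs].ravel()
                av = (amap[ys, xs].ravel()) ** 2
                sa = av.sum()
                sg = (av * gv).sum()
                sf = (av * fv).sum()
                sgg = (av * gv * gv).sum()
                sgf = (av * gv * fv).sum()
                m = np.array([[sgg + lam * sa, sg], [sg, sa]])
                rhs = np.array([sgf, sf])
                sol = np.linalg.solve(m, rhs)
                wk[ch, ky, kx], bk[ch, ky, kx] = sol
    wl = np.empty_like(wk)
    bl = np.empty_like(bk)
    for ch in range(c):
        for iy in range(h):
            for ix in range(w):
                ys = slice(max(iy - r, 0), min(iy + r + 1, h))
                xs = slice(max(ix - r, 0), min(ix + r + 1, w))
                wl[ch, iy, ix] = wk[ch, ys, xs].mean()
                bl[ch, iy, ix] = bk[ch, ys, xs].mean()
    if gl.shape[-2:] == g.shape[-2:]:
        wh, bh = wl, bl
    else:
        wh = _bilinear_loop(wl, g.shape[-2], g.shape[-1])
        bh = _bilinear_loop(bl, g.shape[-2], g.shape[-1])
    return wh * g + bh
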
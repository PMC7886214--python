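"""Multi-pass FFT cross-correlation particle image velocimetry.

The estimator follows standard planar PIV practice: the image pair is
tiled into interrogation windows (64 px down to 16 px by default, 50%
overlap), each window pair is mean-subtracted and cross-correlated by
FFT with zero-padding to twice the window size (linear, not circular,
correlation), the correlation peak is refined to sub-pixel accuracy by
a three-point Gaussian fit, and vectors are screened with a normalized
median test.  Between passes the validated coarse field is rounded to
whole pixels and used to shift the second window (discrete window
offset), so the residual displacement at the final pass stays small.

Coordinate contract: image row 0 is the top of the frame; the physical
y axis points up.  A displacement of (dx, dy) pixels (dx rightward,
dy downward in image coordinates) therefore maps to velocities
``u = dx * magnification / dt`` and ``v = -dy * magnification / dt``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as _field
from typing import List, Tuple

import numpy as np

from .core import ConfigurationError, ParticleImagePair, VelocityField

__all__ = ["PIVConfig", "multipass_piv", "subpixel_peak", "validate_vectors"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PIVConfig:
    """Parameters of the multi-pass estimator."""

    pass_windows: tuple = (64, 16)  # px, strictly decreasing powers of two
    overlap_fraction: float = 0.5
    subpixel: str = "gaussian3"  # or "parabolic"
    validation_threshold: float = 2.0  # normalized median test
    validation_eps: float = 0.1  # px, noise floor of the median test
    magnification: float = 1.0  # m per px
    frame_interval: float = 1.0  # s

    def __post_init__(self) -> None:
        ws = tuple(int(w) for w in self.pass_windows)
        if not ws:
            raise ConfigurationError("need at least one pass window")
        for w in ws:
            if w < 8 or (w & (w - 1)) != 0:
                raise ConfigurationError("window sizes must be powers of two, >= 8 px")
        if any(a <= b for a, b in zip(ws, ws[1:])):
            raise ConfigurationError("window sizes must be strictly decreasing")
        if not 0.0 <= self.overlap_fraction <= 0.75:
            raise ConfigurationError("overlap_fraction must lie in [0, 0.75]")
        if self.subpixel not in ("gaussian3", "parabolic"):
            raise ConfigurationError("subpixel must be 'gaussian3' or 'parabolic'")
        if self.magnification <= 0 or self.frame_interval <= 0:
            raise ConfigurationError("magnification and frame_interval must be positive")


def _axis_offset(cm: float, c0: float, cp: float, method: str) -> float:
    """One-axis sub-pixel offset from the three correlation samples."""
    if method == "gaussian3" and min(cm, c0, cp) > 0:
        lm, l0, lp = np.log(cm), np.log(c0), np.log(cp)
        denom = 2.0 * lm - 4.0 * l0 + 2.0 * lp
        if denom == 0:
            return 0.0
        return float((lm - lp) / denom)
    # parabolic fallback (also used when a neighbor is non-positive)
    if method == "gaussian3":
        log.debug("non-positive correlation neighbor; parabolic fallback")
    denom = 2.0 * cm - 4.0 * c0 + 2.0 * cp
    if denom == 0:
        return 0.0
    return float((cm - cp) / denom)


def subpixel_peak(corr: np.ndarray, method: str = "gaussian3") -> Tuple[float, float]:
    """Sub-pixel (dx, dy) offset of the correlation maximum.

    Fits a three-point Gaussian through the peak and its two neighbors
    along each axis; falls back to a parabolic fit when a neighbor is
    non-positive (the Gaussian fit needs positive samples).  The
    returned offsets are relative to the integer peak and bounded by
    one pixel per axis.

    Raises
    ------
    ValueError
        If the integer peak lies on the border of the plane, where a
        three-point fit is impossible.
    """
    corr = np.asarray(corr, dtype=float)
    iy, ix = np.unravel_index(np.argmax(corr), corr.shape)
    if iy == 0 or ix == 0 or iy == corr.shape[0] - 1 or ix == corr.shape[1] - 1:
        raise ValueError("correlation peak on the plane border; cannot refine")
    dx = _axis_offset(corr[iy, ix - 1], corr[iy, ix], corr[iy, ix + 1], method)
    dy = _axis_offset(corr[iy - 1, ix], corr[iy, ix], corr[iy + 1, ix], method)
    return float(np.clip(dx, -1.0, 1.0)), float(np.clip(dy, -1.0, 1.0))


def _neighbor_stack(a: np.ndarray) -> np.ndarray:
    """Stack of the 8 neighbors of every node, NaN-padded at edges: (8, r, c)."""
    p = np.pad(a, 1, constant_values=np.nan)
    views = []
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == 0 and dc == 0:
                continue
            views.append(p[1 + dr : p.shape[0] - 1 + dr, 1 + dc : p.shape[1] - 1 + dc])
    return np.stack(views)


def validate_vectors(field: VelocityField, threshold: float = 2.0,
                     eps: float = 0.1) -> VelocityField:
    """Normalized median test on the 8-neighborhood (single pass).

    For each unmasked node the median vector of its valid, unmasked
    neighbors is computed; the node's residual, normalized by the median
    neighbor residual plus the noise floor ``eps``, flags an outlier
    when it exceeds ``threshold``.  Outliers are replaced by the
    neighbor median and flagged invalid.  Nodes with fewer than three
    usable neighbors are left unchanged; masked nodes are never
    examined and never contribute to medians.

    ``eps`` is expressed in the field's velocity units; callers working
    in pixel units (as the multipass loop does) pass it in pixels.
    """
    if field.shape[0] < 3 or field.shape[1] < 3:
        raise ValueError("validation needs at least a 3x3 field")
    out = field.copy()
    usable = field.mask & field.valid
    u = np.where(usable, field.u, np.nan)
    v = np.where(usable, field.v, np.nan)
    nu, nv = _neighbor_stack(u), _neighbor_stack(v)
    n_ok = np.sum(np.isfinite(nu), axis=0)
    import warnings

    with np.errstate(all="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mu = np.nanmedian(nu, axis=0)
        mv = np.nanmedian(nv, axis=0)
        res = np.hypot(nu - mu, nv - mv)
        rmed = np.nanmedian(res, axis=0)
        norm = np.hypot(field.u - mu, field.v - mv) / (rmed + eps)
    candidate = field.mask & (n_ok >= 3) & np.isfinite(norm)
    outlier = candidate & (norm > threshold)
    out.u[outlier] = mu[outlier]
    out.v[outlier] = mv[outlier]
    out.valid = out.valid & ~outlier
    # nodes that were already invalid but have enough valid neighbors get
    # the median as a usable fill while keeping their invalid flag
    fill = field.mask & ~field.valid & (n_ok >= 3)
    out.u[fill] = mu[fill]
    out.v[fill] = mv[fill]
    return out


def _node_starts(extent: int, window: int, step: int) -> np.ndarray:
    n = (extent - window) // step + 1
    return np.arange(n) * step


def _extract_windows(img: np.ndarray, r0: np.ndarray, c0: np.ndarray,
                     window: int) -> np.ndarray:
    """Gather (n, window, window) blocks starting at (r0[i], c0[i])."""
    rr = r0[:, None, None] + np.arange(window)[None, :, None]
    cc = c0[:, None, None] + np.arange(window)[None, None, :]
    return img[rr, cc]


def _correlate(win_a: np.ndarray, win_b: np.ndarray) -> np.ndarray:
    """Batched linear cross-correlation planes, zero lag at the centre.

    C(dy, dx) = sum_x a(x) * b(x + d): the peak sits at the displacement
    of B relative to A.  Windows are mean-subtracted and zero-padded to
    2x their size, which makes the circular FFT correlation linear.
    """
    w = win_a.shape[-1]
    n = 2 * w
    a = win_a - win_a.mean(axis=(-2, -1), keepdims=True)
    b = win_b - win_b.mean(axis=(-2, -1), keepdims=True)
    fa = np.fft.rfft2(a, s=(n, n))
    fb = np.fft.rfft2(b, s=(n, n))
    corr = np.fft.irfft2(np.conj(fa) * fb, s=(n, n))
    return np.fft.fftshift(corr, axes=(-2, -1))  # zero lag at (n//2, n//2)


def multipass_piv(pair: ParticleImagePair, config: PIVConfig = PIVConfig()
                  ) -> VelocityField:
    """Estimate the velocity field of an image pair by multi-pass PIV.

    Returns a :class:`VelocityField` on the final-pass node grid with
    velocities in m/s; nodes whose windows carried no texture or whose
    vectors failed the normalized median test are flagged invalid (and
    filled with the neighborhood median where possible).
    """
    a = pair.frame_a
    b = pair.frame_b
    if a.shape != b.shape:
        raise ValueError("frames must share a shape")
    h, w_img = a.shape
    if min(config.pass_windows) < 8:
        raise ConfigurationError("final window must be at least 8 px")

    prev: VelocityField | None = None  # displacement field in px
    prev_centers: Tuple[np.ndarray, np.ndarray] | None = None

    for win in config.pass_windows:
        step = max(1, int(round(win * (1.0 - config.overlap_fraction))))
        r0 = _node_starts(h, win, step)
        c0 = _node_starts(w_img, win, step)
        if r0.size == 0 or c0.size == 0:
            raise ValueError(f"image smaller than the {win} px window")
        rc = r0 + (win - 1) / 2.0  # node centres in image coords
        cc = c0 + (win - 1) / 2.0
        n_r, n_c = r0.size, c0.size

        # predictor: previous-pass displacement interpolated to this grid
        if prev is None:
            pred_dx = np.zeros((n_r, n_c))
            pred_dy = np.zeros((n_r, n_c))
        else:
            pr, pc = prev_centers
            pred_dx = _interp_grid(prev.u, pr, pc, rc, cc)
            pred_dy = _interp_grid(prev.v, pr, pc, rc, cc)
        shift_dx = np.rint(pred_dx).astype(int)
        shift_dy = np.rint(pred_dy).astype(int)

        # clamp the shifted B window into the image
        r0g, c0g = np.meshgrid(r0, c0, indexing="ij")
        br = np.clip(r0g + shift_dy, 0, h - win)
        bc = np.clip(c0g + shift_dx, 0, w_img - win)
        applied_dy = br - r0g
        applied_dx = bc - c0g

        win_a = _extract_windows(a, r0g.ravel(), c0g.ravel(), win)
        win_b = _extract_windows(b, br.ravel(), bc.ravel(), win)
        textured = (win_a.std(axis=(-2, -1)) > 0) & (win_b.std(axis=(-2, -1)) > 0)

        corr = _correlate(win_a, win_b)
        centre = win  # zero-lag index after fftshift of a 2*win plane
        search = win // 2  # residual search radius
        sub = corr[:, centre - search : centre + search + 1,
                   centre - search : centre + search + 1]

        flat = sub.reshape(sub.shape[0], -1)
        idx = np.argmax(flat, axis=1)
        py, px = np.unravel_index(idx, sub.shape[1:])
        dx = np.zeros(sub.shape[0])
        dy = np.zeros(sub.shape[0])
        good = textured.copy()
        for i in range(sub.shape[0]):
            if not textured[i]:
                continue
            iy, ix = int(py[i]), int(px[i])
            if iy == 0 or ix == 0 or iy == sub.shape[1] - 1 or ix == sub.shape[2] - 1:
                good[i] = False  # peak at edge of search region: unreliable
                continue
            sx, sy = _fit_subpixel(sub[i], iy, ix, config.subpixel)
            dx[i] = ix - search + sx
            dy[i] = iy - search + sy

        disp_x = applied_dx + dx.reshape(n_r, n_c)
        disp_y = applied_dy + dy.reshape(n_r, n_c)
        valid = good.reshape(n_r, n_c)
        # untextured/edge nodes keep the predictor value
        disp_x = np.where(valid, disp_x, pred_dx)
        disp_y = np.where(valid, disp_y, pred_dy)

        field_px = VelocityField(u=disp_x, v=disp_y,
                                 x=cc.astype(float), y=rc.astype(float),
                                 spacing=float(step), valid=valid)
        field_px = validate_vectors(field_px, config.validation_threshold,
                                    config.validation_eps)
        prev = field_px
        prev_centers = (rc, cc)

    # convert final pass from pixel displacements to physical velocities
    win = config.pass_windows[-1]
    step = max(1, int(round(win * (1.0 - config.overlap_fraction))))
    mag, dt = config.magnification, config.frame_interval
    u = prev.u * mag / dt
    v = -prev.v * mag / dt  # image rows increase downward, physical y up
    x = prev.x * mag
    y = (h - 1 - prev.y) * mag  # descending with row index
    return VelocityField(u=u, v=v, x=x, y=y, spacing=step * mag,
                         valid=prev.valid.copy())


def _fit_subpixel(plane: np.ndarray, iy: int, ix: int, method: str
                  ) -> Tuple[float, float]:
    sx = _axis_offset(plane[iy, ix - 1], plane[iy, ix], plane[iy, ix + 1], method)
    sy = _axis_offset(plane[iy - 1, ix], plane[iy, ix], plane[iy + 1, ix], method)
    return float(np.clip(sx, -1, 1)), float(np.clip(sy, -1, 1))


def _interp_grid(values: np.ndarray, rows: np.ndarray, cols: np.ndarray,
                 rq: np.ndarray, cq: np.ndarray) -> np.ndarray:
    """Bilinear interpolation of a coarse node grid onto a finer one."""
    from scipy.interpolate import RegularGridInterpolator

    itp = RegularGridInterpolator((rows, cols), values, method="linear",
                                  bounds_error=False, fill_value=None)
    rr, cc = np.meshgrid(np.clip(rq, rows[0], rows[-1]),
                         np.clip(cq, cols[0], cols[-1]), indexing="ij")
    return itp(np.stack([rr, cc], axis=-1))
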
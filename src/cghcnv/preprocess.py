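"""Two-channel preprocessing: LOESS spatial correction, q-spline
normalization, and conversion to ordered per-chromosome log2-ratio tracks.

The pipeline order is spatial correction -> q-spline normalization -> log2
ratios.  Both corrections act per channel on log2 intensities and neither
reorders, adds, nor drops probes.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator, RegularGridInterpolator

TRACK_COLUMNS = ["chrom", "probe_id", "start", "end", "midpoint", "log2_ratio"]


def _loess_surface(u: np.ndarray, v: np.ndarray, y: np.ndarray,
                   span: float, grid_size: int) -> np.ndarray:
    """Locally weighted linear (degree-1, tricube) surface of ``y`` over
    ``(u, v)`` in [0,1]^2, fitted at a ``grid_size x grid_size`` anchor grid
    and bilinearly interpolated back to the probes.

    The bandwidth at each anchor is the distance enclosing a ``span``
    fraction of the probes, so the effective neighborhood adapts to local
    density.  Anchoring on a coarse grid keeps the fit O(grid^2 * n) while
    being exact for planar surfaces (a local linear fit reproduces a plane
    at every anchor, and bilinear interpolation of a plane is that plane).
    """
    gu = np.linspace(0.0, 1.0, grid_size)
    fitted = np.empty((grid_size, grid_size))
    for i, ua in enumerate(gu):
        du = u - ua
        for j, va in enumerate(gu):
            dv = v - va
            d2 = du * du + dv * dv
            h2 = np.quantile(d2, span)
            if h2 == 0.0:
                fitted[i, j] = y[d2 == 0].mean()
                continue
            w = 1.0 - (d2 / h2) ** 1.5
            np.clip(w, 0.0, None, out=w)
            w **= 3
            sel = w > 0
            if sel.sum() < 3:
                raise ValueError(
                    "too few probes within the local neighborhood; increase span")
            sw = np.sqrt(w[sel])
            X = np.column_stack([np.ones(sel.sum()), du[sel], dv[sel]])
            beta, _, rank, _ = np.linalg.lstsq(X * sw[:, None], y[sel] * sw,
                                               rcond=None)
            fitted[i, j] = beta[0]
    interp = RegularGridInterpolator((gu, gu), fitted, method="linear")
    return interp(np.column_stack([u, v]))


def spatial_correct(intensities: pd.DataFrame, span: float = 0.3,
                    grid_size: int = 12) -> pd.DataFrame:
    """Remove smooth array-position artifacts from each channel.

    For each channel a LOESS surface of log2 intensity over the (row, col)
    grid (rescaled to the unit square) is fitted; the surface minus its own
    grand mean is subtracted, so each channel's grand mean log2 intensity is
    preserved and intensities stay positive.
    """
    if not 0 < span <= 1:
        raise ValueError("span must be in (0, 1]")
    n = len(intensities)
    if n < 50:
        raise ValueError("need at least 50 probes for spatial correction")
    u = _rescale(intensities["row"].to_numpy(dtype=float))
    v = _rescale(intensities["col"].to_numpy(dtype=float))
    out = intensities.copy()
    for ch in ("test_intensity", "ref_intensity"):
        y = np.log2(intensities[ch].to_numpy(dtype=float))
        surf = _loess_surface(u, v, y, span, grid_size)
        out[ch] = np.exp2(y - (surf - surf.mean()))
    return out


def _rescale(x: np.ndarray) -> np.ndarray:
    span = x.max() - x.min()
    if span == 0:
        return np.full_like(x, 0.5)
    return (x - x.min()) / span


def qspline_normalize(intensities: pd.DataFrame, n_anchors: int = 100,
                      p_lo: float = 0.005, p_hi: float = 0.995) -> pd.DataFrame:
    """Quantile-spline normalization of the two channels.

    Anchor quantiles of each channel's log2 intensities are computed at
    ``n_anchors`` evenly spaced probabilities; the per-probability target is
    the mean of the two channels' log2 quantiles (the log of their geometric
    mean), treating the channels symmetrically.  Each channel is mapped
    through a monotone cubic (PCHIP) spline through its (quantile, target)
    anchors, with linear extrapolation beyond the anchor range.  This removes
    monotone intensity-dependent dye bias; afterwards the two channels'
    anchor quantiles agree.

    Degenerate input (a near-constant channel yields too few distinct
    anchors) falls back to median scaling with a warning.
    """
    if n_anchors < 5:
        raise ValueError("n_anchors must be >= 5")
    lt = np.log2(intensities["test_intensity"].to_numpy(dtype=float))
    lr = np.log2(intensities["ref_intensity"].to_numpy(dtype=float))
    if not (np.all(np.isfinite(lt)) and np.all(np.isfinite(lr))):
        raise ValueError("intensities must be positive and finite")
    p = np.linspace(p_lo, p_hi, n_anchors)
    qt = np.quantile(lt, p)
    qr = np.quantile(lr, p)
    target = 0.5 * (qt + qr)
    out = intensities.copy()
    try:
        new_t = _monotone_map(lt, qt, target)
        new_r = _monotone_map(lr, qr, target)
    except _DegenerateAnchors:
        warnings.warn("degenerate channel quantiles; falling back to median scaling")
        med_target = 0.5 * (np.median(lt) + np.median(lr))
        new_t = lt - np.median(lt) + med_target
        new_r = lr - np.median(lr) + med_target
    out["test_intensity"] = np.exp2(new_t)
    out["ref_intensity"] = np.exp2(new_r)
    return out


class _DegenerateAnchors(Exception):
    pass


def _monotone_map(x: np.ndarray, anchors_x: np.ndarray,
                  anchors_y: np.ndarray) -> np.ndarray:
    """Evaluate a monotone PCHIP spline through (anchors_x, anchors_y) at x,
    averaging targets over duplicate anchor abscissae and extending linearly
    with the endpoint derivatives outside the anchor range."""
    ux, inverse = np.unique(anchors_x, return_inverse=True)
    if len(ux) < 5:
        raise _DegenerateAnchors
    uy = np.zeros(len(ux))
    counts = np.zeros(len(ux))
    np.add.at(uy, inverse, anchors_y)
    np.add.at(counts, inverse, 1.0)
    uy /= counts
    if np.any(np.diff(uy) < 0):
        raise _DegenerateAnchors
    spline = PchipInterpolator(ux, uy, extrapolate=False)
    deriv = spline.derivative()
    y = spline(x)
    lo = x < ux[0]
    hi = x > ux[-1]
    y[lo] = uy[0] + float(deriv(ux[0])) * (x[lo] - ux[0])
    y[hi] = uy[-1] + float(deriv(ux[-1])) * (x[hi] - ux[-1])
    return y


def to_log2_track(intensities: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    """Per-probe log2(test/ref) grouped per chromosome, ordered by probe
    midpoint (``floor((start+end)/2)``, 1-based).

    Returns a DataFrame with columns ``chrom, probe_id, start, end, midpoint,
    log2_ratio``; chromosomes keep their design order.
    """
    if len(intensities) != len(design):
        raise ValueError("intensities and design have different lengths")
    if not (intensities["probe_id"].to_numpy() == design["probe_id"].to_numpy()).all():
        raise ValueError("intensities are not aligned to the design probe order")
    ratio = np.log2(intensities["test_intensity"].to_numpy(dtype=float)
                    / intensities["ref_intensity"].to_numpy(dtype=float))
    if not np.all(np.isfinite(ratio)):
        raise ValueError("non-finite log2 ratios")
    track = pd.DataFrame({
        "chrom": design["chrom"].to_numpy(),
        "probe_id": design["probe_id"].to_numpy(),
        "start": design["start"].to_numpy(),
        "end": design["end"].to_numpy(),
        "midpoint": (design["start"].to_numpy() + design["end"].to_numpy()) // 2,
        "log2_ratio": ratio,
    })
    order = {c: i for i, c in enumerate(dict.fromkeys(design["chrom"]))}
    track = track.sort_values(
        ["chrom", "midpoint"],
        key=lambda s: s.map(order) if s.name == "chrom" else s,
        kind="stable")
    return track.reset_index(drop=True)
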
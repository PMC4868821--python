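"""Principal-curve pseudo-time.

A smooth one-dimensional curve is fitted through the 2-D embedding by
iterative projection–smoothing (Hastie–Stuetzle): alternate between
scatterplot-smoothing each coordinate against the current arc-length
parameter and re-projecting every cell orthogonally onto the resulting
polyline.  Each cell's pseudo-time is the arc length of its projection.

The curve's orientation is chosen so pseudo-time increases with the mean
embryonic-day label, and the scale is anchored so that a day maps to
2.5 × day units; on that scale 12.5 marks the E5 boundary used as the
default pre-lineage gate.  Two calibrations are available: ``monotone``
(default) interpolates piecewise-linearly between per-day median embryo
arc lengths, anchoring the day-d cohort median at 2.5 × (d + 0.5) — the
expected developmental age of embryos sampled during day d; ``linear``
regresses the median embryo arc length onto day and applies a single
affine map.  The monotone map is preferred because arc length along the
curve is not uniform in developmental time (late stages traverse longer
transcriptional distances), and a single affine map then misplaces whole
day cohorts relative to the gate.  The unit choice is a reconstruction:
thresholds quoted on this scale (e.g. 12.5) carry the operational meaning
"embryos younger than mid-E5".
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.nonparametric.smoothers_lowess import lowess

DAY_SCALE = 2.5  # pseudo-time units per embryonic day after rescaling


@dataclasses.dataclass
class PseudotimeAssignment:
    """Arc-length pseudo-time per cell, its embryo means and the curve."""
    cell_lambda: pd.Series
    embryo_lambda: pd.Series
    curve: np.ndarray        # ordered list of 2-D points


def _project_polyline(points: np.ndarray, curve: np.ndarray):
    """Orthogonal projection of points onto a polyline.

    Returns (arc length of the projection, squared distance) per point.
    """
    a = curve[:-1]                       # (m, 2)
    d = curve[1:] - a                    # segment vectors
    seg_len = np.linalg.norm(d, axis=1)
    keep = seg_len > 0
    a, d, seg_len = a[keep], d[keep], seg_len[keep]
    if len(a) == 0:
        raise ValueError("degenerate curve: all points coincide")
    s0 = np.concatenate([[0.0], np.cumsum(seg_len)])[:-1]
    # t: (n, m) fractional position of each point on each segment
    diff = points[:, None, :] - a[None, :, :]
    t = np.clip((diff * d[None, :, :]).sum(-1) / (seg_len ** 2)[None, :],
                0.0, 1.0)
    proj = a[None, :, :] + t[..., None] * d[None, :, :]
    dist2 = ((points[:, None, :] - proj) ** 2).sum(-1)
    best = np.argmin(dist2, axis=1)
    idx = np.arange(len(points))
    lam = s0[best] + t[idx, best] * seg_len[best]
    return lam, dist2[idx, best]


def principal_curve(points: np.ndarray, max_iter: int = 50,
                    tol: float = 1e-4, frac: float = 0.3):
    """Hastie–Stuetzle principal curve in 2-D.

    Initialised on the first principal component; lowess smoothing with
    span ``frac``; converged when the mean projection displacement falls
    below ``tol`` times the coordinate range.

    Returns ``(lambda, curve)`` with ``lambda`` the per-point arc length.
    """
    points = np.asarray(points, float)
    if np.allclose(points, points[0]):
        raise ValueError("degenerate input: all points coincide")
    centered = points - points.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    lam = centered @ vt[0]
    scale = np.ptp(points, axis=0).max()
    curve = None
    prev_d2 = np.inf
    for _ in range(max_iter):
        order = np.argsort(lam, kind="stable")
        lo = lam[order]
        sm = np.column_stack([
            lowess(points[order, j], lo, frac=frac, it=0,
                   return_sorted=False)
            for j in range(points.shape[1])])
        lam_new, d2 = _project_polyline(points, sm)
        mean_d2 = float(d2.mean())
        # stop once the squared projection distance stops improving
        # meaningfully: further iterations only let the curve fold into
        # off-axis substructure without fitting the data better
        if mean_d2 > prev_d2 * (1.0 - 0.05):
            if curve is None:
                curve, lam = sm, lam_new
            break
        shift = np.mean(np.abs(lam_new - lam_new.mean()
                               - (lam - lam.mean())))
        curve, lam, prev_d2 = sm, lam_new, mean_d2
        if shift < tol * scale:
            break
    return lam, curve


def assign_pseudotime(coords: pd.DataFrame, day_labels: pd.Series,
                      embryo_ids: pd.Series,
                      exclude_mask: pd.Series | None = None,
                      max_iter: int = 50, frac: float = 0.3,
                      rescale: str = "monotone",
                      day_offset: float = 0.5) -> PseudotimeAssignment:
    """Fit the principal curve and assign every cell an arc-length time.

    Cells flagged in ``exclude_mask`` (e.g. ICM cells, to keep the curve a
    time axis) are left out of the fit but still projected onto it.
    Orientation follows the day labels; the scale is 2.5 units per day
    with calibration per ``rescale`` ∈ {"monotone", "linear", "none"}.
    """
    pts = coords.to_numpy(float)
    days = day_labels.reindex(coords.index).to_numpy(float)
    fit_mask = np.ones(len(pts), bool)
    if exclude_mask is not None:
        fit_mask = ~exclude_mask.reindex(coords.index).to_numpy(bool)
        if fit_mask.sum() < 5:
            raise ValueError("too few cells left to fit the curve")
    _, curve = principal_curve(pts[fit_mask], max_iter=max_iter, frac=frac)
    lam, _ = _project_polyline(pts, curve)

    # orient so pseudo-time increases with embryonic day
    rho = scipy.stats.spearmanr(lam, days).statistic
    if np.isnan(rho):
        rho = 0.0
    if rho < 0:
        lam = lam.max() - lam

    cell_lambda = pd.Series(lam, index=coords.index, name="pseudotime")
    embryos = embryo_ids.reindex(coords.index)
    med = cell_lambda.groupby(embryos).median()
    embryo_day = day_labels.groupby(embryos).first()
    cell_lambda = _rescale_lambda(cell_lambda, med, embryo_day, rescale,
                                  day_offset)
    embryo_lambda = cell_lambda.groupby(embryos).mean()
    embryo_lambda.name = "embryo_pseudotime"
    return PseudotimeAssignment(cell_lambda=cell_lambda,
                                embryo_lambda=embryo_lambda, curve=curve)


def _rescale_lambda(cell_lambda: pd.Series, embryo_median: pd.Series,
                    embryo_day: pd.Series, rescale: str,
                    day_offset: float) -> pd.Series:
    if rescale == "none":
        return cell_lambda
    day_median = embryo_median.groupby(embryo_day).median()
    if rescale == "monotone" and len(day_median) >= 2:
        anchors = np.maximum.accumulate(day_median.to_numpy(float))
        targets = DAY_SCALE * (day_median.index.to_numpy(float)
                               + day_offset)
        lam = cell_lambda.to_numpy(float)
        span = max(anchors[-1] - anchors[0], 1e-12)
        # global units-per-arc-length for extrapolation and for day
        # cohorts whose medians collapse onto each other
        global_slope = (targets[-1] - targets[0]) / span
        eps = 1e-6 * span
        keep = np.concatenate([[True], np.diff(anchors) > eps])
        anchors, targets = anchors[keep], targets[keep]
        out = np.interp(lam, anchors, targets)
        below = lam < anchors[0]
        above = lam > anchors[-1]
        out[below] = targets[0] + global_slope * (lam[below] - anchors[0])
        out[above] = targets[-1] + global_slope * (lam[above] - anchors[-1])
        return pd.Series(out, index=cell_lambda.index, name="pseudotime")
    if len(embryo_median) >= 2 and embryo_median.to_numpy().std() > 0:
        slope, intercept, *_ = scipy.stats.linregress(
            embryo_median.to_numpy(), embryo_day.to_numpy(float))
        return DAY_SCALE * (intercept + slope * cell_lambda)
    return cell_lambda
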
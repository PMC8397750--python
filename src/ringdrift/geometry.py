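"""Variance of manifold points along vs perpendicular to the coding direction.

The fitted ring curve defines, at each movie-time bin, a local coding
direction: the unit tangent of the curve at the point nearest the bin's
centroid.  Variance of that bin's points along the tangent ("parallel",
affecting the decoded time) is compared with the variance in the orthogonal
complement ("perpendicular", harmless to decoding).  Three groupings are
supported: all trials pooled, week-averaged points (week-to-week drift), and
single-trial points within each week (within-week noise).  Manifold shape is
summarized by the radius of every point from the cloud center.  One-sided
Wilcoxon / Mann-Whitney comparisons are delegated to scipy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ringdrift.spud import RingCurve, project_to_curve

logger = logging.getLogger(__name__)


def _decompose(points: np.ndarray, tangent: np.ndarray) -> tuple[float, float]:
    """Unbiased variance of points along the tangent and in its complement."""
    n = points.shape[0]
    centered = points - points.mean(axis=0)
    along = centered @ tangent
    par = float((along**2).sum() / (n - 1))
    total = float((centered**2).sum() / (n - 1))
    return par, max(total - par, 0.0)


def _bin_tangent(centroid: np.ndarray, curve: RingCurve) -> np.ndarray:
    assign = project_to_curve(centroid[None, :], curve)
    return assign.tangent[0]


def variance_decomposition(
    points: np.ndarray,
    time_bin: np.ndarray,
    curve: RingCurve,
    week: np.ndarray | None = None,
    mode: str = "all-trials",
    tangent_mode: str = "bin-centroid",
) -> pd.DataFrame:
    """Per-time-bin parallel/perpendicular variance of manifold points.

    ``mode``:

    - ``"all-trials"`` — one row per time bin, variance across all points of
      that bin;
    - ``"week-averaged"`` — points are first averaged within each week, then
      the variance across week-means is decomposed (week-to-week drift);
    - ``"within-week"`` — variance across single-trial points of each week
      separately, rows pooled over weeks.

    For each bin the tangent is taken at the curve point nearest the bin
    centroid (``tangent_mode="bin-centroid"``, one coding direction per bin,
    matching one arrow pair per movie time); ``tangent_mode="per-point"``
    instead uses each point's own projection tangent, as a sensitivity
    variant — the two agree when a bin's points project to nearby curve
    locations and diverge on collapsed manifolds.  The perpendicular
    variance is the total variance of the residual after removing the
    tangent component (in 2-D: the normal direction).  Bins (or bin-week
    cells) with fewer than 2 points are skipped with a log message.
    """
    points = np.asarray(points, dtype=float)
    time_bin = np.asarray(time_bin)
    if mode not in ("all-trials", "week-averaged", "within-week"):
        raise ValueError(f"unknown mode {mode!r}")
    if tangent_mode not in ("bin-centroid", "per-point"):
        raise ValueError(f"unknown tangent_mode {tangent_mode!r}")
    if mode != "all-trials":
        if week is None:
            raise ValueError(f"mode {mode!r} needs week labels")
        week = np.asarray(week)
        if np.unique(week).size < 2 and mode == "week-averaged":
            raise ValueError("week-averaged variance needs at least two weeks")

    rows = []
    n_skipped = 0
    for t in np.unique(time_bin):
        sel = time_bin == t
        pts = points[sel]
        if mode == "all-trials":
            groups = [(None, pts)]
        elif mode == "week-averaged":
            means = [
                pts[week[sel] == w].mean(axis=0) for w in np.unique(week[sel])
            ]
            groups = [(None, np.asarray(means))]
        else:  # within-week
            groups = [
                (int(w), pts[week[sel] == w]) for w in np.unique(week[sel])
            ]
        for w, grp in groups:
            if grp.shape[0] < 2:
                n_skipped += 1
                continue
            if tangent_mode == "bin-centroid":
                tangent = _bin_tangent(grp.mean(axis=0), curve)
                par, perp = _decompose(grp, tangent)
            else:
                assign = project_to_curve(grp, curve)
                centered = grp - grp.mean(axis=0)
                along = np.einsum("ij,ij->i", centered, assign.tangent)
                n = grp.shape[0]
                par = float((along**2).sum() / (n - 1))
                total = float((centered**2).sum() / (n - 1))
                perp = max(total - par, 0.0)
            row = {"time_bin": int(t), "parallel": par, "perpendicular": perp}
            if w is not None:
                row["week"] = w
            rows.append(row)
    if n_skipped:
        logger.info("variance_decomposition(%s): skipped %d cells with <2 points",
                    mode, n_skipped)
    df = pd.DataFrame(rows)
    df.attrs["mode"] = mode
    return df


def week_averaged_variance(
    points: np.ndarray, time_bin: np.ndarray, week: np.ndarray, curve: RingCurve
) -> pd.DataFrame:
    """Variance of per-week trial-averaged points across weeks, per time bin."""
    return variance_decomposition(points, time_bin, curve, week=week,
                                  mode="week-averaged")


def within_week_variance(
    points: np.ndarray, time_bin: np.ndarray, week: np.ndarray, curve: RingCurve
) -> pd.DataFrame:
    """Single-trial variance within each week, rows pooled over weeks."""
    return variance_decomposition(points, time_bin, curve, week=week,
                                  mode="within-week")


@dataclass
class RadiusTable:
    """Distance of each manifold point to the cloud center."""

    radius: np.ndarray
    center: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"radius": self.radius})


def manifold_radius(points: np.ndarray) -> RadiusTable:
    """Euclidean distance of every point to the coordinate-wise mean."""
    points = np.asarray(points, dtype=float)
    if points.shape[0] < 1:
        raise ValueError("need at least one point")
    center = points.mean(axis=0)
    return RadiusTable(
        radius=np.linalg.norm(points - center, axis=1), center=center
    )


def paired_onesided_test(
    a: np.ndarray,
    b: np.ndarray,
    kind: str = "wilcoxon-signed-rank",
    alternative: str = "less",
) -> dict[str, float | str | int]:
    """One-sided comparison of two samples via a standard statistics routine.

    ``kind``: ``"wilcoxon-signed-rank"`` (paired) or ``"mann-whitney"``
    (independent).  ``alternative="less"`` tests whether ``a`` is
    stochastically smaller than ``b``.  All-tied paired samples raise (the
    statistic is undefined).  Returns a JSON-ready record with the statistic,
    p-value, direction and sample sizes.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if kind == "wilcoxon-signed-rank":
        if a.shape != b.shape:
            raise ValueError("paired test needs equal-length samples")
        if np.all(a == b):
            raise ValueError("all-tied samples: signed-rank statistic undefined")
        res = stats.wilcoxon(a, b, alternative=alternative)
    elif kind == "mann-whitney":
        res = stats.mannwhitneyu(a, b, alternative=alternative)
    else:
        raise ValueError(f"unknown test kind {kind!r}")
    return {
        "test": kind,
        "alternative": alternative,
        "statistic": float(res.statistic),
        "p": float(res.pvalue),
        "n_a": int(a.size),
        "n_b": int(b.size),
    }
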
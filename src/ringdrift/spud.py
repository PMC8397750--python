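"""Spline parameterization for unsupervised decoding (SPUD) on a ring manifold.

A closed piecewise-linear curve with a small number of knots is fit to the
embedded point cloud: knots start at K-means centroids (or at trial-averaged
points spread evenly over movie time, for degenerate manifolds), are joined
into a ring by a density-guided Hamiltonian cycle, and are then optimized by
coordinate descent on the objective

    (sum_i distance(x_i, curve)) * |curve length|

which trades point fit against curve length.  Each point is assigned the
arc-length coordinate y in [0, 1) of its nearest point on the curve; the only
supervised step is a final circular shift / flip of the coordinates chosen on
the training set to best match movie time.  Decoded time is the aligned
coordinate scaled to the trial period, and decoding error is the absolute
circular difference between decoded and actual time (chance mean: period/4).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from ringdrift._utils import circular_diff

logger = logging.getLogger(__name__)


@dataclass
class RingCurve:
    """Closed piecewise-linear curve: ordered knots, last connecting to first."""

    knots: np.ndarray  # (n_knots, d)

    def __post_init__(self) -> None:
        self.knots = np.asarray(self.knots, dtype=float)
        if self.knots.ndim != 2 or self.knots.shape[0] < 3:
            raise ValueError("a ring needs at least 3 knots")
        if self.total_length <= 0:
            raise ValueError("curve must have positive length")

    @property
    def n_knots(self) -> int:
        return self.knots.shape[0]

    @property
    def segments(self) -> tuple[np.ndarray, np.ndarray]:
        """(start points, vectors) of the n_knots closing segments."""
        a = self.knots
        b = np.roll(self.knots, -1, axis=0)
        return a, b - a

    @property
    def segment_lengths(self) -> np.ndarray:
        _, vec = self.segments
        return np.linalg.norm(vec, axis=1)

    @property
    def total_length(self) -> float:
        return float(self.segment_lengths.sum())

    def to_frame(self) -> pd.DataFrame:
        cols = {f"dim{j}": self.knots[:, j] for j in range(self.knots.shape[1])}
        return pd.DataFrame({"knot": np.arange(self.n_knots), **cols})


@dataclass
class CoordinateAssignment:
    """Arc-length coordinates and projection geometry of a point set."""

    y: np.ndarray        # (P,) in [0, 1)
    foot: np.ndarray     # (P, d) nearest point on the curve
    tangent: np.ndarray  # (P, d) unit tangent of the nearest segment
    offset: np.ndarray   # (P,) perpendicular offset (signed in 2-D)
    segment: np.ndarray  # (P,) index of the nearest segment


@dataclass
class Alignment:
    shift: float
    flip: bool
    objective: float


@dataclass
class DecodingResult:
    """Decoded time per point with circular errors (seconds)."""

    decoded_time: np.ndarray
    true_time: np.ndarray
    error: np.ndarray
    period: float
    alignment: Alignment


def split_train_test(
    n_points: int, train_frac: float = 0.8, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Seeded uniform partition of point indices (all weeks pooled)."""
    if not 0 < train_frac < 1:
        raise ValueError("train_frac must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_points)
    n_train = int(round(train_frac * n_points))
    if n_train == 0 or n_train == n_points:
        raise ValueError("degenerate split sizes")
    return np.sort(perm[:n_train]), np.sort(perm[n_train:])


def init_knots(points: np.ndarray, n_knots: int = 10, seed: int = 0) -> np.ndarray:
    """Initial knots at K-means centroids (10 restarts, best inertia)."""
    points = np.asarray(points, dtype=float)
    if points.shape[0] < n_knots:
        raise ValueError("fewer points than knots")
    km = KMeans(n_clusters=n_knots, n_init=10, random_state=seed)
    km.fit(points)
    return km.cluster_centers_


def init_knots_time_averaged(
    points: np.ndarray, time_bin: np.ndarray, n_knots: int = 10
) -> np.ndarray:
    """Trial-averaged points at evenly spaced movie times, in time order.

    For manifolds without a clean ring (e.g. shuffled controls), K-means
    initialization can fail; averaging the cloud within evenly spaced
    time-bin windows gives ring-ordered knots by construction.
    """
    time_bin = np.asarray(time_bin)
    edges = np.quantile(time_bin, np.linspace(0, 1, n_knots + 1))
    knots = []
    for i in range(n_knots):
        lo, hi = edges[i], edges[i + 1]
        sel = (time_bin >= lo) & (
            (time_bin < hi) if i < n_knots - 1 else (time_bin <= hi)
        )
        if not np.any(sel):
            continue
        knots.append(points[sel].mean(axis=0))
    return np.asarray(knots)


def _point_segment_distance(
    points: np.ndarray, a: np.ndarray, vec: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Distances and clamped projection parameters of points onto one segment."""
    L2 = float(vec @ vec)
    if L2 == 0:
        t = np.zeros(points.shape[0])
    else:
        t = np.clip((points - a) @ vec / L2, 0.0, 1.0)
    diff = points - (a + t[:, None] * vec)
    return np.linalg.norm(diff, axis=1), t


def project_to_curve(points: np.ndarray, curve: RingCurve) -> CoordinateAssignment:
    """Nearest point on the curve for each data point (ties -> lower segment).

    ``y`` is the arc length from knot 0 to the foot, divided by the total
    length.  The perpendicular offset is signed by the cross-product in 2-D
    and unsigned in higher dimensions.
    """
    points = np.asarray(points, dtype=float)
    a, vec = curve.segments
    n_seg = curve.n_knots
    dists = np.empty((points.shape[0], n_seg))
    ts = np.empty((points.shape[0], n_seg))
    for j in range(n_seg):
        dists[:, j], ts[:, j] = _point_segment_distance(points, a[j], vec[j])
    seg = dists.argmin(axis=1)  # argmin takes the lowest index on ties
    rows = np.arange(points.shape[0])
    t_best = ts[rows, seg]
    foot = a[seg] + t_best[:, None] * vec[seg]
    seg_len = curve.segment_lengths
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    y = (cum[seg] + t_best * seg_len[seg]) / curve.total_length
    y = y % 1.0
    with np.errstate(invalid="ignore", divide="ignore"):
        tangent = vec[seg] / np.where(seg_len[seg] > 0, seg_len[seg], 1.0)[:, None]
    offset = dists[rows, seg]
    if points.shape[1] == 2:
        r = points - foot
        sign = np.sign(tangent[:, 0] * r[:, 1] - tangent[:, 1] * r[:, 0])
        offset = offset * np.where(sign == 0, 1.0, sign)
    return CoordinateAssignment(y=y, foot=foot, tangent=tangent, offset=offset,
                                segment=seg)


def curve_objective(points: np.ndarray, curve: RingCurve) -> float:
    """(sum of point-to-curve distances) x (total curve length)."""
    assign = project_to_curve(points, curve)
    return float(np.abs(assign.offset).sum() * curve.total_length)


def connect_knots(points: np.ndarray, knots: np.ndarray) -> RingCurve:
    """Order knots into a ring guided by data density between knot pairs.

    Each knot pair is scored by the data density *along* the connecting
    segment: the count of training points within a ball (radius = a quarter
    of the median nearest-knot spacing) around each of several interior
    sample points, taking the minimum over samples and dividing by segment
    length.  The minimum makes shortcut chords through empty interior score
    zero even when their endpoints sit in dense regions.  The ring is the
    greedy maximum-score Hamiltonian cycle: edges are added best-first while
    keeping every vertex at degree <= 2 and closing no premature cycle.  If
    the ball counts are empty everywhere, knots fall back to angular ordering
    around their centroid (using the first two dimensions).
    """
    points = np.asarray(points, dtype=float)
    knots = np.asarray(knots, dtype=float)
    n = knots.shape[0]
    if n < 3:
        raise ValueError("need at least 3 knots")
    # ball radius from nearest-knot spacing
    kd = np.linalg.norm(knots[:, None, :] - knots[None, :, :], axis=2)
    np.fill_diagonal(kd, np.inf)
    radius = 0.25 * float(np.median(kd.min(axis=1)))

    sample_t = np.linspace(1 / 6, 5 / 6, 5)
    score = np.full((n, n), -np.inf)
    any_count = False
    for i in range(n):
        for j in range(i + 1, n):
            vec = knots[j] - knots[i]
            length = np.linalg.norm(vec)
            if length == 0:
                continue
            counts = [
                int((np.linalg.norm(points - (knots[i] + t * vec), axis=1)
                     <= radius).sum())
                for t in sample_t
            ]
            count = min(counts)
            any_count = any_count or count > 0
            score[i, j] = score[j, i] = count / length

    if not any_count:
        logger.warning("connect_knots: empty tubes everywhere; angular fallback")
        return _angular_ring(knots)

    order = _greedy_cycle(score)
    if order is None:
        logger.warning("connect_knots: no valid greedy cycle; angular fallback")
        return _angular_ring(knots)
    return RingCurve(knots=knots[order])


def _angular_ring(knots: np.ndarray) -> RingCurve:
    center = knots.mean(axis=0)
    angles = np.arctan2(knots[:, 1] - center[1], knots[:, 0] - center[0])
    return RingCurve(knots=knots[np.argsort(angles)])


def _greedy_cycle(score: np.ndarray) -> np.ndarray | None:
    """Greedy maximum-score Hamiltonian cycle (union-find + degree caps)."""
    n = score.shape[0]
    pairs = [
        (score[i, j], i, j)
        for i in range(n)
        for j in range(i + 1, n)
        if np.isfinite(score[i, j])
    ]
    pairs.sort(key=lambda x: (-x[0], x[1], x[2]))
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    degree = [0] * n
    edges: list[tuple[int, int]] = []
    for s, i, j in pairs:
        if degree[i] >= 2 or degree[j] >= 2:
            continue
        ri, rj = find(i), find(j)
        if ri == rj and len(edges) < n - 1:
            continue  # premature cycle
        if ri == rj and len(edges) == n - 1:
            edges.append((i, j))
            break
        parent[ri] = rj
        degree[i] += 1
        degree[j] += 1
        edges.append((i, j))
    if len(edges) != n:
        # complete the cycle by joining the two remaining degree-1 vertices
        open_v = [v for v in range(n) if degree[v] < 2]
        if len(open_v) == 2 and len(edges) == n - 1:
            edges.append((open_v[0], open_v[1]))
        else:
            return None
    adj: dict[int, list[int]] = {v: [] for v in range(n)}
    for i, j in edges:
        adj[i].append(j)
        adj[j].append(i)
    order = [0]
    prev = -1
    while len(order) < n:
        nxt = [v for v in adj[order[-1]] if v != prev]
        if not nxt:
            return None
        prev = order[-1]
        order.append(nxt[0])
    return np.asarray(order)


def optimize_knots(
    points: np.ndarray,
    ring: RingCurve,
    n_iter: int = 50,
    step: float | None = None,
    tol: float = 1e-6,
) -> RingCurve:
    """Coordinate descent on (sum of distances) x (length).

    Each pass proposes +/- axis-aligned moves of every knot; improving moves
    are accepted (objective non-increasing by construction).  The step is
    halved whenever a full pass finds no improvement; iteration stops after
    ``n_iter`` passes, when the relative objective change falls below
    ``tol``, or when the step underflows.
    """
    points = np.asarray(points, dtype=float)
    knots = ring.knots.copy()
    d = knots.shape[1]
    if step is None:
        step = 0.1 * float(np.mean(RingCurve(knots).segment_lengths))
    best = curve_objective(points, RingCurve(knots))
    min_step = 1e-4 * step
    for _ in range(n_iter):
        improved = False
        start_obj = best
        for i in range(knots.shape[0]):
            for axis in range(d):
                for sign in (+1.0, -1.0):
                    trial = knots.copy()
                    trial[i, axis] += sign * step
                    obj = curve_objective(points, RingCurve(trial))
                    if obj < best:
                        knots, best = trial, obj
                        improved = True
        if not improved:
            step /= 2
            if step < min_step:
                break
        elif start_obj > 0 and (start_obj - best) / start_obj < tol:
            break
    return RingCurve(knots=knots)


def align_coordinates(
    y: np.ndarray,
    true_time_rescaled: np.ndarray,
    n_shift_grid: int = 350,
) -> Alignment:
    """Choose the circular shift and flip minimizing squared circular error.

    Grid search over ``n_shift_grid`` shifts x {flip, no flip}; the objective
    is the mean squared circular difference on the unit circle between the
    transformed coordinates and the rescaled actual time.
    """
    y = np.asarray(y, dtype=float)
    t = np.asarray(true_time_rescaled, dtype=float)
    if y.shape != t.shape:
        raise ValueError("coordinates and times must have equal length")
    shifts = np.arange(n_shift_grid) / n_shift_grid
    best = Alignment(shift=0.0, flip=False, objective=np.inf)
    for flip in (False, True):
        base = (1.0 - y) % 1.0 if flip else y
        for s in shifts:
            err = circular_diff((base + s) % 1.0, t)
            obj = float(np.mean(err**2))
            if obj < best.objective:
                best = Alignment(shift=float(s), flip=flip, objective=obj)
    return best


def apply_alignment(y: np.ndarray, alignment: Alignment) -> np.ndarray:
    base = (1.0 - np.asarray(y, dtype=float)) % 1.0 if alignment.flip else y
    return (base + alignment.shift) % 1.0


def decode_time(
    assignment: CoordinateAssignment,
    alignment: Alignment,
    true_time_s: np.ndarray,
    period: float = 35.0,
) -> DecodingResult:
    """Map aligned coordinates to seconds and score circular errors."""
    aligned = apply_alignment(assignment.y, alignment)
    decoded = aligned * period
    true_time_s = np.asarray(true_time_s, dtype=float)
    error = circular_diff(decoded, true_time_s, period=period)
    return DecodingResult(
        decoded_time=decoded,
        true_time=true_time_s,
        error=error,
        period=period,
        alignment=alignment,
    )


def decoding_error_summary(
    result: DecodingResult, week: np.ndarray | None = None
) -> pd.DataFrame:
    """Median and IQR of per-point circular errors, optionally per week."""
    if result.error.size == 0:
        raise ValueError("empty decoding result")

    def summarize(err: np.ndarray) -> dict[str, float]:
        q1, med, q3 = np.percentile(err, [25, 50, 75])
        return {
            "median_s": float(med),
            "q1_s": float(q1),
            "q3_s": float(q3),
            "mean_s": float(err.mean()),
            "n": int(err.size),
        }

    rows = [{"group": "all", **summarize(result.error)}]
    if week is not None:
        week = np.asarray(week)
        for w in np.unique(week):
            rows.append(
                {"group": f"week_{int(w)}", **summarize(result.error[week == w])}
            )
    return pd.DataFrame(rows)


@dataclass
class SpudFit:
    """A fitted ring decoder: curve plus train-set alignment."""

    curve: RingCurve
    alignment: Alignment
    period: float
    train_idx: np.ndarray
    test_idx: np.ndarray


def fit_spud(
    coords: np.ndarray,
    time_bin: np.ndarray,
    dt: float = 0.1,
    n_knots: int = 10,
    train_frac: float = 0.8,
    seed: int = 0,
    n_iter: int = 50,
    init: str = "kmeans",
    train_idx: np.ndarray | None = None,
    test_idx: np.ndarray | None = None,
    n_timepoints: int | None = None,
) -> tuple[SpudFit, DecodingResult]:
    """Full SPUD protocol: fit + align on train, decode and score on test.

    ``init`` selects knot initialization: ``"kmeans"`` (default) or
    ``"time_average"`` (for shuffled-data comparisons).  A custom train/test
    partition (e.g. train on week-1 odd trials) can be passed explicitly.
    """
    coords = np.asarray(coords, dtype=float)
    time_bin = np.asarray(time_bin)
    if n_timepoints is None:
        n_timepoints = int(time_bin.max()) + 1
    period = n_timepoints * dt
    if train_idx is None or test_idx is None:
        train_idx, test_idx = split_train_test(
            coords.shape[0], train_frac=train_frac, seed=seed
        )
    train_pts = coords[train_idx]
    if init == "time_average":
        knots = init_knots_time_averaged(train_pts, time_bin[train_idx], n_knots)
        curve = optimize_knots(train_pts, RingCurve(knots=knots), n_iter=n_iter)
    else:
        # two unsupervised candidate orderings of the K-means knots; keep the
        # ring whose optimized (sum of distances) x (length) objective is lower
        knots = init_knots(train_pts, n_knots=n_knots, seed=seed)
        candidates = [connect_knots(train_pts, knots), _angular_ring(knots)]
        curve, best_obj = None, np.inf
        for ring in candidates:
            cand = optimize_knots(train_pts, ring, n_iter=n_iter)
            obj = curve_objective(train_pts, cand)
            if obj < best_obj:
                curve, best_obj = cand, obj

    train_assign = project_to_curve(train_pts, curve)
    t_rescaled = (time_bin[train_idx] + 0.5) / n_timepoints
    alignment = align_coordinates(
        train_assign.y, t_rescaled, n_shift_grid=n_timepoints
    )
    test_assign = project_to_curve(coords[test_idx], curve)
    true_time_s = (time_bin[test_idx] + 0.5) * dt
    result = decode_time(test_assign, alignment, true_time_s, period=period)
    fit = SpudFit(
        curve=curve,
        alignment=alignment,
        period=period,
        train_idx=np.asarray(train_idx),
        test_idx=np.asarray(test_idx),
    )
    return fit, result
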
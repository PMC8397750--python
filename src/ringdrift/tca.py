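"""Masked nonnegative tensor component analysis (CP decomposition).

Population activity is organized as a three-way tensor chi (neuron N x time T
x trial K) and approximated by a sum of R rank-one nonnegative components

    x_ntk ~ sum_r W[n,r] * B[t,r] * A[k,r]

fit to minimize the masked squared reconstruction error
``||M * (chi - chi_hat)||_F^2`` subject to W, B, A >= 0, where the binary
mask M excludes entries (here: negative dF/F values, which carry no rate
information).  The optimizer uses masked multiplicative updates, which keep
the factors nonnegative and make the objective non-increasing.

Utilities cover cross-validated rank selection by random 50% entry holdout,
a permutation-invariant model-similarity score (Hungarian matching on
triple-cosine component scores), K-means clustering of trial factors,
within/across-week trial-factor stability, and the factor-shuffle control
(per component: permuted neuron factor, circularly shifted temporal and
trial factors) that destroys episode coordination while preserving each
factor's marginal statistics.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import h5py
import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans

from ringdrift._utils import pearson
from ringdrift.preprocess import DffTensor

logger = logging.getLogger(__name__)


@dataclass
class MaskedTensor:
    """Data tensor plus binary mask (1 = fit this entry)."""

    values: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask)
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask must have the same shape")
        if not np.isin(np.unique(self.mask), (0, 1)).all():
            raise ValueError("mask must be binary")
        if not np.all(np.isfinite(self.values[self.mask.astype(bool)])):
            raise ValueError("masked-in entries must be finite")
        self.mask = self.mask.astype(float)


@dataclass
class TCAModel:
    """Nonnegative factors of an R-component CP model."""

    W: np.ndarray  # (N, R) neuron factors
    B: np.ndarray  # (T, R) temporal factors
    A: np.ndarray  # (K, R) trial factors
    objective: float = float("nan")
    converged: bool = True
    n_iter: int = 0
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("W", "B", "A"):
            m = np.asarray(getattr(self, name), dtype=float)
            if m.ndim != 2 or np.any(m < 0) or not np.all(np.isfinite(m)):
                raise ValueError(f"{name} must be a finite nonnegative matrix")
            setattr(self, name, m)
        if not (self.W.shape[1] == self.B.shape[1] == self.A.shape[1] >= 1):
            raise ValueError("factor matrices must share R >= 1 columns")

    @property
    def rank(self) -> int:
        return self.W.shape[1]

    @property
    def degenerate(self) -> bool:
        """True when any component has an (effectively) all-zero factor column."""
        for m in (self.W, self.B, self.A):
            if np.any(np.linalg.norm(m, axis=0) < 1e-12):
                return True
        return False

    def save(self, path: str) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("W", data=self.W)
            f.create_dataset("B", data=self.B)
            f.create_dataset("A", data=self.A)
            f.attrs["R"] = self.rank
            f.attrs["objective"] = self.objective
            if self.seed is not None:
                f.attrs["seed"] = self.seed

    @classmethod
    def load(cls, path: str) -> "TCAModel":
        with h5py.File(path, "r") as f:
            return cls(
                W=f["W"][()],
                B=f["B"][()],
                A=f["A"][()],
                objective=float(f.attrs.get("objective", np.nan)),
                seed=int(f.attrs["seed"]) if "seed" in f.attrs else None,
            )


def build_mask(t: DffTensor) -> MaskedTensor:
    """Mask out negative dF/F entries (m = 0 where x < 0, else 1)."""
    return MaskedTensor(values=t.values, mask=(t.values >= 0).astype(float))


def _khatri_rao(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Column-wise Khatri-Rao product: (I*J, R) from (I, R) and (J, R)."""
    r = a.shape[1]
    return (a[:, None, :] * b[None, :, :]).reshape(-1, r)


def reconstruct(m: TCAModel) -> np.ndarray:
    """chi_hat[n,t,k] = sum_r W[n,r] B[t,r] A[k,r]."""
    n, t, k = m.W.shape[0], m.B.shape[0], m.A.shape[0]
    return (m.W @ _khatri_rao(m.B, m.A).T).reshape(n, t, k)


def normalized_error(t: MaskedTensor, m: TCAModel) -> float:
    """||M*(chi - chi_hat)||_F^2 / ||M*chi||_F^2."""
    denom = float(np.sum(t.mask * t.values**2))
    if denom == 0:
        raise ValueError("zero-norm masked data")
    resid = t.mask * (t.values - reconstruct(m))
    return float(np.sum(resid**2)) / denom


def _masked_objective(x_masked, mask, W, B, A) -> float:
    xhat = (W @ _khatri_rao(B, A).T).reshape(mask.shape)
    return float(np.sum((x_masked - mask * xhat) ** 2))


def _fit_once(
    t: MaskedTensor,
    rank: int,
    rng: np.random.Generator,
    max_iter: int,
    tol: float,
    eps: float = 1e-9,
    dtype: type = np.float64,
    init: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None,
    min_iter: int = 1,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, bool, int]:
    N, T, K = t.values.shape
    mask = t.mask.astype(dtype)
    xm = mask * t.values.astype(dtype)  # masked data, reused throughout
    # mode unfoldings of the masked data (copies made once)
    x0 = xm.reshape(N, T * K)
    x1 = xm.transpose(1, 0, 2).reshape(T, N * K)
    x2 = xm.transpose(2, 0, 1).reshape(K, N * T)
    scale = np.sqrt(xm.mean() / max(rank, 1)) if xm.mean() > 0 else 1.0
    if init is not None:
        W = np.asarray(init[0], dtype=dtype).copy()
        B = np.asarray(init[1], dtype=dtype).copy()
        A = np.asarray(init[2], dtype=dtype).copy()
        if W.shape != (N, rank) or B.shape != (T, rank) or A.shape != (K, rank):
            raise ValueError("init factors do not match tensor shape and rank")
    else:
        W = (np.abs(rng.normal(0.0, 1.0, (N, rank))) * scale).astype(dtype)
        B = (np.abs(rng.normal(0.0, 1.0, (T, rank))) * scale).astype(dtype)
        A = (np.abs(rng.normal(0.0, 1.0, (K, rank))) * scale).astype(dtype)

    prev = _masked_objective(xm, mask, W, B, A)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # W update
        kr = _khatri_rao(B, A)
        xhat_m = mask * (W @ kr.T).reshape(N, T, K)
        num = x0 @ kr
        den = xhat_m.reshape(N, T * K) @ kr + eps
        W *= num / den
        # B update
        kr = _khatri_rao(W, A)
        xhat_m = mask * (W @ _khatri_rao(B, A).T).reshape(N, T, K)
        num = x1 @ kr
        den = xhat_m.transpose(1, 0, 2).reshape(T, N * K) @ kr + eps
        B *= num / den
        # A update
        kr = _khatri_rao(W, B)
        xhat_m = mask * (W @ _khatri_rao(B, A).T).reshape(N, T, K)
        num = x2 @ kr
        den = xhat_m.transpose(2, 0, 1).reshape(K, N * T) @ kr + eps
        A *= num / den

        obj = _masked_objective(xm, mask, W, B, A)
        if obj > prev * (1 + 1e-9) + 1e-12:
            logger.debug("objective increased at iter %d (%.3e -> %.3e)", it, prev, obj)
        if it >= min_iter and prev > 0 and (prev - obj) / prev < tol:
            prev = obj
            converged = True
            break
        prev = obj
    return (
        W.astype(np.float64),
        B.astype(np.float64),
        A.astype(np.float64),
        float(prev),
        converged,
        it,
    )


def fit(
    t: MaskedTensor,
    rank: int,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-6,
    n_restarts: int = 3,
    dtype: type = np.float64,
    init: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None,
    min_iter: int = 1,
) -> TCAModel:
    """Fit masked nonnegative CP by multiplicative updates; best of restarts.

    Factors start from |Normal(0, 1)| draws (seeded); each restart uses an
    independent substream of ``seed``.  Iteration stops when the relative
    objective decrease falls below ``tol`` or at ``max_iter`` (the model is
    still returned, flagged unconverged).  ``dtype=np.float32`` trades a few
    digits of objective precision for much faster BLAS on large tensors;
    returned factors are always float64.
    """
    if rank < 1:
        raise ValueError("rank must be >= 1")
    if np.sum(t.mask) == 0:
        raise ValueError("all entries are masked out")
    for axis, name in ((0, "neuron"), (1, "time"), (2, "trial")):
        per_slice = t.mask.sum(axis=tuple(i for i in range(3) if i != axis))
        if np.any(per_slice == 0):
            warnings.warn(f"some {name} slices have no unmasked entries")
    best: tuple | None = None
    if init is not None:
        n_restarts = 1  # a provided starting point defines the single run
    ss = np.random.SeedSequence([seed & 0x7FFFFFFF, 99]).spawn(n_restarts)
    for child in ss:
        result = _fit_once(
            t, rank, np.random.default_rng(child), max_iter, tol,
            dtype=dtype, init=init, min_iter=min_iter,
        )
        if best is None or result[3] < best[3]:
            best = result
    W, B, A, obj, converged, n_iter = best
    if not converged:
        logger.warning("TCA fit did not converge within %d iterations", max_iter)
    return TCAModel(
        W=W, B=B, A=A, objective=obj, converged=converged, n_iter=n_iter, seed=seed
    )


def make_holdout_mask(
    shape: tuple[int, int, int],
    data_mask: np.ndarray,
    mask_frac: float = 0.5,
    seed: int = 0,
    max_resample: int = 20,
) -> np.ndarray:
    """Random entry holdout (1 = train) ANDed with the data mask.

    If the holdout empties an entire fiber along any mode the split is
    resampled (with a warning); completion needs at least one observed entry
    per slice.
    """
    rng = np.random.default_rng(seed)
    for _ in range(max_resample):
        holdout = (rng.random(shape) >= mask_frac).astype(float)
        train = holdout * data_mask
        ok = True
        for axis in range(3):
            per_slice = train.sum(axis=tuple(i for i in range(3) if i != axis))
            if np.any(per_slice == 0):
                ok = False
                break
        if ok:
            return holdout
        warnings.warn("holdout left an empty fiber; resampling the split")
    raise ValueError("could not draw a holdout mask leaving all fibers observed")


def cross_validate(
    t: MaskedTensor,
    ranks: list[int],
    mask_frac: float = 0.5,
    seed: int = 0,
    max_iter: int = 300,
    tol: float = 1e-6,
    n_restarts: int = 1,
    warm_start: bool = True,
    dtype: type = np.float64,
) -> dict[str, np.ndarray]:
    """Train/test normalized errors over candidate ranks (50% entry holdout).

    The model is fit on the training entries only; the test error is the
    normalized reconstruction error on the held-out (but data-valid) entries.
    Overfitting shows as the test error turning upward with rank.

    With ``warm_start`` (default) ranks are fit in ascending order and each
    model starts from the previous one padded with a small random component;
    since the updates never increase the objective, the training error is
    non-increasing in rank by construction rather than up to optimizer noise.
    """
    if not ranks:
        raise ValueError("ranks must be non-empty")
    holdout = make_holdout_mask(t.values.shape, t.mask, mask_frac, seed)
    train = MaskedTensor(values=t.values, mask=holdout * t.mask)
    test = MaskedTensor(values=t.values, mask=(1 - holdout) * t.mask)
    order = np.argsort(ranks) if warm_start else np.arange(len(ranks))
    train_err = np.empty(len(ranks))
    test_err = np.empty(len(ranks))
    prev: TCAModel | None = None
    pad_rng = np.random.default_rng(seed)
    for pos in order:
        r = int(ranks[pos])
        init = None
        if warm_start and prev is not None and prev.rank < r:
            extra = r - prev.rank
            pad_scale = 1e-3 * max(float(np.abs(t.values).mean()), 1e-12)

            def pad(m: np.ndarray) -> np.ndarray:
                return np.c_[m, pad_scale
                             * pad_rng.random((m.shape[0], extra))]

            init = (pad(prev.W), pad(prev.B), pad(prev.A))
        model = fit(train, r, seed=seed + r, max_iter=max_iter, tol=tol,
                    n_restarts=n_restarts, dtype=dtype, init=init,
                    min_iter=60 if init is not None else 1)
        train_err[pos] = normalized_error(train, model)
        test_err[pos] = normalized_error(test, model)
        prev = model
    return {
        "rank": np.asarray(ranks),
        "train_error": train_err,
        "test_error": test_err,
    }


def model_similarity(a: TCAModel, b: TCAModel) -> float:
    """Permutation- and scale-invariant similarity in [0, 1].

    Components are matched one-to-one by Hungarian assignment maximizing the
    summed per-pair score; a pair's score is the product over the three modes
    of the cosine similarity between the matched factor columns (columns are
    nonnegative, so each cosine is in [0, 1]).  Returns the mean matched
    score; zero columns score 0.
    """
    if a.rank != b.rank or a.W.shape != b.W.shape or a.B.shape != b.B.shape \
            or a.A.shape != b.A.shape:
        raise ValueError("models must have identical shapes")

    def unit_cols(m: np.ndarray) -> np.ndarray:
        norms = np.linalg.norm(m, axis=0)
        safe = np.where(norms > 0, norms, 1.0)
        return m / safe

    score = np.ones((a.rank, b.rank))
    for ma, mb in ((a.W, b.W), (a.B, b.B), (a.A, b.A)):
        score *= unit_cols(ma).T @ unit_cols(mb)
    row, col = linear_sum_assignment(-score)
    return float(score[row, col].mean())


def cluster_trial_factors(
    m: TCAModel, k_clusters: int = 5, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Order components by K-means clusters of their trial factors.

    K-means runs on the R trial-factor columns (points of dimension K).
    Clusters are ordered by the mean time-to-peak of their members' temporal
    factors; within a cluster components are ordered by time-to-peak.
    Returns ``(order, labels)``: the component ordering and the per-component
    cluster label (in original component numbering).
    """
    if m.rank < k_clusters:
        raise ValueError("need at least as many components as clusters")
    km = KMeans(n_clusters=k_clusters, n_init=10, random_state=seed)
    labels = km.fit_predict(m.A.T)
    peak_time = m.B.argmax(axis=0)
    cluster_rank = {
        c: peak_time[labels == c].mean() for c in range(k_clusters)
    }
    order = sorted(
        range(m.rank), key=lambda r: (cluster_rank[labels[r]], labels[r], peak_time[r])
    )
    return np.asarray(order), labels


def trial_factor_stability(
    m: TCAModel, week_labels: np.ndarray
) -> tuple[float, float]:
    """(within-week CC, across-week CC) of trial-factor vectors.

    For every unordered trial pair the Pearson correlation between the two
    trials' R-length factor vectors is computed; pairs are averaged separately
    within and across weeks.  Constant vectors are excluded pairwise.
    """
    week_labels = np.asarray(week_labels, dtype=int)
    if np.unique(week_labels).size < 2:
        raise ValueError("need at least two weeks")
    K = m.A.shape[0]
    if week_labels.shape != (K,):
        raise ValueError("week_labels must have one entry per trial")
    within, across = [], []
    for i in range(K):
        for j in range(i + 1, K):
            c = pearson(m.A[i], m.A[j])
            if not np.isfinite(c):
                continue
            (within if week_labels[i] == week_labels[j] else across).append(c)
    return (
        float(np.mean(within)) if within else float("nan"),
        float(np.mean(across)) if across else float("nan"),
    )


def shuffle_factors(m: TCAModel, seed: int = 0) -> TCAModel:
    """Destroy episode coordination: per component, permute the neuron factor
    and circularly shift the temporal and trial factors by random amounts."""
    rng = np.random.default_rng(seed)
    W = m.W.copy()
    B = m.B.copy()
    A = m.A.copy()
    for r in range(m.rank):
        W[:, r] = W[rng.permutation(W.shape[0]), r]
        B[:, r] = np.roll(B[:, r], int(rng.integers(B.shape[0])))
        A[:, r] = np.roll(A[:, r], int(rng.integers(A.shape[0])))
    return TCAModel(W=W, B=B, A=A, objective=float("nan"), seed=seed)
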
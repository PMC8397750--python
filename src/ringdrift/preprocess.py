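"""Fluorescence preprocessing and single-neuron week-similarity statistics.

Raw somatic fluorescence is contaminated by perisomatic neuropil signal; the
corrected trace is ``F_soma - alpha * (F_neuropil - mean(F_neuropil))`` with
``alpha`` chosen in [0, 1] to decorrelate the corrected trace from the
neuropil.  dF/F is then ``(F - F0) / F0`` with the baseline ``F0`` taken as
the mode of the corrected-fluorescence density.  Trial-resolved dF/F is held
in a (neuron x time x trial) tensor with per-trial week labels; before tensor
decomposition each neuron is scaled to unit root-mean-square so that high-rate
neurons do not dominate the squared-error objective.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import h5py
import numpy as np
from scipy import stats

from ringdrift._utils import pairwise_mean_corr, pearson

logger = logging.getLogger(__name__)


@dataclass
class FluorescenceTrace:
    """Somatic + neuropil fluorescence for one ROI, with correction parameters."""

    f_soma: np.ndarray
    f_neuropil: np.ndarray
    alpha: float = 1.0

    def __post_init__(self) -> None:
        self.f_soma = np.asarray(self.f_soma, dtype=float)
        self.f_neuropil = np.asarray(self.f_neuropil, dtype=float)
        if self.f_soma.shape != self.f_neuropil.shape:
            raise ValueError("f_soma and f_neuropil must have equal length")
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError(f"alpha must lie in [0, 1], got {self.alpha}")


@dataclass
class DffTensor:
    """dF/F on a (neuron N x time T x trial K) grid with per-trial week labels.

    ``movie_start_bin`` marks the first movie frame; bins before it are the
    gray-screen period.  ``dt`` is seconds per bin (10 Hz sampling -> 0.1 s).
    """

    values: np.ndarray
    week_labels: np.ndarray
    dt: float = 0.1
    movie_start_bin: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.week_labels = np.asarray(self.week_labels, dtype=int)
        if self.values.ndim != 3:
            raise ValueError("values must be (neuron, time, trial)")
        if self.week_labels.shape != (self.values.shape[2],):
            raise ValueError("week_labels must have one entry per trial")
        if np.any(np.diff(self.week_labels) < 0):
            raise ValueError("week_labels must be non-decreasing")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    @property
    def n_neurons(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]

    @property
    def n_trials(self) -> int:
        return self.values.shape[2]

    @property
    def weeks(self) -> np.ndarray:
        return np.unique(self.week_labels)

    def trials_of_week(self, week: int) -> np.ndarray:
        return np.flatnonzero(self.week_labels == week)

    def trial_average(self, week: int | None = None) -> np.ndarray:
        """Trial-averaged traces (N x T), optionally restricted to one week."""
        if week is None:
            return self.values.mean(axis=2)
        idx = self.trials_of_week(week)
        if idx.size == 0:
            raise ValueError(f"no trials in week {week}")
        return self.values[:, :, idx].mean(axis=2)

    def save(self, path: str) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("dff", data=self.values)
            f.create_dataset("week_labels", data=self.week_labels)
            f.create_dataset(
                "time_s", data=np.arange(self.n_timepoints) * self.dt
            )
            f.attrs["dt"] = self.dt
            f.attrs["movie_start_bin"] = self.movie_start_bin

    @classmethod
    def load(cls, path: str) -> "DffTensor":
        with h5py.File(path, "r") as f:
            return cls(
                values=f["dff"][()],
                week_labels=f["week_labels"][()],
                dt=float(f.attrs["dt"]),
                movie_start_bin=int(f.attrs.get("movie_start_bin", 0)),
            )


def neuropil_correct(trace: FluorescenceTrace) -> np.ndarray:
    """Subtract the mean-centered neuropil signal scaled by ``alpha``."""
    neuropil_centered = trace.f_neuropil - trace.f_neuropil.mean()
    return trace.f_soma - trace.alpha * neuropil_centered


def select_alpha(
    f_soma: np.ndarray,
    f_neuropil: np.ndarray,
    grid_step: float = 0.01,
) -> float:
    """Grid-search ``alpha`` in [0, 1] minimizing |corr(corrected, neuropil)|.

    A constant neuropil trace leaves the correlation undefined; 0 is returned
    with a warning (no correction applied).
    """
    f_soma = np.asarray(f_soma, dtype=float)
    f_neuropil = np.asarray(f_neuropil, dtype=float)
    if f_soma.shape != f_neuropil.shape:
        raise ValueError("traces must have equal length")
    if np.ptp(f_neuropil) == 0:
        warnings.warn(
            "constant neuropil trace: correlation undefined, returning alpha=0"
        )
        return 0.0
    grid = np.arange(0.0, 1.0 + grid_step / 2, grid_step)
    centered = f_neuropil - f_neuropil.mean()
    best_alpha, best_score = 0.0, np.inf
    for alpha in grid:
        corrected = f_soma - alpha * centered
        c = pearson(corrected, f_neuropil)
        score = abs(c) if np.isfinite(c) else 0.0
        if score < best_score:
            best_alpha, best_score = float(alpha), score
    return best_alpha


def estimate_f0(trace: np.ndarray, grid_size: int = 512) -> float:
    """Baseline F0 = mode of the fluorescence density.

    Gaussian kernel-density estimate with Silverman bandwidth, mode taken as
    the arg-max on a regular grid spanning the data range.
    """
    trace = np.asarray(trace, dtype=float)
    if not np.all(np.isfinite(trace)):
        raise ValueError("trace must be finite")
    if np.ptp(trace) == 0:
        return float(trace[0])
    kde = stats.gaussian_kde(trace, bw_method="silverman")
    grid = np.linspace(trace.min(), trace.max(), grid_size)
    return float(grid[np.argmax(kde(grid))])


def compute_dff(corrected: np.ndarray, f0: float | None = None) -> np.ndarray:
    """dF/F = (F - F0) / F0 with F0 the density mode of the full series."""
    corrected = np.asarray(corrected, dtype=float)
    if f0 is None:
        f0 = estimate_f0(corrected)
    if f0 <= 0:
        raise ValueError(f"baseline F0 must be positive, got {f0}")
    return (corrected - f0) / f0


def normalize_tensor(t: DffTensor) -> DffTensor:
    """Scale each neuron to unit root-mean-square over all bins and trials.

    After the call ``sqrt(sum_{t,k} x^2 / (T*K)) == 1`` for every retained
    neuron.  All-zero neurons have no defined scale and are dropped with a
    logged warning.
    """
    T, K = t.n_timepoints, t.n_trials
    rms = np.sqrt((t.values**2).sum(axis=(1, 2)) / (T * K))
    keep = rms > 0
    if not np.all(keep):
        logger.warning(
            "normalize_tensor: dropping %d all-zero neuron(s)", int((~keep).sum())
        )
    values = t.values[keep] / rms[keep, None, None]
    return replace(t, values=values)


def week_similarity(
    t: DffTensor, reference_week: int | None = None
) -> dict[int, float]:
    """Per-week similarity to a reference week (Pearson CC of trial averages).

    For each week the per-neuron correlation between the neuron's
    trial-averaged trace in the reference week and in that week is averaged
    over neurons; zero-variance neurons are excluded pairwise.
    """
    weeks = t.weeks
    if weeks.size < 2:
        raise ValueError("week_similarity requires at least two weeks")
    if reference_week is None:
        reference_week = int(weeks[0])
    ref = t.trial_average(reference_week)
    out: dict[int, float] = {}
    for w in weeks:
        avg = t.trial_average(int(w))
        ccs = [pearson(ref[n], avg[n]) for n in range(t.n_neurons)]
        ccs = [c for c in ccs if np.isfinite(c)]
        if len(ccs) < t.n_neurons:
            logger.info(
                "week_similarity: excluded %d zero-variance neuron(s) for week %d",
                t.n_neurons - len(ccs),
                int(w),
            )
        out[int(w)] = float(np.mean(ccs)) if ccs else float("nan")
    return out


def reliability(t: DffTensor, neuron: int) -> float:
    """Mean Pearson CC over all unordered single-trial pairs of one neuron."""
    if t.n_trials < 2:
        raise ValueError("reliability requires at least two trials")
    traces = t.values[neuron].T  # (K, T)
    return pairwise_mean_corr(traces)


def week_change_vs_baseline(
    t: DffTensor, seed: int = 0
) -> tuple[np.ndarray, np.ndarray, float]:
    """Across-week response change vs within-week baseline variability.

    Per neuron, the across-week change is the mean absolute difference between
    the trial-averaged trace of each later week and that of the first week.
    The baseline is the same statistic between two random half-splits of the
    first week's trials, scaled by 1/sqrt(2): a half-mean has twice the
    sampling variance of a full-week mean, so without the correction the
    baseline would overstate within-week variability by sqrt(2) under
    stationary noise.  Returns ``(across, baseline, p)`` where ``p`` is a
    two-sided Mann-Whitney U comparison of the two per-neuron distributions.
    """
    weeks = t.weeks
    if weeks.size < 2:
        raise ValueError("need at least two weeks")
    first = int(weeks[0])
    ref = t.trial_average(first)
    across_terms = []
    for w in weeks[1:]:
        across_terms.append(np.abs(t.trial_average(int(w)) - ref).mean(axis=1))
    across = np.mean(across_terms, axis=0)

    rng = np.random.default_rng(seed)
    idx = rng.permutation(t.trials_of_week(first))
    half = idx.size // 2
    if half == 0:
        raise ValueError("first week needs at least two trials for a half-split")
    a = t.values[:, :, idx[:half]].mean(axis=2)
    b = t.values[:, :, idx[half:]].mean(axis=2)
    baseline = np.abs(a - b).mean(axis=1) / np.sqrt(2)

    stat = stats.mannwhitneyu(across, baseline, alternative="two-sided")
    return across, baseline, float(stat.pvalue)
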
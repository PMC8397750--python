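"""Spiking-episode detection and episode-level gain-stability statistics.

A spiking episode is a short window of temporally precise, elevated inferred
spiking.  Episodes are found on the trial-summed PSTH of inferred spikes:
the PSTH is smoothed with a Gaussian kernel, peaks with topographic
prominence above a threshold are located, and each peak's full width at half
maximum (half-max measured from the peak's prominence base) defines the
episode window; overlapping windows are merged into one episode spanning the
start of the first peak to the end of the last.

Episode-level statistics then ask whether episode *gain* (mean inferred rate
within the window) is stable: correlations of per-episode rates within vs
across weeks, and the similarity of week-gain trajectories between episodes
of the same neuron against two references — an i.i.d. Poisson simulation
(shared trajectory, count noise only) and a week-shuffle chance control.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks, peak_widths

from ringdrift._utils import fit_gaussian, pairwise_mean_corr, pearson

logger = logging.getLogger(__name__)


@dataclass
class Episode:
    """One neuron's spiking episode; [start_bin, end_bin) in 0-based bins."""

    neuron: int
    start_bin: int
    end_bin: int
    peak_bin: int
    dt: float = 0.1

    def __post_init__(self) -> None:
        if not self.start_bin < self.end_bin:
            raise ValueError("episode must satisfy start < end")
        if not (self.start_bin <= self.peak_bin < self.end_bin):
            raise ValueError("peak must lie inside [start, end)")

    @property
    def duration_s(self) -> float:
        return (self.end_bin - self.start_bin) * self.dt


@dataclass
class EpisodeRateTable:
    """Per-episode inferred spike rates per trial and their week means."""

    episodes: list[Episode]
    rates: np.ndarray        # (n_episodes, n_trials), Hz
    week_means: np.ndarray   # (n_episodes, n_weeks), Hz
    week_labels: np.ndarray  # (n_trials,)
    weeks: np.ndarray
    dt: float

    @property
    def neurons(self) -> np.ndarray:
        return np.asarray([e.neuron for e in self.episodes])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, e in enumerate(self.episodes):
            row = {
                "episode": i,
                "neuron": e.neuron,
                "start_bin": e.start_bin,
                "end_bin": e.end_bin,
                "peak_bin": e.peak_bin,
                "duration_s": e.duration_s,
            }
            for j, w in enumerate(self.weeks):
                row[f"week_{int(w)}_rate_hz"] = self.week_means[i, j]
            rows.append(row)
        return pd.DataFrame(rows)


def naive_deconvolve(dff_values: np.ndarray) -> np.ndarray:
    """Crude spike proxy for demos: positive first difference of dF/F.

    This is not a substitute for a proper deconvolution method; it simply
    exposes fast rises of the calcium signal, which is all the episode
    statistics need on clean data.
    """
    d = np.diff(dff_values, axis=1, prepend=dff_values[:, :1, :])
    return np.clip(d, 0.0, None)


def binarize_spikes(deconvolved: np.ndarray, threshold_sd: float = 3.0) -> np.ndarray:
    """Inferred spikes: 1 where the trace exceeds threshold_sd x per-neuron SD.

    The SD is computed over all bins and trials of the neuron (deconvolved
    traces hover around 0, so the threshold is effectively above zero).
    """
    x = np.asarray(deconvolved, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("deconvolved tensor must be finite")
    sd = x.std(axis=(1, 2), keepdims=True)
    return (x > threshold_sd * sd).astype(np.int64)


def compute_psth(
    spikes: np.ndarray, neuron: int, trial_subset: np.ndarray | None = None
) -> np.ndarray:
    """Per-bin spike sum across the selected trials of one neuron."""
    if trial_subset is None:
        trial_subset = np.arange(spikes.shape[2])
    trial_subset = np.asarray(trial_subset)
    if trial_subset.size == 0:
        raise ValueError("trial subset must be non-empty")
    return spikes[neuron][:, trial_subset].sum(axis=1).astype(float)


def smooth_psth(psth: np.ndarray, bandwidth_s: float = 0.2, dt: float = 0.1) -> np.ndarray:
    """Gaussian-kernel smoothing with reflective boundary (mass-preserving)."""
    if bandwidth_s <= 0:
        raise ValueError("bandwidth must be positive")
    sigma_bins = bandwidth_s / dt
    return gaussian_filter1d(np.asarray(psth, dtype=float), sigma_bins, mode="reflect")


def detect_episodes(
    smoothed: np.ndarray,
    neuron: int = 0,
    prominence: float = 3.0,
    dt: float = 0.1,
) -> list[Episode]:
    """Episodes = FWHM windows of prominent smoothed-PSTH peaks, merged.

    Peaks need topographic prominence > ``prominence`` (in units of the
    smoothed summed-count trace).  The window of each peak is its full width
    at half maximum, with half-max measured relative to the peak height above
    its prominence base (the standard peak-analysis convention).  Windows that
    overlap are merged into a single episode spanning the start of the first
    peak to the end of the last; the merged peak is the highest of the merged
    peaks.
    """
    x = np.asarray(smoothed, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("smoothed PSTH must be finite")
    peaks, props = find_peaks(x, prominence=prominence)
    if peaks.size == 0:
        return []
    widths, _, left_ips, right_ips = peak_widths(
        x, peaks, rel_height=0.5, prominence_data=(
            props["prominences"], props["left_bases"], props["right_bases"]
        )
    )
    # window = bins whose centers lie inside the half-max interval
    intervals = []
    for l, r, p in zip(left_ips, right_ips, peaks):
        start, end = int(np.ceil(l)), int(np.floor(r)) + 1
        start, end = min(start, int(p)), max(end, int(p) + 1)
        intervals.append((start, end, int(p)))
    intervals.sort()
    merged: list[list[int]] = []
    for start, end, peak in intervals:
        if merged and start < merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], end)
            if x[peak] > x[merged[-1][2]]:
                merged[-1][2] = peak
        else:
            merged.append([start, end, peak])
    return [
        Episode(neuron=neuron, start_bin=s, end_bin=e, peak_bin=p, dt=dt)
        for s, e, p in merged
    ]


def detect_all_episodes(
    spikes: np.ndarray,
    trial_subset: np.ndarray | None = None,
    prominence: float = 3.0,
    bandwidth_s: float = 0.2,
    dt: float = 0.1,
) -> list[Episode]:
    """Detect episodes for every neuron from its trial-summed smoothed PSTH."""
    out: list[Episode] = []
    for n in range(spikes.shape[0]):
        psth = compute_psth(spikes, n, trial_subset)
        smoothed = smooth_psth(psth, bandwidth_s=bandwidth_s, dt=dt)
        out.extend(detect_episodes(smoothed, neuron=n, prominence=prominence, dt=dt))
    return out


def episode_rates(
    spikes: np.ndarray,
    episodes: list[Episode],
    week_labels: np.ndarray,
    dt: float = 0.1,
) -> EpisodeRateTable:
    """Mean inferred spike rate (Hz) in each episode window, per trial and week."""
    week_labels = np.asarray(week_labels, dtype=int)
    weeks = np.unique(week_labels)
    n_ep = len(episodes)
    n_trials = spikes.shape[2]
    rates = np.zeros((n_ep, n_trials))
    for i, e in enumerate(episodes):
        if e.end_bin > spikes.shape[1]:
            raise ValueError("episode extends beyond the time axis")
        counts = spikes[e.neuron, e.start_bin : e.end_bin, :].sum(axis=0)
        rates[i] = counts / ((e.end_bin - e.start_bin) * dt)
    week_means = np.stack(
        [rates[:, week_labels == w].mean(axis=1) for w in weeks], axis=1
    )
    return EpisodeRateTable(
        episodes=episodes,
        rates=rates,
        week_means=week_means,
        week_labels=week_labels,
        weeks=weeks,
        dt=dt,
    )


def episode_rate_stability(table: EpisodeRateTable) -> tuple[float, float]:
    """(within-week CC, across-week CC) of per-episode rate vectors.

    Across-week: for every week pair, correlate the two weeks' episode-rate
    vectors (one entry per episode) and average.  Within-week: correlate the
    even-trial vs odd-trial episode-rate vectors inside each week and average
    over weeks.  Constant vectors are excluded pairwise.
    """
    if table.weeks.size < 2 or len(table.episodes) < 2:
        raise ValueError("need >=2 weeks and >=2 episodes")
    across = []
    for i in range(table.weeks.size):
        for j in range(i + 1, table.weeks.size):
            c = pearson(table.week_means[:, i], table.week_means[:, j])
            if np.isfinite(c):
                across.append(c)
    within = []
    for w in table.weeks:
        idx = np.flatnonzero(table.week_labels == w)
        even, odd = idx[::2], idx[1::2]
        if even.size == 0 or odd.size == 0:
            continue
        c = pearson(table.rates[:, even].mean(axis=1), table.rates[:, odd].mean(axis=1))
        if np.isfinite(c):
            within.append(c)
    if not across or not within:
        logger.warning("episode_rate_stability: some correlations undefined")
    return (
        float(np.mean(within)) if within else float("nan"),
        float(np.mean(across)) if across else float("nan"),
    )


def episode_pair_similarity(table: EpisodeRateTable) -> pd.Series:
    """Per-neuron mean CC between week-gain trajectories of its episodes.

    Only neurons with at least two episodes enter; for each such neuron the
    Pearson correlation between the week-mean rate vectors of every unordered
    episode pair is averaged.
    """
    if table.weeks.size < 2:
        raise ValueError("need at least two weeks")
    out = {}
    for n in np.unique(table.neurons):
        idx = np.flatnonzero(table.neurons == n)
        if idx.size < 2:
            continue
        cc = pairwise_mean_corr(table.week_means[idx])
        if np.isfinite(cc):
            out[int(n)] = cc
    return pd.Series(out, name="mean_cc", dtype=float)


def poisson_control(
    table: EpisodeRateTable, seed: int = 0
) -> tuple[pd.Series, tuple[float, float]]:
    """Episode-pair similarity expected from i.i.d. Poisson spiking alone.

    For each neuron one of its episodes is selected at random and its
    week-specific mean rates serve as the shared underlying gain trajectory
    for all of that neuron's episodes.  Per-trial counts are drawn as
    Poisson(shared weekly rate x episode duration), converted back to rates,
    averaged per week, and the per-neuron mean episode-pair CC is computed as
    for the data.  Returns the distribution and its Gaussian (mean, SD) fit.
    """
    if table.weeks.size < 2:
        raise ValueError("need at least two weeks")
    rng = np.random.default_rng(seed)
    neurons = table.neurons
    durations = np.asarray(
        [(e.end_bin - e.start_bin) * table.dt for e in table.episodes]
    )
    out = {}
    for n in np.unique(neurons):
        idx = np.flatnonzero(neurons == n)
        if idx.size < 2:
            continue
        chosen = rng.choice(idx)
        shared_weekly = table.week_means[chosen]  # (n_weeks,) Hz
        if np.all(shared_weekly == 0):
            continue  # rate-0 neuron: CC undefined under the control
        sim_week_means = np.zeros((idx.size, table.weeks.size))
        for a, ep_idx in enumerate(idx):
            lam = shared_weekly[
                np.searchsorted(table.weeks, table.week_labels)
            ] * durations[ep_idx]
            counts = rng.poisson(lam)
            sim_rates = counts / durations[ep_idx]
            sim_week_means[a] = [
                sim_rates[table.week_labels == w].mean() for w in table.weeks
            ]
        cc = pairwise_mean_corr(sim_week_means)
        if np.isfinite(cc):
            out[int(n)] = cc
    series = pd.Series(out, name="mean_cc_poisson", dtype=float)
    return series, fit_gaussian(series.to_numpy())


def week_shuffle_control(
    table: EpisodeRateTable, seed: int = 0
) -> tuple[pd.Series, tuple[float, float]]:
    """Chance-level episode-pair similarity: weeks shuffled per episode."""
    rng = np.random.default_rng(seed)
    shuffled = np.stack(
        [row[rng.permutation(row.size)] for row in table.week_means]
    )
    out = {}
    for n in np.unique(table.neurons):
        idx = np.flatnonzero(table.neurons == n)
        if idx.size < 2:
            continue
        cc = pairwise_mean_corr(shuffled[idx])
        if np.isfinite(cc):
            out[int(n)] = cc
    series = pd.Series(out, name="mean_cc_shuffled", dtype=float)
    return series, fit_gaussian(series.to_numpy())


def episodes_to_table(episodes: list[Episode]) -> pd.DataFrame:
    """BED-like tab-separated episode table (use ``.to_csv(path, sep='\\t')``)."""
    return pd.DataFrame(
        [
            {
                "neuron": e.neuron,
                "start_bin": e.start_bin,
                "end_bin": e.end_bin,
                "peak_bin": e.peak_bin,
                "duration_s": e.duration_s,
            }
            for e in episodes
        ]
    )


def match_to_planted(
    detected: list[Episode],
    planted_start: np.ndarray,
    planted_end: np.ndarray,
    planted_neuron: np.ndarray,
    max_peak_error_bins: int = 2,
) -> np.ndarray:
    """Which planted episodes are recovered by detection.

    A planted episode counts as recovered when a detected episode of the same
    neuron has its peak within ``max_peak_error_bins`` of the planted window
    (peak error = distance from the detected peak bin to the planted
    [start, end) interval; 0 when inside).  Returns a boolean array over
    planted episodes.
    """
    recovered = np.zeros(len(planted_start), dtype=bool)
    by_neuron: dict[int, list[Episode]] = {}
    for e in detected:
        by_neuron.setdefault(e.neuron, []).append(e)
    for i, (s, t, n) in enumerate(zip(planted_start, planted_end, planted_neuron)):
        for e in by_neuron.get(int(n), []):
            err = max(0, s - e.peak_bin, e.peak_bin - (t - 1))
            if err <= max_peak_error_bins:
                recovered[i] = True
                break
    return recovered
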
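"""Synthetic calcium-imaging data with planted episodic structure and gain drift.

The generator emulates the structure of a chronic-imaging session series:
each trial is 5 s of gray screen followed by a 30 s movie, sampled at 10 Hz
(350 bins); sessions of 30 trials repeat weekly over ~6 weeks.  Each neuron
carries a small number of "spiking episodes" — short, precisely timed windows
of elevated firing within the movie period.  Episode timing is fixed across
the whole experiment while episode *gain* drifts: every episode belongs to a
gain cluster whose week-gain template scales its firing rate week by week
(e.g. stable, fading, emerging), with additional log-normal trial-to-trial
gain noise within each week.  Spikes are Poisson given the rate; dF/F is the
spike train convolved with a causal difference-of-exponentials calcium kernel
plus Gaussian noise.

Because the planted episodes, rates, cluster identities and gain trajectories
are all recorded in :class:`GroundTruth`, every downstream stage (episode
detection, tensor decomposition, manifold embedding, decoding) can be tested
against a known answer.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import h5py
import numpy as np
from scipy.signal import fftconvolve

from ringdrift.preprocess import DffTensor


def default_gain_profiles(n_weeks: int, n_clusters: int) -> np.ndarray:
    """Week-gain templates, one row per cluster (nonnegative, length n_weeks).

    The first two are always "stable" (all ones) and "fading" (geometric decay
    to 0.1), mirroring the qualitatively distinct trial-factor clusters seen
    in chronic data; further clusters add emerging, transient and slow-wobble
    profiles.  With more clusters than base shapes, scaled copies are cycled.
    """
    w = np.arange(n_weeks)
    base = [
        np.ones(n_weeks),                                       # stable
        np.geomspace(1.0, 0.1, n_weeks),                        # fading
        np.geomspace(0.1, 1.0, n_weeks),                        # emerging
        np.exp(-0.5 * ((w - (n_weeks - 1) / 2) / 1.0) ** 2),    # transient
        1.0 - 0.4 * np.abs(np.sin(np.pi * w / max(n_weeks - 1, 1))),  # wobble
    ]
    profiles = []
    for i in range(n_clusters):
        scale = 1.0 + 0.1 * (i // len(base))
        profiles.append(scale * base[i % len(base)])
    return np.asarray(profiles)


@dataclass
class SyntheticParams:
    """Knobs of the generator; defaults follow the session structure above."""

    n_neurons: int = 100
    n_weeks: int = 6
    trials_per_week: int = 30
    n_timepoints: int = 350
    dt: float = 0.1
    gray_bins: int = 50
    episodes_per_neuron: tuple[int, int] = (1, 4)
    episode_duration_median_s: float = 0.6
    episode_duration_sigma: float = 0.4
    base_rate_hz: tuple[float, float] = (5.0, 15.0)
    n_gain_clusters: int = 5
    gain_cluster_profiles: np.ndarray | None = None
    within_week_gain_cv: float = 0.3
    background_rate_hz: float = 0.0
    calcium_tau: float = 1.5
    calcium_rise: float = 0.1
    dff_noise_sd: float = 0.05
    min_episode_gap_bins: int = 5
    end_margin_bins: int = 5
    loop_convolution: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_neurons", "n_weeks", "trials_per_week", "n_timepoints"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not (0 <= self.gray_bins < self.n_timepoints):
            raise ValueError("gray_bins must lie in [0, n_timepoints)")
        lo, hi = self.episodes_per_neuron
        if lo < 0 or hi < lo:
            raise ValueError("episodes_per_neuron must be a nonnegative range")
        if self.end_margin_bins < 0 or (
            self.gray_bins + self.end_margin_bins >= self.n_timepoints
        ):
            raise ValueError("end_margin_bins leaves no movie window")
        if self.calcium_tau <= 0 or self.calcium_rise <= 0:
            raise ValueError("calcium time constants must be positive")
        if self.calcium_rise >= self.calcium_tau:
            raise ValueError("calcium_rise must be below calcium_tau")
        if self.gain_cluster_profiles is None:
            self.gain_cluster_profiles = default_gain_profiles(
                self.n_weeks, self.n_gain_clusters
            )
        self.gain_cluster_profiles = np.asarray(
            self.gain_cluster_profiles, dtype=float
        )
        if self.gain_cluster_profiles.shape != (self.n_gain_clusters, self.n_weeks):
            raise ValueError("gain_cluster_profiles must be (n_clusters, n_weeks)")
        if np.any(self.gain_cluster_profiles < 0):
            raise ValueError("gain templates must be nonnegative")

    @property
    def n_trials(self) -> int:
        return self.n_weeks * self.trials_per_week

    @property
    def week_labels(self) -> np.ndarray:
        return np.repeat(np.arange(self.n_weeks), self.trials_per_week)

    @property
    def movie_bins(self) -> int:
        return self.n_timepoints - self.gray_bins


@dataclass
class PlantedEpisode:
    """One planted spiking episode: fixed timing, drifting gain."""

    neuron: int
    start_bin: int
    end_bin: int  # exclusive
    base_rate_hz: float
    cluster_id: int
    week_gain: np.ndarray
    trial_gain: np.ndarray

    @property
    def peak_bin(self) -> int:
        return (self.start_bin + self.end_bin - 1) // 2

    @property
    def duration_bins(self) -> int:
        return self.end_bin - self.start_bin


@dataclass
class GroundTruth:
    """Planted structure of one synthetic dataset."""

    episodes: list[PlantedEpisode]
    week_labels: np.ndarray
    n_neurons: int
    n_timepoints: int

    def episodes_of(self, neuron: int) -> list[PlantedEpisode]:
        return [e for e in self.episodes if e.neuron == neuron]

    def to_json(self) -> str:
        payload = {
            "n_neurons": self.n_neurons,
            "n_timepoints": self.n_timepoints,
            "week_labels": self.week_labels.tolist(),
            "episodes": [
                {
                    "neuron": e.neuron,
                    "start_bin": e.start_bin,
                    "end_bin": e.end_bin,
                    "base_rate_hz": e.base_rate_hz,
                    "cluster_id": e.cluster_id,
                    "week_gain": e.week_gain.tolist(),
                    "trial_gain": e.trial_gain.tolist(),
                }
                for e in self.episodes
            ],
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        eps = [
            PlantedEpisode(
                neuron=e["neuron"],
                start_bin=e["start_bin"],
                end_bin=e["end_bin"],
                base_rate_hz=e["base_rate_hz"],
                cluster_id=e["cluster_id"],
                week_gain=np.asarray(e["week_gain"]),
                trial_gain=np.asarray(e["trial_gain"]),
            )
            for e in d["episodes"]
        ]
        return cls(
            episodes=eps,
            week_labels=np.asarray(d["week_labels"], dtype=int),
            n_neurons=d["n_neurons"],
            n_timepoints=d["n_timepoints"],
        )


def _sample_duration_bins(params: SyntheticParams, rng: np.random.Generator) -> int:
    dur_s = rng.lognormal(
        mean=np.log(params.episode_duration_median_s),
        sigma=params.episode_duration_sigma,
    )
    return max(2, int(round(dur_s / params.dt)))


def generate_ground_truth(params: SyntheticParams) -> GroundTruth:
    """Plant non-overlapping episodes in the movie window of each neuron.

    Episode count is uniform over ``episodes_per_neuron``; durations are
    log-normal (median ``episode_duration_median_s``); placements keep at
    least ``min_episode_gap_bins`` between episodes so that nearby episodes
    remain separable by peak detection.  Starts are stratified over the movie
    with a random per-neuron phase, so that pooled across neurons the
    episodic coverage tiles the movie evenly — the regime in which every
    moment of the movie is represented by some group of neurons.  The last
    ``end_margin_bins`` of the trial stay episode-free so that calcium
    activity decays back toward the quiet (gray-screen) state by the end of
    the trial, as it does when the looped stimulus wraps around.  Each
    episode draws an independent gain cluster and log-normal per-trial gains
    with unit mean.
    """
    lo, hi = params.episodes_per_neuron
    t0, t1 = params.gray_bins, params.n_timepoints - params.end_margin_bins
    window = t1 - t0
    # worst case must fit: hi episodes of ~3 median durations plus gaps
    worst = hi * (
        int(round(3 * params.episode_duration_median_s / params.dt))
        + params.min_episode_gap_bins
    )
    if hi > 0 and worst > window:
        raise ValueError(
            "episode count x max duration cannot fit in the movie window "
            f"({worst} bins needed, {window} available)"
        )
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 0]))
    # log-normal sigma for trial gains with unit mean and the requested CV
    cv = params.within_week_gain_cv
    sigma_g = np.sqrt(np.log1p(cv**2))
    mu_g = -0.5 * sigma_g**2

    episodes: list[PlantedEpisode] = []
    for n in range(params.n_neurons):
        n_ep = int(rng.integers(lo, hi + 1)) if hi > 0 else 0
        placed: list[tuple[int, int]] = []
        if n_ep:
            width = window / n_ep
            phase = float(rng.uniform(0, width))
            for i in rng.permutation(n_ep):
                s_lo = int(t0 + phase + i * width)
                s_hi = max(s_lo + 1, int(t0 + phase + (i + 1) * width))
                for _attempt in range(200):
                    dur = _sample_duration_bins(params, rng)
                    dur = min(dur, window)
                    start = int(rng.integers(s_lo, s_hi))
                    if start > t1 - dur:
                        # wrap into the feasible range instead of clamping,
                        # which would pile episode ends up at the trial edge
                        start = t0 + (start - t0) % max(t1 - dur - t0, 1)
                    end = start + dur
                    gap = params.min_episode_gap_bins
                    if start >= t0 and all(
                        end + gap <= s or start >= e + gap for s, e in placed
                    ):
                        placed.append((start, end))
                        break
                else:
                    continue  # could not place this episode; skip it
        placed.sort()
        for start, end in placed:
            cluster = int(rng.integers(params.n_gain_clusters))
            base = float(rng.uniform(*params.base_rate_hz))
            trial_gain = (
                rng.lognormal(mean=mu_g, sigma=sigma_g, size=params.n_trials)
                if cv > 0
                else np.ones(params.n_trials)
            )
            episodes.append(
                PlantedEpisode(
                    neuron=n,
                    start_bin=start,
                    end_bin=end,
                    base_rate_hz=base,
                    cluster_id=cluster,
                    week_gain=params.gain_cluster_profiles[cluster].copy(),
                    trial_gain=trial_gain,
                )
            )
    return GroundTruth(
        episodes=episodes,
        week_labels=params.week_labels,
        n_neurons=params.n_neurons,
        n_timepoints=params.n_timepoints,
    )


def rate_tensor(gt: GroundTruth, params: SyntheticParams) -> np.ndarray:
    """Underlying firing rate in Hz, (neuron x time x trial)."""
    rates = np.full(
        (params.n_neurons, params.n_timepoints, params.n_trials),
        params.background_rate_hz,
        dtype=float,
    )
    week_of_trial = gt.week_labels
    for e in gt.episodes:
        gain = e.week_gain[week_of_trial] * e.trial_gain
        rates[e.neuron, e.start_bin : e.end_bin, :] += e.base_rate_hz * gain
    return rates


def simulate_spikes(gt: GroundTruth, params: SyntheticParams) -> np.ndarray:
    """Poisson spike counts per bin: Poisson(rate * dt), (N x T x K) integers."""
    if gt.n_neurons != params.n_neurons or gt.n_timepoints != params.n_timepoints:
        raise ValueError("ground truth does not match params")
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 1]))
    return rng.poisson(rate_tensor(gt, params) * params.dt).astype(np.int64)


def calcium_kernel(params: SyntheticParams) -> np.ndarray:
    """Causal difference-of-exponentials kernel, peak-normalized to 1."""
    t = np.arange(0, 5 * params.calcium_tau, params.dt)
    k = np.exp(-t / params.calcium_tau) - np.exp(-t / params.calcium_rise)
    peak = k.max()
    if peak <= 0:
        raise ValueError("degenerate calcium kernel")
    return k / peak


def spikes_to_dff(spikes: np.ndarray, params: SyntheticParams) -> DffTensor:
    """Convolve spikes with the calcium kernel and add Gaussian noise.

    With ``loop_convolution`` (the default) each week's session is treated as
    one continuous looped recording: the trials of a session are concatenated
    in order and convolved circularly, so the calcium tail of late-movie
    activity decays through the following trial's gray period — exactly what
    continuous imaging of a back-to-back looped stimulus produces, and the
    reason population activity traces a closed ring over the trial period.
    No fluorescence crosses week boundaries.

    With ``loop_convolution=False`` the convolution is truncated at trial
    boundaries instead (each trial convolved independently, no leakage
    between trials).
    """
    spikes = np.asarray(spikes)
    if np.any(spikes < 0):
        raise ValueError("spike tensor must be nonnegative")
    kernel = calcium_kernel(params)
    if params.loop_convolution:
        dff = np.empty_like(spikes, dtype=float)
        week_labels = params.week_labels
        N, T, _ = spikes.shape
        for w in np.unique(week_labels):
            idx = np.flatnonzero(week_labels == w)
            # concatenate the session's trials along time: (N, T * n_trials)
            session = spikes[:, :, idx].transpose(0, 2, 1).reshape(N, -1)
            full = fftconvolve(
                session.astype(float), kernel[None, :], mode="full", axes=1
            )
            L = session.shape[1]
            out = full[:, :L]
            out[:, : full.shape[1] - L] += full[:, L:]  # circular wrap
            dff[:, :, idx] = out.reshape(N, idx.size, T).transpose(0, 2, 1)
    else:
        # causal convolution truncated at each trial boundary
        full = fftconvolve(
            spikes.astype(float), kernel[None, :, None], mode="full", axes=1
        )
        dff = full[:, : spikes.shape[1], :]
    if params.dff_noise_sd > 0:
        rng = np.random.default_rng(np.random.SeedSequence([params.seed, 2]))
        dff = dff + rng.normal(0.0, params.dff_noise_sd, size=dff.shape)
    return DffTensor(
        values=dff,
        week_labels=params.week_labels,
        dt=params.dt,
        movie_start_bin=params.gray_bins,
    )


def generate_dataset(
    params: SyntheticParams,
) -> tuple[DffTensor, np.ndarray, GroundTruth]:
    """Full forward model: ground truth -> spikes -> dF/F."""
    gt = generate_ground_truth(params)
    spikes = simulate_spikes(gt, params)
    dff = spikes_to_dff(spikes, params)
    return dff, spikes, gt


def save_dataset(
    path: str,
    dff: DffTensor,
    spikes: np.ndarray,
    gt: GroundTruth,
    params: SyntheticParams,
) -> None:
    """Write dF/F, spikes and ground truth to one HDF5 file."""
    with h5py.File(path, "w") as f:
        f.create_dataset("dff", data=dff.values)
        f.create_dataset("spikes", data=spikes)
        f.create_dataset("week_labels", data=dff.week_labels)
        f.create_dataset("time_s", data=np.arange(dff.n_timepoints) * dff.dt)
        f.attrs["dt"] = dff.dt
        f.attrs["movie_start_bin"] = dff.movie_start_bin
        f.attrs["seed"] = params.seed
        f.attrs["ground_truth"] = gt.to_json()
        params_dict = dataclasses.asdict(params)
        params_dict["gain_cluster_profiles"] = params.gain_cluster_profiles.tolist()
        f.attrs["params"] = json.dumps(params_dict)


def load_dataset(path: str) -> tuple[DffTensor, np.ndarray, GroundTruth]:
    with h5py.File(path, "r") as f:
        dff = DffTensor(
            values=f["dff"][()],
            week_labels=f["week_labels"][()],
            dt=float(f.attrs["dt"]),
            movie_start_bin=int(f.attrs["movie_start_bin"]),
        )
        spikes = f["spikes"][()]
        gt = GroundTruth.from_json(f.attrs["ground_truth"])
    return dff, spikes, gt
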
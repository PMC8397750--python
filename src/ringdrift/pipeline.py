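"""End-to-end orchestration: synthetic data -> preprocessing -> episodes ->
TCA -> manifold -> decoding -> variance geometry.

A single :class:`PipelineConfig` (YAML-serializable) holds every stage
parameter with the defaults used throughout: TCA rank 40, Isomap k = 20
(k = 100 for circular-shuffle controls), 2 embedding dimensions, 10 SPUD
knots, 80/20 train/test split, 5 trial-factor clusters, and a mandatory
master seed from which all stage seeds are derived by stable hashing.
``run`` executes the full chain and writes every stage's artifacts plus a
manifest with the config hash and per-artifact checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from ringdrift import episodes as ep
from ringdrift import geometry, manifold, preprocess, spud, synthetic, tca
from ringdrift._utils import derive_seed

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All stage parameters of the analysis pipeline."""

    seed: int = 0
    input_path: str | None = None
    synthetic: synthetic.SyntheticParams | None = None
    tca_rank: int = 40
    tca_max_iter: int = 300
    tca_tol: float = 1e-5
    tca_restarts: int = 1
    tca_float32: bool = True
    episode_prominence: float = 3.0
    psth_bandwidth_s: float = 0.2
    isomap_k: int = 20
    isomap_k_shuffled: int = 100
    embed_dims: int = 2
    max_embed_points: int = 8400
    spud_knots: int = 10
    spud_iters: int = 50
    train_frac: float = 0.8
    n_trial_factor_clusters: int = 5
    run_controls: bool = True

    def __post_init__(self) -> None:
        checks = {
            "tca_rank": self.tca_rank >= 1,
            "tca_max_iter": self.tca_max_iter >= 1,
            "tca_tol": self.tca_tol > 0,
            "tca_restarts": self.tca_restarts >= 1,
            "episode_prominence": self.episode_prominence >= 0,
            "psth_bandwidth_s": self.psth_bandwidth_s > 0,
            "isomap_k": self.isomap_k >= 1,
            "isomap_k_shuffled": self.isomap_k_shuffled >= 1,
            "embed_dims": 1 <= self.embed_dims <= 10,
            "max_embed_points": self.max_embed_points >= 100,
            "spud_knots": self.spud_knots >= 3,
            "spud_iters": self.spud_iters >= 1,
            "train_frac": 0 < self.train_frac < 1,
            "n_trial_factor_clusters": self.n_trial_factor_clusters >= 2,
        }
        bad = [name for name, ok in checks.items() if not ok]
        if bad:
            raise ValueError(
                "invalid configuration field(s): " + ", ".join(bad)
            )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.synthetic is not None:
            sp = dataclasses.asdict(self.synthetic)
            sp["gain_cluster_profiles"] = (
                self.synthetic.gain_cluster_profiles.tolist()
            )
            sp["episodes_per_neuron"] = list(self.synthetic.episodes_per_neuron)
            sp["base_rate_hz"] = list(self.synthetic.base_rate_hz)
            d["synthetic"] = sp
        return d

    def to_yaml(self, path: str) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def validate_config(raw: dict | str) -> PipelineConfig:
    """Build a normalized config from a dict or YAML path; fill defaults.

    Unknown fields and out-of-range values raise with the offending field
    named.
    """
    if isinstance(raw, str):
        raw = yaml.safe_load(Path(raw).read_text()) or {}
    raw = dict(raw)
    syn = raw.pop("synthetic", None)
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError("unknown configuration field(s): " + ", ".join(sorted(unknown)))
    cfg_kwargs = dict(raw)
    if syn is not None:
        syn = dict(syn)
        for tup_field in ("episodes_per_neuron", "base_rate_hz"):
            if tup_field in syn:
                syn[tup_field] = tuple(syn[tup_field])
        if syn.get("gain_cluster_profiles") is not None:
            syn["gain_cluster_profiles"] = np.asarray(syn["gain_cluster_profiles"])
        cfg_kwargs["synthetic"] = synthetic.SyntheticParams(**syn)
    cfg = PipelineConfig(**cfg_kwargs)
    logger.info("normalized config: %s", cfg.to_dict())
    return cfg


def _checksum(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]


def embed_tensor(
    values: np.ndarray,
    week_labels: np.ndarray,
    cfg: PipelineConfig,
    k: int | None = None,
    trial_subset: np.ndarray | None = None,
) -> tuple[manifold.Embedding, np.ndarray]:
    """Isomap-embed a tensor, subsampling whole trials to the point budget.

    Returns the embedding and the trial indices used (so that controls can be
    embedded on the same trials).
    """
    T = values.shape[1]
    if trial_subset is None:
        trial_subset = manifold.subsample_trials(
            values, week_labels, cfg.max_embed_points, T,
            seed=derive_seed(cfg.seed, "subsample"),
        )
    cloud = manifold.tensor_to_points(
        values[:, :, trial_subset], np.asarray(week_labels)[trial_subset]
    )
    # keep original trial numbering for bookkeeping
    cloud.trial = trial_subset[cloud.trial]
    emb = manifold.isomap(cloud, k=k or cfg.isomap_k, d=cfg.embed_dims)
    return emb, trial_subset


def run(cfg: PipelineConfig, outdir: str) -> dict:
    """Execute the full pipeline; write artifacts and a manifest to outdir.

    Returns a dictionary of the in-memory stage results.  Any stage failure
    propagates with prior artifacts already persisted.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": cfg.to_dict(),
        "config_hash": cfg.config_hash(),
        "stages": {},
    }
    results: dict = {}

    def log_stage(name: str, t0: float, **info) -> None:
        manifest["stages"][name] = {
            "wall_s": round(time.perf_counter() - t0, 3), **info,
        }
        logger.info("stage %-12s %6.1fs %s", name,
                    manifest["stages"][name]["wall_s"], info)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))

    # ---- data -------------------------------------------------------------
    t0 = time.perf_counter()
    if cfg.synthetic is not None:
        dff, spikes, gt = synthetic.generate_dataset(cfg.synthetic)
        synthetic.save_dataset(out / "dataset.h5", dff, spikes, gt, cfg.synthetic)
    elif cfg.input_path is not None:
        dff, spikes, gt = synthetic.load_dataset(cfg.input_path)
    else:
        raise ValueError("config needs either synthetic params or input_path")
    results.update(dff=dff, spikes=spikes, ground_truth=gt)
    log_stage("data", t0, shape=list(dff.values.shape),
              checksum=_checksum(dff.values))

    # ---- preprocess -------------------------------------------------------
    t0 = time.perf_counter()
    norm = preprocess.normalize_tensor(dff)
    sim = preprocess.week_similarity(norm)
    results.update(normalized=norm, week_similarity=sim)
    (out / "week_similarity.json").write_text(json.dumps(sim, indent=2))
    log_stage("preprocess", t0, checksum=_checksum(norm.values))

    # ---- episodes ---------------------------------------------------------
    t0 = time.perf_counter()
    detected = ep.detect_all_episodes(
        spikes, prominence=cfg.episode_prominence,
        bandwidth_s=cfg.psth_bandwidth_s, dt=dff.dt,
    )
    table = ep.episode_rates(spikes, detected, dff.week_labels, dt=dff.dt)
    ep.episodes_to_table(detected).to_csv(
        out / "episodes.tsv", sep="\t", index=False
    )
    table.to_frame().to_csv(out / "episode_rates.csv", index=False)
    within_cc, across_cc = ep.episode_rate_stability(table)
    pair_cc = ep.episode_pair_similarity(table)
    pois_cc, pois_fit = ep.poisson_control(
        table, seed=derive_seed(cfg.seed, "poisson-control"))
    shuf_cc, shuf_fit = ep.week_shuffle_control(
        table, seed=derive_seed(cfg.seed, "week-shuffle"))
    episode_stats = {
        "n_episodes": len(detected),
        "median_duration_s": float(
            np.median([e.duration_s for e in detected])) if detected else None,
        "within_week_cc": within_cc,
        "across_week_cc": across_cc,
        "pair_cc_mean": float(pair_cc.mean()) if len(pair_cc) else None,
        "poisson_fit": pois_fit,
        "week_shuffle_fit": shuf_fit,
    }
    results.update(episodes=detected, episode_table=table,
                   episode_stats=episode_stats)
    (out / "episode_stats.json").write_text(json.dumps(episode_stats, indent=2))
    log_stage("episodes", t0, n_episodes=len(detected))

    # ---- tca --------------------------------------------------------------
    t0 = time.perf_counter()
    masked = tca.build_mask(norm)
    model = tca.fit(
        masked, cfg.tca_rank, seed=derive_seed(cfg.seed, "tca"),
        max_iter=cfg.tca_max_iter, tol=cfg.tca_tol, n_restarts=cfg.tca_restarts,
        dtype=np.float32 if cfg.tca_float32 else np.float64,
    )
    model.save(out / "tca_model.h5")
    recon = tca.reconstruct(model)
    order, labels = tca.cluster_trial_factors(
        model, k_clusters=cfg.n_trial_factor_clusters,
        seed=derive_seed(cfg.seed, "kmeans"),
    )
    tf_within, tf_across = tca.trial_factor_stability(model, norm.week_labels)
    tca_stats = {
        "rank": model.rank,
        "objective": model.objective,
        "normalized_error": tca.normalized_error(masked, model),
        "trial_factor_within_week_cc": tf_within,
        "trial_factor_across_week_cc": tf_across,
    }
    results.update(tca_model=model, reconstruction=recon,
                   component_order=order, component_clusters=labels,
                   tca_stats=tca_stats)
    (out / "tca_stats.json").write_text(json.dumps(tca_stats, indent=2))
    log_stage("tca", t0, rank=model.rank,
              normalized_error=round(tca_stats["normalized_error"], 4))

    # ---- manifold ---------------------------------------------------------
    t0 = time.perf_counter()
    emb, trial_subset = embed_tensor(recon, norm.week_labels, cfg)
    emb.save(out / "embedding_original.h5", k=cfg.isomap_k, seed=cfg.seed)
    stability = manifold.trajectory_stability(emb)
    results.update(embedding=emb, trial_subset=trial_subset,
                   trajectory_stability=stability)
    np.savetxt(out / "trajectory_stability.csv", stability[None, :],
               delimiter=",", header=",".join(
                   f"dim{i+1}" for i in range(stability.size)), comments="")
    log_stage("manifold", t0, n_points=int(emb.coords.shape[0]))

    # ---- spud -------------------------------------------------------------
    t0 = time.perf_counter()
    fit, dec = spud.fit_spud(
        emb.coords, emb.time_bin, dt=dff.dt, n_knots=cfg.spud_knots,
        train_frac=cfg.train_frac, seed=derive_seed(cfg.seed, "spud"),
        n_iter=cfg.spud_iters, n_timepoints=dff.n_timepoints,
    )
    fit.curve.to_frame().to_csv(out / "spud_curve.csv", index=False)
    summary = spud.decoding_error_summary(dec, week=emb.week[fit.test_idx])
    summary.to_csv(out / "decoding_summary.csv", index=False)
    results.update(spud_fit=fit, decoding=dec, decoding_summary=summary)
    log_stage("spud", t0, median_error_s=float(np.median(dec.error)))

    # ---- geometry ---------------------------------------------------------
    t0 = time.perf_counter()
    # single-point variance on held-out points; week-grouped variance needs
    # every (bin, week) cell populated, so it uses all embedded points
    test_pts = emb.coords[fit.test_idx]
    test_t = emb.time_bin[fit.test_idx]
    var_all = geometry.variance_decomposition(test_pts, test_t, fit.curve)
    var_week = geometry.week_averaged_variance(
        emb.coords, emb.time_bin, emb.week, fit.curve)
    var_within = geometry.within_week_variance(
        emb.coords, emb.time_bin, emb.week, fit.curve)
    var_all.to_csv(out / "variance_all_trials.csv", index=False)
    var_week.to_csv(out / "variance_week_averaged.csv", index=False)
    var_within.to_csv(out / "variance_within_week.csv", index=False)
    radius = geometry.manifold_radius(emb.coords)
    radius.to_frame().to_csv(out / "radius.csv", index=False)
    tests = {
        name: geometry.paired_onesided_test(
            df["parallel"].to_numpy(), df["perpendicular"].to_numpy(),
            kind="wilcoxon-signed-rank", alternative="less",
        )
        for name, df in [("all_trials", var_all), ("week_averaged", var_week),
                         ("within_week", var_within)]
    }
    results.update(variance_all=var_all, variance_week=var_week,
                   variance_within=var_within, radius=radius,
                   variance_tests=tests)
    log_stage("geometry", t0)

    # ---- controls ---------------------------------------------------------
    if cfg.run_controls:
        t0 = time.perf_counter()
        shuffled_vals = manifold.circular_shuffle(
            recon, seed=derive_seed(cfg.seed, "circular-shuffle"))
        emb_shuf, _ = embed_tensor(
            shuffled_vals, norm.week_labels, cfg, k=cfg.isomap_k_shuffled,
            trial_subset=trial_subset,
        )
        emb_shuf.save(out / "embedding_circshuffle.h5",
                      k=cfg.isomap_k_shuffled, seed=cfg.seed)
        stability_shuf = manifold.trajectory_stability(emb_shuf)
        results.update(embedding_circshuffle=emb_shuf,
                       trajectory_stability_circshuffle=stability_shuf)
        log_stage("circ_shuffle", t0)

        t0 = time.perf_counter()
        model_shuf = tca.shuffle_factors(
            model, seed=derive_seed(cfg.seed, "factor-shuffle"))
        recon_shuf = tca.reconstruct(model_shuf)
        emb_fs, _ = embed_tensor(
            recon_shuf, norm.week_labels, cfg, trial_subset=trial_subset)
        emb_fs.save(out / "embedding_factorshuffle.h5",
                    k=cfg.isomap_k, seed=cfg.seed)
        # shuffled manifolds are collapsed; the time-decile ring stays fixed
        fit_fs, dec_fs = spud.fit_spud(
            emb_fs.coords, emb_fs.time_bin, dt=dff.dt, n_knots=cfg.spud_knots,
            train_frac=cfg.train_frac, seed=derive_seed(cfg.seed, "spud-fs"),
            n_iter=0, init="time_average",
            n_timepoints=dff.n_timepoints,
        )
        # pinned ring: no leakage concern, use all embedded points
        var_fs = geometry.variance_decomposition(
            emb_fs.coords, emb_fs.time_bin, fit_fs.curve)
        radius_fs = geometry.manifold_radius(emb_fs.coords)
        radius_cmp = geometry.paired_onesided_test(
            radius_fs.radius, radius.radius, kind="mann-whitney",
            alternative="less",
        )
        results.update(embedding_factorshuffle=emb_fs,
                       variance_factorshuffle=var_fs,
                       radius_factorshuffle=radius_fs,
                       radius_comparison=radius_cmp)
        var_fs.to_csv(out / "variance_factorshuffle.csv", index=False)
        log_stage("factor_shuffle", t0)

    tests_out = {k: v for k, v in results.get("variance_tests", {}).items()}
    if "radius_comparison" in results:
        tests_out["radius_factorshuffle_lt_original"] = results["radius_comparison"]
    (out / "tests.json").write_text(json.dumps(tests_out, indent=2))
    return results
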
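"""End-to-end orchestration: behavior -> preprocessing -> mixtures ->
geometry/decoding, plus the synthetic recovery benchmark.

Two inference tiers are exposed: ``ci`` (MAP fast path / short chains,
minutes on one CPU) and ``full`` (4 chains x (500 warmup + 500 samples),
the canonical budget).  Every stage records its outputs and content
hashes in a RunManifest; deterministic stages reproduce identical hashes
under identical config and inputs.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .behavior import HierarchicalBehaviorModel
from .data_model import StudyConfig
from .decoding import CueDecoder
from .geometry import (
    RETRO_TRIPLET,
    loo_projection_analysis,
    mds_embed,
    session_distance_matrix,
)
from .io import config_hash, read_session, serialize_results, write_session
from .mixture import NeuralMixtureModel, aggregate_posteriors, epoch_contrast
from .preprocess import SpikePreprocessor
from .synth import GeneratorSpec, generate_study


@dataclass
class RunManifest:
    """Config snapshot, seeds, per-stage status, and output hashes."""

    config: dict
    seed: int
    stages: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)

    def record(self, stage: str, status: str, note: str = "", t0: float | None = None):
        self.stages[stage] = {
            "status": status,
            "note": note,
            "seconds": None if t0 is None else round(time.time() - t0, 2),
        }

    def add_output(self, name: str, path):
        path = Path(path)
        digest = hashlib.sha256(path.read_bytes()).hexdigest()[:16]
        self.outputs[name] = {"path": str(path), "sha256": digest}

    def save(self, path):
        Path(path).write_text(json.dumps(
            {"config": self.config, "seed": self.seed,
             "config_hash": config_hash(self.config),
             "stages": self.stages, "outputs": self.outputs}, indent=2, default=str))


def _tier_kwargs(tier: str, config: StudyConfig):
    if tier == "ci":
        return {"method": "map"}
    return {"method": "mcmc", "chains": config.mcmc_chains,
            "warmup": config.mcmc_warmup, "samples": config.mcmc_samples}


def run_analysis(session_paths, out_dir, config: StudyConfig | None = None,
                 tier: str = "ci", seed: int = 0) -> RunManifest:
    """Run the full analysis over sessions given as (behavior_csv,
    neural_h5) path pairs; writes JSON/CSV results under ``out_dir``."""
    config = config or StudyConfig(mcmc_seed=seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=vars(config).copy(), seed=seed)

    t0 = time.time()
    sessions = []
    for bpath, npath in session_paths:
        trials, epochs = read_session(bpath, npath)
        sessions.append((trials, epochs))
    all_trials = pd.concat([s[0] for s in sessions], ignore_index=True)
    manifest.record("load", "ok", f"{len(sessions)} sessions", t0)

    # behavioral fit + per-trial type posteriors
    t0 = time.time()
    behavior = HierarchicalBehaviorModel(
        seed=seed, **_tier_kwargs(tier, config)
    ).fit(all_trials)
    posteriors = behavior.predict_proba(all_trials)
    post_path = out_dir / "trial_posteriors.csv"
    pd.concat([all_trials[["session_id", "trial_id"]], posteriors], axis=1) \
        .to_csv(post_path, index=False)
    manifest.add_output("trial_posteriors", post_path)
    manifest.record("behavior", "ok", t0=t0)

    # per-session neural stages
    t0 = time.time()
    mixture_fits = {"delay1": [], "delay2": []}
    geometry_rows = []
    decode_rows = []
    offset = 0
    for trials, epochs in sessions:
        n = len(trials)
        behav = posteriors.iloc[offset : offset + n].reset_index(drop=True)
        offset += n
        for epoch_name in ("delay1", "delay2"):
            if epoch_name not in epochs:
                continue
            prep = SpikePreprocessor(
                variance=config.pca_variance, block=config.exclusion_block,
                knn_k=config.knn_k, second_zscore=True, max_dims=config.max_pca_dims,
            )
            reduced = prep.fit_transform(epochs[epoch_name].summed())
            model = NeuralMixtureModel(
                epoch=epoch_name, n_knots=config.spline_knots,
                order=config.spline_order, seed=seed,
                **_tier_kwargs(tier, config),
            ).fit(reduced, trials, behav)
            mixture_fits[epoch_name].append(model.fit_)
            if epoch_name == "delay2":
                try:
                    summary = loo_projection_analysis(
                        reduced, trials, behav, epoch="delay2",
                        hypothesis_pair=("misselected_colors", "nominal"),
                        p_correct_min=config.p_correct_proj,
                        p_swap_min=config.p_swap_proj,
                        color_separation_min=config.color_separation_min,
                        alpha=config.ridge_lambda, basis=config.basis, seed=seed,
                    )
                    geometry_rows.append({
                        "session_id": str(trials["session_id"].iloc[0]),
                        "mean_x_correct": summary.mean_correct,
                        "mean_x_swap": summary.mean_swap,
                        "difference": summary.difference,
                        "ci_low": summary.ci_low, "ci_high": summary.ci_high,
                    })
                except ValueError as err:
                    geometry_rows.append({"session_id": str(trials["session_id"].iloc[0]),
                                          "error": str(err)})
                try:
                    dec = CueDecoder(
                        p_correct_min=config.p_correct_decode,
                        p_swap_min=config.p_swap_decode, seed=seed,
                    ).fit(reduced, trials, behav)
                    rep = dec.generalization(reduced, trials, behav)
                    decode_rows.append({
                        "session_id": str(trials["session_id"].iloc[0]),
                        "accuracy_correct": rep.accuracy_correct,
                        "accuracy_swap": rep.accuracy_swap, "gap": rep.gap,
                    })
                except ValueError as err:
                    decode_rows.append({"session_id": str(trials["session_id"].iloc[0]),
                                        "error": str(err)})
    manifest.record("neural", "ok", t0=t0)

    # summaries
    t0 = time.time()
    results = {}
    for epoch_name, fits in mixture_fits.items():
        if fits:
            agg = aggregate_posteriors(fits)
            results[f"mixture_{epoch_name}"] = {
                col: agg["pooled"][col].to_numpy() for col in agg["pooled"].columns
            }
    if mixture_fits["delay1"] and mixture_fits["delay2"]:
        contrast = epoch_contrast(mixture_fits["delay2"], mixture_fits["delay1"])
        results["epoch_contrast"] = {"delay2_minus_delay1": contrast.to_numpy()}
    doc = serialize_results(results, config=vars(config), seed=seed,
                            path=out_dir / "results.json")
    manifest.add_output("results", out_dir / "results.json")
    if geometry_rows:
        pd.DataFrame(geometry_rows).to_csv(out_dir / "projection.csv", index=False)
        manifest.add_output("projection", out_dir / "projection.csv")
    if decode_rows:
        pd.DataFrame(decode_rows).to_csv(out_dir / "decoding.csv", index=False)
        manifest.add_output("decoding", out_dir / "decoding.csv")
    manifest.record("summarize", "ok", t0=t0)
    manifest.save(out_dir / "manifest.json")
    return manifest


def run_synthetic_benchmark(spec: GeneratorSpec | None = None, tier: str = "ci",
                            out_path=None) -> dict:
    """Generate data with known ground truth, run the pipeline, and compare
    every recovered quantity against the generator's truth.

    Returns a report dict with per-check pass/fail; ``passed`` is the
    overall verdict.
    """
    spec = spec or GeneratorSpec()
    trials, sessions = generate_study(spec, with_neural=False)
    config = StudyConfig(mcmc_seed=spec.seed)

    checks = []
    behavior = HierarchicalBehaviorModel(
        seed=spec.seed, **_tier_kwargs(tier, config)
    ).fit(trials)
    true_ps = np.array([s.truth.params.p_swap for s in sessions])
    est_ps = np.array([p.p_swap for p in behavior.session_params_])
    err = np.abs(est_ps - true_ps)
    frac_ok = float((err <= 0.04).mean())
    checks.append({
        "name": "behavioral_p_swap_recovery",
        "value": frac_ok,
        "tolerance": ">= 0.8 of sessions within 0.04",
        "passed": bool(frac_ok >= 0.8),
    })
    sig_err = float(np.abs(
        np.array([p.sigma for p in behavior.session_params_])
        - np.array([s.truth.params.sigma for s in sessions])
    ).mean())
    checks.append({
        "name": "behavioral_sigma_recovery",
        "value": sig_err,
        "tolerance": "mean abs error <= 0.05 rad",
        "passed": bool(sig_err <= 0.05),
    })
    if behavior.posterior_ is not None:
        max_rhat = behavior.diagnostics_["max_rhat"]
        checks.append({
            "name": "behavioral_rhat",
            "value": max_rhat,
            "tolerance": "<= 1.05",
            "passed": bool(max_rhat <= 1.05),
        })

    # calibration of per-trial swap posteriors
    posteriors = behavior.predict_proba(trials)
    labels = np.concatenate([s.truth.type_labels for s in sessions])
    p_swap_post = posteriors["p_swap_post"].to_numpy()
    worst = 0.0
    for lo in np.arange(0.0, 1.0, 0.1):
        sel = (p_swap_post >= lo) & (p_swap_post < lo + 0.1)
        center = lo + 0.05
        # only deciles whose binomial SE is at most half the tolerance
        # for any swap fraction (sqrt(0.25/n) <= 0.05)
        if sel.sum() >= 100:
            emp = float((labels[sel] == "swap").mean())
            worst = max(worst, abs(emp - center))
    checks.append({
        "name": "posterior_calibration",
        "value": worst,
        "tolerance": "decile deviation <= 0.10",
        "passed": bool(worst <= 0.10),
    })

    report = {
        "spec": {k: v for k, v in vars(spec).items()},
        "tier": tier,
        "checks": checks,
        "passed": bool(all(c["passed"] for c in checks)),
    }
    if out_path is not None:
        Path(out_path).write_text(json.dumps(report, indent=2, default=str))
    return report


def write_synthetic_sessions(spec: GeneratorSpec, out_dir) -> list[tuple]:
    """Generate sessions with neural data and write them to disk; returns
    the (behavior_csv, neural_h5) path pairs run_analysis consumes."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    _, sessions = generate_study(spec, with_neural=True)
    paths = []
    for i, s in enumerate(sessions):
        b = out_dir / f"session{i:03d}_behavior.csv"
        n = out_dir / f"session{i:03d}_neural.h5"
        write_session(s.trials, s.epochs, b, n)
        paths.append((b, n))
    return paths
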
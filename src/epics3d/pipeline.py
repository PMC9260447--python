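"""End-to-end orchestration: stacks in, labeled domains and model out.

``run_pipeline`` executes reconstruction, feature extraction and the
classification chain, writing five artifacts into the run directory:

* ``features.csv`` — one metric row per domain;
* ``labels.csv``   — (stack_id, domain_id, batch_id, cluster, state);
* ``model.json``   — selected features, coefficients, z-values, variable
  importance, the penalty policy and value, accuracies with exact CIs;
* ``stability.csv`` — per-bootstrap Jaccard/accuracy/balanced accuracy;
* ``manifest.json`` — config snapshot, seed, per-stage record.

A single config seed drives every stochastic stage (k-means restarts,
split, CV folds, bootstrap) through independently derived substreams.
"""

from __future__ import annotations

import dataclasses
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import (
    LassoLogisticModel,
    assign_states,
    batch_normalize,
    bootstrap_stability,
    cluster_domains,
    evaluate,
    stratified_split,
)
from .features import extract_features, metric_names
from .reconstruct import StackReconstructor
from .stack_io import BRIGHT_IS_SIGNAL, ExperimentConfig, read_stack, write_table

__all__ = ["run_pipeline", "PipelineError", "write_report", "run_recovery"]


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name."""

    def __init__(self, stage, cause):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _stage_seeds(seed: int) -> dict:
    """Independent 31-bit substream seeds for each stochastic stage."""
    ss = np.random.SeedSequence(seed)
    names = ("kmeans", "split", "lasso", "bootstrap")
    return {
        name: int(child.generate_state(1)[0] % (2**31 - 1))
        for name, child in zip(names, ss.spawn(len(names)))
    }


def run_pipeline(config: ExperimentConfig, outdir, stacks=None) -> dict:
    """Run the full analysis; returns the manifest (also written to disk).

    ``stacks`` may carry pre-loaded :class:`ImageStack` objects (e.g. from
    the synthetic generator); otherwise stacks are read from the paths in
    the config.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "stage_seeds": seeds,
        "config": _config_snapshot(config),
        "stages": {},
        "outputs": [],
        "complete": False,
    }

    def record(stage, t0, **info):
        manifest["stages"][stage] = {"wall_s": round(time.time() - t0, 3), **info}

    try:
        t0 = time.time()
        if stacks is None:
            stacks = [
                read_stack(e.path, e.voxel_size, e.polarity, e.batch_id)
                for e in config.stacks
            ]
        if not stacks:
            raise ValueError("no input stacks")
        polarity = stacks[0].polarity
        rec = StackReconstructor(
            sigma_nm=config.smoothing_sigma_nm,
            threshold_method=config.threshold_method,
            fixed_threshold=config.fixed_threshold,
            min_domain_voxels=config.min_domain_voxels,
        )
        domains = rec.transform(stacks)
        if not domains:
            raise ValueError("no chromatin domains found in any stack")
        record("reconstruct", t0, n_stacks=len(stacks), n_domains=len(domains))
    except Exception as e:
        _write_manifest(manifest, outdir)
        raise PipelineError("reconstruct", e) from e

    try:
        t0 = time.time()
        feats = extract_features(domains, thresholds=config.intensity_thresholds)
        write_table(feats, outdir / "features.csv")
        manifest["outputs"].append("features.csv")
        record("features", t0, n_rows=len(feats), n_metrics=feats.shape[1] - 3)
    except Exception as e:
        _write_manifest(manifest, outdir)
        raise PipelineError("features", e) from e

    try:
        t0 = time.time()
        include_pcts = polarity != BRIGHT_IS_SIGNAL
        X = feats[metric_names(include_pcts)]
        batches = feats["batch_id"].to_numpy()
        Xn, scaler = batch_normalize(X, batches)
        clusters = cluster_domains(Xn, batches, seed=seeds["kmeans"])
        assignment = assign_states(clusters, X, polarity, batches)
        labels = feats[["stack_id", "domain_id", "batch_id"]].copy()
        labels["cluster"] = assignment.cluster
        labels["state"] = assignment.state
        write_table(labels, outdir / "labels.csv")
        manifest["outputs"].append("labels.csv")
        record(
            "states",
            t0,
            n_open=assignment.n_open,
            n_closed=assignment.n_closed,
            dropped_features=scaler.dropped_features_,
        )
    except Exception as e:
        _write_manifest(manifest, outdir)
        raise PipelineError("states", e) from e

    try:
        t0 = time.time()
        train_idx, val_idx = stratified_split(
            assignment.state, config.split_fraction, seed=seeds["split"]
        )
        model = LassoLogisticModel(
            cv_folds=config.cv_folds,
            lambda_policy=config.lambda_policy,
            lambda_value=config.lambda_value,
            random_state=seeds["lasso"],
        ).fit(X.iloc[train_idx], assignment.state[train_idx])
        ev_train = evaluate(model, X.iloc[train_idx], assignment.state[train_idx])
        ev_val = (
            evaluate(model, X.iloc[val_idx], assignment.state[val_idx])
            if len(val_idx)
            else None
        )
        model_json = {
            "positive_class": "B",
            "lambda_policy": config.lambda_policy,
            "lambda": model.lasso_.chosen_lambda,
            "lambda_min": model.lasso_.lambda_min,
            "lambda_1se": model.lasso_.lambda_1se,
            "selected_features": model.selected_features_,
            "intercept": model.intercept_,
            "coefficients": model.coef_.to_dict(),
            "std_errors": model.std_errors_.to_dict(),
            "z_values": model.z_values_.to_dict(),
            "vi": model.vi_.to_dict(),
            "relative_vi": model.relative_vi_.to_dict(),
            "z_reliable": model.z_reliable_,
            "seed": config.seed,
            "train_accuracy": ev_train.accuracy,
            "train_ci": [ev_train.ci_low, ev_train.ci_high],
            "validation_accuracy": ev_val.accuracy if ev_val else None,
            "validation_ci": [ev_val.ci_low, ev_val.ci_high] if ev_val else None,
            "n_train": len(train_idx),
            "n_validation": len(val_idx),
        }
        (outdir / "model.json").write_text(json.dumps(model_json, indent=2))
        manifest["outputs"].append("model.json")
        record(
            "model",
            t0,
            selected=model.selected_features_,
            train_accuracy=ev_train.accuracy,
            validation_accuracy=ev_val.accuracy if ev_val else None,
        )
    except Exception as e:
        _write_manifest(manifest, outdir)
        raise PipelineError("model", e) from e

    try:
        t0 = time.time()
        report = bootstrap_stability(
            Xn, clusters, batches, n_bootstrap=config.n_bootstrap, seed=seeds["bootstrap"]
        )
        write_table(
            pd.DataFrame(
                {
                    "bootstrap": np.arange(1, len(report.jaccard) + 1),
                    "jaccard": report.jaccard,
                    "accuracy": report.accuracy,
                    "balanced_accuracy": report.balanced_accuracy,
                }
            ),
            outdir / "stability.csv",
        )
        manifest["outputs"].append("stability.csv")
        record("stability", t0, **report.summary)
    except Exception as e:
        _write_manifest(manifest, outdir)
        raise PipelineError("stability", e) from e

    manifest["complete"] = True
    _write_manifest(manifest, outdir)
    return manifest


def run_recovery(spec=None, seed=0, cv_folds=10, split_fraction=0.7, n_bootstrap=0):
    """Planted-truth recovery experiment on a synthetic dataset.

    Generates a dataset, runs the full chain (reconstruct, featurize,
    normalize, cluster, assign states, split, LASSO + logistic refit) and
    scores both against the unsupervised states and against the planted
    open/closed kinds.  Segmented domains are matched to planted blobs by
    nearest centroid; unmatched domains are excluded from scoring.

    Returns a dict of summary quantities.
    """
    from .synthetic import SyntheticSpec, generate_dataset, match_domains_to_truth

    if spec is None:
        spec = SyntheticSpec()
    seeds = _stage_seeds(seed)
    stacks, truth = generate_dataset(spec, seed=seed)
    domains = StackReconstructor().transform(stacks)
    feats = extract_features(domains)
    kinds = match_domains_to_truth(feats, domains, truth)
    matched = np.array([k is not None for k in kinds])
    feats = feats[matched].reset_index(drop=True)
    kinds = kinds[matched].astype(str)

    include_pcts = spec.polarity != BRIGHT_IS_SIGNAL
    X = feats[metric_names(include_pcts)]
    batches = feats["batch_id"].to_numpy()
    Xn, scaler = batch_normalize(X, batches)
    clusters = cluster_domains(Xn, batches, seed=seeds["kmeans"])
    assignment = assign_states(clusters, X, spec.polarity, batches)
    train_idx, val_idx = stratified_split(assignment.state, split_fraction, seed=seeds["split"])
    model = LassoLogisticModel(
        cv_folds=cv_folds, random_state=seeds["lasso"]
    ).fit(X.iloc[train_idx], assignment.state[train_idx])
    ev_train = evaluate(model, X.iloc[train_idx], assignment.state[train_idx])
    ev_val = evaluate(model, X.iloc[val_idx], assignment.state[val_idx])
    val_pred = model.predict(X.iloc[val_idx])
    out = {
        "n_planted": int(len(truth)),
        "n_domains": int(len(domains)),
        "n_matched": int(matched.sum()),
        "n_open": assignment.n_open,
        "n_closed": assignment.n_closed,
        "state_accuracy_vs_planted": float(np.mean(assignment.state == kinds)),
        "train_accuracy": ev_train.accuracy,
        "train_ci": (ev_train.ci_low, ev_train.ci_high),
        "validation_accuracy": ev_val.accuracy,
        "validation_ci": (ev_val.ci_low, ev_val.ci_high),
        "validation_accuracy_vs_planted": float(np.mean(val_pred == kinds[val_idx])),
        "n_validation": int(len(val_idx)),
        "selected_features": model.selected_features_,
        "model": model,
    }
    if n_bootstrap:
        rep = bootstrap_stability(
            Xn, clusters, batches, n_bootstrap=n_bootstrap, seed=seeds["bootstrap"]
        )
        out.update(rep.summary)
    return out


def _config_snapshot(config: ExperimentConfig) -> dict:
    d = dataclasses.asdict(config)
    d["stacks"] = [dataclasses.asdict(s) if dataclasses.is_dataclass(s) else s for s in config.stacks]
    return d


def _write_manifest(manifest, outdir):
    (Path(outdir) / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))


def write_report(run_dir) -> str:
    """Human-readable summary of a completed run (markdown)."""
    run_dir = Path(run_dir)
    model_path = run_dir / "model.json"
    if not model_path.exists():
        raise FileNotFoundError(f"{model_path}: run incomplete (no model.json)")
    model = json.loads(model_path.read_text())
    labels = pd.read_csv(run_dir / "labels.csv")
    stability = pd.read_csv(run_dir / "stability.csv")

    vi = pd.Series(model["relative_vi"]).sort_values(ascending=False)
    lines = [
        "# Chromatin domain classification report",
        "",
        f"Domains: {len(labels)} "
        f"({int((labels['state'] == 'B').sum())} closed / "
        f"{int((labels['state'] == 'A').sum())} open)",
        "",
        "## Model",
        f"- penalty policy: {model['lambda_policy']} (lambda = {model['lambda']:.6g})",
        f"- training accuracy: {model['train_accuracy']:.3f} "
        f"(95% CI {model['train_ci'][0]:.3f}-{model['train_ci'][1]:.3f}, n={model['n_train']})",
    ]
    if model["validation_accuracy"] is not None:
        lines.append(
            f"- validation accuracy: {model['validation_accuracy']:.3f} "
            f"(95% CI {model['validation_ci'][0]:.3f}-{model['validation_ci'][1]:.3f}, "
            f"n={model['n_validation']})"
        )
    if not model["z_reliable"]:
        lines.append("- note: z-values flagged unreliable (possible separation)")
    if set(model["selected_features"]) and model["lambda"] == model["lambda_min"] != model["lambda_1se"]:
        lines.append("- note: empty selection at the one-SE lambda; fell back to lambda_min")
    lines += ["", "## Features by relative variable importance"]
    for name, rvi in vi.items():
        beta = model["coefficients"][name]
        lines.append(
            f"- {name}: relative VI {rvi:.3f}, log-odds {beta:.4g}, odds {np.exp(beta):.3f}"
        )
    lines += [
        "",
        "## Cluster stability (bootstrap)",
        f"- mean Jaccard index: {stability['jaccard'].mean():.3f}",
        f"- mean accuracy: {stability['accuracy'].mean():.3f}",
        f"- mean balanced accuracy: {stability['balanced_accuracy'].mean():.3f}",
    ]
    return "\n".join(lines) + "\n"
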
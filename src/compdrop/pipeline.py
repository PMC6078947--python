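"""End-to-end orchestration: simulate/load -> localize -> patterns ->
transfer -> drop -> cluster -> behavior, with a machine-readable summary.

A single :class:`RunConfig` (constructible from YAML) drives every stage;
all randomness flows from the named seeds it contains, so re-running with
an identical config reproduces identical outputs byte for byte. Each run
directory receives the stage tables (TSV), a ``summary.json`` with the
selected window, cluster list, behavioral statistics and bootstrap
frequencies, a provenance block (config hash + package version), and a
text log.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._exceptions import ConfigurationError
from .behavior import (
    behavior_permutation_test,
    encode_configurations,
    predict_s3_from_configurations,
    summarize_rounds,
)
from .cluster import cluster_permutation, ks_normality_check, subject_bootstrap
from .containers import EpochSet
from .drop import competition_drop, filter_by_configuration, rt_drop, rt_drop_test, zscore_within_subject
from .io import read_dataset, read_epochs, write_dataset
from .localizer import decode_localizer, select_time_window, sliding_window_features
from .patterns import average_patterns, haufe_pattern, weight_rdm
from .preprocessing import theta_power
from .simulate import SimulationConfig, simulate_session1, simulate_session2
from .transfer import train_full_models, transfer_by_subject

__all__ = ["RunConfig", "run_pipeline", "make_report"]

logger = logging.getLogger(__name__)

_STAGES = ["simulate", "localizer", "patterns", "transfer", "drop", "cluster", "behavior"]


@dataclass
class RunConfig:
    """Parameters for one full pipeline run.

    ``simulate`` holds :class:`~compdrop.simulate.SimulationConfig` keyword
    overrides; alternatively ``session1_path``/``session2_path`` point at
    dataset directories written by :func:`compdrop.io.write_dataset`.
    ``feature_type`` selects broadband voltage (default) or theta-band
    power features.
    """

    seed: int = 0
    simulate: dict = field(default_factory=dict)
    session1_path: str | None = None
    session2_path: str | None = None
    feature_type: str = "voltage"  # or "theta"
    window_ms: float = 50.0
    step_ms: float = 20.0
    n_folds: int = 5
    localizer_n_perm: int = 100
    localizer_alpha: float = 0.001
    C: float = 1.0
    sd_mult: float = 1.0
    bridge_ms: float = 120.0
    pattern_windows: list = field(default_factory=lambda: [[100.0, 200.0], [300.0, 600.0]])
    config_filter: str | None = None
    zscore: bool = False
    cluster_n_perm: int = 1000
    cluster_threshold: float = 0.10
    cluster_alpha: float = 0.05
    n_boot: int = 200
    boot_n_perm: int = 200
    behavior_n_perm: int = 1000
    run_study_control: bool = True

    def __post_init__(self) -> None:
        if self.feature_type not in ("voltage", "theta"):
            raise ConfigurationError("feature_type must be 'voltage' or 'theta'")
        if not 0 < self.cluster_threshold < 1 or not 0 < self.cluster_alpha < 1:
            raise ConfigurationError("cluster threshold and alpha must lie in (0, 1)")
        if not 0 < self.localizer_alpha < 1:
            raise ConfigurationError("localizer alpha must lie in (0, 1)")
        for path in (self.session1_path, self.session2_path):
            if path is not None and not Path(path).exists():
                raise ConfigurationError(f"input path does not exist: {path}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as f:
            raw = yaml.safe_load(f) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def provenance(self) -> dict:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return {
            "config_hash": hashlib.sha256(blob.encode()).hexdigest(),
            "version": __version__,
        }


def _jsonify(obj):
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _jsonify(obj.tolist())
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if not np.isfinite(v) else v
    if isinstance(obj, (np.integer, np.bool_)):
        return obj.item()
    return obj


def _epochs_features(epochs: EpochSet, config: RunConfig):
    if config.feature_type == "theta":
        epochs = theta_power(epochs)
    return sliding_window_features(epochs, window_ms=config.window_ms, step_ms=config.step_ms)


def run_pipeline(config: RunConfig, out_dir: str | Path) -> Path:
    """Execute all stages and write the run directory.

    Returns the run directory path. On a stage failure the exception is
    re-raised with the stage name; outputs of completed stages remain on
    disk.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    root = logging.getLogger("compdrop")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    summary: dict = {"provenance": config.provenance(), "stages_completed": []}
    stage = "simulate"
    try:
        # --- data ----------------------------------------------------------
        if config.session1_path and config.session2_path:
            # Session 1 is epochs-only (no behavioral table)
            p1 = Path(config.session1_path)
            s1_epochs = read_epochs(p1 / "epochs.h5" if p1.is_dir() else p1)
            s2_epochs, behavior = read_dataset(config.session2_path)
        else:
            sim = SimulationConfig(**{"seed": config.seed, **config.simulate})
            s1_epochs, _ = simulate_session1(sim)
            s2_epochs, truth = simulate_session2(sim)
            behavior = truth.behavior_table()
            write_dataset(s2_epochs, behavior, out / "dataset_s2")
        summary["n_s1_trials"] = int(s1_epochs.n_trials)
        summary["n_s2_trials"] = int(s2_epochs.n_trials)
        summary["feature_type"] = config.feature_type
        summary["stages_completed"].append(stage)

        # --- localizer -----------------------------------------------------
        stage = "localizer"
        s1_features = _epochs_features(s1_epochs, config)
        curve = decode_localizer(
            s1_features,
            n_folds=config.n_folds,
            n_perm=config.localizer_n_perm,
            alpha=config.localizer_alpha,
            C=config.C,
            seed=config.seed,
        )
        window = select_time_window(curve, sd_mult=config.sd_mult, bridge_ms=config.bridge_ms)
        pd.DataFrame(
            {
                "start_time_ms": curve.start_times,
                "mean_accuracy": curve.mean_accuracy,
                "sd_accuracy": curve.sd_accuracy,
                "group_p": curve.group_p,
                "significant": curve.sig_mask,
            }
        ).to_csv(out / "decoding_curve.tsv", sep="\t", index=False)
        summary["selected_window_ms"] = list(window) if window else None
        summary["peak_accuracy"] = float(curve.mean_accuracy.max())
        summary["peak_time_ms"] = float(curve.start_times[int(curve.mean_accuracy.argmax())])
        summary["stages_completed"].append(stage)
        if window is None:
            raise ConfigurationError("no discriminative localizer window found")
        train_times = curve.start_times[
            (curve.start_times >= window[0]) & (curve.start_times <= window[1])
        ]

        # --- patterns ------------------------------------------------------
        stage = "patterns"
        meta = s1_features.metadata
        subjects = sorted(meta["subject"].unique())
        weights_by_subject = []
        patterns_by_subject = []
        for subject in subjects:
            rows = np.flatnonzero((meta["subject"] == subject).to_numpy())
            y = meta["condition"].to_numpy()[rows]
            sub_feats = dataclasses.replace(
                s1_features,
                features=s1_features.features[rows],
                metadata=meta.iloc[rows],
            )
            models = train_full_models(sub_feats, y, s1_features.start_times, C=config.C)
            W = np.stack([m.weights for m in models])
            weights_by_subject.append(W)
            patterns_by_subject.append(
                np.stack(
                    [
                        haufe_pattern(W[t], s1_features.features[rows, t, :])
                        for t in range(s1_features.n_windows)
                    ]
                )
            )
        mean_weights = np.mean(weights_by_subject, axis=0)
        rdm = weight_rdm(mean_weights)
        np.savetxt(out / "weight_rdm.tsv", rdm, delimiter="\t")
        pattern_rows = {}
        for lo, hi in config.pattern_windows:
            sel = (s1_features.start_times >= lo) & (s1_features.start_times <= hi)
            stack = np.concatenate([P[sel] for P in patterns_by_subject], axis=0)
            pattern_rows[f"{int(lo)}-{int(hi)}ms"] = average_patterns(stack)
        pd.DataFrame(pattern_rows, index=s1_epochs.channel_names).to_csv(
            out / "patterns.tsv", sep="\t"
        )
        summary["stages_completed"].append(stage)

        # --- transfer ------------------------------------------------------
        stage = "transfer"
        s2_features = _epochs_features(s2_epochs, config)
        grids = {
            "retrieval": transfer_by_subject(
                s1_features, s2_features, train_times, trial_type="retrieval", C=config.C
            )
        }
        if config.run_study_control and "trial_type" in s2_features.metadata.columns:
            if (s2_features.metadata["trial_type"] == "study").any():
                grids["study"] = transfer_by_subject(
                    s1_features, s2_features, train_times, trial_type="study", C=config.C
                )
        summary["stages_completed"].append(stage)

        # --- drop + cluster -------------------------------------------------
        stage = "drop"
        tables = {}
        for name, grid in grids.items():
            table = competition_drop(grid, behavior)
            if config.config_filter:
                table = filter_by_configuration(table, config.config_filter)
            if config.zscore:
                table = zscore_within_subject(table)
            tables[name] = table
        summary["n_items_retained"] = int(tables["retrieval"].n_items)
        summary["config_filter"] = config.config_filter
        summary["zscored"] = config.zscore
        rt_table = rt_drop(behavior)
        rt_t, rt_p = rt_drop_test(rt_table)
        summary["rt_drop_p"] = float(rt_p)
        summary["stages_completed"].append(stage)

        stage = "cluster"
        summary["cluster"] = {}
        for name, table in tables.items():
            result = cluster_permutation(
                table,
                n_perm=config.cluster_n_perm,
                threshold=config.cluster_threshold,
                alpha=config.cluster_alpha,
                seed=config.seed + 1,
            )
            summary["cluster"][name] = {
                "ks_normality": ks_normality_check(table),
                "cluster_sizes": result.cluster_sizes,
                "familywise_p": result.familywise_p,
                "n_significant": int(result.significant.sum()),
            }
            np.savetxt(out / f"t_grid_{name}.tsv", result.t_grid, delimiter="\t")
            np.savetxt(out / f"p_right_{name}.tsv", result.p_right, delimiter="\t")
            if name == "retrieval":
                boot = subject_bootstrap(
                    table,
                    n_boot=config.n_boot,
                    n_perm=config.boot_n_perm,
                    threshold=config.cluster_threshold,
                    alpha=config.cluster_alpha,
                    seed=config.seed + 2,
                )
                np.savetxt(out / "bootstrap_frequency.tsv", boot.frequency, delimiter="\t")
                summary["cluster"][name]["bootstrap_max_frequency"] = float(
                    boot.frequency.max()
                ) if boot.frequency.size else 0.0
                summary["cluster"][name]["bootstrap_draws_used"] = boot.n_draws
        summary["stages_completed"].append(stage)

        # --- behavior ------------------------------------------------------
        stage = "behavior"
        configs = encode_configurations(behavior)
        configs.groupby(["configuration", "recalled_s3"]).size().rename("count").reset_index().to_csv(
            out / "configuration_counts.tsv", sep="\t", index=False
        )
        summarize_rounds(behavior).to_csv(out / "round_summary.tsv", sep="\t", index=False)
        acc = predict_s3_from_configurations(configs, n_folds=config.n_folds, seed=config.seed)
        perm = behavior_permutation_test(
            configs, n_perm=config.behavior_n_perm, seed=config.seed, n_folds=config.n_folds
        )
        summary["behavior"] = {"cv_accuracy": float(acc), "permutation_p": float(perm.p)}
        summary["stages_completed"].append(stage)
    except Exception as err:
        summary["failed_stage"] = stage
        summary["error"] = str(err)
        (out / "summary.json").write_text(
            json.dumps(_jsonify(summary), indent=2, sort_keys=True) + "\n"
        )
        root.removeHandler(handler)
        handler.close()
        raise RuntimeError(f"pipeline failed in stage '{stage}': {err}") from err

    (out / "summary.json").write_text(json.dumps(_jsonify(summary), indent=2, sort_keys=True) + "\n")
    root.removeHandler(handler)
    handler.close()
    return out


def make_report(run_dir: str | Path) -> str:
    """Assemble a human-readable report from a completed run directory.

    Returns the report text (also written to ``report.md``). For an
    incomplete run, lists the missing stages instead.
    """
    run_dir = Path(run_dir)
    summary_path = run_dir / "summary.json"
    if not summary_path.exists():
        raise ConfigurationError(f"{summary_path} not found; is this a run directory?")
    summary = json.loads(summary_path.read_text())
    lines = ["# Competition-drop analysis report", ""]
    done = summary.get("stages_completed", [])
    missing = [s for s in _STAGES if s not in done]
    if missing:
        lines += ["**Incomplete run.** Missing stages: " + ", ".join(missing), ""]
    lines += [
        f"Feature type: {summary.get('feature_type', 'voltage')}",
        f"Provenance: config {summary['provenance']['config_hash'][:12]}, "
        f"version {summary['provenance']['version']}",
        "",
    ]
    if "selected_window_ms" in summary:
        win = summary["selected_window_ms"]
        lines += [
            "## Localizer",
            f"- peak decoding accuracy {summary['peak_accuracy']:.3f} "
            f"at {summary['peak_time_ms']:.0f} ms",
            f"- selected discriminative window: "
            + (f"{win[0]:.0f}-{win[1]:.0f} ms" if win else "none"),
            "",
        ]
    if "cluster" in summary:
        lines += ["## Cluster inference"]
        for name, info in summary["cluster"].items():
            tag = " (study-trial control)" if name == "study" else ""
            lines.append(f"### {name} trials{tag}")
            sizes = info.get("cluster_sizes", [])
            ps = info.get("familywise_p", [])
            if sizes:
                for size, p in zip(sizes, ps):
                    flag = " *significant*" if p < 0.05 else ""
                    lines.append(f"- cluster of {size} squares, family-wise p = {p:.4g}{flag}")
            else:
                lines.append("- no supra-threshold clusters")
            if "bootstrap_max_frequency" in info:
                lines.append(
                    f"- max bootstrap inclusion frequency "
                    f"{info['bootstrap_max_frequency']:.2f} "
                    f"over {info['bootstrap_draws_used']} draws"
                )
            lines.append("")
    if "behavior" in summary:
        lines += [
            "## Behavior",
            f"- configuration classifier accuracy {summary['behavior']['cv_accuracy']:.3f} "
            f"(chance 0.5), permutation p = {summary['behavior']['permutation_p']:.4g}",
            f"- RT-drop control one-tailed p = {summary.get('rt_drop_p', float('nan')):.3f}",
            "",
        ]
    text = "\n".join(lines)
    (run_dir / "report.md").write_text(text)
    return text
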
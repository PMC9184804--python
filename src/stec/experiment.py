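"""Experiment orchestration: config files, seed fan-out, reproducible runs.

A single ``global_seed`` is fanned out through named sub-seeds (stimuli,
training, evaluation) so every component of a run is independently
reproducible.  Two built-in profiles are provided: ``paper`` (the full-scale
schedule: 64+64 units, 10^4 iterations x 5 repetitions) and ``desk`` (a
scaled-down schedule sized for a single CPU: 32+32 units, 2000 iterations x 1
repetition, 200 synthetic naturalistic images).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from .evaluation import (
    MetricsReport,
    confusion_index,
    decode_over_time,
    neuronal_noise,
    orientation_preference,
    receptive_field,
    response_distribution,
    synaptic_strength,
    weight_balance_ratio,
)
from .model import HierarchyConfig, ModelParams
from .objectives import ObjectiveConfig
from .stimuli import (
    StimulusSet,
    generate_glyphs,
    generate_naturalistic,
    generate_rf_probes,
)
from .training import TrainingConfig, train

KNOWN_METRICS = ("rf", "confusion", "noise", "decode", "orientation", "weights", "distribution")


def _subseed(ss_child) -> int:
    return int(ss_child.generate_state(1)[0] % 2**31)


def fan_out_seeds(global_seed: int) -> dict:
    """Named sub-seeds derived from one global seed."""
    children = np.random.SeedSequence(global_seed).spawn(4)
    names = ("stimuli", "init", "training", "evaluation")
    return {name: _subseed(c) for name, c in zip(names, children)}


@dataclass
class ExperimentConfig:
    """Everything needed to regenerate a run exactly."""

    model: HierarchyConfig = field(default_factory=HierarchyConfig)
    objective: ObjectiveConfig = field(default_factory=ObjectiveConfig)
    training: TrainingConfig = field(default_factory=TrainingConfig)
    stimuli: dict = field(default_factory=lambda: {"kind": "naturalistic", "n": 200})
    metrics: tuple = ()
    output_dir: str | None = None
    global_seed: int = 0

    def to_dict(self) -> dict:
        return {
            "model": dataclasses.asdict(self.model),
            "objective": dataclasses.asdict(self.objective),
            "training": dataclasses.asdict(self.training),
            "stimuli": dict(self.stimuli),
            "metrics": list(self.metrics),
            "output_dir": self.output_dir,
            "global_seed": self.global_seed,
        }

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        def build(klass, sub):
            sub = dict(sub or {})
            for key in ("units", "image_shape", "patch_shape", "spatial_time_steps"):
                if key in sub and sub[key] is not None:
                    sub[key] = tuple(sub[key])
            return klass(**sub)

        return cls(
            model=build(HierarchyConfig, d.get("model")),
            objective=build(ObjectiveConfig, d.get("objective")),
            training=build(TrainingConfig, d.get("training")),
            stimuli=dict(d.get("stimuli") or {"kind": "naturalistic", "n": 200}),
            metrics=tuple(d.get("metrics") or ()),
            output_dir=d.get("output_dir"),
            global_seed=int(d.get("global_seed", 0)),
        )

    @classmethod
    def from_yaml(cls, text: str) -> "ExperimentConfig":
        return cls.from_dict(yaml.safe_load(text))


def desk_profile(**overrides) -> ExperimentConfig:
    """Scaled-down profile for a single CPU."""
    cfg = ExperimentConfig(
        model=HierarchyConfig(units=(32, 32)),
        objective=ObjectiveConfig(lambda_reg=10.0),
        training=TrainingConfig(iterations_per_repetition=2000, repetitions=1),
        stimuli={"kind": "naturalistic", "n": 200},
    )
    return replace(cfg, **overrides)


def paper_profile(**overrides) -> ExperimentConfig:
    """Full-scale profile (64+64 units, 10^4 iterations x 5 repetitions)."""
    cfg = ExperimentConfig(
        model=HierarchyConfig(),
        objective=ObjectiveConfig(lambda_reg=10.0),
        training=TrainingConfig(),
        stimuli={"kind": "naturalistic", "n": 4212},
    )
    return replace(cfg, **overrides)


def generate_stimuli(spec: dict, shape: tuple[int, int], seed: int) -> StimulusSet:
    kind = spec.get("kind", "naturalistic")
    n = int(spec.get("n", 200))
    if kind == "naturalistic":
        return generate_naturalistic(n, shape=shape, seed=seed)
    if kind == "glyph":
        return generate_glyphs(n, shape=shape, seed=seed)
    if kind == "probe":
        return generate_rf_probes(n, shape=shape, seed=seed)
    raise ValueError(f"unknown stimulus kind {kind!r}")


def compute_metrics(
    params: ModelParams, stimuli: StimulusSet, metrics: tuple, seed: int
) -> MetricsReport:
    """Run the requested subset of the evaluation battery."""
    report = MetricsReport()
    n_images = len(stimuli)
    for name in metrics:
        if name == "rf":
            probes = generate_rf_probes(
                min(2000, 20 * params.config.n_pixels // 256),
                shape=params.config.image_shape, seed=seed,
            )
            rf = receptive_field(params, probes)
            report.results["rf_coverage_min"] = float(np.nanmin(rf["coverage"]))
        elif name == "confusion":
            ci = confusion_index(params, stimuli)
            report.results["confusion_mean_per_time"] = {
                h: v for h, v in ci["mean_per_time"].items()
            }
        elif name == "noise":
            nn = neuronal_noise(params, stimuli)
            report.results["noise_entropy"] = nn["entropy"]
        elif name == "decode":
            dec = decode_over_time(params, stimuli)
            report.results["decoding_accuracy"] = dec["accuracy"]
            report.results["decoding_chance"] = dec["chance"]
        elif name == "orientation":
            op = orientation_preference(params)
            report.results["orientation"] = {
                h: {"histogram": d["histogram"], "cardinal_fraction": d["cardinal_fraction"]}
                for h, d in op.items()
            }
        elif name == "weights":
            report.results["synaptic_strength"] = {
                k: v["mean"] for k, v in synaptic_strength(params).items()
            }
            report.results["weight_balance_ratio"] = weight_balance_ratio(params)
        elif name == "distribution":
            rd = response_distribution(params, stimuli)
            report.results["middle_mass"] = rd["middle_mass"]
        else:
            raise ValueError(f"unknown metric {name!r} (known: {KNOWN_METRICS})")
    report.results.setdefault("n_images", n_images)
    return report


def run_experiment(config: ExperimentConfig):
    """Generate stimuli, train, evaluate, and (optionally) write artifacts.

    Returns ``(params, log, report)`` where ``report`` is ``None`` when no
    metrics were requested.  If ``config.output_dir`` is set, the checkpoint
    (NPZ), training log (JSON lines), metrics (JSON) and the exact config
    snapshot (YAML) are written there.
    """
    seeds = fan_out_seeds(config.global_seed)
    stimuli = generate_stimuli(config.stimuli, config.model.image_shape, seeds["stimuli"])
    train_cfg = replace(config.training, seed=seeds["training"])
    params, log = train(stimuli, config.model, config.objective, train_cfg)
    report = None
    if config.metrics:
        report = compute_metrics(params, stimuli, config.metrics, seeds["evaluation"])

    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        params.save(out / "checkpoint.npz")
        (out / "training_log.jsonl").write_text(log.to_json_lines())
        (out / "config.yaml").write_text(config.to_yaml())
        if report is not None:
            (out / "metrics.json").write_text(report.to_json())
    return params, log, report


def compare_conditions(
    base: ExperimentConfig, output_dir: str | None = None
) -> "pandas.DataFrame":
    """Train the four standard conditions and tabulate summary statistics.

    Conditions: TEC (lambda=0), STEC (lambda=10), SEC (lambda=1000) and
    Sparse (lambda=1000 + sparseness constraint).
    """
    import pandas as pd

    conditions = {
        "TEC": replace(base.objective, lambda_reg=0.0, sparse_constraint=False),
        "STEC": replace(base.objective, lambda_reg=10.0, sparse_constraint=False),
        "SEC": replace(base.objective, lambda_reg=1000.0, sparse_constraint=False),
        "Sparse": replace(base.objective, lambda_reg=1000.0, sparse_constraint=True),
    }
    rows = []
    for name, obj in conditions.items():
        cfg = replace(
            base,
            objective=obj,
            output_dir=str(Path(output_dir) / name) if output_dir else None,
            metrics=("noise", "decode", "weights"),
        )
        params, log, report = run_experiment(cfg)
        acc = report.results["decoding_accuracy"]
        late = float(np.mean([acc[t] for t in sorted(acc)[-3:]]))
        rows.append(
            {
                "condition": name,
                "lambda": obj.lambda_reg,
                "sparse": obj.sparse_constraint,
                "final_l_total": log.l_total[-1],
                "mean_noise": float(np.mean(report.results["noise_entropy"])),
                "late_decoding_accuracy": late,
                "weight_balance_ratio": report.results["weight_balance_ratio"],
            }
        )
    table = pd.DataFrame(rows)
    if output_dir:
        Path(output_dir).mkdir(parents=True, exist_ok=True)
        table.to_csv(Path(output_dir) / "comparison.csv", index=False)
    return table
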
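"""Pipeline configuration and the end-to-end synthetic demo.

A single YAML file drives the whole pipeline; every section maps 1:1 onto a
module's parameter dataclass and unknown keys are rejected up front, before
any compute. One global seed fans out deterministically to per-stage seeds
(cohort synthesis, splitting, augmentation, training), so a run is fully
reproducible from its ``run_metadata.json`` alone.

Stage order follows the classification scheme: synthesize (or load) the
cohort -> split 70:15:15 -> rebalance the training partition by augmentation
-> extract and fuse MFCC features -> train the 3-session ensemble -> report
metrics, the channel ablation and class-activation maps.

Augmentation runs AFTER the split by default, on the training partition
only, so near-duplicate augmented copies cannot leak into evaluation;
``augment_after_split: false`` reproduces the augment-then-split ordering
instead.
"""

from __future__ import annotations

import dataclasses
import json
import platform
import sys
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .augment import AugmentRanges, BalancePolicy, rebalance
from .evaluation import report_tables, run_ablation
from .features import MfccParams
from .model import ModelConfig, activation_map, save_checkpoint
from .synth import CohortSpec, synthesize_cohort, write_cohort
from .training import SplitSpec, TrainConfig, prepare_inputs, split, train_ensemble
from .vocab import LABEL_TO_INDEX

__all__ = ["PipelineConfig", "ConfigError", "load_config", "run_end_to_end", "derive_seed"]


class ConfigError(ValueError):
    pass


def derive_seed(seed: int, stage: int) -> int:
    """Deterministic per-stage seed below 2**31."""
    return int(np.random.SeedSequence([int(seed), int(stage)]).generate_state(1)[0] % (2**31))


@dataclass
class PipelineConfig:
    seed: int = 0
    synth: CohortSpec = field(default_factory=CohortSpec)
    split: SplitSpec = field(default_factory=SplitSpec)
    augment_policy: BalancePolicy = field(default_factory=BalancePolicy)
    augment_ranges: AugmentRanges = field(default_factory=AugmentRanges)
    augment_after_split: bool = True
    features: MfccParams = field(default_factory=MfccParams)
    model: ModelConfig = field(default_factory=ModelConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    ablation_subsets: tuple[tuple[str, ...], ...] = ()
    write_audio: bool = False

    def __post_init__(self):
        # fan the global seed out to stages that did not set one explicitly
        if self.synth.seed == 0:
            self.synth = replace(self.synth, seed=derive_seed(self.seed, 1))
        if self.split.seed == 0:
            self.split = replace(self.split, seed=derive_seed(self.seed, 2))
        if self.train.seed == 0:
            self.train = replace(self.train, seed=derive_seed(self.seed, 3))
        self.ablation_subsets = tuple(tuple(s) for s in self.ablation_subsets)

    def to_dict(self) -> dict:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, tuple):
                return [enc(v) for v in obj]
            if isinstance(obj, dict):
                return {k: enc(v) for k, v in obj.items()}
            return obj

        return {f.name: enc(getattr(self, f.name)) for f in dataclasses.fields(self)}


_SECTION_TYPES = {
    "synth": CohortSpec,
    "split": SplitSpec,
    "augment_policy": BalancePolicy,
    "augment_ranges": AugmentRanges,
    "features": MfccParams,
    "model": ModelConfig,
    "train": TrainConfig,
}

_TUPLE_FIELDS = {
    "class_proportions",
    "positions",
    "fractions",
    "stage_widths",
    "input_shape",
    "base_noise_band",
    "transforms",
    "background_kinds",
    "w",
    "stretch",
    "pitch",
    "sigma",
    "shift_ms",
    "mask_fraction",
    "gain",
}


def _build_section(cls, data: dict, path: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigError(f"unknown keys in {path}: {sorted(unknown)}")
    kwargs = {}
    for k, v in data.items():
        if isinstance(v, list) and k in _TUPLE_FIELDS:
            v = tuple(tuple(x) if isinstance(x, list) else x for x in v)
        kwargs[k] = v
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid {path} section: {exc}") from exc


def config_from_dict(data: dict) -> PipelineConfig:
    data = dict(data or {})
    top_names = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(data) - top_names
    if unknown:
        raise ConfigError(f"unknown top-level keys: {sorted(unknown)}")
    kwargs = {}
    for key, value in data.items():
        if key in _SECTION_TYPES:
            if not isinstance(value, dict):
                raise ConfigError(f"section {key!r} must be a mapping")
            if key == "augment_policy":
                value = {"multiplicity": value.get("multiplicity", value)}
            kwargs[key] = _build_section(_SECTION_TYPES[key], value, key)
        elif key == "ablation_subsets":
            kwargs[key] = tuple(tuple(s) for s in value)
        else:
            kwargs[key] = value
    try:
        return PipelineConfig(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return config_from_dict(data or {})


def demo_config(seed: int = 0) -> PipelineConfig:
    """A minutes-scale end-to-end demonstration configuration.

    60 balanced subjects, 6-second recordings, a narrow backbone, 12 epochs
    at batch 8 and 2 sessions, light augmentation and a 1-channel vs
    4-channel ablation. The demo exercises every stage deterministically in
    about a minute; at this miniature scale the reported accuracies are
    noisy and the multi-channel advantage does not yet emerge (see
    ``lungsound.benchmarks`` for the meaningful measurements).
    """
    return PipelineConfig(
        seed=seed,
        synth=CohortSpec(
            n_subjects=60,
            class_proportions=(1 / 3, 1 / 3, 1 / 3),
            duration_s=6.0,
            snr_db=30.0,
        ),
        augment_policy=BalancePolicy({"wheeze": 1, "fine_crackle": 2}),
        model=ModelConfig(stage_widths=(8, 16, 32, 64)),
        train=TrainConfig(
            epochs=12, batch_size=8, n_sessions=2, lr_start=3e-3, lr_end=1.5e-3
        ),
        ablation_subsets=(("BRUL",), ("BRUL", "BLUL", "BLLL", "BRLL")),
    )


class StageFailure(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def run_end_to_end(config: PipelineConfig, out_dir, log=print) -> Path:
    """Run synth -> split -> augment -> features -> ensemble -> reports.

    Writes, under ``out_dir``: the cohort manifest (and WAVs when
    ``write_audio``), feature arrays with a JSON parameter sidecar, one
    checkpoint per session, metric and ablation tables (CSV + text),
    activation-map images for one test example per class, and
    ``run_metadata.json`` recording config, seeds and versions. Any stage
    failure is re-raised naming the stage.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    def stage(name, fn):
        log(f"[stage] {name}")
        try:
            return fn()
        except Exception as exc:  # noqa: BLE001 - deliberately annotated re-raise
            raise StageFailure(name, exc) from exc

    recordings, manifest = stage("synth", lambda: synthesize_cohort(config.synth))
    if config.write_audio:
        stage("synth-write", lambda: write_cohort(recordings, manifest, out_dir / "audio"))
    else:
        manifest.to_csv(out_dir / "manifest.csv")

    if config.augment_after_split:
        tr, va, te = stage("split", lambda: split(recordings, config.split))
        tr = stage(
            "augment",
            lambda: rebalance(
                tr, config.augment_policy, config.augment_ranges, derive_seed(config.seed, 4)
            ),
        )
    else:
        aug = stage(
            "augment",
            lambda: rebalance(
                recordings, config.augment_policy, config.augment_ranges, derive_seed(config.seed, 4)
            ),
        )
        tr, va, te = stage("split", lambda: split(aug, config.split))

    kind = config.model.input_kind
    parts = stage(
        "features",
        lambda: [prepare_inputs(p, input_kind=kind, params=config.features) for p in (tr, va, te)],
    )
    feat_dir = out_dir / "features"
    feat_dir.mkdir(exist_ok=True)
    for name, (x, y) in zip(("train", "val", "test"), parts):
        np.savez_compressed(feat_dir / f"{name}.npz", x=x, y=y)
    (feat_dir / "params.json").write_text(
        json.dumps(dataclasses.asdict(config.features), indent=2) + "\n"
    )

    models, histories, reports, agg = stage(
        "train",
        lambda: train_ensemble(config.model, parts[0], parts[1], parts[2], config.train, log=log),
    )
    ckpt_dir = out_dir / "checkpoints"
    ckpt_dir.mkdir(exist_ok=True)
    for i, m in enumerate(models):
        save_checkpoint(m, ckpt_dir / f"session{i}.npz")
    hist_rows = []
    for i, h in enumerate(histories):
        for e in range(len(h.train_loss)):
            hist_rows.append(
                {
                    "session": i,
                    "epoch": e,
                    "lr": h.lr[e],
                    "train_loss": h.train_loss[e],
                    "train_acc": h.train_acc[e],
                    "val_loss": h.val_loss[e],
                    "val_acc": h.val_acc[e],
                }
            )
    import pandas as pd

    pd.DataFrame(hist_rows).to_csv(out_dir / "history.csv", index=False)

    def write_report():
        rows = [{"metric": m, "mean": agg.mean[m], "sd": agg.sd[m], "cell": agg.cell(m)} for m in agg.mean]
        pd.DataFrame(rows).to_csv(out_dir / "metrics.csv", index=False)
        np.savetxt(out_dir / "confusion.csv", sum(r.confusion for r in reports), fmt="%d", delimiter=",")

    stage("evaluate", write_report)

    if config.ablation_subsets:
        result = stage(
            "ablate",
            lambda: run_ablation(
                recordings,
                config.ablation_subsets,
                config.model,
                config.train,
                config.split,
                mfcc_params=config.features,
                log=log,
            ),
        )
        report_tables(result, out_dir)

    stage("cam", lambda: _write_cams(models[0], parts[2], out_dir / "activation_maps"))

    meta = {
        "config": config.to_dict(),
        "derived_seeds": {str(i): derive_seed(config.seed, i) for i in range(1, 5)},
        "versions": {
            "python": sys.version.split()[0],
            "platform": platform.platform(),
            "numpy": np.__version__,
            "lungsound": __version__,
        },
    }
    (out_dir / "run_metadata.json").write_text(json.dumps(meta, indent=2) + "\n")
    log(f"[done] artifacts in {out_dir}")
    return out_dir


def _write_cams(model, test_data, cam_dir):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cam_dir = Path(cam_dir)
    cam_dir.mkdir(parents=True, exist_ok=True)
    x_te, y_te = test_data
    for label, idx in LABEL_TO_INDEX.items():
        where = np.flatnonzero(y_te == idx)
        if where.size == 0:
            continue
        grid = x_te[where[0], 0]
        cam = activation_map(model, grid, idx)
        fig, axes = plt.subplots(2, 1, figsize=(8, 5), sharex=True)
        axes[0].imshow(grid, aspect="auto", origin="lower", cmap="magma")
        axes[0].set_title(f"input ({label})")
        axes[1].imshow(cam, aspect="auto", origin="lower", cmap="jet", vmin=0, vmax=1)
        axes[1].set_title("class activation map")
        fig.tight_layout()
        fig.savefig(cam_dir / f"cam_{label}.png", dpi=100)
        plt.close(fig)
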
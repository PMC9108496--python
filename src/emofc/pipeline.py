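"""End-to-end orchestration: simulate -> preprocess -> encode -> train
-> select -> connect -> report.

Each stage reads the previous stage's outputs from the run directory, writes
its own outputs plus a manifest, and logs to ``logs/<stage>.log``. A run is
fully determined by its :class:`RunConfig`: the single global seed fans out
to per-stage seeds through a fixed derivation (``SeedSequence([seed, stage
index])``), so any stage can be rerun in isolation and reproduce its
manifest byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify, connectivity, image_features, preprocess
from .channel_select import backward_select, frontal_subset, make_cv_evaluator
from .classify import ModelConfig
from .connectivity import SpectralParams
from .containers import CLASSES
from .io import load_recording, load_segments, save_recording, save_segments
from .montage import ANALYSIS_30, FRONTAL_8
from .synthetic import PlantSpec, ProtocolConfig, generate_dataset

logger = logging.getLogger(__name__)

STAGES = ("simulate", "preprocess", "encode", "train", "select", "connect", "report")

__all__ = ["RunConfig", "run_pipeline", "STAGES"]


@dataclass
class RunConfig:
    """Serializable configuration of a full pipeline run."""

    protocol: ProtocolConfig = field(default_factory=ProtocolConfig)
    plant: PlantSpec = field(default_factory=PlantSpec)
    notch: tuple[float, float] = (49.0, 51.0)
    band: tuple[float, float] = (1.0, 40.0)
    baseline_s: float = 5.0
    points_per_second: int = 20
    model: ModelConfig = field(default_factory=lambda: ModelConfig(scale="mini", epochs=10))
    split_by: str = "sample"  # or "subject": keep each subject's samples in one role
    select_min_size: int = 2
    select_evaluator: str = "logreg"
    spectral: SpectralParams = field(default_factory=SpectralParams)
    dynamic_k_max: int = 6
    folds: int = 5
    seed: int = 0

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        def plain(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: plain(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, (list, tuple)):
                return [plain(v) for v in obj]
            if isinstance(obj, dict):
                return {k: plain(v) for k, v in obj.items()}
            return obj

        return plain(self)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True, default_flow_style=False)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        protocol = ProtocolConfig(**{**d.pop("protocol", {})})
        plant_d = d.pop("plant", {})
        if "coherent_pairs" in plant_d:
            plant_d["coherent_pairs"] = [tuple(p[:2]) + (p[2],) for p in plant_d["coherent_pairs"]]
        if "osc_bands" in plant_d:
            plant_d["osc_bands"] = tuple(tuple(b) for b in plant_d["osc_bands"])
        plant = PlantSpec(**plant_d)
        model = ModelConfig(**d.pop("model", {}))
        spectral_d = d.pop("spectral", {})
        if "band" in spectral_d:
            spectral_d["band"] = tuple(spectral_d["band"])
        spectral = SpectralParams(**spectral_d)
        for key in ("notch", "band"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(protocol=protocol, plant=plant, model=model, spectral=spectral, **d)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(text))

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the global seed."""
        ss = np.random.SeedSequence([self.seed, STAGES.index(stage)])
        return int(ss.generate_state(1)[0] % (2**31))


def _stage_logger(run_dir: Path, stage: str) -> logging.Logger:
    log_dir = run_dir / "logs"
    log_dir.mkdir(parents=True, exist_ok=True)
    lg = logging.getLogger(f"emofc.pipeline.{stage}")
    lg.handlers = [logging.FileHandler(log_dir / f"{stage}.log")]
    lg.handlers[0].setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    lg.setLevel(logging.INFO)
    lg.propagate = False
    return lg


def _require(run_dir: Path, upstream: str, needed_by: str) -> Path:
    path = run_dir / upstream
    if not path.exists():
        raise FileNotFoundError(
            f"stage '{needed_by}' requires outputs of stage '{upstream}' "
            f"(missing directory {path})"
        )
    return path


def run_pipeline(cfg: RunConfig, stages: list[str], out_dir: str | Path) -> Path:
    """Run the requested stages in canonical order; returns the run directory."""
    run_dir = Path(out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    (run_dir / "config.yaml").write_text(cfg.to_yaml())
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stage(s): {sorted(unknown)}")
    for stage in STAGES:
        if stage in stages:
            _RUNNERS[stage](cfg, run_dir)
    return run_dir


# ---------------------------------------------------------------------------
# Stage runners
# ---------------------------------------------------------------------------


def _analysis_channels(cfg: RunConfig) -> tuple[str, ...]:
    return tuple(ch for ch in cfg.protocol.channel_labels if ch in ANALYSIS_30)


def _run_simulate(cfg: RunConfig, run_dir: Path) -> None:
    lg = _stage_logger(run_dir, "simulate")
    dataset = generate_dataset(cfg.protocol, cfg.plant)
    out = run_dir / "simulate"
    out.mkdir(parents=True, exist_ok=True)
    for rec in dataset.recordings:
        save_recording(rec, out / f"subject_{rec.subject_id:02d}")
    dataset.manifest.to_csv(out / "manifest.csv", index=False)
    lg.info("wrote %d recordings, %d trials", len(dataset.recordings), len(dataset.manifest))


def _run_preprocess(cfg: RunConfig, run_dir: Path) -> None:
    lg = _stage_logger(run_dir, "preprocess")
    sim = _require(run_dir, "simulate", "preprocess")
    segments = []
    for sub_dir in sorted(sim.glob("subject_*")):
        rec = load_recording(sub_dir)
        segments += preprocess.preprocess_recording(
            rec,
            notch_band=cfg.notch,
            band=cfg.band,
            analysis_labels=[ch for ch in _analysis_channels(cfg) if ch in rec.labels],
            stim_s=cfg.protocol.stim_s,
            baseline_s=min(cfg.baseline_s, cfg.protocol.rest_s),
        )
    out = save_segments(segments, run_dir / "preprocess")
    pd.DataFrame(
        [{"subject": s.subject_id, "trial": s.trial_index, "label": s.label} for s in segments]
    ).to_csv(out / "manifest.csv", index=False)
    lg.info("segmented %d trials", len(segments))


def _run_encode(cfg: RunConfig, run_dir: Path) -> None:
    lg = _stage_logger(run_dir, "encode")
    _require(run_dir, "preprocess", "encode")
    segments = load_segments(run_dir / "preprocess")
    channels = _analysis_channels(cfg)
    windows = [
        sm
        for seg in segments
        for sm in image_features.window_per_second(seg, cfg.points_per_second, channels)
    ]
    tensor = np.stack([w.X for w in windows]).astype(np.float32)
    out = run_dir / "encode"
    out.mkdir(exist_ok=True)
    np.save(out / "tensor.npy", tensor)
    manifest = pd.DataFrame(
        [
            {"subject": w.subject_id, "trial": w.trial_index, "second": w.second, "label": w.label}
            for w in windows
        ]
    )
    manifest.to_csv(out / "manifest.csv", index=False)
    (out / "meta.json").write_text(json.dumps({"channels": list(channels)}))
    lg.info("encoded %d per-second windows", len(windows))


def _load_encoded(run_dir: Path):
    tensor = np.load(run_dir / "encode" / "tensor.npy")
    manifest = pd.read_csv(run_dir / "encode" / "manifest.csv")
    meta = json.loads((run_dir / "encode" / "meta.json").read_text())
    return tensor, manifest, tuple(meta["channels"])


def _run_train(cfg: RunConfig, run_dir: Path) -> None:
    lg = _stage_logger(run_dir, "train")
    _require(run_dir, "encode", "train")
    tensor, manifest, channels = _load_encoded(run_dir)
    seed = cfg.stage_seed("train")
    evaluator_sets = {"all": channels, "frontal": tuple(ch for ch in FRONTAL_8 if ch in channels)}
    out = run_dir / "train"
    out.mkdir(exist_ok=True)
    rows = []
    y = manifest["label"].to_numpy()
    for name, subset in evaluator_sets.items():
        idx = [channels.index(ch) for ch in subset]
        sub = tensor[:, idx, :]
        lo = sub.min(axis=(1, 2), keepdims=True)
        hi = sub.max(axis=(1, 2), keepdims=True)
        X = np.repeat(
            (np.floor((sub - lo) * 255.0 / np.where(hi > lo, hi - lo, 1.0) + 0.5))[:, None],
            3,
            axis=1,
        ) / 255.0
        yi = np.array([classify.CLASS_INDEX[lb] for lb in y])
        model_cfg = dataclasses.replace(cfg.model, seed=seed)
        groups = manifest["subject"].to_numpy() if cfg.split_by == "subject" else None
        result = classify.cross_validate(
            X, yi, lambda Xt, yt, Xv, yv: classify.train_cnn(Xt, yt, model_cfg, Xv, yv),
            k=cfg.folds, seed=seed, groups=groups,
        )
        for fold_i, (c, m) in enumerate(zip(result.folds, result.metrics)):
            rows.append(
                {"channel_set": name, "fold": fold_i, "TP": c.TP, "TN": c.TN, "FP": c.FP,
                 "FN": c.FN, **{k: getattr(m, k) for k in ("accuracy", "sensitivity", "specificity", "f1")}}
            )
        lg.info("channel set %s: %s", name, result.summary)
    pd.DataFrame(rows).to_csv(out / "fold_metrics.csv", index=False)
    summary = (
        pd.DataFrame(rows)
        .groupby("channel_set")[["accuracy", "sensitivity", "specificity", "f1"]]
        .agg(["mean", "std"])
    )
    summary.to_csv(out / "summary.csv")


def _run_select(cfg: RunConfig, run_dir: Path) -> None:
    lg = _stage_logger(run_dir, "select")
    _require(run_dir, "encode", "select")
    tensor, manifest, channels = _load_encoded(run_dir)
    start = frontal_subset(channels)
    seed = cfg.stage_seed("select")
    evaluator = make_cv_evaluator(
        tensor,
        np.array([classify.CLASS_INDEX[lb] for lb in manifest["label"]]),
        channels,
        kind=cfg.select_evaluator,
        k=cfg.folds,
        seed=seed,
        model_config=dataclasses.replace(cfg.model, seed=seed),
    )
    trace = backward_select(start, evaluator, min_size=cfg.select_min_size, montage_order=channels)
    out = run_dir / "select"
    out.mkdir(exist_ok=True)
    trace.to_frame().to_csv(out / "trace.csv", index=False)
    (out / "best.json").write_text(
        json.dumps({"best_subset": list(trace.best_subset), "best_accuracy": trace.best_accuracy})
    )
    lg.info("best subset %s at %.2f%% (%d evaluations)",
            trace.best_subset, trace.best_accuracy, trace.n_evaluations)


def _run_connect(cfg: RunConfig, run_dir: Path) -> None:
    lg = _stage_logger(run_dir, "connect")
    _require(run_dir, "preprocess", "connect")
    segments = load_segments(run_dir / "preprocess")
    frontal = tuple(ch for ch in FRONTAL_8 if ch in segments[0].labels)
    out = run_dir / "connect"
    out.mkdir(exist_ok=True)

    by_subject: dict[int, dict[str, list]] = {}
    rows = []
    for seg in segments:
        fc = connectivity.trial_fc_matrix(seg, frontal, cfg.spectral)
        by_subject.setdefault(seg.subject_id, {s: [] for s in CLASSES})[seg.label].append(fc)
        for i in range(len(frontal)):
            for j in range(i + 1, len(frontal)):
                rows.append(
                    {"subject": seg.subject_id, "trial": seg.trial_index, "label": seg.label,
                     "ch_a": frontal[i], "ch_b": frontal[j], "coherence": fc.values[i, j]}
                )
    pd.DataFrame(rows).to_csv(out / "fc_long.csv", index=False)

    stats = connectivity.compare_states(by_subject)
    (out / "state_comparison.json").write_text(
        json.dumps(
            {"mean_coherence": stats.mean_coherence, "sd_coherence": stats.sd_coherence,
             "t": stats.t, "p": stats.p}
        )
    )
    lg.info("mean FC %s, paired t=%.3f p=%.4f", stats.mean_coherence, stats.t, stats.p)

    seed = cfg.stage_seed("connect")
    k_max = min(cfg.dynamic_k_max, cfg.protocol.n_trials_per_class)
    curve = connectivity.dynamic_classification_curve(
        by_subject, ks=tuple(range(1, k_max + 1)), k_folds=cfg.folds, seed=seed
    )
    curve_rows = []
    for k, result in curve.items():
        acc = result.summary.get("accuracy", (float("nan"), float("nan")))
        f1 = result.summary.get("f1", (float("nan"), float("nan")))
        curve_rows.append({"k": k, "accuracy_mean": acc[0], "accuracy_sd": acc[1],
                           "f1_mean": f1[0], "f1_sd": f1[1]})
    pd.DataFrame(curve_rows).to_csv(out / "dynamic_curve.csv", index=False)
    lg.info("dynamic curve: %s", curve_rows)


def _run_report(cfg: RunConfig, run_dir: Path) -> None:
    lg = _stage_logger(run_dir, "report")
    lines = ["# emofc run report", ""]
    train_csv = run_dir / "train" / "summary.csv"
    if train_csv.exists():
        lines += ["## Cross-validated classification (mean ± SD over folds)", "",
                  "```", train_csv.read_text(), "```", ""]
    best = run_dir / "select" / "best.json"
    if best.exists():
        lines += ["## Channel selection", "", "```", best.read_text(), "```", ""]
    comp = run_dir / "connect" / "state_comparison.json"
    if comp.exists():
        lines += ["## Functional-connectivity state comparison", "", "```",
                  comp.read_text(), "```", ""]
    curve = run_dir / "connect" / "dynamic_curve.csv"
    if curve.exists():
        lines += ["## Dynamic FC classification curve", "", "```", curve.read_text(), "```", ""]
    (run_dir / "report.md").write_text("\n".join(lines))
    lg.info("report written")


_RUNNERS = {
    "simulate": _run_simulate,
    "preprocess": _run_preprocess,
    "encode": _run_encode,
    "train": _run_train,
    "select": _run_select,
    "connect": _run_connect,
    "report": _run_report,
}
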
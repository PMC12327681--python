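"""Experiment orchestration shared by the CLI, the test suite and the
acceptance script: config loading, end-to-end cross-validated training,
hold-out evaluation and the four-variant ablation ladder.

An experiment config is a plain dict (serialized as YAML/JSON) with the keys
``seed``, ``data`` (a named synthetic profile or a directory of runs),
``msmce``, ``classifier`` and ``train``.  Every run writes a reproducibility
manifest next to its outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import yaml

from . import __version__, nn
from .classifiers import ClassifierSpec, ComposedModel, make_classifier
from .evaluation import (MetricsReport, bootstrap_ci, confusion_matrix,
                         macro_metrics)
from .ms_io import read_run
from .msmce import MSMCE, ChannelEmbedding, Encoder, MSMCEConfig
from .preprocess import BinGrid, build_feature_matrix, tic_normalize
from .synth import Benchmark, make_benchmark
from .training import (TrainConfig, class_weights, predict, stratified_file_split,
                       stratified_kfold, train_model)

logger = logging.getLogger(__name__)

__all__ = ["ExperimentConfig", "load_config", "load_dataset", "build_model",
           "run_experiment", "run_ablation", "ABLATION_VARIANTS"]

ABLATION_VARIANTS = ("baseline", "encoder", "channel_embedding", "concatenation")


@dataclass
class ExperimentConfig:
    seed: int = 0
    data: dict | None = None          # {"profile": name} or {"dir": ..., "mode": ...}
    msmce: dict | None = None         # MSMCEConfig kwargs minus D
    classifier: dict | None = None    # ClassifierSpec kwargs minus n_classes
    train: dict | None = None         # TrainConfig kwargs
    use_msmce: bool = True
    out_dir: str | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path: str | Path) -> ExperimentConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f for f in ExperimentConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return ExperimentConfig(**raw)


def load_dataset(data: dict | None, seed: int) -> Benchmark:
    """Resolve the ``data`` section to train/test feature matrices.

    Either a named synthetic profile (``{"profile": "easy"}``) or a directory
    of fixture/mzML runs with preprocessing parameters.
    """
    data = data or {"profile": "easy"}
    if "profile" in data:
        return make_benchmark(data["profile"], seed=seed)
    run_dir = Path(data["dir"])
    paths = sorted(p for p in run_dir.iterdir()
                   if p.suffix.lower() in (".jsonl", ".fixture", ".mzml", ".txt"))
    if not paths:
        raise FileNotFoundError(f"no run files found in {run_dir}")
    runs = [read_run(p) for p in paths]
    lo, hi = data.get("mass_range") or (
        min(s.mz.min() for r in runs for s in r.spectra),
        max(s.mz.max() for r in runs for s in r.spectra) + 1e-9,
    )
    grid = BinGrid(float(lo), float(hi), float(data.get("bin_width", 0.1)))
    mode = data.get("mode", "spidermass")
    files = [(r.file_id, r.label) for r in runs]
    train_ids, test_ids = stratified_file_split(
        files, test_frac=float(data.get("test_frac", 0.10)), seed=seed)
    by_id = {r.file_id: r for r in runs}
    kwargs = dict(mode=mode, window=float(data.get("window", 10.0)),
                  tic_threshold=float(data.get("tic_threshold", 1e4)))
    train_fm = tic_normalize(build_feature_matrix(
        [by_id[i] for i in train_ids], grid, **kwargs))
    test_fm = tic_normalize(build_feature_matrix(
        [by_id[i] for i in test_ids], grid, **kwargs))
    classes = sorted({r.label for r in runs})
    meta = {"dir": str(run_dir), "mode": mode, "n_bins": grid.n_bins,
            "classes": classes, "seed": seed}
    return Benchmark(train_fm, test_fm, classes, meta)


# --------------------------------------------------------------------------
# Ablation wrappers: partial stacks of the embedding module
# --------------------------------------------------------------------------

class _EncoderOnly(nn.Module):
    """X -> (B, 1, d): just the fully connected encoder, as one channel."""

    def __init__(self, cfg: MSMCEConfig, rng: np.random.Generator):
        super().__init__()
        self.encoder = Encoder(cfg, rng)

    def forward(self, x):
        e = self.encoder(x)
        return e.reshape(e.shape[0], 1, e.shape[1])


class _EncoderChannels(nn.Module):
    """X -> (B, C, d): encoder plus channel embedding, no concatenation."""

    def __init__(self, cfg: MSMCEConfig, rng: np.random.Generator):
        super().__init__()
        self.encoder = Encoder(cfg, rng)
        self.channel_embedding = ChannelEmbedding(cfg, rng)

    def forward(self, x):
        return self.channel_embedding(self.encoder(x))


def build_model(variant: str, D: int, n_classes: int, msmce_kwargs: dict,
                classifier_kwargs: dict, seed: int) -> nn.Module:
    """Construct one ablation-ladder variant (or the full composed model)."""
    rng = np.random.default_rng(seed)
    cls_kwargs = dict(classifier_kwargs or {})
    family = cls_kwargs.pop("family", "cnn1d")
    if variant == "baseline":
        spec = ClassifierSpec(family=family, n_classes=n_classes, in_channels=1,
                              input_len=D, **cls_kwargs)
        return make_classifier(spec, rng, segment_input=True)
    cfg = MSMCEConfig(D=D, **(msmce_kwargs or {}))
    if variant == "encoder":
        channels = 1
        embedder: nn.Module = _EncoderOnly(cfg, rng)
    elif variant == "channel_embedding":
        channels = cfg.C
        embedder = _EncoderChannels(cfg, rng)
    elif variant == "concatenation":
        channels = cfg.out_channels
        embedder = MSMCE(cfg, rng)
    else:
        raise ValueError(f"unknown variant {variant!r}; "
                         f"choose from {ABLATION_VARIANTS}")
    spec = ClassifierSpec(family=family, n_classes=n_classes,
                          in_channels=channels, input_len=cfg.d, **cls_kwargs)
    classifier = make_classifier(spec, rng, feat_len=cfg.d, segment_input=False)
    return ComposedModel(embedder, classifier)


def _write_manifest(out_dir: Path, cfg: ExperimentConfig, extra: dict) -> None:
    manifest = {"config": cfg.to_dict(), "package_version": __version__}
    manifest.update(extra)
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))


def run_experiment(cfg: ExperimentConfig, out_dir: str | Path | None = None) -> dict:
    """Cross-validated training plus hold-out evaluation.

    Returns per-fold and hold-out metrics; if ``out_dir`` is given, also
    writes history tables, the metrics report and a manifest.
    """
    bench = load_dataset(cfg.data, cfg.seed)
    X_tr, y_tr = bench.X_train, bench.y_train
    X_te, y_te = bench.X_test, bench.y_test
    n_classes = len(bench.classes)
    tcfg = TrainConfig(seed=cfg.seed, **(cfg.train or {}))
    folds = stratified_kfold(y_tr, k=tcfg.k, seed=cfg.seed)
    variant = "concatenation" if cfg.use_msmce else "baseline"
    report = MetricsReport()
    histories = []
    fold_holdout_acc = []
    for fold_i, (tr_idx, val_idx) in enumerate(folds):
        model = build_model(variant, X_tr.shape[1], n_classes, cfg.msmce,
                            cfg.classifier, seed=cfg.seed + fold_i)
        weights = class_weights(y_tr[tr_idx]) if tcfg.use_class_weights else None
        model, hist = train_model(model, (X_tr[tr_idx], y_tr[tr_idx]),
                                  (X_tr[val_idx], y_tr[val_idx]), tcfg,
                                  weights=weights)
        histories.append(hist)
        cm_val = confusion_matrix(y_tr[val_idx], predict(model, X_tr[val_idx]),
                                  n_classes)
        fold_m = macro_metrics(cm_val)
        cm_hold = confusion_matrix(y_te, predict(model, X_te), n_classes)
        hold_m = macro_metrics(cm_hold)
        fold_holdout_acc.append(hold_m["accuracy"])
        fold_m["holdout_accuracy"] = hold_m["accuracy"]
        fold_m["holdout_macro_f1"] = hold_m["macro_f1"]
        report.fold_metrics.append(fold_m)
        logger.info("fold %d: val acc %.4f, hold-out acc %.4f",
                    fold_i, fold_m["accuracy"], hold_m["accuracy"])
    # final model trained on the full training set for the hold-out report
    final = build_model(variant, X_tr.shape[1], n_classes, cfg.msmce,
                        cfg.classifier, seed=cfg.seed)
    inner = stratified_kfold(y_tr, k=max(tcfg.k, 5), seed=cfg.seed + 1)[0]
    final, final_hist = train_model(final, (X_tr[inner[0]], y_tr[inner[0]]),
                                    (X_tr[inner[1]], y_tr[inner[1]]), tcfg)
    cm = confusion_matrix(y_te, predict(final, X_te), n_classes)
    report.holdout_confusion = cm
    report.holdout_metrics = macro_metrics(cm)
    if len(fold_holdout_acc) >= 2:
        report.bootstrap_cis["holdout_accuracy"] = bootstrap_ci(
            fold_holdout_acc, seed=cfg.seed)
    result = {
        "report": report.to_dict(),
        "meta": bench.meta,
        "fold_holdout_accuracy": fold_holdout_acc,
        "holdout_accuracy": report.holdout_metrics["accuracy"],
        "holdout_macro_f1": report.holdout_metrics["macro_f1"],
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "metrics.json").write_text(json.dumps(result, indent=2))
        _dump_histories(out_dir, histories + [final_hist])
        _write_manifest(out_dir, cfg, {"meta": bench.meta})
    return result


def _dump_histories(out_dir: Path, histories: list[dict]) -> None:
    lines = ["fold,epoch,train_loss,val_loss,val_acc,lr"]
    for i, hist in enumerate(histories):
        for e in range(len(hist["train_loss"])):
            lines.append(f"{i},{e},{hist['train_loss'][e]:.6g},"
                         f"{hist['val_loss'][e]:.6g},{hist['val_acc'][e]:.6g},"
                         f"{hist['lr'][e]:.6g}")
    (out_dir / "history.csv").write_text("\n".join(lines) + "\n")


def run_ablation(cfg: ExperimentConfig, out_dir: str | Path | None = None,
                 variants: tuple[str, ...] = ABLATION_VARIANTS) -> list[dict]:
    """Train each ladder variant on the full training set (no k-fold) and
    evaluate on the hold-out set; returns one result row per variant."""
    bench = load_dataset(cfg.data, cfg.seed)
    X_tr, y_tr = bench.X_train, bench.y_train
    X_te, y_te = bench.X_test, bench.y_test
    n_classes = len(bench.classes)
    tcfg = TrainConfig(seed=cfg.seed, **(cfg.train or {}))
    # small stratified validation carve-out drives scheduling/early stopping
    inner_tr, inner_val = stratified_kfold(y_tr, k=max(tcfg.k, 5),
                                           seed=cfg.seed + 1)[0]
    rows = []
    for variant in variants:
        model = build_model(variant, X_tr.shape[1], n_classes, cfg.msmce,
                            cfg.classifier, seed=cfg.seed)
        model, _ = train_model(model, (X_tr[inner_tr], y_tr[inner_tr]),
                               (X_tr[inner_val], y_tr[inner_val]), tcfg)
        cm = confusion_matrix(y_te, predict(model, X_te), n_classes)
        m = macro_metrics(cm)
        rows.append({"variant": variant, "accuracy": m["accuracy"],
                     "macro_f1": m["macro_f1"]})
        logger.info("ablation %s: acc %.4f, macro-F1 %.4f",
                    variant, m["accuracy"], m["macro_f1"])
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "ablation.json").write_text(json.dumps(rows, indent=2))
        lines = ["variant,accuracy,macro_f1"]
        lines += [f"{r['variant']},{r['accuracy']:.6g},{r['macro_f1']:.6g}"
                  for r in rows]
        (out_dir / "ablation.csv").write_text("\n".join(lines) + "\n")
        _write_manifest(out_dir, cfg, {"meta": bench.meta})
    return rows
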
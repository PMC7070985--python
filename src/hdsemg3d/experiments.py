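"""Desk-scale experiment protocols: preprocess -> cubes -> train -> evaluate.

Reproduces the two benchmark evaluation protocols on synthetic (or
user-supplied) data for both classifier variants:

``capgmyo-half-half``
    Per gesture, alternating trials form the train/test halves; the
    training half may use an overlapping extraction stride as augmentation.
``csl-leave-one-out``
    Each trial index serves once as the test fold while the remaining
    trials train.

Every run writes deterministic artifacts into the output directory:
``report.json`` (config, seeds, accuracies, conventions), accuracy-vs-window
tables for both models, confusion matrices as CSV, the analytic
parameter-count table, and loss histories.  Wall-clock timings go to
``run.log`` only, so two runs with the same config and seed produce
bitwise-identical tables.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .cubes import CubeDataset, ImageSequence, build_image_sequence, extract_cubes
from .grid_io import Recording
from .network import (
    TrainingConfig, build_2d_cnn, build_3d_cnn, count_parameters, train,
    COUNT_CONVENTIONS, ShapeError,
)
from .preprocess import (
    NoActivityError, bandpass_zero_lag, intensity_envelope,
    normalize_unit_interval, segment_activity,
)
from .synth import SynthConfig, make_benchmark
from .voting import accuracy_vs_window_sweep, evaluate_voted, vote_entire_trial

__all__ = [
    "ExperimentConfig", "run_protocol", "report_table1",
    "trial_to_sequence", "prepare_sequences",
]

_DEFAULT_POOL = {(8, 16): 2, (7, 24): 4}


@dataclass
class ExperimentConfig:
    """One synthetic experiment: data conditions, protocol, model budget."""

    synth: SynthConfig = field(default_factory=SynthConfig)
    dynamic: bool = False
    protocol: str = "capgmyo-half-half"
    l_cube: int = 10
    train_stride: int = 20
    pool_s: int | None = None
    voting_grid_ms: tuple = (40, 80, 120, 150)
    training: TrainingConfig = field(default_factory=lambda: TrainingConfig(
        lr0=0.1, max_epochs=30, batch_size=32))
    conv_channels: tuple = (8, 16, 16)
    dense_units: tuple = (64, 32)
    seg_window_len: int = 150
    tie_break: str = "most-recent"
    count_convention: str = "bn-activation"
    folds: tuple | None = None  # leave-one-out folds; None = all

    def __post_init__(self) -> None:
        if self.protocol not in ("capgmyo-half-half", "csl-leave-one-out"):
            raise ValueError(f"unknown protocol {self.protocol!r}")
        if self.pool_s is None:
            g = self.synth.grid
            self.pool_s = _DEFAULT_POOL.get((g.rows, g.cols), 2)


def trial_to_sequence(rec: Recording, seg_window_len: int = 150,
                      presegmented: bool = False) -> ImageSequence:
    """Full conditioning chain for one raw trial.

    Band-pass 20-400 Hz (zero-lag), intensity envelope, windowed-threshold
    activity segmentation, then [0, 1] normalization of the *denoised*
    signal against its own extrema and image formation over the detected
    segment.  ``presegmented`` trials (already trimmed and in [-1, 1])
    skip filtering and segmentation entirely.
    """
    if presegmented:
        norm = Recording(normalize_unit_interval(rec.signal, (-1.0, 1.0)),
                         rec.fs, rec.grid, rec.meta)
        return build_image_sequence(norm)
    high = min(400.0, 0.45 * rec.fs)
    filtered = bandpass_zero_lag(rec.signal, rec.fs, 20.0, high)
    env = intensity_envelope(filtered, rec.fs)
    segment = segment_activity(env, window_len=seg_window_len)
    lo, hi = filtered.min(), filtered.max()
    norm = Recording(normalize_unit_interval(filtered, (lo, hi)),
                     rec.fs, rec.grid, rec.meta)
    return build_image_sequence(norm, segment)


def prepare_sequences(trials: list[Recording], seg_window_len: int = 150,
                      presegmented: bool = False,
                      log: list[str] | None = None) -> list[ImageSequence]:
    """Condition a trial list; trials with no detectable activity are
    dropped with a log entry."""
    out = []
    for i, rec in enumerate(trials):
        try:
            out.append(trial_to_sequence(rec, seg_window_len, presegmented))
        except NoActivityError:
            if log is not None:
                log.append(f"trial {i} (gesture {rec.meta.get('gesture')}): "
                           f"no activity detected; dropped")
    return out


def _split_half_half(seqs: list[ImageSequence]):
    """Alternating trial indices per gesture: even train, odd test."""
    train, test = [], []
    for seq in seqs:
        (train if seq.meta.get("trial", 0) % 2 == 0 else test).append(seq)
    return train, test


def _train_cubes(seqs: list[ImageSequence], l: int, stride: int) -> CubeDataset:
    return CubeDataset.concatenate(
        [extract_cubes(s, l=l, stride=stride) for s in seqs])


def _evaluate_pair(cfg: ExperimentConfig, train_seqs, test_seqs, G):
    """Train and evaluate the spatiotemporal model and its per-frame
    ablation on one train/test split.  Returns a result dict."""
    grid = cfg.synth.grid
    l, stride = cfg.l_cube, cfg.train_stride
    result = {}

    spec3d = build_3d_cnn((l, grid.rows, grid.cols, 1), cfg.pool_s, G,
                          cfg.conv_channels, cfg.dense_units)
    model3d = train(spec3d, _train_cubes(train_seqs, l, stride), cfg.training)
    labels3d = np.concatenate([
        model3d.predict(extract_cubes(s, l, l))[0] == s.label
        for s in test_seqs])
    result["3d"] = {
        "per_cube_accuracy": 100.0 * float(labels3d.mean()),
        "sweep": accuracy_vs_window_sweep(
            model3d, test_seqs, l, cfg.voting_grid_ms, cfg.tie_break),
        "loss_history": model3d.loss_history,
        "trial_votes": [
            (s.label, vote_entire_trial(model3d, s, l, cfg.tie_break))
            for s in test_seqs],
    }
    acc, cm, eq3 = evaluate_voted(model3d, test_seqs, l,
                                  cfg.voting_grid_ms[-1], cfg.tie_break)
    result["3d"]["voted_accuracy"] = acc
    result["3d"]["eq3_mean"] = eq3
    result["3d"]["confusion"] = cm

    spec2d = build_2d_cnn((grid.rows, grid.cols, 1), G,
                          cfg.conv_channels, cfg.dense_units)
    model2d = train(spec2d, _train_cubes(train_seqs, 1, stride), cfg.training)
    labels2d = np.concatenate([
        model2d.predict(extract_cubes(s, 1, 1))[0] == s.label
        for s in test_seqs])
    result["2d"] = {
        "per_frame_accuracy": 100.0 * float(labels2d.mean()),
        "sweep": accuracy_vs_window_sweep(
            model2d, test_seqs, 1, cfg.voting_grid_ms, cfg.tie_break),
        "loss_history": model2d.loss_history,
    }
    acc, cm, eq3 = evaluate_voted(model2d, test_seqs, 1,
                                  cfg.voting_grid_ms[-1], cfg.tie_break)
    result["2d"]["voted_accuracy"] = acc
    result["2d"]["eq3_mean"] = eq3
    result["2d"]["confusion"] = cm
    return result


def run_protocol(cfg: ExperimentConfig, out_dir: str | Path | None = None
                 ) -> dict:
    """Execute one full protocol for both model variants.

    Returns the run report as a dict and, when ``out_dir`` is given, writes
    the table/CSV/JSON artifacts there.
    """
    t0 = time.perf_counter()
    log: list[str] = []
    G = cfg.synth.G
    trials = make_benchmark(cfg.synth, dynamic=cfg.dynamic)
    seqs = prepare_sequences(trials, cfg.seg_window_len, log=log)
    log.append(f"prepared {len(seqs)}/{len(trials)} sequences "
               f"[{time.perf_counter() - t0:.1f}s]")

    if cfg.protocol == "capgmyo-half-half":
        train_seqs, test_seqs = _split_half_half(seqs)
        folds = {"half-half": _evaluate_pair(cfg, train_seqs, test_seqs, G)}
    else:
        n_trials = cfg.synth.n_trials_per_gesture
        fold_ids = cfg.folds if cfg.folds is not None else tuple(range(n_trials))
        for k in fold_ids:
            if not 0 <= k < n_trials:
                raise ValueError(f"leave-one-out fold {k} out of range "
                                 f"[0, {n_trials})")
        folds = {}
        for k in fold_ids:
            test_seqs = [s for s in seqs if s.meta.get("trial") == k]
            train_seqs = [s for s in seqs if s.meta.get("trial") != k]
            folds[f"fold-{k}"] = _evaluate_pair(cfg, train_seqs, test_seqs, G)
            log.append(f"fold {k} done [{time.perf_counter() - t0:.1f}s]")

    # pooled summaries
    def pooled(model_key: str, field_name: str) -> float:
        vals = [f[model_key][field_name] for f in folds.values()]
        return float(np.mean(vals))

    report = {
        "config": _config_dict(cfg),
        "protocol": cfg.protocol,
        "dynamic": cfg.dynamic,
        "count_convention": cfg.count_convention,
        "tie_break": cfg.tie_break,
        "n_sequences": len(seqs),
        "folds": {
            name: {
                mk: {k: v for k, v in res[mk].items() if k != "confusion"}
                for mk in ("3d", "2d")
            } for name, res in folds.items()
        },
        "summary": {
            "3d_voted_accuracy": pooled("3d", "voted_accuracy"),
            "2d_voted_accuracy": pooled("2d", "voted_accuracy"),
        },
        "parameter_counts": {
            "3d": count_parameters(
                build_3d_cnn((cfg.l_cube, cfg.synth.grid.rows,
                              cfg.synth.grid.cols, 1), cfg.pool_s, G,
                             cfg.conv_channels, cfg.dense_units),
                cfg.count_convention),
            "2d": count_parameters(
                build_2d_cnn((cfg.synth.grid.rows, cfg.synth.grid.cols, 1),
                             G, cfg.conv_channels, cfg.dense_units),
                cfg.count_convention),
        },
    }

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "report.json").write_text(json.dumps(report, indent=1))
        for name, res in folds.items():
            for mk in ("3d", "2d"):
                sweep = pd.DataFrame(res[mk]["sweep"],
                                     columns=["window_ms", "accuracy_pct"])
                sweep.to_csv(out_dir / f"sweep_{mk}_{name}.tsv",
                             sep="\t", index=False)
                res[mk]["confusion"].to_csv(
                    out_dir / f"confusion_{mk}_{name}.csv")
        table1 = report_table1(
            [cfg.l_cube], (cfg.synth.grid.rows, cfg.synth.grid.cols),
            cfg.pool_s, G, conv_channels=cfg.conv_channels,
            dense_units=cfg.dense_units)
        table1.to_csv(out_dir / "parameter_counts.tsv", sep="\t", index=False)
        log.append(f"artifacts written to {out_dir} "
                   f"[{time.perf_counter() - t0:.1f}s]")
        (out_dir / "run.log").write_text("\n".join(log) + "\n")
    report["_folds_full"] = folds
    return report


def report_table1(
    l_values,
    input_hw: tuple[int, int],
    pool_s: int,
    G: int,
    conventions=COUNT_CONVENTIONS,
    conv_channels: tuple = (32, 64, 64),
    dense_units: tuple = (512, 128),
    fs: float | None = None,
) -> pd.DataFrame:
    """Weight-count table over cube lengths, one column per convention.

    ``l_values`` are in frames; when ``fs`` is given an extra column
    reports the equivalent window duration in ms so the two units are
    never ambiguous.  A length whose temporal trace collapses is reported
    as a flagged row rather than aborting the table.  The per-frame (2D)
    model's counts, independent of l, are appended as a final row.
    """
    h, w = input_hw
    rows = []
    for l in l_values:
        row: dict = {"l_frames": l}
        if fs is not None:
            row["window_ms"] = 1000.0 * l / fs
        try:
            spec = build_3d_cnn((l, h, w, 1), pool_s, G,
                                conv_channels, dense_units)
            for conv in conventions:
                row[conv] = count_parameters(spec, conv)
            row["note"] = ""
        except ShapeError as exc:
            for conv in conventions:
                row[conv] = np.nan
            row["note"] = f"shape collapse: {exc}"
        rows.append(row)
    spec2d = build_2d_cnn((h, w, 1), G, conv_channels, dense_units)
    row2d: dict = {"l_frames": "2d (any l)"}
    if fs is not None:
        row2d["window_ms"] = np.nan
    for conv in conventions:
        row2d[conv] = count_parameters(spec2d, conv)
    row2d["note"] = "per-frame ablation"
    rows.append(row2d)
    return pd.DataFrame(rows)


def _config_dict(cfg: ExperimentConfig) -> dict:
    d = asdict(cfg)
    g = cfg.synth.grid
    d["synth"]["grid"] = {"rows": g.rows, "cols": g.cols,
                          "layout_name": g.layout_name}
    return d
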
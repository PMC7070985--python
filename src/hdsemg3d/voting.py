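"""Majority voting over consecutive cube predictions and voted evaluation.

A prosthesis controller must issue one command per decision window, and the
window must stay under the 300 ms real-time bound.  Consecutive per-cube
classifier outputs within a voting window of ``nc`` cubes are therefore
fused: the headline decision is the majority vote (one label per window),
while the within-window fraction of correct cube predictions
(:func:`eq3_fraction`) is reported alongside as a finer-grained score.

Voting windows are non-overlapping within a trial and never span trial
boundaries; trailing cubes that do not fill a window are dropped.  Vote
ties resolve to the most recent occurrence among the tied labels, favoring
the newest evidence in an online setting (configurable).
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .cubes import ImageSequence, extract_cubes

__all__ = [
    "REALTIME_BOUND_MS",
    "VotingWindow",
    "ConfusionMatrix",
    "eq3_fraction",
    "majority_vote",
    "evaluate_voted",
    "vote_entire_trial",
    "accuracy_vs_window_sweep",
]

REALTIME_BOUND_MS = 300.0


@dataclass(frozen=True)
class VotingWindow:
    """``nc`` consecutive cubes of ``t_cube`` ms each."""

    nc: int
    t_cube_ms: float

    def __post_init__(self) -> None:
        if self.nc < 1 or self.t_cube_ms <= 0:
            raise ValueError("need nc >= 1 and positive cube duration")
        if self.length_ms > REALTIME_BOUND_MS:
            warnings.warn(
                f"voting window {self.length_ms:.0f} ms exceeds the "
                f"{REALTIME_BOUND_MS:.0f} ms real-time bound"
            )

    @property
    def length_ms(self) -> float:
        return self.nc * self.t_cube_ms


@dataclass
class ConfusionMatrix:
    """G x G count matrix, rows = true gesture, cols = predicted."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("confusion matrix must be square")

    @classmethod
    def empty(cls, G: int) -> "ConfusionMatrix":
        return cls(np.zeros((G, G), dtype=np.int64))

    def add(self, true_label: int, predicted: int) -> None:
        self.counts[true_label, predicted] += 1

    def percentages(self) -> np.ndarray:
        """Row-normalized percentages (rows with no decisions stay 0)."""
        totals = self.counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = np.where(totals > 0, 100.0 * self.counts / totals, 0.0)
        return pct

    def accuracy(self) -> float:
        total = self.counts.sum()
        return 100.0 * np.trace(self.counts) / total if total else float("nan")

    def to_csv(self, path: str | Path) -> Path:
        import pandas as pd

        path = Path(path)
        G = self.counts.shape[0]
        pd.DataFrame(self.counts, index=range(G), columns=range(G)).to_csv(path)
        return path


def eq3_fraction(predictions, target: int) -> float:
    """Percentage of predictions in the window equal to the target gesture."""
    preds = list(predictions)
    if not preds:
        raise ValueError("empty prediction sequence")
    m = sum(1 for p in preds if p == target)
    return 100.0 * m / len(preds)


def majority_vote(predictions, tie_break: str = "most-recent") -> int:
    """Modal label of the window.

    Ties between equally frequent labels resolve to the one whose latest
    occurrence is most recent (``most-recent``, default) or to the smallest
    label (``smallest``).
    """
    preds = list(predictions)
    if not preds:
        raise ValueError("empty prediction sequence")
    counts = Counter(preds)
    top = max(counts.values())
    tied = [lab for lab, c in counts.items() if c == top]
    if len(tied) == 1:
        return tied[0]
    if tie_break == "most-recent":
        last_seen = {lab: i for i, lab in enumerate(preds)}
        return max(tied, key=lambda lab: last_seen[lab])
    if tie_break == "smallest":
        return min(tied)
    raise ValueError(f"unknown tie_break {tie_break!r}")


def _trial_cube_predictions(model, seq: ImageSequence, l_cube: int):
    """Non-overlapping per-cube labels for one trial."""
    ds = extract_cubes(seq, l=l_cube, stride=l_cube)
    labels, _ = model.predict(ds)
    return labels


def evaluate_voted(
    model,
    sequences: list[ImageSequence],
    l_cube: int,
    voting_ms: float,
    tie_break: str = "most-recent",
):
    """Voted accuracy and confusion matrix over a list of test trials.

    Per trial, non-overlapping cubes of ``l_cube`` frames are classified;
    consecutive groups of ``nc = floor(voting_ms / t_cube_ms)`` predictions
    form one majority-vote decision.  Returns
    ``(accuracy_percent, ConfusionMatrix, mean_eq3_percent)``.
    """
    if not sequences:
        raise ValueError("no test sequences")
    fs = sequences[0].fs
    t_cube_ms = 1000.0 * l_cube / fs
    if voting_ms < t_cube_ms:
        raise ValueError(
            f"voting window {voting_ms} ms shorter than one cube "
            f"({t_cube_ms:.1f} ms)"
        )
    nc = int(voting_ms // t_cube_ms)
    VotingWindow(nc=nc, t_cube_ms=t_cube_ms)  # emits real-time warning
    G = _infer_G(model)
    cm = ConfusionMatrix.empty(G)
    eq3_scores = []
    n_correct = n_total = 0
    for seq in sequences:
        preds = _trial_cube_predictions(model, seq, l_cube)
        for w0 in range(0, len(preds) - nc + 1, nc):
            window = preds[w0:w0 + nc].tolist()
            decision = majority_vote(window, tie_break=tie_break)
            cm.add(seq.label, decision)
            eq3_scores.append(eq3_fraction(window, seq.label))
            n_correct += decision == seq.label
            n_total += 1
    if n_total == 0:
        raise ValueError("no voting window fits any test trial")
    return 100.0 * n_correct / n_total, cm, float(np.mean(eq3_scores))


def vote_entire_trial(model, sequence: ImageSequence, l_cube: int,
                      tie_break: str = "most-recent") -> int:
    """One majority decision from all non-overlapping cubes of a trial."""
    preds = _trial_cube_predictions(model, sequence, l_cube)
    return majority_vote(preds.tolist(), tie_break=tie_break)


def accuracy_vs_window_sweep(
    model,
    sequences: list[ImageSequence],
    l_cube: int,
    window_grid_ms,
    tie_break: str = "most-recent",
) -> list[tuple[float, float]]:
    """Voted accuracy at each window length; ``(window_ms, accuracy%)`` rows."""
    grid = list(window_grid_ms)
    if grid != sorted(grid):
        raise ValueError("window grid must be sorted ascending")
    curve = []
    for ms in grid:
        acc, _, _ = evaluate_voted(model, sequences, l_cube, ms,
                                   tie_break=tie_break)
        curve.append((float(ms), acc))
    return curve


def _infer_G(model) -> int:
    spec = getattr(model, "spec", None)
    if spec is not None:
        return spec.n_classes
    raise ValueError("model does not expose a network spec")
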
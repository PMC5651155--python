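"""Classification stage: formula scoring, per-channel KNN, regional vote.

Every channel of a region is scored window-by-window with the evolved
formula, each score is classified spike/nonspike by the shared KNN
reference set, and the region's 26 (occipital: 24) per-channel binary
decisions are combined by strict majority voting: a window is a regional
spike iff more than half the channels vote spike (>13 of 26, >12 of 24).
Performance is summarized as sensitivity = 100*TP/(TP+FN) and
specificity = 100*TN/(TN+FP).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .gp import Tree, evaluate_formula
from .knn import KNNModel
from .preprocess import (
    NONSPIKE,
    SPIKE,
    UNKNOWN,
    Recording,
    SegmentationConfig,
    label_segment,
    recording_features,
)

VOTE_THRESHOLDS = {26: 13, 24: 12}  # spike iff votes strictly exceed


class EvaluationError(ValueError):
    """Regional decisions without known ground truth cannot be scored."""


@dataclass
class RegionalDecision:
    start_sample: int
    channel_votes: np.ndarray
    decision: int
    truth: int = UNKNOWN


@dataclass
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.tn + other.tn, self.fn + other.fn)


def score_segments(recording: Recording, formula: Tree,
                   cfg: SegmentationConfig) -> tuple[np.ndarray, np.ndarray]:
    """(starts, scores): formula output per channel per window.

    scores has shape (channels, n_windows); every value is finite.
    """
    starts, feats = recording_features(recording, cfg)
    c, w, f = feats.shape
    scores = np.asarray(
        evaluate_formula(formula, feats.reshape(c * w, f))).reshape(c, w)
    return starts, scores


def vote_region(channel_votes: np.ndarray) -> int:
    """Strict-majority regional decision over 24 or 26 channel votes."""
    votes = np.asarray(channel_votes, dtype=int)
    if votes.size not in VOTE_THRESHOLDS:
        raise ValueError(f"expected 24 or 26 channel votes, got {votes.size}")
    return SPIKE if votes.sum() > VOTE_THRESHOLDS[votes.size] else NONSPIKE


def detect(recording: Recording, formula: Tree, model: KNNModel,
           cfg: SegmentationConfig,
           annotations: Sequence[tuple[int, int]] | None = None,
           ) -> list[RegionalDecision]:
    """One RegionalDecision per window position.

    Each channel's formula score is classified by the KNN model ("1" spike
    / "0" spike-free) and the votes are combined regionally.  If
    annotations are given, each decision also carries the window's ground
    truth (>= half-window overlap rule).
    """
    starts, scores = score_segments(recording, formula, cfg)
    votes = model.classify_many(scores)  # (channels, windows)
    n = cfg.window_samples(recording.fs)
    threshold = VOTE_THRESHOLDS[recording.channel_count]
    spike_counts = votes.sum(axis=0)
    decisions = []
    for j, start in enumerate(starts):
        truth = UNKNOWN if annotations is None else label_segment(
            int(start), n, annotations)
        decisions.append(RegionalDecision(
            start_sample=int(start),
            channel_votes=votes[:, j],
            decision=SPIKE if spike_counts[j] > threshold else NONSPIKE,
            truth=truth,
        ))
    return decisions


def confusion(decisions: Sequence[RegionalDecision]) -> ConfusionCounts:
    c = ConfusionCounts()
    for d in decisions:
        if d.truth == UNKNOWN:
            raise EvaluationError(
                f"decision at sample {d.start_sample} has unknown truth")
        if d.truth == SPIKE:
            if d.decision == SPIKE:
                c.tp += 1
            else:
                c.fn += 1
        else:
            if d.decision == NONSPIKE:
                c.tn += 1
            else:
                c.fp += 1
    return c


def evaluate(decisions: Sequence[RegionalDecision],
             ) -> tuple[float | None, float | None, ConfusionCounts]:
    """(sensitivity %, specificity %, counts).

    A metric whose denominator is zero is returned as None (reported as
    not applicable), never silently as 0.
    """
    c = confusion(decisions)
    sensitivity = 100.0 * c.tp / (c.tp + c.fn) if c.tp + c.fn else None
    specificity = 100.0 * c.tn / (c.tn + c.fp) if c.tn + c.fp else None
    return sensitivity, specificity, c


def merge_events(decisions: Sequence[RegionalDecision], window: int,
                 step: int) -> list[tuple[int, int]]:
    """Merge adjacent positive windows into human-readable event intervals.

    Consecutive spike decisions whose starts differ by one step are fused;
    purely a reporting convenience, not used in evaluation.
    """
    events: list[tuple[int, int]] = []
    for d in decisions:
        if d.decision != SPIKE:
            continue
        start, end = d.start_sample, d.start_sample + window
        if events and start <= events[-1][1]:
            events[-1] = (events[-1][0], max(events[-1][1], end))
        else:
            events.append((start, end))
    return events


def decisions_frame(decisions: Sequence[RegionalDecision],
                    window: int) -> pd.DataFrame:
    """TSV-ready table: start_sample, end_sample, decision, n_spike_votes."""
    return pd.DataFrame({
        "start_sample": [d.start_sample for d in decisions],
        "end_sample": [d.start_sample + window for d in decisions],
        "decision": [d.decision for d in decisions],
        "n_spike_votes": [int(np.sum(d.channel_votes)) for d in decisions],
    })


def report_text(sensitivity: float | None, specificity: float | None,
                counts: ConfusionCounts) -> str:
    def fmt(x: float | None) -> str:
        return "NA" if x is None else f"{x:.2f}"

    return (
        f"sensitivity\t{fmt(sensitivity)}\n"
        f"specificity\t{fmt(specificity)}\n"
        f"TP\t{counts.tp}\nFP\t{counts.fp}\n"
        f"TN\t{counts.tn}\nFN\t{counts.fn}\n"
    )
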
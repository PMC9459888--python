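"""Strict AND fusion of the two branch classifiers, FalseAlarm metrics, and
per-tree infestation alarm counting.

A window is declared infested only when *both* the temporal and the spectral
CNN call it infested; because the merged positive set is the intersection of
the branch positive sets, its FP and TP counts are bounded by each branch's.
The critical metric is FalseAlarm = FP / (TP + FP): the fraction of
infestation calls that are wrong, which drives needless tree treatment or
removal.  Tree-level decisions accumulate merged alarms per tree and compare
them against the maximum count among reference healthy trees.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionCounts",
    "AlarmLedger",
    "merged_classify",
    "confusion_counts",
    "false_alarm",
    "improvement_pct",
    "count_alarms",
    "infestation_threshold",
    "announce_infested",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion counts with "infested" as the positive class."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.total

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [[self.tp, self.fn], [self.fp, self.tn]],
            index=pd.Index(["infested", "healthy"], name="true"),
            columns=pd.Index(["infested", "healthy"], name="predicted"),
        )


def merged_classify(
    p_temporal: np.ndarray | float,
    p_spectral: np.ndarray | float,
    threshold: float = 0.5,
) -> np.ndarray:
    """Strict AND rule: infested iff both branch probabilities reach threshold.

    Returns a boolean array (True = infested).
    """
    pt = np.asarray(p_temporal, dtype=float)
    ps = np.asarray(p_spectral, dtype=float)
    if np.any((pt < 0) | (pt > 1) | (ps < 0) | (ps > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    return (pt >= threshold) & (ps >= threshold)


def confusion_counts(y_true_infested: np.ndarray, y_pred_infested: np.ndarray) -> ConfusionCounts:
    """Counts from boolean (or {0,1}) arrays where True means infested."""
    t = np.asarray(y_true_infested, dtype=bool)
    p = np.asarray(y_pred_infested, dtype=bool)
    if t.shape != p.shape:
        raise ValueError("shape mismatch between truth and prediction")
    return ConfusionCounts(
        tp=int(np.sum(t & p)),
        fp=int(np.sum(~t & p)),
        tn=int(np.sum(~t & ~p)),
        fn=int(np.sum(t & ~p)),
    )


def false_alarm(counts: ConfusionCounts) -> float:
    """FalseAlarm = 100 x FP / (TP + FP), in percent.

    Undefined (NaN) when no positive calls were made — never reported as 0.
    """
    denom = counts.tp + counts.fp
    if denom == 0:
        return float("nan")
    return 100.0 * counts.fp / denom


def improvement_pct(fa_single: float, fa_merged: float) -> float:
    """Relative FalseAlarm reduction of the merged rule over one branch,
    in percent to one decimal."""
    if not fa_single > 0:
        raise ValueError("improvement undefined for a zero single-branch FalseAlarm")
    return round(100.0 * (fa_single - fa_merged) / fa_single, 1)


@dataclass
class AlarmLedger:
    """Per-tree tally of merged infestation alarms over one experiment."""

    n_examples: dict[str, int] = field(default_factory=dict)
    n_alarms: dict[str, int] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def alarm_rate(self, tree_id: str) -> float:
        n = self.n_examples[tree_id]
        return self.n_alarms[tree_id] / n if n else 0.0

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"tree_id": tid, "n_examples": self.n_examples[tid],
             "n_alarms": self.n_alarms[tid], "alarm_rate": self.alarm_rate(tid)}
            for tid in self.n_examples
        ]
        return pd.DataFrame(rows)


def count_alarms(
    clf_temporal,
    clf_spectral,
    streams: Mapping[str, tuple[np.ndarray, np.ndarray]],
    threshold: float = 0.5,
    metadata: dict | None = None,
) -> AlarmLedger:
    """Run both classifiers over each tree's window stream and tally merged alarms.

    ``streams`` maps tree_id to its (X_temporal, X_spectral) window stacks.
    Equal per-tree counts are expected within one experiment; unequal counts
    trigger a warning (the normalized alarm rate stays meaningful).
    """
    ledger = AlarmLedger(metadata=metadata or {})
    sizes = {tid: xt.shape[0] for tid, (xt, _) in streams.items()}
    if len(set(sizes.values())) > 1:
        warnings.warn(f"unequal per-tree example counts {sizes}; compare alarm rates",
                      stacklevel=2)
    for tid, (xt, xs) in streams.items():
        if xt.shape[0] != xs.shape[0]:
            raise ValueError(f"tree {tid}: temporal/spectral stream length mismatch")
        if xt.shape[0] == 0:
            ledger.n_examples[tid] = 0
            ledger.n_alarms[tid] = 0
            continue
        pt = clf_temporal.predict_proba(xt)[:, 1]
        ps = clf_spectral.predict_proba(xs)[:, 1]
        merged = merged_classify(pt, ps, threshold)
        ledger.n_examples[tid] = int(xt.shape[0])
        ledger.n_alarms[tid] = int(merged.sum())
    return ledger


def infestation_threshold(
    reference_healthy_counts: Mapping[str, int] | list[int] | np.ndarray,
    safety_factor: float = 1.0,
) -> float:
    """Alarm-count threshold from reference healthy trees: their maximum
    false-alarm count (optionally scaled).  A tree is announced infested iff
    its count is strictly greater."""
    counts = (list(reference_healthy_counts.values())
              if isinstance(reference_healthy_counts, Mapping)
              else list(reference_healthy_counts))
    if len(counts) == 0:
        raise ValueError("need at least one reference healthy tree")
    return float(max(counts)) * safety_factor


def announce_infested(ledger: AlarmLedger, threshold: float) -> dict[str, bool]:
    """Tree-level verdicts: alarm count strictly above the reference threshold."""
    return {tid: ledger.n_alarms[tid] > threshold for tid in ledger.n_examples}
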
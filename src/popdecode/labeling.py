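"""Frame labels, windowed training samples, and cut-level aggregation.

Each (frame, character) pair carries one of three labels: YES (character
visibly present), NO (certainly absent), or DNK ("do not know") for
frames inside an ambiguity interval — e.g. a dialogue where the camera
alternates between two partners — where a listed but momentarily
off-screen character cannot be called absent with certainty. DNK pairs
are masked out of the loss and excluded from all performance metrics.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import RateMatrix
from .synthetic import CharacterTimeline

__all__ = ["YES", "NO", "DNK", "FrameLabelTable", "WindowSampleSet",
           "FoldPlan", "build_frame_labels", "make_window_samples",
           "make_fold_plan", "aggregate_frames_to_cuts",
           "confusion_vs_reference", "upsample_predictions"]

YES, NO, DNK = 0, 1, 2
LABEL_NAMES = {YES: "YES", NO: "NO", DNK: "DNK"}


@dataclass
class FrameLabelTable:
    frame_times: np.ndarray    # (F,)
    labels: np.ndarray         # (F, C) int8 in {YES, NO, DNK}

    @property
    def n_characters(self) -> int:
        return self.labels.shape[1]

    def to_frame(self) -> pd.DataFrame:
        f_idx, chars = np.meshgrid(np.arange(len(self.frame_times)),
                                   np.arange(self.n_characters),
                                   indexing="ij")
        return pd.DataFrame({
            "frame_idx": f_idx.ravel(),
            "time_s": np.repeat(self.frame_times, self.n_characters),
            "character": chars.ravel(),
            "label": [LABEL_NAMES[v] for v in self.labels.ravel()]})

    def fractions(self) -> dict[str, float]:
        total = self.labels.size
        return {name: float((self.labels == code).sum()) / total
                for code, name in LABEL_NAMES.items()}


def build_frame_labels(timeline: CharacterTimeline,
                       ambiguity_intervals=None) -> FrameLabelTable:
    """YES where the character occupies the frame; DNK for listed-but-absent
    characters inside an ambiguity interval; NO elsewhere."""
    if ambiguity_intervals is None:
        ambiguity_intervals = timeline.ambiguity_intervals
    intervals = sorted(ambiguity_intervals, key=lambda iv: iv[0])
    for (s1, e1, set1), (s2, e2, set2) in zip(intervals, intervals[1:]):
        if s2 < e1 and frozenset(set1) != frozenset(set2):
            raise ValueError(
                f"contradictory overlapping ambiguity intervals at {s2:.2f}s")
    labels = np.where(timeline.occupancy, YES, NO).astype(np.int8)
    t = timeline.frame_times
    for start, end, chars in intervals:
        in_iv = (t >= start) & (t < end)
        for c in chars:
            absent = in_iv & ~timeline.occupancy[:, c]
            labels[absent, c] = DNK
    return FrameLabelTable(frame_times=t.copy(), labels=labels)


@dataclass
class WindowSampleSet:
    x: np.ndarray              # (n, window, n_units) firing rates
    y: np.ndarray              # (n, C) int8 labels
    frame_times: np.ndarray    # (n,)
    unit_ids: np.ndarray
    n_dropped: int

    @property
    def n_samples(self) -> int:
        return self.x.shape[0]


def make_window_samples(rates: RateMatrix, labels: FrameLabelTable,
                        window_steps: int = 60) -> WindowSampleSet:
    """One sample per eligible frame: the ``window_steps`` rate samples
    covering [t - 1 s, t + 1 s) around the frame time, all units.

    The frame sits between samples window/2 - 1 and window/2 (symmetric
    context). Frames whose window would leave the recording or touch an
    excluded artifact sample are dropped.
    """
    fs = rates.sample_rate_hz
    half = window_steps // 2
    n_samples_total = rates.rates.shape[1]
    xs, ys, ts = [], [], []
    dropped = 0
    for f, t in enumerate(labels.frame_times):
        center = int(round((t - rates.t0) * fs))
        lo, hi = center - half, center + half
        if lo < 0 or hi > n_samples_total:
            dropped += 1
            continue
        if rates.excluded[lo:hi].any():
            dropped += 1
            continue
        xs.append(np.arange(lo, hi))
        ys.append(labels.labels[f])
        ts.append(t)
    if not xs:
        raise ValueError("no eligible frames")
    idx = np.asarray(xs)
    rt = rates.rates.T.astype(np.float32, copy=False)
    x = rt[idx]                                 # (n, window, n_units)
    return WindowSampleSet(x=x, y=np.asarray(ys, dtype=np.int8),
                           frame_times=np.asarray(ts),
                           unit_ids=rates.unit_ids.copy(), n_dropped=dropped)


@dataclass
class FoldPlan:
    folds: list[dict]          # each: {"train","val","test"} index arrays
    seed: int

    @property
    def n_folds(self) -> int:
        return len(self.folds)


def make_fold_plan(n_samples: int, seed: int, n_folds: int = 5) -> FoldPlan:
    """Shuffled n-fold plan: per fold 20% test; of the remaining 80%,
    87.5% train and 12.5% validation (70/10/20 overall)."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_samples)
    groups = np.array_split(order, n_folds)
    folds = []
    for f in range(n_folds):
        test = groups[f]
        rest = np.concatenate([groups[g] for g in range(n_folds) if g != f])
        n_train = int(round(len(rest) * 0.875))
        folds.append({"train": rest[:n_train], "val": rest[n_train:],
                      "test": test})
    return FoldPlan(folds=folds, seed=seed)


def aggregate_frames_to_cuts(frame_pred: np.ndarray, frame_times: np.ndarray,
                             cuts: list[tuple[float, float]],
                             fps: float = 30.0, long_cut_s: float = 1.3,
                             min_frames: int = 12,
                             frac_thresh: float = 0.4) -> pd.DataFrame:
    """Aggregate per-frame detections (at the full frame rate) to cut-level
    presence.

    A character is present in a cut iff the cut is longer than
    ``long_cut_s`` and detections exceed ``frac_thresh`` of its frames,
    or the cut is at most ``long_cut_s`` long and detections reach
    ``min_frames``.
    """
    n_char = frame_pred.shape[1]
    rows = []
    for ci, (start, end) in enumerate(cuts):
        in_cut = (frame_times >= start) & (frame_times < end)
        total = int(in_cut.sum())
        det = frame_pred[in_cut].sum(axis=0) if total else np.zeros(n_char)
        length = end - start
        if length > long_cut_s:
            present = det > frac_thresh * total
        else:
            present = det >= min_frames
        if total == 0:
            present = np.zeros(n_char, dtype=bool)
        rows.append({"cut_id": ci, "start_s": start, "end_s": end,
                     **{f"char_{c}": bool(present[c]) for c in range(n_char)}})
    return pd.DataFrame(rows)


def upsample_predictions(pred: np.ndarray, frame_times: np.ndarray,
                         factor: int = 4) -> tuple[np.ndarray, np.ndarray]:
    """Repeat decoded-grid predictions onto the original (4x finer) grid."""
    up = np.repeat(pred, factor, axis=0)
    dt = (frame_times[1] - frame_times[0]) / factor if len(frame_times) > 1 \
        else 1.0 / 30.0
    times = frame_times[0] + np.arange(len(up)) * dt
    return up, times


def confusion_vs_reference(pred: pd.DataFrame, truth: pd.DataFrame
                           ) -> dict:
    """Normalized per-character and pooled 2x2 confusion matrices.

    Rows are truth (YES, NO), columns prediction (YES, NO); the YES row
    is normalized by the number of truth-YES cuts, the NO row by
    truth-NO cuts. Undefined rows (zero truth cuts) are NaN.
    """
    chars = [c for c in pred.columns if c.startswith("char_")]
    out: dict = {}
    pooled = np.zeros((2, 2))
    pooled_counts = np.zeros(2)
    for c in chars:
        p = pred[c].to_numpy(dtype=bool)
        t = truth[c].to_numpy(dtype=bool)
        mat = np.full((2, 2), np.nan)
        raw = np.array([[np.sum(t & p), np.sum(t & ~p)],
                        [np.sum(~t & p), np.sum(~t & ~p)]], dtype=float)
        pooled += raw
        pooled_counts += np.array([t.sum(), (~t).sum()])
        if t.sum():
            mat[0] = raw[0] / t.sum()
        if (~t).sum():
            mat[1] = raw[1] / (~t).sum()
        out[c] = mat
    overall = np.full((2, 2), np.nan)
    for r in range(2):
        if pooled_counts[r]:
            overall[r] = pooled[r] / pooled_counts[r]
    out["overall"] = overall
    return out
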
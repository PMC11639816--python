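"""Supervised dataset construction: shift-lag labels, sliding windows,
padded segments, and patient-wise splits.

The forecasting target is built by a -L minute shift (default L = 5): row *t*
is paired with the label observed at *t + L*, and the final L rows of each
admission are dropped.  Tree models consume single shifted rows; sequence
models consume 5-minute sliding windows (stride 1, so consecutive windows
overlap by 4 minutes) cut from 1024-row segments padded with the constant
1000, which cannot collide with any clamped feature value.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .preprocess import FEATURE_COLUMNS

__all__ = [
    "Segment",
    "SplitAssignment",
    "WindowDataset",
    "shift_labels",
    "make_windows",
    "segment_and_pad",
    "split_patients",
    "class_weights",
    "build_tree_dataset",
]

DEFAULT_LAG = 5
DEFAULT_WIDTH = 5
SEGMENT_LEN = 1024
PAD_VALUE = 1000.0


def shift_labels(frame: pd.DataFrame, lag_minutes: int = DEFAULT_LAG) -> pd.DataFrame:
    """Pair each row with the label ``lag_minutes`` later (per admission).

    Rows whose future label does not exist are dropped; an admission shorter
    than the lag contributes nothing (with a warning).
    """
    if lag_minutes < 0:
        raise ValueError("lag must be non-negative")
    if lag_minutes == 0:
        return frame.copy()
    parts = []
    group_key = "admission_id" if "admission_id" in frame.columns else None
    groups = frame.groupby(group_key, sort=False) if group_key else [(None, frame)]
    for adm, g in groups:
        if len(g) <= lag_minutes:
            warnings.warn(
                f"admission {adm!r}: length {len(g)} <= lag {lag_minutes}; dropped",
                stacklevel=2,
            )
            continue
        out = g.iloc[:-lag_minutes].copy()
        out["label"] = g["label"].to_numpy()[lag_minutes:]
        parts.append(out)
    if not parts:
        return frame.iloc[0:0].copy()
    return pd.concat(parts, ignore_index=True)


@dataclass
class WindowDataset:
    """Stacked sliding windows: ``X`` (n, W, F), ``y`` (n,), validity flags."""

    X: np.ndarray
    y: np.ndarray
    valid: np.ndarray
    meta: dict = field(default_factory=dict)

    def training_view(self) -> tuple[np.ndarray, np.ndarray]:
        """Only windows free of padded rows."""
        return self.X[self.valid], self.y[self.valid]

    def __len__(self) -> int:
        return len(self.y)


def make_windows(
    features: np.ndarray,
    labels: np.ndarray,
    width: int = DEFAULT_WIDTH,
    stride: int = 1,
    real_rows: np.ndarray | None = None,
) -> WindowDataset:
    """Cut stride-1 sliding windows from one contiguous (shifted) series.

    The window target is the shifted label of the window's last row, i.e. the
    severity ``lag`` minutes after that row.  Windows touching a padded row
    (``real_rows`` = 0) are kept but flagged invalid and excluded from
    training views.
    """
    features = np.asarray(features)
    labels = np.asarray(labels)
    T = features.shape[0]
    if labels.shape[0] != T:
        raise ValueError("features and labels length mismatch")
    if T < width:
        return WindowDataset(
            X=np.empty((0, width, features.shape[1] if features.ndim > 1 else 1)),
            y=np.empty(0, dtype=labels.dtype),
            valid=np.empty(0, dtype=bool),
        )
    starts = np.arange(0, T - width + 1, stride)
    X = np.stack([features[s : s + width] for s in starts])
    y = labels[starts + width - 1]
    if real_rows is None:
        valid = np.ones(starts.size, dtype=bool)
    else:
        real = np.asarray(real_rows).astype(bool)
        valid = np.array([real[s : s + width].all() for s in starts])
    return WindowDataset(X=X, y=y, valid=valid)


@dataclass
class Segment:
    """A fixed-length block of one admission, right-padded with PAD_VALUE."""

    data: np.ndarray  # (seg_len, F)
    labels: np.ndarray  # (seg_len,)
    pad_mask: np.ndarray  # (seg_len,) 1 = real row, 0 = padding

    @property
    def n_real(self) -> int:
        return int(self.pad_mask.sum())


def segment_and_pad(
    features: np.ndarray,
    labels: np.ndarray,
    seg_len: int = SEGMENT_LEN,
    pad_value: float = PAD_VALUE,
) -> list[Segment]:
    """Split a series into ``seg_len``-row segments; pad the last one.

    Only the final segment may contain padding; concatenating all segments and
    dropping padded rows reproduces the input exactly.
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    T = features.shape[0]
    if T == 0:
        raise ValueError("cannot segment an empty series")
    n_seg = -(-T // seg_len)
    segments = []
    for i in range(n_seg):
        chunk = features[i * seg_len : (i + 1) * seg_len]
        lab = labels[i * seg_len : (i + 1) * seg_len]
        n = chunk.shape[0]
        if n < seg_len:
            pad = np.full((seg_len - n, features.shape[1]), pad_value)
            chunk = np.vstack([chunk, pad])
            lab = np.concatenate([lab, np.full(seg_len - n, -1, dtype=labels.dtype)])
        pad_mask = np.zeros(seg_len, dtype=np.int8)
        pad_mask[:n] = 1
        segments.append(Segment(data=chunk, labels=lab, pad_mask=pad_mask))
    return segments


@dataclass
class SplitAssignment:
    """Patient-wise train/val/test partition."""

    assignment: dict
    fractions: tuple[float, float, float]
    seed: int

    def patients(self, split: str) -> list:
        return sorted(p for p, s in self.assignment.items() if s == split)

    def split_frame(self, frame: pd.DataFrame, split: str) -> pd.DataFrame:
        wanted = set(self.patients(split))
        return frame[frame["patient_id"].isin(wanted)].reset_index(drop=True)

    def manifest(self) -> dict:
        digest = hashlib.sha256(
            json.dumps({str(k): v for k, v in sorted(self.assignment.items(), key=lambda kv: str(kv[0]))}).encode()
        ).hexdigest()
        return {
            "seed": self.seed,
            "fractions": list(self.fractions),
            "n_patients": len(self.assignment),
            "assignment_sha256": digest,
        }

    def save(self, path: str | Path) -> None:
        payload = self.manifest()
        payload["assignment"] = {str(k): v for k, v in self.assignment.items()}
        Path(path).write_text(json.dumps(payload, indent=2))


def split_patients(
    patient_ids: Sequence,
    fractions: tuple[float, float, float] = (0.75, 0.125, 0.125),
    seed: int = 0,
) -> SplitAssignment:
    """Randomly partition patients into train/val/test.

    Split sizes follow the fractions by largest-remainder rounding; the
    assignment is reproducible for a fixed seed.  Splitting is by patient,
    never by admission, so no patient leaks across splits.
    """
    ids = list(dict.fromkeys(patient_ids))  # stable de-dup
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    if len(ids) < 8:
        raise ValueError("need at least 8 patients to split")
    n = len(ids)
    quotas = [f * n for f in fractions]
    sizes = [int(q) for q in quotas]
    remainders = [q - s for q, s in zip(quotas, sizes)]
    for i in sorted(range(3), key=lambda i: -remainders[i])[: n - sum(sizes)]:
        sizes[i] += 1
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    names = ("train",) * sizes[0] + ("val",) * sizes[1] + ("test",) * sizes[2]
    assignment = {ids[order[i]]: names[i] for i in range(n)}
    return SplitAssignment(assignment=assignment, fractions=tuple(fractions), seed=seed)


def class_weights(label_counts: Mapping[int, int]) -> dict[int, float]:
    """Inverse-frequency class weights: w_c = N / (K * n_c)."""
    if any(c <= 0 for c in label_counts.values()):
        missing = [k for k, c in label_counts.items() if c <= 0]
        raise ValueError(f"cannot weight absent classes: {missing}")
    total = sum(label_counts.values())
    k = len(label_counts)
    return {cls: total / (k * cnt) for cls, cnt in label_counts.items()}


def build_tree_dataset(
    frame: pd.DataFrame, lag_minutes: int = DEFAULT_LAG
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Single-row (no window) dataset for tree models, labels shifted by lag."""
    shifted = shift_labels(frame, lag_minutes)
    X = shifted[list(FEATURE_COLUMNS)].to_numpy(dtype=np.float64)
    y = shifted["label"].to_numpy(dtype=np.int64)
    return X, y, shifted


def build_window_datasets(
    frame: pd.DataFrame,
    lag_minutes: int = DEFAULT_LAG,
    width: int = DEFAULT_WIDTH,
    stride: int = 1,
    seg_len: int = SEGMENT_LEN,
) -> WindowDataset:
    """Sequence-model dataset: shift labels, segment each admission, then cut
    windows inside segments (windows touching padding are flagged invalid)."""
    shifted = shift_labels(frame, lag_minutes)
    Xs, ys, valids = [], [], []
    for _, g in shifted.groupby("admission_id", sort=False):
        feats = g[list(FEATURE_COLUMNS)].to_numpy(dtype=np.float64)
        labels = g["label"].to_numpy(dtype=np.int64)
        for seg in segment_and_pad(feats, labels, seg_len=seg_len):
            ds = make_windows(seg.data, seg.labels, width=width, stride=stride,
                              real_rows=seg.pad_mask)
            if len(ds):
                Xs.append(ds.X)
                ys.append(ds.y)
                valids.append(ds.valid)
    if not Xs:
        return WindowDataset(
            X=np.empty((0, width, len(FEATURE_COLUMNS))),
            y=np.empty(0, dtype=np.int64),
            valid=np.empty(0, dtype=bool),
        )
    return WindowDataset(
        X=np.concatenate(Xs), y=np.concatenate(ys), valid=np.concatenate(valids)
    )
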
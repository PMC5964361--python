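"""Mean-absolute-value features and labelled feature tables."""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .preprocess import TrialWindow

__all__ = [
    "FeatureTable",
    "compute_mav",
    "build_feature_table",
    "normalize_features",
]


@dataclass
class FeatureTable:
    """Trials x channels MAV matrix with class labels and trial metadata."""

    values: np.ndarray
    labels: np.ndarray
    trial_ids: np.ndarray
    channel_ids: np.ndarray
    normalised: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        self.trial_ids = np.asarray(self.trial_ids, dtype=int)
        self.channel_ids = np.asarray(self.channel_ids, dtype=int)
        n, c = self.values.shape
        if len(self.labels) != n or len(self.trial_ids) != n:
            raise ValueError("labels/trial_ids must align with value rows")
        if len(self.channel_ids) != c:
            raise ValueError("channel_ids must align with value columns")
        if np.any(~np.isfinite(self.values)):
            raise ValueError("feature table contains non-finite values")
        if np.any(self.values < 0):
            raise ValueError("MAV values must be nonnegative")

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    def select_channels(self, channels: Sequence[int]) -> "FeatureTable":
        """Column subset (by position) as a new table."""
        idx = list(channels)
        return FeatureTable(
            values=self.values[:, idx],
            labels=self.labels.copy(),
            trial_ids=self.trial_ids.copy(),
            channel_ids=self.channel_ids[idx],
            normalised=self.normalised,
        )

    # -- persistence: CSV + JSON sidecar ---------------------------------
    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        df = pd.DataFrame(
            self.values, columns=[f"ch{c}" for c in self.channel_ids]
        )
        df.insert(0, "class_id", self.labels)
        df.insert(0, "trial_id", self.trial_ids)
        df.to_csv(path, index=False, float_format="%.17g")
        sidecar = {
            "channel_ids": self.channel_ids.tolist(),
            "normalised": self.normalised,
        }
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(sidecar, indent=2)
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureTable":
        path = Path(path)
        df = pd.read_csv(path, float_precision="round_trip")
        sidecar_path = path.with_suffix(path.suffix + ".json")
        if sidecar_path.exists():
            sidecar = json.loads(sidecar_path.read_text())
        else:
            sidecar = {
                "channel_ids": [
                    int(c[2:]) for c in df.columns if c.startswith("ch")
                ],
                "normalised": False,
            }
        value_cols = [c for c in df.columns if c.startswith("ch")]
        return cls(
            values=df[value_cols].to_numpy(dtype=float),
            labels=df["class_id"].to_numpy(dtype=int),
            trial_ids=df["trial_id"].to_numpy(dtype=int),
            channel_ids=np.asarray(sidecar["channel_ids"], dtype=int),
            normalised=bool(sidecar["normalised"]),
        )


def compute_mav(window: TrialWindow) -> np.ndarray:
    """Per-channel mean absolute value, ``MAV_i = mean(|x_i|)``."""
    if window.samples.size == 0 or window.samples.shape[1] == 0:
        raise ValueError("cannot compute MAV of a zero-length window")
    return np.mean(np.abs(window.samples), axis=1)


def build_feature_table(windows: Sequence[TrialWindow]) -> FeatureTable:
    """One MAV row per trial window, labels and trial ids attached."""
    if not windows:
        raise ValueError("no trial windows supplied")
    n_ch = windows[0].n_channels
    if any(w.n_channels != n_ch for w in windows):
        raise ValueError("all windows must share the same channel count")
    return FeatureTable(
        values=np.stack([compute_mav(w) for w in windows]),
        labels=np.array([w.class_id for w in windows]),
        trial_ids=np.array([w.trial_id for w in windows]),
        channel_ids=np.arange(n_ch),
        normalised=False,
    )


def normalize_features(table: FeatureTable) -> FeatureTable:
    """Per-channel min-max scaling to [0, 1] across trials.

    Used for scatter visualisation only — never fed to the classifier.
    Constant channels map to 0.
    """
    if table.normalised:
        raise ValueError("table is already normalised")
    lo = table.values.min(axis=0)
    hi = table.values.max(axis=0)
    span = hi - lo
    scaled = np.zeros_like(table.values)
    nz = span > 0
    scaled[:, nz] = (table.values[:, nz] - lo[nz]) / span[nz]
    return replace(table, values=scaled, normalised=True)
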
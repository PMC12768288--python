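"""Spectral smoothing and feature scaling.

Spectra are smoothed row-wise with a Savitzky–Golay filter (default
window 15, polynomial order 3) and both modalities are rescaled by
per-feature max–min normalization, x' = (x − min)/(max − min).

The normalization statistics are fitted on the training split only and
then applied to any split; transformed test values may fall outside
[0, 1] and are deliberately not clipped. A constant training column maps
to 0 everywhere.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.signal import savgol_filter

from .synthetic import SpectrumTable

__all__ = ["SGParams", "MinMaxStats", "savitzky_golay_smooth", "fit_min_max", "apply_min_max"]


@dataclass(frozen=True)
class SGParams:
    window: int = 15
    polyorder: int = 3

    def __post_init__(self) -> None:
        if self.window % 2 == 0:
            raise ValueError(f"SG window must be odd, got {self.window}")
        if self.window <= self.polyorder:
            raise ValueError(
                f"SG window ({self.window}) must exceed polyorder ({self.polyorder})"
            )


def savitzky_golay_smooth(table: SpectrumTable, params: SGParams = SGParams()) -> SpectrumTable:
    """Row-wise SG smoothing; grid and labels pass through unchanged.

    Edges use scipy's polynomial-fit extrapolation (``mode='interp'``), so
    any signal that is a polynomial of degree ≤ polyorder is reproduced
    exactly everywhere, including the boundaries.
    """
    if table.grid.n_channels < params.window:
        raise ValueError(
            f"SG window {params.window} exceeds channel count {table.grid.n_channels}"
        )
    smoothed = savgol_filter(
        table.intensities, params.window, params.polyorder, axis=1, mode="interp"
    )
    return SpectrumTable(smoothed, table.grid, table.labels.copy())


@dataclass
class MinMaxStats:
    """Per-feature training minima/maxima; ``constant`` flags min == max."""

    minimum: np.ndarray
    maximum: np.ndarray
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.minimum = np.asarray(self.minimum, dtype=float)
        self.maximum = np.asarray(self.maximum, dtype=float)
        if self.minimum.shape != self.maximum.shape:
            raise ValueError("minimum/maximum shapes differ")
        if np.any(self.maximum < self.minimum):
            raise ValueError("per-feature maximum below minimum")
        if not self.feature_names:
            self.feature_names = [f"f{j}" for j in range(len(self.minimum))]
        if len(self.feature_names) != len(self.minimum):
            raise ValueError("feature_names length mismatch")

    @property
    def constant(self) -> np.ndarray:
        return self.maximum == self.minimum

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "feature_names": self.feature_names,
            "minimum": self.minimum.tolist(),
            "maximum": self.maximum.tolist(),
        }))

    @classmethod
    def from_json(cls, path: str | Path) -> "MinMaxStats":
        d = json.loads(Path(path).read_text())
        return cls(np.asarray(d["minimum"]), np.asarray(d["maximum"]), d["feature_names"])


def fit_min_max(X: np.ndarray, feature_names: list[str] | None = None) -> MinMaxStats:
    X = np.asarray(X, dtype=float)
    if X.size == 0:
        raise ValueError("cannot fit max-min statistics on an empty matrix")
    bad = np.flatnonzero(~np.isfinite(X).all(axis=0))
    if bad.size:
        raise ValueError(f"non-finite values in columns {bad.tolist()}")
    return MinMaxStats(X.min(axis=0), X.max(axis=0), list(feature_names or []))


def apply_min_max(X: np.ndarray, stats: MinMaxStats) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != len(stats.minimum):
        raise ValueError(
            f"matrix has {X.shape[-1] if X.ndim == 2 else '?'} columns, "
            f"stats describe {len(stats.minimum)}"
        )
    span = stats.maximum - stats.minimum
    out = np.zeros_like(X)
    ok = ~stats.constant
    out[:, ok] = (X[:, ok] - stats.minimum[ok]) / span[ok]
    return out
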
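"""Feature and image normalization, fitted on training data only.

Tabular features feeding the regression/forest models are z-scored (zero
mean, unit variance on the training subset).  Clinical features feeding the
network are min-max scaled to [0, 1] with out-of-range held-out values
clamped.  MRI intensity volumes are affinely mapped so the training-set
global min/max land on [-1, +1]; Jacobian-determinant volumes pass through
unchanged.  All statistics live in :class:`NormalizationStats`, which is
serialized alongside every trained model so prediction is reproducible.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ConfigurationError, DataError

__all__ = [
    "NormalizationStats",
    "fit_standardizer",
    "apply_standardizer",
    "invert_standardizer",
    "fit_minmax",
    "minmax_unit",
    "fit_mri_range",
    "normalize_mri",
    "crop_or_pad",
]


@dataclass
class NormalizationStats:
    """Per-feature affine normalization statistics (training subset only)."""

    feature_names: list[str] = field(default_factory=list)
    mean: dict[str, float] = field(default_factory=dict)
    sd: dict[str, float] = field(default_factory=dict)
    min: dict[str, float] = field(default_factory=dict)
    max: dict[str, float] = field(default_factory=dict)
    mri_min: float | None = None
    mri_max: float | None = None
    fitted_on: str = ""

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1))

    @classmethod
    def from_json(cls, path) -> "NormalizationStats":
        return cls(**json.loads(Path(path).read_text()))


def _check_matrix(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise DataError(f"expected a 2-D feature matrix, got shape {X.shape}")
    return X


def fit_standardizer(train_features, feature_names=None, fitted_on: str = "train") -> NormalizationStats:
    """Fit z-scoring statistics (and min/max, for unit scaling) on training rows."""
    X = _check_matrix(train_features)
    if X.shape[0] < 2:
        raise DataError("standardizer needs >= 2 training rows")
    names = list(feature_names) if feature_names is not None else [f"f{i}" for i in range(X.shape[1])]
    if len(names) != X.shape[1]:
        raise DataError("feature_names length does not match matrix width")
    sd = X.std(axis=0, ddof=0)
    for name, s in zip(names, sd):
        if s == 0:
            raise DataError(f"feature '{name}' is constant on the training subset")
    return NormalizationStats(
        feature_names=names,
        mean={n: float(m) for n, m in zip(names, X.mean(axis=0))},
        sd={n: float(s) for n, s in zip(names, sd)},
        min={n: float(v) for n, v in zip(names, X.min(axis=0))},
        max={n: float(v) for n, v in zip(names, X.max(axis=0))},
        fitted_on=fitted_on,
    )


fit_minmax = fit_standardizer  # same statistics object covers both transforms


def _vectors(stats: NormalizationStats, which: tuple[str, str]) -> tuple[np.ndarray, np.ndarray]:
    a = np.array([getattr(stats, which[0])[n] for n in stats.feature_names])
    b = np.array([getattr(stats, which[1])[n] for n in stats.feature_names])
    return a, b


def apply_standardizer(stats: NormalizationStats, features) -> np.ndarray:
    """z = (x - mean) / sd, with the training-fitted statistics."""
    X = _check_matrix(features)
    mean, sd = _vectors(stats, ("mean", "sd"))
    if X.shape[1] != mean.size:
        raise DataError("feature matrix width does not match fitted statistics")
    return (X - mean) / sd


def invert_standardizer(stats: NormalizationStats, z) -> np.ndarray:
    mean, sd = _vectors(stats, ("mean", "sd"))
    return np.asarray(z, dtype=float) * sd + mean


def minmax_unit(stats: NormalizationStats, features, clamp: bool = True) -> np.ndarray:
    """Map to [0, 1] using training min/max; held-out values are clamped."""
    X = _check_matrix(features)
    lo, hi = _vectors(stats, ("min", "max"))
    if np.any(hi <= lo):
        bad = [n for n, l, h in zip(stats.feature_names, lo, hi) if h <= l]
        raise DataError(f"degenerate training range for feature(s): {bad}")
    U = (X - lo) / (hi - lo)
    return np.clip(U, 0.0, 1.0) if clamp else U


def fit_mri_range(train_volumes, stats: NormalizationStats | None = None,
                  fitted_on: str = "train") -> NormalizationStats:
    """Record the global intensity min/max over the training MRI volumes."""
    stats = stats or NormalizationStats(fitted_on=fitted_on)
    lo, hi = np.inf, -np.inf
    n = 0
    for vol in train_volumes:
        v = np.asarray(vol)
        lo, hi = min(lo, float(v.min())), max(hi, float(v.max()))
        n += 1
    if n == 0:
        raise DataError("no training volumes supplied")
    if hi <= lo:
        raise DataError("degenerate MRI intensity range (max <= min)")
    stats.mri_min, stats.mri_max = lo, hi
    return stats


def normalize_mri(stats: NormalizationStats, volume, literal_formula: bool = False) -> np.ndarray:
    """Map MRI intensities to [-1, 1].

    Default: the exact affine map sending the training-set global min to -1
    and max to +1.  ``literal_formula=True`` instead applies
    ``x / (0.5 * max) - 1`` after subtracting the minimum, which reaches
    [-1, 1] only when the minimum is 0 (compatibility switch).
    """
    if stats.mri_min is None or stats.mri_max is None:
        raise DataError("MRI range not fitted; call fit_mri_range first")
    v = np.asarray(volume, dtype=float)
    if literal_formula:
        return (v - stats.mri_min) / (0.5 * stats.mri_max) - 1.0
    return 2.0 * (v - stats.mri_min) / (stats.mri_max - stats.mri_min) - 1.0


def crop_or_pad(volume, target_shape, mode: str) -> np.ndarray:
    """Center-aligned crop or symmetric zero-pad to ``target_shape``.

    Odd size differences put the extra voxel on the high-index side.  Crop
    requires source >= target on every axis, pad requires source <= target.
    """
    v = np.asarray(volume)
    target = tuple(int(n) for n in target_shape)
    if v.ndim != len(target):
        raise ConfigurationError("target_shape rank does not match the volume")
    if mode == "crop":
        if any(s < t for s, t in zip(v.shape, target)):
            raise ConfigurationError(
                f"cannot crop {v.shape} to larger shape {target}")
        slices = tuple(slice((s - t) // 2, (s - t) // 2 + t)
                       for s, t in zip(v.shape, target))
        return v[slices].copy()
    if mode == "pad":
        if any(s > t for s, t in zip(v.shape, target)):
            raise ConfigurationError(
                f"cannot zero-pad {v.shape} to smaller shape {target}")
        pads = tuple(((t - s) // 2, t - s - (t - s) // 2)
                     for s, t in zip(v.shape, target))
        return np.pad(v, pads, mode="constant")
    raise ConfigurationError(f"mode must be 'crop' or 'pad', got {mode!r}")
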
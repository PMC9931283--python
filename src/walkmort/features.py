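"""Per-epoch time-domain feature extraction.

Each 30-second epoch holds ``n = sampling_rate * 30`` tri-axial samples
``a_i = (x_i, y_i, z_i)`` in g, with magnitude ``r_i = sqrt(x_i^2 + y_i^2 +
z_i^2)``.  All 76 registry features are functions of these four series.

Conventions (committed once, applied uniformly):

* ``Sd`` is the sample standard deviation (n-1 denominator); ``MPD`` and the
  covariances use the population (n) denominator, so Sd and MPD differ.
* Quantiles interpolate linearly between order statistics.
* ``kurt`` is excess kurtosis (normal -> 0); kurt/skew use plain moment
  estimators and are defined as 0 for a constant series.
* ``autocorr`` is the lag-1-sample Pearson autocorrelation (10 ms at 100 Hz);
  correlations involving a constant series are defined as 0.
* Crossing counts: a sample exactly on the threshold registers no crossing.
* Orientation angles are reported in degrees; ``yaw`` uses the z-axis formula
  by symmetry (a static accelerometer cannot observe yaw; this is a naming
  convention, not physics).
"""

from __future__ import annotations

import warnings

import numpy as np

from .registry import FEATURE_NAMES, N_FEATURES

EPOCH_SECONDS = 30.0

__all__ = [
    "EPOCH_SECONDS",
    "enmo_features",
    "moment_features",
    "crossing_features",
    "dependence_features",
    "orientation_features",
    "extract_epoch_features",
    "extract_feature_table",
    "aggregate_participant",
]


def _as_samples(epoch) -> np.ndarray:
    samples = getattr(epoch, "samples", epoch)
    samples = np.asarray(samples, dtype=float)
    if samples.ndim != 2 or samples.shape[1] != 3:
        raise ValueError(f"epoch samples must be (n, 3); got shape {samples.shape}")
    if samples.shape[0] < 2:
        raise ValueError("epoch must contain at least 2 samples")
    if not np.all(np.isfinite(samples)):
        raise ValueError("epoch contains non-finite samples")
    return samples


def _magnitude(samples: np.ndarray) -> np.ndarray:
    return np.sqrt(np.einsum("ij,ij->i", samples, samples))


def _series(samples: np.ndarray) -> dict[str, np.ndarray]:
    return {
        "": _magnitude(samples),
        "x": samples[:, 0],
        "y": samples[:, 1],
        "z": samples[:, 2],
    }


def enmo_features(epoch) -> dict[str, float]:
    """Euclidean Norm Minus One, truncated and absolute variants (g)."""
    r = _magnitude(_as_samples(epoch))
    dev = r - 1.0
    return {
        "ENMOtrunc": float(np.mean(np.maximum(dev, 0.0))),
        "ENMOabs": float(np.mean(np.abs(dev))),
    }


def _sample_sd(s: np.ndarray) -> float:
    return float(np.std(s, ddof=1))


def moment_features(epoch) -> dict[str, float]:
    """Location, spread, shape and order statistics of magnitude and axes."""
    samples = _as_samples(epoch)
    out: dict[str, float] = {}
    for prefix, s in _series(samples).items():
        mean = float(np.mean(s))
        sd = _sample_sd(s)
        out[f"{prefix}Mean"] = mean
        out[f"{prefix}Sd"] = sd
        out[f"{prefix}Min"] = float(np.min(s))
        out[f"{prefix}Max"] = float(np.max(s))
        q25, q50, q75 = np.quantile(s, [0.25, 0.5, 0.75])
        out[f"{prefix}25thp"] = float(q25)
        out[f"{prefix}Median"] = float(q50)
        out[f"{prefix}75thp"] = float(q75)
        out[f"{prefix}coefvariation"] = sd / mean if (sd > 0.0 and mean != 0.0) else 0.0
        out[f"{prefix}RMS"] = float(np.sqrt(np.mean(s * s)))
        if prefix == "":
            dev = s - mean
            m2 = float(np.mean(dev**2))
            out["MAD"] = float(np.mean(np.abs(dev)))
            out["MPD"] = float(np.sqrt(m2))
            if m2 > 0.0:
                out["skew"] = float(np.mean(dev**3)) / m2**1.5
                out["kurt"] = float(np.mean(dev**4)) / m2**2 - 3.0
            else:
                out["skew"] = 0.0
                out["kurt"] = 0.0
        else:
            out[f"{prefix}Range"] = out[f"{prefix}Max"] - out[f"{prefix}Min"]
    return out


def _crossing_count(s: np.ndarray, level: float) -> int:
    d = s - level
    return int(np.count_nonzero(d[:-1] * d[1:] < 0.0))


def crossing_features(epoch, duration_s: float = EPOCH_SECONDS) -> dict[str, float]:
    """Mean/min-max crossing rates (crossings per second) and activity counts.

    TAC for the magnitude sums the gravity-adjusted positive deviations
    ``max(r_i - 1, 0)``; per-axis TAC sums absolute deviations about the axis
    mean.  MMCR averages the crossing rates of the two levels halfway between
    the mean and the extrema.
    """
    samples = _as_samples(epoch)
    out: dict[str, float] = {}
    for prefix, s in _series(samples).items():
        mean = float(np.mean(s))
        out[f"{prefix}MCR"] = _crossing_count(s, mean) / duration_s
        hi = 0.5 * (mean + float(np.max(s)))
        lo = 0.5 * (mean + float(np.min(s)))
        out[f"{prefix}MMCR"] = 0.5 * (
            _crossing_count(s, hi) / duration_s + _crossing_count(s, lo) / duration_s
        )
        if prefix == "":
            out["TAC"] = float(np.sum(np.maximum(s - 1.0, 0.0)))
        else:
            out[f"{prefix}TAC"] = float(np.sum(np.abs(s - mean)))
    return out


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    # constancy is checked on the values (max == min), not on a rounded
    # variance, so an exactly-flat series reliably hits the 0 convention
    if a.max() == a.min() or b.max() == b.min():
        return 0.0
    sa = float(np.std(a))
    sb = float(np.std(b))
    cov = float(np.mean((a - np.mean(a)) * (b - np.mean(b))))
    return cov / (sa * sb)


def dependence_features(epoch) -> dict[str, float]:
    """Axis-pair covariance/correlation and lag-1 autocorrelations."""
    samples = _as_samples(epoch)
    series = _series(samples)
    out: dict[str, float] = {}
    for pair in ("xy", "xz", "yz"):
        a, b = series[pair[0]], series[pair[1]]
        out[f"Cov{pair}"] = float(np.mean((a - np.mean(a)) * (b - np.mean(b))))
        out[f"corr{pair}"] = _pearson(a, b)
    for prefix, s in series.items():
        out[f"{prefix}autocorr"] = _pearson(s[:-1], s[1:])
    return out


def _angles_deg(x, y, z) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    pitch = np.degrees(np.arctan2(x, np.sqrt(y**2 + z**2)))
    roll = np.degrees(np.arctan2(y, np.sqrt(x**2 + z**2)))
    yaw = np.degrees(np.arctan2(z, np.sqrt(x**2 + y**2)))
    return pitch, roll, yaw


def orientation_features(epoch) -> dict[str, float]:
    """Pitch/roll/yaw of the gravity vector and their per-sample spread.

    The ``g`` variants evaluate the angle formulas on the epoch-mean vector;
    ``avg``/``sd`` are the mean and sample standard deviation of the
    per-sample angles.  A zero mean vector yields all-zero orientation
    features with a warning.
    """
    samples = _as_samples(epoch)
    mean_vec = samples.mean(axis=0)
    names = ("pitch", "roll", "yaw")
    out: dict[str, float] = {}
    if np.allclose(mean_vec, 0.0):
        warnings.warn("zero epoch-mean vector; orientation features set to 0", stacklevel=2)
        for angle in names:
            out[f"{angle}g"] = 0.0
            out[f"avg{angle}"] = 0.0
            out[f"sd{angle}"] = 0.0
        return out
    g_angles = _angles_deg(*mean_vec)
    per_sample = _angles_deg(samples[:, 0], samples[:, 1], samples[:, 2])
    for angle, g_val, series in zip(names, g_angles, per_sample):
        out[f"{angle}g"] = float(g_val)
        out[f"avg{angle}"] = float(np.mean(series))
        out[f"sd{angle}"] = _sample_sd(series)
    return out


def extract_epoch_features(epoch, duration_s: float = EPOCH_SECONDS) -> np.ndarray:
    """All 76 registry features of one epoch, in registry order."""
    values: dict[str, float] = {}
    values.update(enmo_features(epoch))
    values.update(moment_features(epoch))
    values.update(crossing_features(epoch, duration_s=duration_s))
    values.update(dependence_features(epoch))
    values.update(orientation_features(epoch))
    vec = np.array([values[name] for name in FEATURE_NAMES], dtype=float)
    if not np.all(np.isfinite(vec)):
        bad = [n for n, v in zip(FEATURE_NAMES, vec) if not np.isfinite(v)]
        raise AssertionError(f"non-finite feature values for {bad}")
    return vec


def extract_feature_table(epochs, duration_s: float = EPOCH_SECONDS) -> np.ndarray:
    """Stack epoch feature vectors into an (n_epochs, 76) array."""
    rows = [extract_epoch_features(ep, duration_s=duration_s) for ep in epochs]
    if not rows:
        return np.empty((0, N_FEATURES))
    return np.vstack(rows)


def aggregate_participant(feature_vectors) -> np.ndarray:
    """Participant-level feature vector: element-wise mean over included epochs."""
    arr = np.asarray(feature_vectors, dtype=float)
    if arr.ndim == 1:
        arr = arr.reshape(1, -1)
    if arr.size == 0:
        raise ValueError("no epoch feature vectors to aggregate; participant should have been excluded")
    if arr.shape[1] != N_FEATURES:
        raise ValueError(f"expected {N_FEATURES}-dimensional vectors, got {arr.shape[1]}")
    return arr.mean(axis=0)
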
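"""The 23 per-segment scalar features of an SCR driver.

Four families: temporal (M, SD, MA, MI, DR, D1, D2, D1M, D2M, D1SD,
D2SD), morphological (AL, IN, AP, RMS, IL, EL), statistical (SK, KU, MO)
and frequency-band power (F1, F2, F3 over 0.1–0.2, 0.2–0.3 and
0.3–0.4 Hz).  Degenerate cases (zero variance, zero area) yield NaN
sentinels with a warning instead of raising, so a sheet can always be
assembled; downstream analyses skip flagged entries with a logged count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, fields

import numpy as np
from scipy import signal as sps

#: frozen column order of the feature sheet
FEATURE_NAMES: tuple[str, ...] = (
    "M", "SD", "MA", "MI", "DR", "D1", "D2", "D1M", "D2M", "D1SD", "D2SD",
    "AL", "IN", "AP", "RMS", "IL", "EL",
    "SK", "KU", "MO",
    "F1", "F2", "F3",
)

#: half-open frequency bands, Hz
BANDS: dict[str, tuple[float, float]] = {
    "F1": (0.1, 0.2),
    "F2": (0.2, 0.3),
    "F3": (0.3, 0.4),
}

#: degree of each feature under amplitude scaling y -> c*y (c > 0);
#: used as a property check, and handy when reasoning about units
SCALE_DEGREE: dict[str, float] = {
    "M": 1, "SD": 1, "MA": 1, "MI": 1, "DR": 1,
    "D1": 1, "D2": 1, "D1M": 1, "D2M": 1, "D1SD": 1, "D2SD": 1,
    "IN": 1, "AP": 2, "RMS": 1,
    "SK": 0, "KU": 0, "MO": 3,
    "F1": 2, "F2": 2, "F3": 2,
    # AL, IL, EL are not homogeneous (mix time and amplitude units)
}


@dataclass
class FeatureVector:
    """The 23 per-segment scalars in the frozen sheet order, plus metadata."""

    M: float; SD: float; MA: float; MI: float; DR: float
    D1: float; D2: float; D1M: float; D2M: float; D1SD: float; D2SD: float
    AL: float; IN: float; AP: float; RMS: float; IL: float; EL: float
    SK: float; KU: float; MO: float
    F1: float; F2: float; F3: float
    fs: float = 0.0
    n_samples: int = 0

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in FEATURE_NAMES])

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in FEATURE_NAMES}

    def validate(self) -> None:
        vals = self.as_dict()
        assert np.isclose(vals["DR"], vals["MA"] - vals["MI"], atol=1e-9)
        assert vals["MI"] <= vals["M"] + 1e-12 and vals["M"] <= vals["MA"] + 1e-12
        if np.isfinite(vals["AP"]):
            assert np.isclose(vals["RMS"], np.sqrt(vals["AP"]), atol=1e-12)


def _flag(name: str, reason: str) -> float:
    warnings.warn(f"feature {name} undefined ({reason}); NaN sentinel", stacklevel=3)
    return np.nan


def temporal_features(y: np.ndarray, fs: float) -> dict[str, float]:
    """Mean/spread/range plus first- and second-derivative summaries.

    The first derivative is the central difference (one-sided at the
    edges); the second derivative is the second difference scaled by fs².
    D1 and D2 are the peak absolute derivative values ("peak slope").
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if n < 4:
        raise ValueError(f"need >= 4 samples for temporal features, got {n}")
    d1 = np.gradient(y, 1.0 / fs)
    d2 = np.diff(y, 2) * fs**2
    return {
        "M": float(np.mean(y)),
        "SD": float(np.std(y, ddof=1)),
        "MA": float(np.max(y)),
        "MI": float(np.min(y)),
        "DR": float(np.max(y) - np.min(y)),
        "D1": float(np.max(np.abs(d1))),
        "D2": float(np.max(np.abs(d2))),
        "D1M": float(np.mean(d1)),
        "D2M": float(np.mean(d2)),
        "D1SD": float(np.std(d1, ddof=1)),
        "D2SD": float(np.std(d2, ddof=1)),
    }


def morphological_features(y: np.ndarray, fs: float) -> dict[str, float]:
    """Arc length, area, power and their ratios.

    AL = sum sqrt(dt² + Δy²); IN = trapezoidal ∫|y| dt; AP = mean(y²);
    RMS = sqrt(AP); IL = AL / IN; EL = E / AL with E = sum y² dt.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if n < 2:
        raise ValueError("need >= 2 samples for morphological features")
    dt = 1.0 / fs
    al = float(np.sum(np.sqrt(dt**2 + np.diff(y) ** 2)))
    integral = float(np.trapezoid(np.abs(y), dx=dt))
    ap = float(np.mean(y**2))
    energy = float(np.sum(y**2) * dt)
    il = al / integral if integral != 0 else _flag("IL", "zero integral area")
    el = energy / al if al != 0 else _flag("EL", "zero arc length")
    return {"AL": al, "IN": integral, "AP": ap, "RMS": float(np.sqrt(ap)), "IL": il, "EL": el}


def statistical_features(y: np.ndarray, mo_order: int = 3) -> dict[str, float]:
    """Skewness, kurtosis and the "momentum" central moment.

    SK is the biased Fisher–Pearson skewness m3/m2^1.5; KU is non-excess
    Pearson kurtosis m4/m2²; MO is the unnormalised central moment of
    ``mo_order`` (3 by default).
    """
    y = np.asarray(y, dtype=float)
    if y.size < 4:
        raise ValueError("need >= 4 samples for statistical features")
    m = y.mean()
    dev = y - m
    m2 = float(np.mean(dev**2))
    mo = float(np.mean(dev**mo_order))
    if m2 == 0:
        return {"SK": _flag("SK", "zero variance"), "KU": _flag("KU", "zero variance"), "MO": 0.0}
    m3 = float(np.mean(dev**3))
    m4 = float(np.mean(dev**4))
    return {"SK": m3 / m2**1.5, "KU": m4 / m2**2, "MO": mo}


def frequency_features(y: np.ndarray, fs: float) -> dict[str, float]:
    """Band-integrated periodogram power in the three 0.1-Hz-wide bands.

    The periodogram is the plain (untapered) one-sided FFT power spectrum
    of the mean-removed series; each Fk sums P(f)·df over the half-open
    band [lo, hi).
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if fs < 0.8:
        raise ValueError("fs must be >= 0.8 Hz for the 0.1–0.4 Hz bands")
    if n / fs < 20.0:
        raise ValueError(
            f"segment of {n / fs:.1f} s too short; need >= 20 s for 0.05 Hz resolution"
        )
    f, p = sps.periodogram(y, fs=fs, window="boxcar", detrend="constant")
    df = fs / n
    out = {}
    for name, (lo, hi) in BANDS.items():
        mask = (f >= lo) & (f < hi)
        out[name] = float(np.sum(p[mask]) * df)
    return out


def extract_features(y: np.ndarray, fs: float, mo_order: int = 3) -> FeatureVector:
    """All 23 features of one segment driver, in the frozen order."""
    vals = {}
    vals.update(temporal_features(y, fs))
    vals.update(morphological_features(y, fs))
    vals.update(statistical_features(y, mo_order=mo_order))
    vals.update(frequency_features(y, fs))
    fv = FeatureVector(**vals, fs=fs, n_samples=int(np.asarray(y).size))
    fv.validate()
    return fv
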
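"""Time-series statistics for growth, vesicle and thickness dynamics.

Small, self-contained estimators used on tip-growth time lapses: relative
fluctuation amplitude, normalized time-lagged cross-correlation, photobleach
correction against a fixed-cell reference, kymograph fiducial tracking (an
advection check), and the kinematic strain rate of a hemispherical tip.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "Kymograph",
    "relative_std",
    "cross_correlation",
    "bleach_correct",
    "fiducial_drift",
    "strain_rate_from_kinematics",
]


@dataclass(frozen=True)
class Kymograph:
    """Thickness field h(s, t) on a rectangular grid, plus tip position.

    t : (nt,) minutes; s : (ns,) um, arclength behind the tip;
    h : (nt, ns) nm; tip_position : (nt,) um, lab-frame tip coordinate.
    """

    t: np.ndarray
    s: np.ndarray
    h: np.ndarray
    tip_position: np.ndarray

    def __post_init__(self):
        h = np.asarray(self.h)
        if h.shape != (len(self.t), len(self.s)):
            raise ValueError("h must have shape (len(t), len(s))")


def relative_std(series) -> float:
    """Sample standard deviation (n-1) over the mean.

    The dimensionless fluctuation amplitude of a quasi-stationary trace.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 samples")
    m = x.mean()
    if m == 0:
        raise ValueError("zero-mean series: relative std undefined")
    return float(x.std(ddof=1) / abs(m))


def cross_correlation(a, b, max_lag: int) -> pd.DataFrame:
    """Normalized time-lagged cross-correlation of two uniform series.

    For each lag ``dt`` (in samples), the mean over the overlap of
    (a(t) - <a>)*(b(t+dt) - <b>) divided by the product of the full-series
    standard deviations.  Means and standard deviations are those of the
    full series (population normalization, so the autocorrelation at dt=0 is
    exactly 1); the overlap simply shrinks at larger lags, which is why
    ``max_lag`` is capped at n/3.

    Returns a DataFrame with columns (lag, corr); positive lag means b is
    evaluated later than a.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be 1-D and the same length")
    n = len(a)
    if max_lag > n // 3:
        raise ValueError(f"max_lag {max_lag} exceeds n/3 = {n // 3}")
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        raise ValueError("zero-variance input")
    da, db = a - a.mean(), b - b.mean()
    lags = np.arange(-max_lag, max_lag + 1)
    corr = np.empty(len(lags))
    for i, dt in enumerate(lags):
        if dt >= 0:
            prod = da[: n - dt] * db[dt:]
        else:
            prod = da[-dt:] * db[: n + dt]
        corr[i] = prod.mean() / (sa * sb)
    return pd.DataFrame({"lag": lags, "corr": corr})


def bleach_correct(trace, reference_trace,
                   fit_exponential: bool = False) -> np.ndarray:
    """Divide a trace by a photobleaching reference.

    The reference is an intensity trace from fixed cells imaged with the
    same illumination cadence; it is normalized to its initial value, so a
    constant reference leaves the trace unchanged.  With
    ``fit_exponential=True`` a single-exponential decay is fitted to the
    reference (log-linear least squares) and the fit, rather than the raw
    noisy reference, divides the trace -- this keeps reference shot noise
    out of the corrected trace.
    """
    tr = np.asarray(trace, dtype=float)
    ref = np.asarray(reference_trace, dtype=float)
    if tr.shape != ref.shape:
        raise ValueError("trace and reference must be the same length")
    if ref[0] <= 0:
        raise ValueError("reference must start positive")
    if np.any(ref <= 0):
        raise ValueError("reference reaches zero or below; cannot correct")
    if fit_exponential:
        i = np.arange(len(ref), dtype=float)
        k, logA = np.polyfit(i, np.log(ref), 1)
        ref = np.exp(logA + k * i)
    refn = ref / ref[0]
    return tr / refn


def _parabolic_refine(y: np.ndarray, i: int) -> float:
    """Subpixel extremum position by a parabola through (i-1, i, i+1)."""
    if i <= 0 or i >= len(y) - 1:
        return float(i)
    denom = y[i - 1] - 2 * y[i] + y[i + 1]
    if denom == 0:
        return float(i)
    return i + 0.5 * (y[i - 1] - y[i + 1]) / denom


def fiducial_drift(kymo: Kymograph, min_frames: int = 5) -> float:
    """Lab-frame drift speed (um/min) of a local thickness mark.

    A local thickness extremum is localized per frame (parabolic subpixel
    refinement of |h - median(h)| along s), converted to the lab frame as
    tip_position(t) - s_mark(t), and the drift is the least-squares slope of
    that position against time.  Zero drift means the mark is fixed in the
    lab frame, i.e. no advective backward flow of wall material.
    """
    nt = len(kymo.t)
    ds = float(np.mean(np.diff(kymo.s)))
    positions = np.full(nt, np.nan)
    for k in range(nt):
        prof = kymo.h[k]
        dev = np.abs(prof - np.median(prof))
        i = int(np.argmax(dev))
        # require the mark to stand out from frame noise
        if dev[i] < 3.0 * np.median(np.abs(prof - np.median(prof)) + 1e-12):
            continue
        s_mark = kymo.s[0] + _parabolic_refine(prof, i) * ds
        positions[k] = kymo.tip_position[k] - s_mark
    ok = np.isfinite(positions)
    if ok.sum() < min_frames:
        raise ValueError(
            f"thickness mark trackable in only {int(ok.sum())} frames "
            f"(< {min_frames}); no persistent fiducial"
        )
    slope = np.polyfit(kymo.t[ok], positions[ok], 1)[0]
    return float(slope)


def strain_rate_from_kinematics(tip_speed: float, R: float) -> float:
    """Strain rate G (1/min) from tip speed (um/min) and tip radius R (um).

    G is the surface growth rate over R^2; a hemispherical cap advancing at
    v creates surface at 2*pi*R*v, hence G = 2*pi*v/R.
    """
    if R <= 0:
        raise ValueError("R must be positive")
    return 2.0 * np.pi * tip_speed / R
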
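"""Beringian paleotemperature from a smoothed, anchor-calibrated δ18O record.

The global benthic δ18O curve is a proxy for temperature (heavier values =
colder).  The pipeline smooths the record with a 50-point running mean and
maps smoothed δ18O onto Beringian mean annual temperature through three
anchors: −9 °C today (0 Ma), 4 °C at 9 Ma and 11 °C at 14 Ma.  The map is
piecewise linear in δ18O space and passes through the anchors exactly, so the
calibrated curve reproduces the anchor temperatures by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_ANCHORS",
    "IsotopeSeries",
    "CalibrationAnchors",
    "PaleoCurve",
    "running_mean",
    "calibrate",
]

DEFAULT_ANCHORS: Tuple[Tuple[float, float], ...] = ((0.0, -9.0), (9.0, 4.0), (14.0, 11.0))


@dataclass
class IsotopeSeries:
    """δ18O samples ordered by age (Ma before present)."""

    age_ma: np.ndarray
    d18o: np.ndarray

    def __post_init__(self) -> None:
        self.age_ma = np.asarray(self.age_ma, dtype=float)
        self.d18o = np.asarray(self.d18o, dtype=float)
        if self.age_ma.shape != self.d18o.shape or self.age_ma.ndim != 1:
            raise ValueError("age and d18o must be 1-D arrays of equal length")
        if not np.all(np.isfinite(self.age_ma)):
            raise ValueError("ages must be finite")
        diffs = np.diff(self.age_ma)
        if np.all(diffs > 0):
            pass
        elif np.all(diffs < 0):
            self.age_ma = self.age_ma[::-1]
            self.d18o = self.d18o[::-1]
        else:
            raise ValueError("ages must be strictly monotone")

    def __len__(self) -> int:
        return len(self.age_ma)

    @classmethod
    def from_csv(cls, path_or_buf) -> "IsotopeSeries":
        df = pd.read_csv(path_or_buf)
        return cls(df["age_ma"].to_numpy(), df["d18o_permil"].to_numpy())


@dataclass
class CalibrationAnchors:
    """(age Ma, temperature °C) pairs pinning the δ18O→temperature map."""

    anchors: Tuple[Tuple[float, float], ...] = DEFAULT_ANCHORS

    def __post_init__(self) -> None:
        if len(self.anchors) < 2:
            raise ValueError("need at least two anchors")
        ages = [a for a, _ in self.anchors]
        if len(set(ages)) != len(ages):
            raise ValueError("anchor ages must be distinct")
        self.anchors = tuple(sorted(self.anchors))


@dataclass
class PaleoCurve:
    """Calibrated (age, smoothed δ18O, temperature) series."""

    age_ma: np.ndarray
    d18o_smoothed: np.ndarray
    temp_c: np.ndarray
    window: int = 50
    anchors: CalibrationAnchors = field(default_factory=CalibrationAnchors)

    def temp_at(self, age: float) -> float:
        """Temperature at `age` by linear interpolation; no extrapolation."""
        lo, hi = self.age_ma[0], self.age_ma[-1]
        if not (lo <= age <= hi):
            raise ValueError(
                f"age {age} Ma outside the curve span [{lo}, {hi}] Ma")
        return float(np.interp(age, self.age_ma, self.temp_c))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "age_ma": self.age_ma,
            "d18o_smoothed": self.d18o_smoothed,
            "temp_c": self.temp_c,
        })


def running_mean(series: IsotopeSeries, window: int = 50) -> IsotopeSeries:
    """Centered moving average over `window` samples.

    At the edges the window shrinks symmetrically (the first and last points
    are averaged over fewer samples) so the output stays aligned to the input
    ages.
    """
    n = len(series)
    if window < 1:
        raise ValueError("window must be >= 1")
    if window > n:
        raise ValueError(f"window {window} exceeds series length {n}")
    half = (window - 1) // 2
    out = np.empty(n)
    cum = np.concatenate([[0.0], np.cumsum(series.d18o)])
    for i in range(n):
        h = min(half, i, n - 1 - i)
        out[i] = (cum[i + h + 1] - cum[i - h]) / (2 * h + 1)
    return IsotopeSeries(series.age_ma.copy(), out)


def calibrate(smoothed: IsotopeSeries,
              anchors: CalibrationAnchors | Sequence[Tuple[float, float]] = DEFAULT_ANCHORS,
              window: int = 50,
              method: str = "anchor_exact") -> PaleoCurve:
    """Map smoothed δ18O to temperature through the calibration anchors.

    ``anchor_exact`` (default) builds the piecewise-linear map in δ18O space
    through the (smoothed δ18O at anchor age, anchor temperature) pairs,
    linearly extended beyond the outermost anchors, so every anchor is
    reproduced exactly.  ``least_squares`` fits a single straight line to the
    same pairs instead.
    """
    if not isinstance(anchors, CalibrationAnchors):
        anchors = CalibrationAnchors(tuple(anchors))
    span_lo, span_hi = smoothed.age_ma[0], smoothed.age_ma[-1]
    for a, _ in anchors.anchors:
        if not (span_lo <= a <= span_hi):
            raise ValueError(f"anchor age {a} Ma outside series span")
    # make every anchor age an explicit grid point so that age-interpolation
    # through temp_at reproduces the anchors exactly
    ages = smoothed.age_ma
    vals = smoothed.d18o
    missing = [a for a, _ in anchors.anchors if a not in ages]
    if missing:
        add = np.array(missing)
        ages = np.sort(np.concatenate([ages, add]))
        vals = np.interp(ages, smoothed.age_ma, smoothed.d18o)
        smoothed = IsotopeSeries(ages, vals)
    iso_at = [float(np.interp(a, smoothed.age_ma, smoothed.d18o))
              for a, _ in anchors.anchors]
    temps = [t for _, t in anchors.anchors]
    if len(set(np.round(iso_at, 12))) != len(iso_at):
        raise ValueError(
            "smoothed δ18O values coincide at two anchors; the δ18O→temperature "
            "map would be degenerate — adjust anchors or smoothing")
    if method == "anchor_exact":
        # sort knots by δ18O for a well-defined piecewise-linear map
        knots = sorted(zip(iso_at, temps))
        xs = np.array([k[0] for k in knots])
        ys = np.array([k[1] for k in knots])

        def apply(v: np.ndarray) -> np.ndarray:
            out = np.interp(v, xs, ys)
            # linear extension beyond the outer knots
            lo_slope = (ys[1] - ys[0]) / (xs[1] - xs[0])
            hi_slope = (ys[-1] - ys[-2]) / (xs[-1] - xs[-2])
            below = v < xs[0]
            above = v > xs[-1]
            out = np.where(below, ys[0] + lo_slope * (v - xs[0]), out)
            out = np.where(above, ys[-1] + hi_slope * (v - xs[-1]), out)
            return out

        temp = apply(smoothed.d18o)
    elif method == "least_squares":
        slope, intercept = np.polyfit(iso_at, temps, 1)
        temp = intercept + slope * smoothed.d18o
    else:
        raise ValueError(f"unknown calibration method {method!r}")
    return PaleoCurve(smoothed.age_ma.copy(), smoothed.d18o.copy(), temp,
                      window=window, anchors=anchors)
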
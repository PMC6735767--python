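"""Melting-temperature estimation from fluorescence melting profiles.

Tm is operationalized as the peak of the negative first derivative
-dF/dT (the standard melt-curve convention): the fluorescence trace is
smoothed by a centered moving average over a small odd window, the
derivative is taken by central differences, and the peak location is
refined by quadratic interpolation through the peak and its two
neighbours so the grid spacing does not quantize small shifts.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["MeltCurve", "TmEstimate", "estimate_tm", "tm_shift", "read_melt_csv"]

MIN_POINTS = 25
SPACING_TOLERANCE = 0.01  # relative non-uniformity allowed in the grid


@dataclass(frozen=True)
class MeltCurve:
    """A temperature-fluorescence melting profile on a uniform grid."""

    temps: np.ndarray
    fluor: np.ndarray
    condition: str = ""

    def __post_init__(self) -> None:
        temps = np.asarray(self.temps, dtype=float)
        fluor = np.asarray(self.fluor, dtype=float)
        object.__setattr__(self, "temps", temps)
        object.__setattr__(self, "fluor", fluor)
        if temps.ndim != 1 or temps.shape != fluor.shape:
            raise ValueError("temps and fluor must be 1-D arrays of equal length")
        if len(temps) < MIN_POINTS:
            raise ValueError(f"need >= {MIN_POINTS} points, got {len(temps)}")
        steps = np.diff(temps)
        if np.any(steps <= 0):
            raise ValueError("temperature grid must be strictly increasing")
        mean_step = steps.mean()
        if np.max(np.abs(steps - mean_step)) > SPACING_TOLERANCE * mean_step:
            raise ValueError("temperature grid spacing non-uniform beyond 1%")


@dataclass(frozen=True)
class TmEstimate:
    """Result of a Tm estimation: peak location, height and window used."""

    tm: float
    peak_height: float
    window: int


def _centered_mean(values: np.ndarray, span: int) -> np.ndarray:
    """Centered moving average; the window shrinks at the boundaries."""
    half = span // 2
    out = np.empty_like(values, dtype=float)
    for i in range(len(values)):
        lo = max(0, i - half)
        hi = min(len(values), i + half + 1)
        out[i] = values[lo:hi].mean()
    return out


def estimate_tm(curve: MeltCurve, smooth_span: int = 5) -> TmEstimate | None:
    """Estimate the melting temperature of one profile.

    Returns None (an explicit no-estimate) when the profile carries no
    melting transition: constant fluorescence, or a non-positive
    derivative peak.

    Raises
    ------
    ValueError
        If *smooth_span* is not an odd integer >= 3.
    """
    if smooth_span < 3 or smooth_span % 2 == 0:
        raise ValueError(f"smooth_span must be odd and >= 3, got {smooth_span}")
    smoothed = _centered_mean(curve.fluor, smooth_span)
    if np.ptp(smoothed) == 0.0:
        return None
    neg_deriv = np.gradient(-smoothed, curve.temps)
    i = int(np.argmax(neg_deriv))
    peak = float(neg_deriv[i])
    if peak <= 0.0:
        return None
    tm = float(curve.temps[i])
    if 0 < i < len(neg_deriv) - 1:
        y0, y1, y2 = neg_deriv[i - 1], neg_deriv[i], neg_deriv[i + 1]
        denom = y0 - 2.0 * y1 + y2
        if denom < 0.0:  # proper local maximum; refine to sub-grid resolution
            step = float(curve.temps[i + 1] - curve.temps[i])
            offset = 0.5 * float(y0 - y2) / float(denom)
            tm += step * max(-0.5, min(0.5, offset))
    tm = float(np.clip(tm, curve.temps[0], curve.temps[-1]))
    return TmEstimate(tm=tm, peak_height=peak, window=smooth_span)


def tm_shift(curve_a: MeltCurve, curve_b: MeltCurve,
             smooth_span: int = 5) -> float | None:
    """Tm(a) - Tm(b): positive when condition b melts at a lower temperature.

    Propagates a no-estimate (None) from either curve.
    """
    est_a = estimate_tm(curve_a, smooth_span)
    est_b = estimate_tm(curve_b, smooth_span)
    if est_a is None or est_b is None:
        return None
    return est_a.tm - est_b.tm


def read_melt_csv(path: str | Path) -> list[MeltCurve]:
    """Read melting profiles from CSV (temperature, fluorescence[, condition]).

    Rows sharing a condition label form one curve; without a condition
    column the file is a single unlabelled curve.  Curves are returned
    in order of first appearance of their condition.
    """
    frame = pd.read_csv(path)
    required = {"temperature", "fluorescence"}
    if not required <= set(frame.columns):
        raise ValueError(f"melt CSV needs columns {sorted(required)}")
    if "condition" not in frame.columns:
        frame = frame.assign(condition="")
    curves = []
    for condition in frame["condition"].drop_duplicates():
        sub = frame[frame["condition"] == condition]
        curves.append(
            MeltCurve(
                temps=sub["temperature"].to_numpy(dtype=float),
                fluor=sub["fluorescence"].to_numpy(dtype=float),
                condition=str(condition),
            )
        )
    return curves
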
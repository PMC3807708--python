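"""Thermal-shift assay: melt-curve normalization and Tm estimation.

Fluorescence of an environment-sensitive dye rises as a protein unfolds;
the melting temperature Tm is the inflection of the transition, located as
the maximum of the first derivative of the reference-subtracted, min-max
normalized melt curve. The derivative is taken by central differences on
the measured grid (typically 0.5 C steps) and the peak is refined by
quadratic interpolation through the peak and its two neighbours.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "MeltCurve",
    "TmEstimate",
    "normalize_melt",
    "estimate_tm",
    "melt_to_csv",
    "melt_from_csv",
]


@dataclass
class MeltCurve:
    temperature: np.ndarray   # C, strictly increasing
    fluorescence: np.ndarray  # arbitrary units
    label: str = ""
    reference_subtracted: bool = False
    normalized: bool = False

    def __post_init__(self) -> None:
        self.temperature = np.asarray(self.temperature, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if len(self.temperature) != len(self.fluorescence):
            raise ValueError("temperature/fluorescence length mismatch")
        if np.any(np.diff(self.temperature) <= 0):
            raise ValueError("temperature grid must be strictly increasing")


@dataclass
class TmEstimate:
    tm: float                      # C
    derivative_peak_height: float  # AU/C
    method: str                    # 'grid-max' or 'quadratic-refined'


def normalize_melt(raw: MeltCurve, reference: MeltCurve | None = None) -> MeltCurve:
    """Reference-subtract then min-max scale the fluorescence to [0, 1].

    A reference on a different grid is linearly resampled. A constant
    signal after subtraction cannot be normalized (degenerate curve).
    """
    signal = raw.fluorescence.astype(float)
    if reference is not None:
        ref = np.interp(raw.temperature, reference.temperature, reference.fluorescence)
        signal = signal - ref
    lo, hi = float(signal.min()), float(signal.max())
    if hi - lo < 1e-12:
        raise ValueError(f"melt curve {raw.label!r}: constant signal, cannot normalize")
    return MeltCurve(
        temperature=raw.temperature,
        fluorescence=(signal - lo) / (hi - lo),
        label=raw.label,
        reference_subtracted=reference is not None,
        normalized=True,
    )


def estimate_tm(c: MeltCurve, smooth_window: int | None = None) -> TmEstimate:
    """Tm = temperature of the maximum first derivative of the melt curve.

    Central differences on the measured grid; the grid maximum is refined by
    a parabola through the peak and its neighbours. No smoothing is applied
    by default; ``smooth_window`` (odd number of points) applies a moving
    average to the derivative for noisy plates. A derivative maximum at the
    grid boundary cannot be refined — a warning is issued and the grid-max
    value returned. A curve with no rising segment has no melting transition
    at all.
    """
    if len(c.temperature) < 7:
        raise ValueError("need at least 7 points to estimate Tm")
    deriv = np.gradient(c.fluorescence, c.temperature)
    if smooth_window is not None:
        if smooth_window < 1 or smooth_window % 2 == 0:
            raise ValueError("smooth_window must be a positive odd integer")
        kernel = np.ones(smooth_window) / smooth_window
        deriv = np.convolve(deriv, kernel, mode="same")
    if not np.any(deriv > 0):
        raise ValueError(f"melt curve {c.label!r}: no melting transition (derivative never positive)")
    i = int(np.argmax(deriv))
    if i == 0 or i == len(deriv) - 1:
        warnings.warn(
            f"melt curve {c.label!r}: derivative peak at grid boundary; Tm unrefined",
            stacklevel=2,
        )
        return TmEstimate(tm=float(c.temperature[i]), derivative_peak_height=float(deriv[i]),
                          method="grid-max")
    # quadratic through (x_{i-1}, y_{i-1}), (x_i, y_i), (x_{i+1}, y_{i+1})
    x = c.temperature[i - 1 : i + 2]
    y = deriv[i - 1 : i + 2]
    a, b, _ = np.polyfit(x, y, 2)
    if a >= 0:  # not a concave peak, keep the grid maximum
        return TmEstimate(tm=float(c.temperature[i]), derivative_peak_height=float(deriv[i]),
                          method="grid-max")
    tm = float(-b / (2 * a))
    lo, hi = float(x[0]), float(x[-1])
    tm = min(max(tm, lo), hi)
    peak = float(np.polyval(np.array([a, b, _]), tm))
    return TmEstimate(tm=tm, derivative_peak_height=peak, method="quadratic-refined")


def melt_to_csv(curves, path) -> None:
    """CSV: temperature_C, fluorescence_AU, label."""
    if isinstance(curves, MeltCurve):
        curves = [curves]
    with open(path, "w") as fh:
        fh.write("temperature_C,fluorescence_AU,label\n")
        for c in curves:
            for t, f in zip(c.temperature, c.fluorescence):
                fh.write(f"{float(t)!r},{float(f)!r},{c.label}\n")


def melt_from_csv(path) -> list[MeltCurve]:
    import pandas as pd

    df = pd.read_csv(path)
    required = ["temperature_C", "fluorescence_AU", "label"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    out = []
    for label, grp in df.groupby("label", sort=True):
        grp = grp.sort_values("temperature_C")
        out.append(
            MeltCurve(
                temperature=grp["temperature_C"].to_numpy(),
                fluorescence=grp["fluorescence_AU"].to_numpy(),
                label=str(label),
            )
        )
    return out


def tm_to_json(estimates: dict[str, TmEstimate], path) -> None:
    with open(path, "w") as fh:
        json.dump(
            {
                label: {
                    "tm_C": e.tm,
                    "derivative_peak_height": e.derivative_peak_height,
                    "method": e.method,
                }
                for label, e in estimates.items()
            },
            fh,
            indent=2,
        )
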
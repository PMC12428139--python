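"""Two-state DSC thermogram simulation and analysis.

A differential scanning calorimeter records the excess molar heat capacity of
a protein solution against temperature.  For a two-state unfolding
equilibrium N ⇌ U with van't Hoff enthalpy ΔH_vH, the unfolded fraction is
f(T) = K/(1+K) with K(T) = exp[−(ΔH_vH/R)(1/T − 1/Tm)] (absolute
temperatures), and the excess heat capacity is

    Cp_ex(T) = ΔH_cal · ΔH_vH · K / (R · T² · (1+K)²),

i.e. ΔH_cal · df/dT: the calorimetric enthalpy ΔH_cal scales the peak area
while ΔH_vH sets its sharpness.  A ΔH_cal/ΔH_vH ratio below one indicates
that only a fraction of the loaded protein participates in the cooperative
transition (e.g. because the rest is aggregated).

ΔH values are cal·mol⁻¹ — an integral of Cp over temperature.  The analyzer
subtracts a linear baseline fitted through configurable pre-/post-transition
windows, reports Tm as the temperature of maximum excess heat capacity and
ΔH_cal as the trapezoidal integral of the positive excess, and flags
non-classic thermogram shapes (flat; inverted/aggregation-dominated).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError

__all__ = ["DSCTrace", "DSCResult", "R_CAL", "two_state_excess_heat_capacity",
           "simulate_endotherm", "analyze_trace", "enthalpy_ratio",
           "default_grid"]

R_CAL = 1.98720425864083  # gas constant, cal·mol⁻¹·K⁻¹
_T0 = 273.15


@dataclass(frozen=True)
class DSCTrace:
    """One thermogram: strictly increasing °C grid (≥ 50 points) and per-point
    excess heat capacity in cal·mol⁻¹·°C⁻¹; scan rate is metadata only."""

    temperature: np.ndarray
    excess_heat_capacity: np.ndarray
    scan_rate: float = 1.5   # °C/min
    label: str = ""

    def __post_init__(self):
        t = np.asarray(self.temperature, dtype=float)
        cp = np.asarray(self.excess_heat_capacity, dtype=float)
        object.__setattr__(self, "temperature", t)
        object.__setattr__(self, "excess_heat_capacity", cp)
        if t.ndim != 1 or t.size < 50:
            raise ValidationError("temperature grid needs >= 50 points")
        if cp.shape != t.shape:
            raise ValidationError("temperature and heat-capacity shapes differ")
        if np.any(np.diff(t) <= 0):
            raise ValidationError("temperature grid must be strictly increasing")


@dataclass(frozen=True)
class DSCResult:
    tm: float                       # °C, peak of baseline-subtracted excess Cp
    delta_h: float                  # cal·mol⁻¹, integral of the positive excess
    baseline: tuple[float, float]   # (slope, intercept) of subtracted baseline
    quality: str                    # classic | inverted_aggregation | flat


def default_grid(start: float = 15.0, stop: float = 100.0,
                 step: float = 0.05) -> np.ndarray:
    """°C grid mirroring a 15–100 °C scan."""
    return np.arange(start, stop + step / 2, step)


def two_state_excess_heat_capacity(t_celsius, tm: float, delta_h: float,
                                   vant_hoff_h: float):
    """Closed-form two-state excess Cp (cal·mol⁻¹·°C⁻¹) on a °C grid."""
    t = np.asarray(t_celsius, dtype=float) + _T0
    tm_k = tm + _T0
    k_eq = np.exp(-(vant_hoff_h / R_CAL) * (1.0 / t - 1.0 / tm_k))
    return delta_h * vant_hoff_h * k_eq / (R_CAL * t ** 2 * (1.0 + k_eq) ** 2)


def simulate_endotherm(tm: float, delta_h: float, vant_hoff_h: float,
                       baseline_slope: float = 0.0,
                       baseline_intercept: float = 0.0,
                       grid: np.ndarray | None = None,
                       scan_rate: float = 1.5,
                       label: str = "") -> DSCTrace:
    """Generate an idealized two-state endotherm plus a linear baseline."""
    if not delta_h > 0 or not vant_hoff_h > 0:
        raise ValidationError("delta_h and vant_hoff_h must be > 0")
    t = default_grid() if grid is None else np.asarray(grid, dtype=float)
    if not t[0] <= tm <= t[-1]:
        raise ValidationError(f"tm={tm} lies outside the grid [{t[0]}, {t[-1]}]")
    cp = two_state_excess_heat_capacity(t, tm, delta_h, vant_hoff_h)
    cp = cp + baseline_intercept + baseline_slope * (t - t[0])
    return DSCTrace(temperature=t, excess_heat_capacity=cp,
                    scan_rate=scan_rate, label=label)


def analyze_trace(trace: DSCTrace, baseline_fraction: float = 0.10,
                  flat_snr: float = 5.0,
                  inverted_threshold: float = 0.25) -> DSCResult:
    """Extract (Tm, ΔH) from a thermogram.

    A straight line fitted through the first and last ``baseline_fraction`` of
    the grid is subtracted, then refined: points whose provisional excess
    exceeds 0.5 % of the provisional peak are treated as transition region and
    excluded, and the line is refitted on the remaining pre-/post-transition
    points (two passes; the refinement is skipped if it would leave fewer
    than 10 baseline points).  Tm is the argmax of the residual excess, ΔH
    its trapezoidal integral over the positive part.  Quality flags:

    * ``flat`` — peak height below ``flat_snr`` times the baseline-window
      noise (nothing melts in the scanned range);
    * ``inverted_aggregation`` — a negative-going lobe preceding the
      endotherm dominates (disaggregation absorbs before the residual folded
      fraction unfolds);
    * ``classic`` otherwise.

    Deterministic for a fixed trace.
    """
    t = trace.temperature
    cp = trace.excess_heat_capacity
    n_win = max(int(round(baseline_fraction * t.size)), 2)
    idx = np.r_[0:n_win, t.size - n_win:t.size]
    slope, intercept = np.polyfit(t[idx], cp[idx], 1)
    excess = cp - (slope * t + intercept)
    # refine: drop the transition region from the baseline windows so a peak
    # near a grid edge cannot tilt the fitted line
    for _ in range(2):
        magnitude = np.max(np.abs(excess))
        if magnitude == 0.0:
            break
        in_transition = np.flatnonzero(np.abs(excess) > 0.005 * magnitude)
        if in_transition.size == 0:
            break
        keep = np.r_[0:in_transition[0], in_transition[-1] + 1:t.size]
        if keep.size < 10:
            break
        idx = keep
        slope, intercept = np.polyfit(t[idx], cp[idx], 1)
        excess = cp - (slope * t + intercept)

    noise = float(np.std(excess[idx]))
    i_max = int(np.argmax(excess))
    peak = float(excess[i_max])
    tm = float(t[i_max])
    delta_h = float(np.trapezoid(np.clip(excess, 0.0, None), t))

    i_min = int(np.argmin(excess))
    trough = float(excess[i_min])

    if peak <= 0.0 or peak <= flat_snr * noise:
        quality = "flat"
    elif trough < 0.0 and i_min < i_max and -trough > inverted_threshold * peak:
        quality = "inverted_aggregation"
    else:
        quality = "classic"
    return DSCResult(tm=tm, delta_h=delta_h,
                     baseline=(float(slope), float(intercept)),
                     quality=quality)


def enthalpy_ratio(delta_h_num: float, delta_h_den: float) -> float:
    """100 × ΔH_num/ΔH_den (percent); reporting rounds to the nearest integer."""
    if not delta_h_den > 0:
        raise ValidationError("enthalpy_ratio denominator must be > 0")
    if delta_h_num < 0:
        raise ValidationError("enthalpy_ratio numerator must be >= 0")
    return 100.0 * delta_h_num / delta_h_den
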
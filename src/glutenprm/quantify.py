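"""Quantitative core: XIC integration, calibration, LOD/LOQ, CV, matrix effects.

Abundance is the trapezoidal integral of the extracted ion current over the
scheduled retention window, summed across a peptide's monitored fragment
traces.  Concentrations come from an unweighted ordinary-least-squares
external calibration; detection limits follow the residual-standard-
deviation-over-slope rule (LOD = 3.3 S/slope, LOQ = 10 S/slope), with a
blank-based alternative (mean + k * sd, k = 10 by default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ChromatogramTrace",
    "CalibrationCurve",
    "LodLoq",
    "QuantResult",
    "MatrixEffectReport",
    "ReplicabilityReport",
    "integrate_xic",
    "fit_calibration",
    "residual_sd",
    "loq",
    "lod",
    "lod_blank",
    "lodloq_from_curve",
    "back_calculate",
    "internal_standard_recovery",
    "matrix_effect",
    "cv",
]

#: Default SPE dilution factor: 200 uL loaded, 2 x 210 uL eluted.
DEFAULT_DILUTION_FACTOR = 2.1


@dataclass(frozen=True)
class ChromatogramTrace:
    """Time-ordered intensity series for one transition in one sample."""

    sample_id: str
    transition_id: str
    time_min: np.ndarray
    intensity: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.time_min, dtype=float)
        y = np.asarray(self.intensity, dtype=float)
        if t.ndim != 1 or t.shape != y.shape:
            raise ValueError("time and intensity must be equal-length 1-D arrays")
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly ascending")
        object.__setattr__(self, "time_min", t)
        object.__setattr__(self, "intensity", y)

    def __len__(self) -> int:
        return self.time_min.size


@dataclass(frozen=True)
class CalibrationCurve:
    """OLS line mapping concentration (x, ug/mL) to abundance (y, counts*min)."""

    peptide: str
    slope: float
    intercept: float
    r: float
    rss: float
    n: int
    conc_range: tuple

    def __post_init__(self):
        if self.n < 3:
            raise ValueError("calibration requires n >= 3 points")
        if not -1.0 - 1e-12 <= self.r <= 1.0 + 1e-12:
            raise ValueError("correlation must lie in [-1, 1]")
        if self.rss < 0:
            raise ValueError("residual sum of squares must be >= 0")

    def predict(self, concentration: float) -> float:
        return self.slope * concentration + self.intercept


@dataclass(frozen=True)
class LodLoq:
    """Detection/quantification limits from residual sd and slope."""

    peptide: str
    s: float
    loq: float
    lod: float
    lod_blank: float | None = None
    n_injections: int | None = None


@dataclass(frozen=True)
class QuantResult:
    """One back-calculated sample concentration with its corrections."""

    sample_id: str
    peptide: str
    abundance: float
    raw_conc: float
    dilution_factor: float
    recovery: float
    final_conc: float
    below_loq: bool = False
    clipped_negative: bool = False


@dataclass(frozen=True)
class MatrixEffectReport:
    """Suppression (+) / enhancement (-) percent per matrix fraction."""

    peptide: str
    control_abundance: float
    percent_by_fraction: dict = field(default_factory=dict)


@dataclass(frozen=True)
class ReplicabilityReport:
    peptide: str
    day_means: tuple
    grand_mean: float
    cv_percent: float
    passes: bool  # CV < 10 %


def integrate_xic(
    traces: ChromatogramTrace | list,
    window: tuple,
    baseline: str = "none",
) -> float:
    """Trapezoidal abundance over ``window`` (min), floored at zero.

    Multiple traces (a peptide's monitored fragments) are summed, matching
    a total-extracted-ion-current readout.  ``baseline="linear"`` subtracts
    the chord between the window endpoints of each trace before
    integration.
    """
    if isinstance(traces, ChromatogramTrace):
        traces = [traces]
    start, end = window
    if not start < end:
        raise ValueError(f"window start {start} must be < end {end}")
    total = 0.0
    for trace in traces:
        t, y = trace.time_min, trace.intensity
        if t.size == 0:
            continue
        if start < t[0] - 1e-12 or end > t[-1] + 1e-12:
            raise ValueError(
                f"window [{start}, {end}] outside trace span "
                f"[{t[0]}, {t[-1]}] for {trace.transition_id}"
            )
        mask = (t >= start) & (t <= end)
        if mask.sum() < 2:
            continue
        tw, yw = t[mask], y[mask]
        if baseline == "linear":
            chord = yw[0] + (yw[-1] - yw[0]) * (tw - tw[0]) / (tw[-1] - tw[0])
            yw = yw - chord
        elif baseline != "none":
            raise ValueError(f"unknown baseline mode {baseline!r}")
        total += float(np.trapezoid(yw, tw))
    return max(total, 0.0)


def fit_calibration(
    levels,
    abundances,
    peptide: str = "",
    weighting: str | None = None,
) -> CalibrationCurve:
    """Least-squares line through (concentration, abundance) points.

    Unweighted OLS by default; ``weighting`` may be ``"1/x"`` or ``"1/x2"``
    for variance stabilisation at low concentration.  RSS and Pearson r are
    always reported on the unweighted scale.
    """
    x = np.asarray(levels, dtype=float)
    y = np.asarray(abundances, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("levels and abundances must be equal-length 1-D")
    if x.size < 3:
        raise ValueError("calibration requires at least 3 points")
    if np.unique(x).size < 2:
        raise ValueError("all calibration levels identical: degenerate design")

    if weighting is None:
        w = np.ones_like(x)
    elif weighting == "1/x":
        w = 1.0 / x
    elif weighting == "1/x2":
        w = 1.0 / x**2
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    if weighting is not None and np.any(x <= 0):
        raise ValueError("weighted fits require strictly positive levels")

    sw = w.sum()
    xbar = (w * x).sum() / sw
    ybar = (w * y).sum() / sw
    sxx = (w * (x - xbar) ** 2).sum()
    slope = (w * (x - xbar) * (y - ybar)).sum() / sxx
    intercept = ybar - slope * xbar

    resid = y - (slope * x + intercept)
    rss = float((resid**2).sum())
    r = float(np.corrcoef(x, y)[0, 1])
    return CalibrationCurve(
        peptide=peptide, slope=float(slope), intercept=float(intercept),
        r=r, rss=rss, n=int(x.size),
        conc_range=(float(x.min()), float(x.max())),
    )


def residual_sd(curve: CalibrationCurve) -> float:
    """Standard deviation of the regression residuals: sqrt(RSS / (n - 2))."""
    if curve.n <= 2:
        raise ValueError("residual sd needs n > 2")
    return math.sqrt(curve.rss / (curve.n - 2))


def loq(s: float, slope: float) -> float:
    """Limit of quantification: 10 * S / |slope|."""
    if slope == 0:
        raise ValueError("slope must be non-zero")
    if s < 0:
        raise ValueError("residual sd must be >= 0")
    return 10.0 * s / abs(slope)


def lod(s: float, slope: float) -> float:
    """Limit of detection: 3.3 * S / |slope|."""
    if slope == 0:
        raise ValueError("slope must be non-zero")
    if s < 0:
        raise ValueError("residual sd must be >= 0")
    return 3.3 * s / abs(slope)


def lod_blank(blank_abundances, k: float = 10.0) -> float:
    """Blank-based detection limit on the abundance scale: mean + k * sd.

    Sample (n-1) standard deviation; ``k`` defaults to 10, with 3.3 as the
    conventional alternative.
    """
    y = np.asarray(blank_abundances, dtype=float)
    if y.size < 2:
        raise ValueError("blank-based LOD needs >= 2 measurements")
    return float(y.mean() + k * y.std(ddof=1))


def lodloq_from_curve(curve: CalibrationCurve,
                      n_injections: int | None = None) -> LodLoq:
    """Bundle residual-sd LOD/LOQ for one calibration curve."""
    s = residual_sd(curve)
    return LodLoq(
        peptide=curve.peptide, s=s,
        loq=loq(s, curve.slope), lod=lod(s, curve.slope),
        n_injections=n_injections,
    )


def back_calculate(
    abundance: float,
    curve: CalibrationCurve,
    dilution_factor: float = DEFAULT_DILUTION_FACTOR,
    is_recovery: float = 1.0,
    limits: LodLoq | None = None,
    sample_id: str = "",
) -> QuantResult:
    """Concentration from abundance via the calibration line.

    ``raw = (abundance - intercept) / slope``;
    ``final = raw * dilution_factor / recovery``.  A negative raw
    concentration is reported as 0 with ``clipped_negative`` set rather
    than propagated; ``below_loq`` is flagged from ``limits`` when given.
    """
    if curve.slope == 0:
        raise ValueError("calibration slope must be non-zero")
    if not 0.0 < is_recovery <= 1.5:
        raise ValueError("internal-standard recovery must be in (0, 1.5]")
    if dilution_factor <= 0:
        raise ValueError("dilution factor must be > 0")
    raw = (abundance - curve.intercept) / curve.slope
    clipped = raw < 0
    if clipped:
        raw = 0.0
    below = limits is not None and raw < limits.loq
    return QuantResult(
        sample_id=sample_id, peptide=curve.peptide, abundance=abundance,
        raw_conc=raw, dilution_factor=dilution_factor, recovery=is_recovery,
        final_conc=raw * dilution_factor / is_recovery,
        below_loq=below, clipped_negative=clipped,
    )


def internal_standard_recovery(observed: float, expected: float) -> float:
    """Fraction of the spiked internal standard recovered."""
    if expected <= 0:
        raise ValueError("expected internal-standard abundance must be > 0")
    return observed / expected


def matrix_effect(
    control_abundance: float,
    sample_abundances: dict,
    peptide: str = "",
) -> MatrixEffectReport:
    """Percent suppression (+) or enhancement (-) versus the pure control.

    ``sample_abundances`` maps matrix fraction to observed abundance; the
    control (fraction 1.0 of clean matrix, no sample) defines 0 %.
    """
    if control_abundance <= 0:
        raise ValueError("control abundance must be > 0")
    percents = {
        float(frac): 100.0 * (control_abundance - ab) / control_abundance
        for frac, ab in sample_abundances.items()
    }
    return MatrixEffectReport(
        peptide=peptide, control_abundance=control_abundance,
        percent_by_fraction=percents,
    )


def cv(values) -> float:
    """Coefficient of variation, percent: 100 * sd(n-1) / mean."""
    y = np.asarray(values, dtype=float)
    if y.size < 2:
        raise ValueError("CV needs >= 2 values")
    mean = y.mean()
    if mean == 0:
        raise ValueError("CV undefined for zero mean")
    return float(100.0 * y.std(ddof=1) / abs(mean))


def replicability(day_values: dict, peptide: str = "",
                  threshold: float = 10.0) -> ReplicabilityReport:
    """Day-to-day CV of per-day mean concentrations.

    ``day_values`` maps a day key to that day's replicate concentrations;
    the CV is computed across the per-day means.
    """
    means = tuple(float(np.mean(v)) for _, v in sorted(day_values.items()))
    if len(means) < 2:
        raise ValueError("replicability needs >= 2 days")
    cv_pct = cv(means)
    return ReplicabilityReport(
        peptide=peptide, day_means=means,
        grand_mean=float(np.mean(means)), cv_percent=cv_pct,
        passes=cv_pct < threshold,
    )
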
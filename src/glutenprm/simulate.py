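"""Synthetic extracted-ion-chromatogram generator with known ground truth.

Every downstream stage (integration, calibration, LOD/LOQ, matrix-effect and
replicability statistics) is testable against construction ground truth:
traces are Gaussian (optionally exponentially-modified Gaussian) elution
peaks whose area follows ``slope * concentration + intercept``, on top of a
constant baseline and seeded white noise.

All randomness derives from one explicit integer seed via
``numpy.random.SeedSequence`` spawning — identical scenario and seed give
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import exponnorm, norm

from glutenprm.quantify import ChromatogramTrace

__all__ = [
    "PeakModel",
    "SimulationScenario",
    "SampleSet",
    "DEFAULT_PEAK_MODELS",
    "CALIBRATION_LEVELS",
    "LODLOQ_LEVELS",
    "MATRIX_FRACTIONS",
    "simulate_trace",
    "calibration_series",
    "matrix_series",
    "day_series",
    "write_chromatogram_csv",
    "read_chromatogram_csv",
]

#: Serial-dilution levels (ug/mL) for the working calibration range.
CALIBRATION_LEVELS = (0.5, 1.0, 2.0, 5.0, 10.0)

#: Extended low-end dilution levels (ug/mL) for LOD/LOQ determination.
LODLOQ_LEVELS = (10.0, 5.0, 2.0, 1.0, 0.5, 0.3, 0.1, 0.05, 0.03, 0.01)

#: Matrix-effect dilution fractions (1.0 = undiluted digesta matrix).
MATRIX_FRACTIONS = (1.0, 0.75, 0.5, 0.2)

#: Internal-standard spike concentration for matrix-effect runs (ug/mL).
DEFAULT_SPIKE = 3.0


@dataclass(frozen=True)
class PeakModel:
    """Parameters generating one peptide's XIC peak.

    ``slope``/``intercept`` map concentration (ug/mL) to integrated area
    (counts*min); ``tailing_tau`` > 0 switches to an exponentially-modified
    Gaussian with that decay constant (min).
    """

    peptide: str
    rt_min: float
    sigma_min: float = 0.05
    slope: float = 1e6
    intercept: float = 0.0
    noise_sd: float = 0.0
    baseline: float = 0.0
    dt_min: float = 0.005
    tailing_tau: float = 0.0

    def __post_init__(self):
        if self.sigma_min <= 0:
            raise ValueError("peak sigma must be > 0")
        if self.dt_min <= 0:
            raise ValueError("sampling interval must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")


#: Regression-scale defaults so simulated abundances live on a realistic
#: counts*min scale; retention times match the scheduled transition list.
DEFAULT_PEAK_MODELS = {
    "P1": PeakModel("P1", rt_min=6.11, slope=3_405_436, intercept=404_809),
    "P2": PeakModel("P2", rt_min=6.59, slope=1_776_389, intercept=224_381),
    "P3": PeakModel("P3", rt_min=7.12, slope=1_637_587, intercept=63_340),
    "P4": PeakModel("P4", rt_min=6.43, slope=2_063_579, intercept=-13_216),
    "P5": PeakModel("P5", rt_min=7.29, slope=420_669, intercept=16_042),
    "P6": PeakModel("P6", rt_min=3.48, slope=1_140_396, intercept=-729_751),
    "P1H": PeakModel("P1H", rt_min=6.11, slope=3_405_436, intercept=0.0),
}


@dataclass(frozen=True)
class SimulationScenario:
    """A reproducible bundle of peak models, truths, and suppression factors."""

    peak_models: dict
    true_concentrations: dict = field(default_factory=dict)  # sample -> ug/mL
    suppression: dict = field(default_factory=dict)  # sample -> (0, 1]
    replicates: int = 1
    seed: int = 0

    def __post_init__(self):
        if any(c < 0 for c in self.true_concentrations.values()):
            raise ValueError("true concentrations must be >= 0")
        if any(not 0 < s <= 1 for s in self.suppression.values()):
            raise ValueError("suppression factors must be in (0, 1]")


@dataclass(frozen=True)
class SampleSet:
    """Simulated traces plus the ground-truth manifest describing them."""

    traces: tuple
    manifest: pd.DataFrame

    def by_sample(self, sample_id: str) -> list:
        return [t for t in self.traces if t.sample_id == sample_id]


def _peak_shape(t: np.ndarray, model: PeakModel) -> np.ndarray:
    """Unit-area elution profile on the time grid ``t``."""
    if model.tailing_tau > 0:
        k = model.tailing_tau / model.sigma_min
        return exponnorm.pdf(t, k, loc=model.rt_min, scale=model.sigma_min)
    return norm.pdf(t, loc=model.rt_min, scale=model.sigma_min)


def simulate_trace(
    model: PeakModel,
    concentration: float,
    seed,
    sample_id: str = "sample",
    window_halfwidth: float = 0.5,
    suppression: float = 1.0,
) -> ChromatogramTrace:
    """One seeded XIC trace around the model's retention time.

    Peak area is ``(slope * concentration + intercept) * suppression``,
    clamped at zero (a negative intercept cannot produce negative signal).
    ``seed`` may be an int or a ``numpy.random.SeedSequence``/Generator.
    """
    if concentration < 0:
        raise ValueError("concentration must be >= 0")
    if not 0 < suppression <= 1:
        raise ValueError("suppression must be in (0, 1]")
    rng = np.random.default_rng(seed)
    start = model.rt_min - window_halfwidth
    n = int(round(2 * window_halfwidth / model.dt_min)) + 1
    t = start + model.dt_min * np.arange(n)
    area = max((model.slope * concentration + model.intercept) * suppression,
               0.0)
    y = area * _peak_shape(t, model) + model.baseline
    if model.noise_sd > 0:
        y = y + rng.normal(0.0, model.noise_sd, size=t.size)
    return ChromatogramTrace(
        sample_id=sample_id, transition_id=model.peptide,
        time_min=t, intensity=y,
    )


def _spawn(seed, n: int):
    ss = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    return ss.spawn(n)


def calibration_series(
    peak_models: dict,
    levels=CALIBRATION_LEVELS,
    replicates: int = 1,
    seed: int = 0,
) -> SampleSet:
    """Labelled traces for each calibration level x replicate x peptide.

    Use ``levels=LODLOQ_LEVELS`` with ``replicates >= 5`` for a
    detection-limit dilution series.  ``replicates=0`` returns an empty set
    (with a warning via the manifest being empty).
    """
    levels = tuple(float(v) for v in levels)
    if not levels:
        raise ValueError("levels must be non-empty")
    traces: list[ChromatogramTrace] = []
    rows = []
    names = sorted(peak_models)
    children = _spawn(seed, len(levels) * max(replicates, 0) * len(names))
    i = 0
    for level in levels:
        for rep in range(replicates):
            sample_id = f"cal_{level:g}_{rep}"
            for name in names:
                traces.append(simulate_trace(
                    peak_models[name], level, children[i],
                    sample_id=sample_id,
                ))
                rows.append({
                    "sample_id": sample_id, "peptide": name,
                    "true_concentration": level, "suppression": 1.0,
                    "replicate": rep,
                })
                i += 1
    manifest = pd.DataFrame(
        rows, columns=["sample_id", "peptide", "true_concentration",
                       "suppression", "replicate"],
    )
    return SampleSet(traces=tuple(traces), manifest=manifest)


def matrix_series(
    model: PeakModel,
    spike: float = DEFAULT_SPIKE,
    matrix_fractions=MATRIX_FRACTIONS,
    suppression=None,
    seed: int = 0,
) -> SampleSet:
    """Spiked internal standard in serially diluted matrix, plus a control.

    ``suppression`` maps matrix fraction to the fraction of signal retained
    (defaults to 1.0 everywhere, i.e. no matrix effect).  The clean-eluate
    control is always included as fraction 0.0 with no suppression.
    """
    fractions = tuple(float(f) for f in matrix_fractions)
    if any(not 0 < f <= 1 for f in fractions):
        raise ValueError("matrix fractions must be in (0, 1]")
    suppression = dict(suppression or {})
    traces = []
    rows = []
    all_fracs = (0.0,) + fractions  # 0.0 = pure-eluate control
    children = _spawn(seed, len(all_fracs))
    for child, frac in zip(children, all_fracs):
        sup = 1.0 if frac == 0.0 else float(suppression.get(frac, 1.0))
        sample_id = "control" if frac == 0.0 else f"matrix_{frac:g}"
        traces.append(simulate_trace(
            model, spike, child, sample_id=sample_id, suppression=sup,
        ))
        rows.append({
            "sample_id": sample_id, "peptide": model.peptide,
            "true_concentration": spike, "suppression": sup,
            "matrix_fraction": frac,
        })
    manifest = pd.DataFrame(
        rows, columns=["sample_id", "peptide", "true_concentration",
                       "suppression", "matrix_fraction"],
    )
    return SampleSet(traces=tuple(traces), manifest=manifest)


def day_series(
    model: PeakModel,
    concentration: float,
    days: int = 3,
    replicates_per_day: int = 3,
    day_cv_percent: float = 5.0,
    seed: int = 0,
) -> SampleSet:
    """Day-to-day variation scenario: a shared per-day scale factor.

    Each day draws one multiplicative factor from N(1, day_cv/100) applied
    to all of that day's replicates, emulating between-day preparation
    variability on top of within-day noise.
    """
    if days < 2:
        raise ValueError("need >= 2 days")
    children = _spawn(seed, days * replicates_per_day + 1)
    day_rng = np.random.default_rng(children[0])
    factors = day_rng.normal(1.0, day_cv_percent / 100.0, size=days)
    factors = np.clip(factors, 1e-6, None)
    traces = []
    rows = []
    i = 1
    for d in range(days):
        for rep in range(replicates_per_day):
            sample_id = f"day{d}_rep{rep}"
            conc = concentration * factors[d]
            traces.append(simulate_trace(
                model, conc, children[i], sample_id=sample_id,
            ))
            rows.append({
                "sample_id": sample_id, "peptide": model.peptide,
                "true_concentration": conc, "suppression": 1.0,
                "day": d, "replicate": rep,
            })
            i += 1
    manifest = pd.DataFrame(
        rows, columns=["sample_id", "peptide", "true_concentration",
                       "suppression", "day", "replicate"],
    )
    return SampleSet(traces=tuple(traces), manifest=manifest)


def write_chromatogram_csv(traces, path) -> None:
    """Long-format CSV: sample_id, transition_id, time_min, intensity."""
    frames = [
        pd.DataFrame({
            "sample_id": t.sample_id, "transition_id": t.transition_id,
            "time_min": t.time_min, "intensity": t.intensity,
        })
        for t in traces
    ]
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["sample_id", "transition_id", "time_min", "intensity"])
    out.to_csv(path, index=False)


def read_chromatogram_csv(path) -> list:
    """Inverse of :func:`write_chromatogram_csv`."""
    frame = pd.read_csv(path)
    traces = []
    for (sample, tid), grp in frame.groupby(
            ["sample_id", "transition_id"], sort=False):
        grp = grp.sort_values("time_min")
        traces.append(ChromatogramTrace(
            sample_id=str(sample), transition_id=str(tid),
            time_min=grp["time_min"].to_numpy(),
            intensity=grp["intensity"].to_numpy(),
        ))
    return traces
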
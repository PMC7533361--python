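"""Configuration loading/validation and the end-to-end quantification pipeline."""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from glutenprm.chem import EpitopeMotif, IsotopeLabel, Peptide
from glutenprm.digestion import DEFAULT_FLUIDS
from glutenprm.quantify import (
    CalibrationCurve,
    LodLoq,
    QuantResult,
    back_calculate,
    fit_calibration,
    integrate_xic,
    lodloq_from_curve,
)
from glutenprm.simulate import PeakModel
from glutenprm.transitions import (
    AcquisitionMethod,
    Discrepancy,
    FragmentEntry,
    GradientStep,
    Transition,
    validate_transitions,
)

__all__ = [
    "ConfigError",
    "PipelineError",
    "ToolConfig",
    "load_config",
    "dump_config",
    "default_config",
    "validate_config",
    "run_pipeline",
]


class ConfigError(ValueError):
    """A configuration file failed to parse or validate."""


class PipelineError(RuntimeError):
    """A pipeline run failed on otherwise-valid inputs."""


_QUANT_DEFAULTS = {
    "match_tolerance_th": 0.01,
    "precursor_tol_th": 0.005,
    "fragment_tol_th": 0.015,
    "dilution_factor": 2.1,
    "blank_k": 10,
    "window_halfwidth_min": 0.5,
    "weighting": None,
    "calibration_levels": [0.5, 1, 2, 5, 10],
    "lodloq_levels": [10, 5, 2, 1, 0.5, 0.3, 0.1, 0.05, 0.03, 0.01],
    "lodloq_injections": 5,
    "internal_standard": "P1H",
    "spike_concentration": 3.0,
}

_SIM_DEFAULTS = {
    "sigma_min": 0.05,
    "noise_sd": 0.0,
    "baseline": 0.0,
    "dt_min": 0.005,
}


@dataclass(frozen=True)
class ToolConfig:
    """Fully validated toolkit configuration."""

    peptides: tuple = ()
    epitopes: tuple = ()
    transitions: tuple = ()
    acquisition: AcquisitionMethod = field(default_factory=AcquisitionMethod)
    quant: dict = field(default_factory=lambda: dict(_QUANT_DEFAULTS))
    simulation: dict = field(default_factory=lambda: dict(_SIM_DEFAULTS))
    fluids: dict = field(default_factory=lambda: dict(DEFAULT_FLUIDS))
    seed: int = 0

    def peptide(self, name: str) -> Peptide:
        for p in self.peptides:
            if p.name == name:
                return p
        raise KeyError(name)

    def peak_models(self) -> dict:
        """Per-peptide simulation models: configured RT + regression scale.

        Slopes/intercepts default to the shipped regression parameters when
        the peptide is one of the named markers, else to a generic scale.
        """
        from glutenprm.simulate import DEFAULT_PEAK_MODELS

        sim = self.simulation
        models = {}
        for p in self.peptides:
            base = DEFAULT_PEAK_MODELS.get(p.name)
            models[p.name] = PeakModel(
                peptide=p.name,
                rt_min=p.rt_min if p.rt_min is not None else 5.0,
                sigma_min=float(sim.get("sigma_min", 0.05)),
                slope=base.slope if base else 1e6,
                intercept=base.intercept if base else 0.0,
                noise_sd=float(sim.get("noise_sd", 0.0)),
                baseline=float(sim.get("baseline", 0.0)),
                dt_min=float(sim.get("dt_min", 0.005)),
            )
        return models

    def to_dict(self) -> dict:
        out = {
            "seed": self.seed,
            "peptides": [],
            "epitopes": [{"name": e.name, "core": e.core}
                         for e in self.epitopes],
            "transitions": [],
            "acquisition": {
                "gradient": [[s.time_min, s.percent_b, s.flow_ml_min]
                             for s in self.acquisition.gradient],
                "instrument": dict(self.acquisition.instrument),
            },
            "quant": dict(self.quant),
            "simulation": dict(self.simulation),
        }
        for p in self.peptides:
            entry = {"name": p.name, "sequence": p.sequence,
                     "charges": list(p.charges)}
            if p.rt_min is not None:
                entry["rt_min"] = p.rt_min
            if p.label is not None:
                lab = {"position": p.label.position, "c13": p.label.c13,
                       "n15": p.label.n15}
                if p.label.delta_da is not None:
                    lab["delta_da"] = p.label.delta_da
                entry["label"] = lab
            out["peptides"].append(entry)
        for t in self.transitions:
            entry = {
                "peptide": t.peptide, "precursor_mz": t.precursor_mz,
                "charge": t.charge,
                "fragments": [
                    {"label": f.label, "mz": f.mz}
                    | ({} if f.assigned else {"assigned": False})
                    for f in t.fragments
                ],
            }
            if t.rt_min is not None:
                entry["rt_min"] = t.rt_min
            out["transitions"].append(entry)
        return out

    def config_hash(self) -> str:
        """Stable sha256 of the canonical YAML dump."""
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()


def _require(mapping: dict, key: str, context: str):
    if key not in mapping:
        raise ConfigError(f"{context}: missing required key {key!r}")
    return mapping[key]


def config_from_dict(raw: dict) -> ToolConfig:
    if not isinstance(raw, dict) or not raw:
        raise ConfigError("config must be a non-empty mapping")

    peptides = []
    for i, entry in enumerate(raw.get("peptides", [])):
        ctx = f"peptides[{i}]"
        label = None
        if "label" in entry:
            lab = entry["label"]
            label = IsotopeLabel(
                position=int(_require(lab, "position", f"{ctx}.label")),
                c13=int(lab.get("c13", 0)),
                n15=int(lab.get("n15", 0)),
                delta_da=(float(lab["delta_da"])
                          if lab.get("delta_da") is not None else None),
            )
        try:
            peptides.append(Peptide(
                name=str(_require(entry, "name", ctx)),
                sequence=str(_require(entry, "sequence", ctx)),
                charges=tuple(entry.get("charges", (2,))),
                label=label,
                rt_min=(float(entry["rt_min"])
                        if entry.get("rt_min") is not None else None),
            ))
        except ValueError as exc:
            raise ConfigError(f"{ctx}: {exc}") from exc

    epitopes = []
    for i, entry in enumerate(raw.get("epitopes", [])):
        ctx = f"epitopes[{i}]"
        try:
            epitopes.append(EpitopeMotif(
                name=str(_require(entry, "name", ctx)),
                core=str(_require(entry, "core", ctx)),
            ))
        except ValueError as exc:
            raise ConfigError(f"{ctx}: {exc}") from exc

    transitions = []
    for i, entry in enumerate(raw.get("transitions", [])):
        ctx = f"transitions[{i}]"
        frags = tuple(
            FragmentEntry(
                label=str(_require(f, "label", f"{ctx}.fragments")),
                mz=float(_require(f, "mz", f"{ctx}.fragments")),
                assigned=bool(f.get("assigned", True)),
            )
            for f in entry.get("fragments", [])
        )
        try:
            transitions.append(Transition(
                peptide=str(_require(entry, "peptide", ctx)),
                precursor_mz=float(_require(entry, "precursor_mz", ctx)),
                charge=int(_require(entry, "charge", ctx)),
                fragments=frags,
                rt_min=(float(entry["rt_min"])
                        if entry.get("rt_min") is not None else None),
            ))
        except ValueError as exc:
            raise ConfigError(f"{ctx}: {exc}") from exc

    acq_raw = raw.get("acquisition", {})
    try:
        acquisition = AcquisitionMethod(
            gradient=tuple(
                GradientStep(float(t), float(b), float(fl))
                for t, b, fl in acq_raw.get("gradient", [])
            ),
            instrument=dict(acq_raw.get("instrument", {})),
        )
    except ValueError as exc:
        raise ConfigError(f"acquisition: {exc}") from exc

    quant = {**_QUANT_DEFAULTS, **raw.get("quant", {})}
    simulation = {**_SIM_DEFAULTS, **raw.get("simulation", {})}

    return ToolConfig(
        peptides=tuple(peptides),
        epitopes=tuple(epitopes),
        transitions=tuple(transitions),
        acquisition=acquisition,
        quant=quant,
        simulation=simulation,
        seed=int(raw.get("seed", 0)),
    )


def load_config(path) -> ToolConfig:
    """Load and validate a YAML config; errors carry file/line anchors."""
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        mark = getattr(exc, "problem_mark", None)
        where = f"{path}:{mark.line + 1}" if mark else str(path)
        raise ConfigError(f"{where}: invalid YAML: {exc}") from exc
    if raw is None:
        raise ConfigError(f"{path}: empty config")
    try:
        return config_from_dict(raw)
    except ConfigError as exc:
        raise ConfigError(f"{path}: {exc}") from exc


def dump_config(config: ToolConfig, path) -> None:
    Path(path).write_text(
        yaml.safe_dump(config.to_dict(), sort_keys=False)
    )


def default_config() -> ToolConfig:
    """The shipped six-peptide default configuration."""
    ref = resources.files("glutenprm.data").joinpath("default_config.yaml")
    raw = yaml.safe_load(ref.read_text())
    return config_from_dict(raw)


def validate_config(config: ToolConfig) -> list[Discrepancy]:
    """Cross-check the configured transitions against recomputation.

    For the shipped default the expected finding set is exactly::

        precursor_swap:P3/P4          (printed precursors transposed)
        label_override:P1H            (+6.000 Da override vs +10.027 nominal)
        fragment_unassigned:P1:b6     (470.240 matches no backbone ion)
        fragment_unassigned:P1H:b6*   (heavy analogue of the same ion)
        fragment_mismatch:P2:b9       (printed 1049.544, computed 1049.578)
        fragment_mismatch:P3:b7       (printed 824.429, computed 824.466)
        fragment_mismatch:P6:b9       (printed 995.508 is the computed b8)
    """
    return validate_transitions(
        list(config.peptides),
        list(config.transitions),
        precursor_tol=float(config.quant["precursor_tol_th"]),
        fragment_tol=float(config.quant["fragment_tol_th"]),
    )


@dataclass(frozen=True)
class PipelineResult:
    """Everything one pipeline run produced."""

    curves: dict            # peptide -> CalibrationCurve
    limits: dict            # peptide -> LodLoq
    results: tuple          # QuantResult per unknown sample x peptide
    calibration_report: pd.DataFrame
    results_report: pd.DataFrame | None
    run_log: dict


def _peptide_of(transition_id: str) -> str:
    return transition_id.split(":", 1)[0]


def _abundance(config: ToolConfig, traces: list, peptide_name: str) -> float:
    pep = config.peptide(peptide_name)
    half = float(config.quant["window_halfwidth_min"])
    rt = pep.rt_min
    spans = [(t.time_min[0], t.time_min[-1]) for t in traces if len(t)]
    if not spans:
        return 0.0
    lo = max(s[0] for s in spans)
    hi = min(s[1] for s in spans)
    if rt is None:
        window = (lo, hi)
    else:
        window = (max(lo, rt - half), min(hi, rt + half))
    return integrate_xic(traces, window)


def run_pipeline(
    config: ToolConfig,
    traces: list,
    calibration_manifest: pd.DataFrame,
    unknowns_manifest: pd.DataFrame | None = None,
    out_dir=None,
) -> PipelineResult:
    """Calibrate, derive detection limits, and quantify unknowns.

    ``calibration_manifest`` needs columns ``sample_id, peptide, level``;
    ``unknowns_manifest`` needs ``sample_id, peptide`` with optional
    ``dilution_factor`` and ``recovery`` overrides.  Traces are grouped by
    ``(sample_id, peptide)`` where the peptide is the transition id up to
    the first ``:`` (a peptide's fragment traces are summed).
    """
    grouped: dict = {}
    for trace in traces:
        grouped.setdefault(
            (trace.sample_id, _peptide_of(trace.transition_id)), []
        ).append(trace)

    curves: dict[str, CalibrationCurve] = {}
    limits: dict[str, LodLoq] = {}
    cal_rows = []
    for pep_name, grp in calibration_manifest.groupby("peptide", sort=True):
        levels, abundances = [], []
        for _, row in grp.iterrows():
            key = (str(row["sample_id"]), str(pep_name))
            if key not in grouped:
                raise PipelineError(
                    f"no chromatogram for calibration sample "
                    f"{row['sample_id']!r}, peptide {pep_name!r}"
                )
            levels.append(float(row["level"]))
            abundances.append(_abundance(config, grouped[key], str(pep_name)))
        curve = fit_calibration(
            levels, abundances, peptide=str(pep_name),
            weighting=config.quant.get("weighting"),
        )
        curves[str(pep_name)] = curve
        ll = lodloq_from_curve(curve)
        limits[str(pep_name)] = ll
        cal_rows.append({
            "peptide": pep_name, "slope": curve.slope,
            "intercept": curve.intercept, "r": curve.r, "rss": curve.rss,
            "n": curve.n, "s_residual": ll.s, "lod": ll.lod, "loq": ll.loq,
        })
    calibration_report = pd.DataFrame(cal_rows)

    results: list[QuantResult] = []
    results_report = None
    if unknowns_manifest is not None and len(unknowns_manifest):
        default_df = float(config.quant["dilution_factor"])
        for _, row in unknowns_manifest.iterrows():
            pep_name = str(row["peptide"])
            if pep_name not in curves:
                raise PipelineError(
                    f"unknown sample {row['sample_id']!r} requests peptide "
                    f"{pep_name!r} but no calibration was provided for it"
                )
            key = (str(row["sample_id"]), pep_name)
            if key not in grouped:
                raise PipelineError(
                    f"no chromatogram for unknown sample "
                    f"{row['sample_id']!r}, peptide {pep_name!r}"
                )
            ab = _abundance(config, grouped[key], pep_name)
            df_factor = float(row.get("dilution_factor", default_df)
                              if "dilution_factor" in row else default_df)
            recovery = float(row.get("recovery", 1.0)
                             if "recovery" in row else 1.0)
            results.append(back_calculate(
                ab, curves[pep_name], dilution_factor=df_factor,
                is_recovery=recovery, limits=limits[pep_name],
                sample_id=str(row["sample_id"]),
            ))
        results_report = pd.DataFrame([{
            "sample_id": r.sample_id, "peptide": r.peptide,
            "abundance": r.abundance, "raw_conc": r.raw_conc,
            "dilution_factor": r.dilution_factor, "recovery": r.recovery,
            "final_conc": r.final_conc, "below_loq": r.below_loq,
            "clipped_negative": r.clipped_negative,
        } for r in results])

    run_log = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "n_traces": len(traces),
        "n_calibration_points": int(len(calibration_manifest)),
        "n_unknowns": int(len(unknowns_manifest))
        if unknowns_manifest is not None else 0,
        "peptides_calibrated": sorted(curves),
    }

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        calibration_report.to_csv(
            out_dir / "calibration_report.tsv", sep="\t", index=False)
        if results_report is not None:
            results_report.to_csv(
                out_dir / "results.tsv", sep="\t", index=False)
        yaml.safe_dump(run_log, (out_dir / "run_log.yaml").open("w"),
                       sort_keys=True)

    return PipelineResult(
        curves=curves, limits=limits, results=tuple(results),
        calibration_report=calibration_report,
        results_report=results_report, run_log=run_log,
    )
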
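"""PRM inclusion-list construction, validation, and retention scheduling.

A transition is a scheduled precursor plus the identifier/quantifier fragment
ions monitored for it.  Fragment labels are stored as free text so that
printed-but-unassignable ions survive export/import round trips unchanged;
only labels matching ``b<k>``/``y<k>``/``a<k>`` are recomputed during
validation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import pandas as pd

from glutenprm.chem import (
    MASS_TABLE,
    AminoAcidMassTable,
    FragmentIon,
    Peptide,
    fragment_mz,
    parse_fragment_label,
    precursor_mz,
)

__all__ = [
    "FragmentEntry",
    "Transition",
    "GradientStep",
    "AcquisitionMethod",
    "ObservedSpectrum",
    "Discrepancy",
    "build_inclusion_list",
    "match_ions",
    "select_fragments",
    "schedule_windows",
    "validate_transitions",
    "transitions_to_frame",
    "frame_to_transitions",
    "export_csv",
    "read_csv",
]

#: Default gradient end (min) used to clip retention windows.
DEFAULT_RUN_END = 15.07

#: Precursor recomputation tolerance (Th).
PRECURSOR_TOL = 0.005

#: Fragment recomputation tolerance (Th); looser than the precursor tolerance
#: because printed fragment values carry more rounding drift.
FRAGMENT_TOL = 0.015


@dataclass(frozen=True)
class FragmentEntry:
    """One monitored fragment: free-text label plus m/z.

    ``assigned=False`` marks an ion stored as printed but with no series
    assignment; the validator reports it instead of recomputing it.
    """

    label: str
    mz: float
    assigned: bool = True

    def __post_init__(self):
        if self.mz <= 0:
            raise ValueError(f"fragment m/z must be > 0, got {self.mz}")

    @property
    def series_ordinal(self) -> tuple[str, int] | None:
        if not self.assigned:
            return None
        return parse_fragment_label(self.label)


@dataclass(frozen=True)
class Transition:
    """A precursor with its monitored fragments and retention schedule."""

    peptide: str
    precursor_mz: float
    charge: int
    fragments: tuple = ()
    rt_min: float | None = None
    window: tuple | None = None   # (start, end) in minutes

    def __post_init__(self):
        object.__setattr__(self, "fragments", tuple(self.fragments))
        if self.charge < 1:
            raise ValueError("charge must be >= 1")
        if self.precursor_mz <= 0:
            raise ValueError("precursor m/z must be > 0")

    @property
    def scheduled(self) -> bool:
        return self.rt_min is not None


@dataclass(frozen=True)
class GradientStep:
    time_min: float
    percent_b: float
    flow_ml_min: float

    def __post_init__(self):
        if not 0.0 <= self.percent_b <= 100.0:
            raise ValueError("%B must be in [0, 100]")


@dataclass(frozen=True)
class AcquisitionMethod:
    """Chromatography gradient plus free-text instrument parameters."""

    gradient: tuple = ()
    instrument: dict = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "gradient", tuple(self.gradient))
        times = [s.time_min for s in self.gradient]
        if any(b >= a for a, b in zip(times[1:], times[:-1])):
            raise ValueError("gradient times must be strictly increasing")

    @property
    def run_end(self) -> float:
        if not self.gradient:
            return DEFAULT_RUN_END
        return self.gradient[-1].time_min


@dataclass(frozen=True)
class ObservedSpectrum:
    """Centroided peak list (m/z ascending, intensities >= 0) for one precursor."""

    mz: tuple
    intensity: tuple

    def __post_init__(self):
        mz = tuple(float(v) for v in self.mz)
        it = tuple(float(v) for v in self.intensity)
        if len(mz) != len(it):
            raise ValueError("mz and intensity lengths differ")
        if any(b <= a for a, b in zip(mz, mz[1:])):
            raise ValueError("m/z values must be strictly ascending")
        if any(v < 0 for v in it):
            raise ValueError("intensities must be >= 0")
        object.__setattr__(self, "mz", mz)
        object.__setattr__(self, "intensity", it)

    def __len__(self) -> int:
        return len(self.mz)


@dataclass(frozen=True)
class Discrepancy:
    """One validation finding: a stable code plus a human-readable message."""

    code: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.code}: {self.message}"


def build_inclusion_list(
    peptides: list[Peptide],
    fragment_selections: dict[str, list[FragmentEntry]] | None = None,
    table: AminoAcidMassTable = MASS_TABLE,
) -> list[Transition]:
    """One transition per peptide/charge with recomputed precursor m/z.

    Fragments come from ``fragment_selections`` keyed by peptide name (may be
    absent, giving a precursor-only entry).  Peptides without a retention
    time are emitted unscheduled with a warning.  Output order is
    deterministic: input peptide order, then ascending charge.
    """
    fragment_selections = fragment_selections or {}
    out = []
    for pep in peptides:
        if pep.rt_min is None:
            warnings.warn(
                f"peptide {pep.name} has no retention time; "
                "transition emitted unscheduled",
                stacklevel=2,
            )
        frags = tuple(fragment_selections.get(pep.name, ()))
        for z in sorted(pep.charges):
            out.append(Transition(
                peptide=pep.name,
                precursor_mz=precursor_mz(pep, z, table),
                charge=z,
                fragments=frags,
                rt_min=pep.rt_min,
            ))
    return out


def match_ions(
    theoretical: list[FragmentIon],
    observed: ObservedSpectrum,
    tolerance: float = 0.01,
    ppm: bool = False,
) -> tuple[list[tuple[FragmentIon, int]], list[int]]:
    """Assign each observed peak to its nearest theoretical ion within tolerance.

    Returns ``(assignments, unmatched)`` where assignments are
    ``(fragment, peak_index)`` pairs and unmatched is the list of peak
    indices with no ion inside the tolerance.  Each peak is assigned to at
    most one ion; exact distance ties go to the lower-ordinal ion.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be > 0")
    assignments: list[tuple[FragmentIon, int]] = []
    unmatched: list[int] = []
    for idx, peak_mz in enumerate(observed.mz):
        tol = tolerance * peak_mz * 1e-6 if ppm else tolerance
        best: FragmentIon | None = None
        best_d = tol
        for ion in theoretical:
            d = abs(ion.mz - peak_mz)
            if d < best_d or (
                best is not None and d == best_d and ion.ordinal < best.ordinal
            ):
                best, best_d = ion, d
        if best is None:
            unmatched.append(idx)
        else:
            assignments.append((best, idx))
    return assignments, unmatched


def select_fragments(
    assignments: list[tuple[FragmentIon, int]],
    observed: ObservedSpectrum,
    k: int,
    allow_a: bool = False,
) -> list[FragmentEntry]:
    """Top-``k`` matched direct-sequence ions by observed intensity.

    Only b/y ions count as direct-sequence unless ``allow_a`` is set.  Ties
    break deterministically: higher intensity first, then lower m/z.  If
    fewer than ``k`` ions matched, all of them are returned with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    allowed = ("b", "y", "a") if allow_a else ("b", "y")
    candidates = [
        (ion, observed.intensity[idx])
        for ion, idx in assignments
        if ion.series in allowed
    ]
    if len(candidates) < k:
        warnings.warn(
            f"only {len(candidates)} matched ions available for k={k}",
            stacklevel=2,
        )
    candidates.sort(key=lambda c: (-c[1], c[0].mz))
    return [
        FragmentEntry(label=ion.label, mz=ion.mz)
        for ion, _ in candidates[:k]
    ]


def schedule_windows(
    transitions: list[Transition],
    half_width: float = 0.5,
    run_end: float = DEFAULT_RUN_END,
) -> list[Transition]:
    """Attach ``[RT - h, RT + h]`` windows clipped to ``[0, run_end]``.

    Unscheduled transitions get the full run as their window.
    """
    if half_width <= 0:
        raise ValueError("half_width must be > 0")
    out = []
    for t in transitions:
        if t.rt_min is None:
            window = (0.0, run_end)
        else:
            window = (max(0.0, t.rt_min - half_width),
                      min(run_end, t.rt_min + half_width))
        out.append(replace(t, window=window))
    return out


def _fragment_matches(pep: Peptide, series: str, ordinal: int,
                      printed_mz: float, max_charge: int,
                      tol: float, table: AminoAcidMassTable) -> bool:
    """True if the printed value matches the labelled ion at any charge state.

    Charge is not printed next to fragment labels, so charges 1..max_charge
    are tried (multiply-protonated fragments do occur for long peptides).
    """
    if ordinal >= len(pep.sequence):
        return False
    for z in range(1, max_charge + 1):
        if abs(fragment_mz(pep, series, ordinal, z, table) - printed_mz) <= tol:
            return True
    return False


def validate_transitions(
    peptides: list[Peptide],
    transitions: list[Transition],
    precursor_tol: float = PRECURSOR_TOL,
    fragment_tol: float = FRAGMENT_TOL,
    table: AminoAcidMassTable = MASS_TABLE,
) -> list[Discrepancy]:
    """Cross-check every transition against first-principles recomputation.

    Reported findings (never silently corrected):

    * ``precursor_swap`` — a pair of peptides whose printed precursors match
      each other's recomputed values (a transposed pair in the source list);
    * ``precursor_mismatch`` — printed precursor off by more than
      ``precursor_tol`` with no swap partner;
    * ``label_override`` — a peptide whose isotope-label delta override
      disagrees with its composition-derived delta by more than 0.01 Da;
    * ``fragment_unassigned`` — a fragment stored without a series
      assignment (opaque m/z);
    * ``fragment_mismatch`` — an assigned fragment whose printed m/z matches
      the labelled ion at no charge state within ``fragment_tol``.
    """
    by_name = {p.name: p for p in peptides}
    findings: list[Discrepancy] = []

    # Precursor check with swap detection.
    mismatches: list[tuple[Transition, float]] = []
    for t in transitions:
        pep = by_name.get(t.peptide)
        if pep is None:
            findings.append(Discrepancy(
                code=f"unknown_peptide:{t.peptide}",
                message=f"transition references unknown peptide {t.peptide!r}",
            ))
            continue
        calc = precursor_mz(pep, t.charge, table)
        if abs(calc - t.precursor_mz) > precursor_tol:
            mismatches.append((t, calc))

    consumed = set()
    for i, (ti, calc_i) in enumerate(mismatches):
        if i in consumed:
            continue
        for j in range(i + 1, len(mismatches)):
            if j in consumed:
                continue
            tj, calc_j = mismatches[j]
            if (abs(ti.precursor_mz - calc_j) <= precursor_tol
                    and abs(tj.precursor_mz - calc_i) <= precursor_tol):
                findings.append(Discrepancy(
                    code=f"precursor_swap:{ti.peptide}/{tj.peptide}",
                    message=(
                        f"printed precursors of {ti.peptide} "
                        f"({ti.precursor_mz:.3f}) and {tj.peptide} "
                        f"({tj.precursor_mz:.3f}) match each other's "
                        f"recomputed values ({calc_i:.3f} / {calc_j:.3f}); "
                        "likely transposed"
                    ),
                ))
                consumed.update((i, j))
                break
        else:
            findings.append(Discrepancy(
                code=f"precursor_mismatch:{ti.peptide}",
                message=(
                    f"{ti.peptide} printed precursor {ti.precursor_mz:.3f} "
                    f"vs recomputed {calc_i:.3f} ({ti.charge}+)"
                ),
            ))
            consumed.add(i)

    # Label override vs composition.
    for pep in peptides:
        if pep.label is None or pep.label.delta_da is None:
            continue
        comp = pep.label.composition_delta(table)
        if abs(pep.label.delta_da - comp) > 0.01:
            findings.append(Discrepancy(
                code=f"label_override:{pep.name}",
                message=(
                    f"{pep.name} label delta override "
                    f"{pep.label.delta_da:+.3f} Da differs from "
                    f"composition-derived {comp:+.3f} Da"
                ),
            ))

    # Fragment checks.
    for t in transitions:
        pep = by_name.get(t.peptide)
        if pep is None:
            continue
        for frag in t.fragments:
            so = frag.series_ordinal
            if so is None:
                findings.append(Discrepancy(
                    code=f"fragment_unassigned:{t.peptide}:{frag.label}",
                    message=(
                        f"{t.peptide} fragment {frag.label!r} at "
                        f"{frag.mz:.3f} stored without a series assignment"
                    ),
                ))
                continue
            series, ordinal = so
            if not _fragment_matches(pep, series, ordinal, frag.mz,
                                     t.charge, fragment_tol, table):
                findings.append(Discrepancy(
                    code=f"fragment_mismatch:{t.peptide}:{frag.label}",
                    message=(
                        f"{t.peptide} fragment {frag.label} printed at "
                        f"{frag.mz:.3f} matches no recomputed {series}-ion "
                        f"of that ordinal at charges 1..{t.charge}"
                    ),
                ))
    return findings


_CSV_COLUMNS = [
    "peptide", "precursor_mz", "charge", "fragment_label", "fragment_mz",
    "fragment_assigned", "rt_min", "window_start_min", "window_end_min",
]


def transitions_to_frame(transitions: list[Transition]) -> pd.DataFrame:
    """One row per fragment (precursor-only transitions get one bare row)."""
    rows = []
    for t in transitions:
        base = {
            "peptide": t.peptide,
            "precursor_mz": t.precursor_mz,
            "charge": t.charge,
            "rt_min": t.rt_min,
            "window_start_min": t.window[0] if t.window else None,
            "window_end_min": t.window[1] if t.window else None,
        }
        if not t.fragments:
            rows.append({**base, "fragment_label": None, "fragment_mz": None,
                         "fragment_assigned": None})
        for frag in t.fragments:
            rows.append({**base, "fragment_label": frag.label,
                         "fragment_mz": frag.mz,
                         "fragment_assigned": frag.assigned})
    return pd.DataFrame(rows, columns=_CSV_COLUMNS)


def frame_to_transitions(frame: pd.DataFrame) -> list[Transition]:
    out = []
    keys = ["peptide", "precursor_mz", "charge"]
    for (pep, pmz, z), grp in frame.groupby(keys, sort=False):
        frags = []
        for _, row in grp.iterrows():
            if pd.isna(row["fragment_mz"]):
                continue
            frags.append(FragmentEntry(
                label=str(row["fragment_label"]),
                mz=float(row["fragment_mz"]),
                assigned=bool(row["fragment_assigned"]),
            ))
        first = grp.iloc[0]
        rt = None if pd.isna(first["rt_min"]) else float(first["rt_min"])
        window = None
        if not pd.isna(first["window_start_min"]):
            window = (float(first["window_start_min"]),
                      float(first["window_end_min"]))
        out.append(Transition(
            peptide=str(pep), precursor_mz=float(pmz), charge=int(z),
            fragments=tuple(frags), rt_min=rt, window=window,
        ))
    return out


def export_csv(transitions: list[Transition], path) -> None:
    transitions_to_frame(transitions).to_csv(path, index=False)


def read_csv(path) -> list[Transition]:
    return frame_to_transitions(pd.read_csv(path))
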
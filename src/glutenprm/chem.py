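"""Peptide and fragment-ion mass arithmetic for targeted (PRM) proteomics.

All mass-to-charge computation uses monoisotopic residue masses and a proton
charge carrier (positive-mode ESI).  Average masses are provided separately
for reconciling molecular-weight columns rounded to kilodaltons.  A single
residue-specific stable-isotope label (e.g. a 13C9,15N phenylalanine) is
supported, with either a composition-derived mass delta or an explicit
override in daltons.

Positions are 1-based in every user-facing interface ("residue six" means
``sequence[5]``).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterator, Sequence

__all__ = [
    "AminoAcidMassTable",
    "IsotopeLabel",
    "Peptide",
    "FragmentIon",
    "EpitopeMotif",
    "UnknownResidueError",
    "MASS_TABLE",
    "monoisotopic_mass",
    "average_mass",
    "precursor_mz",
    "fragment_mz",
    "fragment_table",
    "proline_percent",
    "count_motif",
]

FRAGMENT_SERIES = ("b", "y", "a")

#: Monoisotopic residue (amino-acid minus water) masses, Da.
_MONO = {
    "G": 57.021464, "A": 71.037114, "S": 87.032028, "P": 97.052764,
    "V": 99.068414, "T": 101.047678, "C": 103.009185, "L": 113.084064,
    "I": 113.084064, "N": 114.042927, "D": 115.026943, "Q": 128.058578,
    "K": 128.094963, "E": 129.042593, "M": 131.040485, "H": 137.058912,
    "F": 147.068414, "R": 156.101111, "Y": 163.063329, "W": 186.079313,
}

#: Average residue masses, Da.
_AVG = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167,
    "V": 99.1326, "T": 101.1051, "C": 103.1388, "L": 113.1594,
    "I": 113.1594, "N": 114.1038, "D": 115.0886, "Q": 128.1307,
    "K": 128.1741, "E": 129.1155, "M": 131.1926, "H": 137.1411,
    "F": 147.1766, "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}


class UnknownResidueError(ValueError):
    """Raised when a sequence contains a letter outside the mass table.

    Attributes
    ----------
    residue : str
        The offending one-letter code.
    position : int
        1-based position of the offending residue in the sequence.
    """

    def __init__(self, residue: str, position: int):
        self.residue = residue
        self.position = position
        super().__init__(
            f"unknown amino-acid letter {residue!r} at position {position}"
        )


@dataclass(frozen=True)
class AminoAcidMassTable:
    """Residue masses plus the physical constants used for ion arithmetic.

    The defaults cover the 20 standard residues.  Looking up any other
    letter raises :class:`UnknownResidueError`.
    """

    monoisotopic: dict = field(default_factory=lambda: dict(_MONO))
    average: dict = field(default_factory=lambda: dict(_AVG))
    water: float = 18.0105646863          # H2O, monoisotopic
    water_average: float = 18.01528
    proton: float = 1.00727646688         # charge carrier
    carbon_monoxide: float = 27.9949146221  # CO, for a = b - CO
    delta_13c: float = 1.003354838        # 13C - 12C
    delta_15n: float = 0.997034893        # 15N - 14N

    def residue_mass(self, letter: str, position: int = 0,
                     average: bool = False) -> float:
        table = self.average if average else self.monoisotopic
        try:
            return table[letter]
        except KeyError:
            raise UnknownResidueError(letter, position) from None

    def validate_sequence(self, sequence: str) -> None:
        """Raise :class:`UnknownResidueError` at the first bad letter."""
        if not sequence:
            raise ValueError("sequence must be non-empty")
        for i, letter in enumerate(sequence, start=1):
            if letter not in self.monoisotopic:
                raise UnknownResidueError(letter, i)


#: Shared default table; every operation accepts an explicit override.
MASS_TABLE = AminoAcidMassTable()


@dataclass(frozen=True)
class IsotopeLabel:
    """A stable-isotope label on a single residue.

    The effective mass delta is ``c13 * (13C-12C) + n15 * (15N-14N)`` unless
    ``delta_da`` is given, in which case the override wins.  This allows a
    transition list whose printed heavy-peptide m/z imply a delta different
    from the label's nominal composition to be represented faithfully.
    """

    position: int            # 1-based residue index
    c13: int = 0
    n15: int = 0
    delta_da: float | None = None

    def __post_init__(self):
        if self.position < 1:
            raise ValueError("label position is 1-based and must be >= 1")
        if self.c13 < 0 or self.n15 < 0:
            raise ValueError("isotope substitution counts must be >= 0")

    def mass_delta(self, table: AminoAcidMassTable = MASS_TABLE) -> float:
        if self.delta_da is not None:
            return self.delta_da
        return self.c13 * table.delta_13c + self.n15 * table.delta_15n

    def composition_delta(self, table: AminoAcidMassTable = MASS_TABLE) -> float:
        """Delta implied by the isotope counts, ignoring any override."""
        return self.c13 * table.delta_13c + self.n15 * table.delta_15n


@dataclass(frozen=True)
class Peptide:
    """A named peptide with charge states and an optional isotope label."""

    name: str
    sequence: str
    charges: tuple = (2,)
    label: IsotopeLabel | None = None
    rt_min: float | None = None

    def __post_init__(self):
        MASS_TABLE.validate_sequence(self.sequence)
        object.__setattr__(self, "charges", tuple(int(z) for z in self.charges))
        if not self.charges:
            raise ValueError(f"{self.name}: at least one charge state required")
        if any(z < 1 for z in self.charges):
            raise ValueError(f"{self.name}: charge states must be >= 1")
        if self.label is not None and self.label.position > len(self.sequence):
            raise ValueError(
                f"{self.name}: label position {self.label.position} exceeds "
                f"sequence length {len(self.sequence)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class FragmentIon:
    """One backbone fragment ion (b, y or a series)."""

    series: str
    ordinal: int
    charge: int
    mz: float

    @property
    def label(self) -> str:
        return f"{self.series}{self.ordinal}"


@dataclass(frozen=True)
class EpitopeMotif:
    """A 9-residue T-cell epitope core used for motif scanning."""

    name: str
    core: str

    def __post_init__(self):
        if len(self.core) != 9:
            raise ValueError(
                f"epitope core must be 9 residues, got {len(self.core)} "
                f"for {self.name!r}"
            )
        MASS_TABLE.validate_sequence(self.core)


def _as_peptide(peptide: Peptide | str) -> Peptide:
    if isinstance(peptide, Peptide):
        return peptide
    return Peptide(name=peptide, sequence=peptide)


def _residue_sum(sequence: str, table: AminoAcidMassTable,
                 average: bool = False) -> float:
    total = 0.0
    for i, letter in enumerate(sequence, start=1):
        total += table.residue_mass(letter, i, average=average)
    return total


def monoisotopic_mass(peptide: Peptide | str,
                      table: AminoAcidMassTable = MASS_TABLE) -> float:
    """Neutral monoisotopic mass in Da: residues + water + label delta."""
    pep = _as_peptide(peptide)
    mass = _residue_sum(pep.sequence, table) + table.water
    if pep.label is not None:
        mass += pep.label.mass_delta(table)
    return mass


def average_mass(peptide: Peptide | str,
                 table: AminoAcidMassTable = MASS_TABLE) -> float:
    """Neutral average mass in Da: residues + water + label delta."""
    pep = _as_peptide(peptide)
    mass = _residue_sum(pep.sequence, table, average=True) + table.water_average
    if pep.label is not None:
        mass += pep.label.mass_delta(table)
    return mass


def precursor_mz(peptide: Peptide | str, charge: int,
                 table: AminoAcidMassTable = MASS_TABLE) -> float:
    """Precursor m/z for a given positive charge state."""
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    return (monoisotopic_mass(peptide, table) + charge * table.proton) / charge


def fragment_mz(peptide: Peptide | str, series: str, ordinal: int,
                charge: int = 1,
                table: AminoAcidMassTable = MASS_TABLE) -> float:
    """m/z of the b/y/a fragment ion with the given ordinal and charge.

    b ions carry the N-terminal prefix, y ions the C-terminal suffix plus
    water, a ions are b minus carbon monoxide.  A residue label contributes
    its delta only when the labelled position falls inside the fragment.
    """
    pep = _as_peptide(peptide)
    n = len(pep.sequence)
    if series not in FRAGMENT_SERIES:
        raise ValueError(f"series must be one of {FRAGMENT_SERIES}, got {series!r}")
    if not 1 <= ordinal < n:
        raise ValueError(
            f"fragment ordinal must be in [1, {n - 1}] for a {n}-residue "
            f"peptide, got {ordinal}"
        )
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")

    delta = pep.label.mass_delta(table) if pep.label is not None else 0.0
    label_pos = pep.label.position if pep.label is not None else 0

    if series in ("b", "a"):
        neutral = _residue_sum(pep.sequence[:ordinal], table)
        if label_pos and label_pos <= ordinal:
            neutral += delta
        mz = (neutral + charge * table.proton) / charge
        if series == "a":
            mz -= table.carbon_monoxide / charge
        return mz

    # y series
    neutral = _residue_sum(pep.sequence[n - ordinal:], table) + table.water
    if label_pos and label_pos > n - ordinal:
        neutral += delta
    return (neutral + charge * table.proton) / charge


def fragment_table(peptide: Peptide | str, max_charge: int = 1,
                   table: AminoAcidMassTable = MASS_TABLE) -> list[FragmentIon]:
    """All b/y/a ions for ordinals ``1..len-1`` and charges ``1..max_charge``.

    Ordered deterministically by (series, ordinal, charge) with series in
    b, y, a order.
    """
    if max_charge < 1:
        raise ValueError(f"max_charge must be >= 1, got {max_charge}")
    pep = _as_peptide(peptide)
    ions = []
    for series in FRAGMENT_SERIES:
        for ordinal in range(1, len(pep.sequence)):
            for charge in range(1, max_charge + 1):
                ions.append(FragmentIon(
                    series=series, ordinal=ordinal, charge=charge,
                    mz=fragment_mz(pep, series, ordinal, charge, table),
                ))
    return ions


def proline_percent(sequence: str, ndigits: int = 1) -> float:
    """Percentage of proline residues, rounded to ``ndigits`` decimals."""
    MASS_TABLE.validate_sequence(sequence)
    return round(100.0 * sequence.count("P") / len(sequence), ndigits)


def count_motif(sequence: str, motif: str) -> int:
    """Count possibly-overlapping exact occurrences of ``motif`` (shift-by-one)."""
    if not motif:
        raise ValueError("motif must be non-empty")
    count = 0
    start = 0
    while True:
        idx = sequence.find(motif, start)
        if idx < 0:
            return count
        count += 1
        start = idx + 1


_LABEL_RE = re.compile(r"^([bya])(\d+)$")


def parse_fragment_label(label: str) -> tuple[str, int] | None:
    """Parse ``"y2"``-style fragment labels; return None if unparseable.

    Labels carrying extra annotation (e.g. a trailing ``*`` marking a heavy
    residue) are deliberately left unparsed so printed-but-unassignable ions
    survive round trips without being recomputed.
    """
    m = _LABEL_RE.match(label.strip())
    if m is None:
        return None
    return m.group(1), int(m.group(2))
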
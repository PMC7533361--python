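"""Static in vitro gastrointestinal digestion planning arithmetic.

Implements the deterministic bench arithmetic of a three-phase
(oral/gastric/intestinal) static digestion: simulated-fluid recipes from
1.25x stocks, the per-phase volume schedule for a given dry sample mass,
loss accounting for mid-run sampling, and acid-quench volumes.

All densities are treated as 1 g/mL for v/w arithmetic, matching the worked
examples the schedule is calibrated against.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "FluidRecipe",
    "DigestionPlan",
    "DEFAULT_FLUIDS",
    "volume_schedule",
    "quench_volume",
    "working_fluid",
]

#: Dilution of the 1.25x stock down to working strength.
STOCK_FACTOR = 1.25

#: Rehydration: 1.25 g dry sample per 4 mL water.
REHYDRATION_ML_PER_G = 4.0 / 1.25

#: CaCl2 is dosed from a concentrated stock (mmol/L).
CACL2_STOCK_MM = 300.0


@dataclass(frozen=True)
class FluidRecipe:
    """Working-strength simulated digestive fluid for one phase.

    ``stock_mmol`` holds the 1.25x stock-salt concentrations (mmol/L);
    ``enzymes`` maps enzyme name to working activity (U/mL);
    ``cacl2_mmol`` is the working CaCl2 concentration (mmol/L).
    """

    phase: str
    stock_mmol: dict = field(default_factory=dict)
    ph: float = 7.0
    enzymes: dict = field(default_factory=dict)
    cacl2_mmol: float = 0.0

    def __post_init__(self):
        if self.phase not in ("oral", "gastric", "intestinal"):
            raise ValueError(f"unknown phase {self.phase!r}")


#: Salt stocks at 1.25x working strength (mmol/L) and working enzyme/CaCl2
#: doses for each phase.
DEFAULT_FLUIDS = {
    "oral": FluidRecipe(
        phase="oral",
        stock_mmol={
            "KCl": 15.1, "KH2PO4": 3.70, "NaHCO3": 13.6,
            "MgCl2(H2O)6": 0.15, "(NH4)2CO3": 0.06,
        },
        ph=7.0,
        enzymes={"alpha-amylase": 75.0},
        cacl2_mmol=0.75,
    ),
    "gastric": FluidRecipe(
        phase="gastric",
        stock_mmol={
            "KCl": 6.90, "KH2PO4": 0.90, "NaHCO3": 25.0, "NaCl": 47.2,
            "MgCl2(H2O)6": 0.10, "(NH4)2CO3": 0.50,
        },
        ph=3.0,
        enzymes={"pepsin": 2000.0},
        cacl2_mmol=0.075,
    ),
    "intestinal": FluidRecipe(
        phase="intestinal",
        stock_mmol={
            "KCl": 6.80, "KH2PO4": 0.80, "NaHCO3": 85.0, "NaCl": 38.4,
            "MgCl2(H2O)6": 0.33,
        },
        ph=7.0,
        enzymes={"chymotrypsin": 25.0, "trypsin": 100.0},
        cacl2_mmol=0.3,
    ),
}


@dataclass(frozen=True)
class DigestionPlan:
    """Bench volumes for one digestion run of ``dry_mass_g`` of sample."""

    dry_mass_g: float
    water_ml: float
    oral_ml: float
    gastric_ml: float
    intestinal_ml: float
    gastric_aliquots_ml: tuple = ()
    quench_ul: tuple = ()        # TFA stock volume per gastric aliquot
    losses_ml: float = 0.0       # total volume removed before intestinal phase

    def bench_sheet(self) -> str:
        """Human-readable plan for printing."""
        lines = [
            f"Digestion plan for {self.dry_mass_g:g} g freeze-dried sample",
            f"  rehydration water : {self.water_ml:.2f} mL",
            f"  oral fluid        : {self.oral_ml:.2f} mL",
            f"  gastric fluid     : {self.gastric_ml:.2f} mL",
            f"  intestinal fluid  : {self.intestinal_ml:.2f} mL"
            + (f"  (after {self.losses_ml:.2f} mL sampling loss)"
               if self.losses_ml else ""),
        ]
        for i, (v, q) in enumerate(zip(self.gastric_aliquots_ml,
                                       self.quench_ul), start=1):
            lines.append(
                f"  gastric aliquot {i}: {v:.2f} mL, quench with "
                f"{q:.2f} uL TFA stock"
            )
        return "\n".join(lines)


def volume_schedule(
    dry_mass_g: float,
    gastric_aliquots_ml: tuple | list = (),
    mode: str = "worked_example",
    tfa_stock_percent: float = 12.0,
    tfa_target_percent: float = 0.1,
) -> DigestionPlan:
    """Per-phase fluid volumes for a given dry sample mass.

    Two readings of "1:1 v/w with the total solution" exist:

    * ``worked_example`` (default): gastric fluid equals sample mass plus
      oral volume; intestinal equals the running total.  This is the reading
      the protocol's own numeric examples follow (1.25 g -> 2.5 mL gastric,
      5 mL intestinal) and excludes the rehydration water.
    * ``literal``: the rehydration water counts toward the total at every
      step.

    Volume removed as gastric-phase aliquots is subtracted before the
    intestinal addition.
    """
    if dry_mass_g <= 0:
        raise ValueError("dry mass must be > 0")
    if mode not in ("worked_example", "literal"):
        raise ValueError(f"unknown mode {mode!r}")
    aliquots = tuple(float(v) for v in gastric_aliquots_ml)
    if any(v <= 0 for v in aliquots):
        raise ValueError("aliquot volumes must be > 0")

    water = dry_mass_g * REHYDRATION_ML_PER_G
    oral = dry_mass_g * 1.0
    if mode == "worked_example":
        bolus = dry_mass_g + oral
    else:
        bolus = water + dry_mass_g + oral
    gastric = bolus
    gastric_total = bolus + gastric

    losses = sum(aliquots)
    if losses >= gastric_total:
        raise ValueError(
            f"aliquot total {losses:g} mL is not less than the gastric-phase "
            f"volume {gastric_total:g} mL"
        )
    intestinal = gastric_total - losses

    quench = tuple(
        quench_volume(v, tfa_stock_percent, tfa_target_percent)
        for v in aliquots
    )
    return DigestionPlan(
        dry_mass_g=dry_mass_g,
        water_ml=water,
        oral_ml=oral,
        gastric_ml=gastric,
        intestinal_ml=intestinal,
        gastric_aliquots_ml=aliquots,
        quench_ul=quench,
        losses_ml=losses,
    )


def quench_volume(aliquot_ml: float, stock_percent: float = 12.0,
                  target_percent: float = 0.1) -> float:
    """Microlitres of acid stock bringing an aliquot to the target % v/v.

    Solves ``v * stock = (aliquot + v) * target`` for the stock volume ``v``,
    i.e. the final mixture is exactly ``target_percent`` v/v.
    """
    if aliquot_ml < 0:
        raise ValueError("aliquot volume must be >= 0")
    if target_percent < 0:
        raise ValueError("target percent must be >= 0")
    if target_percent >= stock_percent:
        raise ValueError(
            f"target {target_percent}% must be below stock {stock_percent}%"
        )
    aliquot_ul = aliquot_ml * 1000.0
    return aliquot_ul * target_percent / (stock_percent - target_percent)


def working_fluid(recipe: FluidRecipe, final_volume_ml: float) -> dict:
    """Constituent volumes to prepare ``final_volume_ml`` of working fluid.

    The 1.25x salt stock is diluted to strength (``final/1.25``); CaCl2 is
    dosed from a 300 mmol/L stock; when enzymes are requested, half of the
    remaining free volume is reserved as enzyme solution (the lyophilised
    enzyme is dissolved in it to the required total units) and water fills
    the rest.  Enzyme totals are ``activity (U/mL) x final volume``.

    Returns a dict with ``volumes_ml`` (summing exactly to the final
    volume), ``enzyme_units`` and ``ph``.
    """
    if final_volume_ml <= 0:
        raise ValueError("final volume must be > 0")
    stock = final_volume_ml / STOCK_FACTOR
    cacl2 = final_volume_ml * recipe.cacl2_mmol / CACL2_STOCK_MM
    free = final_volume_ml - stock - cacl2
    if free < 0:
        raise ValueError("CaCl2 dose exceeds available dilution volume")
    enzyme_sol = free / 2.0 if recipe.enzymes else 0.0
    water = free - enzyme_sol

    volumes = {"salt_stock_1.25x": stock, "cacl2_stock": cacl2,
               "water": water}
    if enzyme_sol:
        volumes["enzyme_solution"] = enzyme_sol
    units = {name: act * final_volume_ml
             for name, act in recipe.enzymes.items()}
    return {"phase": recipe.phase, "volumes_ml": volumes,
            "enzyme_units": units, "ph": recipe.ph}
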
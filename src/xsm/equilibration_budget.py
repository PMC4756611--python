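"""Vapour-diffusion equilibration mass balance and protein-volume budgets.

A sitting drop mixed from protein stock and precipitant cocktail sits over a
reservoir of the cocktail itself.  Assuming the protein does not change
phase and equilibration runs to completion with only water vapour
transferred, the drop shrinks until its precipitant concentration matches
the reservoir, so every solute is concentrated by the same factor

    factor = (p + q) / q        for a p:q protein:precipitant drop.

The standard 2:1, 1:1 and 1:2 drops therefore concentrate threefold,
twofold and 1.5-fold between mixing and equilibrium.  The same per-drop
arithmetic gives the protein volume a screening plan consumes: a p:q drop
of volume V holds V*p/(p+q) of protein sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .core_model import MixingRatio, DEFAULT_DROP_LAYOUT

__all__ = [
    "DropSpec",
    "EquilibrationResult",
    "ScreeningPlan",
    "concentration_factor",
    "equilibrate_drop",
    "protein_budget",
    "BudgetResult",
]

#: The standard three-ratio layout as a tuple of ratios (2:1, 1:1, 1:2).
STANDARD_RATIOS = tuple(DEFAULT_DROP_LAYOUT[sw] for sw in ("A", "B", "C"))


@dataclass(frozen=True)
class DropSpec:
    """One sitting drop as mixed: stocks, mixing ratio and volume.

    ``precipitant_conc0`` is the cocktail stock concentration in whatever
    unit the screen uses (M, % w/v, ...); the reservoir is assumed to hold
    the cocktail at this same concentration unless ``reservoir_conc`` says
    otherwise.
    """

    protein_conc0: float      # mg/ml protein stock
    precipitant_conc0: float  # cocktail stock, any consistent unit
    ratio: MixingRatio
    drop_volume_nl: float = 150.0
    reservoir_conc: float | None = None

    def __post_init__(self) -> None:
        if self.protein_conc0 <= 0:
            raise ValueError("protein stock concentration must be positive")
        if self.precipitant_conc0 <= 0:
            raise ValueError("precipitant stock concentration must be positive")
        if self.drop_volume_nl <= 0:
            raise ValueError("drop volume must be positive")
        if self.reservoir_conc is not None and self.reservoir_conc <= 0:
            raise ValueError("reservoir concentration must be positive")


@dataclass(frozen=True)
class EquilibrationResult:
    """Concentrations just after mixing and at complete equilibration."""

    postmix_protein: float
    postmix_precipitant: float
    final_protein: float
    final_precipitant: float
    factor: float
    final_volume_nl: float


def concentration_factor(ratio: MixingRatio) -> float:
    """Fold-concentration of every drop solute at complete equilibration.

    For a p:q protein:precipitant drop over a reservoir of the precipitant
    stock the drop must shrink by (p+q)/q to bring its diluted precipitant
    back to reservoir strength; 2:1 -> 3, 1:1 -> 2, 1:2 -> 1.5.  A drop
    with no precipitant part has no equilibration driver and is rejected.
    """
    if ratio.precipitant_parts < 1:
        raise ValueError("precipitant parts = 0: drop has no vapour-diffusion driver")
    return ratio.total_parts / ratio.precipitant_parts


def equilibrate_drop(spec: DropSpec) -> EquilibrationResult:
    """Mass balance of one drop from mixing to complete equilibration.

    Solute amounts are conserved (no phase change), so final concentrations
    are the post-mix concentrations times the concentration factor, and the
    final drop volume is the mixed volume divided by it.  With the default
    reservoir (the precipitant stock itself) the final precipitant
    concentration equals the stock.
    """
    p, q = spec.ratio.protein_parts, spec.ratio.precipitant_parts
    if q < 1:
        raise ValueError("precipitant parts = 0: drop has no vapour-diffusion driver")
    total = p + q
    postmix_protein = spec.protein_conc0 * p / total
    postmix_precipitant = spec.precipitant_conc0 * q / total
    reservoir = (spec.precipitant_conc0 if spec.reservoir_conc is None
                 else spec.reservoir_conc)
    # equilibrium: drop precipitant concentration == reservoir concentration;
    # with a sub-stock reservoir the factor drops below 1 (water flows in)
    # and the same mass balance applies.
    factor = reservoir / postmix_precipitant
    return EquilibrationResult(
        postmix_protein=postmix_protein,
        postmix_precipitant=postmix_precipitant,
        final_protein=postmix_protein * factor,
        final_precipitant=postmix_precipitant * factor,
        factor=factor,
        final_volume_nl=spec.drop_volume_nl / factor,
    )


@dataclass(frozen=True)
class ScreeningPlan:
    """A coarse-screening campaign for one protein sample.

    Defaults describe the recommended full experiment: four sparse-matrix
    screens, both incubation temperatures, 96 conditions each with the
    standard three drop ratios in 150 nl drops.
    """

    n_screens: int = 4
    temperatures: tuple[int, ...] = (277, 293)
    conditions_per_screen: int = 96
    drop_ratios: tuple[MixingRatio, ...] = STANDARD_RATIOS
    drop_volume_nl: float = 150.0

    def __post_init__(self) -> None:
        if self.n_screens < 1 or self.conditions_per_screen < 1:
            raise ValueError("plan counts must be positive")
        if len(self.temperatures) < 1:
            raise ValueError("plan needs at least one temperature")
        if len(self.drop_ratios) < 1:
            raise ValueError("plan needs at least one drop ratio")
        if self.drop_volume_nl <= 0:
            raise ValueError("drop volume must be positive")


@dataclass(frozen=True)
class BudgetResult:
    """Protein-volume budget of a screening plan."""

    total_ul: float
    per_plate_ul: float
    n_plates: int
    n_droplets: int
    per_drop_nl: dict = field(default_factory=dict)  # ratio string -> nl protein


def protein_budget(plan: ScreeningPlan) -> BudgetResult:
    """Protein sample volume consumed by a screening plan.

    Pure drop arithmetic: a p:q drop of volume V holds V*p/(p+q) protein.
    Dead volume and dispensing losses are deliberately excluded.  The
    single-screen/one-temperature standard plan (96 conditions x 2:1, 1:1,
    1:2 at 150 nl = 288 droplets) consumes 21.6 ul; the full four-screen,
    two-temperature plan consumes 172.8 ul.
    """
    per_drop = {str(r): plan.drop_volume_nl * r.protein_fraction
                for r in plan.drop_ratios}
    per_condition_nl = sum(per_drop.values())
    per_plate_ul = per_condition_nl * plan.conditions_per_screen / 1000.0
    n_plates = plan.n_screens * len(plan.temperatures)
    return BudgetResult(
        total_ul=per_plate_ul * n_plates,
        per_plate_ul=per_plate_ul,
        n_plates=n_plates,
        n_droplets=n_plates * plan.conditions_per_screen * len(plan.drop_ratios),
        per_drop_nl=per_drop,
    )
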
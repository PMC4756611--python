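"""Screen success attribution, descriptive summaries and screen diversity.

Success attribution credits each deposited structure to the sparse-matrix
screen it came from -- either directly (the crystal was harvested from the
screen) or via optimization of a condition first found in that screen --
and normalizes by how often each screen was set up.  A screen's "success
rate" is meaningful only for the proteins actually sampled with it: unless
all proteins were tested equally in all screens and followed up with equal
rigour, rates cannot be generalized, and the summary table should be read
with that caveat.

The internal diversity score of a screen is the mean pairwise distance
between its 96 conditions in a chemical-composition space.  The distance is
pluggable; the default is a component-overlap (Gower-style) measure, *not*
the published cocktail-distance of the screening literature, so diversity
values are comparable within this package only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core_model import DEFAULT_THRESHOLDS, Thresholds

__all__ = [
    "ScreenAttribution",
    "attributions_from_crystals",
    "screen_success_rates",
    "summarize_descriptives",
    "DescriptiveSummary",
    "build_depositions",
    "Component",
    "ScreenComposition",
    "component_overlap_distance",
    "internal_diversity",
    "read_screen_compositions",
]

logger = logging.getLogger("xsm.screen_performance")


# ---------------------------------------------------------------------------
# success attribution
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScreenAttribution:
    """Structures attributable to one screen, and its plate throughput."""

    screen: str
    n_direct: int
    n_optimized: int
    n_screens_set_up: int

    def __post_init__(self) -> None:
        if min(self.n_direct, self.n_optimized, self.n_screens_set_up) < 0:
            raise ValueError("attribution counts must be >= 0")


def attributions_from_crystals(plates: pd.DataFrame, crystals: pd.DataFrame,
                               thresholds: Thresholds = DEFAULT_THRESHOLDS
                               ) -> list[ScreenAttribution]:
    """Build per-screen attributions from deposited crystals.

    A crystal counts as a structure when it carries a deposition id and
    diffracted.  Direct crystals credit the screen of their plate;
    optimized crystals credit their explicit ``source_screen`` (falling
    back to the plate's screen when the optimization started from the same
    screen's condition).
    """
    plate_screen = dict(zip(plates["plate_id"], plates["screen"]))
    deposited = crystals[
        crystals["deposition_id"].notna()
        & (crystals["quality_score"] >= thresholds.diffraction_min_quality)]
    direct: dict[str, int] = {}
    optimized: dict[str, int] = {}
    for rec in deposited.itertuples():
        if rec.provenance == "direct":
            screen = plate_screen.get(rec.plate_id)
            if screen is not None:
                direct[screen] = direct.get(screen, 0) + 1
        else:
            screen = rec.source_screen or plate_screen.get(rec.plate_id)
            if screen is not None:
                optimized[screen] = optimized.get(screen, 0) + 1
    setup = plates["screen"].value_counts().to_dict()
    screens = sorted(set(direct) | set(optimized) | set(setup))
    return [ScreenAttribution(screen=s, n_direct=direct.get(s, 0),
                              n_optimized=optimized.get(s, 0),
                              n_screens_set_up=int(setup.get(s, 0)))
            for s in screens]


def screen_success_rates(attributions: Sequence[ScreenAttribution]
                         ) -> pd.DataFrame:
    """Per-screen success rate: structures per screen set up, in percent.

    Screens with zero plates are omitted with a warning (too few samples
    for a rate to mean anything).
    """
    rows = []
    for a in attributions:
        if a.n_screens_set_up == 0:
            logger.warning("screen %s has no plates set up; rate omitted", a.screen)
            continue
        n_structures = a.n_direct + a.n_optimized
        rows.append({
            "screen": a.screen,
            "n_direct": a.n_direct,
            "n_optimized": a.n_optimized,
            "n_structures": n_structures,
            "n_screens_set_up": a.n_screens_set_up,
            "success_rate_pct": 100.0 * n_structures / a.n_screens_set_up,
        })
    return pd.DataFrame(rows, columns=["screen", "n_direct", "n_optimized",
                                       "n_structures", "n_screens_set_up",
                                       "success_rate_pct"])


# ---------------------------------------------------------------------------
# descriptive summaries
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DescriptiveSummary:
    """Per-screen resolution distribution and the concentration/mass
    correlation per subwell (NaN where undefined)."""

    resolution_by_screen: pd.DataFrame
    conc_mass_correlation: dict


def build_depositions(plates: pd.DataFrame, crystals: pd.DataFrame,
                      target_masses: Mapping[str, float] | None = None,
                      thresholds: Thresholds = DEFAULT_THRESHOLDS
                      ) -> pd.DataFrame:
    """Join deposited direct-from-screen crystals with their plate metadata.

    Only direct crystals are kept because only for those is the mixing
    ratio unambiguously linked to the subwell position.  ``target_masses``
    (target_id -> kDa) supplies molecular masses where known.
    """
    deposited = crystals[
        crystals["deposition_id"].notna()
        & (crystals["quality_score"] >= thresholds.diffraction_min_quality)
        & (crystals["provenance"] == "direct")]
    meta = plates[["plate_id", "target_id", "screen", "protein_conc_mg_ml"]]
    out = deposited.merge(meta, on="plate_id", how="inner")
    masses = target_masses or {}
    out["molecular_mass_kda"] = [masses.get(t, np.nan) for t in out["target_id"]]
    return out.reset_index(drop=True)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if len(x) < 3:
        return float("nan")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")  # zero variance: correlation undefined
    return float(np.corrcoef(x, y)[0, 1])


def summarize_descriptives(depositions: pd.DataFrame) -> DescriptiveSummary:
    """Resolution distribution per screen and conc-vs-mass correlation per
    subwell, over deposited direct-from-screen structures.

    Statistics over fewer than three points are reported as NaN.
    """
    rows = []
    for screen, sub in depositions.groupby("screen", sort=True):
        res = sub["resolution_angstrom"].dropna().to_numpy(dtype=float)
        enough = len(res) >= 3
        rows.append({
            "screen": screen,
            "n": len(res),
            "median": float(np.median(res)) if enough else float("nan"),
            "q1": float(np.percentile(res, 25)) if enough else float("nan"),
            "q3": float(np.percentile(res, 75)) if enough else float("nan"),
        })
    correlations = {}
    for subwell, sub in depositions.groupby("subwell", sort=True):
        correlations[subwell] = _pearson(
            sub["molecular_mass_kda"].to_numpy(dtype=float),
            sub["protein_conc_mg_ml"].to_numpy(dtype=float))
    return DescriptiveSummary(
        resolution_by_screen=pd.DataFrame(
            rows, columns=["screen", "n", "median", "q1", "q3"]),
        conc_mass_correlation=correlations)


# ---------------------------------------------------------------------------
# internal diversity
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Component:
    """One chemical component of a crystallization cocktail."""

    name: str
    concentration: float
    unit: str
    ph: float | None = None

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("component name must be non-empty")
        if self.concentration < 0:
            raise ValueError("component concentration must be >= 0")


@dataclass(frozen=True)
class ScreenComposition:
    """A screen's conditions; each condition is a tuple of components."""

    screen: str
    conditions: tuple

    def __post_init__(self) -> None:
        if len(self.conditions) < 2:
            raise ValueError("a screen needs at least two conditions")
        for cond in self.conditions:
            if len(cond) == 0:
                raise ValueError("conditions must have at least one component")


def component_overlap_distance(a: Sequence[Component],
                               b: Sequence[Component]) -> float:
    """Default condition distance: Gower-style mean over the component union.

    Shared components (same name) contribute ``1 - similarity`` where the
    similarity is the concentration ratio min/max when the units agree and
    0 otherwise; components present in only one condition contribute 1.
    This is a documented stand-in, not the published cocktail distance.
    """
    by_name_a = {c.name: c for c in a}
    by_name_b = {c.name: c for c in b}
    names = sorted(set(by_name_a) | set(by_name_b))
    total = 0.0
    for name in names:
        ca, cb = by_name_a.get(name), by_name_b.get(name)
        if ca is None or cb is None:
            total += 1.0
            continue
        if ca.unit != cb.unit:
            total += 1.0
            continue
        hi = max(ca.concentration, cb.concentration)
        lo = min(ca.concentration, cb.concentration)
        similarity = 1.0 if hi == 0 else lo / hi
        total += 1.0 - similarity
    return total / len(names)


def internal_diversity(composition: ScreenComposition,
                       distance: Callable | None = None) -> float:
    """Mean pairwise condition distance of a screen, in [0, 1].

    The plug-in ``distance`` must be symmetric, bounded to [0, 1] and zero
    on identical conditions; violations raise an error when detected.
    """
    d = distance or component_overlap_distance
    conditions = composition.conditions
    total = 0.0
    n_pairs = 0
    for x, y in combinations(conditions, 2):
        dxy, dyx = d(x, y), d(y, x)
        if abs(dxy - dyx) > 1e-9:
            raise ValueError("condition distance is not symmetric")
        if not 0.0 <= dxy <= 1.0 + 1e-12:
            raise ValueError(f"condition distance {dxy} outside [0, 1]")
        total += dxy
        n_pairs += 1
    return total / n_pairs


def read_screen_compositions(path) -> dict[str, ScreenComposition]:
    """Read ``screens.csv`` (long format: screen,condition_index,component,
    concentration,unit,ph) into one composition per screen."""
    raw = pd.read_csv(path, dtype={"screen": str, "component": str, "unit": str},
                      keep_default_na=False)
    required = ["screen", "condition_index", "component", "concentration",
                "unit", "ph"]
    missing = [c for c in required if c not in raw.columns]
    if missing:
        raise ValueError(f"screens.csv: missing columns {missing}")
    out: dict[str, ScreenComposition] = {}
    for screen, sub in raw.groupby("screen", sort=True):
        conditions = []
        for _, cond in sub.groupby("condition_index", sort=True):
            conditions.append(tuple(
                Component(name=r.component, concentration=float(r.concentration),
                          unit=r.unit,
                          ph=float(r.ph) if str(r.ph).strip() else None)
                for r in cond.itertuples()))
        out[screen] = ScreenComposition(screen=screen,
                                        conditions=tuple(conditions))
    return out
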
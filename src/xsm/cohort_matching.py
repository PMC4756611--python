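"""Matched-experiment reconstruction for counterfactual strategy analyses.

Two matched designs are mined from plate metadata:

* *temperature pairs* -- the same sparse-matrix screen and protein sample
  (same purification batch and fresh/frozen state), set up the same day at
  identical concentration with identical co-crystallization compounds, and
  incubated at both 277 and 293 K;
* *screen groups* -- three or four plates of distinct screens (JCSG, LFS,
  HCS, HIN), same sample/day/temperature/compounds, at a *similar*
  concentration (relative tolerance, default 10%, since the matched designs
  only require comparable supersaturation).

Both designs are restricted to units with at least one confirmed
diffracting crystal, so that protein quality is not limiting.
"""

from __future__ import annotations

import logging

import pandas as pd

from .core_model import DEFAULT_THRESHOLDS, FOUR_MAIN_SCREENS, Thresholds

__all__ = [
    "PAIR_KEY",
    "GROUP_KEY",
    "find_temperature_pairs",
    "find_screen_groups",
]

logger = logging.getLogger("xsm.cohort_matching")

#: Metadata that must match exactly between the two plates of a pair.
PAIR_KEY = ["target_id", "sample_id", "fresh_or_frozen", "screen",
            "setup_date", "protein_conc_mg_ml", "compounds"]
#: Metadata shared by all plates of a screen group (concentration is
#: matched separately, with a tolerance).
GROUP_KEY = ["target_id", "sample_id", "fresh_or_frozen", "setup_date",
             "temperature_k", "compounds"]


def _diffracting_plates(crystals: pd.DataFrame, thresholds: Thresholds) -> set:
    if crystals.empty:
        return set()
    ok = crystals["quality_score"] >= thresholds.diffraction_min_quality
    return set(crystals.loc[ok, "plate_id"])


def find_temperature_pairs(plates: pd.DataFrame, crystals: pd.DataFrame,
                           thresholds: Thresholds = DEFAULT_THRESHOLDS
                           ) -> pd.DataFrame:
    """Find 277/293 K plate pairs sharing screen, sample, day, concentration
    and compounds, keeping pairs with >= 1 diffracting crystal on either plate.

    When several plates are eligible on one side of a pair they are matched
    in lexicographic plate-id order (a stated convention -- the original
    disambiguation is unknowable) and a warning is logged.
    """
    diffracting = _diffracting_plates(crystals, thresholds)
    rows = []
    for key, group in plates.groupby(PAIR_KEY, sort=True):
        at_277 = sorted(group.loc[group["temperature_k"] == 277, "plate_id"])
        at_293 = sorted(group.loc[group["temperature_k"] == 293, "plate_id"])
        if not at_277 or not at_293:
            continue
        if len(at_277) > 1 or len(at_293) > 1:
            logger.warning(
                "ambiguous temperature pair for key %s: %d x 277K, %d x 293K plates;"
                " matching in lexicographic order", key, len(at_277), len(at_293))
        for p277, p293 in zip(at_277, at_293):
            if p277 in diffracting or p293 in diffracting:
                rows.append({"plate_277": p277, "plate_293": p293,
                             **dict(zip(PAIR_KEY, key))})
    return pd.DataFrame(rows, columns=["plate_277", "plate_293", *PAIR_KEY])


def find_screen_groups(plates: pd.DataFrame, crystals: pd.DataFrame,
                       conc_tolerance: float = 0.10,
                       screens: tuple = FOUR_MAIN_SCREENS,
                       thresholds: Thresholds = DEFAULT_THRESHOLDS
                       ) -> pd.DataFrame:
    """Find same-temperature groups of 3-4 plates with pairwise-distinct
    screens at similar concentration and >= 1 diffracting crystal overall.

    Concentrations are similar when every plate lies within
    ``conc_tolerance`` (relative to the group minimum) of every other.
    Candidate plates are scanned in (concentration, plate_id) order and
    grouped greedily, which resolves overlapping candidates into a
    deterministic maximal non-overlapping assignment.
    """
    if conc_tolerance < 0:
        raise ValueError("conc_tolerance must be non-negative")
    diffracting = _diffracting_plates(crystals, thresholds)
    candidates = plates[plates["screen"].isin(screens)]
    rows = []
    for key, group in candidates.groupby(GROUP_KEY, sort=True):
        pool = group.sort_values(["protein_conc_mg_ml", "plate_id"],
                                 kind="stable")
        members: list[tuple[str, str, float]] = []  # (plate_id, screen, conc)

        def flush():
            if len(members) >= 3:
                ids = tuple(m[0] for m in members)
                if any(pid in diffracting for pid in ids):
                    rows.append({
                        "plate_ids": ids,
                        "screens": tuple(m[1] for m in members),
                        **dict(zip(GROUP_KEY, key)),
                        "protein_conc_mg_ml": members[0][2],
                    })
            members.clear()

        for rec in pool.itertuples():
            conc = rec.protein_conc_mg_ml
            if members and (conc > members[0][2] * (1 + conc_tolerance)
                            or len(members) == len(screens)):
                flush()
            if any(rec.screen == m[1] for m in members):
                logger.debug("plate %s duplicates screen %s within its group"
                             " candidates; left ungrouped", rec.plate_id, rec.screen)
                continue
            members.append((rec.plate_id, rec.screen, conc))
        flush()
    out = pd.DataFrame(rows, columns=["plate_ids", "screens", *GROUP_KEY,
                                      "protein_conc_mg_ml"])
    if not out.empty:
        out.insert(0, "group_id", [f"G{i:05d}" for i in range(len(out))])
    else:
        out.insert(0, "group_id", pd.Series(dtype=str))
    return out
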
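"""Counterfactual screening-strategy comparisons on matched experiments.

Given the matched designs of :mod:`xsm.cohort_matching`, these analyses ask
what a smaller experiment would have found, droplet subset by droplet
subset, against the full experiment actually performed:

* temperature exclusivity -- for each 277/293 K pair, whether hits (or
  diffracting crystals) appeared at only one temperature or at both;
* multiple screens vs multiple droplets -- at a fixed 21.6 ul protein
  budget (288 droplets), one droplet at 1:1 in each of three screens vs all
  three mixing ratios in a single screen;
* multiple temperatures vs multiple droplets -- at a fixed budget of 192
  droplets, two droplets (2:1 and 1:2) at one temperature vs one 1:1
  droplet at each of the two temperatures.

Every strategy is evaluated by pure droplet-set restriction of the
recorded hits, so the full experiment's success always contains any
restricted strategy's success.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .core_model import (DEFAULT_THRESHOLDS, MixingRatio, Thresholds,
                         hit_droplets)

__all__ = [
    "ExclusivityResult",
    "temperature_exclusivity",
    "ScreensVsDrops",
    "screens_vs_drops",
    "screens_vs_drops_table",
    "single_drop_ratio_success",
    "temps_vs_drops",
]

logger = logging.getLogger("xsm.strategy_comparison")

RATIO_21, RATIO_11, RATIO_12 = MixingRatio(2, 1), MixingRatio(1, 1), MixingRatio(1, 2)


def _hit_sets(scores: pd.DataFrame, thresholds: Thresholds) -> dict:
    """plate_id -> set of (well, subwell) droplets whose final score is a hit."""
    hits = hit_droplets(scores, thresholds)
    out: dict[str, set] = {}
    for plate_id, well, subwell in zip(hits["plate_id"], hits["well"],
                                       hits["subwell"]):
        out.setdefault(plate_id, set()).add((well, subwell))
    return out


def _layouts(plates: pd.DataFrame) -> dict:
    return dict(zip(plates["plate_id"], plates["drop_layout"]))


def _subwell_for_ratio(layout: Mapping[str, MixingRatio],
                       ratio: MixingRatio) -> str | None:
    for subwell, r in layout.items():
        if r == ratio:
            return subwell
    return None


def _diffracting_sets(crystals: pd.DataFrame, thresholds: Thresholds) -> dict:
    """plate_id -> set of wells with a confirmed diffracting crystal."""
    out: dict[str, set] = {}
    if crystals.empty:
        return out
    ok = crystals[crystals["quality_score"] >= thresholds.diffraction_min_quality]
    for plate_id, well in zip(ok["plate_id"], ok["well"]):
        out.setdefault(plate_id, set()).add(well)
    return out


# ---------------------------------------------------------------------------
# temperature exclusivity (paired 277/293 K experiments)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExclusivityResult:
    """Temperature-exclusivity table plus excluded-unit counts per endpoint.

    ``table`` has one row per (stratum, endpoint, category) with the pair
    count and the within-(stratum, endpoint) proportion.  Note the
    diffracting endpoint inherits any harvesting bias of the source data
    (crystals are typically harvested at a single temperature), so its
    exclusivity overstates a true temperature effect; it is reported as-is.
    """

    table: pd.DataFrame
    n_excluded: dict


def temperature_exclusivity(pairs: pd.DataFrame, scores: pd.DataFrame,
                            crystals: pd.DataFrame | None = None,
                            thresholds: Thresholds = DEFAULT_THRESHOLDS
                            ) -> ExclusivityResult:
    """Classify each pair as crystallizing at 277 K only, 293 K only or both.

    Rarity stratification uses the union of crystallizing conditions across
    both plates of the pair (a pair is one experiment on one sample); the
    rare/promiscuous boundary is ``thresholds.rare_max_wells``.  Pairs with
    no event at an endpoint are excluded from that endpoint with their
    count reported.
    """
    hit_sets = _hit_sets(scores, thresholds)
    endpoints = {"hits": None}
    if crystals is not None:
        endpoints["diffracting"] = _diffracting_sets(crystals, thresholds)

    records = []
    n_excluded = {name: 0 for name in endpoints}
    for rec in pairs.itertuples():
        wells_277 = {w for (w, _s) in hit_sets.get(rec.plate_277, set())}
        wells_293 = {w for (w, _s) in hit_sets.get(rec.plate_293, set())}
        n_union = len(wells_277 | wells_293)
        stratum = ("rare" if n_union <= thresholds.rare_max_wells
                   else "promiscuous")
        for endpoint, diff_sets in endpoints.items():
            if endpoint == "hits":
                at_277, at_293 = bool(wells_277), bool(wells_293)
            else:
                at_277 = bool(diff_sets.get(rec.plate_277))
                at_293 = bool(diff_sets.get(rec.plate_293))
            if not at_277 and not at_293:
                n_excluded[endpoint] += 1
                continue
            category = ("both" if at_277 and at_293
                        else "277 only" if at_277 else "293 only")
            records.append({"stratum": stratum, "endpoint": endpoint,
                            "category": category})

    raw = pd.DataFrame(records, columns=["stratum", "endpoint", "category"])
    rows = []
    for stratum in ("rare", "promiscuous", "all"):
        sub = raw if stratum == "all" else raw[raw["stratum"] == stratum]
        for endpoint in endpoints:
            cell = sub[sub["endpoint"] == endpoint]
            total = len(cell)
            if total == 0:
                continue
            freq = cell["category"].value_counts()
            for category in ("277 only", "293 only", "both"):
                count = int(freq.get(category, 0))
                rows.append({"stratum": stratum, "endpoint": endpoint,
                             "category": category, "count": count,
                             "proportion": count / total})
    table = pd.DataFrame(rows, columns=["stratum", "endpoint", "category",
                                        "count", "proportion"])
    return ExclusivityResult(table=table, n_excluded=n_excluded)


# ---------------------------------------------------------------------------
# multiple screens vs multiple droplets (fixed 21.6 ul / 288 droplets)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScreensVsDrops:
    """Outcome counts of the three-screens/one-drop vs one-screen/three-drops
    comparison for one screen combination.

    ``n_one_screen_three_drops`` is reported per screen (every screen of the
    combination gets its own count); ``n_missed_by_both`` counts groups
    whose hits sit outside every droplet both strategies sample, i.e.
    groups with no hit at all among the combination's plates.
    """

    combination: tuple
    n_groups: int
    n_three_screens_one_drop: int
    n_one_screen_three_drops: dict
    n_missed_by_both: int
    n_skipped: int


def _groups_for_combination(groups: pd.DataFrame, combination: Sequence[str]):
    want = frozenset(combination)
    for rec in groups.itertuples():
        if want <= set(rec.screens):
            plate_by_screen = dict(zip(rec.screens, rec.plate_ids))
            yield rec, {s: plate_by_screen[s] for s in combination}


def screens_vs_drops(groups: pd.DataFrame, plates: pd.DataFrame,
                     scores: pd.DataFrame, combination: Sequence[str],
                     thresholds: Thresholds = DEFAULT_THRESHOLDS
                     ) -> ScreensVsDrops:
    """Compare three screens with one 1:1 droplet each against any single
    screen with all three droplets, on groups containing the combination.

    Both strategies spend the same 288-droplet (21.6 ul) protein budget.
    Groups lacking a 1:1 subwell in some plate's layout are skipped and
    logged.
    """
    combination = tuple(combination)
    if len(set(combination)) != 3:
        raise ValueError("combination must name three distinct screens")
    hit_sets = _hit_sets(scores, thresholds)
    layouts = _layouts(plates)
    n_groups = n_s1 = n_missed = n_skipped = 0
    n_s2 = {screen: 0 for screen in combination}
    for rec, plate_by_screen in _groups_for_combination(groups, combination):
        sw11 = {s: _subwell_for_ratio(layouts[p], RATIO_11)
                for s, p in plate_by_screen.items()}
        if any(v is None for v in sw11.values()):
            logger.warning("group %s lacks a 1:1 subwell; skipped", rec.group_id)
            n_skipped += 1
            continue
        n_groups += 1
        found_s1 = any(
            any(sw == sw11[s] for (_w, sw) in hit_sets.get(p, set()))
            for s, p in plate_by_screen.items())
        found_any = False
        for screen, plate in plate_by_screen.items():
            found = bool(hit_sets.get(plate))
            n_s2[screen] += found
            found_any = found_any or found
        n_s1 += found_s1
        n_missed += not found_any
    return ScreensVsDrops(combination=combination, n_groups=n_groups,
                          n_three_screens_one_drop=n_s1,
                          n_one_screen_three_drops=n_s2,
                          n_missed_by_both=n_missed, n_skipped=n_skipped)


def screens_vs_drops_table(groups: pd.DataFrame, plates: pd.DataFrame,
                           scores: pd.DataFrame,
                           thresholds: Thresholds = DEFAULT_THRESHOLDS
                           ) -> pd.DataFrame:
    """Run :func:`screens_vs_drops` for every three-screen combination
    observed in the groups; one row per (combination, strategy)."""
    combos = {frozenset(c) for rec in groups.itertuples()
              for c in _three_subsets(rec.screens)}
    rows = []
    for combo in sorted(tuple(sorted(c)) for c in combos):
        res = screens_vs_drops(groups, plates, scores, combo, thresholds)
        if res.n_groups == 0:
            continue
        rows.append({"combination": "+".join(combo),
                     "strategy": "three screens, one 1:1 drop",
                     "n_success": res.n_three_screens_one_drop,
                     "n_groups": res.n_groups})
        for screen, count in res.n_one_screen_three_drops.items():
            rows.append({"combination": "+".join(combo),
                         "strategy": f"one screen ({screen}), three drops",
                         "n_success": count, "n_groups": res.n_groups})
        rows.append({"combination": "+".join(combo),
                     "strategy": "missed by both",
                     "n_success": res.n_missed_by_both, "n_groups": res.n_groups})
    return pd.DataFrame(rows, columns=["combination", "strategy", "n_success",
                                       "n_groups"])


def _three_subsets(screens: Sequence[str]):
    screens = sorted(set(screens))
    if len(screens) == 3:
        return [tuple(screens)]
    return [tuple(s for s in screens if s != drop) for drop in screens]


def single_drop_ratio_success(groups: pd.DataFrame, plates: pd.DataFrame,
                              scores: pd.DataFrame, combination: Sequence[str],
                              thresholds: Thresholds = DEFAULT_THRESHOLDS
                              ) -> pd.DataFrame:
    """Per-ratio success of the one-drop/multi-screen strategy.

    For each mixing ratio, success means >= 1 hit among that ratio's
    droplets across the three screens of the combination.
    """
    combination = tuple(combination)
    hit_sets = _hit_sets(scores, thresholds)
    layouts = _layouts(plates)
    counts = {str(r): 0 for r in (RATIO_21, RATIO_11, RATIO_12)}
    n_groups = 0
    for rec, plate_by_screen in _groups_for_combination(groups, combination):
        sw_for = {str(r): {s: _subwell_for_ratio(layouts[p], r)
                           for s, p in plate_by_screen.items()}
                  for r in (RATIO_21, RATIO_11, RATIO_12)}
        if any(v is None for m in sw_for.values() for v in m.values()):
            logger.warning("group %s lacks a required subwell; skipped",
                           rec.group_id)
            continue
        n_groups += 1
        for ratio, mapping in sw_for.items():
            counts[ratio] += any(
                any(sw == mapping[s] for (_w, sw) in hit_sets.get(p, set()))
                for s, p in plate_by_screen.items())
    return pd.DataFrame(
        [{"ratio": ratio, "n_success": n, "n_groups": n_groups,
          "success_rate": (n / n_groups if n_groups else float("nan"))}
         for ratio, n in counts.items()])


# ---------------------------------------------------------------------------
# multiple temperatures vs multiple droplets (fixed 192 droplets)
# ---------------------------------------------------------------------------

def temps_vs_drops(pairs: pd.DataFrame, plates: pd.DataFrame,
                   scores: pd.DataFrame,
                   thresholds: Thresholds = DEFAULT_THRESHOLDS) -> pd.DataFrame:
    """Two droplets (2:1 and 1:2) at one temperature vs one 1:1 droplet at
    each temperature, per pair, against the full six-droplet experiment.

    Returns one row per temperature with the number of pairs found by the
    two-drops/one-temperature strategy at that temperature, by the
    one-drop/two-temperatures strategy, and missed by both relative to the
    pairs in which the full experiment found a hit.
    """
    hit_sets = _hit_sets(scores, thresholds)
    layouts = _layouts(plates)
    counts = {277: {"two_drops_one_temp": 0, "one_drop_two_temps": 0,
                    "n_missed": 0, "n_full": 0},
              293: {"two_drops_one_temp": 0, "one_drop_two_temps": 0,
                    "n_missed": 0, "n_full": 0}}
    for rec in pairs.itertuples():
        plate_at = {277: rec.plate_277, 293: rec.plate_293}
        hit_subwells = {t: {sw for (_w, sw) in hit_sets.get(p, set())}
                        for t, p in plate_at.items()}
        full = any(hit_subwells.values())
        if not full:
            continue
        one_drop = any(
            _subwell_for_ratio(layouts[plate_at[t]], RATIO_11) in hit_subwells[t]
            for t in (277, 293))
        for t in (277, 293):
            layout = layouts[plate_at[t]]
            two_sw = {_subwell_for_ratio(layout, RATIO_21),
                      _subwell_for_ratio(layout, RATIO_12)} - {None}
            two_drop = bool(two_sw & hit_subwells[t])
            counts[t]["n_full"] += 1
            counts[t]["two_drops_one_temp"] += two_drop
            counts[t]["one_drop_two_temps"] += one_drop
            counts[t]["n_missed"] += not (two_drop or one_drop)
    return pd.DataFrame(
        [{"temperature_k": t, **c} for t, c in counts.items()],
        columns=["temperature_k", "two_drops_one_temp", "one_drop_two_temps",
                 "n_missed", "n_full"])
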
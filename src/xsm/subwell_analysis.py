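"""Per-plate crystallizing-well counts and subwell hit-combination mining.

Each 96-well condition holds up to three droplets (subwells A/B/C at 2:1,
1:1 and 1:2 protein:precipitant).  For every crystallizing well the subwell
combination that produced the hit(s) is one of the seven non-empty subsets
of {A, B, C}.  Plates are stratified by their number of crystallizing
conditions; plates with at most five are *rare* ("difficult") crystallizers
and the rest promiscuous ("easy").  Plates sharing a protein are treated as
independent experiments throughout, reflecting a plain hit-identification
exercise.
"""

from __future__ import annotations

import pandas as pd

from .core_model import (DEFAULT_THRESHOLDS, SUBWELLS, Thresholds,
                         hit_droplets)

__all__ = [
    "COMBINATIONS",
    "combination_label",
    "well_outcomes",
    "classify_promiscuity",
    "plate_well_counts",
    "subwell_combination_frequencies",
    "restrict_to_diffracting",
]

#: The seven non-empty subwell subsets, in display order.
COMBINATIONS = ("A only", "B only", "C only",
                "A&B only", "B&C only", "A&C only", "A&B&C")


def combination_label(hit_subwells) -> str:
    """Display label of a non-empty subwell subset ({'A','C'} -> 'A&C only')."""
    subset = frozenset(hit_subwells)
    if not subset or not subset <= set(SUBWELLS):
        raise ValueError(f"hit subwells must be a non-empty subset of {SUBWELLS}")
    joined = "&".join(sw for sw in SUBWELLS if sw in subset)
    return joined if len(subset) == 3 else f"{joined} only"


def well_outcomes(scores: pd.DataFrame,
                  thresholds: Thresholds = DEFAULT_THRESHOLDS) -> pd.DataFrame:
    """Per-condition outcome: which subwells ended as hits.

    Applies last-score-wins per droplet, keeps wells with at least one hit
    subwell, and returns one row per crystallizing well with its
    ``hit_subwells`` frozenset and combination label.
    """
    hits = hit_droplets(scores, thresholds)
    if hits.empty:
        return pd.DataFrame(columns=["plate_id", "well", "hit_subwells", "combination"])
    grouped = (hits.groupby(["plate_id", "well"], sort=True)["subwell"]
               .agg(frozenset).reset_index(name="hit_subwells"))
    grouped["combination"] = [combination_label(s) for s in grouped["hit_subwells"]]
    return grouped


def plate_well_counts(outcomes: pd.DataFrame) -> pd.Series:
    """Number of crystallizing wells per plate (plates with >= 1 hit only)."""
    if outcomes.empty:
        return pd.Series(dtype=int, name="n_crystallizing_wells")
    counts = outcomes.groupby("plate_id", sort=True).size()
    counts.name = "n_crystallizing_wells"
    return counts


def classify_promiscuity(outcomes,
                         thresholds: Thresholds = DEFAULT_THRESHOLDS
                         ) -> tuple[int, str]:
    """Classify one plate as a rare or promiscuous crystallizer.

    ``outcomes`` is either the outcome frame of a single plate or a bare
    crystallizing-well count.  Plates without any crystallizing well are
    excluded upstream and rejected here.
    """
    if isinstance(outcomes, pd.DataFrame):
        if outcomes["plate_id"].nunique() > 1:
            raise ValueError("classify_promiscuity expects outcomes of one plate")
        n = len(outcomes)
    else:
        n = int(outcomes)
    if n < 1:
        raise ValueError("plate has no crystallizing wells; excluded upstream")
    return n, ("rare" if n <= thresholds.rare_max_wells else "promiscuous")


def _stratum_label(n: int, max_stratum: int) -> str:
    return str(n) if n <= max_stratum else f">{max_stratum}"


def subwell_combination_frequencies(outcomes: pd.DataFrame,
                                    max_stratum: int = 10) -> pd.DataFrame:
    """Frequency of each subwell combination, stratified by plate promiscuity.

    Strata are the number of crystallizing wells per plate: 1, 2, ...,
    ``max_stratum`` and a single ``>max_stratum`` bucket (exact binning of
    the large counts is immaterial to the read-out).  Within a stratum the
    proportions run over crystallizing *wells* and sum to one; each row also
    reports the supporting plate and well counts.  Empty strata are simply
    absent.
    """
    if outcomes.empty:
        return pd.DataFrame(columns=["stratum", *COMBINATIONS, "n_plates", "n_wells"])
    counts = plate_well_counts(outcomes)
    strata = counts.map(lambda n: _stratum_label(n, max_stratum))
    tagged = outcomes.merge(strata.rename("stratum"), left_on="plate_id",
                            right_index=True)
    rows = []
    order = [_stratum_label(n, max_stratum) for n in range(1, max_stratum + 1)]
    order.append(f">{max_stratum}")
    for stratum in order:
        sub = tagged[tagged["stratum"] == stratum]
        if sub.empty:
            continue
        freq = sub["combination"].value_counts()
        n_wells = len(sub)
        row = {"stratum": stratum}
        for combo in COMBINATIONS:
            row[combo] = freq.get(combo, 0) / n_wells
        row["n_plates"] = sub["plate_id"].nunique()
        row["n_wells"] = n_wells
        rows.append(row)
    return pd.DataFrame(rows)


def restrict_to_diffracting(plates: pd.DataFrame, crystals: pd.DataFrame,
                            thresholds: Thresholds = DEFAULT_THRESHOLDS
                            ) -> pd.DataFrame:
    """Keep only plates with at least one confirmed diffracting crystal."""
    if crystals.empty:
        return plates.iloc[0:0]
    good = crystals.loc[
        crystals["quality_score"] >= thresholds.diffraction_min_quality, "plate_id"]
    return plates[plates["plate_id"].isin(set(good))].reset_index(drop=True)
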
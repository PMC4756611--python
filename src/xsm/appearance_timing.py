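"""Bounding crystal appearance times from sparse inspection histories.

Automated imaging visits each plate on a fixed schedule (nominally days 1,
2, 4, 7, 14, 28 and 56), so the true appearance time of a crystal is only
known to lie between the last inspection without it and the first
inspection with a crystal annotation.  This module computes those bounds,
applies manual curation corrections (a crystal visible in an earlier image
that was not annotated then has its appearance moved back to the earliest
image showing it), and summarizes late appearances and the cumulative
appearance curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .core_model import DEFAULT_THRESHOLDS, SubwellScore, Thresholds, parse_well

__all__ = [
    "AppearanceEstimate",
    "appearance_bounds",
    "appearance_estimates",
    "read_corrections",
    "late_fraction",
    "LateFraction",
    "cumulative_appearance",
]

_DROPLET = ["plate_id", "well", "subwell"]


@dataclass(frozen=True)
class AppearanceEstimate:
    """Appearance-time bounds of one hit droplet.

    ``annotation_day`` is the raw first-annotation day; ``upper_bound_days``
    equals it unless a curation correction moved the appearance earlier.
    ``lower_bound_days`` is the latest recorded inspection before the upper
    bound (0 when none was recorded).
    """

    plate_id: str
    well: int
    subwell: str
    lower_bound_days: float
    upper_bound_days: float
    annotation_day: float
    is_late: bool


def appearance_bounds(history, corrected_day: float | None = None,
                      thresholds: Thresholds = DEFAULT_THRESHOLDS
                      ) -> AppearanceEstimate:
    """Bound the appearance time of one droplet from its score history.

    ``history`` is the time-sorted :class:`SubwellScore` sequence of a
    single droplet and must contain at least one hit.  ``corrected_day``
    optionally overrides the first-annotation day with a curated earlier
    inspection; it must name an inspection present in the history.
    """
    items = list(history)
    if not items:
        raise ValueError("empty score history")
    plate_id, well, subwell = items[0].plate_id, items[0].well, items[0].subwell
    days = [s.days_since_setup for s in items]
    hit_days = [s.days_since_setup for s in items
                if s.score >= thresholds.hit_min_score]
    if not hit_days:
        raise ValueError("history contains no hit; appearance undefined")
    annotation_day = min(hit_days)
    upper = annotation_day
    if corrected_day is not None:
        if corrected_day not in days:
            raise ValueError(
                f"correction day {corrected_day} not an inspection of this droplet")
        upper = float(corrected_day)
    earlier = [d for d in days if d < upper]
    lower = max(earlier) if earlier else 0.0
    return AppearanceEstimate(
        plate_id=plate_id, well=parse_well(well), subwell=subwell,
        lower_bound_days=float(lower), upper_bound_days=float(upper),
        annotation_day=float(annotation_day),
        is_late=upper > thresholds.late_threshold_days)


def read_corrections(path) -> pd.DataFrame:
    """Read a curation file: plate_id,well,subwell,corrected_upper_bound_days."""
    raw = pd.read_csv(path, dtype={"plate_id": str, "subwell": str, "well": str},
                      keep_default_na=False)
    required = [*_DROPLET, "corrected_upper_bound_days"]
    missing = [c for c in required if c not in raw.columns]
    if missing:
        raise ValueError(f"corrections.csv: missing columns {missing}")
    return pd.DataFrame({
        "plate_id": raw["plate_id"].str.strip(),
        "well": [parse_well(w) for w in raw["well"]],
        "subwell": raw["subwell"].str.strip().str.upper(),
        "corrected_upper_bound_days":
            pd.to_numeric(raw["corrected_upper_bound_days"]).astype(float),
    })


def appearance_estimates(scores: pd.DataFrame,
                         corrections: pd.DataFrame | None = None,
                         droplets: pd.DataFrame | None = None,
                         thresholds: Thresholds = DEFAULT_THRESHOLDS
                         ) -> pd.DataFrame:
    """Appearance bounds for every annotated hit droplet (vectorized).

    Optionally restricted to the droplets listed in ``droplets`` (e.g. the
    droplets that yielded deposited crystals).  Corrections referencing a
    droplet inspection that does not exist raise an error.
    """
    cols = [*_DROPLET, "lower_bound_days", "upper_bound_days",
            "annotation_day", "is_late"]
    ordered = scores.sort_values([*_DROPLET, "inspected_at"], kind="stable")
    if droplets is not None:
        keys = droplets[_DROPLET].drop_duplicates()
        ordered = ordered.merge(keys, on=_DROPLET)
    hits = ordered[ordered["image_score"] >= thresholds.hit_min_score]
    if hits.empty:
        return pd.DataFrame(columns=cols)
    first = (hits.groupby(_DROPLET, sort=True).head(1)
             [[*_DROPLET, "days_since_setup"]]
             .rename(columns={"days_since_setup": "annotation_day"}))
    est = first.copy()
    est["upper_bound_days"] = est["annotation_day"]

    if corrections is not None and not corrections.empty:
        est = est.merge(corrections, on=_DROPLET, how="left")
        inspection_days = (ordered.groupby(_DROPLET)["days_since_setup"]
                           .agg(lambda d: frozenset(d)))
        has_corr = est["corrected_upper_bound_days"].notna()
        for rec in est[has_corr].itertuples():
            key = (rec.plate_id, rec.well, rec.subwell)
            if rec.corrected_upper_bound_days not in inspection_days.get(key, frozenset()):
                raise ValueError(
                    f"correction for {key} references day "
                    f"{rec.corrected_upper_bound_days}, not an inspection of that droplet")
        est.loc[has_corr, "upper_bound_days"] = est.loc[
            has_corr, "corrected_upper_bound_days"]
        est = est.drop(columns=["corrected_upper_bound_days"])

    # lower bound: latest recorded inspection strictly before the upper bound
    merged = ordered.merge(est[[*_DROPLET, "upper_bound_days"]], on=_DROPLET)
    earlier = merged[merged["days_since_setup"] < merged["upper_bound_days"]]
    lowers = (earlier.groupby(_DROPLET)["days_since_setup"].max()
              .rename("lower_bound_days").reset_index())
    est = est.merge(lowers, on=_DROPLET, how="left")
    est["lower_bound_days"] = est["lower_bound_days"].fillna(0.0)
    est["is_late"] = est["upper_bound_days"] > thresholds.late_threshold_days
    return est[cols].reset_index(drop=True)


@dataclass(frozen=True)
class LateFraction:
    """Late-appearance summary; ``fraction`` is None for empty input."""

    n_total: int
    n_late: int
    fraction: float | None


def late_fraction(estimates: pd.DataFrame, threshold_days: float | None = None,
                  basis: str = "bound",
                  thresholds: Thresholds = DEFAULT_THRESHOLDS) -> LateFraction:
    """Fraction of crystals first observed after the late threshold.

    ``basis='bound'`` uses the (possibly curated) upper bound,
    ``basis='annotation'`` the raw first-annotation day; the two are kept
    separate because curation can move appearances earlier.
    """
    if basis not in ("bound", "annotation"):
        raise ValueError("basis must be 'bound' or 'annotation'")
    t = thresholds.late_threshold_days if threshold_days is None else threshold_days
    if estimates.empty:
        return LateFraction(0, 0, None)
    col = "upper_bound_days" if basis == "bound" else "annotation_day"
    n_late = int((estimates[col] > t).sum())
    return LateFraction(len(estimates), n_late, n_late / len(estimates))


def cumulative_appearance(estimates: pd.DataFrame,
                          basis: str = "bound") -> pd.DataFrame:
    """Cumulative appearance curve over the latest-estimate days.

    A non-decreasing step function whose steps sit on actual inspection
    days; the final step reaches 1.  Returns columns ``day``, ``n``,
    ``cumulative_count`` and ``cumulative_proportion``.
    """
    if basis not in ("bound", "annotation"):
        raise ValueError("basis must be 'bound' or 'annotation'")
    cols = ["day", "n", "cumulative_count", "cumulative_proportion"]
    if estimates.empty:
        return pd.DataFrame(columns=cols)
    col = "upper_bound_days" if basis == "bound" else "annotation_day"
    counts = estimates[col].value_counts().sort_index()
    out = pd.DataFrame({"day": counts.index.astype(float), "n": counts.values})
    out["cumulative_count"] = out["n"].cumsum()
    out["cumulative_proportion"] = out["cumulative_count"] / len(estimates)
    return out[cols]
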
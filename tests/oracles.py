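"""Independent brute-force oracles for the analysis operations.

Everything here works on plain tuples and dictionaries with explicit
loops, deliberately sharing no code path with the package, so agreement
with the pipeline is a meaningful check rather than a tautology.
"""

from itertools import product

SUBWELLS = ("A", "B", "C")
SCHEDULE = (1, 2, 4, 7, 14, 28, 56)


# ---------------------------------------------------------------------------
# raw-score reduction
# ---------------------------------------------------------------------------

def last_score_per_droplet(records):
    """records: iterable of (plate, well, subwell, day, score) tuples.
    Returns {(plate, well, subwell): score} using the latest day (later
    list position wins ties)."""
    best = {}
    for plate, well, sw, day, score in records:
        key = (plate, well, sw)
        if key not in best or day >= best[key][0]:
            best[key] = (day, score)
    return {key: score for key, (day, score) in best.items()}


def hit_droplets(records, hit_min=3):
    return {key for key, score in last_score_per_droplet(records).items()
            if score >= hit_min}


# ---------------------------------------------------------------------------
# subwell combination frequencies
# ---------------------------------------------------------------------------

def combination_name(subset):
    joined = "&".join(sw for sw in SUBWELLS if sw in subset)
    return joined if len(subset) == 3 else f"{joined} only"


def subwell_frequency_table(records, hit_min=3, max_stratum=10):
    """{stratum_label: ({combination: proportion}, n_plates, n_wells)}."""
    hits = hit_droplets(records, hit_min)
    wells_by_plate = {}
    for plate, well, sw in hits:
        wells_by_plate.setdefault(plate, {}).setdefault(well, set()).add(sw)
    table = {}
    for plate, wells in wells_by_plate.items():
        n = len(wells)
        stratum = str(n) if n <= max_stratum else f">{max_stratum}"
        combos, n_plates, n_wells = table.setdefault(stratum, ({}, set(), 0))
        for well, subset in wells.items():
            name = combination_name(subset)
            combos[name] = combos.get(name, 0) + 1
        n_plates.add(plate)
        table[stratum] = (combos, n_plates, n_wells + n)
    return {
        stratum: ({name: count / n_wells for name, count in combos.items()},
                  len(n_plates), n_wells)
        for stratum, (combos, n_plates, n_wells) in table.items()}


# ---------------------------------------------------------------------------
# strategy evaluations over explicit droplet subsets
# ---------------------------------------------------------------------------

def screens_vs_drops_counts(groups, hits):
    """groups: list of {screen: plate}; hits: set of (plate, well, subwell).
    Subwell B is the 1:1 drop.  Returns (n_strategy1, {screen: n_strategy2},
    n_missed)."""
    n_s1, n_missed = 0, 0
    n_s2 = {s: 0 for s in groups[0]} if groups else {}
    for group in groups:
        s1 = any((plate, well, "B") in hits
                 for plate in group.values() for well in range(1, 97))
        any_hit = False
        for screen, plate in group.items():
            found = any((plate, well, sw) in hits
                        for well in range(1, 97) for sw in SUBWELLS)
            n_s2[screen] = n_s2.get(screen, 0) + found
            any_hit = any_hit or found
        n_s1 += s1
        n_missed += not any_hit
    return n_s1, n_s2, n_missed


def ratio_success_counts(groups, hits):
    """Per-ratio single-drop/multi-screen successes; subwells A/B/C carry
    ratios 2:1/1:1/1:2."""
    counts = {"2:1": 0, "1:1": 0, "1:2": 0}
    for group in groups:
        for sw, ratio in zip(SUBWELLS, ("2:1", "1:1", "1:2")):
            counts[ratio] += any((plate, well, sw) in hits
                                 for plate in group.values()
                                 for well in range(1, 97))
    return counts


def temps_vs_drops_counts(pairs, hits):
    """pairs: list of (plate_277, plate_293).  Returns per-temperature
    {two_drop, one_drop, missed, full} counts by enumerating all six
    droplets."""
    out = {277: dict(two_drop=0, one_drop=0, missed=0, full=0),
           293: dict(two_drop=0, one_drop=0, missed=0, full=0)}
    for p277, p293 in pairs:
        plate_at = {277: p277, 293: p293}
        full = any((plate, well, sw) in hits
                   for plate in (p277, p293)
                   for well, sw in product(range(1, 97), SUBWELLS))
        if not full:
            continue
        one_drop = any((plate_at[t], well, "B") in hits
                       for t in (277, 293) for well in range(1, 97))
        for t in (277, 293):
            two_drop = any((plate_at[t], well, sw) in hits
                           for well, sw in product(range(1, 97), ("A", "C")))
            out[t]["full"] += 1
            out[t]["two_drop"] += two_drop
            out[t]["one_drop"] += one_drop
            out[t]["missed"] += not (two_drop or one_drop)
    return out


# ---------------------------------------------------------------------------
# appearance curve
# ---------------------------------------------------------------------------

def cumulative_curve(upper_days):
    """[(day, cumulative_proportion)] by direct counting."""
    days = sorted(set(upper_days))
    n = len(upper_days)
    return [(day, sum(1 for d in upper_days if d <= day) / n) for day in days]


# ---------------------------------------------------------------------------
# random small-instance generators
# ---------------------------------------------------------------------------

def records_to_frame(records):
    """Convert raw (plate, well, subwell, day, score) tuples into the
    package's scores-table schema (test plumbing, not oracle logic)."""
    import pandas as pd

    base = pd.Timestamp("2012-01-01 09:00:00")
    return pd.DataFrame({
        "plate_id": [r[0] for r in records],
        "well": [r[1] for r in records],
        "subwell": [r[2] for r in records],
        "inspected_at": [base + pd.Timedelta(days=float(r[3])) for r in records],
        "days_since_setup": [float(r[3]) for r in records],
        "image_score": [r[4] for r in records],
    })


def random_score_records(rng, n_plates=3, max_wells=8):
    """Random sparse score histories over a few plates and wells."""
    records = []
    for p in range(n_plates):
        plate = f"X{p}"
        wells = rng.choice(96, size=rng.integers(1, max_wells + 1),
                           replace=False) + 1
        for well in wells:
            for sw in SUBWELLS:
                if rng.random() < 0.5:
                    continue
                days = sorted(rng.choice(SCHEDULE,
                                         size=rng.integers(1, 4),
                                         replace=False).tolist())
                for day in days:
                    records.append((plate, int(well), sw, day,
                                    int(rng.integers(0, 11))))
    return records
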
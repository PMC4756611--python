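"""Domain model for sitting-drop crystallization screening campaigns.

A campaign is recorded in three flat CSV tables:

* ``plates.csv``   -- one row per 96-well sitting-drop plate: screen identity,
  incubation temperature, protein sample/batch, concentration, setup date,
  co-crystallization compounds and the subwell drop layout.
* ``scores.csv``   -- time-stamped droplet image scores on a 0-10 scale, one
  row per annotated inspection of one subwell.
* ``crystals.csv`` -- harvested crystals with a Crystal Quality Score and
  optional deposition / resolution metadata.

Score semantics follow the screening facility's conventions: an Image Score
of 3 or higher marks crystallinity worth pursuing (a *hit*), a Crystal
Quality Score of 1 or higher marks confirmed protein diffraction, and when a
droplet was annotated at several inspections the *last* recorded score is
taken as conclusive.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SUBWELLS",
    "TEMPERATURES_K",
    "FOUR_MAIN_SCREENS",
    "Thresholds",
    "DEFAULT_THRESHOLDS",
    "MixingRatio",
    "DEFAULT_DROP_LAYOUT",
    "PlateExperiment",
    "SubwellScore",
    "CrystalRecord",
    "parse_well",
    "well_name",
    "is_hit",
    "is_diffracting",
    "final_score",
    "final_scores",
    "hit_droplets",
    "droplet_image_count",
    "read_plates",
    "write_plates",
    "read_scores",
    "write_scores",
    "read_crystals",
    "write_crystals",
    "validate_campaign",
]

SUBWELLS = ("A", "B", "C")
TEMPERATURES_K = (277, 293)
#: The four sparse-matrix screens that dominated the facility's throughput.
FOUR_MAIN_SCREENS = ("JCSG", "LFS", "HCS", "HIN")

_ROWS = "ABCDEFGH"

PLATE_COLUMNS = [
    "plate_id", "target_id", "sample_id", "fresh_or_frozen", "screen",
    "temperature_k", "setup_date", "protein_conc_mg_ml", "compounds",
    "drop_volume_nl", "layout",
]
SCORE_COLUMNS = [
    "plate_id", "well", "subwell", "inspected_at", "days_since_setup",
    "image_score",
]
CRYSTAL_COLUMNS = [
    "plate_id", "well", "subwell", "quality_score", "provenance",
    "deposition_id", "resolution_angstrom", "source_screen",
]


# ---------------------------------------------------------------------------
# thresholds and score semantics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Thresholds:
    """Cut-offs and schedule constants used throughout the analyses.

    hit_min_score
        Minimum Image Score (0-10 scale) for a droplet to count as a hit.
    diffraction_min_quality
        Minimum Crystal Quality Score for confirmed diffraction.
    rare_max_wells
        A plate with at most this many crystallizing conditions is a *rare*
        ("difficult") crystallizer; more makes it promiscuous ("easy").
    late_threshold_days
        Crystals first observed after this many days are late-appearing.
    incubation_days
        Standard scheduled-imaging residence time of a plate.
    inspection_schedule_days
        Nominal automated imaging days, counted from setup.
    """

    hit_min_score: int = 3
    diffraction_min_quality: int = 1
    rare_max_wells: int = 5
    late_threshold_days: float = 30.0
    incubation_days: int = 60
    inspection_schedule_days: tuple[int, ...] = (1, 2, 4, 7, 14, 28, 56)

    def __post_init__(self) -> None:
        for name in ("hit_min_score", "diffraction_min_quality",
                     "rare_max_wells", "late_threshold_days",
                     "incubation_days"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        sched = self.inspection_schedule_days
        if len(sched) == 0 or any(b <= a for a, b in zip(sched, sched[1:])):
            raise ValueError("inspection schedule must be strictly increasing")


DEFAULT_THRESHOLDS = Thresholds()


def validate_image_score(value: int) -> int:
    """Check an Image Score lies on the 0-10 scale (0 collapses all
    non-crystalline classes: clear drops, precipitate, droplet errors)."""
    v = int(value)
    if not 0 <= v <= 10:
        raise ValueError(f"image score {value} outside 0-10")
    return v


def is_hit(score: int, thresholds: Thresholds = DEFAULT_THRESHOLDS) -> bool:
    """True when an Image Score marks crystallinity (microcrystals or better)."""
    return validate_image_score(score) >= thresholds.hit_min_score


def is_diffracting(record, thresholds: Thresholds = DEFAULT_THRESHOLDS) -> bool:
    """True when a crystal produced protein diffraction.

    Accepts a :class:`CrystalRecord` or a bare quality score.
    """
    quality = record.quality_score if isinstance(record, CrystalRecord) else int(record)
    if quality < 0:
        raise ValueError("quality score must be >= 0")
    return quality >= thresholds.diffraction_min_quality


# ---------------------------------------------------------------------------
# well addressing
# ---------------------------------------------------------------------------

def parse_well(well) -> int:
    """Canonicalize a well address to 1-96 (row-major, 1-based, A1=1, H12=96).

    Accepts integers, numeric strings, or alphanumeric addresses "A1".."H12".
    """
    if isinstance(well, str):
        w = well.strip().upper()
        if len(w) >= 2 and w[0] in _ROWS and w[1:].isdigit():
            col = int(w[1:])
            if not 1 <= col <= 12:
                raise ValueError(f"well column {col} outside 1-12 in {well!r}")
            return _ROWS.index(w[0]) * 12 + col
        if w.lstrip("-").isdigit():
            well = int(w)
        else:
            raise ValueError(f"unrecognized well address {well!r}")
    w = int(well)
    if not 1 <= w <= 96:
        raise ValueError(f"well {w} outside 1-96")
    return w


def well_name(well: int) -> str:
    """Alphanumeric name of a canonical well index (1 -> "A1", 96 -> "H12")."""
    w = parse_well(well)
    return f"{_ROWS[(w - 1) // 12]}{(w - 1) % 12 + 1}"


# ---------------------------------------------------------------------------
# domain records
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class MixingRatio:
    """Volumetric protein:precipitant mixing ratio of one droplet.

    Crystallization drops have both parts >= 1; a zero protein part is
    accepted only for degenerate book-keeping (a drop of pure precipitant),
    and a zero precipitant part is rejected by the equilibration operations
    because such a drop has no vapour-diffusion driver.
    """

    protein_parts: int
    precipitant_parts: int

    def __post_init__(self) -> None:
        if self.protein_parts < 0 or self.precipitant_parts < 0:
            raise ValueError("mixing-ratio parts must be non-negative")
        if self.protein_parts + self.precipitant_parts < 1:
            raise ValueError("mixing ratio must have at least one part")

    @classmethod
    def parse(cls, text: str) -> "MixingRatio":
        try:
            p, q = text.strip().split(":")
            return cls(int(p), int(q))
        except (ValueError, AttributeError) as exc:
            raise ValueError(f"unrecognized mixing ratio {text!r}") from exc

    @property
    def total_parts(self) -> int:
        return self.protein_parts + self.precipitant_parts

    @property
    def protein_fraction(self) -> float:
        return self.protein_parts / self.total_parts

    def __str__(self) -> str:
        return f"{self.protein_parts}:{self.precipitant_parts}"


#: Standard three-droplet layout: subwell A at 2:1, B at 1:1, C at 1:2.
DEFAULT_DROP_LAYOUT: Mapping[str, MixingRatio] = {
    "A": MixingRatio(2, 1),
    "B": MixingRatio(1, 1),
    "C": MixingRatio(1, 2),
}


@dataclass(frozen=True)
class PlateExperiment:
    """Metadata of one 96-well sitting-drop plate."""

    plate_id: str
    target_id: str
    sample_id: str
    fresh_or_frozen: str
    screen: str
    temperature_k: int
    setup_date: dt.date
    protein_conc_mg_ml: float
    compounds: frozenset = frozenset()
    drop_layout: Mapping[str, MixingRatio] = field(
        default_factory=lambda: dict(DEFAULT_DROP_LAYOUT))
    drop_volume_nl: float = 150.0

    def __post_init__(self) -> None:
        if self.fresh_or_frozen not in ("fresh", "frozen"):
            raise ValueError(
                f"fresh_or_frozen must be 'fresh' or 'frozen', got {self.fresh_or_frozen!r}")
        if self.temperature_k not in TEMPERATURES_K:
            raise ValueError(f"unknown temperature {self.temperature_k}")
        if self.protein_conc_mg_ml <= 0:
            raise ValueError("protein concentration must be positive")
        if self.drop_volume_nl <= 0:
            raise ValueError("drop volume must be positive")
        bad = set(self.drop_layout) - set(SUBWELLS)
        if bad:
            raise ValueError(f"drop layout has unknown subwells {sorted(bad)}")


@dataclass(frozen=True)
class SubwellScore:
    """One time-stamped image score for one subwell of one well."""

    plate_id: str
    well: int
    subwell: str
    inspected_at: dt.datetime
    days_since_setup: float
    score: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "well", parse_well(self.well))
        if self.subwell not in SUBWELLS:
            raise ValueError(f"subwell must be one of {SUBWELLS}, got {self.subwell!r}")
        if self.days_since_setup < 0:
            raise ValueError("days_since_setup must be non-negative")
        object.__setattr__(self, "score", validate_image_score(self.score))


@dataclass(frozen=True)
class CrystalRecord:
    """A tested crystal: where it grew and how well it diffracted."""

    plate_id: str
    well: int
    subwell: str
    quality_score: int
    provenance: str = "direct"
    deposition_id: str | None = None
    resolution_angstrom: float | None = None
    source_screen: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "well", parse_well(self.well))
        if self.subwell not in SUBWELLS:
            raise ValueError(f"subwell must be one of {SUBWELLS}, got {self.subwell!r}")
        if self.quality_score < 0:
            raise ValueError("quality score must be >= 0")
        if self.provenance not in ("direct", "optimized"):
            raise ValueError(f"provenance must be 'direct' or 'optimized', got {self.provenance!r}")
        if self.resolution_angstrom is not None and not self.resolution_angstrom > 0:
            raise ValueError("resolution must be positive")


# ---------------------------------------------------------------------------
# score reduction
# ---------------------------------------------------------------------------

def final_score(history: Sequence) -> int:
    """Conclusive score of one droplet: the last recorded one wins.

    ``history`` is a sequence of :class:`SubwellScore` records (or bare
    ``(inspected_at, score)`` pairs) for a single (plate, well, subwell).
    Ties on the timestamp are broken by the later position in the sequence,
    mirroring last-recorded semantics.
    """
    items = list(history)
    if not items:
        raise ValueError("empty score history")

    def _key(pair):
        index, item = pair
        when = item.inspected_at if isinstance(item, SubwellScore) else item[0]
        return (when, index)

    _, last = max(enumerate(items), key=_key)
    score = last.score if isinstance(last, SubwellScore) else last[1]
    return validate_image_score(score)


def final_scores(scores: pd.DataFrame) -> pd.DataFrame:
    """Vectorized last-score-wins reduction over a scores table.

    Returns one row per annotated droplet with its conclusive ``image_score``
    and the inspection day that produced it.  Rows sharing a timestamp keep
    input order, so the later row wins, as in :func:`final_score`.
    """
    cols = ["plate_id", "well", "subwell", "image_score", "days_since_setup"]
    if scores.empty:
        return pd.DataFrame(columns=cols)
    ordered = scores.sort_values(
        ["plate_id", "well", "subwell", "inspected_at"], kind="stable")
    last = ordered.groupby(["plate_id", "well", "subwell"], sort=True).tail(1)
    return last[cols].reset_index(drop=True)


def hit_droplets(scores: pd.DataFrame,
                 thresholds: Thresholds = DEFAULT_THRESHOLDS) -> pd.DataFrame:
    """Droplets whose conclusive score marks a hit (Image Score >= 3)."""
    finals = final_scores(scores)
    return finals[finals["image_score"] >= thresholds.hit_min_score].reset_index(drop=True)


def droplet_image_count(n_inspections: int = 8, n_wells: int = 96,
                        drops_per_well: int = 3) -> int:
    """Total droplet images of one fully used plate over a full schedule.

    The default full schedule has eight inspections (a day-0 reference image
    plus the seven scheduled days), so a three-subwell 96-well plate yields
    8 x 288 = 2304 images.
    """
    if min(n_inspections, n_wells, drops_per_well) < 1:
        raise ValueError("image-count factors must be positive")
    return n_inspections * n_wells * drops_per_well


# ---------------------------------------------------------------------------
# CSV readers / writers
# ---------------------------------------------------------------------------

def _require_columns(df: pd.DataFrame, required: Iterable[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{what}: missing columns {missing}")


def _format_float(x: float) -> str:
    return repr(float(x))


def _layout_to_str(layout: Mapping[str, MixingRatio]) -> str:
    return ";".join(f"{sw}={layout[sw]}" for sw in SUBWELLS if sw in layout)


def _layout_from_str(text: str) -> dict[str, MixingRatio]:
    layout: dict[str, MixingRatio] = {}
    if not text.strip():
        return dict(DEFAULT_DROP_LAYOUT)
    for part in text.split(";"):
        sw, _, ratio = part.partition("=")
        sw = sw.strip().upper()
        if sw not in SUBWELLS:
            raise ValueError(f"layout subwell {sw!r} not in {SUBWELLS}")
        layout[sw] = MixingRatio.parse(ratio)
    return layout


def read_plates(path) -> pd.DataFrame:
    """Read and canonicalize ``plates.csv``.

    Returns a frame with parsed dates, integer temperatures, frozenset
    compounds and a ``drop_layout`` column of subwell -> MixingRatio maps.
    Duplicate plate ids and unknown temperatures are rejected with an error
    naming the offending row.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(raw, PLATE_COLUMNS, "plates.csv")
    rows = []
    seen: set[str] = set()
    for i, rec in enumerate(raw.to_dict("records")):
        where = f"plates.csv row {i + 2}"  # 1-based + header
        plate_id = rec["plate_id"].strip()
        if not plate_id:
            raise ValueError(f"{where}: empty plate_id")
        if plate_id in seen:
            raise ValueError(f"{where}: duplicate plate_id {plate_id!r}")
        seen.add(plate_id)
        try:
            temperature = int(rec["temperature_k"])
        except ValueError as exc:
            raise ValueError(f"{where}: field temperature_k: {rec['temperature_k']!r}") from exc
        if temperature not in TEMPERATURES_K:
            raise ValueError(f"{where}: unknown temperature {temperature}")
        try:
            plate = PlateExperiment(
                plate_id=plate_id,
                target_id=rec["target_id"].strip(),
                sample_id=rec["sample_id"].strip(),
                fresh_or_frozen=rec["fresh_or_frozen"].strip(),
                screen=rec["screen"].strip(),
                temperature_k=temperature,
                setup_date=dt.date.fromisoformat(rec["setup_date"].strip()),
                protein_conc_mg_ml=float(rec["protein_conc_mg_ml"]),
                compounds=frozenset(
                    c.strip() for c in rec["compounds"].split(";") if c.strip()),
                drop_layout=_layout_from_str(rec["layout"]),
                drop_volume_nl=float(rec["drop_volume_nl"]),
            )
        except ValueError as exc:
            raise ValueError(f"{where}: {exc}") from exc
        rows.append({
            "plate_id": plate.plate_id,
            "target_id": plate.target_id,
            "sample_id": plate.sample_id,
            "fresh_or_frozen": plate.fresh_or_frozen,
            "screen": plate.screen,
            "temperature_k": plate.temperature_k,
            "setup_date": plate.setup_date,
            "protein_conc_mg_ml": plate.protein_conc_mg_ml,
            "compounds": plate.compounds,
            "drop_layout": dict(plate.drop_layout),
            "drop_volume_nl": plate.drop_volume_nl,
        })
    return pd.DataFrame(rows)


def write_plates(plates: pd.DataFrame, path) -> None:
    """Write a canonical ``plates.csv`` (inverse of :func:`read_plates`)."""
    out = pd.DataFrame({
        "plate_id": plates["plate_id"],
        "target_id": plates["target_id"],
        "sample_id": plates["sample_id"],
        "fresh_or_frozen": plates["fresh_or_frozen"],
        "screen": plates["screen"],
        "temperature_k": plates["temperature_k"].astype(int),
        "setup_date": [d.isoformat() for d in plates["setup_date"]],
        "protein_conc_mg_ml": [_format_float(x) for x in plates["protein_conc_mg_ml"]],
        "compounds": [";".join(sorted(c)) for c in plates["compounds"]],
        "drop_volume_nl": [_format_float(x) for x in plates["drop_volume_nl"]],
        "layout": [_layout_to_str(lay) for lay in plates["drop_layout"]],
    })
    out.to_csv(path, index=False)


def read_scores(path) -> pd.DataFrame:
    """Read and canonicalize ``scores.csv``.

    Wells are canonicalized to 1-96 row-major (both numeric and "A1".."H12"
    addresses accepted), timestamps parsed, and rows stably sorted by
    (plate, well, subwell, time) so that shuffled input yields the same
    canonical table.
    """
    raw = pd.read_csv(path, dtype={"plate_id": str, "subwell": str, "well": str},
                      keep_default_na=False)
    _require_columns(raw, SCORE_COLUMNS, "scores.csv")
    wells = np.empty(len(raw), dtype=int)
    for i, w in enumerate(raw["well"]):
        try:
            wells[i] = parse_well(w)
        except ValueError as exc:
            raise ValueError(f"scores.csv row {i + 2}: field well: {exc}") from exc
    subwell = raw["subwell"].str.strip().str.upper()
    bad = ~subwell.isin(SUBWELLS)
    if bad.any():
        i = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(
            f"scores.csv row {i + 2}: field subwell: {raw['subwell'].iat[i]!r} not in {SUBWELLS}")
    score = pd.to_numeric(raw["image_score"], errors="raise").astype(int)
    out_of_range = (score < 0) | (score > 10)
    if out_of_range.any():
        i = int(np.flatnonzero(out_of_range.to_numpy())[0])
        raise ValueError(
            f"scores.csv row {i + 2}: field image_score: {score.iat[i]} outside 0-10")
    days = pd.to_numeric(raw["days_since_setup"], errors="raise").astype(float)
    if (days < 0).any():
        i = int(np.flatnonzero((days < 0).to_numpy())[0])
        raise ValueError(f"scores.csv row {i + 2}: field days_since_setup: negative")
    df = pd.DataFrame({
        "plate_id": raw["plate_id"].str.strip(),
        "well": wells,
        "subwell": subwell,
        "inspected_at": pd.to_datetime(raw["inspected_at"]),
        "days_since_setup": days,
        "image_score": score,
    })
    return df.sort_values(["plate_id", "well", "subwell", "inspected_at"],
                          kind="stable").reset_index(drop=True)


def write_scores(scores: pd.DataFrame, path) -> None:
    """Write a canonical ``scores.csv`` (numeric wells, ISO timestamps)."""
    out = pd.DataFrame({
        "plate_id": scores["plate_id"],
        "well": scores["well"].astype(int),
        "subwell": scores["subwell"],
        "inspected_at": [pd.Timestamp(t).isoformat() for t in scores["inspected_at"]],
        "days_since_setup": [_format_float(x) for x in scores["days_since_setup"]],
        "image_score": scores["image_score"].astype(int),
    })
    out.to_csv(path, index=False)


def read_crystals(path) -> pd.DataFrame:
    """Read and canonicalize ``crystals.csv``.

    ``deposition_id`` / ``source_screen`` are None when empty;
    ``resolution_angstrom`` is NaN when absent.  The ``source_screen``
    column itself is optional (it matters only for optimized crystals whose
    originating sparse-matrix screen differs from the plate that was
    optimized from).
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(raw, [c for c in CRYSTAL_COLUMNS if c != "source_screen"],
                     "crystals.csv")
    if "source_screen" not in raw.columns:
        raw = raw.assign(source_screen="")
    rows = []
    for i, rec in enumerate(raw.to_dict("records")):
        where = f"crystals.csv row {i + 2}"
        try:
            crystal = CrystalRecord(
                plate_id=rec["plate_id"].strip(),
                well=parse_well(rec["well"]),
                subwell=rec["subwell"].strip().upper(),
                quality_score=int(rec["quality_score"]),
                provenance=rec["provenance"].strip(),
                deposition_id=rec["deposition_id"].strip() or None,
                resolution_angstrom=(float(rec["resolution_angstrom"])
                                     if rec["resolution_angstrom"].strip() else None),
                source_screen=rec["source_screen"].strip() or None,
            )
        except ValueError as exc:
            raise ValueError(f"{where}: {exc}") from exc
        rows.append({
            "plate_id": crystal.plate_id,
            "well": crystal.well,
            "subwell": crystal.subwell,
            "quality_score": crystal.quality_score,
            "provenance": crystal.provenance,
            "deposition_id": crystal.deposition_id,
            "resolution_angstrom": (np.nan if crystal.resolution_angstrom is None
                                    else crystal.resolution_angstrom),
            "source_screen": crystal.source_screen,
        })
    return pd.DataFrame(rows, columns=CRYSTAL_COLUMNS)


def write_crystals(crystals: pd.DataFrame, path) -> None:
    """Write a canonical ``crystals.csv`` (inverse of :func:`read_crystals`)."""
    out = pd.DataFrame({
        "plate_id": crystals["plate_id"],
        "well": crystals["well"].astype(int),
        "subwell": crystals["subwell"],
        "quality_score": crystals["quality_score"].astype(int),
        "provenance": crystals["provenance"],
        "deposition_id": ["" if d is None else d for d in crystals["deposition_id"]],
        "resolution_angstrom": ["" if pd.isna(r) else _format_float(r)
                                for r in crystals["resolution_angstrom"]],
        "source_screen": ["" if s is None else s for s in crystals["source_screen"]],
    })
    out.to_csv(path, index=False)


def validate_campaign(plates: pd.DataFrame, scores: pd.DataFrame,
                      crystals: pd.DataFrame) -> list[str]:
    """Cross-reference the three campaign tables; return a list of problems.

    Checks that every scored or harvested droplet belongs to a known plate
    and to a subwell present in that plate's drop layout.
    """
    problems: list[str] = []
    known = set(plates["plate_id"])
    layouts = dict(zip(plates["plate_id"], plates["drop_layout"]))
    for name, table in (("scores", scores), ("crystals", crystals)):
        missing = sorted(set(table["plate_id"]) - known)
        if missing:
            problems.append(f"{name}.csv references unknown plates: {missing[:5]}"
                            + (" ..." if len(missing) > 5 else ""))
        for plate_id, subwell in zip(table["plate_id"], table["subwell"]):
            layout = layouts.get(plate_id)
            if layout is not None and subwell not in layout:
                problems.append(
                    f"{name}.csv: plate {plate_id} has no subwell {subwell} in its layout")
                break
    return problems
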
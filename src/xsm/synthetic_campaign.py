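"""Synthetic screening-campaign generator with a retained truth record.

The generator emulates the statistical structure of a large sitting-drop
screening database: a mixture of rare (<= 5 crystallizing conditions) and
promiscuous experiments, a mixing-ratio bias favouring the
protein-concentrating 2:1 subwell, temperature-shared and
temperature-exclusive hit sets across 277/293 K plate pairs, the nominal
inspection schedule (days 1, 2, 4, 7, 14, 28, 56), sparse human scoring
with occasional misses and rescinded false positives, protein
concentrations centred near 10 mg/ml, and a small (default 2%) heavy tail
of crystal appearances beyond 30 days.

Every latent quantity (experiment class, temperature category, per-droplet
appearance day) is kept in a :class:`CampaignTruth` record so that each
analysis stage can be tested for parameter recovery without external data.
The latent hit/no-hit state of a droplet is decoupled from its observed
scores: noise perturbs individual inspections (missed annotations,
transient spurious scores later rescinded) while the conclusive
last-recorded score remains faithful to the latent state, reflecting that
final annotations are curated far more carefully than interim ones.  Noise
rates are order-of-magnitude guesses -- the source data quantify no
inter-scorer variability -- and are explicit, documented configuration.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core_model import (DEFAULT_THRESHOLDS, SUBWELLS, MixingRatio,
                         Thresholds, write_crystals, write_plates,
                         write_scores)

_R21, _R11, _R12 = MixingRatio(2, 1), MixingRatio(1, 1), MixingRatio(1, 2)

__all__ = [
    "CampaignConfig",
    "CampaignTruth",
    "CampaignResult",
    "default_config",
    "generate_campaign",
    "write_campaign",
    "load_config",
    "save_config",
]


@dataclass
class CampaignConfig:
    """Generative parameters of a synthetic screening campaign.

    Structure: each target gets ``sessions_per_target`` screening sessions
    (one purification batch each); a session sets up 3 or 4 distinct
    sparse-matrix screens, each at both incubation temperatures, giving the
    matched pairs and groups the strategy analyses need.

    Hit structure: each screen-experiment (one screen of one session) is a
    rare crystallizer with probability ``rare_fraction``; its number of
    crystallizing conditions is Poisson with the class rate, truncated to
    1-5 (rare) or 6-96 (promiscuous).  The experiment draws a temperature
    regime -- exclusive to one temperature with the class's exclusivity
    probability, otherwise shared with each condition crystallizing at both
    temperatures with probability ``temp_shared_prob`` (coverage of both
    temperatures is enforced for shared experiments).  Hit subwells follow
    a logistic model with additive per-subwell log-odds favouring the
    protein-rich 2:1 drop.

    Timing: appearance days are a mixture of an early log-normal (median
    ``appearance_median_days``, truncated to the 28-day inspection) and a
    ``late_mass`` component beyond day 30 (shifted log-normal, truncated to
    the day-56 final inspection so every true hit is observable).

    Diffraction: each experiment yields diffracting crystals with
    probability ``diffraction_prob`` -- a per-sample protein-quality draw,
    independent of the hit pattern so that diffracting-crystal eligibility
    filters do not distort recovered proportions.
    """

    n_targets: int = 150
    sessions_per_target: int = 2
    p_four_screens: float = 0.5
    screens: tuple = ("JCSG", "LFS", "HCS", "HIN")
    # hit structure
    rare_fraction: float = 0.77
    rare_well_rate: float = 2.5
    promiscuous_well_rate: float = 20.0
    base_logodds: float = -1.1
    subwell_logodds: dict = field(
        default_factory=lambda: {"A": 0.4, "B": 0.0, "C": -0.2})
    # temperature structure
    temp_exclusive_prob_rare: float = 0.45
    temp_exclusive_prob_promiscuous: float = 0.05
    temp_shared_prob: float = 0.7
    # appearance timing (days)
    appearance_median_days: float = 4.0
    appearance_sigma: float = 0.9
    late_mass: float = 0.02
    late_median_offset_days: float = 10.0
    late_sigma: float = 0.6
    # scoring noise (order-of-magnitude guesses; see module docstring)
    miss_prob: float = 0.03
    transient_fp_prob: float = 0.0005
    benign_score_prob: float = 0.01
    # protein sample
    conc_median_mg_ml: float = 10.0
    conc_sigma: float = 0.3
    compound_session_prob: float = 0.1
    frozen_prob: float = 0.3
    mass_median_kda: float = 30.0
    mass_sigma: float = 0.5
    # diffraction and depositions
    diffraction_prob: float = 0.45
    quality_zero_prob: float = 0.2
    deposition_prob: float = 0.5
    resolution_median_angstrom: float = 2.2
    resolution_sigma: float = 0.15
    # plate hardware / schedule
    drop_volume_nl: float = 150.0
    include_day0_inspection: bool = False
    start_date: str = "2010-01-04"
    seed: int = 7

    def __post_init__(self) -> None:
        probs = ["p_four_screens", "rare_fraction", "temp_exclusive_prob_rare",
                 "temp_exclusive_prob_promiscuous", "temp_shared_prob",
                 "late_mass", "miss_prob", "transient_fp_prob",
                 "benign_score_prob", "compound_session_prob", "frozen_prob",
                 "diffraction_prob", "quality_zero_prob", "deposition_prob"]
        for name in probs:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability in [0, 1], got {v}")
        if self.n_targets < 1 or self.sessions_per_target < 1:
            raise ValueError("campaign size parameters must be positive")
        if not self.rare_well_rate < self.promiscuous_well_rate:
            raise ValueError("rare_well_rate must be below promiscuous_well_rate")
        if set(self.subwell_logodds) != set(SUBWELLS):
            raise ValueError(f"subwell_logodds must cover {SUBWELLS}")
        if len(self.screens) < 3:
            raise ValueError("need at least three screens for group designs")


def default_config() -> CampaignConfig:
    """The calibrated default campaign.

    In expectation, ~77% of hit-containing plates have at most five
    crystallizing wells, ~45% of rare pairs crystallize at a single
    temperature, and ~2% of diffracting crystals appear after day 30; the
    seed is fixed so default fixtures are reproducible.
    """
    return CampaignConfig()


@dataclass
class CampaignTruth:
    """Latent generative record of a campaign (the recovery-test oracle)."""

    config: CampaignConfig
    experiments: pd.DataFrame   # one row per screen-experiment
    hits: pd.DataFrame          # one row per latent hit droplet
    target_masses: dict

    def to_json(self, path) -> None:
        payload = {
            "config": dataclasses.asdict(self.config),
            "target_masses": self.target_masses,
            "experiments": self.experiments.assign(
                setup_date=[d.isoformat() for d in self.experiments["setup_date"]]
            ).to_dict("records"),
            "hits": self.hits.to_dict("records"),
        }
        payload["config"]["screens"] = list(self.config.screens)
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "CampaignTruth":
        payload = json.loads(Path(path).read_text())
        cfg = payload["config"]
        cfg["screens"] = tuple(cfg["screens"])
        experiments = pd.DataFrame(payload["experiments"])
        experiments["setup_date"] = [dt.date.fromisoformat(d)
                                     for d in experiments["setup_date"]]
        return cls(config=CampaignConfig(**cfg), experiments=experiments,
                   hits=pd.DataFrame(payload["hits"]),
                   target_masses=payload["target_masses"])


@dataclass
class CampaignResult:
    """Generated campaign tables plus the latent truth."""

    plates: pd.DataFrame
    scores: pd.DataFrame
    crystals: pd.DataFrame
    truth: CampaignTruth


def _truncated_poisson(rng: np.random.Generator, rate: float,
                       lo: int, hi: int) -> int:
    for _ in range(10_000):
        k = int(rng.poisson(rate))
        if lo <= k <= hi:
            return k
    raise RuntimeError(f"truncated Poisson({rate}) on [{lo}, {hi}] failed")


def _draw_appearance(rng: np.random.Generator, cfg: CampaignConfig,
                     last_early_day: float, last_day: float) -> float:
    """Appearance day: early log-normal (<= last early inspection) with
    probability 1 - late_mass, else a shifted log-normal beyond day 30
    truncated to the final inspection so the hit is observable."""
    if rng.random() < cfg.late_mass:
        for _ in range(10_000):
            day = 30.0 + float(rng.lognormal(
                math.log(cfg.late_median_offset_days), cfg.late_sigma))
            if day <= last_day:
                return day
        raise RuntimeError("late appearance draw failed")
    for _ in range(10_000):
        day = float(rng.lognormal(math.log(cfg.appearance_median_days),
                                  cfg.appearance_sigma))
        if day <= last_early_day:
            return day
    raise RuntimeError("early appearance draw failed")


def _draw_subwells(rng: np.random.Generator, probs: dict) -> tuple:
    """Non-empty subwell hit set under independent per-subwell Bernoullis;
    after a few empty draws, fall back to a single subwell picked with
    probability proportional to the per-subwell rates."""
    for _ in range(8):
        chosen = tuple(sw for sw in SUBWELLS if rng.random() < probs[sw])
        if chosen:
            return chosen
    weights = np.array([probs[sw] for sw in SUBWELLS])
    return (SUBWELLS[int(rng.choice(len(SUBWELLS), p=weights / weights.sum()))],)


def generate_campaign(config: CampaignConfig | None = None,
                      thresholds: Thresholds = DEFAULT_THRESHOLDS
                      ) -> CampaignResult:
    """Generate a campaign (plates, scores, crystals) plus its truth record.

    Identical config and seed give identical output.  Score histories
    follow the inspection schedule: a latent hit is first scored at the
    first scheduled inspection at or after its true appearance day (each
    annotation independently missed with ``miss_prob``), with a zero score
    recorded at the preceding inspection when one exists, emulating the
    pre-appearance image a curator would verify.
    """
    cfg = config or default_config()
    rng = np.random.default_rng(cfg.seed)
    schedule = list(thresholds.inspection_schedule_days)
    if cfg.include_day0_inspection:
        schedule = [0, *schedule]
    last_day = float(schedule[-1])
    early_days = [d for d in schedule if d <= thresholds.late_threshold_days]
    last_early_day = float(early_days[-1]) if early_days else last_day
    probs = {sw: 1.0 / (1.0 + math.exp(-(cfg.base_logodds + cfg.subwell_logodds[sw])))
             for sw in SUBWELLS}
    start = dt.date.fromisoformat(cfg.start_date)

    plate_rows, score_rows, crystal_rows = [], [], []
    exp_rows, hit_rows = [], []
    target_masses: dict[str, float] = {}
    plate_n = exp_n = dep_n = 0

    for t in range(cfg.n_targets):
        target_id = f"T{t:04d}"
        target_masses[target_id] = round(float(
            rng.lognormal(math.log(cfg.mass_median_kda), cfg.mass_sigma)), 1)
        for s in range(cfg.sessions_per_target):
            sample_id = f"{target_id}-B{s + 1}"
            setup_date = start + dt.timedelta(days=int(rng.integers(0, 3000)))
            fresh = "frozen" if rng.random() < cfg.frozen_prob else "fresh"
            conc = round(float(rng.lognormal(
                math.log(cfg.conc_median_mg_ml), cfg.conc_sigma)), 2)
            compounds = (frozenset({f"CPD{int(rng.integers(0, 500)):03d}"})
                         if rng.random() < cfg.compound_session_prob
                         else frozenset())
            n_screens = 4 if rng.random() < cfg.p_four_screens else 3
            chosen = [cfg.screens[i]
                      for i in sorted(rng.permutation(len(cfg.screens))[:n_screens])]
            for screen in chosen:
                exp_id = f"E{exp_n:05d}"
                exp_n += 1
                plate_at: dict[int, str] = {}
                for temp in (277, 293):
                    plate_id = f"P{plate_n:05d}"
                    plate_n += 1
                    plate_at[temp] = plate_id
                    plate_rows.append({
                        "plate_id": plate_id, "target_id": target_id,
                        "sample_id": sample_id, "fresh_or_frozen": fresh,
                        "screen": screen, "temperature_k": temp,
                        "setup_date": setup_date,
                        "protein_conc_mg_ml": conc, "compounds": compounds,
                        "drop_layout": {"A": _R21, "B": _R11, "C": _R12},
                        "drop_volume_nl": cfg.drop_volume_nl,
                    })

                is_rare = rng.random() < cfg.rare_fraction
                if is_rare:
                    n_wells = _truncated_poisson(rng, cfg.rare_well_rate, 1,
                                                 thresholds.rare_max_wells)
                else:
                    n_wells = _truncated_poisson(
                        rng, cfg.promiscuous_well_rate,
                        thresholds.rare_max_wells + 1, 96)
                wells = sorted(int(w) + 1 for w in
                               rng.choice(96, size=n_wells, replace=False))

                p_excl = (cfg.temp_exclusive_prob_rare if is_rare
                          else cfg.temp_exclusive_prob_promiscuous)
                if rng.random() < p_excl:
                    side = 277 if rng.random() < 0.5 else 293
                    category = str(side)
                    temps_by_well = {w: (side,) for w in wells}
                else:
                    category = "both"
                    temps_by_well = {}
                    for w in wells:
                        if rng.random() < cfg.temp_shared_prob:
                            temps_by_well[w] = (277, 293)
                        else:
                            temps_by_well[w] = (
                                (277,) if rng.random() < 0.5 else (293,))
                    for temp in (277, 293):  # enforce coverage of both temps
                        if not any(temp in ts for ts in temps_by_well.values()):
                            w = wells[int(rng.integers(len(wells)))]
                            temps_by_well[w] = (277, 293)

                observed_hits: list[tuple] = []  # (plate_id, well, subwell, day)
                hit_droplets_by_plate: dict[str, set] = {
                    p: set() for p in plate_at.values()}
                for w in wells:
                    for temp in temps_by_well[w]:
                        plate_id = plate_at[temp]
                        for sw in _draw_subwells(rng, probs):
                            appearance = _draw_appearance(
                                rng, cfg, last_early_day, last_day)
                            hit_droplets_by_plate[plate_id].add((w, sw))
                            first_i = next(i for i, d in enumerate(schedule)
                                           if d >= appearance)
                            quality_score = int(rng.integers(3, 10))
                            if first_i > 0:
                                score_rows.append(_score_row(
                                    plate_id, w, sw, setup_date,
                                    schedule[first_i - 1], 0))
                            recorded = False
                            for i in range(first_i, len(schedule)):
                                if rng.random() < cfg.miss_prob:
                                    continue
                                score_rows.append(_score_row(
                                    plate_id, w, sw, setup_date,
                                    schedule[i], quality_score))
                                recorded = True
                            hit_rows.append({
                                "exp_id": exp_id, "plate_id": plate_id,
                                "temperature_k": temp, "well": w,
                                "subwell": sw,
                                "appearance_day": round(appearance, 3),
                                "observed": recorded,
                            })
                            if recorded:
                                observed_hits.append(
                                    (plate_id, w, sw, appearance))

                _emit_noise(rng, cfg, schedule, setup_date, plate_at,
                            hit_droplets_by_plate, score_rows)

                diffracting = rng.random() < cfg.diffraction_prob
                if diffracting and observed_hits:
                    k = min(1 + int(rng.random() < 0.5), len(observed_hits))
                    picks = sorted(rng.choice(len(observed_hits), size=k,
                                              replace=False))
                    for pick in picks:
                        plate_id, w, sw, _day = observed_hits[int(pick)]
                        deposited = rng.random() < cfg.deposition_prob
                        if deposited:
                            dep_id = f"D{dep_n:05d}"
                            dep_n += 1
                        else:
                            dep_id = None
                        optimized = rng.random() < 0.1
                        crystal_rows.append({
                            "plate_id": plate_id, "well": w, "subwell": sw,
                            "quality_score": int(rng.integers(1, 4)),
                            "provenance": "optimized" if optimized else "direct",
                            "deposition_id": dep_id,
                            "resolution_angstrom": round(float(rng.lognormal(
                                math.log(cfg.resolution_median_angstrom),
                                cfg.resolution_sigma)), 2),
                            "source_screen": screen if optimized else None,
                        })
                elif observed_hits and rng.random() < cfg.quality_zero_prob:
                    plate_id, w, sw, _day = observed_hits[
                        int(rng.integers(len(observed_hits)))]
                    crystal_rows.append({
                        "plate_id": plate_id, "well": w, "subwell": sw,
                        "quality_score": 0, "provenance": "direct",
                        "deposition_id": None, "resolution_angstrom": np.nan,
                        "source_screen": None,
                    })

                exp_rows.append({
                    "exp_id": exp_id, "target_id": target_id,
                    "sample_id": sample_id, "screen": screen,
                    "setup_date": setup_date, "is_rare": is_rare,
                    "temp_category": category, "n_union_wells": n_wells,
                    "diffracting": bool(diffracting and observed_hits),
                })

    plates = pd.DataFrame(plate_rows)
    scores = (pd.DataFrame(
        score_rows, columns=["plate_id", "well", "subwell", "inspected_at",
                             "days_since_setup", "image_score"])
        .sort_values(["plate_id", "well", "subwell", "inspected_at"],
                     kind="stable").reset_index(drop=True))
    crystals = pd.DataFrame(
        crystal_rows, columns=["plate_id", "well", "subwell", "quality_score",
                               "provenance", "deposition_id",
                               "resolution_angstrom", "source_screen"])
    truth = CampaignTruth(
        config=cfg,
        experiments=pd.DataFrame(exp_rows),
        hits=pd.DataFrame(
            hit_rows, columns=["exp_id", "plate_id", "temperature_k", "well",
                               "subwell", "appearance_day", "observed"]),
        target_masses=target_masses,
    )
    return CampaignResult(plates=plates, scores=scores, crystals=crystals,
                          truth=truth)


def _score_row(plate_id: str, well: int, subwell: str, setup_date: dt.date,
               day: float, score: int) -> dict:
    when = (pd.Timestamp(setup_date) + pd.Timedelta(days=float(day))
            + pd.Timedelta(hours=9))
    return {"plate_id": plate_id, "well": well, "subwell": subwell,
            "inspected_at": when, "days_since_setup": float(day),
            "image_score": score}


def _emit_noise(rng: np.random.Generator, cfg: CampaignConfig, schedule: list,
                setup_date: dt.date, plate_at: dict,
                hit_droplets_by_plate: dict, score_rows: list) -> None:
    """Inspection-level scoring noise on non-hit droplets.

    Transient false positives get a crystalline score at one inspection and
    are rescinded by a zero at a later one (the conclusive last score stays
    truthful); benign low scores (0-2) emulate routine clear/precipitate
    annotations.
    """
    n_droplets = 96 * len(SUBWELLS)
    for temp in (277, 293):
        plate_id = plate_at[temp]
        taken = hit_droplets_by_plate[plate_id]
        n_fp = rng.binomial(n_droplets - len(taken), cfg.transient_fp_prob)
        n_benign = rng.binomial(n_droplets, cfg.benign_score_prob)
        for kind, count in (("fp", n_fp), ("benign", n_benign)):
            for _ in range(count):
                for _try in range(20):
                    d = int(rng.integers(n_droplets))
                    well, sw = d // 3 + 1, SUBWELLS[d % 3]
                    if (well, sw) not in taken:
                        break
                else:
                    continue
                if kind == "fp":
                    if len(schedule) < 2:
                        continue
                    i = int(rng.integers(0, len(schedule) - 1))
                    j = int(rng.integers(i + 1, len(schedule)))
                    score_rows.append(_score_row(
                        plate_id, well, sw, setup_date, schedule[i],
                        int(rng.integers(3, 6))))
                    score_rows.append(_score_row(
                        plate_id, well, sw, setup_date, schedule[j], 0))
                else:
                    i = int(rng.integers(0, len(schedule)))
                    score_rows.append(_score_row(
                        plate_id, well, sw, setup_date, schedule[i],
                        int(rng.integers(0, 3))))


def write_campaign(result: CampaignResult, outdir) -> None:
    """Write plates.csv, scores.csv, crystals.csv and truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_plates(result.plates, outdir / "plates.csv")
    write_scores(result.scores, outdir / "scores.csv")
    write_crystals(result.crystals, outdir / "crystals.csv")
    result.truth.to_json(outdir / "truth.json")


def load_config(path) -> CampaignConfig:
    """Load a flat YAML config; missing keys fall back to defaults."""
    payload = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in dataclasses.fields(CampaignConfig)}
    unknown = set(payload) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "screens" in payload:
        payload["screens"] = tuple(payload["screens"])
    return CampaignConfig(**payload)


def save_config(config: CampaignConfig, path) -> None:
    payload = dataclasses.asdict(config)
    payload["screens"] = list(config.screens)
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))
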
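import numpy as np
import pandas as pd
import pytest

import oracles
from xsm import appearance_timing as at
from xsm.core_model import SubwellScore

BASE = pd.Timestamp("2012-03-01 09:00:00")
SCHEDULE = (1, 2, 4, 7, 14, 28, 56)


def history(day_scores, plate="P1", well=1, subwell="A"):
    return [SubwellScore(plate_id=plate, well=well, subwell=subwell,
                         inspected_at=BASE + pd.Timedelta(days=day),
                         days_since_setup=float(day), score=score)
            for day, score in day_scores]


class TestAppearanceBounds:
    def test_late_hit_bounded_by_previous_inspection(self):
        h = history([(d, 0) for d in SCHEDULE[:-1]] + [(56, 6)])
        est = at.appearance_bounds(h)
        assert (est.lower_bound_days, est.upper_bound_days) == (28.0, 56.0)
        assert est.is_late

    def test_day_one_hit_bounded_by_setup(self):
        est = at.appearance_bounds(history([(1, 4), (2, 5)]))
        assert (est.lower_bound_days, est.upper_bound_days) == (0.0, 1.0)
        assert not est.is_late

    def test_curation_moves_upper_bound_earlier(self):
        h = history([(d, 0) for d in (1, 2, 4, 7, 14, 28)] + [(56, 6)])
        est = at.appearance_bounds(h, corrected_day=14.0)
        assert est.upper_bound_days == 14.0
        assert est.lower_bound_days == 7.0
        assert not est.is_late
        assert est.annotation_day == 56.0  # raw annotation kept separately

    def test_correction_must_reference_an_inspection(self):
        h = history([(1, 0), (56, 6)])
        with pytest.raises(ValueError, match="not an inspection"):
            at.appearance_bounds(h, corrected_day=14.0)

    def test_history_without_hit_rejected(self):
        with pytest.raises(ValueError, match="no hit"):
            at.appearance_bounds(history([(1, 0), (2, 2)]))

    def test_vectorized_estimates_match_scalar(self, campaign):
        est = at.appearance_estimates(campaign.scores)
        assert not est.empty
        sample = est.sample(25, random_state=1)
        scores = campaign.scores
        for rec in sample.itertuples():
            sub = scores[(scores.plate_id == rec.plate_id)
                         & (scores.well == rec.well)
                         & (scores.subwell == rec.subwell)]
            h = history(list(zip(sub["days_since_setup"], sub["image_score"])),
                        plate=rec.plate_id, well=rec.well, subwell=rec.subwell)
            single = at.appearance_bounds(h)
            assert single.upper_bound_days == rec.upper_bound_days
            assert single.lower_bound_days == rec.lower_bound_days

    def test_no_hit_strictly_before_lower_bound(self, campaign):
        est = at.appearance_estimates(campaign.scores)
        hits = campaign.scores[campaign.scores["image_score"] >= 3]
        first_hit = (hits.sort_values("days_since_setup")
                     .groupby(["plate_id", "well", "subwell"])
                     ["days_since_setup"].min())
        merged = est.merge(first_hit.rename("first_hit").reset_index(),
                           on=["plate_id", "well", "subwell"])
        assert (merged["first_hit"] >= merged["lower_bound_days"]).all()
        assert (est["lower_bound_days"] < est["upper_bound_days"]).all()

    def test_vectorized_corrections_applied(self):
        scores = oracles.records_to_frame(
            [("P1", 1, "A", d, 0) for d in (1, 2, 4, 7, 14, 28)]
            + [("P1", 1, "A", 56, 6)])
        corrections = pd.DataFrame([
            {"plate_id": "P1", "well": 1, "subwell": "A",
             "corrected_upper_bound_days": 14.0}])
        est = at.appearance_estimates(scores, corrections)
        assert est.loc[0, "upper_bound_days"] == 14.0
        assert est.loc[0, "lower_bound_days"] == 7.0
        bad = corrections.assign(corrected_upper_bound_days=3.0)
        with pytest.raises(ValueError, match="not an inspection"):
            at.appearance_estimates(scores, bad)


class TestLateFraction:
    def _estimates(self, uppers):
        return pd.DataFrame({
            "plate_id": "P", "well": 1, "subwell": "A",
            "lower_bound_days": 0.0, "upper_bound_days": uppers,
            "annotation_day": uppers,
            "is_late": [u > 30 for u in uppers]})

    def test_simple_proportion(self):
        lf = at.late_fraction(self._estimates([1.0] * 9 + [56.0]))
        assert lf.fraction == pytest.approx(0.10)
        assert (lf.n_total, lf.n_late) == (10, 1)

    def test_threshold_beyond_final_inspection(self):
        lf = at.late_fraction(self._estimates([1.0, 56.0]), threshold_days=60)
        assert lf.fraction == 0.0

    def test_empty_input_undefined(self):
        lf = at.late_fraction(self._estimates([]))
        assert lf.fraction is None

    def test_monotone_nonincreasing_in_threshold(self):
        est = self._estimates([1.0, 7.0, 14.0, 56.0, 56.0])
        fracs = [at.late_fraction(est, threshold_days=t).fraction
                 for t in (0.5, 7, 14, 30, 60)]
        assert fracs == sorted(fracs, reverse=True)

    def test_recovers_configured_late_mass(self, campaign):
        from scipy.stats import binom

        diffracting = campaign.crystals[campaign.crystals["quality_score"] >= 1]
        est = at.appearance_estimates(campaign.scores, droplets=diffracting)
        lf = at.late_fraction(est)
        p0 = campaign.truth.config.late_mass
        lo, hi = binom.interval(0.95, lf.n_total, p0)
        assert lo <= lf.n_late <= hi


class TestCumulativeAppearance:
    def test_single_day_steps_to_one(self):
        est = pd.DataFrame({"plate_id": "P", "well": 1, "subwell": "A",
                            "lower_bound_days": 0.0,
                            "upper_bound_days": [1.0, 1.0, 1.0],
                            "annotation_day": 1.0, "is_late": False})
        curve = at.cumulative_appearance(est)
        assert curve["day"].tolist() == [1.0]
        assert curve["cumulative_proportion"].tolist() == [1.0]

    def test_uniform_schedule_increments(self):
        uppers = [float(d) for d in SCHEDULE]
        est = pd.DataFrame({"plate_id": "P", "well": 1, "subwell": "A",
                            "lower_bound_days": 0.0,
                            "upper_bound_days": uppers,
                            "annotation_day": uppers, "is_late": False})
        curve = at.cumulative_appearance(est)
        assert curve["day"].tolist() == list(map(float, SCHEDULE))
        assert np.allclose(np.diff(curve["cumulative_proportion"]), 1 / 7)

    def test_matches_brute_force_counting(self):
        rng = np.random.default_rng(55)
        for _ in range(60):
            uppers = [float(rng.choice(SCHEDULE))
                      for _ in range(int(rng.integers(1, 30)))]
            est = pd.DataFrame({"plate_id": "P", "well": 1, "subwell": "A",
                                "lower_bound_days": 0.0,
                                "upper_bound_days": uppers,
                                "annotation_day": uppers, "is_late": False})
            curve = at.cumulative_appearance(est)
            expected = oracles.cumulative_curve(uppers)
            assert curve["day"].tolist() == [d for d, _ in expected]
            assert curve["cumulative_proportion"].tolist() == pytest.approx(
                [p for _, p in expected])

    def test_monotone_and_ends_at_one(self, campaign):
        est = at.appearance_estimates(campaign.scores)
        curve = at.cumulative_appearance(est)
        props = curve["cumulative_proportion"].to_numpy()
        assert (np.diff(props) >= 0).all()
        assert props[-1] == pytest.approx(1.0)
        assert set(curve["day"]) <= {float(d) for d in SCHEDULE}
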
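import datetime as dt

import numpy as np
import pandas as pd
import pytest

import oracles
from xsm import cohort_matching as cmatch
from xsm import strategy_comparison as strat
from xsm.core_model import DEFAULT_DROP_LAYOUT


def plates_frame(plate_ids):
    return pd.DataFrame([
        {"plate_id": p, "target_id": "T", "sample_id": "S",
         "fresh_or_frozen": "fresh", "screen": "JCSG", "temperature_k": 277,
         "setup_date": dt.date(2012, 3, 1), "protein_conc_mg_ml": 10.0,
         "compounds": frozenset(), "drop_layout": dict(DEFAULT_DROP_LAYOUT),
         "drop_volume_nl": 150.0}
        for p in plate_ids])


def pairs_frame(pairs):
    return pd.DataFrame([{"plate_277": a, "plate_293": b} for a, b in pairs])


def groups_frame(groups):
    """groups: list of {screen: plate_id}."""
    return pd.DataFrame([
        {"group_id": f"G{i}", "plate_ids": tuple(g.values()),
         "screens": tuple(g.keys())}
        for i, g in enumerate(groups)])


def scores_from_hits(hits):
    """One conclusive hit score per droplet in ``hits``."""
    return oracles.records_to_frame([(p, w, sw, 7, 5) for (p, w, sw) in hits])


class TestTemperatureExclusivity:
    def test_single_sided_hits_are_exclusive(self):
        pairs = pairs_frame([("A1", "B1")])
        scores = scores_from_hits([("A1", 3, "A")])
        table = strat.temperature_exclusivity(pairs, scores).table
        row = table[(table.stratum == "rare") & (table.category == "277 only")]
        assert row["proportion"].iloc[0] == 1.0

    def test_hits_on_both_plates_are_shared(self):
        pairs = pairs_frame([("A1", "B1")])
        scores = scores_from_hits([("A1", 3, "A"), ("B1", 9, "C")])
        table = strat.temperature_exclusivity(pairs, scores).table
        row = table[(table.stratum == "all") & (table.category == "both")]
        assert row["proportion"].iloc[0] == 1.0

    def test_pair_without_hits_excluded_and_counted(self):
        pairs = pairs_frame([("A1", "B1"), ("A2", "B2")])
        scores = scores_from_hits([("A1", 3, "A")])
        res = strat.temperature_exclusivity(pairs, scores)
        assert res.n_excluded["hits"] == 1
        kept = res.table[(res.table.endpoint == "hits")
                         & (res.table.stratum == "all")]
        assert kept["count"].sum() == 1

    def test_rarity_uses_union_of_both_plates(self):
        # 3 wells at 277 plus 3 further wells at 293: union 6 -> promiscuous
        pairs = pairs_frame([("A1", "B1")])
        hits = [("A1", w, "A") for w in (1, 2, 3)]
        hits += [("B1", w, "B") for w in (10, 11, 12)]
        table = strat.temperature_exclusivity(pairs, scores_from_hits(hits)).table
        assert table[(table.stratum == "promiscuous")
                     & (table.endpoint == "hits")]["count"].sum() == 1
        assert table[(table.stratum == "rare")
                     & (table.endpoint == "hits")]["count"].sum() == 0

    def test_recovers_configured_exclusive_fraction(self, campaign):
        from scipy.stats import binom

        pairs = cmatch.find_temperature_pairs(campaign.plates, campaign.crystals)
        table = strat.temperature_exclusivity(
            pairs, campaign.scores, campaign.crystals).table
        rare = table[(table.stratum == "rare") & (table.endpoint == "hits")]
        n = int(rare["count"].sum())
        k = int(rare[rare.category.isin(["277 only", "293 only"])]["count"].sum())
        p0 = campaign.truth.config.temp_exclusive_prob_rare
        lo, hi = binom.interval(0.95, n, p0)
        assert lo <= k <= hi


class TestScreensVsDrops:
    COMBO = ("JCSG", "HCS", "HIN")

    def test_hit_in_a_subwell_found_only_by_three_drop_strategy(self):
        groups = groups_frame([dict(zip(self.COMBO, ("P1", "P2", "P3")))])
        plates = plates_frame(["P1", "P2", "P3"])
        scores = scores_from_hits([("P2", 40, "A")])
        res = strat.screens_vs_drops(groups, plates, scores, self.COMBO)
        assert res.n_three_screens_one_drop == 0
        assert res.n_one_screen_three_drops["HCS"] == 1
        assert res.n_one_screen_three_drops["JCSG"] == 0
        assert res.n_missed_by_both == 0

    def test_one_to_one_hit_found_by_both_strategies(self):
        groups = groups_frame([dict(zip(self.COMBO, ("P1", "P2", "P3")))])
        plates = plates_frame(["P1", "P2", "P3"])
        scores = scores_from_hits([("P3", 40, "B")])
        res = strat.screens_vs_drops(groups, plates, scores, self.COMBO)
        assert res.n_three_screens_one_drop == 1
        assert res.n_one_screen_three_drops["HIN"] == 1

    def test_group_without_hits_missed_by_both(self):
        groups = groups_frame([dict(zip(self.COMBO, ("P1", "P2", "P3")))])
        plates = plates_frame(["P1", "P2", "P3"])
        res = strat.screens_vs_drops(groups, plates, scores_from_hits([]),
                                     self.COMBO)
        assert res.n_missed_by_both == 1

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(123)
        for _ in range(60):
            n_groups = int(rng.integers(1, 10))
            groups, all_plates, hits = [], [], set()
            for g in range(n_groups):
                mapping = {s: f"P{g}_{s}" for s in self.COMBO}
                groups.append(mapping)
                all_plates.extend(mapping.values())
                for plate in mapping.values():
                    for _ in range(int(rng.integers(0, 4))):
                        hits.add((plate, int(rng.integers(1, 97)),
                                  "ABC"[int(rng.integers(3))]))
            res = strat.screens_vs_drops(
                groups_frame(groups), plates_frame(all_plates),
                scores_from_hits(sorted(hits)), self.COMBO)
            e_s1, e_s2, e_missed = oracles.screens_vs_drops_counts(groups, hits)
            assert res.n_three_screens_one_drop == e_s1
            assert res.n_one_screen_three_drops == e_s2
            assert res.n_missed_by_both == e_missed

            ratio = strat.single_drop_ratio_success(
                groups_frame(groups), plates_frame(all_plates),
                scores_from_hits(sorted(hits)), self.COMBO)
            expected = oracles.ratio_success_counts(groups, hits)
            got = dict(zip(ratio["ratio"], ratio["n_success"]))
            assert got == expected

    def test_three_screen_one_drop_contains_single_screen_one_drop(self, campaign):
        """Success of the pooled 1:1 strategy must contain each screen's own
        1:1 success, group by group."""
        groups = cmatch.find_screen_groups(campaign.plates, campaign.crystals)
        from xsm.core_model import hit_droplets

        hits = set(map(tuple, hit_droplets(campaign.scores)
                       [["plate_id", "well", "subwell"]].to_numpy()))
        checked = 0
        for rec in groups.itertuples():
            plate_by_screen = dict(zip(rec.screens, rec.plate_ids))
            pooled = any((p, w, "B") in hits for p in rec.plate_ids
                         for w in range(1, 97))
            for screen, p in plate_by_screen.items():
                single = any((p, w, "B") in hits for w in range(1, 97))
                assert pooled or not single
                checked += 1
        assert checked >= 3


class TestTempsVsDrops:
    def test_one_to_one_hit_at_293_found_by_two_temp_strategy_only(self):
        pairs = pairs_frame([("A1", "B1")])
        plates = plates_frame(["A1", "B1"])
        scores = scores_from_hits([("B1", 20, "B")])
        table = strat.temps_vs_drops(pairs, plates, scores).set_index("temperature_k")
        assert table.loc[277, "two_drops_one_temp"] == 0
        assert table.loc[293, "two_drops_one_temp"] == 0
        assert table.loc[277, "one_drop_two_temps"] == 1
        assert table.loc[277, "n_missed"] == 0

    def test_hits_everywhere_found_by_all_strategies(self):
        pairs = pairs_frame([("A1", "B1")])
        plates = plates_frame(["A1", "B1"])
        hits = [(p, 1, sw) for p in ("A1", "B1") for sw in "ABC"]
        table = strat.temps_vs_drops(pairs, plates, scores_from_hits(hits))
        assert (table["two_drops_one_temp"] == 1).all()
        assert (table["one_drop_two_temps"] == 1).all()
        assert (table["n_missed"] == 0).all()

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(321)
        for _ in range(60):
            n_pairs = int(rng.integers(1, 10))
            pairs, all_plates, hits = [], [], set()
            for i in range(n_pairs):
                a, b = f"A{i}", f"B{i}"
                pairs.append((a, b))
                all_plates.extend([a, b])
                for plate in (a, b):
                    for _ in range(int(rng.integers(0, 3))):
                        hits.add((plate, int(rng.integers(1, 97)),
                                  "ABC"[int(rng.integers(3))]))
            table = strat.temps_vs_drops(
                pairs_frame(pairs), plates_frame(all_plates),
                scores_from_hits(sorted(hits))).set_index("temperature_k")
            expected = oracles.temps_vs_drops_counts(pairs, hits)
            for t in (277, 293):
                assert table.loc[t, "two_drops_one_temp"] == expected[t]["two_drop"]
                assert table.loc[t, "one_drop_two_temps"] == expected[t]["one_drop"]
                assert table.loc[t, "n_missed"] == expected[t]["missed"]
                assert table.loc[t, "n_full"] == expected[t]["full"]

    def test_full_experiment_contains_every_restricted_strategy(self, campaign):
        pairs = cmatch.find_temperature_pairs(campaign.plates, campaign.crystals)
        table = strat.temps_vs_drops(pairs, campaign.plates, campaign.scores)
        for _, row in table.iterrows():
            assert row["two_drops_one_temp"] <= row["n_full"]
            assert row["one_drop_two_temps"] <= row["n_full"]
            assert (row["two_drops_one_temp"] + row["one_drop_two_temps"]
                    + row["n_missed"] >= row["n_full"])
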
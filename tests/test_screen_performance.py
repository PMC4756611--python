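import math

import numpy as np
import pandas as pd
import pytest

from xsm import screen_performance as sp


def condition(*components):
    return tuple(sp.Component(name=n, concentration=c, unit=u)
                 for (n, c, u) in components)


class TestSuccessRates:
    def test_hand_computed_rates(self):
        attrs = [sp.ScreenAttribution("JCSG", 6, 4, 1000),
                 sp.ScreenAttribution("LFS", 0, 0, 500),
                 sp.ScreenAttribution("HCS", 2, 0, 50)]
        table = sp.screen_success_rates(attrs).set_index("screen")
        assert table.loc["JCSG", "success_rate_pct"] == pytest.approx(1.0)
        assert table.loc["LFS", "success_rate_pct"] == pytest.approx(0.0)
        assert table.loc["HCS", "success_rate_pct"] == pytest.approx(4.0)

    def test_zero_plate_screen_omitted_with_warning(self, caplog):
        attrs = [sp.ScreenAttribution("RARE", 1, 0, 0),
                 sp.ScreenAttribution("JCSG", 1, 0, 10)]
        with caplog.at_level("WARNING", logger="xsm.screen_performance"):
            table = sp.screen_success_rates(attrs)
        assert table["screen"].tolist() == ["JCSG"]
        assert any("no plates" in r.message for r in caplog.records)

    def test_rates_scale_invariant(self):
        base = sp.screen_success_rates([sp.ScreenAttribution("S", 3, 2, 40)])
        scaled = sp.screen_success_rates([sp.ScreenAttribution("S", 30, 20, 400)])
        assert base.loc[0, "success_rate_pct"] == pytest.approx(
            scaled.loc[0, "success_rate_pct"])

    def test_attributions_from_campaign(self, campaign):
        attrs = sp.attributions_from_crystals(campaign.plates, campaign.crystals)
        deposited = campaign.crystals[
            campaign.crystals["deposition_id"].notna()
            & (campaign.crystals["quality_score"] >= 1)]
        assert sum(a.n_direct + a.n_optimized for a in attrs) == len(deposited)
        by_screen = {a.screen: a for a in attrs}
        counts = campaign.plates["screen"].value_counts()
        for screen, a in by_screen.items():
            assert a.n_screens_set_up == counts[screen]


class TestDescriptives:
    def test_correlation_matches_closed_form(self):
        x = np.array([10.0, 20.0, 30.0, 40.0])
        y = np.array([2.0, 1.0, 5.0, 4.0])
        # explicit Pearson formula, independent of np.corrcoef
        n = len(x)
        num = n * (x * y).sum() - x.sum() * y.sum()
        den = math.sqrt(n * (x ** 2).sum() - x.sum() ** 2) * \
            math.sqrt(n * (y ** 2).sum() - y.sum() ** 2)
        expected = num / den
        dep = pd.DataFrame({
            "screen": "JCSG", "subwell": "A", "resolution_angstrom": 2.0,
            "molecular_mass_kda": x, "protein_conc_mg_ml": y})
        summary = sp.summarize_descriptives(dep)
        assert summary.conc_mass_correlation["A"] == pytest.approx(expected)

    def test_zero_variance_correlation_undefined(self):
        dep = pd.DataFrame({
            "screen": "JCSG", "subwell": "B", "resolution_angstrom": 2.0,
            "molecular_mass_kda": [10.0, 20.0, 30.0],
            "protein_conc_mg_ml": [10.0, 10.0, 10.0]})
        summary = sp.summarize_descriptives(dep)
        assert math.isnan(summary.conc_mass_correlation["B"])

    def test_resolution_median_and_small_n(self):
        dep = pd.DataFrame({
            "screen": ["JCSG"] * 3 + ["LFS"] * 2,
            "subwell": "A",
            "resolution_angstrom": [1.8, 2.0, 2.6, 1.5, 3.0],
            "molecular_mass_kda": np.nan, "protein_conc_mg_ml": 10.0})
        table = sp.summarize_descriptives(dep).resolution_by_screen.set_index("screen")
        assert table.loc["JCSG", "median"] == pytest.approx(2.0)
        assert math.isnan(table.loc["LFS", "median"])  # fewer than 3 points

    def test_build_depositions_keeps_direct_only(self, campaign):
        dep = sp.build_depositions(campaign.plates, campaign.crystals,
                                   campaign.truth.target_masses)
        assert (dep["provenance"] == "direct").all()
        assert dep["deposition_id"].notna().all()
        assert dep["molecular_mass_kda"].notna().all()
        summary = sp.summarize_descriptives(dep)
        # concentration was drawn independently of mass: correlation ~ 0,
        # within ~4 null standard errors (1/sqrt(n)) per subwell
        for subwell, value in summary.conc_mass_correlation.items():
            n = (dep["subwell"] == subwell).sum()
            if n >= 10:
                assert abs(value) < 4.0 / np.sqrt(n)


class TestInternalDiversity:
    def test_identical_conditions_have_zero_diversity(self):
        cond = condition(("PEG 3350", 20.0, "% w/v"), ("NaCl", 0.2, "M"))
        comp = sp.ScreenComposition("S", tuple([cond] * 4))
        assert sp.internal_diversity(comp) == 0.0

    def test_disjoint_conditions_have_unit_distance(self):
        a = condition(("PEG 3350", 20.0, "% w/v"))
        b = condition(("ammonium sulfate", 2.0, "M"))
        assert sp.component_overlap_distance(a, b) == 1.0
        assert sp.internal_diversity(sp.ScreenComposition("S", (a, b))) == 1.0

    def test_mean_over_pairs_matches_double_loop(self):
        rng = np.random.default_rng(9)
        names = ["PEG", "NaCl", "MES", "glycerol", "LiCl"]
        conditions = tuple(
            condition(*[(n, float(rng.uniform(0.1, 2)), "M")
                        for n in names if rng.random() < 0.7] or [("PEG", 1.0, "M")])
            for _ in range(5))
        comp = sp.ScreenComposition("S", conditions)
        total, count = 0.0, 0
        for i in range(len(conditions)):       # brute-force double loop
            for j in range(i + 1, len(conditions)):
                total += sp.component_overlap_distance(conditions[i], conditions[j])
                count += 1
        assert sp.internal_diversity(comp) == pytest.approx(total / count)

    def test_invariant_under_condition_permutation(self):
        a = condition(("PEG", 1.0, "M"))
        b = condition(("NaCl", 0.5, "M"))
        c = condition(("PEG", 0.5, "M"), ("NaCl", 0.5, "M"))
        d1 = sp.internal_diversity(sp.ScreenComposition("S", (a, b, c)))
        d2 = sp.internal_diversity(sp.ScreenComposition("S", (c, a, b)))
        assert d1 == pytest.approx(d2)

    def test_asymmetric_distance_rejected(self):
        a = condition(("PEG", 1.0, "M"))
        b = condition(("NaCl", 0.5, "M"))
        calls = []

        def lopsided(x, y):
            calls.append(1)
            return 0.2 if len(calls) % 2 else 0.8

        with pytest.raises(ValueError, match="not symmetric"):
            sp.internal_diversity(sp.ScreenComposition("S", (a, b)), lopsided)

    def test_screens_csv_round_trip(self, tmp_path):
        path = tmp_path / "screens.csv"
        path.write_text(
            "screen,condition_index,component,concentration,unit,ph\n"
            "S,1,PEG 3350,20.0,% w/v,7.0\n"
            "S,1,NaCl,0.2,M,\n"
            "S,2,ammonium sulfate,2.0,M,4.6\n")
        comps = sp.read_screen_compositions(path)
        comp = comps["S"]
        assert len(comp.conditions) == 2
        assert comp.conditions[0][0].name == "PEG 3350"
        assert comp.conditions[0][1].ph is None
        assert comp.conditions[1][0].ph == 4.6
        assert 0.0 <= sp.internal_diversity(comp) <= 1.0
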
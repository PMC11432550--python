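import itertools

import numpy as np
import pandas as pd
import pytest

from conftest import make_panel, make_phenotypes, make_table
from gchapkit.association import (
    anova_f_brute, compact_letter_display, contrast_traits,
    favorable_allele_frequencies, gchap_trait_anova,
    label_favorable_unfavorable,
)


class TestFavorablePair:
    def test_rank1_and_rarest_major(self):
        table = make_table("g", {"Hap1": 60, "Hap2": 30, "Hap3": 5, "Hap4": 5})
        pair = label_favorable_unfavorable(table, list(table.assignments), 0.04)
        assert pair.favorable_hap == "Hap1"
        assert pair.unfavorable_hap in ("Hap3", "Hap4")

    def test_exactly_two_majors(self):
        table = make_table("g", {"Hap1": 6, "Hap2": 4})
        pair = label_favorable_unfavorable(table, list(table.assignments))
        assert (pair.favorable_hap, pair.unfavorable_hap) == ("Hap1", "Hap2")
        assert pair.favorable_freq >= pair.unfavorable_freq

    def test_single_major_is_error(self):
        table = make_table("g", {"Hap1": 995, "Hap2": 5})
        with pytest.raises(ValueError, match="contrast undefined"):
            label_favorable_unfavorable(table, list(table.assignments))


class TestContrasts:
    def _pair_and_table(self, n=10):
        table = make_table("g", {"Hap1": n, "Hap2": n})
        pair = label_favorable_unfavorable(table, list(table.assignments))
        return pair, table

    def test_identical_groups_not_significant(self):
        pair, table = self._pair_and_table()
        pheno = make_phenotypes(
            {"TGW": {v: 25.0 for v in table.assignments}}
        )
        pair = contrast_traits(pair, table, pheno, ["TGW"])
        c = pair.contrasts["TGW"]
        assert c.difference == 0.0 and not c.significant

    def test_planted_effect_recovered(self):
        rng = np.random.default_rng(5)
        table = make_table("g", {"Hap1": 200, "Hap2": 200})
        values = {}
        for v, hap in table.assignments.items():
            values[v] = 25.0 + (2.0 if hap == "Hap1" else 0.0) + rng.normal(0, 1)
        pair = label_favorable_unfavorable(table, list(table.assignments))
        pair = contrast_traits(pair, table, make_phenotypes({"TGW": values}),
                               ["TGW"])
        c = pair.contrasts["TGW"]
        assert c.significant
        assert c.difference == pytest.approx(2.0, abs=0.3)

    def test_all_missing_group_is_insufficient(self):
        pair, table = self._pair_and_table()
        values = {v: (25.0 if h == "Hap1" else np.nan)
                  for v, h in table.assignments.items()}
        pair = contrast_traits(pair, table, make_phenotypes({"TGW": values}),
                               ["TGW"])
        assert pair.contrasts["TGW"].status == "insufficient data"


class TestAnova:
    def test_equal_groups_share_letter(self):
        table = make_table("g", {"Hap1": 6, "Hap2": 6})
        pheno = make_phenotypes({"TGW": {
            v: 25.0 for v in table.assignments
        }})
        res = gchap_trait_anova(table, pheno, "TGW", min_n=3)
        assert res.f_stat == 0.0
        assert res.letters["Hap1"] == res.letters["Hap2"] == "a"

    def test_textbook_three_groups_distinct_letter(self):
        rng = np.random.default_rng(12)
        table = make_table("g", {"Hap1": 5, "Hap2": 5, "Hap3": 5})
        values = {}
        for v, hap in table.assignments.items():
            mean = 5.0 if hap == "Hap3" else 0.0
            values[v] = mean + rng.normal(0, 1)
        res = gchap_trait_anova(
            table, make_phenotypes({"TGW": values}), "TGW", min_n=3
        )
        assert res.letters["Hap1"] == res.letters["Hap2"]
        assert res.letters["Hap3"] != res.letters["Hap1"]
        assert res.anova_pvalue < 0.01

    def test_f_matches_brute_force_sums_of_squares(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            sizes = rng.integers(5, 30, size=rng.integers(2, 6))
            groups = [rng.normal(rng.normal(0, 2), 1, size=n) for n in sizes]
            from scipy.stats import f_oneway

            f, p = f_oneway(*groups)
            fb, pb = anova_f_brute(groups)
            assert f == pytest.approx(fb, abs=1e-10)
            assert p == pytest.approx(pb, abs=1e-10)

    def test_small_group_dropped_and_recorded(self):
        table = make_table("g", {"Hap1": 10, "Hap2": 10, "Hap3": 3})
        values = dict(zip(
            table.assignments,
            np.random.default_rng(1).normal(25, 1, size=23),
        ))
        res = gchap_trait_anova(
            table, make_phenotypes({"TGW": values}), "TGW",
            major_threshold=0.01, min_n=5,
        )
        assert res.dropped == ["Hap3"]
        assert set(res.groups) == {"Hap1", "Hap2"}

    def test_fewer_than_two_groups_is_error(self):
        table = make_table("g", {"Hap1": 10, "Hap2": 2})
        values = dict(zip(
            table.assignments,
            np.random.default_rng(1).normal(25, 1, size=12),
        ))
        with pytest.raises(ValueError, match="fewer than 2"):
            gchap_trait_anova(table, make_phenotypes({"TGW": values}), "TGW",
                              min_n=5)


class TestCompactLetters:
    @pytest.mark.parametrize("n_groups", [2, 3, 4, 5, 6])
    def test_share_letter_iff_not_significant(self, n_groups):
        """Exhaustive check over random Tukey decision patterns."""
        rng = np.random.default_rng(n_groups)
        ids = [f"Hap{i}" for i in range(1, n_groups + 1)]
        means = {h: float(rng.normal()) for h in ids}
        for _ in range(20):
            pairwise = {
                pair: float(rng.uniform())
                for pair in itertools.combinations(ids, 2)
            }
            letters = compact_letter_display(ids, means, pairwise, alpha=0.5)
            for (a, b), p in pairwise.items():
                share = bool(set(letters[a]) & set(letters[b]))
                assert share == (p >= 0.5), (pairwise, letters)

    def test_every_group_gets_a_letter(self):
        ids = ["Hap1", "Hap2"]
        letters = compact_letter_display(
            ids, {"Hap1": 1.0, "Hap2": 0.0}, {("Hap1", "Hap2"): 0.001}
        )
        assert letters["Hap1"] and letters["Hap2"]
        assert letters["Hap1"] != letters["Hap2"]


class TestFavorableFrequencies:
    def test_best_mean_hap_selected_by_direction(self):
        table = make_table("g", {"Hap1": 10, "Hap2": 10})
        panel = make_panel(20)
        values = {v: (25.0 if h == "Hap1" else 22.0)
                  for v, h in table.assignments.items()}
        rng = np.random.default_rng(2)
        values = {v: x + rng.normal(0, 0.1) for v, x in values.items()}
        res = gchap_trait_anova(table, make_phenotypes({"TGW": values}),
                                "TGW", min_n=3)
        freqs = favorable_allele_frequencies(table, panel, res, "higher")
        assert (freqs["favorable_hap"] == "Hap1").all()
        row = freqs[freqs["group"] == "Xian"].iloc[0]
        assert row["frequency"] == 0.5 and row["n_accession"] == 10

    def test_absent_hap_reports_zero(self):
        import pandas as pd

        from gchapkit.io import VarietyPanel

        table = make_table("g", {"Hap1": 5, "Hap2": 5})
        rows = [{"variety_id": v, "population": "Xian" if h == "Hap1" else "Geng",
                 "improvement": "LAN"} for v, h in table.assignments.items()]
        panel = VarietyPanel(pd.DataFrame(rows))
        values = {v: (25.0 if h == "Hap1" else 22.0)
                  for v, h in table.assignments.items()}
        rng = np.random.default_rng(2)
        values = {v: x + rng.normal(0, 0.1) for v, x in values.items()}
        res = gchap_trait_anova(table, make_phenotypes({"TGW": values}),
                                "TGW", min_n=3)
        freqs = favorable_allele_frequencies(table, panel, res, "higher")
        geng = freqs[freqs["group"] == "Geng"].iloc[0]
        assert geng["frequency"] == 0.0 and geng["n_accession"] == 0

    def test_unknown_direction_rejected(self):
        table = make_table("g", {"Hap1": 5, "Hap2": 5})
        values = dict(zip(table.assignments,
                          np.random.default_rng(0).normal(25, 1, 10)))
        res = gchap_trait_anova(table, make_phenotypes({"TGW": values}),
                                "TGW", min_n=3)
        with pytest.raises(ValueError, match="direction"):
            favorable_allele_frequencies(table, make_panel(10), res, "sideways")
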
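import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import make_panel, make_table
from gchapkit.diversity import (
    diversity_summary, evenness_from_counts, nei_identity,
    pairwise_differentiation, shannon_evenness,
)

freq_vectors = st.lists(
    st.floats(min_value=0.01, max_value=1.0), min_size=2, max_size=10
).map(lambda w: [x / sum(w) for x in w])


class TestShannonEvenness:
    def test_uniform_is_one(self):
        assert shannon_evenness([0.25] * 4) == pytest.approx(1.0)

    def test_singleton_is_zero(self):
        assert shannon_evenness([1.0]) == 0.0

    def test_worked_case(self):
        # H = -(0.7 ln0.7 + 0.2 ln0.2 + 0.1 ln0.1) = 0.80181; ln3 = 1.09861
        assert shannon_evenness([0.7, 0.2, 0.1]) == pytest.approx(
            0.72985, abs=1e-5
        )

    def test_two_hap_case(self):
        assert shannon_evenness([0.6, 0.4]) == pytest.approx(
            -(0.6 * np.log(0.6) + 0.4 * np.log(0.4)) / np.log(2), abs=1e-12
        )

    def test_negative_frequency_rejected(self):
        with pytest.raises(ValueError):
            shannon_evenness([1.2, -0.2])

    @given(freq_vectors)
    @settings(max_examples=100, deadline=None)
    def test_bounds_and_relabeling_invariance(self, freqs):
        e = shannon_evenness(freqs)
        assert 0 <= e <= 1 + 1e-12
        assert shannon_evenness(freqs[::-1]) == pytest.approx(e, abs=1e-12)

    @given(freq_vectors, st.floats(min_value=0.05, max_value=0.95))
    @settings(max_examples=100, deadline=None)
    def test_transfer_from_rich_to_poor_increases_evenness(self, freqs, frac):
        """Pigou-Dalton: moving mass from the most to the least frequent
        haplotype (without crossing them over) increases E_H."""
        freqs = sorted(freqs, reverse=True)
        if freqs[0] - freqs[-1] < 1e-4:
            return
        delta = frac * (freqs[0] - freqs[-1]) / 2
        moved = list(freqs)
        moved[0] -= delta
        moved[-1] += delta
        assert shannon_evenness(moved) > shannon_evenness(freqs)

    @given(freq_vectors)
    @settings(max_examples=50, deadline=None)
    def test_matches_direct_recomputation(self, freqs):
        """Second code path: plain-Python entropy over the same vector."""
        p = [x for x in freqs if x > 0]
        expected = -sum(x * math.log(x) for x in p) / math.log(len(p))
        assert shannon_evenness(freqs) == pytest.approx(expected, abs=1e-12)
        counts = np.asarray([int(round(1e6 * x)) for x in freqs])
        assert evenness_from_counts(counts)[0] == pytest.approx(
            expected, abs=1e-4
        )


class TestNeiIdentity:
    def test_identical_vectors_give_one(self):
        assert nei_identity([0.3, 0.7], [0.3, 0.7]) == pytest.approx(1.0)

    def test_disjoint_supports_give_zero(self):
        assert nei_identity([1, 0], [0, 1]) == 0.0

    def test_worked_case(self):
        assert nei_identity([0.5, 0.5, 0], [0.5, 0, 0.5]) == pytest.approx(
            0.5, abs=1e-12
        )

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            nei_identity([0, 0], [0, 0])

    @given(freq_vectors, freq_vectors)
    @settings(max_examples=100, deadline=None)
    def test_symmetry_bounds_and_count_scale_invariance(self, x, y):
        n = min(len(x), len(y))
        x, y = x[:n], y[:n]
        i = nei_identity(x, y)
        assert 0 <= i <= 1 + 1e-12
        assert nei_identity(y, x) == pytest.approx(i, abs=1e-12)
        # multiplying counts by a constant leaves I unchanged
        assert nei_identity([37 * v for v in x], y) == pytest.approx(i, abs=1e-12)

    @given(freq_vectors, freq_vectors)
    @settings(max_examples=50, deadline=None)
    def test_matches_direct_recomputation(self, x, y):
        n = min(len(x), len(y))
        x, y = x[:n], y[:n]
        num = sum(a * b for a, b in zip(x, y))
        den = math.sqrt(sum(a * a for a in x) * sum(b * b for b in y))
        assert nei_identity(x, y) == pytest.approx(num / den, abs=1e-12)


class TestSummaries:
    def test_two_hap_record(self):
        table = make_table("g", {"Hap1": 600, "Hap2": 400})
        panel = make_panel(1000)
        records = diversity_summary(table, panel)
        whole = [r for r in records if r.population == "ALL"][0]
        assert whole.gchap_n == 2
        assert whole.e_h == pytest.approx(0.971, abs=1e-3)
        assert whole.dominant_hap == "Hap1"
        assert whole.f_p == 0.6

    def test_single_hap_record(self):
        table = make_table("g", {"Hap1": 10})
        records = diversity_summary(table, make_panel(10))
        assert records[-1].e_h == 0.0 and records[-1].f_p == 1.0

    def test_differentiation_flags_divergent_pair(self):
        import pandas as pd

        from gchapkit.io import VarietyPanel

        # two populations with mirrored 0.95/0.05 compositions
        rows, assignments = [], {}
        i = 0
        for hap, pop, n in [("Hap1", "Xian", 95), ("Hap2", "Xian", 5),
                            ("Hap1", "Geng", 5), ("Hap2", "Geng", 95)]:
            for _ in range(n):
                rows.append({"variety_id": f"v{i}", "population": pop,
                             "improvement": "LAN"})
                assignments[f"v{i}"] = hap
                i += 1
        table = make_table("g", {"Hap1": 1, "Hap2": 1})
        table.assignments = assignments
        panel = VarietyPanel(pd.DataFrame(rows))
        diff = pairwise_differentiation(table, panel, ["Xian", "Geng"])
        expected = 2 * 0.95 * 0.05 / (0.95**2 + 0.05**2)
        assert diff.identity.loc["Xian", "Geng"] == pytest.approx(
            expected, abs=1e-12
        )
        assert ("Xian", "Geng") in diff.flagged

    def test_identical_populations_not_flagged(self):
        import pandas as pd

        from gchapkit.io import VarietyPanel

        rows = []
        assignments = {}
        i = 0
        for pop in ("Xian", "Geng"):
            for hap, n in [("Hap1", 6), ("Hap2", 4)]:
                for _ in range(n):
                    rows.append({"variety_id": f"v{i}", "population": pop,
                                 "improvement": "LAN"})
                    assignments[f"v{i}"] = hap
                    i += 1
        table = make_table("g", {"Hap1": 1, "Hap2": 1})
        table.assignments = assignments
        panel = VarietyPanel(pd.DataFrame(rows))
        diff = pairwise_differentiation(table, panel, ["Xian", "Geng"])
        assert diff.identity.loc["Xian", "Geng"] == pytest.approx(1.0)
        assert not diff.flagged

    def test_threshold_zero_flags_nothing(self):
        import pandas as pd

        from gchapkit.io import VarietyPanel

        rows, assignments = [], {}
        for i in range(10):
            pop = "Xian" if i < 5 else "Geng"
            rows.append({"variety_id": f"v{i}", "population": pop,
                         "improvement": "LAN"})
            assignments[f"v{i}"] = "Hap1" if pop == "Xian" else "Hap2"
        table = make_table("g", {"Hap1": 1, "Hap2": 1})
        table.assignments = assignments
        panel = VarietyPanel(pd.DataFrame(rows))
        diff = pairwise_differentiation(table, panel, threshold=0.0)
        assert not diff.flagged
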
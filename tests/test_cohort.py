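import math

import numpy as np
import pytest

from arddpcr.cohort import (
    CohortRecord,
    ContingencyTable2x2,
    build_table4,
    fisher_exact_2x2,
    healthy_threshold_summary,
    mann_whitney,
    pearson_correlation,
)

from oracles import fisher_margin_oracle, fisher_two_sided_oracle, mann_whitney_exact_oracle


class TestHealthySummary:
    def test_constant_values(self):
        s = healthy_threshold_summary([1.0, 1.0, 1.0])
        assert s["mean"] == 1.0 and s["sem"] == 0.0
        assert s["suggested_threshold"] == 2.0

    def test_sem_uses_sample_sd(self):
        vals = [0.72, 0.95, 1.08, 1.20, 1.33]
        s = healthy_threshold_summary(vals)
        assert s["sem"] == pytest.approx(np.std(vals, ddof=1) / math.sqrt(5))
        assert (s["min"], s["max"]) == (0.72, 1.33)

    def test_healthy_range_yields_conservative_threshold(self):
        # any healthy cohort inside the normal CN band suggests the floor of 2
        s = healthy_threshold_summary([0.72, 0.9, 1.1, 1.33])
        assert s["suggested_threshold"] == 2.0

    def test_threshold_never_below_healthy_max(self):
        s = healthy_threshold_summary([1.0, 2.33])
        assert s["suggested_threshold"] == pytest.approx(2.4)

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            healthy_threshold_summary([1.0])


class TestFisher:
    def test_matches_rational_enumeration_on_moderate_tables(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            a, b, c, d = rng.integers(0, 12, size=4)
            if a + b + c + d == 0:
                continue
            got = fisher_exact_2x2(ContingencyTable2x2(int(a), int(b), int(c), int(d)))
            want = fisher_two_sided_oracle(int(a), int(b), int(c), int(d))
            assert got["p_two_sided"] == pytest.approx(want, abs=1e-9)

    def test_symmetry_invariances(self):
        t = ContingencyTable2x2(5, 4, 7, 14)
        p = fisher_exact_2x2(t)["p_two_sided"]
        transposed = ContingencyTable2x2(5, 7, 4, 14)
        swapped = ContingencyTable2x2(14, 7, 4, 5)
        assert fisher_exact_2x2(transposed)["p_two_sided"] == pytest.approx(p)
        assert fisher_exact_2x2(swapped)["p_two_sided"] == pytest.approx(p)

    def test_empty_row_is_uninformative(self):
        assert fisher_exact_2x2(ContingencyTable2x2(0, 0, 5, 5))["p_two_sided"] == 1.0

    def test_odds_ratio_edge_cases(self):
        assert fisher_exact_2x2(ContingencyTable2x2(2, 2, 7, 19))["odds_ratio"] == pytest.approx(38 / 14)
        assert fisher_exact_2x2(ContingencyTable2x2(3, 0, 2, 5))["odds_ratio"] == math.inf
        assert math.isnan(fisher_exact_2x2(ContingencyTable2x2(0, 0, 2, 5))["odds_ratio"])

    def test_all_zero_table_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable2x2(0, 0, 0, 0)


class TestMannWhitney:
    def test_fully_separated_small_groups(self):
        res = mann_whitney([1, 2, 3], [10, 11, 12])
        assert res["U"] == 0.0
        assert res["p_two_sided"] == pytest.approx(0.1)  # 2/20 assignments

    def test_exact_mode_matches_permutation_enumeration(self):
        rng = np.random.default_rng(12)
        for _ in range(25):
            na, nb = int(rng.integers(2, 7)), int(rng.integers(2, 7))
            vals = rng.choice(500, size=na + nb, replace=False).astype(float)
            a, b = vals[:na], vals[na:]
            u_want, p_want = mann_whitney_exact_oracle(a, b)
            res = mann_whitney(a, b)
            assert res["method"] == "exact"
            assert res["U"] == pytest.approx(u_want)
            assert res["p_two_sided"] == pytest.approx(p_want)

    def test_null_calibration(self):
        # identical distributions: p should exceed 0.05 in >=95% of draws
        rng = np.random.default_rng(3)
        false_positives = 0
        n_draws = 40
        for _ in range(n_draws):
            pooled = rng.normal(size=30)
            false_positives += mann_whitney(pooled[:15], pooled[15:])["p_two_sided"] <= 0.05
        assert false_positives <= 0.05 * n_draws + 1

    def test_ties_fall_back_to_asymptotic(self):
        res = mann_whitney([1.0, 2.0, 2.0], [2.0, 3.0, 4.0])
        assert res["method"] == "asymptotic"

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestPearson:
    def test_identity(self):
        x = [1.0, 2.0, 5.0, 9.0]
        assert pearson_correlation(x, x)["r"] == pytest.approx(1.0)

    def test_negation(self):
        x = [1.0, 2.0, 5.0, 9.0]
        assert pearson_correlation(x, [-v for v in x])["r"] == pytest.approx(-1.0)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            pearson_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_short_input_rejected(self):
        with pytest.raises(ValueError):
            pearson_correlation([1.0, 2.0], [1.0, 2.0])


def _patient(i, cn1, cn2, chemo=None, enz=None, state="CRPC"):
    return CohortRecord(
        sample_id=f"P{i:02d}", sex="male", disease_state=state,
        cn_assay1=cn1, cn_assay2=cn2, chemo=chemo, enz_abi=enz,
    )


def _cohort_with_margins():
    """30 flagged patients reproducing the worked-example chemo margins."""
    recs = []
    i = 0
    layout = [  # (n, amplified, chemo, enz)
        (2, True, True, True), (3, True, True, False),
        (2, True, False, True), (2, True, False, False),
        (2, False, True, True), (5, False, True, False),
        (8, False, False, True), (6, False, False, False),
    ]
    for n, amp, chemo, enz in layout:
        for _ in range(n):
            i += 1
            cn = 8.0 if amp else 1.1
            recs.append(_patient(i, cn, cn, chemo, enz))
    return recs


class TestBuildTable4:
    def test_reproduces_margin_layout(self):
        recs = _cohort_with_margins()
        res = build_table4(recs, "chemo")
        assert res.table.as_array().tolist() == [[5, 4], [7, 14]]
        res = build_table4(recs, "enz_abi")
        assert res.table.as_array().tolist() == [[4, 5], [10, 11]]
        res = build_table4(recs, "chemo_and_enz_abi")
        assert res.table.as_array().tolist() == [[2, 7], [2, 19]]

    def test_conserves_included_records(self):
        recs = _cohort_with_margins()
        res = build_table4(recs, "chemo")
        assert res.table.total == res.n_included == 30

    def test_missing_flags_excluded_with_warning(self):
        recs = _cohort_with_margins() + [_patient(99, 1.0, 1.0, chemo=None, enz=None)]
        with pytest.warns(UserWarning, match="missing treatment"):
            res = build_table4(recs, "chemo")
        assert res.n_excluded_missing == 1
        assert res.table.total == 30

    def test_discordant_samples_reported_not_resolved(self):
        recs = _cohort_with_margins() + [_patient(98, 5.0, 1.0, chemo=True, enz=True)]
        res = build_table4(recs, "chemo")
        assert res.n_discordant == 1
        assert res.discordant_ids == ("P98",)
        assert res.table.total == 30

    def test_healthy_records_ignored(self):
        recs = _cohort_with_margins() + [
            CohortRecord("HC1", "male", "healthy", 1.0, 1.0)
        ]
        assert build_table4(recs, "chemo").table.total == 30

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            build_table4([], "chemo")

    def test_unknown_grouping_rejected(self):
        with pytest.raises(ValueError):
            build_table4(_cohort_with_margins(), "radiation")
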
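import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from srhkit.concordance import (
    SurveyTable,
    build_report,
    cohens_kappa,
    fleiss_kappa,
    percent_agreement,
    relative_accuracy,
    synthetic_survey_table,
)


def brute_force_kappa(a, b):
    """Cohen's kappa straight from the contingency table, the long way."""
    labels = sorted(set(a) | set(b))
    k = len(labels)
    idx = {lab: i for i, lab in enumerate(labels)}
    table = np.zeros((k, k))
    for x, y in zip(a, b):
        table[idx[x], idx[y]] += 1
    n = table.sum()
    p_o = np.trace(table) / n
    p_e = sum(table[i, :].sum() * table[:, i].sum() for i in range(k)) / n ** 2
    if p_o == 1.0:
        return 1.0
    if p_e == 1.0:
        return float("nan")
    return (p_o - p_e) / (1 - p_e)


class TestPercentAgreement:
    @pytest.mark.parametrize("matches,n,pct,rounded", [(12, 16, 75.0, 75), (14, 16, 87.5, 88)])
    def test_fraction_and_rounding(self, matches, n, pct, rounded):
        resp = ["a"] * matches + ["b"] * (n - matches)
        ref = ["a"] * n
        pa = percent_agreement(resp, ref)
        assert pa.percent == pct
        assert pa.percent_rounded == rounded

    def test_identical_vectors_give_100(self):
        pa = percent_agreement(list("abcabc"), list("abcabc"))
        assert pa.percent == 100.0

    def test_zero_cases_rejected(self):
        with pytest.raises(ValueError):
            percent_agreement([], [])


class TestCohensKappa:
    def test_perfect_agreement_is_exactly_one(self):
        assert cohens_kappa(list("aabb"), list("aabb")) == 1.0

    def test_constant_identical_vectors_define_kappa_one(self):
        assert cohens_kappa(["x"] * 5, ["x"] * 5) == 1.0

    def test_perfect_disagreement_balanced_marginals(self):
        a = ["x"] * 8 + ["y"] * 8
        b = ["y"] * 8 + ["x"] * 8
        assert cohens_kappa(a, b) == -1.0

    def test_printed_contingency_example(self):
        # table [[6,2],[1,7]]: p_o = 13/16, p_e = 0.5 -> kappa = 0.625
        a = ["x"] * 8 + ["y"] * 8
        b = ["x"] * 6 + ["y"] * 2 + ["x"] * 1 + ["y"] * 7
        assert cohens_kappa(a, b) == pytest.approx(0.625)

    def test_constant_rater_against_mixed_reference(self):
        # constant rater, mixed reference: p_o = p_e, kappa = 0 (chance-level)
        assert cohens_kappa(["x", "x"], ["x", "y"]) == pytest.approx(0.0)

    def test_matches_bruteforce_on_random_tables(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            n = rng.integers(2, 51)
            k = rng.integers(2, 6)
            a = [f"c{i}" for i in rng.integers(0, k, n)]
            b = [f"c{i}" for i in rng.integers(0, k, n)]
            expected = brute_force_kappa(a, b)
            got = cohens_kappa(a, b)
            assert got == pytest.approx(expected, abs=1e-12)
            assert got <= 1.0

    def test_matches_sklearn(self):
        from sklearn.metrics import cohen_kappa_score

        rng = np.random.default_rng(0)
        for _ in range(20):
            a = rng.integers(0, 4, 30)
            b = rng.integers(0, 4, 30)
            assert cohens_kappa(list(map(str, a)), list(map(str, b))) == pytest.approx(
                cohen_kappa_score(a, b), abs=1e-12)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.sampled_from("abc"), min_size=2, max_size=30))
    def test_kappa_is_one_iff_perfect(self, labels):
        assert cohens_kappa(labels, list(labels)) == 1.0


class TestFleissKappa:
    def test_unanimous_raters_with_two_categories(self):
        counts = np.array([[3, 0], [0, 3], [3, 0], [0, 3]])
        assert fleiss_kappa(counts) == 1.0

    def test_hand_evaluated_example(self):
        # 4 cases x 3 raters, counts [[3,0],[0,3],[2,1],[1,2]] -> kappa = 1/3
        counts = np.array([[3, 0], [0, 3], [2, 1], [1, 2]])
        assert fleiss_kappa(counts) == pytest.approx(1.0 / 3.0)

    def test_matches_statsmodels(self):
        from statsmodels.stats.inter_rater import fleiss_kappa as sm_fleiss

        rng = np.random.default_rng(5)
        for _ in range(20):
            raw = rng.integers(0, 3, (12, 4))  # 12 cases, 4 raters, 3 categories
            counts = np.stack([np.bincount(row, minlength=3) for row in raw])
            assert fleiss_kappa(counts) == pytest.approx(sm_fleiss(counts), abs=1e-12)

    def test_single_rater_rejected(self):
        with pytest.raises(ValueError):
            fleiss_kappa(np.array([[1, 0], [0, 1]]))

    def test_unequal_rater_counts_rejected(self):
        with pytest.raises(ValueError, match="same number"):
            fleiss_kappa(np.array([[2, 1], [1, 0]]))

    def test_single_category_everywhere_is_undefined(self):
        with pytest.warns(UserWarning, match="undefined"):
            assert np.isnan(fleiss_kappa(np.array([[3, 0], [3, 0]])))

    def test_near_zero_under_uniform_null(self):
        rng = np.random.default_rng(11)
        raw = rng.integers(0, 3, (200, 3))
        counts = np.stack([np.bincount(row, minlength=3) for row in raw])
        assert abs(fleiss_kappa(counts)) < 0.08


class TestRelativeAccuracy:
    @pytest.mark.parametrize("srh,ffpe,expected", [
        (94, 100, 94),   # 15/16 agreeing cases
        (75, 81, 92),    # 12/13 -- count arithmetic, not percentage ratio
        (69, 81, 85),
        (88, 100, 88),
        (81, 94, 87),
        (50, 50, 100),   # self-ratio
    ])
    def test_count_based_ratio(self, srh, ffpe, expected):
        assert relative_accuracy(srh, ffpe, 16).percent == expected

    def test_scale_free_in_counts(self):
        small = relative_accuracy(75, 100, 16)
        big = relative_accuracy(75, 100, 32)
        assert big.srh_count == 2 * small.srh_count
        assert big.percent == small.percent

    def test_zero_ffpe_is_missing(self):
        ra = relative_accuracy(50, 0, 16)
        assert ra.percent is None and np.isnan(ra.ratio)

    def test_unrounded_ratio_reported(self):
        assert relative_accuracy(75, 81, 16).ratio == pytest.approx(100 * 12 / 13)


class TestSurveyTable:
    def test_duplicate_response_rejected(self):
        rows = pd.DataFrame([
            dict(case_id="c1", rater_id="N1", modality="SRH",
                 question="final_diagnosis", response="meningioma"),
            dict(case_id="c1", rater_id="N1", modality="SRH",
                 question="final_diagnosis", response="schwannoma"),
        ])
        ref = pd.DataFrame([dict(case_id="c1", question="final_diagnosis",
                                 response="meningioma")])
        with pytest.raises(ValueError, match="multiple responses"):
            SurveyTable(rows, ref)

    def test_confidence_range_enforced(self):
        rows = pd.DataFrame([dict(case_id="c1", rater_id="N1", modality="SRH",
                                  question="confidence", response=5)])
        ref = pd.DataFrame([dict(case_id="c1", question="final_diagnosis", response="x")])
        with pytest.raises(ValueError, match="confidence"):
            SurveyTable(rows, ref)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            SurveyTable(pd.DataFrame(columns=["case_id", "rater_id", "modality",
                                              "question", "response"]),
                        pd.DataFrame(columns=["case_id", "question", "response"]))


class TestBuildReport:
    def test_perfect_table_reports_all_ones(self):
        counts = {(r, m, q): 16
                  for r in ("N1", "N2", "N3")
                  for m in ("SRH", "HE_frozen", "HE_FFPE")
                  for q in ("final_diagnosis", "nuclear_shape")}
        table = synthetic_survey_table(counts, 16, seed=0)
        rep = build_report(table)
        used = rep.agreement.dropna(subset=["percent"])
        assert (used.percent == 100.0).all()
        assert (used.kappa == 1.0).all()
        sub = rep.relative.dropna(subset=["percent"])
        assert (sub.percent == 100.0).all()
        kf = rep.fleiss.dropna(subset=["kappa"])
        assert (kf.kappa == 1.0).all()

    def test_constructed_14_of_16_vs_16_of_16_gives_88(self):
        counts = {("N1", "SRH", "final_diagnosis"): 14,
                  ("N1", "HE_FFPE", "final_diagnosis"): 16}
        rep = build_report(synthetic_survey_table(counts, 16, seed=1))
        cell = rep.relative_cell("N1", "final_diagnosis")
        assert cell.percent == 88

    def test_differential_membership_scoring(self):
        rows = pd.DataFrame([
            dict(case_id="c1", rater_id="N1", modality="SRH", question="differential",
                 response="schwannoma; meningioma"),
            dict(case_id="c2", rater_id="N1", modality="SRH", question="differential",
                 response="chordoma"),
        ])
        ref = pd.DataFrame([
            dict(case_id="c1", question="differential", response="meningioma"),
            dict(case_id="c2", question="differential", response="meningioma"),
        ])
        rep = build_report(SurveyTable(rows, ref))
        cell = rep.agreement_cell("N1", "SRH", "differential")
        assert cell.matches == 1 and cell.n == 2

    def test_missing_responses_excluded_pairwise(self):
        counts = {("N1", "SRH", "nuclear_shape"): 8}
        table = synthetic_survey_table(counts, 8, seed=2)
        # rater N2 answered nothing: the cell reports n=0 and NaN agreement
        rep = build_report(table)
        assert rep.agreement_cell("N1", "SRH", "nuclear_shape").n == 8

    def test_confidence_means(self):
        counts = {("N1", "SRH", "final_diagnosis"): 16}
        table = synthetic_survey_table(counts, 16, seed=3,
                                       confidence_means={("N1", "SRH"): 3.13})
        rep = build_report(table)
        row = rep.confidence[(rep.confidence.rater == "N1")
                             & (rep.confidence.modality == "SRH")].iloc[0]
        assert row.mean_confidence == pytest.approx(3.13, abs=0.04)

    def test_empty_reference_rejected(self):
        rows = pd.DataFrame([dict(case_id="c1", rater_id="N1", modality="SRH",
                                  question="final_diagnosis", response="x")])
        with pytest.raises(ValueError):
            build_report(SurveyTable(rows, pd.DataFrame(
                columns=["case_id", "question", "response"])))


class TestIndependenceNull:
    def test_mean_kappas_near_zero_under_rater_independence(self):
        """Chance-corrected agreement is unbiased: mean kappa ~ 0 for independent raters."""
        # 200 cases per replicate: kappa's finite-sample bias is O(1/n), so
        # small panels would sit visibly below zero even under independence
        rng = np.random.default_rng(2024)
        n_rep, n_cases, k = 500, 200, 3
        kc, kf = [], []
        for _ in range(n_rep):
            ref = rng.integers(0, k, n_cases)
            r1 = rng.integers(0, k, n_cases)
            kc.append(cohens_kappa(list(map(str, r1)), list(map(str, ref))))
            raw = rng.integers(0, k, (n_cases, 3))
            counts = np.stack([np.bincount(row, minlength=k) for row in raw])
            kf.append(fleiss_kappa(counts))
        assert abs(np.nanmean(kc)) < 0.02
        assert abs(np.nanmean(kf)) < 0.02
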
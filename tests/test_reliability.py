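"""ICC(2,1), percentage agreement, Bland-Altman, and the report layout."""

import numpy as np
import pandas as pd
import pytest

from skillmatch.errors import DegenerateDataError, InsufficientDataError, ValidationError
from skillmatch.reliability import (
    CountTable,
    bland_altman,
    fleiss_category,
    format_report,
    icc_two_way_random_single,
    percentage_agreement,
    report,
    report_to_json,
)


def _pingouin_icc2(a, b):
    """Independent oracle: pingouin's two-way random absolute-agreement
    single-measures ICC."""
    import pingouin as pg

    n = len(a)
    df = pd.DataFrame({
        "targets": list(range(n)) * 2,
        "raters": ["a"] * n + ["b"] * n,
        "score": list(a) + list(b),
    })
    res = pg.intraclass_corr(data=df, targets="targets", raters="raters", ratings="score")
    row = res[res["Type"] == "ICC(A,1)"].iloc[0]
    return float(row["ICC"]), row["CI95"]


class TestICC:
    def test_perfect_agreement(self):
        res = icc_two_way_random_single([1, 4, 7, 9], [1, 4, 7, 9])
        assert res.icc == pytest.approx(1.0)
        assert res.category == "excellent"

    def test_worked_example_matches_anova_oracle(self):
        # frozen from the independent mean-squares oracle
        res = icc_two_way_random_single([4, 5, 7, 9], [4, 6, 8, 9])
        assert res.icc == pytest.approx(0.95, abs=1e-10)
        oracle_icc, _ = _pingouin_icc2([4, 5, 7, 9], [4, 6, 8, 9])
        assert res.icc == pytest.approx(oracle_icc, abs=1e-10)

    def test_matches_oracle_on_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(40):
            n = int(rng.integers(4, 25))
            a = rng.poisson(12, n).astype(float)
            b = a + rng.normal(0, rng.uniform(0.5, 4), n)
            mine = icc_two_way_random_single(a, b)
            oracle_icc, oracle_ci = _pingouin_icc2(a, b)
            assert mine.icc == pytest.approx(oracle_icc, abs=1e-10)
            # oracle reports its CI rounded to 2 decimals
            assert mine.ci95_low == pytest.approx(oracle_ci[0], abs=0.006)
            assert mine.ci95_high == pytest.approx(oracle_ci[1], abs=0.006)
            assert mine.ci95_low <= mine.icc <= mine.ci95_high

    def test_shift_and_swap_invariance(self):
        rng = np.random.default_rng(1)
        a = rng.poisson(10, 12).astype(float)
        b = a + rng.normal(0, 2, 12)
        base = icc_two_way_random_single(a, b).icc
        assert icc_two_way_random_single(a + 7, b + 7).icc == pytest.approx(base, abs=1e-12)
        assert icc_two_way_random_single(b, a).icc == pytest.approx(base, abs=1e-12)

    def test_recovers_theoretical_icc_of_random_effects_model(self):
        # x_ij = mu + p_i + r_j + e_ij; ICC = sp^2 / (sp^2 + sr^2 + se^2)
        sp, sr, se = 4.0, 1.0, 1.0
        theory = sp**2 / (sp**2 + sr**2 + se**2)
        rng = np.random.default_rng(7)
        vals = []
        for _ in range(200):
            n = 1000
            subj = rng.normal(0, sp, n)
            rat = rng.normal(0, sr, 2)
            x = 10 + subj[:, None] + rat[None, :] + rng.normal(0, se, (n, 2))
            vals.append(icc_two_way_random_single(x[:, 0], x[:, 1]).icc)
        assert np.mean(vals) == pytest.approx(theory, abs=0.02)

    def test_fleiss_categories(self):
        assert fleiss_category(0.84) == "excellent"
        assert fleiss_category(0.69) == "moderate"
        assert fleiss_category(0.39) == "poor"
        assert fleiss_category(0.75) == "excellent"
        assert fleiss_category(0.40) == "moderate"

    def test_error_cases(self):
        with pytest.raises(InsufficientDataError):
            icc_two_way_random_single([1, 2], [1, 2])
        with pytest.raises(DegenerateDataError):
            icc_two_way_random_single([3, 3, 3, 3], [3, 3, 3, 3])


class TestPercentageAgreement:
    def test_identical_vectors(self):
        assert percentage_agreement([3, 5, 7], [3, 5, 7]) == 100.0

    def test_ratio_definition(self):
        assert percentage_agreement([20], [10]) == pytest.approx(50.0)
        assert percentage_agreement([0, 10], [0, 8]) == pytest.approx(90.0)

    def test_bounds_and_identity_condition(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            a = rng.poisson(6, 10)
            b = rng.poisson(6, 10)
            pa = percentage_agreement(a, b)
            assert 0.0 <= pa <= 100.0
            assert (pa == 100.0) == bool((a == b).all())

    def test_negative_counts_rejected(self):
        with pytest.raises(ValidationError):
            percentage_agreement([-1, 2], [1, 2])


class TestBlandAltman:
    def test_identical_vectors_have_zero_limits(self):
        res = bland_altman([2, 4, 6], [2, 4, 6])
        assert res.mean_diff == 0.0
        assert res.loa_low == res.loa_high == 0.0

    def test_hand_computed_example(self):
        res = bland_altman(np.array([1.0, -1.0, 1.0, -1.0]), np.zeros(4))
        assert res.mean_diff == 0.0
        assert res.sd_diff == pytest.approx(np.sqrt(4 / 3))
        assert res.loa_high == pytest.approx(1.96 * np.sqrt(4 / 3))
        assert res.loa_low == pytest.approx(-1.96 * np.sqrt(4 / 3))

    def test_limits_symmetric_about_mean(self):
        rng = np.random.default_rng(4)
        a = rng.poisson(20, 30).astype(float)
        b = rng.poisson(18, 30).astype(float)
        res = bland_altman(a, b)
        assert res.loa_high - res.mean_diff == pytest.approx(res.mean_diff - res.loa_low)

    def test_limits_cover_about_95_percent(self):
        rng = np.random.default_rng(5)
        a = rng.normal(20, 3, 4000)
        b = a + rng.normal(1.0, 2.0, 4000)
        res = bland_altman(a, b)
        inside = ((res.diffs >= res.loa_low) & (res.diffs <= res.loa_high)).mean()
        assert 0.93 <= inside <= 0.97

    def test_too_short_rejected(self):
        with pytest.raises(InsufficientDataError):
            bland_altman([1.0], [2.0])


def _synthetic_gameplay_table():
    """43-participant table (synthetic stand-in for the study's count data)
    whose game-play totals are fixed at 873/945 jumps and 189/243 sidesteps
    for consensus vs system."""
    n = 43
    jump_cons = np.full(n, 20)
    jump_cons[:13] += 1  # 873
    jump_sys = np.full(n, 21)
    jump_sys[:42] += 1  # 945
    side_cons = np.full(n, 4)
    side_cons[:17] += 1  # 189
    side_sys = np.full(n, 5)
    side_sys[:28] += 1  # 243
    rows = []
    for i in range(n):
        rows.append(dict(participant=f"p{i:02d}", condition="gameplay", skill="jump",
                         rater1=int(jump_cons[i]), rater2=int(jump_sys[i] - 1),
                         consensus=int(jump_cons[i]), system=int(jump_sys[i])))
        rows.append(dict(participant=f"p{i:02d}", condition="gameplay", skill="sidestep",
                         rater1=int(side_cons[i]), rater2=int(side_cons[i]),
                         consensus=int(side_cons[i]), system=int(side_sys[i])))
    return CountTable(pd.DataFrame(rows))


class TestReport:
    def test_totals_are_exact_integer_sums(self):
        table = _synthetic_gameplay_table()
        rep = report(table, "sidestep", "gameplay", "consensus_vs_system")
        assert rep["total"] == {"consensus": 189, "system": 243}
        text = format_report(rep)
        assert "189" in text and "243" in text
        rep_j = report(table, "jump", "gameplay", "consensus_vs_system")
        assert rep_j["total"] == {"consensus": 873, "system": 945}

    def test_single_participant_flags_small_n(self):
        df = pd.DataFrame([dict(participant="p0", condition="fms", skill="jump",
                                rater1=3, rater2=3, consensus=3, system=4)])
        rep = report(CountTable(df), "jump", "fms", "consensus_vs_system")
        assert rep["small_n"]
        assert rep["sd"]["consensus"] == 0.0
        assert rep["mean"]["system"] == 4.0
        assert "single participant" in format_report(rep)

    def test_json_and_text_agree(self):
        import json

        table = _synthetic_gameplay_table()
        rep = report(table, "jump", "gameplay", "raters")
        payload = json.loads(report_to_json(rep))
        text = format_report(rep)
        assert f"ICC(2,1) = {payload['icc']['value']:.2f}" in text
        assert f"{payload['percentage_agreement']:.2f}%" in text

    def test_unknown_selector_rejected(self):
        table = _synthetic_gameplay_table()
        with pytest.raises(ValidationError):
            report(table, "cartwheel", "gameplay", "raters")
        with pytest.raises(ValidationError):
            report(table, "jump", "gameplay", "nonsense")


class TestCountTable:
    def test_csv_round_trip(self, tmp_path):
        table = _synthetic_gameplay_table()
        path = tmp_path / "counts.csv"
        table.df.to_csv(path, index=False)
        back = CountTable.from_csv(path)
        pd.testing.assert_frame_equal(back.df, table.df)

    def test_xlsx_with_column_mapping(self, tmp_path):
        table = _synthetic_gameplay_table()
        renamed = table.df.rename(columns={"participant": "ID", "system": "tool count"})
        path = tmp_path / "counts.xlsx"
        renamed.to_excel(path, index=False)
        mapping = {c: c for c in table.df.columns}
        mapping["participant"] = "ID"
        mapping["system"] = "tool count"
        back = CountTable.from_xlsx(path, mapping)
        pd.testing.assert_frame_equal(back.df, table.df)

    def test_invalid_counts_rejected(self):
        df = _synthetic_gameplay_table().df.copy()
        df.loc[0, "system"] = -2
        with pytest.raises(ValidationError, match="negative"):
            CountTable(df)
        df2 = _synthetic_gameplay_table().df.copy()
        df2["rater1"] = df2["rater1"].astype(float)
        df2.loc[0, "rater1"] = 2.5
        with pytest.raises(ValidationError, match="integral"):
            CountTable(df2)
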
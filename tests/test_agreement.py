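import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from datquant.agreement import (
    PairedSURTable,
    agreement_report,
    bland_altman,
    icc_oneway,
    pearson,
    percent_error,
    ttest_two_sample,
    variability,
)


class TestPercentError:
    def test_phantom_worked_example(self):
        # manual 0.77 vs mismatched-template automatic -0.07
        assert percent_error(0.77, -0.07) == pytest.approx(109.0909, abs=0.001)

    def test_equal_pair_is_zero(self):
        assert percent_error(1.234, 1.234) == 0.0

    def test_rounded_table_values_give_their_own_arithmetic(self):
        # 0.77 vs 0.80 -> 3.896%, not a re-rounded figure
        assert percent_error(0.77, 0.80) == pytest.approx(3.8961, abs=1e-3)

    def test_zero_manual_rejected(self):
        with pytest.raises(ValueError):
            percent_error(0.0, 1.0)


class TestVariability:
    @pytest.mark.parametrize(
        "m,a,expected",
        [(0.5, 0.5, 0.0), (0.77, 0.75, 0.02 / 0.76), (1.0, 3.0, 1.0)],
    )
    def test_hand_cases(self, m, a, expected):
        assert variability(m, a) == pytest.approx(expected, abs=1e-12)

    def test_zero_pair_mean_rejected(self):
        with pytest.raises(ValueError):
            variability(1.0, -1.0)


class TestICC:
    def test_perfect_agreement_gives_one(self):
        icc, comp = icc_oneway([(1, 1), (2, 2), (3, 3)])
        assert icc == 1.0
        assert comp.msws == 0.0

    def test_pure_disagreement_gives_minus_one(self):
        icc, comp = icc_oneway([(1, 2), (2, 1)])
        assert comp.msbs == pytest.approx(0.0, abs=1e-12)
        assert comp.msws == pytest.approx(0.5, abs=1e-12)
        assert icc == pytest.approx(-1.0, abs=1e-12)

    def test_matches_pingouin_icc1(self, rng):
        pg = pytest.importorskip("pingouin")
        for _ in range(25):
            n = rng.integers(5, 30)
            pairs = rng.normal(2.0, 1.0, size=(n, 2))
            icc, _ = icc_oneway(pairs)
            df = pd.DataFrame({
                "subject": np.repeat(np.arange(n), 2),
                "rater": np.tile(["m", "a"], n),
                "score": pairs.ravel(),
            })
            ref = pg.intraclass_corr(df, targets="subject", raters="rater",
                                     ratings="score")
            icc1 = float(ref.loc[ref["Type"].str.startswith("ICC1") |
                                 (ref["Type"] == "ICC(1,1)"), "ICC"].iloc[0])
            assert icc == pytest.approx(icc1, abs=1e-10)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            icc_oneway([(1.0, 2.0)])

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.tuples(st.floats(-10, 10), st.floats(-10, 10)), min_size=2, max_size=40))
    def test_icc_bounded_for_paired_data(self, pairs):
        icc, _ = icc_oneway(pairs)
        assert -1.0 - 1e-9 <= icc <= 1.0 + 1e-9


class TestPearson:
    def test_perfect_linear_is_one(self):
        pairs = [(x, 2 * x + 1) for x in (1.0, 2.0, 3.0, 4.0)]
        assert pearson(pairs) == pytest.approx(1.0)

    def test_anti_linear_is_minus_one(self):
        pairs = [(x, -x) for x in (1.0, 2.0, 5.0)]
        assert pearson(pairs) == pytest.approx(-1.0)

    def test_matches_covariance_formula(self, rng):
        pairs = rng.normal(size=(100, 2))
        x, y = pairs[:, 0], pairs[:, 1]
        brute = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
            np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
        assert pearson(pairs) == pytest.approx(brute, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson([(1.0, 2.0), (1.0, 3.0)])


class TestBlandAltman:
    def test_identical_columns(self):
        ba = bland_altman([(1.0, 1.0), (2.0, 2.0), (3.0, 3.0)])
        assert ba.mean_diff == 0.0
        assert ba.loa_low == 0.0 and ba.loa_high == 0.0

    def test_constant_offset(self):
        pairs = [(x, x + 0.5) for x in (1.0, 2.0, 3.0)]
        ba = bland_altman(pairs)
        assert ba.mean_diff == pytest.approx(-0.5)
        assert ba.sd_diff == pytest.approx(0.0, abs=1e-12)

    def test_systematically_higher_automatic_gives_negative_mean_diff(self, rng):
        manual = rng.uniform(0.5, 2.0, 30)
        automatic = manual + rng.uniform(0.2, 0.6, 30)
        ba = bland_altman(np.column_stack([manual, automatic]))
        assert ba.mean_diff < 0

    def test_direction_flip_negates_mean_diff(self, rng):
        pairs = rng.normal(size=(20, 2))
        fwd = bland_altman(pairs, "manual_minus_automatic")
        rev = bland_altman(pairs, "automatic_minus_manual")
        assert fwd.mean_diff == pytest.approx(-rev.mean_diff, abs=1e-12)

    def test_limits_bracket_mean_symmetrically(self, rng):
        pairs = rng.normal(size=(15, 2))
        ba = bland_altman(pairs)
        assert ba.loa_high - ba.mean_diff == pytest.approx(ba.mean_diff - ba.loa_low, abs=1e-12)


class TestTTest:
    def test_equal_groups_t_zero_p_one(self):
        t, p = ttest_two_sample([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_separated_groups_significant(self):
        t, p = ttest_two_sample([1.0, 1.1, 0.9], [9.0, 9.1, 8.9])
        assert p < 0.01

    def test_matches_pooled_variance_formula(self, rng):
        a = rng.normal(0, 1, 12)
        b = rng.normal(0.4, 1.3, 9)
        t, _ = ttest_two_sample(a, b)
        na, nb = len(a), len(b)
        sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
        brute = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
        assert t == pytest.approx(brute, abs=1e-10)


class TestPairedTableAndReport:
    @pytest.fixture()
    def table(self, rng):
        manual = rng.uniform(0.4, 2.2, 20)
        return PairedSURTable(pd.DataFrame({
            "subject_id": [f"s{i}" for i in range(20)],
            "Manual": manual,
            "MBT": manual + rng.normal(0, 0.15, 20),
            "HMPAO": rng.normal(0.2, 0.4, 20),
        }))

    def test_header_synonyms_case_insensitive(self, table):
        assert set(table.methods) == {"mbt", "hmpao"}
        assert table.pairs("MBT").shape == (20, 2)

    def test_perfect_agreement_report(self):
        vals = [0.5, 1.0, 1.5, 2.0]
        t = PairedSURTable(pd.DataFrame({"manual": vals, "auto": vals}))
        rep = agreement_report(t, "auto")
        assert rep.pearson_r == pytest.approx(1.0)
        assert rep.variability_mean == 0.0
        assert rep.icc == 1.0
        assert rep.mean_diff == 0.0

    def test_report_invariant_to_row_order(self, table, rng):
        rep = agreement_report(table, "mbt")
        shuffled = table.data.sample(frac=1.0, random_state=0).reset_index(drop=True)
        rep2 = agreement_report(PairedSURTable(shuffled), "mbt")
        for key in ("pearson_r", "variability_mean", "variability_sd",
                    "mean_diff", "loa_low", "loa_high", "icc"):
            assert rep.to_dict()[key] == pytest.approx(rep2.to_dict()[key], abs=1e-12)

    def test_csv_and_xlsx_give_identical_reports(self, table, tmp_path):
        table.data.to_csv(tmp_path / "t.csv", index=False)
        table.data.to_excel(tmp_path / "t.xlsx", index=False)
        rep_csv = agreement_report(PairedSURTable.from_file(tmp_path / "t.csv"), "mbt")
        rep_xlsx = agreement_report(PairedSURTable.from_file(tmp_path / "t.xlsx"), "mbt")
        assert rep_csv.to_dict() == pytest.approx(rep_xlsx.to_dict())

    def test_column_mapping_override(self, tmp_path, rng):
        df = pd.DataFrame({"hand drawn": [1.0, 2.0], "software": [1.1, 2.1]})
        df.to_csv(tmp_path / "odd.csv", index=False)
        t = PairedSURTable.from_file(tmp_path / "odd.csv",
                                     column_mapping={"hand drawn": "manual", "software": "mbt"})
        assert t.methods == ["mbt"]

    def test_unknown_method_rejected(self, table):
        with pytest.raises(KeyError, match="hbt"):
            table.pairs("hbt")

    def test_duplicate_subjects_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            PairedSURTable(pd.DataFrame({"subject_id": ["a", "a"], "manual": [1, 2],
                                         "mbt": [1, 2]}))


def test_panel_matches_brute_force_on_random_tables():
    """Pearson, Bland-Altman, ICC and variability against plain-formula
    recomputations on 1000 random paired tables."""
    rng = np.random.default_rng(123)
    for _ in range(1000):
        n = int(rng.integers(3, 25))
        x = rng.normal(rng.uniform(-1, 2), rng.uniform(0.2, 1.5), n)
        y = x * rng.uniform(0.2, 1.5) + rng.normal(0, rng.uniform(0.05, 1.0), n)
        pairs = np.column_stack([x, y])

        r_bf = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
            np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
        assert pearson(pairs) == pytest.approx(r_bf, abs=1e-10)

        d = x - y
        ba = bland_altman(pairs)
        assert ba.mean_diff == pytest.approx(d.mean(), abs=1e-12)
        assert ba.loa_high == pytest.approx(d.mean() + 1.96 * d.std(ddof=1), abs=1e-10)

        # one-way ANOVA from scratch: subjects are groups of k=2 ratings
        m_i = pairs.mean(axis=1)
        g = pairs.mean()
        msbs = 2 * np.sum((m_i - g) ** 2) / (n - 1)
        msws = np.sum((pairs - m_i[:, None]) ** 2) / n
        icc_bf = (msbs - msws) / (msbs + msws)
        icc, _ = icc_oneway(pairs)
        assert icc == pytest.approx(icc_bf, abs=1e-10)

        i = int(rng.integers(0, n))
        if (x[i] + y[i]) != 0:
            assert variability(x[i], y[i]) == pytest.approx(
                abs(x[i] - y[i]) / ((x[i] + y[i]) / 2), abs=1e-12)


@settings(max_examples=50, deadline=None)
@given(
    m=st.floats(0.1, 5.0), a=st.floats(0.1, 5.0), c=st.floats(0.01, 100.0),
)
def test_percent_error_and_variability_scale_invariance(m, a, c):
    """Both statistics are ratios: common scaling of the pair cancels."""
    assert percent_error(c * m, c * a) == pytest.approx(percent_error(m, a), rel=1e-9)
    assert variability(c * m, c * a) == pytest.approx(variability(m, a), rel=1e-9)
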
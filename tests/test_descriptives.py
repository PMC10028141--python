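import numpy as np
import pytest
from scipy import stats

from symptomnet import cohort
from symptomnet.datasets import ValidationError
from symptomnet.descriptives import (
    ContingencyTable,
    GroupSummary,
    anova_from_summary,
    chi_square_independence,
    cronbach_alpha,
    describe_dataset,
    proportion_ci,
)
from symptomnet.simulate import make_three_group_study

COHORT_TABLES = {
    "sex": (cohort.SEX_TABLE, 242.4),
    "education": (cohort.EDUCATION_TABLE, 4.4),
    "residence": (cohort.RESIDENCE_TABLE, 13.0),
    "ethnicity": (cohort.ETHNICITY_TABLE, 1.5),
    "family_type": (cohort.FAMILY_TYPE_TABLE, 141.5),
    "income": (cohort.INCOME_TABLE, 15.3),
    "only_child": (cohort.ONLY_CHILD_TABLE, 0.2),
}


def brute_force_chi2(counts: np.ndarray) -> tuple[float, int]:
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    E = np.outer(counts.sum(axis=1), counts.sum(axis=0)) / total
    stat = float(((counts - E) ** 2 / E).sum())
    return stat, (counts.shape[0] - 1) * (counts.shape[1] - 1)


class TestChiSquare:
    @pytest.mark.parametrize("name", sorted(COHORT_TABLES))
    def test_cohort_rows_round_to_published_values(self, name):
        counts, published = COHORT_TABLES[name]
        stat, df, p = chi_square_independence(np.asarray(counts))
        assert round(stat, 1) == published
        assert df == (len(counts) - 1) * 2

    @pytest.mark.parametrize("name", sorted(COHORT_TABLES))
    def test_matches_brute_force_expected_matrix(self, name):
        counts, _ = COHORT_TABLES[name]
        stat, df, _ = chi_square_independence(np.asarray(counts))
        stat_bf, df_bf = brute_force_chi2(counts)
        assert stat == pytest.approx(stat_bf, abs=1e-9)
        assert df == df_bf

    def test_proportional_rows_give_zero(self):
        table = np.array([[10, 20, 30], [20, 40, 60]])
        stat, _, p = chi_square_independence(table)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValidationError, match="marginal"):
            chi_square_independence(np.array([[0, 0], [5, 5]]))

    def test_contingency_type_validation(self):
        with pytest.raises(ValidationError):
            ContingencyTable(np.array([[1, 2]]), ["a"], ["x", "y"])
        with pytest.raises(ValidationError):
            ContingencyTable(np.array([[1, -2], [3, 4]]), ["a", "b"], ["x", "y"])


class TestProportionCI:
    @pytest.mark.parametrize(
        "count,expected",
        [
            (1191, (1.24, 1.17, 1.31)),
            (3479, (3.62, 3.50, 3.73)),
        ],
    )
    def test_published_prevalences_reproduced(self, count, expected):
        est = proportion_ci(count, cohort.TOTAL_SCREENED)
        assert tuple(round(v, 2) for v in est) == expected

    def test_pa_point_estimate(self):
        assert round(proportion_ci(1272, cohort.TOTAL_SCREENED)[0], 2) == 1.32

    def test_zero_count_degenerate_interval_warns(self):
        with pytest.warns(UserWarning, match="degenerate"):
            est = proportion_ci(0, 100)
        assert est == (0.0, 0.0, 0.0)

    def test_count_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            proportion_ci(11, 10)

    def test_width_shrinks_as_inverse_sqrt_n(self):
        _, lo1, hi1 = proportion_ci(30, 100)
        _, lo4, hi4 = proportion_ci(120, 400)
        assert (hi1 - lo1) / (hi4 - lo4) == pytest.approx(2.0)

    def test_wilson_variant_available(self):
        p, lo, hi = proportion_ci(1191, cohort.TOTAL_SCREENED, method="wilson")
        assert round(lo, 2) == 1.17 and round(hi, 2) == 1.31


class TestAnovaFromSummary:
    def _summary(self, instrument):
        rows = cohort.SCALE_SUMMARIES[instrument]
        return GroupSummary(
            n=tuple(cohort.GROUP_SIZES[g] for g in ("EA", "PA", "SA")),
            mean=tuple(rows[g][0] for g in ("EA", "PA", "SA")),
            sd=tuple(rows[g][1] for g in ("EA", "PA", "SA")),
        )

    def test_depression_scale_f_matches_published_to_input_rounding(self):
        f, df1, df2, p = anova_from_summary(self._summary("PHQ9"))
        # summaries are printed at 2 decimals, so agreement is to rounding
        assert 298.0 <= f <= 299.5
        assert (df1, df2) == (2, 5939)
        assert p < 1e-10

    @pytest.mark.parametrize("instrument,published", [("GAD7", 231.4), ("TSQ", 153.3)])
    def test_other_scales_near_published(self, instrument, published):
        f, *_ = anova_from_summary(self._summary(instrument))
        assert abs(f - published) < 1.0

    def test_identical_groups_give_zero(self):
        f, _, _, p = anova_from_summary(
            GroupSummary(n=(50, 50), mean=(3.0, 3.0), sd=(1.0, 1.0))
        )
        assert f == 0.0

    def test_summary_path_equals_raw_data_anova(self):
        rng = np.random.default_rng(0)
        samples = [rng.normal(loc, 1.0, size=n) for loc, n in ((0.0, 40), (0.5, 55), (0.2, 70))]
        summary = GroupSummary(
            n=tuple(len(s) for s in samples),
            mean=tuple(float(s.mean()) for s in samples),
            sd=tuple(float(s.std(ddof=1)) for s in samples),
        )
        f, df1, df2, p = anova_from_summary(summary)
        oracle = stats.f_oneway(*samples)
        assert f == pytest.approx(oracle.statistic, rel=1e-12)
        assert p == pytest.approx(oracle.pvalue, rel=1e-9)

    def test_negative_sd_rejected(self):
        with pytest.raises(ValidationError):
            GroupSummary(n=(5, 5), mean=(1.0, 2.0), sd=(1.0, -0.1))


class TestCronbachAlpha:
    def test_parallel_duplicated_columns_give_one(self):
        col = np.array([0, 1, 2, 3, 1, 2] * 4, dtype=float)
        X = np.column_stack([col, col, col])
        assert cronbach_alpha(X) == pytest.approx(1.0)

    def test_independent_items_near_zero(self):
        rng = np.random.default_rng(1)
        X = rng.integers(0, 4, size=(10_000, 5))
        assert abs(cronbach_alpha(X)) < 0.05

    def test_hand_computed_small_matrix(self):
        X = np.array([[0, 1], [1, 2], [2, 2], [3, 3]], dtype=float)
        k = 2
        expected = k / (k - 1) * (1 - X.var(axis=0, ddof=1).sum() / X.sum(axis=1).var(ddof=1))
        assert cronbach_alpha(X) == pytest.approx(expected)

    def test_matches_pingouin(self):
        import pandas as pd
        import pingouin as pg

        rng = np.random.default_rng(2)
        latent = rng.normal(size=400)
        X = np.column_stack([latent + rng.normal(0, 1, 400) for _ in range(4)])
        alpha = pg.cronbach_alpha(pd.DataFrame(X))[0]
        assert cronbach_alpha(X) == pytest.approx(alpha, abs=1e-10)

    def test_zero_total_variance_rejected(self):
        with pytest.raises(ValidationError):
            cronbach_alpha(np.array([[1, 2], [2, 1], [1, 2]]))


class TestDescribeDataset:
    def test_synthetic_study_summary_shape_and_group_gradient(self):
        ds = make_three_group_study(seed=3, sizes=(300, 300, 300))
        out = describe_dataset(ds)
        assert out["groups"] == ["EA", "PA", "SA"]
        phq = out["scales"]["PHQ9"]
        # thresholds make EA the most severe group by construction
        assert phq["mean"]["EA"] > phq["mean"]["PA"] > phq["mean"]["SA"]
        assert phq["anova"]["p"] < 0.001
        assert 0.0 < phq["cronbach_alpha"] < 1.0
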
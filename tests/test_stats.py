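"""Agreement and diagnostic statistics against independent oracles."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import stats as sps

from lvfractal.stats import (
    DegenerateDataError,
    bland_altman,
    clopper_pearson_interval,
    diagnostic_metrics,
    fleiss_kappa,
    group_tests,
    icc_absolute_agreement,
    pearson_corr,
    rank_sum_test,
    roc_auc_and_youden,
    welch_t_test,
)

# ---------------------------------------------------------------------------
# worked 6-subject, 2-rater ICC table.  Expected value computed by hand from
# the two-way ANOVA mean squares before the implementation was written:
#   data rows (rater1, rater2): (7,9) (5,6) (8,8) (2,4) (6,5) (9,9)
#   grand mean 6.5; MSR = 2*var(row means) -> SSR=2*sum((rm-6.5)^2)=33.5, MSR=6.7
#   SSC = 6*((6.1667-6.5)^2+(6.8333-6.5)^2) = 1.3333, MSC = 1.3333
#   SST = 53; SSE = 53-33.5-1.3333 = 18.1667... recomputed exactly below
# ---------------------------------------------------------------------------
ICC_TABLE = np.array([[7, 9], [5, 6], [8, 8], [2, 4], [6, 5], [9, 9]], dtype=float)


def icc21_brute_force(x):
    """Variance-component oracle, written independently of stats.py."""
    n, k = x.shape
    grand = x.mean()
    msr = k * ((x.mean(axis=1) - grand) ** 2).sum() / (n - 1)
    msc = n * ((x.mean(axis=0) - grand) ** 2).sum() / (k - 1)
    sse = ((x - grand) ** 2).sum() - (n - 1) * msr - (k - 1) * msc
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


class TestICC:
    def test_identical_columns_give_one(self):
        x = np.column_stack([[1.0, 2.0, 3.0, 4.0]] * 2)
        res = icc_absolute_agreement(x)
        assert res.value == pytest.approx(1.0)

    def test_worked_table_matches_variance_components(self):
        res = icc_absolute_agreement(ICC_TABLE)
        assert res.value == pytest.approx(icc21_brute_force(ICC_TABLE), abs=1e-12)
        assert res.ci_lower <= res.value <= res.ci_upper

    def test_matches_pingouin_reference(self):
        """Cross-check ICC(2,1) and its CI against an independent package."""
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        n = ICC_TABLE.shape[0]
        df = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(n), 2),
                "rater": np.tile([0, 1], n),
                "score": ICC_TABLE.ravel(),
            }
        )
        ref = pingouin.intraclass_corr(
            df, targets="subject", raters="rater", ratings="score"
        ).set_index("Type").loc["ICC(A,1)"]
        res = icc_absolute_agreement(ICC_TABLE)
        assert res.value == pytest.approx(float(ref["ICC"]), abs=1e-9)
        assert res.ci_lower == pytest.approx(ref["CI95"][0], abs=0.01)
        assert res.ci_upper == pytest.approx(ref["CI95"][1], abs=0.01)

    def test_independent_noise_gives_near_zero(self):
        rng = np.random.default_rng(0)
        x = np.column_stack([rng.normal(0, 1, 200), rng.normal(0, 1, 200)])
        res = icc_absolute_agreement(x)
        assert abs(res.value) < 0.15
        assert res.value == pytest.approx(icc21_brute_force(x), abs=1e-12)

    def test_degenerate_data_rejected(self):
        with pytest.raises(DegenerateDataError):
            icc_absolute_agreement(np.full((5, 2), 3.0))
        with pytest.raises(DegenerateDataError):
            icc_absolute_agreement(np.array([[1.0, 2.0]]))


class TestBlandAltman:
    def test_identical_pairs(self):
        ba = bland_altman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert ba.bias == 0.0 and ba.loa_lower == 0.0 and ba.loa_upper == 0.0

    def test_three_pair_hand_computation(self):
        # d = {-0.1, 0.1, -0.2}; bias = -0.0667; sd = 0.15275 (ddof=1)
        ba = bland_altman([1.0, 2.0, 3.0], [1.1, 1.9, 3.2])
        d = np.array([-0.1, 0.1, -0.2])
        assert ba.bias == pytest.approx(d.mean())
        assert ba.loa_lower == pytest.approx(d.mean() - 1.96 * d.std(ddof=1))
        assert ba.loa_upper == pytest.approx(d.mean() + 1.96 * d.std(ddof=1))

    def test_swapping_columns_negates_bias_and_mirrors_limits(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(0, 1, 30), rng.normal(0, 1, 30)
        ab, ba_ = bland_altman(x, y), bland_altman(y, x)
        assert ab.bias == pytest.approx(-ba_.bias)
        assert ab.loa_lower == pytest.approx(-ba_.loa_upper)
        assert ab.loa_upper == pytest.approx(-ba_.loa_lower)

    def test_too_few_pairs(self):
        with pytest.raises(DegenerateDataError):
            bland_altman([1.0, 2.0], [1.0, 2.0])


def auc_concordance_oracle(scores, labels):
    """Pairwise concordant fraction (+1/2 per tie), brute force."""
    scores = np.asarray(scores)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = conc = 0.0
    for p in pos:
        for q in neg:
            total += 1
            if p > q:
                conc += 1
            elif p == q:
                conc += 0.5
    return conc / total


class TestROC:
    def test_perfect_separation(self):
        scores = [0.1, 0.2, 0.3, 0.8, 0.9, 1.0]
        labels = [0, 0, 0, 1, 1, 1]
        auc, thr, j = roc_auc_and_youden(scores, labels)
        assert auc == 1.0 and j == 1.0
        assert 0.3 < thr <= 0.8

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_auc_equals_concordant_pair_fraction(self, seed):
        rng = np.random.default_rng(seed)
        n = 50
        scores = np.round(rng.normal(0, 1, n), 1)  # rounding forces ties
        labels = (rng.random(n) < 0.4).astype(int)
        if len(np.unique(labels)) < 2:
            labels[0], labels[1] = 0, 1
        auc, thr, j = roc_auc_and_youden(scores, labels)
        assert auc == pytest.approx(auc_concordance_oracle(scores, labels))
        # reported J equals the brute-force maximum over all thresholds
        # (including the degenerate "call nothing positive" one)
        def j_at(t):
            sens = np.mean(scores[labels == 1] >= t)
            spec = np.mean(scores[labels == 0] < t)
            return sens + spec - 1

        candidates = list(np.unique(scores)) + [np.inf]
        assert j == pytest.approx(max(j_at(t) for t in candidates))

    def test_uninformative_scores_give_auc_near_half(self):
        rng = np.random.default_rng(42)
        scores = rng.normal(0, 1, 200)
        labels = rng.permutation([0, 1] * 100)
        auc, _, _ = roc_auc_and_youden(scores, labels)
        assert abs(auc - 0.5) < 0.08

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateDataError):
            roc_auc_and_youden([1.0, 2.0, 3.0], [1, 1, 1])


def fleiss_oracle(table):
    """Textbook Fleiss computation from a subject x category count table."""
    table = np.asarray(table, dtype=float)
    n_sub, _ = table.shape
    n_rat = table[0].sum()
    p_j = table.sum(axis=0) / (n_sub * n_rat)
    p_i = ((table**2).sum(axis=1) - n_rat) / (n_rat * (n_rat - 1))
    p_bar, p_e = p_i.mean(), (p_j**2).sum()
    return (p_bar - p_e) / (1 - p_e)


class TestFleissKappa:
    def test_unanimous_ratings_give_one(self):
        ratings = np.array([[0, 0, 0], [1, 1, 1], [2, 2, 2], [1, 1, 1]])
        assert fleiss_kappa(ratings) == pytest.approx(1.0)

    def test_worked_three_by_three_table(self):
        ratings = np.array([[0, 0, 1], [1, 1, 1], [0, 2, 2]])
        # count table rows: [2,1,0],[0,3,0],[1,0,2]
        expected = fleiss_oracle([[2, 1, 0], [0, 3, 0], [1, 0, 2]])
        assert fleiss_kappa(ratings) == pytest.approx(expected, abs=1e-12)

    def test_random_ratings_near_zero(self):
        rng = np.random.default_rng(3)
        ratings = rng.integers(0, 3, size=(500, 4))
        assert abs(fleiss_kappa(ratings)) < 0.1

    def test_degenerate_shapes_rejected(self):
        with pytest.raises(DegenerateDataError):
            fleiss_kappa(np.array([[0, 1]]))
        with pytest.raises(DegenerateDataError):
            fleiss_kappa(np.array([[0], [1]]))


def clopper_pearson_oracle(x, n, alpha=0.05):
    """CI by direct search over the binomial CDF (grid inversion)."""
    grid = np.linspace(0, 1, 200001)
    # lower limit: largest p with P(X >= x | p) <= alpha/2
    upper_tail = 1 - sps.binom.cdf(x - 1, n, grid)
    lo = 0.0 if x == 0 else grid[upper_tail <= alpha / 2].max()
    lower_tail = sps.binom.cdf(x, n, grid)
    hi = 1.0 if x == n else grid[lower_tail <= alpha / 2].min()
    return lo, hi


class TestDiagnostics:
    def test_perfect_sensitivity_upper_ci_is_one(self):
        m = diagnostic_metrics(tp=10, fp=0, tn=5, fn=0)
        assert m["sensitivity"].value == 1.0
        assert m["sensitivity"].ci_upper == 1.0

    def test_exact_interval_matches_cdf_inversion(self):
        for x, n in [(8, 10), (1, 12), (0, 7), (7, 7), (15, 30)]:
            lo, hi = clopper_pearson_interval(x, n)
            olo, ohi = clopper_pearson_oracle(x, n)
            assert lo == pytest.approx(olo, abs=2e-4)
            assert hi == pytest.approx(ohi, abs=2e-4)

    def test_sens_spec_swap_symmetry(self):
        a = diagnostic_metrics(tp=8, fp=3, tn=14, fn=2)
        b = diagnostic_metrics(tp=14, fp=2, tn=8, fn=3)
        assert a["sensitivity"].value == b["specificity"].value
        assert a["specificity"].value == b["sensitivity"].value

    def test_zero_denominator_reported_undefined(self):
        m = diagnostic_metrics(tp=0, fp=0, tn=10, fn=0)
        assert np.isnan(m["sensitivity"].value)
        assert (m["sensitivity"].ci_lower, m["sensitivity"].ci_upper) == (0.0, 1.0)

    def test_exact_interval_coverage_on_simulation_grid(self):
        """Empirical coverage >= nominal on p x n grid, 2000 reps each."""
        rng = np.random.default_rng(12345)
        for p in (0.1, 0.5, 0.9):
            for n in (10, 30):
                draws = rng.binomial(n, p, size=2000)
                covered = 0
                for x in np.unique(draws):
                    lo, hi = clopper_pearson_interval(int(x), n)
                    covered += ((lo <= p) & (p <= hi)) * np.sum(draws == x)
                assert covered / 2000 >= 0.95 - 0.015


class TestGroupTests:
    def test_identical_groups_high_p(self):
        _, p = rank_sum_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p > 0.9

    def test_fully_separated_tiny_groups_minimal_exact_p(self):
        # n=3,3 exact: most extreme of C(6,3)=20 arrangements -> p = 2/20
        _, p = rank_sum_test([1.0, 2.0, 3.0], [101.0, 102.0, 103.0])
        assert p == pytest.approx(0.1)

    def test_pearson_of_affine_pair_is_one(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        r, _ = pearson_corr(x, 2 * x + 1)
        assert r == pytest.approx(1.0)

    def test_constant_inputs_rejected(self):
        with pytest.raises(DegenerateDataError):
            rank_sum_test([2.0, 2.0, 2.0], [2.0, 2.0, 2.0])
        with pytest.raises(DegenerateDataError):
            welch_t_test([1.0, 1.0, 1.0], [2.0, 2.0, 2.0])
        with pytest.raises(DegenerateDataError):
            pearson_corr([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_pairwise_structure(self):
        groups = {
            "lvnc": [5.0, 6.0, 7.0, 8.0],
            "hyper": [3.0, 4.0, 5.0, 5.5],
            "normal": [1.0, 2.0, 2.5, 3.0],
        }
        out = group_tests(groups)
        assert set(out) == {"lvnc_vs_hyper", "hyper_vs_normal"}
        for cmp in out.values():
            assert 0 <= cmp["rank_sum_p"] <= 1
            assert cmp["mean_a"] > cmp["mean_b"]
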
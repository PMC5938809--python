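import math

import numpy as np
import pandas as pd
import pytest

import paraspinal as pp
from paraspinal.exceptions import CompletenessError, GridMismatchError


def _mask(arr, **kw):
    defaults = dict(muscle="multifidus", side="left", method=2, subject_id="s1")
    defaults.update(kw)
    return pp.RoiMask(np.asarray(arr, dtype=bool), **defaults)


def icc_oracle_loops(grid):
    """Independent ICC(A,k) oracle: mean squares from explicit double loops."""
    n, k = grid.shape
    grand = sum(grid[i][j] for i in range(n) for j in range(k)) / (n * k)
    row_means = [sum(grid[i][j] for j in range(k)) / k for i in range(n)]
    col_means = [sum(grid[i][j] for i in range(n)) / n for j in range(k)]
    msr = k * sum((rm - grand) ** 2 for rm in row_means) / (n - 1)
    msc = n * sum((cm - grand) ** 2 for cm in col_means) / (k - 1)
    sse = sum(
        (grid[i][j] - row_means[i] - col_means[j] + grand) ** 2
        for i in range(n) for j in range(k)
    )
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (msc - mse) / n)


class TestAreaFractionOverlap:
    def test_identical_masks(self):
        base = np.zeros((8, 8)); base[2:6, 2:6] = 1
        res = pp.area_fraction_overlap([_mask(base, rater_id=f"r{i}") for i in range(3)])
        assert res.fraction == 1.0
        assert res.n_common == res.n_union == 16

    def test_disjoint_masks(self):
        a = np.zeros((8, 8)); a[:2] = 1
        b = np.zeros((8, 8)); b[6:] = 1
        res = pp.area_fraction_overlap([_mask(a), _mask(b, rater_id="r2")])
        assert res.fraction == 0.0

    def test_nested_masks_brute_force(self):
        # C (50 px) inside B inside A, union 100 px -> overlap 0.5
        a = np.zeros((10, 10)); a.flat[:100] = 1
        b = np.zeros((10, 10)); b.flat[:80] = 1
        c = np.zeros((10, 10)); c.flat[:50] = 1
        res = pp.area_fraction_overlap(
            [_mask(a), _mask(b, rater_id="r2"), _mask(c, rater_id="r3")]
        )
        assert res.fraction == 0.5
        assert res.n_common == 50 and res.n_union == 100

    def test_permutation_invariance(self, grade1_rater_masks):
        m2 = [m for m in grade1_rater_masks if m.method == 2]
        f1 = pp.area_fraction_overlap(m2).fraction
        f2 = pp.area_fraction_overlap(m2[::-1]).fraction
        assert f1 == f2

    def test_at_most_pairwise(self, grade1_rater_masks):
        m2 = [m for m in grade1_rater_masks if m.method == 2]
        triple = pp.area_fraction_overlap(m2).fraction
        for i, j in [(0, 1), (0, 2), (1, 2)]:
            assert triple <= pp.area_fraction_overlap([m2[i], m2[j]]).fraction

    def test_grid_mismatch_rejected(self):
        with pytest.raises(GridMismatchError):
            pp.area_fraction_overlap(
                [_mask(np.ones((4, 4))), _mask(np.ones((5, 5)), rater_id="r2")]
            )

    def test_mixed_labels_rejected(self):
        with pytest.raises(ValueError, match="labels"):
            pp.area_fraction_overlap(
                [_mask(np.ones((4, 4))), _mask(np.ones((4, 4)), method=1)]
            )

    def test_empty_union_flagged(self):
        res = pp.area_fraction_overlap(
            [_mask(np.zeros((4, 4))), _mask(np.zeros((4, 4)), rater_id="r2")]
        )
        assert res.fraction == 0.0 and res.empty_union


class TestICC:
    def test_perfect_agreement(self):
        grid = np.tile(np.arange(5, dtype=float)[:, None], (1, 3))
        res = pp.icc_absolute_agreement_k(grid)
        assert res.estimate == 1.0
        assert res.interpretation == "excellent"

    def test_location_invariance(self, rng):
        grid = rng.normal(size=(12, 3))
        a = pp.icc_absolute_agreement_k(grid).estimate
        b = pp.icc_absolute_agreement_k(grid + 17.3).estimate
        assert a == pytest.approx(b, abs=1e-12)

    def test_matches_explicit_loop_oracle(self):
        grid = np.array([
            [9, 2, 5], [6, 1, 3], [8, 4, 6], [7, 1, 2], [10, 5, 6], [6, 2, 4]
        ], dtype=float)
        res = pp.icc_absolute_agreement_k(grid)
        assert res.estimate == pytest.approx(icc_oracle_loops(grid), abs=1e-10)

    def test_matches_pingouin_cross_check(self, rng):
        pingouin = pytest.importorskip("pingouin")
        grid = rng.normal(size=(15, 3)) + rng.normal(size=(15, 1)) * 2
        df = pd.DataFrame({
            "subject": np.repeat(np.arange(15), 3),
            "rater": np.tile(np.arange(3), 15),
            "score": grid.ravel(),
        })
        ref = pingouin.intraclass_corr(df, targets="subject", raters="rater",
                                       ratings="score")
        mask = ref["Type"].isin(["ICC2k", "ICC(A,k)"])
        row = ref[mask].iloc[0]
        ci_col = "CI95%" if "CI95%" in ref.columns else "CI95"
        res = pp.icc_absolute_agreement_k(grid)
        assert res.estimate == pytest.approx(row["ICC"], abs=1e-8)
        # pingouin rounds the interval to two decimals
        assert res.ci_low == pytest.approx(row[ci_col][0], abs=6e-3)
        assert res.ci_high == pytest.approx(row[ci_col][1], abs=6e-3)

    def test_long_table_accepted(self):
        df = pp.simulate_score_table(pp.ScoreSimParams(n_subjects=10, seed=4))
        res = pp.icc_absolute_agreement_k(df)
        assert res.n == 10 and res.k == 3
        assert res.ci_low <= res.estimate <= res.ci_high

    def test_missing_cells_rejected(self):
        df = pd.DataFrame({
            "subject": ["a", "a", "b"], "rater": ["r1", "r2", "r1"],
            "score": [1.0, 2.0, 3.0],
        })
        with pytest.raises(CompletenessError):
            pp.icc_absolute_agreement_k(df)

    def test_degenerate_no_subject_variance(self):
        grid = np.tile(np.array([[1.0, 2.0, 3.0]]), (5, 1))
        res = pp.icc_absolute_agreement_k(grid)
        assert res.degenerate
        assert res.estimate <= 0

    @pytest.mark.parametrize(
        "value,band",
        [(0.2, "poor"), (0.39999, "poor"), (0.40, "fair"), (0.59, "fair"),
         (0.60, "good"), (0.74, "good"), (0.75, "excellent"), (0.99, "excellent")],
    )
    def test_cicchetti_bands(self, value, band):
        assert pp.interpret_icc(value) == band


class TestBetweenRaterCV:
    def test_no_dispersion(self):
        assert pp.between_rater_cv([10, 10, 10]).cv == 0.0

    def test_hand_arithmetic(self):
        rec = pp.between_rater_cv([1, 2, 3])
        assert rec.cv == pytest.approx(0.5)
        assert rec.measure_value == 2.0

    def test_nonpositive_mean_flagged(self):
        rec = pp.between_rater_cv([-1.0, 1.0])
        assert rec.undefined and math.isnan(rec.cv)

    def test_single_value_rejected(self):
        with pytest.raises(ValueError):
            pp.between_rater_cv([5.0])

    def test_monte_carlo_matches_sigma_over_mu(self, rng):
        # triples from N(5, 0.4): mean CV tracks sigma/mu = 0.08
        vals = rng.normal(5.0, 0.4, size=(1000, 3))
        cvs = [pp.between_rater_cv(row).cv for row in vals]
        assert np.mean(cvs) == pytest.approx(0.08, abs=0.01)
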
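import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from segrel.classic_metrics import (
    icc_oneway,
    krippendorff_alpha_interval,
    pct_within_tolerance,
    reliability_matrix,
    sensitivity_sweep,
)
from segrel.deviations import reference_medians
from segrel.mixture_reliability import PsoConfig


# --- independent oracles ---------------------------------------------------


def alpha_by_pair_enumeration(values: np.ndarray) -> float:
    """Brute-force interval alpha: explicit loops over all ordered pairs."""
    units = [row[~np.isnan(row)] for row in values]
    units = [u for u in units if len(u) >= 2]
    pooled = np.concatenate(units)
    n = len(pooled)
    d_obs = 0.0
    for u in units:
        m = len(u)
        pair_sum = 0.0
        for i in range(m):
            for j in range(m):
                if i != j:
                    pair_sum += (u[i] - u[j]) ** 2
        d_obs += pair_sum / (m - 1)
    d_obs /= n
    d_exp = 0.0
    for i in range(n):
        for j in range(n):
            if i != j:
                d_exp += (pooled[i] - pooled[j]) ** 2
    d_exp /= n * (n - 1)
    return 1.0 - d_obs / d_exp


def icc_by_anova_decomposition(values: np.ndarray) -> float:
    """Direct one-way ANOVA mean squares, written out longhand."""
    groups = [row[~np.isnan(row)] for row in values]
    groups = [g for g in groups if len(g) >= 1]
    all_vals = np.concatenate(groups)
    grand = all_vals.mean()
    n_units = len(groups)
    total_n = len(all_vals)
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    msb = ssb / (n_units - 1)
    msw = ssw / (total_n - n_units)
    k0 = (total_n - sum(len(g) ** 2 for g in groups) / total_n) / (n_units - 1)
    return (msb - msw) / (msb + (k0 - 1) * msw)


# --- Krippendorff's alpha --------------------------------------------------


class TestAlpha:
    def test_perfect_agreement_is_exactly_one(self):
        rng = np.random.default_rng(0)
        units = rng.normal(0, 1000, size=50)
        m = pd.DataFrame(np.tile(units[:, None], (1, 4)))
        assert krippendorff_alpha_interval(m) == 1.0

    def test_two_by_two_crossed_matches_hand_value(self):
        m = pd.DataFrame([[1.0, 2.0], [2.0, 1.0]])
        assert krippendorff_alpha_interval(m) == pytest.approx(-0.5, abs=1e-12)
        assert krippendorff_alpha_interval(m) == pytest.approx(
            alpha_by_pair_enumeration(m.to_numpy()), abs=1e-12
        )

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_pair_enumeration_oracle_with_missing(self, seed):
        rng = np.random.default_rng(seed)
        values = rng.normal(0, 10, size=(6, 4))
        mask = rng.uniform(size=values.shape) < 0.25
        values[mask] = np.nan
        counts = np.sum(~np.isnan(values), axis=1)
        values[counts < 2] = np.nan  # drop unpairable units entirely
        if np.sum(~np.isnan(values)) < 4:
            pytest.skip("degenerate draw")
        m = pd.DataFrame(values)
        assert krippendorff_alpha_interval(m) == pytest.approx(
            alpha_by_pair_enumeration(values), abs=1e-12
        )

    def test_missing_rater_column_leaves_alpha_unchanged(self):
        rng = np.random.default_rng(3)
        values = rng.normal(0, 5, size=(10, 3))
        m = pd.DataFrame(values)
        extended = m.copy()
        extended["ghost"] = np.nan
        assert krippendorff_alpha_interval(extended) == krippendorff_alpha_interval(m)

    def test_all_values_identical_is_an_error_not_a_number(self):
        m = pd.DataFrame(np.full((4, 3), 7.0))
        with pytest.raises(ValueError, match="undefined"):
            krippendorff_alpha_interval(m)

    @given(st.floats(min_value=-1e4, max_value=1e4), st.integers(0, 3))
    def test_invariant_to_shift_and_rater_permutation(self, shift, rotation):
        rng = np.random.default_rng(8)
        values = rng.normal(0, 5, size=(8, 4))
        base = krippendorff_alpha_interval(pd.DataFrame(values))
        shifted = np.roll(values + shift, rotation, axis=1)
        assert krippendorff_alpha_interval(pd.DataFrame(shifted)) == pytest.approx(
            base, abs=1e-9
        )


# --- ICC -------------------------------------------------------------------


class TestIcc:
    def test_identical_within_units_gives_one(self):
        units = np.arange(5, dtype=float) * 100
        m = pd.DataFrame(np.tile(units[:, None], (1, 3)))
        assert icc_oneway(m) == pytest.approx(1.0)

    def test_matches_anova_oracle_on_small_fixture(self):
        values = np.array([[1.0, 2.0], [4.0, 6.0], [9.0, 7.0]])
        m = pd.DataFrame(values)
        assert icc_oneway(m) == pytest.approx(
            icc_by_anova_decomposition(values), abs=1e-12
        )

    def test_matches_anova_oracle_unbalanced(self):
        rng = np.random.default_rng(21)
        values = rng.normal(0, 4, size=(7, 4))
        values[0, 3] = np.nan
        values[4, 1:] = np.nan
        m = pd.DataFrame(values)
        assert icc_oneway(m) == pytest.approx(
            icc_by_anova_decomposition(values), abs=1e-12
        )

    def test_dominant_within_unit_variance_is_negative(self):
        rng = np.random.default_rng(2)
        values = rng.normal(0, 50, size=(10, 4))  # no between-unit structure
        values -= values.mean(axis=1, keepdims=True)  # remove what little there is
        assert icc_oneway(pd.DataFrame(values)) < 0

    def test_matches_pingouin_icc1(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(4)
        values = rng.normal(0, 3, size=(12, 4)) + rng.normal(0, 8, size=(12, 1))
        long = pd.DataFrame(
            {
                "targets": np.repeat(np.arange(12), 4),
                "raters": np.tile(np.arange(4), 12),
                "ratings": values.ravel(),
            }
        )
        ref = pingouin.intraclass_corr(
            long, targets="targets", raters="raters", ratings="ratings"
        )
        icc1 = ref.loc[ref["Type"].isin(["ICC1", "ICC(1,1)"]), "ICC"].iloc[0]
        assert icc_oneway(pd.DataFrame(values)) == pytest.approx(icc1, abs=1e-9)


# --- percentage within tolerance -------------------------------------------


class TestPctWithin:
    @pytest.mark.parametrize(
        "devs, tol, expected",
        [([0, 5, -30], 10, 2 / 3), ([0, 5, -30], 1e9, 1.0), ([10, -10, 10], 10, 1.0)],
    )
    def test_examples_inclusive_boundary(self, devs, tol, expected):
        assert pct_within_tolerance(devs, tol) == pytest.approx(expected)

    @given(st.lists(st.floats(-100, 100), min_size=1, max_size=30))
    def test_monotone_in_tolerance(self, devs):
        tols = [1.0, 5.0, 20.0, 100.0]
        vals = [pct_within_tolerance(devs, t) for t in tols]
        assert vals == sorted(vals)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            pct_within_tolerance([], 5)


# --- sensitivity sweep ------------------------------------------------------


def _sweep_annotations(n_tokens=60, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    centers = rng.uniform(0, 100_000, n_tokens)
    for t in range(n_tokens):
        for a in range(3):
            rows.append(
                (f"T{t}", "t1", 1, "w", "S1", "medium", "baseline", f"a{a}",
                 "onset", centers[t] + rng.normal(0, 3))
            )
    from segrel.annotation_io import ANNOTATION_COLUMNS

    return pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)


class TestSensitivitySweep:
    def test_identity_tweak_reproduces_untweaked_metrics(self):
        ann = _sweep_annotations()
        refs = reference_medians(ann)
        result = sensitivity_sweep(
            ann, refs, [1.0], [0.0], [10.0], seed=0,
            pso_config=PsoConfig(n_particles=8, max_iter=50),
        )
        matrix = reliability_matrix(ann)
        assert result.loc[0, "alpha"] == pytest.approx(
            krippendorff_alpha_interval(matrix), abs=1e-12
        )
        assert result.loc[0, "icc"] == pytest.approx(icc_oneway(matrix), abs=1e-12)

    def test_collapsed_deviations_give_perfect_scores(self):
        ann = _sweep_annotations()
        refs = reference_medians(ann)
        result = sensitivity_sweep(
            ann, refs, [0.0], [0.0], [5.0], seed=0,
            pso_config=PsoConfig(n_particles=8, max_iter=50),
        )
        assert result.loc[0, "alpha"] == pytest.approx(1.0, abs=1e-12)
        assert result.loc[0, "pct_within_5"] == 1.0

    def test_reproducible_under_seed(self):
        ann = _sweep_annotations()
        refs = reference_medians(ann)
        kwargs = dict(pso_config=PsoConfig(n_particles=8, max_iter=50))
        a = sensitivity_sweep(ann, refs, [1.0, 2.0], [0.0, 1.0], [10.0], 7, **kwargs)
        b = sensitivity_sweep(ann, refs, [1.0, 2.0], [0.0, 1.0], [10.0], 7, **kwargs)
        pd.testing.assert_frame_equal(a, b)
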
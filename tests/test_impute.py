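"""Missingness classification rules and imputation contracts."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu

from evfrac.impute import (
    DEFAULT_FRACTION_CUTOFFS,
    MAR,
    MNAR,
    CutoffSet,
    classify_missingness,
    hybrid_impute,
    impute_mar,
    impute_mnar,
)

from conftest import make_matrix


def cell_label(cls, protein, sample):
    row = cls[(cls["protein"] == protein) & (cls["sample"] == sample)]
    assert len(row) == 1
    return row["label"].iloc[0]


class TestClassifyMissingness:
    def test_absent_in_fraction_is_mnar(self, small_design):
        rng = np.random.default_rng(0)
        values = rng.normal(20, 1, size=(3, len(small_design)))
        m = make_matrix(small_design, values)
        f2 = m.fraction_columns(2)
        m.values.loc["P0", f2] = np.nan  # completely absent from fraction 2
        cls = classify_missingness(m, CutoffSet())
        labels = cls[(cls["protein"] == "P0") & (cls["fraction"] == 2)]
        assert (labels["label"] == MNAR).all()
        assert labels["basis"].isna().all()

    def test_fraction_mean_below_cutoff_is_mnar(self, small_design):
        """Fraction-4 mean 13.0 against the printed cutoff 14.3 -> MNAR."""
        assert DEFAULT_FRACTION_CUTOFFS[4] == 14.3
        values = np.full((1, len(small_design)), 20.0)
        m = make_matrix(small_design, values)
        f4 = m.fraction_columns(4)
        m.values.loc["P0", f4[0]] = np.nan
        m.values.loc["P0", f4[1:]] = 13.0
        cls = classify_missingness(m, CutoffSet())
        assert cell_label(cls, "P0", f4[0]) == MNAR
        assert np.isclose(cls["basis"].iloc[0], 13.0)

    def test_fraction_mean_above_cutoff_is_mar(self, small_design):
        values = np.full((1, len(small_design)), 20.0)
        m = make_matrix(small_design, values)
        f4 = m.fraction_columns(4)
        m.values.loc["P0", f4[0]] = np.nan
        cls = classify_missingness(m, CutoffSet())
        assert cell_label(cls, "P0", f4[0]) == MAR

    def test_toy_labels_equal_exhaustive_rule_evaluation(self, small_design):
        rng = np.random.default_rng(5)
        values = rng.normal(15, 2, size=(5, len(small_design)))
        values[rng.random(values.shape) < 0.35] = np.nan
        m = make_matrix(small_design, values)
        cutoffs = CutoffSet()
        cls = classify_missingness(m, cutoffs)

        seen = set()
        for acc in m.accessions:
            for sample in m.samples:
                if not np.isnan(m.values.at[acc, sample]):
                    continue
                fraction = int(m.design.set_index("sample").at[sample, "fraction"])
                cols = m.fraction_columns(fraction)
                observed = m.values.loc[acc, cols].dropna()
                if len(observed) == 0 or observed.mean() < cutoffs[fraction]:
                    expected = MNAR
                else:
                    expected = MAR
                assert cell_label(cls, acc, sample) == expected
                seen.add((acc, sample))
        assert len(cls) == len(seen)  # covers every missing cell exactly once

    def test_missing_fraction_cutoff_rejected(self, small_design):
        values = np.full((1, len(small_design)), 20.0)
        m = make_matrix(small_design, values)
        m.values.iloc[0, 0] = np.nan
        with pytest.raises(KeyError, match="fraction 1"):
            classify_missingness(m, CutoffSet(cutoffs={2: 14.0}))

    def test_raising_cutoff_only_converts_mar_to_mnar(self, small_design):
        rng = np.random.default_rng(8)
        values = rng.normal(15, 2, size=(20, len(small_design)))
        values[rng.random(values.shape) < 0.3] = np.nan
        m = make_matrix(small_design, values)
        lo = classify_missingness(m, CutoffSet.uniform(13.0)).set_index(["protein", "sample"])
        hi = classify_missingness(m, CutoffSet.uniform(16.0)).set_index(["protein", "sample"])
        assert set(lo.index) == set(hi.index)
        flipped = lo["label"] != hi.loc[lo.index, "label"]
        assert (lo.loc[flipped, "label"] == MAR).all()
        assert (hi.loc[lo.index[flipped], "label"] == MNAR).all()


class TestImputeMnar:
    def test_no_mnar_cells_leaves_matrix_unchanged(self, small_design):
        values = np.full((2, len(small_design)), 20.0)
        m = make_matrix(small_design, values)
        m.values.iloc[0, 0] = np.nan  # MAR: mean 20 above any cutoff
        cls = classify_missingness(m, CutoffSet())
        out = impute_mnar(m, cls, seed=0)
        pd.testing.assert_frame_equal(out.values, m.values)

    def test_draws_match_direct_reimplementation(self, small_design):
        rng = np.random.default_rng(9)
        values = rng.normal(12, 2, size=(10, len(small_design)))
        m = make_matrix(small_design, values)
        m.values.iloc[0:4, 0] = np.nan
        m.values.iloc[2:6, 5] = np.nan
        cls = classify_missingness(m, CutoffSet.uniform(30.0))  # everything MNAR
        out = impute_mnar(m, cls, shift=1.8, width=0.3, seed=42)

        replay = np.random.default_rng(42)
        expected = m.values.copy()
        mnar = cls[cls["label"] == MNAR]
        for sample, cells in mnar.groupby("sample", sort=True):
            obs = m.values[sample].dropna()
            mu, sigma = obs.mean(), obs.std(ddof=1)
            draws = replay.normal(mu - 1.8 * sigma, 0.3 * sigma, size=len(cells))
            expected.loc[cells["protein"].to_numpy(), sample] = draws
        pd.testing.assert_frame_equal(out.values, expected)

    def test_imputed_mean_matches_closed_form_moment(self, small_design):
        """Mean of many imputed values in one sample ~ mu_s - 1.8 sigma_s."""
        rng = np.random.default_rng(10)
        n = 20_000
        values = rng.normal(15, 2, size=(n, len(small_design)))
        m = make_matrix(small_design, values)
        target = m.samples[0]
        missing_rows = m.accessions[: n // 2]
        m.values.loc[missing_rows, target] = np.nan
        cls = classify_missingness(m, CutoffSet.uniform(40.0))
        obs = m.values[target].dropna()
        mu, sigma = obs.mean(), obs.std(ddof=1)
        out = impute_mnar(m, cls, seed=3)
        imputed = out.values.loc[missing_rows, target]
        mc_se = 0.3 * sigma / np.sqrt(len(imputed))
        assert abs(imputed.mean() - (mu - 1.8 * sigma)) < 3 * mc_se

    def test_too_few_observed_values_rejected(self, tiny_design):
        values = np.full((4, 6), 20.0)
        values[0:3, 0] = np.nan
        m = make_matrix(tiny_design, values)
        cls = classify_missingness(m, CutoffSet.uniform(30.0))
        with pytest.raises(ValueError, match="observed values"):
            impute_mnar(m, cls, seed=0)


class TestImputeMar:
    def test_constant_neighbours_impute_their_value(self, small_design):
        values = np.full((12, len(small_design)), 20.0)
        values[0] = 20.0
        m = make_matrix(small_design, values)
        m.values.iloc[0, 3] = np.nan
        cls = classify_missingness(m, CutoffSet.uniform(10.0))  # mean 20 -> MAR
        out, report = impute_mar(m, cls, k=10)
        assert out.values.iloc[0, 3] == 20.0
        assert report.empty

    def test_no_mar_cells_leaves_matrix_unchanged(self, small_design):
        values = np.full((3, len(small_design)), 20.0)
        m = make_matrix(small_design, values)
        cls = classify_missingness(m, CutoffSet())
        out, _ = impute_mar(m, cls, k=5)
        pd.testing.assert_frame_equal(out.values, m.values)

    def test_toy_values_equal_exhaustive_knn(self, tiny_design):
        rng = np.random.default_rng(12)
        values = rng.normal(20, 3, size=(6, 6))
        m = make_matrix(tiny_design, values)
        m.values.iloc[0, 2] = np.nan
        cls = classify_missingness(m, CutoffSet.uniform(5.0))
        k = 2
        out, _ = impute_mar(m, cls, k=k)

        # brute force: nan-euclidean over jointly observed samples
        target_row = m.values.iloc[0].to_numpy()
        dists = {}
        for i in range(1, 6):
            other = m.values.iloc[i].to_numpy()
            joint = ~np.isnan(target_row) & ~np.isnan(other)
            d2 = np.mean((target_row[joint] - other[joint]) ** 2) * 6
            dists[i] = np.sqrt(d2)
        eligible = sorted(
            (i for i in dists if not np.isnan(m.values.iloc[i, 2])),
            key=lambda i: dists[i],
        )[:k]
        expected = np.mean([m.values.iloc[i, 2] for i in eligible])
        assert np.isclose(out.values.iloc[0, 2], expected)

    def test_no_neighbour_falls_back_to_group_mean(self, tiny_design):
        values = np.full((2, 6), 20.0)
        m = make_matrix(tiny_design, values)
        # column 0 (group F1-3) missing in every protein: no donor rows
        m.values.iloc[:, 0] = np.nan
        m.values.iloc[0, 1] = 24.0
        cls = classify_missingness(m, CutoffSet.uniform(5.0))
        out, report = impute_mar(m, cls, k=3)
        assert not out.values.isna().any().any()
        assert (report["fallback"] == "fraction-group mean").all()
        # fraction-group F1-3 of protein 0 spans columns 0-1 -> mean of 24.0
        assert out.values.iloc[0, 0] == 24.0


class TestHybridImpute:
    def test_complete_input_is_identity(self, small_design):
        values = np.random.default_rng(1).normal(20, 2, size=(5, len(small_design)))
        m = make_matrix(small_design, values)
        out, cls, report = hybrid_impute(m, seed=0)
        pd.testing.assert_frame_equal(out.values, m.values)
        assert report["n_missing"] == 0 and cls.empty

    def test_observed_cells_bit_identical_and_output_complete(self, reduced_study):
        m = reduced_study.observed
        out, cls, report = hybrid_impute(m, CutoffSet.uniform(12.0), seed=5)
        assert not out.values.isna().any().any()
        mask = m.mask.to_numpy()
        assert np.array_equal(
            out.values.to_numpy()[mask], m.values.to_numpy()[mask]
        )
        assert report["n_missing"] == int((~mask).sum())
        assert report["n_mnar"] + report["n_mar"] == report["n_missing"]

    def test_mnar_imputed_lower_than_mar_imputed(self, reduced_study):
        m = reduced_study.observed
        out, cls, _ = hybrid_impute(m, CutoffSet.uniform(12.0), seed=5)
        # samples are drawn on a common scale, so pool imputed cells
        by_label = {
            label: [out.values.at[p, s] for p, s, l in
                    zip(cls["protein"], cls["sample"], cls["label"]) if l == label]
            for label in (MNAR, MAR)
        }
        assert len(by_label[MNAR]) >= 100 and len(by_label[MAR]) >= 100
        assert mannwhitneyu(by_label[MNAR], by_label[MAR], alternative="less").pvalue < 1e-6
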
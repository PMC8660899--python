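"""riBAQ, detection filters, replicate averaging, quantile and count normalization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import ovodiff as od
from ovodiff.normalize import (
    average_replicates,
    compute_ribaq,
    filter_constitutive,
    filter_min_detection,
    log_transform,
    normalize_counts,
    quantile_normalize,
    size_factors_median_of_ratios,
)


def _two_sample_matrix(col1, col2):
    design = pd.DataFrame(
        {
            "sample_id": ["s1", "s2"],
            "stage": ["oocyte", "oocyte"],
            "treatment": ["superovulation", "natural"],
            "replicate": [1, 1],
        }
    )
    values = pd.DataFrame({"s1": col1, "s2": col2},
                          index=[f"g{i}" for i in range(len(col1))])
    return od.ExpressionMatrix.from_values(values, design)


class TestRibaq:
    def test_molar_fractions(self):
        mat = _two_sample_matrix([2.0, 3.0, 5.0], [1.0, 1.0, 2.0])
        out = compute_ribaq(mat)
        assert np.allclose(out.values["s1"], [0.2, 0.3, 0.5])

    def test_undetected_stay_undetected(self):
        mat = _two_sample_matrix([1.0, 0.0, 0.0], [1.0, 1.0, 1.0])
        out = compute_ribaq(mat)
        assert out.values.loc["g0", "s1"] == 1.0
        assert not out.detected.loc["g1", "s1"]
        assert out.values.loc["g1", "s1"] == 0.0

    @given(st.lists(st.floats(0.1, 1e6), min_size=2, max_size=12))
    def test_detected_values_sum_to_one(self, intensities):
        mat = _two_sample_matrix(intensities, intensities)
        out = compute_ribaq(mat)
        assert abs(out.values["s1"].sum() - 1.0) < 1e-12

    def test_all_zero_sample_errors(self):
        mat = _two_sample_matrix([1.0, 2.0], [0.0, 0.0])
        with pytest.raises(ValueError, match="all-zero"):
            compute_ribaq(mat)


class TestDetectionFilters:
    def test_min_detection_boundary(self, default_proteome):
        matrix, _ = default_proteome
        filtered, report = filter_min_detection(matrix, min_samples=2)
        n_det = matrix.detected.sum(axis=1)
        assert set(filtered.feature_ids) == set(matrix.values.index[n_det >= 2])
        assert (filtered.detected.sum(axis=1) >= 2).all()
        assert report.n_input_features == matrix.n_features
        assert report.n_after_min_detection == filtered.n_features

    def test_min_detection_zero_is_identity(self, default_proteome):
        matrix, _ = default_proteome
        filtered, _ = filter_min_detection(matrix, min_samples=0)
        assert filtered.n_features == matrix.n_features

    def test_constitutive_definition(self, full_design):
        rng = np.random.default_rng(0)
        values = pd.DataFrame(
            rng.uniform(1, 2, size=(3, len(full_design))),
            index=["keep", "drop", "partial"],
            columns=full_design.index,
        )
        # 'drop': undetected in both replicates of (morula, natural)
        for col in ("morula_natural_r1", "morula_natural_r2"):
            values.loc["drop", col] = 0.0
        # 'partial': undetected in one replicate only -> still constitutive
        values.loc["partial", "morula_natural_r1"] = 0.0
        mat = od.ExpressionMatrix.from_values(values, full_design)
        kept = filter_constitutive(mat)
        assert set(kept.feature_ids) == {"keep", "partial"}

    def test_constitutive_idempotent_and_empty_ok(self, default_proteome):
        matrix, _ = default_proteome
        once = filter_constitutive(matrix)
        twice = filter_constitutive(once)
        assert once.feature_ids == twice.feature_ids
        empty = matrix.subset_features([])
        assert filter_constitutive(empty).n_features == 0

    def test_missing_design_cell_errors(self, full_design):
        sub = full_design[full_design.index != "morula_natural_r1"]
        sub = sub[sub.index != "morula_natural_r2"]
        rng = np.random.default_rng(0)
        values = pd.DataFrame(
            rng.uniform(1, 2, size=(2, len(sub))), index=["a", "b"], columns=sub.index
        )
        mat = od.ExpressionMatrix.from_values(values, sub)
        with pytest.raises(od.datamodel.DesignError, match="morula"):
            filter_constitutive(mat)


class TestAverageReplicates:
    def test_rules(self, full_design):
        values = pd.DataFrame(
            1.0, index=["f"], columns=full_design.index
        )
        values.loc["f", "oocyte_superovulation_r1"] = 0.2
        values.loc["f", "oocyte_superovulation_r2"] = 0.4
        values.loc["f", "oocyte_natural_r1"] = 0.2
        values.loc["f", "oocyte_natural_r2"] = 0.0      # single detected value
        values.loc["f", "1-cell_natural_r1"] = 0.0
        values.loc["f", "1-cell_natural_r2"] = 0.0      # both undetected
        mat = od.ExpressionMatrix.from_values(values, full_design)
        avg = average_replicates(mat)
        assert avg.values.loc["f", "oocyte_superovulation"] == pytest.approx(0.3)
        assert avg.values.loc["f", "oocyte_natural"] == pytest.approx(0.2)
        assert not avg.detected.loc["f", "1-cell_natural"]
        assert avg.n_samples == 14


class TestQuantileNormalize:
    def test_mean_of_order_statistics(self):
        mat = _two_sample_matrix([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        out, ref = quantile_normalize(mat)
        assert np.allclose(out.values["s1"], [2.5, 3.5, 4.5])
        assert np.allclose(out.values["s2"], [2.5, 3.5, 4.5])
        assert np.allclose(ref, [2.5, 3.5, 4.5])

    def test_identical_columns_unchanged(self):
        mat = _two_sample_matrix([1.0, 2.0, 7.0], [1.0, 2.0, 7.0])
        out, _ = quantile_normalize(mat)
        assert np.allclose(out.values.to_numpy(), mat.values.to_numpy())

    def test_column_means_equal_and_idempotent(self):
        rng = np.random.default_rng(1)
        mat = _two_sample_matrix(rng.lognormal(size=40), rng.lognormal(1.0, size=40))
        out, _ = quantile_normalize(mat)
        means = out.values.mean(axis=0)
        assert np.allclose(means.iloc[0], means.iloc[1])
        again, _ = quantile_normalize(out)
        assert np.allclose(again.values.to_numpy(), out.values.to_numpy())

    def test_ties_get_mean_of_reference_values(self):
        mat = _two_sample_matrix([1.0, 1.0, 3.0], [4.0, 5.0, 6.0])
        out, ref = quantile_normalize(mat)
        # tied pair in s1 shares the mean of the two lowest reference values
        assert out.values.loc["g0", "s1"] == out.values.loc["g1", "s1"]
        assert out.values.loc["g0", "s1"] == pytest.approx((ref[0] + ref[1]) / 2)


class TestLogTransform:
    def test_log10_values(self):
        mat = _two_sample_matrix([100.0, 1.0], [10.0, 1.0])
        out = log_transform(mat, base=10)
        assert out.values.loc["g0", "s1"] == pytest.approx(2.0)
        assert out.values.loc["g1", "s1"] == pytest.approx(0.0)
        assert out.scale == "log10"

    def test_round_trip(self):
        from ovodiff.normalize import delog_transform

        mat = _two_sample_matrix([100.0, 0.0], [10.0, 2.0])
        back = delog_transform(log_transform(mat, base=10))
        assert np.allclose(back.values.to_numpy(), mat.values.to_numpy())
        assert back.detected.equals(mat.detected)

    def test_bad_base_errors(self):
        mat = _two_sample_matrix([1.0], [1.0])
        with pytest.raises(ValueError, match="base"):
            log_transform(mat, base=3)


class TestNormalizeCounts:
    def _count_matrix(self, cols):
        design = pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(len(cols))],
                "stage": ["oocyte"] * len(cols),
                "treatment": ["superovulation", "natural"] * (len(cols) // 2)
                or ["superovulation"],
                "replicate": [1 + i // 2 for i in range(len(cols))],
            }
        )
        values = pd.DataFrame(
            {f"s{i}": c for i, c in enumerate(cols)},
            index=[f"g{j}" for j in range(len(cols[0]))],
        )
        return od.ExpressionMatrix.from_values(values, design, modality="transcript")

    def test_doubled_library_gives_sqrt2_factors(self):
        mat = self._count_matrix([[10, 20, 30], [20, 40, 60]])
        _, report = normalize_counts(mat)
        assert np.allclose(report.size_factors, [1 / np.sqrt(2), np.sqrt(2)])

    def test_identical_samples_unit_factors(self):
        mat = self._count_matrix([[5, 9, 14], [5, 9, 14]])
        _, report = normalize_counts(mat)
        assert np.allclose(report.size_factors, [1.0, 1.0])

    def test_scaling_equivariance(self):
        base = [[10, 20, 30], [7, 21, 35]]
        sf1 = size_factors_median_of_ratios(
            self._count_matrix(base).values
        )
        scaled = [[10, 20, 30], [21, 63, 105]]
        sf2 = size_factors_median_of_ratios(
            self._count_matrix(scaled).values
        )
        assert sf2["s1"] / sf1["s1"] == pytest.approx(3.0 ** 0.5, rel=1e-9)

    def test_no_all_positive_feature_errors(self):
        mat = self._count_matrix([[0, 3], [2, 0]])
        with pytest.raises(ValueError, match="pseudocount"):
            normalize_counts(mat)
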
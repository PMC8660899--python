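"""Exact sign-flip permutation test, BH correction, fold-change census."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import ovodiff as od
from ovodiff.de import (
    abundance_shift_check,
    bh_adjust,
    classify_up_down,
    exact_permutation_pvalue,
    fold_change_census,
    monte_carlo_pvalue,
    naive_signflip_pvalue,
    paired_de_test,
    signed_rank_statistic,
)


class TestSignedRankStatistic:
    @pytest.mark.parametrize(
        "d, expected",
        [
            ([1, -2, 3], 2.0),       # signed ranks 1 - 2 + 3
            ([1, 1, 1], 6.0),        # tied -> mid-rank 2 each
            ([0, 0], 0.0),           # zero-exclusion leaves nothing
            ([-1, -2], -3.0),
        ],
    )
    def test_examples(self, d, expected):
        assert signed_rank_statistic(d) == expected

    def test_pratt_keeps_zero_ranks(self):
        # |d| = [0, 1, 2]: ranks 1,2,3; zeros excluded from the sum only
        assert signed_rank_statistic([0.0, 1.0, 2.0], zero_policy="pratt") == 5.0


class TestExactPermutationPvalue:
    @pytest.mark.parametrize(
        "d, expected",
        [
            ([1.0, 2.0, 3.0], 2 / 8),          # all same sign, n = 3
            ([1, 2, 3, 4, 5, 6, 7], 2 / 128),  # stage-level floor, n = 7
            ([1.0, -1.0], 1.0),                # T_obs = 0
            ([], 1.0),
        ],
    )
    def test_examples(self, d, expected):
        assert exact_permutation_pvalue(d) == pytest.approx(expected, abs=0)

    def test_matches_naive_oracle_on_random_instances(self):
        rng = np.random.default_rng(11)
        for _ in range(60):
            n = int(rng.integers(1, 9))
            d = np.round(rng.normal(size=n), 2)
            if rng.random() < 0.3:  # provoke ties and zeros
                d = np.round(d, 0)
            assert exact_permutation_pvalue(d) == pytest.approx(
                naive_signflip_pvalue(d), abs=1e-12
            )

    def test_enumeration_bound_errors(self):
        d = np.arange(1, 23, dtype=float)
        with pytest.raises(ValueError, match="Monte|monte"):
            exact_permutation_pvalue(d)

    def test_monte_carlo_is_seeded_and_close_to_exact(self):
        d = np.array([0.5, 1.2, -0.3, 2.2, 0.9, 1.1, -0.2, 0.8])
        p1 = monte_carlo_pvalue(d, n_resamples=4000, seed=5)
        p2 = monte_carlo_pvalue(d, n_resamples=4000, seed=5)
        assert p1 == p2
        assert p1 == pytest.approx(exact_permutation_pvalue(d), abs=0.02)

    def test_floor_is_two_over_two_to_n(self):
        for n in (3, 7, 10, 14):
            d = np.arange(1, n + 1, dtype=float)
            assert exact_permutation_pvalue(d) == 2 / 2**n


class TestBHAdjust:
    def test_hand_stepped_example(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_and_degenerate(self):
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)
        assert np.allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)
        assert bh_adjust([]).size == 0

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @given(
        st.lists(st.floats(0.0, 1.0, allow_nan=False), min_size=1, max_size=40)
    )
    def test_qvalues_dominate_p_and_preserve_order(self, p):
        p = np.asarray(p)
        q = bh_adjust(p)
        assert (q <= 1.0 + 1e-12).all()
        assert (q >= p / len(p) - 1e-12).all()
        order = np.argsort(p, kind="stable")
        assert (np.diff(q[order]) >= -1e-12).all()


def _shifted_matrix(n_features=50, delta=1.0, noise=0.1, frac=0.2, seed=3):
    """Averaged-layout log10 matrix with a constant treatment shift on a
    labelled feature subset (all seven stage differences share the sign)."""
    design_rows = [
        (f"{s}_{t}", s, t, 1) for s in od.STAGES for t in od.TREATMENTS
    ]
    design = pd.DataFrame(
        design_rows, columns=["sample_id", "stage", "treatment", "replicate"]
    )
    rng = np.random.default_rng(seed)
    base = rng.normal(-5, 1, size=(n_features, 1))
    values = {}
    n_shift = int(frac * n_features)
    for sid, stage, treatment, _ in design_rows:
        x = base[:, 0] + rng.normal(0, noise, size=n_features)
        if treatment == "superovulation":
            x[:n_shift] += delta
        values[sid] = x
    frame = pd.DataFrame(values, index=[f"g{i}" for i in range(n_features)])
    mat = od.ExpressionMatrix.from_values(
        frame, design, scale="log10", modality="protein"
    )
    return mat, [f"g{i}" for i in range(n_shift)]


class TestPairedDETest:
    def test_shifted_features_hit_the_stage_pairing_floor(self):
        mat, shifted = _shifted_matrix()
        res = paired_de_test(mat, pairing="stage")
        assert np.allclose(res.loc[shifted, "p_exact"], 2 / 128)
        assert (res.loc[shifted, "direction"] == "up").all()

    def test_duplicating_features_changes_no_p_or_q(self):
        mat, _ = _shifted_matrix(n_features=30)
        res = paired_de_test(mat, pairing="stage")
        doubled = od.ExpressionMatrix(
            pd.concat([mat.values, mat.values.set_axis(
                [f"{i}_dup" for i in mat.feature_ids])]),
            pd.concat([mat.detected, mat.detected.set_axis(
                [f"{i}_dup" for i in mat.feature_ids])]),
            mat.design, scale="log10", modality="protein",
        )
        res2 = paired_de_test(doubled, pairing="stage")
        assert np.allclose(
            res["p_exact"], res2.loc[res.index, "p_exact"]
        )
        assert np.allclose(res["q_bh"], res2.loc[res.index, "q_bh"])

    def test_insufficient_pairs_flagged_not_dropped(self):
        mat, _ = _shifted_matrix(n_features=5)
        det = mat.detected.copy()
        det.iloc[0, :] = False
        det.iloc[0, 0] = True  # a single detected column -> < 2 pairs
        vals = mat.values.where(det)
        crippled = od.ExpressionMatrix(
            vals, det, mat.design, scale="log10", modality="protein"
        )
        res = paired_de_test(crippled, pairing="stage")
        fid = mat.feature_ids[0]
        assert res.loc[fid, "insufficient_pairs"]
        assert res.loc[fid, "p_exact"] == 1.0

    def test_replicate_pairing_doubles_the_pairs(self, default_proteome_run):
        de = default_proteome_run.de
        assert de["n_pairs"].max() == 14
        assert de["p_exact"].min() >= 2 / 2**14


class TestFoldChangeCensus:
    def _linear_matrix(self, fc_at_8cell):
        design_rows = [
            (f"{s}_{t}", s, t, 1) for s in od.STAGES for t in od.TREATMENTS
        ]
        design = pd.DataFrame(
            design_rows, columns=["sample_id", "stage", "treatment", "replicate"]
        )
        values = pd.DataFrame(
            {sid: [1.0] for sid, *_ in design_rows}, index=["f"]
        )
        values.loc["f", "8-cell_superovulation"] = fc_at_8cell
        return od.ExpressionMatrix.from_values(values, design)

    def test_boundary_is_inclusive(self):
        census = fold_change_census(self._linear_matrix(4.0))
        assert census.loc["8-cell", 4] == 1
        assert census.loc["8-cell", 5] == 0

    def test_reciprocal_fold_changes_count(self):
        census = fold_change_census(self._linear_matrix(0.25))
        assert census.loc["8-cell", 4] == 1

    def test_identical_profiles_give_zero(self):
        census = fold_change_census(self._linear_matrix(1.0))
        assert (census.to_numpy() == 0).all()

    def test_counts_non_increasing_in_threshold(self, default_proteome_run):
        census = default_proteome_run.census
        assert (census.to_numpy()[:, :-1] >= census.to_numpy()[:, 1:]).all()


class TestClassifyUpDown:
    def test_twofold_exact_not_counted(self):
        res = pd.DataFrame(
            {
                "significant": [True, True, True],
                "max_abs_fc": [2.0, 2.5, 3.0],
                "direction": ["up", "up", "down"],
            },
            index=["a", "b", "c"],
        )
        assert classify_up_down(res, fc_cut=2.0) == (1, 1)

    def test_empty_input(self):
        assert classify_up_down(pd.DataFrame()) == (0, 0)


class TestAbundanceShift:
    def test_shifted_subset_detected(self, default_proteome):
        matrix, truth = default_proteome
        # affected features are drawn with an abundance bias -> higher riBAQ
        from ovodiff.normalize import compute_ribaq

        ribaq = compute_ribaq(matrix)
        out = abundance_shift_check(ribaq, truth.de_ids())
        assert out["p_value"] < 1e-6
        assert out["median_shift_log10"] > 0

    def test_full_or_empty_subset_errors(self, default_proteome):
        matrix, _ = default_proteome
        with pytest.raises(ValueError):
            abundance_shift_check(matrix, [])
        with pytest.raises(ValueError):
            abundance_shift_check(matrix, matrix.feature_ids)
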
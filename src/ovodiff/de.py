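"""Stage-paired exact permutation test on the Wilcoxon signed-rank statistic.

For each feature, the superovulation and natural-ovulation expression
values are paired — by developmental stage (seven pairs) or by stage and
replicate (up to fourteen pairs) — and the per-pair differences d_s are
reduced to the signed-rank statistic T = sum sign(d_i) * rank(|d_i|).
Significance is assessed with the *exact* sign-flip permutation
distribution: under the null of no treatment effect the sign of every
difference is exchangeable, so all 2^n sign assignments on the fixed
absolute ranks are enumerated and the two-sided p-value is the fraction of
assignments with |T*| >= |T_obs|.  This is distribution-free and valid at
finite n, at the cost of a discrete p-value floor of 2 / 2^n.

P-values are corrected across all tested features with Benjamini-Hochberg
step-up FDR control.

Ties receive mid-ranks; zero differences are dropped before ranking by
default (classical zero-exclusion), with Pratt's zero-rank variant
available via ``zero_policy="pratt"``.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from statsmodels.stats.multitest import multipletests

from .datamodel import STAGES, ExpressionMatrix

#: Full-enumeration bound: 2^20 sign assignments is the largest table kept.
ENUMERATION_LIMIT = 20


@dataclass
class PairedVector:
    """Per-feature stage-paired differences (superovulation - natural)."""

    feature_id: str
    differences: np.ndarray

    def __post_init__(self) -> None:
        self.differences = np.asarray(self.differences, dtype=float)
        self.differences = self.differences[np.isfinite(self.differences)]

    @property
    def n_pairs(self) -> int:
        return self.differences.size

    @property
    def n_nonzero(self) -> int:
        return int(np.count_nonzero(self.differences))


def _prepare(d, zero_policy: str = "exclude") -> tuple[np.ndarray, np.ndarray]:
    """Signed half-integer ranks as integers (2x rank) and their signs.

    Returns (ranks2, signs) over the differences that carry a sign.  Under
    ``exclude``, zeros are removed before ranking; under ``pratt``, zeros
    participate in the ranking of absolute values but contribute no signed
    term.  Working in doubled ranks keeps mid-ranks exactly representable
    as integers, so tail counts are exact.
    """
    d = np.asarray(d, dtype=float)
    d = d[np.isfinite(d)]
    if zero_policy == "exclude":
        d = d[d != 0]
        if d.size == 0:
            return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
        ranks2 = np.round(2 * rankdata(np.abs(d))).astype(np.int64)
        return ranks2, np.sign(d).astype(np.int64)
    elif zero_policy == "pratt":
        if d.size == 0 or not np.any(d):
            return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
        ranks2 = np.round(2 * rankdata(np.abs(d))).astype(np.int64)
        nz = d != 0
        return ranks2[nz], np.sign(d[nz]).astype(np.int64)
    raise ValueError(f"unknown zero_policy {zero_policy!r}")


def signed_rank_statistic(d, zero_policy: str = "exclude") -> float:
    """T = sum of signed mid-ranks of |d|; zeros handled per policy.

    With no nonzero difference the statistic is defined as 0.
    """
    ranks2, signs = _prepare(d, zero_policy)
    return float((signs * ranks2).sum()) / 2.0


@lru_cache(maxsize=4096)
def _signflip_tail_table(ranks2: tuple[int, ...]) -> tuple[np.ndarray, int]:
    """Sorted |T*| values (doubled scale) over all 2^n sign assignments."""
    t = np.zeros(1, dtype=np.int64)
    for r in ranks2:
        t = np.concatenate([t + r, t - r])
    return np.sort(np.abs(t)), t.size


def _pvalue_from_table(ranks2: np.ndarray, t2_obs: int) -> float:
    table, total = _signflip_tail_table(tuple(int(r) for r in ranks2))
    idx = np.searchsorted(table, abs(int(t2_obs)), side="left")
    return float(total - idx) / total


def exact_permutation_pvalue(
    d, zero_policy: str = "exclude", enumeration_limit: int = ENUMERATION_LIMIT
) -> float:
    """Two-sided exact sign-flip p-value for the signed-rank statistic.

    Enumerates all 2^n sign assignments on the fixed absolute ranks;
    p = #{|T*| >= |T_obs|} / 2^n.  With no signed difference, p = 1.  The
    smallest attainable p is 2 / 2^n.  Errors out beyond the enumeration
    bound rather than silently approximating.
    """
    ranks2, signs = _prepare(d, zero_policy)
    n = ranks2.size
    if n == 0:
        return 1.0
    if n > enumeration_limit:
        raise ValueError(
            f"{n} signed differences exceed the full-enumeration bound "
            f"({enumeration_limit}); use monte_carlo_pvalue with an explicit seed"
        )
    return _pvalue_from_table(ranks2, int((signs * ranks2).sum()))


def monte_carlo_pvalue(
    d, n_resamples: int, seed: int, zero_policy: str = "exclude"
) -> float:
    """Seeded Monte-Carlo approximation of the sign-flip p-value.

    Uses the add-one estimator (observed assignment counted in the tail),
    so the result is a valid p-value for any number of resamples.
    """
    ranks2, signs = _prepare(d, zero_policy)
    if ranks2.size == 0:
        return 1.0
    rng = np.random.default_rng(seed)
    t_obs = abs(int((signs * ranks2).sum()))
    flips = rng.choice([-1, 1], size=(n_resamples, ranks2.size))
    t_star = np.abs(flips @ ranks2)
    return (1.0 + float((t_star >= t_obs).sum())) / (n_resamples + 1.0)


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values), clipped to 1."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def build_paired_differences(
    matrix: ExpressionMatrix, pairing: str = "stage"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-feature difference vectors (superovulation minus natural).

    ``pairing="stage"`` yields one difference per stage, computed between
    the treatment means over detected replicates (a no-op when the matrix
    is already replicate-averaged).  ``pairing="stage_replicate"`` pairs
    replicate k of one treatment with replicate k of the other within each
    stage, giving up to stages x replicates differences.  Incomplete pairs
    are NaN.

    Returns (differences, stage_differences); the latter always has one
    column per stage and feeds the per-stage fold changes.
    """
    if matrix.scale == "linear":
        raise ValueError("paired differences expect log-scale expression values")
    groups = matrix.group_columns()
    values, detected = matrix.values, matrix.detected

    def cell_mean(stage: str, treatment: str) -> pd.Series:
        sids = groups.get((stage, treatment), [])
        if not sids:
            return pd.Series(np.nan, index=values.index)
        return values[sids].where(detected[sids]).mean(axis=1)

    stage_diffs = pd.DataFrame(
        {s: cell_mean(s, "superovulation") - cell_mean(s, "natural") for s in STAGES}
    )
    if pairing == "stage":
        return stage_diffs.copy(), stage_diffs
    if pairing != "stage_replicate":
        raise ValueError(f"pairing must be 'stage' or 'stage_replicate', got {pairing!r}")

    cols = {}
    for stage in STAGES:
        sup = matrix.design[
            (matrix.design["stage"] == stage)
            & (matrix.design["treatment"] == "superovulation")
        ].sort_values("replicate")
        nat = matrix.design[
            (matrix.design["stage"] == stage)
            & (matrix.design["treatment"] == "natural")
        ].sort_values("replicate")
        for (sid_s, _), (sid_n, _) in zip(sup.iterrows(), nat.iterrows()):
            a = values[sid_s].where(detected[sid_s])
            b = values[sid_n].where(detected[sid_n])
            cols[f"{stage}_pair{len(cols)}"] = a - b
    return pd.DataFrame(cols), stage_diffs


def paired_de_test(
    matrix: ExpressionMatrix,
    pairing: str = "stage",
    alpha_fdr: float = 0.1,
    fc_cut: float = 2.0,
    zero_policy: str = "exclude",
    enumeration_limit: int = ENUMERATION_LIMIT,
) -> pd.DataFrame:
    """Per-feature exact paired permutation test with BH FDR.

    Expects a normalized log-scale matrix (typically restricted to
    constitutive features).  Returns one row per feature with the
    signed-rank statistic ``T``, the exact two-sided permutation p-value,
    the BH ``q``, per-stage fold changes on the linear scale of the
    matrix's log base, the maximal fold change ``max_abs_fc`` (as
    max(FC, 1/FC)), a direction call by the sign of the median stage
    log-fold-change, and a ``significant`` flag (q < ``alpha_fdr``).

    Features with fewer than two complete pairs are reported with p = 1
    and ``insufficient_pairs=True`` rather than dropped.  BH is applied
    once across all tested features.
    """
    diffs, stage_diffs = build_paired_differences(matrix, pairing)
    base = 10.0 if matrix.scale == "log10" else 2.0
    d_arr = diffs.to_numpy(dtype=float)

    n_pairs = np.isfinite(d_arr).sum(axis=1)
    rows = []
    for i, fid in enumerate(diffs.index):
        d = d_arr[i]
        d = d[np.isfinite(d)]
        insufficient = d.size < 2
        t = signed_rank_statistic(d, zero_policy)
        ranks2, signs = _prepare(d, zero_policy)
        if insufficient or ranks2.size == 0:
            p = 1.0
        else:
            p = _pvalue_from_table(ranks2, int((signs * ranks2).sum()))
        rows.append((fid, int(n_pairs[i]), int(ranks2.size), t, p, insufficient))
    result = pd.DataFrame(
        rows,
        columns=["feature_id", "n_pairs", "n_nonzero", "T", "p_exact", "insufficient_pairs"],
    ).set_index("feature_id")
    result["q_bh"] = bh_adjust(result["p_exact"].to_numpy())
    result["significant"] = result["q_bh"] < alpha_fdr

    fcs = base ** stage_diffs
    fcs.columns = [f"fc_{s}" for s in stage_diffs.columns]
    result = result.join(fcs)
    log_fc = stage_diffs.to_numpy(dtype=float)
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
        abs_fc = base ** np.abs(log_fc)
        result["max_abs_fc"] = np.nanmax(
            np.where(np.isfinite(abs_fc), abs_fc, np.nan), axis=1
        )
        med = np.nanmedian(log_fc, axis=1)
    result["direction"] = np.select([med > 0, med < 0], ["up", "down"], default="none")
    result.attrs["pairing"] = pairing
    result.attrs["alpha_fdr"] = alpha_fdr
    result.attrs["fc_cut"] = fc_cut
    return result


def classify_up_down(results: pd.DataFrame, fc_cut: float = 2.0) -> tuple[int, int]:
    """Count significant features altered strictly beyond ``fc_cut``-fold.

    Direction is the sign of the median stage log-fold-change; a feature
    is counted only if its maximal stage fold change strictly exceeds the
    cut ("in excess of" two-fold, so FC = 2.0 exactly is not counted).
    """
    if results.empty:
        return (0, 0)
    sig = results[results["significant"] & (results["max_abs_fc"] > fc_cut)]
    return int((sig["direction"] == "up").sum()), int((sig["direction"] == "down").sum())


def fold_change_census(
    matrix: ExpressionMatrix,
    thresholds=(4, 5, 6, 7, 8),
) -> pd.DataFrame:
    """Stage x threshold census of strong treatment fold changes.

    Operates on a linear, replicate-averaged matrix.  At each stage the
    fold change is the superovulation/natural ratio of the averaged linear
    values; a feature is counted at threshold t if max(FC, 1/FC) >= t.
    Features undetected in either treatment at a stage are excluded from
    that stage's census (no infinite fold changes).
    """
    if matrix.scale != "linear":
        raise ValueError("census expects a linear-scale matrix")
    groups = matrix.group_columns()
    counts = {}
    for stage in STAGES:
        sup_ids = groups.get((stage, "superovulation"), [])
        nat_ids = groups.get((stage, "natural"), [])
        if not sup_ids or not nat_ids:
            counts[stage] = {int(t): 0 for t in thresholds}
            continue
        ok = matrix.detected[sup_ids].any(axis=1) & matrix.detected[nat_ids].any(axis=1)
        sup = matrix.values[sup_ids].where(matrix.detected[sup_ids]).mean(axis=1)
        nat = matrix.values[nat_ids].where(matrix.detected[nat_ids]).mean(axis=1)
        fc = (sup / nat)[ok]
        mag = np.maximum(fc, 1.0 / fc)
        counts[stage] = {int(t): int((mag >= t).sum()) for t in thresholds}
    table = pd.DataFrame(counts).T
    table.index.name = "stage"
    table.columns.name = "threshold"
    return table


def abundance_shift_check(
    matrix: ExpressionMatrix, subset_ids
) -> dict:
    """Is a feature subset systematically more abundant than its complement?

    Compares per-feature mean log10 riBAQ (over detected samples) between
    the subset and the remaining features with a two-sample rank-sum test.
    Returns the p-value, the median shift in log10 units, and ECDF arrays
    for plotting the two probability density/distribution functions.
    """
    from .phenotypes import wilcoxon_rank_sum

    subset_ids = list(subset_ids)
    if not subset_ids:
        raise ValueError("empty subset")
    unknown = set(subset_ids) - set(matrix.values.index)
    if unknown:
        raise KeyError(f"subset ids not in matrix: {sorted(unknown)[:5]}")
    if len(subset_ids) == matrix.n_features:
        raise ValueError("subset equals the full feature set; no complement")
    if matrix.scale == "linear":
        vals = matrix.values.where(matrix.detected)
        mean_log = np.log10(vals).mean(axis=1)
    else:
        mean_log = matrix.values.where(matrix.detected).mean(axis=1)
    sub = mean_log.loc[subset_ids].dropna().to_numpy()
    comp = mean_log.drop(index=subset_ids).dropna().to_numpy()
    p, mode = wilcoxon_rank_sum(sub, comp)
    return {
        "p_value": p,
        "mode": mode,
        "median_shift_log10": float(np.median(sub) - np.median(comp)),
        "subset_sorted": np.sort(sub),
        "complement_sorted": np.sort(comp),
    }


def naive_signflip_pvalue(d) -> float:
    """Independent brute-force oracle for :func:`exact_permutation_pvalue`.

    Recomputes the signed-rank statistic from scratch for every sign
    vector via itertools, with no rank caching or doubled-rank tricks.
    Exponential in n; testing use only.
    """
    d = np.asarray(d, dtype=float)
    d = d[np.isfinite(d)]
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 1.0
    ranks = rankdata(np.abs(d))
    t_obs = abs(float(np.sum(np.sign(d) * ranks)))
    hits = 0
    for signs in itertools.product((-1.0, 1.0), repeat=n):
        t = abs(float(np.sum(np.array(signs) * ranks)))
        if t >= t_obs - 1e-9:
            hits += 1
    return hits / 2**n
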
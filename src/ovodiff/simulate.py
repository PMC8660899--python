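"""Synthetic proteome/transcriptome generator with ground truth.

The generator emulates the study design — seven ordered developmental
stages x two ovulation treatments x two biological replicates — and the
qualitative structure of the real data:

* log10 abundances with a per-feature baseline, a smooth per-feature stage
  drift, and a shared morula/blastocyst regime shift (the embryonic genome
  activation / differentiation signature that makes late-stage samples
  cluster away from the cleavage stages, across treatments);
* a treatment effect on a labelled feature subset whose magnitude follows
  a stage profile peaking at the 8-cell stage and fading by the
  blastocyst;
* abundance-dependent logistic detection dropout, so that the
  minimum-detection and constitutive filters are meaningfully exercised;
* a treatment-affected subset biased toward high abundance (the affected
  proteins in the study were systematically more abundant than the parent
  proteome);
* a transcriptome of negative-binomial counts sharing the same trajectory
  structure but with a (default) zero treatment effect — the null
  contrast.

Every dataset is bitwise reproducible from (config, seed) and ships a
:class:`SyntheticTruth` with per-feature labels for recovery tests.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import STAGES, TREATMENTS, ExpressionMatrix, make_design

#: Relative magnitude of the treatment effect per stage (peaks at 8-cell,
#: smallest at blastocyst), multiplying ``SimConfig.delta``.
DEFAULT_STAGE_PROFILE = (0.55, 0.60, 0.70, 0.85, 1.00, 0.70, 0.35)


@dataclass
class SimConfig:
    """Generator parameters; defaults define the emulated study conditions.

    Abundance model (log10, riBAQ-fraction-like scale):
    ``x = baseline + slope * stage_position + late_shift + treatment_effect
    + noise``.  Baselines are Normal(mu0=-5, sigma0=1); slopes
    Normal(0, slope_sd) against centered stage positions -3..3; morula and
    blastocyst receive a per-feature regime shift Normal(0, late_shift_sd)
    with an extra independent blastocyst offset; a fraction ``pi_de`` of
    features (sampled with probability weight exp(w * standardized
    baseline), biasing them toward high abundance) get a signed treatment
    shift ``delta * stage_profile[s]`` in the superovulation arm;
    replicate noise is Normal(0, noise_sd).  Detection is Bernoulli with
    P(detect) = logistic(dropout_a + dropout_b * x).

    Transcript mode: negative-binomial counts with dispersion ``phi``
    (variance mu + phi mu^2) around library-size-scaled relative
    abundances from the same trajectory model, and treatment effect
    ``delta_t`` (default 0: the near-null contrast).
    """

    n_features: int = 2000
    n_replicates: int = 2
    baseline_mean: float = -5.0
    baseline_sd: float = 1.0
    slope_sd: float = 0.02
    late_shift_sd: float = 0.5
    blastocyst_extra_sd: float = 0.3
    pi_de: float = 0.1
    delta: float = 0.8
    stage_profile: tuple = DEFAULT_STAGE_PROFILE
    noise_sd: float = 0.2
    dropout_a: float = 12.0
    dropout_b: float = 2.0
    abundance_bias_w: float = 1.0
    # transcript mode
    dispersion: float = 0.1
    library_size: float = 2e6
    library_size_cv: float = 0.15
    delta_t: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_features <= 0:
            raise ValueError("invalid config field n_features: must be positive")
        if self.n_replicates <= 0:
            raise ValueError("invalid config field n_replicates: must be positive")
        if not 0.0 <= self.pi_de <= 1.0:
            raise ValueError("invalid config field pi_de: must be in [0, 1]")
        for name in ("noise_sd", "dispersion", "library_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"invalid config field {name}: must be positive")
        for name in ("baseline_sd", "slope_sd", "late_shift_sd", "blastocyst_extra_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"invalid config field {name}: must be >= 0")
        if len(self.stage_profile) != len(STAGES):
            raise ValueError(
                f"invalid config field stage_profile: needs {len(STAGES)} entries"
            )
        self.stage_profile = tuple(float(v) for v in self.stage_profile)

    def replace(self, **kwargs) -> "SimConfig":
        return dataclasses.replace(self, **kwargs)

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside a synthetic dataset."""

    is_de: pd.Series                 # bool per feature
    true_log10_fc: pd.DataFrame      # feature x stage signed log10 fold change
    config: SimConfig

    def de_ids(self) -> list[str]:
        return list(self.is_de.index[self.is_de])


def _feature_effects(config: SimConfig, rng: np.random.Generator):
    """Draw the per-feature components shared by both modalities."""
    f = config.n_features
    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=f)
    slope = rng.normal(0.0, config.slope_sd, size=f)
    late = rng.normal(0.0, config.late_shift_sd, size=f)
    blast_extra = rng.normal(0.0, config.blastocyst_extra_sd, size=f)

    n_de = int(round(config.pi_de * f)) if config.pi_de > 0 else 0
    weights = np.exp(
        config.abundance_bias_w
        * (baseline - config.baseline_mean)
        / max(config.baseline_sd, 1e-12)
    )
    weights = weights / weights.sum()
    de_idx = (
        rng.choice(f, size=n_de, replace=False, p=weights) if n_de else np.array([], int)
    )
    is_de = np.zeros(f, dtype=bool)
    is_de[de_idx] = True
    sign = np.where(rng.random(f) < 0.5, 1.0, -1.0)
    sign[~is_de] = 0.0
    return baseline, slope, late, blast_extra, is_de, sign


def _log_abundance(config: SimConfig, effects, delta: float) -> np.ndarray:
    """Noise-free expected log10 abundance, features x stages x treatments."""
    baseline, slope, late, blast_extra, is_de, sign = effects
    positions = np.arange(len(STAGES)) - (len(STAGES) - 1) / 2.0
    profile = np.asarray(config.stage_profile)
    x = (
        baseline[:, None]
        + slope[:, None] * positions[None, :]
        + late[:, None] * np.isin(STAGES, ("morula", "blastocyst"))[None, :]
        + blast_extra[:, None] * (np.array(STAGES) == "blastocyst")[None, :]
    )
    x = np.repeat(x[:, :, None], len(TREATMENTS), axis=2)
    # treatment axis order follows TREATMENTS: superovulation first
    x[:, :, 0] += sign[:, None] * delta * profile[None, :]
    return x


def _logistic(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def generate_proteome(config: SimConfig) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Simulate an iBAQ-like linear-intensity proteome with dropout.

    Returns a linear-scale protein matrix with 7 x 2 x n_replicates sample
    columns (zeros where undetected) and the matching ground truth.
    """
    rng = np.random.default_rng(config.seed)
    effects = _feature_effects(config, rng)
    expected = _log_abundance(config, effects, config.delta)
    design = make_design(n_replicates=config.n_replicates)

    cols = {}
    for sid, row in design.iterrows():
        s = STAGES.index(row["stage"])
        t = TREATMENTS.index(row["treatment"])
        x = expected[:, s, t] + rng.normal(0.0, config.noise_sd, size=config.n_features)
        detect = rng.random(config.n_features) < _logistic(
            config.dropout_a + config.dropout_b * x
        )
        intensity = np.where(detect, 10.0 ** (x + 9.0), 0.0)  # arbitrary iBAQ scale
        cols[sid] = intensity
    feature_ids = [f"P{i:05d}" for i in range(config.n_features)]
    values = pd.DataFrame(cols, index=pd.Index(feature_ids, name="feature_id"))
    matrix = ExpressionMatrix.from_values(values, design, scale="linear", modality="protein")

    baseline, slope, late, blast_extra, is_de, sign = effects
    profile = np.asarray(config.stage_profile)
    truth = SyntheticTruth(
        is_de=pd.Series(is_de, index=feature_ids, name="is_de"),
        true_log10_fc=pd.DataFrame(
            sign[:, None] * config.delta * profile[None, :],
            index=feature_ids,
            columns=list(STAGES),
        ),
        config=config,
    )
    return matrix, truth


def generate_transcriptome(config: SimConfig) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Simulate negative-binomial transcript counts with the same design.

    Counts share the trajectory structure of the proteome model; the
    treatment effect is ``delta_t`` (default 0), emulating the study's
    near-null transcriptome contrast.  Variance is mu + dispersion * mu^2.
    """
    rng = np.random.default_rng(config.seed)
    effects = _feature_effects(config, rng)
    expected = _log_abundance(config, effects, config.delta_t)
    design = make_design(n_replicates=config.n_replicates)

    rel = 10.0 ** expected
    rel = rel / rel.sum(axis=0, keepdims=True)  # relative abundance per condition
    phi = config.dispersion
    size = 1.0 / phi  # NB shape parameter
    cols = {}
    for sid, row in design.iterrows():
        s = STAGES.index(row["stage"])
        t = TREATMENTS.index(row["treatment"])
        lib = config.library_size * np.exp(
            rng.normal(0.0, config.library_size_cv)
        )
        mu = rel[:, s, t] * lib
        p = size / (size + mu)
        cols[sid] = rng.negative_binomial(size, p)
    feature_ids = [f"T{i:05d}" for i in range(config.n_features)]
    values = pd.DataFrame(cols, index=pd.Index(feature_ids, name="feature_id"))
    matrix = ExpressionMatrix.from_values(
        values, design, scale="linear", modality="transcript"
    )
    baseline, slope, late, blast_extra, is_de, sign = effects
    profile = np.asarray(config.stage_profile)
    truth = SyntheticTruth(
        is_de=pd.Series(is_de & (config.delta_t != 0), index=feature_ids, name="is_de"),
        true_log10_fc=pd.DataFrame(
            sign[:, None] * config.delta_t * profile[None, :],
            index=feature_ids,
            columns=list(STAGES),
        ),
        config=config,
    )
    return matrix, truth


def evaluate_recovery(
    results: pd.DataFrame,
    truth: SyntheticTruth,
    alpha: float = 0.1,
) -> dict:
    """Score a differential-expression result against the ground truth.

    Sensitivity and FDR are computed over the tested feature set (the
    results' index): ``sensitivity`` = TP / (TP + FN) among true-DE
    features that reached the test, ``realized_fdr`` = FP / max(1,
    discoveries) (0/0 convention: no discoveries means FDR 0).  True-DE
    features removed upstream (e.g. by the constitutive filter) are
    reported separately as ``n_true_de_filtered`` so that a whole-pipeline
    recall TP / n_true_de_total can be formed when wanted.
    """
    unknown = set(results.index) - set(truth.is_de.index)
    if unknown:
        raise ValueError(
            f"result features absent from truth: {sorted(unknown)[:5]}"
        )
    discovered = set(results.index[results["q_bh"] < alpha])
    true_de_all = set(truth.is_de.index[truth.is_de])
    true_de = true_de_all & set(results.index)
    tp = len(discovered & true_de)
    fp = len(discovered - true_de)
    fn = len(true_de - discovered)
    return {
        "n_discoveries": len(discovered),
        "tp": tp,
        "fp": fp,
        "fn": fn,
        "n_true_de_total": len(true_de_all),
        "n_true_de_tested": len(true_de),
        "n_true_de_filtered": len(true_de_all - set(results.index)),
        "sensitivity": tp / (tp + fn) if (tp + fn) else 0.0,
        "realized_fdr": fp / max(1, len(discovered)),
    }


def census_error(
    census: pd.DataFrame, truth: SyntheticTruth, thresholds=(4, 5, 6, 7, 8)
) -> pd.DataFrame:
    """Observed census counts minus the truth-implied counts, per cell.

    The truth-implied count at (stage, t) is the number of features whose
    true fold change 10^|log10 FC| meets the threshold.
    """
    mag = 10.0 ** truth.true_log10_fc.abs()
    implied = pd.DataFrame(
        {int(t): (mag >= t).sum(axis=0) for t in thresholds}
    )
    implied.index.name = "stage"
    return census.loc[implied.index, implied.columns] - implied
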
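# Methods

`ovodiff` reimplements, as a tested library, a tandem proteome/transcriptome
differential-expression analysis contrasting hormonally superovulated mouse
oocytes and their derivative preimplantation embryos with naturally ovulated
counterparts, across the seven ordered stages oocyte, 1-cell, 2-cell, 4-cell,
8-cell, morula and blastocyst, with two biological replicates per
stage-by-treatment cell (28 samples per modality).  This note records the
models, the numerical choices, and the limits of what the synthetic-data
tests can show.

## Normalization

**Proteome (riBAQ pipeline).**  Raw per-sample iBAQ intensities are converted
to relative iBAQ, `riBAQ_i = iBAQ_i / Σ_i iBAQ_i`, a molar-fraction-like
quantity whose detected values sum to 1 per sample.  Detection is defined as
a positive value on the linear scale; blank cells are zeros.  The pipeline
order is fixed: riBAQ → discard features with positive values in fewer than
two samples → optional *constitutive* filter (at least one detected replicate
in every one of the 14 stage-by-treatment cells) → replicate averaging (mean
of detected replicates, else the single detected value, else undetected) →
quantile normalization → log10.  Whether quantile normalization precedes or
follows replicate averaging is genuinely open; averaging-first is adopted and
the alternative order is switchable (`average_before_quantile`).

**Quantile normalization with missing values.**  The classical method (each
column's order statistics replaced by the across-column mean of order
statistics, ties receiving the mean of their reference values) is only
defined for complete matrices.  We generalize it: the reference is the mean
of the per-column empirical quantile functions, and every detected value is
mapped onto the reference at its mid-rank quantile within its own column;
undetected cells are never imputed.  On complete data this reproduces the
classical method exactly.  The generalization matters: riBAQ is
compositional (one sample's values are constrained to sum to 1), so a strong
asymmetric treatment effect on abundant proteins deflates every other
protein in that sample by a common factor.  An early variant that left
incompletely detected features unnormalized let this shared offset through
and inflated the realized false-discovery rate on synthetic null features to
roughly 0.5 in replicate-paired mode; normalizing every detected value
removes the offset and restores calibration (~0.05 measured).

**Transcriptome.**  Counts are library-size normalized with
median-of-ratios size factors (median over all-positive features of the
count-to-row-geometric-mean ratio), then transformed as
`log2(count/sf + 1)`.  This is a deliberate stand-in for a regularized-log
transform: the size factors are identical, but no dispersion shrinkage is
applied.  The transcript track's analytical role here is a near-null
contrast, for which the stand-in suffices; outputs are labelled accordingly.
Replicate averaging for transcripts is performed on the log scale, matching
the published processing order for that modality.

## The stage-paired exact permutation test

For each feature the treatment contrast is reduced to paired differences
`d_s = x_superovulation,s − x_natural,s` — one per stage (*stage* pairing,
n ≤ 7) or one per stage and replicate (*stage_replicate* pairing, n ≤ 14).
The statistic is the Wilcoxon signed-rank sum `T = Σ sign(d_i)·rank(|d_i|)`
with mid-ranks for ties; zero differences are dropped before ranking
(classical zero-exclusion; Pratt's variant is available via
`zero_policy="pratt"`).  Significance comes from the exact sign-flip
distribution: under the null the sign of each difference is exchangeable, so
all `2^n` sign assignments on the fixed absolute ranks are enumerated and
the two-sided p-value is the fraction with `|T*| ≥ |T_obs|`.  Two-sidedness
via `|T|` is well-defined under ties, where tail-doubling is not.  Ranks are
held as doubled integers so mid-ranks stay exactly representable and tail
counts are exact; enumeration is refused above n = 20 (a seeded Monte-Carlo
mode with the add-one estimator is the explicit opt-in alternative).
P-values are corrected once across all tested features per modality with
Benjamini–Hochberg step-up FDR control, never per stage.

**The discreteness constraint.**  The smallest attainable two-sided p is
`2/2^n`: 0.015625 at stage pairing (n = 7) and ≈ 1.22e-4 at replicate
pairing (n = 14).  At stage pairing, BH at FDR < 0.1 over m = 2844 features
can only ever reject if at least `ceil(0.015625·m/0.1) = 445` features sit
exactly at the floor.  A published analysis of this design that reports 278
discoveries among 2844 constitutive proteins at FDR < 0.1 is therefore
arithmetically incompatible with pure stage-level pairing; the effective
pairing must have used more resolution (e.g. replicate-level pairs).  Both
modes are implemented; the package defaults to `stage` for fidelity to the
described procedure and documents the conflict rather than resolving it.

**Fold changes.**  The census counts, per stage, features whose
superovulation/natural ratio of replicate-averaged linear riBAQ values
satisfies `max(FC, 1/FC) ≥ t` for t ∈ {4,5,6,7,8}; features undetected in
either treatment at a stage are excluded from that stage (no infinite
ratios).  The up/down classification among significant features uses the
sign of the median stage log-fold-change and a strict `max(FC, 1/FC) > 2`
("in excess of twofold").

## Structure diagnostics

Samples are clustered by complete linkage on `d = 1 − r` (Pearson
correlation between expression profiles; the `1 − r` transform, rather than
`(1−r)/2` or `1−|r|`, is the common convention and is configurable).
Heatmap row order comes from a complete-linkage tree on feature–feature
Euclidean distances, with the traversal canonicalized (subtree containing
the lexicographically smallest feature id first) so the order is independent
of input row order.  PCA is centered and unscaled on the log expression
values, all samples weighted equally, full SVD; variance fractions are
normalized squared singular values.  A component "separates" the treatments
iff a scalar threshold puts all superovulation scores strictly to one side —
a deliberately strict criterion that is brittle at 14–28 samples, which is
why the point-biserial correlation is reported alongside.

## Enrichment

Over-representation uses the exact hypergeometric upper tail against a
user-chosen universe — by default the constitutive feature set of the
analyzed matrix rather than the genome, to respect detection bias — with BH
correction across the collection (enriched at q ≤ 0.01).  Terms are ranked
by a combined score `ln(p) · z`, where `z = (observed_rank − mean_rank)/sd`
is a seeded Monte-Carlo standardization of the term's p-value rank against
random queries of the same size (default 1000 resamples).  Under this sign
convention a strongly enriched term with a better-than-expected rank has
`ln p < 0` and `z < 0`, hence a large positive score.  Term-level agreement
with results produced by hosted enrichment services is qualitative only:
those depend on specific gene-set library snapshots and precomputed rank
tables that are not reproducible offline.

## Phenotype statistics

Oocyte morphometry: diameter from the traced perimeter, `d = P/π`; volume by
spherical approximation `V = (4/3)π(d/2)^3`, reported in picoliters (1 pL =
1000 µm³).  With the study's printed mean diameters, 79.4 µm (natural) gives
262 pL and 78.1 µm (superovulated) gives 250 pL at two significant figures;
the printed 4.7% volume difference was evidently computed from unrounded
means (the rounded diameters give 4.8%).  Count data use Fisher's exact test
(2×2; two-sided by probability-mass summation, the convention that
reproduces the printed embryo-transfer p = 0.202) or the chi-square
homogeneity test (k×2, no continuity correction by default, with a warning
when any expected count is below 5).  Continuous measurements use the
two-sample Wilcoxon rank-sum test: exact enumeration when the pooled size is
at most 12 and tie-free, tie-corrected normal approximation otherwise, with
the mode recorded.

## Synthetic data generator

The generator emulates the study design and its qualitative structure; its
defaults are the package's frozen study conditions.

Per-feature log10 abundance (riBAQ-fraction scale):
`x = baseline + slope·position + late_shift + treatment_effect + noise`, with

| parameter | default | meaning |
|---|---|---|
| `baseline` | Normal(−5, 1) | log10 molar fraction |
| `slope_sd` | 0.02 | smooth per-feature stage drift (centered positions −3..3) |
| `late_shift_sd` | 0.5 | per-feature morula+blastocyst regime shift (embryonic genome activation signature) |
| `blastocyst_extra_sd` | 0.3 | extra blastocyst-specific offset |
| `pi_de` | 0.1 | fraction of treatment-affected features |
| `delta` | 0.8 | peak treatment shift, log10 units |
| `stage_profile` | (0.55, 0.60, 0.70, 0.85, 1.00, 0.70, 0.35) | stage modulation of δ, peaking at 8-cell, smallest at blastocyst |
| `noise_sd` | 0.2 | replicate noise, log10 units |
| `dropout_a`, `dropout_b` | 12, 2 | P(detect) = logistic(a + b·x) |
| `abundance_bias_w` | 1.0 | affected features drawn ∝ exp(w·standardized baseline) |

Affected features get a random sign, constant across stages.  Transcript
mode shares the trajectory machinery and emits negative-binomial counts
(variance `µ + φµ²`, φ = 0.1) around library-size-scaled relative
abundances (library size 2e6, lognormal CV 0.15), with treatment effect
`delta_t` defaulting to 0 — the null contrast.  Everything is generated
from one seeded generator; outputs are bitwise reproducible from (config,
seed), and the full config is echoed next to every CLI output.

The defaults were calibrated once, before being frozen, so that the
qualitative published patterns emerge robustly at 2000 features: the
morula/blastocyst samples form one supercluster across treatments while the
cleavage-stage samples split by treatment; PC1 tracks development and PC2
the treatment in the proteome, while the transcriptome has no separating
component among the first three; and the fold-change census peaks at the
8-cell stage and bottoms out at the blastocyst.  These are design targets of
the generator, not claims about effect sizes in real data.

**What the generator does not emulate:** peptide-level structure and
protein inference, isotope/isobaric channel artifacts, batch and run-order
effects, correlated feature blocks (co-regulation), missing-not-at-random
mechanisms beyond abundance-dependent dropout, and transcript length or GC
biases.  Passing recovery tests therefore demonstrate the correctness and
calibration of the statistical machinery under the modelled conditions, not
performance guarantees on real LC–MS/MS or RNA-seq data.

## Numerical choices and degenerate inputs

Detected values must be finite; linear-scale undetected cells are stored as
0 and log-scale ones as NaN.  Samples with all-zero intensities, constant
profiles passed to correlation distances, empty universes/queries, and
degenerate contingency margins raise errors rather than producing NaN.
Features with fewer than two complete pairs are reported with p = 1 and an
`insufficient_pairs` flag, never dropped silently.  Expression tables are
written with shortest round-trip float formatting and re-parsed with
correctly rounded conversion, so write→read is bit-identical.  Complete
linkage follows the standard agglomerative algorithm; merge ties are broken
by condensed-matrix position, which is deterministic for a fixed input
order.

## Evaluation conventions

`evaluate_recovery` scores a result table against the generator's truth over
the tested feature set: sensitivity = TP/(TP+FN) among true-affected
features that reached the test, realized FDR = FP/max(1, discoveries)
(0/0 → 0).  True-affected features removed upstream by the detection filters
are reported separately (`n_true_de_filtered`); they measure the filter, not
the test, and a whole-pipeline recall can be formed from the reported
counts when wanted.

## Known limitations

- The exact DESeq2 regularized log is not reimplemented; the shifted-log
  stand-in differs most at low counts.
- The enrichment z-score is Monte-Carlo, so combined scores carry sampling
  noise of order 1/√resamples; p and q values are exact.
- Stage-level pairing is faithful to the described procedure but, with
  seven pairs, cannot reject below p = 0.015625 — see the discreteness
  constraint above.
- The permutation test treats features independently; BH's FDR control
  holds under positive regression dependence, which the compositional
  normalization is designed to keep plausible but cannot guarantee.
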
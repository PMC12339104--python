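# Methods

`segnav` implements, end to end on synthetic data with known ground
truth, the computational chain that links resting-state functional
network segregation, peripheral metabolic state and APOE genotype to
path-integration performance through staged mixed-effects moderation
models.  This note documents the models, their assumptions, the choices
made where the design was genuinely open, and what the validation
battery does and does not demonstrate.

## Network segregation

Parcel-level BOLD series (vertex/voxel signals averaged without weights
within each parcel) are correlated pairwise over time (Pearson), Fisher
z-transformed, and negative z-values are **removed** — excluded from all
subsequent means via a validity mask, not truncated to zero.  Removal
and zero-replacement differ in the denominator of every mean; exclusion
also makes the result invariant to whether masking happens before or
after the within/between split.  A zero correlation survives the mask.
The diagonal is never an edge.  Parcels assigned to no network ("none"
label) are dropped before correlation so they cannot leak into
between-network means.

For each network with mean within-connectivity `Zw` and mean
connectivity to all other networks `Zb`,

    segregation = (Zw - Zb) / Zw

so 1 means fully segregated and 0 means no within/between distinction.
`Zw` is the mean over the network's parcels of the parcel-level means
`zW_i` (mean of means, not mean over unique edges): the partialization
regression needs parcel-level observations, and computing the raw and
partialized variants on the same construction keeps them comparable.
With equal per-parcel edge counts the two definitions coincide.
Undefined quantities (a parcel with no retained edges in a class, a
network with `Zw = 0`) propagate as explicit NaN flags with log
messages; nothing is silently imputed.

### Gray-matter partialization

Per subject, covariate (cortical thickness or a T1w/T2w myelin proxy)
and target (within or between), the parcel profile is regressed once on
the per-parcel covariate `R_i`, pooled across the whole set of
non-excluded parcels (not per network):

    y_i = b0 + b1 * R_i + e_i
    PFC_i = y_i - b1 * (R_i - mean(R))

The slope contribution is removed **about the covariate mean**, so the
grand connectivity level is preserved (`mean(PFC) = mean(y)`); a zero
slope reproduces the input exactly, a noiseless linear profile collapses
to a constant (segregation 0), and the operation is idempotent.
Removing `b1 * R_i` without centring would instead shift both `Zw` and
`Zb` down by `b1 * mean(R)` — with thickness near 2.5 mm that shift
dwarfs the z-values themselves, inflates the index past 1 and destroys
the comparability the adjustment exists to provide, which is why the
centred form is used.  Negative `PFC_i` are retained: negative-edge
removal is an edge-level rule applied upstream, and residualization
defines no second removal.

The regression is fit per subject.  Whether pooling subjects would be
preferable is an open design point; per-subject fits keep the adjusted
index a subject-level quantity, which the downstream models require.

## Metabolic indices

HOMA-IR = insulin (mU/l) x glucose (mmol/l) / 22.5; insulin measured in
pmol/l is first divided by 6.  The continuous metabolic syndrome score

    MtbS = 2*waist/height + glucose/5.6 + triglycerides/1.7
           + systolic/130 - HDL/(40 male | 50 female)

uses the dichotomous cut-off of each component as its denominator, so a
subject at every cut-off scores exactly 3.  All cut-off comparisons are
inclusive (>=; HDL flags use <) and centralized in one `Cutoffs` block.
The HDL denominators printed in the equation (40/50) follow mg/dl
conventions while HDL concentrations are commonly recorded in mmol/l
(cut-offs 0.9/1.1); the two readings are not reconcilable from the
equation alone, so the denominator pair is a configuration parameter
defaulting to the printed (40, 50).

## Statistical machinery

Positive dependent variables are Box-Cox transformed, mixed-sign ones
Yeo-Johnson transformed; the exponent is chosen by profile maximum
likelihood on the fixed grid [-2, 2] in steps of 0.01 (seed-independent,
resolution well below any downstream sensitivity).  Both transforms use
`expm1`/`log1p` forms, stable as the exponent approaches its branch
points.  Continuous predictors are Z-scored.

The model ladders are ordered, strictly nested fixed-effect sets over a
constant random structure — a participant random intercept only.  All
fits use **maximum likelihood** (not REML) so likelihood-ratio
comparisons of fixed effects are valid; adjacent rungs are compared by
`2*(LL_full - LL_reduced)` on a chi-square with df equal to the
fixed-parameter difference.  Nesting is verified on the design-matrix
columns, not the term strings.  Degenerate or non-converged fits are
reported with their diagnostics and excluded from the LRT chain rather
than silently dropped; a derivative-free (Powell) restart is attempted
first, since gradient optimizers occasionally stall on weakly identified
subject-level designs.  Note the chi-square reference is slightly
liberal for subject-level predictors when the number of participants is
modest (~60); the null rejection rate sits near 0.06 rather than 0.05,
a known property of ML-based LRTs in mixed models, not an error.

Multicollinearity is screened by the variance inflation factor
(`VIF_j = 1/(1 - R2_j)`, intercept included in the auxiliary
regressions); VIF > 5 flags a term, the signal to refit per network.
The resulting per-network p-value family is corrected by the
Holm-Bonferroni step-down; adjusted p-values are the running maximum of
`min(1, (m - rank)*p)`.

Effect sizes: Cohen's `f2 = (R2_full - R2_reduced)/(1 - R2_full)` for
main effects; for interactions, t-statistic approximations — `delta =
2t/sqrt(df)` for categorical x continuous and `rho = t/sqrt(t^2 + df)`
for continuous x continuous, with df defaulting to residual degrees of
freedom.  Both are zero iff the coefficient is zero, carry its sign, and
grow monotonically with it.  Confidence intervals use the bias-corrected
and accelerated (BCa) bootstrap: bias correction from the fraction of
replicates below the point estimate, acceleration from jackknife
skewness, B >= 1000 enforced, degenerate bootstrap distributions
collapse to a point with a logged flag.

## Synthetic-data generator

The generator is first-class, tested code; its defaults are the
conditions under which every validation claim is made.

**BOLD.**  Multivariate normal draws whose covariance is exactly the
block correlation matrix (`r_within` inside networks, `r_between`
elsewhere, unit diagonal), optionally passed through an AR(1) recursion
whose innovations are scaled by `sqrt(1 - ar1^2)` so the stationary
spatial correlation is preserved exactly.  No hemodynamic model: the
segregation index consumes only second-order structure.  Positive
semi-definiteness is verified by eigenvalue check at construction and
violations raise a constructive error naming the offending parameters —
silent clipping would corrupt every recovery experiment downstream.  The
default series length is 250 timepoints, a typical single-run
resting-state acquisition.  With equal blocks the index has the closed
form `(atanh r_w - atanh r_b)/atanh r_w`, the anchor for the analytic
recovery check.

**Gray matter.**  Thickness-like (~2.5 mm) and myelin-like (~1.5)
per-parcel covariates: a shared log-scale topography plus subject noise,
hence strictly positive.  The default dispersions are deliberately
modest (CV ~3%): these covariates exist to carry a *planted linear*
contamination of connectivity (each edge shifted by
`slope*(g_i + g_j)/2`, centred covariate), and if the perturbation is
not small against the between-network z-level the re-derived
negative-edge mask churns and the planted effect is no longer the linear
model the partialization regression can remove — the recovery experiment
would then measure mask truncation, not adjustment.  Larger, more
anatomically typical dispersions are available through the `profiles`
argument.  For the same reason the partialization-recovery study uses a
12-network scheme (the network count of the primary parcellation it
emulates): with K networks the partner-side contamination of
between-network connectivity — invisible to a regression on the
parcel's own covariate — scales as 1/(K-1), and below K ≈ 6 it
dominates, making the raw index closer to truth by construction.  The
study also uses 2000 timepoints so edge-level sampling noise does not
churn the mask.

**Phenotypes.**  Log-normal marginals matched in location and scale to a
late-middle-aged metabolic-risk cohort (e.g. HOMA-IR mean ~2.5, MtbS
~3, glucose ~6 mmol/l); age uniform on 52-75; APOE coded as a binary
e4-carrier indicator (no e2 carriers, no e4 homozygotes, mirroring the
design such cohorts use); carrier fraction defaults to 0.3.

**Trials.**  Drop error (Euclidean distance between estimated and true
goal) is generated from a linear mixed model on the Box-Cox(lambda)
scale, lambda defaulting to 0 (log-normal errors, hence strictly
positive without retries; non-zero lambda uses bounded redraws of the
residual).  Fixed effects: intercept ~8.25 (≈ 3 800 virtual units),
subtask offsets making landmark/boundary environments easier than the
cue-free one (-0.17/-0.19), optional HOMA-IR, segregation, APOE, their
interactions, and an incoming-distance slope (distance uniform on
2 000-12 000 virtual units, entered Z-scored).  Random structure: a
participant intercept (SD 0.25) plus residual noise (SD 0.45), which
puts trial-level variability near the coefficient of variation such
navigation tasks show.  Defaults produce 24 trials per subject (two
subtasks x 12); the per-subtask count is a parameter, since task
variants with 32 trials per subtask exist.  Every planted coefficient —
including the structural zeros of unconfigured terms — is returned in a
truth table whose keys match the generated design columns, so recovery
is a direct join.

## Validation battery and problem sizes

`segnav.experiments` holds the studies; `tests/test_acceptance.py` runs
them at full size and `scripts/acceptance.py` re-runs them from scratch
and writes the numbers as JSON.  Sizes are chosen so the whole battery
completes in a few minutes on one CPU:

* brute-force oracle equivalence on 100 random masked instances
  (<= 20 parcels);
* analytic recovery, 40 subjects x 60 parcels x 250 timepoints;
* partialization recovery, 40 subjects, 12 networks x 5 parcels,
  T = 2000, slope 0.5;
* null LRT calibration, 500 replicates of 60 subjects x 24 trials;
* coefficient recovery, 100 replicates of 200 subjects, scored as the
  pooled fraction of (replicate, coefficient) pairs within 2 SE;
* Holm family-wise error, 2000 replicates of 12 per-network slope tests;
* BCa coverage, 500 replicates of the log-normal(0,1) mean at n = 50.

Two calibration facts to read alongside the battery: the 2-SE band has
nominal coverage 95.4%, so the pooled recovery fraction hovers just
above 0.95; and BCa intervals for a heavily right-skewed mean at n = 50
genuinely undercover (~0.92-0.93 here and for scipy's independent BCa
on the identical data) — the bootstrap literature's known small-sample
behavior, reproduced rather than hidden.

## What the synthetic data does not show

The generator emulates second-order network structure, linear GM
contamination, and a correctly specified trial model.  Real resting-state
data add head motion, physiological nuisance structure, non-Gaussian
BOLD fluctuations, spatially correlated parcellation error, and
GM-connectivity relationships that are neither linear nor univariate;
real navigation data add learning effects, censored errors and
heteroscedastic difficulty.  Passing this battery therefore shows the
*pipeline* is correct and calibrated under its stated model, not that
the model captures any particular empirical dataset.

## Reproducibility

Every generator takes an explicit seed; the pipeline takes one run-level
seed and splits it into per-stage substreams (`numpy.random.SeedSequence`),
so adding a stage never perturbs earlier streams and reruns are
bit-identical for deterministic stages.  All artifacts are plain TSV or
JSON; masked connectivity edges serialize as the literal token `NA`.
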
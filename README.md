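# segnav

Functional **seg**regation of resting-state brain networks, metabolic
indices, and mixed-effects moderation models of spatial **nav**igation
performance — as one tested, reproducible pipeline, exercised end to end
on synthetic data with known ground truth.

## The problem

In aging cohorts at risk for Alzheimer's disease, path-integration
ability (estimating one's position from self-motion alone; measured as
the *drop error*, the distance between an estimated and a true goal
location) depends on how functionally segregated large-scale brain
networks are, and that dependence is moderated by insulin resistance and
by APOE ε4 carriership.  Testing such moderation chains takes several
coupled steps — connectivity construction, a segregation index and its
gray-matter-adjusted variants, derived metabolic scores, and a ladder of
nested mixed models — each with choices that are easy to get silently
wrong.  `segnav` packages the whole chain for methodologists and
neuroimaging analysts, with every step validated against closed forms,
brute-force oracles, or planted-coefficient recovery.

## The core quantities

For each network, with mean within-network Fisher-z connectivity Z̄W and
mean connectivity to all other networks Z̄B (negative z-values removed
from both means):

    segregation = (Z̄W − Z̄B) / Z̄W

Its gray-matter-partialized variant regresses the parcel-level
connectivity profile y\_i on a per-parcel covariate R\_i (cortical
thickness or T1w/T2w myelin proxy) and recomputes the index from
PFC\_i = y\_i − β₁(R\_i − R̄).

Metabolic state enters as HOMA-IR = insulin·glucose/22.5 and the
continuous metabolic-syndrome score
MtbS = 2·waist/height + glucose/5.6 + triglycerides/1.7 + systolic/130 −
HDL/(40 M | 50 F).

Moderation is tested by ladders of nested linear mixed models (participant
random intercept, maximum likelihood) such as

    dropE ~ HOMA-IR × segregation + APOE + subtask + covariates + (1 | participant)

compared rung by rung with likelihood-ratio tests, with Box-Cox/
Yeo-Johnson response transforms, VIF screening, Holm-Bonferroni control
across per-network families, Cohen's f², the δ/ρ interaction effect
sizes, and BCa bootstrap intervals.

## Worked example

```python
from segnav.pipeline import RunConfig, SimulationBlock, run_pipeline, report

cfg = RunConfig(
    seed=7,
    simulation=SimulationBlock(
        n_subjects=60, network_sizes=[5] * 12, n_timepoints=250,
        beta_homa=0.08, beta_homa_x_seg=0.15,   # planted moderation effect
    ),
    variants=["raw"],
    ladder="homa_moderation",
)
run_pipeline(cfg, "demo_run")
print(report("demo_run"))
```

prints (abridged):

```
Per-network segregation (mean +/- SD over subjects):
  raw                N0         0.7997 +/- 0.0280
  ...
  raw                N9         0.8017 +/- 0.0273

Likelihood-ratio comparisons (full vs reduced):
  1 vs 0: chi2(1) = 14.45, p = 0.0001437
  2 vs 1: chi2(3) = 1.39, p = 0.7074
```

Reading it: the per-network segregation means sit near 0.80, the
population value (atanh 0.5 − atanh 0.1)/atanh 0.5 ≈ 0.817 implied by the
simulated block correlations, minus the small finite-series bias at
T=250.  The first ladder comparison detects the planted
HOMA-IR × segregation interaction (χ²(1) = 14.45, p ≈ 1.4·10⁻⁴); the
second correctly finds nothing for the three-way interaction with
subtask, which was not planted.

The same stages are scriptable from a shell:

```
segnav simulate --n-subjects 40 --network-sizes 15,15,15,15 --seed 1 --out run/
segnav run --config config.yaml --out run/ --seed 1
segnav report run/
```

(`segnav connectivity`, `segregation`, `metabolic` and `fit` expose the
individual stages; `docs/run_config.schema.json` documents the YAML
config.)

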
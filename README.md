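# propriolearn

Analysis toolkit for passively guided motor-learning experiments in which a
robot moves a participant's limb along a target movement and the participant
later reproduces it actively. The scientific question the pipeline serves:
which perceptual and mnemonic abilities predict how much a learner gains
from purely proprioceptive instruction? The package implements the three
per-participant measures used in that literature, the causal analysis that
relates them, and a calibrated synthetic-cohort generator so the whole
pipeline can be exercised, tested and benchmarked without human data.

## The measures and models

**Recognition memory (signal detection).** A 60-trial task presents three
elbow angles (8°–82°, 2° grid, pairwise separations ≥ 10°) to memorize; a
test angle is one of them on half the trials. From the hit/miss/false-alarm/
correct-rejection counts the package computes

- sensitivity = hit / (hit + miss),
- precision = hit / (hit + false alarm),
- d′ = Z(hit rate) − Z(false-alarm rate), with extreme rates replaced by
  1/(2n) before the quantile transform,

plus per-serial-position sensitivities and the memory-preference index
(position 3 − position 1; negative = better memory for older items).

**Proprioceptive acuity (2AFC psychometrics).** An 80-trial task compares a
reference angle (30° or 50°) with a test angle deviating by ±2, 4, 6, 8°.
The proportion of "larger" responses is fitted with a cumulative Gaussian
Φ((Δ − μ)/σ) by maximum likelihood, and acuity is summarised by the
just-noticeable difference JND = (x₇₅ − x₂₅)/2 = 0.6745·σ (lower = better).

**Trajectory learning (peak cross-correlation).** Reproductions of a 10-s,
250-Hz elbow trajectory are scored by the peak over ±2.5 s of lags of the
overlap-only Pearson correlation with the target (onset timing is
deliberately ignored), plus a zero-lag RMSE that retains timing errors. The
learning index is mean post-learning minus mean pre-learning peak
correlation.

**Causal structure (DirectLiNGAM → SEM).** The z-scored triple
(JND, sensitivity, improvement) is fed to a DirectLiNGAM implementation:
greedy causal-order search by residual-independence (nonlinear-moment
entropy approximation), adaptive-LASSO pruning (weights 1/|OLS|, BIC
penalty, OLS refit on the support), row-resampling bootstrap for path and
graph probabilities, and HSIC + Shapiro–Wilk checks of the independence and
non-Gaussianity assumptions. The selected recursive path model is re-fit by
ML as an SEM with z-tests per path and CFI/TLI/RMSEA/SRMR fit indices.

**Synthetic cohort.** Each simulated participant carries latent traits
A (acuity), M (memory), L (learning) following A → M → L with standardized
path coefficients −0.39 and 0.70, uniform disturbances, and no direct A → L
path. Fixed monotone links map the traits to mechanistic task parameters
(perceptual noise, encoding noise, serial-position decay, guessing rate,
reproduction fidelity), calibrated once so that cohort-level pipeline
outputs match the published cohort summaries the package is built around.
See `docs/methods.md` for the model, the calibration and its limits.

## Worked example

```python
from propriolearn import CohortConfig, run_study

report = run_study(CohortConfig(n_participants=40, seed=21), n_resamples=200)
print({k: round(v["mean"], 3) for k, v in report.summary.items()
       if k in ("sensitivity", "precision", "d_prime", "jnd", "improvement")})
print("paired t:", {k: round(v, 3) for k, v in report.paired_t.items()})
print("r(sensitivity, improvement) =",
      round(report.correlations["sensitivity_vs_improvement"]["r"], 3))
print("causal order:", report.causal["order"])
print("edges:", [(e["cause"], e["effect"], round(e["coefficient"], 2))
                 for e in report.causal["edges"]])
```

prints (exact numbers are seed-dependent; these are from the run above):

```
{'sensitivity': 0.823, 'precision': 0.647, 'd_prime': 1.254, 'jnd': 4.433, 'improvement': 0.143}
paired t: {'t': 12.287, 'df': 39, 'p': 0.0}
r(sensitivity, improvement) = 0.606
causal order: ['sensitivity', 'jnd', 'improvement']
edges: [('sensitivity', 'jnd', -0.54), ('sensitivity', 'improvement', 0.61)]
```

Read: the simulated cohort improved strongly from pre- to post-learning
(paired t on the per-participant mean peak correlations), memory
sensitivity predicts the improvement, and there is no direct
acuity → learning edge. At n = 40 the direction of the weak acuity–memory
edge is not reliably identified (here it came out reversed — exactly the
kind of instability the bootstrap probabilities quantify); at the
n = 2000 trait level the full A → M → L structure is recovered (see the
acceptance checks).

The same stages are scriptable from a shell:

```bash
propriolearn simulate --n 21 --seed 1 --out cohort_dir
propriolearn run --seed 1 --n 40 --resamples 3000 --out study_dir
propriolearn causal --metrics study_dir/participant_metrics.csv --resamples 3000 --seed 1 --out causal_dir
propriolearn reproduce-reference --out repro_dir   # calibrated 500-participant cohort
```

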
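# fatiguedyn

Trial-by-trial computational modelling of subjective effort and fatigue in
grip-force tasks.

## The problem

In tasks that alternate brief physical exertions (squeezing a dynamometer to
30/39/48 % of one's maximum voluntary contraction, MVC) with matched rest
periods, people's ratings of how *effortful* a squeeze felt (0–20 scale) or
how *fatigued* they feel (0–100 scale) drift systematically from trial to
trial.  `fatiguedyn` implements a latent-state account of those dynamics and
everything needed to fit and test it: momentary fatigue is

```
F(t) = F_start + RF(t) + UF(t)
```

with a **recoverable** component that rises with the force exerted and falls
with time rested (clamped at zero),

```
RF(t) = max(0, RF(t-1) + α·E(t) − δ·T_rest(t))
```

and an **unrecoverable** component that only accumulates,

```
UF(t) = UF(t-1) + θ·E(t)
```

Here `E` is the trial's force output — the area under the force-time curve,
normalised by the participant's maximum and scaled by 10 — and `T_rest` is
7.5 s on rest trials, 2.5 s on work trials.  Fatigue ratings are read out as
`F` itself; perceived-effort ratings as `PE = (γ + F)·E` on work trials (an
additive variant `γ·E + F` is also available) and 0 on rest trials.

Each candidate model — from a static null model (γ only) through UF-only,
RF-only, one-parameter-RF and combined variants up to the full α, δ, θ
dynamics — is fitted per participant by residual-sum-of-squares minimisation
(Nelder–Mead restarted from a factorial grid of six initial values per free
parameter, parameters constrained non-negative) and scored with
`AIC = n·ln(RSS/n) + 2d` and the squared observed–predicted correlation.
Group-level comparison reports summed AICs, best-fit counts, and
random-effects Bayesian model selection on inverted AICs (variational
Dirichlet scheme plus Monte-Carlo exceedance probabilities).

A synthetic-experiment generator produces complete cohorts — counterbalanced
120-trial sequences, ramp-and-hold force traces, integer bound-censored
ratings from known ground-truth parameters — so parameter recovery, model
recovery and the whole pipeline are testable without any real data.

## Worked example

```python
from fatiguedyn import FatigueRatingModel, compare_fits, fit_cohort
from fatiguedyn.simulate import recovery_config, simulate_cohort

config = recovery_config(n_participants=5, seed=12)   # fatigue readout, noise sd 5
cohort = simulate_cohort(config)

subject = cohort[0]
est = FatigueRatingModel(model_id="full", readout="fatigue").fit(subject)
print("true params:", subject.truth["params"])
print("fitted     :", est.params_)
print(f"RSS={est.rss_:.1f}  AIC={est.aic_:.1f}  R^2={est.r_squared_:.3f}")

fits, _ = fit_cohort(cohort, ["uf", "rf", "rf1", "uf_rf1", "full"])
result = compare_fits(fits, ep_samples=200_000, seed=12)
for mid, ep, n in zip(result.model_ids, result.exceedance_probability,
                      result.best_count_aic):
    print(f"{mid:8s} EP={ep:.3f}  best for {n}/5 subjects")
```

prints

```
true params: FatigueParams(alpha=0.5431425273150972, delta=0.9596894457892348, theta=0.045633183163267636, gamma=0.0)
fitted     : FatigueParams(alpha=0.6041069866133538, delta=1.0590856367098471, theta=0.044178047153779286, gamma=0.0)
RSS=3001.6  AIC=392.3  R^2=0.797
full     EP=0.945  best for 5/5 subjects
rf       EP=0.014  best for 0/5 subjects
rf1      EP=0.013  best for 0/5 subjects
uf       EP=0.014  best for 0/5 subjects
uf_rf1   EP=0.014  best for 0/5 subjects
```

The fitted α, δ, θ land close to the generating values despite 5 units of
rating noise and integer quantisation; the residual RSS ≈ 3000 over 120
trials is the noise floor (120 · 5²); and the group comparison identifies
the generating (full) model with exceedance probability 0.945 even in a
cohort of five.

The same workflow is available from the shell:

```
fatiguedyn simulate --config sim.yaml --seed 3 --out cohort/
fatiguedyn fit --data cohort/trials.csv --readout fatigue --out fits.csv
fatiguedyn compare --fits fits.csv --out comparison.json
fatiguedyn recover --config sim.yaml --out recovery/   # simulate→fit→compare→report
fatiguedyn run --config run.yaml                       # full pipeline + manifest
```

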
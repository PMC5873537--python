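# loda — longitudinal discriminant analysis with multivariate GLMMs

Clinicians following patients at risk of a disease collect repeated
measurements of several markers of mixed types — continuous lab values,
counts, binary findings. `loda` classifies such patients into prognostic
groups from their whole longitudinal history rather than their latest
visit, using Bayesian multivariate generalised linear mixed models
(MGLMMs) and three alternative posterior group-membership probability
constructions.

## Model

For marker *r* = 1..R, observation *j* of a patient in group *g*:

```
h_r^{-1}( E[Y_rj | b] ) = x_rj' α_r^g + z_rj' b,      b | U=g ~ Σ_k w_k N(μ_k^g, D_k^g)
```

with canonical links (identity, log, logit for Gaussian, Poisson and
Bernoulli markers), marker-specific fixed effects α and a joint
random-effects vector **b** shared across markers (a single normal
component in all fitted models). Each group's model is fitted separately
by MCMC (block Gibbs with conjugate updates; Laplace independence
Metropolis–Hastings for non-Gaussian random-effect blocks).

A new patient's group probability is, averaged over the retained draws
(ψ, θ)⁽ᵐ⁾,

```
P(U=g | y) = (1/M) Σ_m  π_g f_g(y; ψ_g^(m), θ_g^(m)) / Σ_h π_h f_h(y; ψ_h^(m), θ_h^(m))
```

with three choices of predictive density f_g:

| approach | f_g | focus |
|---|---|---|
| `marginal` | ∫ f(y \| b) f(b) db | group mean profiles |
| `conditional` | f(y \| b̂_g) at the patient's random-effects estimate | patient-specific profile |
| `random_effects` | f(b̂_g), the random-effects density at the estimate | patient-specific variability |

Classification uses the argmax rule or a cutoff chosen as the ROC point
closest to the top-left corner; accuracy is summarised by sensitivity,
specificity, proportion correctly classified (PCC), AUC, PPV and NPV.

## Worked example

Simulate the built-in two-marker scenario (two groups that differ only in
measurement-error scale), fit both group models, and compute one held-out
patient's group probabilities:

```python
from loda import (MCMCConfig, PriorProbabilities, builtin_scenario, classify,
                  fit_group_model, group_probabilities, posterior_summary,
                  simulate_dataset)

scn = builtin_scenario("scenario2")
patients = simulate_dataset(scn, seed=11)
fits = [
    fit_group_model([p for p in patients if p.group == g], scn.specs,
                    MCMCConfig.fast(seed=g))
    for g in (0, 1)
]
print(posterior_summary(fits[0]).loc[
    ["E[albumin:intercept]", "E[lbili:intercept]", "SD[albumin:residual]"]
].round(3))

new_patient = patients[205]          # a poor-prognosis (group 1) patient
res = group_probabilities(new_patient, fits,
                          PriorProbabilities.from_counts([200, 50]))
for approach, probs in res.probabilities.items():
    print(f"{approach:>15}: P(group 1) = {probs[1]:.3f}")
print("argmax class:", classify(res.probabilities["marginal"]))
```

```
                       mean  hpd_low  hpd_high     sd
parameter
E[albumin:intercept]  3.003    2.976     3.042  0.017
E[lbili:intercept]    1.013    0.976     1.059  0.023
SD[albumin:residual]  0.327    0.305     0.348  0.011
       marginal: P(group 1) = 0.950
    conditional: P(group 1) = 0.988
 random_effects: P(group 1) = 0.192
argmax class: 1
```

The posterior means sit on the generating values (albumin intercept 3.00,
log-bilirubin intercept 1.00, albumin residual SD 0.314 in group 0). The
marginal and conditional densities identify the patient's group from the
tight residual scatter of their trajectories, while the random-effects
approach — blind to residual scale — does not.

The same pipeline is scriptable from the shell:

```bash
loda simulate --scenario scenario2 --seed 11 --out data.csv
loda fit --data data.csv --scenario scenario2 --group 0 --out g0.npz
loda fit --data data.csv --scenario scenario2 --group 1 --out g1.npz
loda predict --data data.csv --models g0.npz --models g1.npz --out pred.csv
loda evaluate --pred pred.csv --out metrics.csv
loda study --scenario scenario2 --replicates 10 --seed 1 --out study_out/
```

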
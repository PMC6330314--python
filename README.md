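# verticality

Tools for studying **perceived verticality under whole-body roll tilt** —
the psychophysics workflow of a developmental subjective-vertical experiment,
from adaptive trial placement to a Bayesian observer model of the resulting
biases.

When an observer lies tilted 90° to the side and judges whether a bar is
tilted toward or away from their body, the perceived vertical is typically
biased *toward* the body tilt (the Aubert or **A-effect**; negative bias in
our convention) and occasionally *away* from it (the **E-effect**, positive
bias). The size and sign of the bias depend on age and on the sensory
modality used (vision, touch, or both). This package implements the full
computational chain needed to collect, analyse and model such data — and,
because raw data of this kind are rarely public, a synthetic-study generator
that emulates the design (age groups 6–11 years and adults, 50 trials per
condition for children, 100 for adults, stimuli in ±45°).

## What is implemented

- **`verticality.psychometric`** — the cumulative-Gaussian observer
  P(away | x) = λ/2 + (1−λ)·Φ((x−α)/σ), maximum-likelihood estimation of the
  point of subjective equality α (PSE, the bias) and the just noticeable
  difference σ (JND, inverse precision), with convergence gating and bias
  classification (A-effect / E-effect / unbiased).
- **`verticality.psi`** — the PSI adaptive procedure: a discrete posterior
  over (α, σ) is updated by Bayes' rule after each response, and every trial
  presents the orientation that minimises the expected posterior entropy.
- **`verticality.integration`** — maximum-likelihood cue combination:
  σ²_VH = σ²_V σ²_H/(σ²_V+σ²_H), Ŝ_VH = w_V Ŝ_V + w_H Ŝ_H with
  inverse-variance weights, plus predicted-vs-observed group comparisons
  that expose a failure to integrate.
- **`verticality.prior`** — the Bayesian prior observer model: a Gaussian
  likelihood centred at the true tilt (−90°) whose width varies linearly
  with age, σ_a(age) = a0 + a1·age (rectified to stay positive), multiplied
  by a Gaussian prior over body orientations peaked at upright (0°),
  upside-down (−180°) or flat, with four placement policies (possibly
  different for children and adults). The posterior peak gives the predicted
  bias (true tilt − peak); the model is fit to group mean biases by
  exhaustive least-squares grid search over (policy, σ_p, a0, a1).
- **`verticality.synth`** — synthetic cohorts with ground-truth observers
  and PSI-collected trials; bimodal ground truth under optimal fusion,
  visual capture, or no integration.
- **`verticality.pipeline` / `verticality.cli`** — one-command orchestration
  (`verticality run --config …`) producing fits, group summaries, integration
  comparisons, prior-model fits and a run manifest.

## Worked example

Simulate one adaptive session against a known observer and refit it:

```python
import numpy as np
from verticality.psi import gaussian_observer, run_session
from verticality.psychometric import fit_pse_jnd, classify_bias

recs = run_session(gaussian_observer(pse_deg=-12.0, jnd_deg=3.0), 100, seed=42)
fit = fit_pse_jnd(np.array([t.stimulus_deg for t in recs]),
                  np.array([t.response for t in recs]))
print(f"PSE = {fit.pse_deg:+.2f} deg   JND = {fit.jnd_deg:.2f} deg   "
      f"converged = {fit.converged}   bias class = {classify_bias(fit.pse_deg)}")
```

```
PSE = -12.03 deg   JND = 2.48 deg   converged = True   bias class = A_effect
```

The 100 adaptively placed trials recover the generating bias (−12°) to a
fraction of a degree; the negative PSE classifies as an A-effect. Forward
predictions of the prior observer model, here for the reference visual
configuration (upright prior, σ_p = 24.7°, a0 = 5.3, a1 = 0.16):

```python
from verticality.prior import DEFAULT_VISUAL_PRIOR_FIT, forward_predict
ages = np.array([6, 8, 10, 25.0])
for a, b in zip(ages, forward_predict(*DEFAULT_VISUAL_PRIOR_FIT, ages)):
    print(f"age {a:4.0f} y: predicted visual bias {b:+6.2f} deg")
```

```
age    6 y: predicted visual bias  -5.60 deg
age    8 y: predicted visual bias  -6.13 deg
age   10 y: predicted visual bias  -6.69 deg
age   25 y: predicted visual bias -11.39 deg
```

A-effects at every age, growing with age as the sensory likelihood widens —
the noisier the sense, the harder the upright prior pulls the estimate.

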
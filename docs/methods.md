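# Methods

This note documents the models, numerical choices and known limitations of
the package, in the order data flow through the pipeline.

## Psychometric observer and fitting

The 2AFC observer is a cumulative Gaussian with a fixed symmetric lapse:

    P(away | x) = λ/2 + (1 − λ) Φ((x − α) / σ)

with α the PSE (deg; negative = A-effect, toward the body tilt), σ the JND
(deg) and λ the lapse rate. **λ is fixed at 0.02**, split evenly across both
asymptotes, for fitting and for all simulated observers: a free lapse is not
identifiable from 50-trial blocks, and holding it fixed keeps the adaptive
procedure, the generator and the fitter mutually consistent.

Fitting maximises the Bernoulli log-likelihood over (α, log σ) — the log
scale avoids boundary pathologies in σ — seeded by a coarse grid scan
(α: −40…40 step 2; log σ: 9 points over 0.4…35) and polished with
Nelder-Mead. A fit is **non-converged** when the optimiser fails, σ leaves
(0.2°, 40°), |α| ≥ 45°, or the finite-difference Hessian of the negative
log-likelihood at the optimum is not positive definite. Non-converged fits
(including the degenerate all-same-response case, which returns a flagged
record rather than raising) are excluded from every group-level aggregate;
the pipeline counts and reports them. Response probabilities are clipped at
1e−12 from both ends inside the likelihood.

## PSI adaptive procedure

A discrete posterior over (α, σ) starts uniform on a grid — α from −40° to
40° in 1° steps, σ log-spaced over 0.5°–30° with 25 points — and the
stimulus grid spans ±45° in 1.5° steps. Only the stimulus range is dictated
by the experimental design; the parameter grids are our choice, wide enough
to contain every plausible observer and fine enough that grid quantisation
is below the refit noise. The uniform start realises an unbiased initial
estimate through grid symmetry: the initial PSE-marginal mode is 0°. (A
non-uniform prior peaked at 0° would be an alternative reading; we default
to uniform.)

Each trial presents the stimulus minimising the expected posterior Shannon
entropy, averaging over both candidate responses weighted by their
predictive probabilities. The per-trial cost is four matrix–vector products
against precomputed likelihood tables, so full cohorts simulate in seconds.
All ties — in expected entropy, and in posterior modes — break
deterministically toward the smallest absolute value, negative before
positive, making sessions reproducible bit-for-bit under a fixed seed.

Final PSE/JND estimates always come from the separate maximum-likelihood
refit of the collected trials, not from the PSI posterior; the posterior
exists to place stimuli.

## Cue integration

Standard inverse-variance fusion: σ²_VH = σ²_V σ²_H/(σ²_V + σ²_H), weights
w_m ∝ 1/σ²_m, Ŝ_VH = w_V Ŝ_V + w_H Ŝ_H. Subjects enter the integration
analysis only with converged fits in all three conditions. The group
comparison (children < 18 y vs adults) reports means, mean paired
differences (observed − predicted) and two-sided paired t statistics with
Bonferroni correction over the groups present; it refuses groups with fewer
than three matched subjects and draws no scientific conclusion itself —
inference on real data is the user's job.

## Bayesian prior observer model

The estimate of body orientation is the peak of the product of a Gaussian
likelihood centred at the true tilt (−90°, assumed unbiased) and a Gaussian
prior over body orientations. Four prior-placement policies: flat
everywhere; upright (0°) everywhere; upright for children / flat for
adults; upright for children / upside-down (−180°) for adults. "Adult"
means age ≥ 18 y (the cohorts contain no one between 13 and 22, so the cut
is not load-bearing). The angle axis is treated as linear, not circular:
with centres at 0/−180 and tilts near −90 nothing wraps.

The likelihood width varies linearly with age, σ_a = a0 + a1·age, evaluated
at each group's mean age. Because a1 may be negative, σ_a is rectified over
the evaluated age set: if all values are positive, σ_b = σ_a + ε; otherwise
σ_b = σ_a − min(σ_a) + ε, which keeps every width positive, preserves the
age trend, and maps the most precise age to ε. (The alternative of *adding*
the minimum cannot produce positive widths once σ_a dips sufficiently
negative, so it cannot express a decreasing-width observer at all; the
subtraction is the only reading consistent with the model's stated intent.)
ε = 0.1° throughout.

The closed-form posterior peak (μ_L σ_p² + μ_p σ_b²)/(σ_p² + σ_b²) is
verified in the tests against the argmax of the numerically evaluated
density product on a 0.01° grid. Predicted bias = true tilt − peak: peaks
between −90° and 0° give negative biases (undercompensation, A-effect),
peaks between −180° and −90° positive ones (overcompensation, E-effect).

**Fitting** is an exhaustive grid search minimising unweighted SSE over
policy × σ_p × a0 × a1 (σ_p: 1–60° step 0.3; a0: −5–15 step 0.1; a1:
−0.5–0.5 step 0.02), with R² = 1 − SSE/SST over the observed group biases.
Weighting groups by n or SEM would be a defensible alternative; we fit
unweighted. Ties break deterministically: flat before peaked policies, then
smaller σ_p, smaller |a1|, smaller a0. `PriorModelSearch` precomputes the
forward predictions for all grid points (~340 MB for the default grids) so
Monte-Carlo replicate fits cost ~0.5 s each.

Two identifiability caveats, by construction of the model rather than of
the search: (i) whenever min(σ_a) ≤ 0 over the age set, a0 cancels out of
σ_a − min(σ_a), so a0 is not identified in that branch (the tie-break then
reports the smallest a0 among the ties); (ii) scaling σ_p and all σ_b by a
common factor leaves every predicted bias unchanged, so the parameters are
identified only up to the grid's discreteness. Fits of noisy data should be
read as policy-plus-shape estimates, not as precise parameter estimates —
consistent with the modest R² such models achieve on real group biases.

## Synthetic cohorts

The default cohort mirrors the reference design: groups of 6, 7, 10, 8, 15,
7 children at nominal ages 6–11 (ages jittered ±0.5 y) and 8 adults aged
22–37; 50 trials/condition for children, 100 for adults; conditions visual,
haptic, bimodal; one PSI session per subject × condition.

Ground-truth unimodal biases come from the forward prior model. The
defaults are the reference configurations: visual — upright prior at all
ages, σ_p = 24.7°, a0 = 5.3, a1 = 0.16 (A-effects of ~−6…−11° growing with
age); haptic — upright-children/upside-down-adults, σ_p = 28.3°, a0 = 0.3,
a1 = −0.16 (child A-effects shrinking with age, adults marginally
positive). Gaussian between-subject scatter (sd 4°, our choice of a typical
between-subject spread for tilted-vertical tasks) is added per modality.
True JNDs are log-normal (log-sd 0.25) around a median declining from 8° at
age 6 by 0.25°/year to a 3° floor — the 3–8° range typical of such tasks.
The bimodal truth follows the chosen regime: optimal fusion, visual
capture, or no integration (the more reliable modality is copied outright).

What the generator does *not* emulate: attentional lapses beyond the fixed
λ, distracted-child exclusions, sequential effects, any tilt-magnitude
dependence of the likelihood width, and circular-angle effects. Passing
recovery tests therefore demonstrates the internal consistency of the
analysis chain under its own assumptions, not the behaviour of real
children.

## Problem sizes and frozen thresholds

Monte-Carlo tests run at sizes chosen to make their statistics stable:
posterior-peak oracle, 1,000 draws at 0.02° tolerance; noisy policy
recovery, 100 replicates of 7 group biases with 2° noise (≥ 90% bar); PSI
recovery, 200 replicates each at 50 and 100 trials (±3° bar at ≥ 90%, and
median error at 100 < at 50); integration discriminability, 20 replicate
pairs of 10-adult cohorts (≥ 90% bar, a pair counting as distinguished when
the unfused cohort's observed−predicted JND gap is positive and exceeds the
magnitude of the fused cohort's gap). The haptic-like generator used for the
noisy policy-recovery check is (σ_p = 28.3°, a0 = 14, a1 = −0.24), which
produces child biases of ~−15…−13° and an adult bias of ~+5° — the
child-negative/adult-positive pattern with an adult signal resolvable above
2° group noise; the reference haptic configuration itself predicts an adult
E-effect of only ~+0.001°, which no finite-noise fit could distinguish from
a flat adult prior. All thresholds were calibrated once and frozen.

## Limitations

- The prior model is fit to biases only; JNDs are not fit, and the bimodal
  condition is not modelled by the prior observer.
- The linear (non-circular) angle treatment restricts validity to tilts
  away from the wrap-around points, which the ±45° stimulus range ensures.
- Group-level descriptive statistics are provided, but mixed-model ANOVAs,
  correlation batteries and corrected post-hoc tests on real data are out
  of scope by design.
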
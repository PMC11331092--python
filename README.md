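# swapmix

Mixture-model analyses of **swap errors** in delayed-estimation working
memory. In the underlying task a subject remembers two colors (an upper
and a lower item), is cued to one of them, and reports the cued color on
a continuous color wheel. Some error trials are *swaps* — reports of the
uncued item's color — and the central scientific question is *which
neural mechanism produces them*: misbinding of colors to locations
during storage, misinterpretation of the cue, or an error when the cued
item is selected from an intact memory.

The package provides, as a tested and reusable pipeline:

* a **hierarchical behavioral mixture model** of continuous reports,
* **spline-basis linear encoding models** of population activity,
* a **neural mixture model** over hypothesized error representations,
* **cross-validated projection, cue-decoding, and representational
  geometry** analyses, and
* a **synthetic-data generator** with known ground truth that every
  analysis is validated against.

It is aimed at systems/computational neuroscientists analysing binned
population spike counts from continuous-report working-memory tasks.

## Models

**Behavior.** The report r on a trial with target color t and distractor
d (angles on the hue circle) follows a three-component mixture,

```
p_i(r) = p_correct_i N_w(r − t; σ_i) + p_swap_i N_w(r − d; σ_i) + p_guess_i / 2π
```

with N_w a wrapped normal and one (p_swap, p_guess, σ) per session i.
Sessions are partially pooled through a softmax-logit hierarchy,
w_type_i ~ N(w_type, s_type), fit by Hamiltonian Monte Carlo
(4 chains × 500 warmup + 500 samples). Bayes' rule then gives each
trial posterior probabilities of being a correct, swap, or guess
response.

**Neural activity.** Population activity (dead units excluded, zero runs
imputed, z-scored, PCA-reduced) is modelled linearly on a periodic
B-spline basis f(·) with K = 5 knots:
`r(u, l) = W_u f(u) + W_l f(l) + η` before the cue, and with
role-specific weights plus cue intercepts
(`W_ut f(u) + W_ld f(l) + b_1` when the upper item is cued) after it.

**The neural mixture.** Each trial's activity is a mixture of Gaussians
centered on encoding-model *prototypes* — the nominal representation,
the color-swapped (misbound / misselected) one, the cue-flipped one, and
a reported-color variant for guesses — with weights gated by the trial's
behavioral type posteriors. The free scalars (p_misbind during the
first delay; p_selection, p_cue during the second; p_resp for guesses)
measure how often each error representation actually appears, and are
fit jointly with the encoding weights by HMC.

**Cross-validated analyses.** A leave-one-out projection index
x = (r̄_A − r̄_B)·(r − r̄_B)/‖r̄_A − r̄_B‖² locates held-out trials between
the nominal (x = 0) and error (x = 1) prototypes; a linear cue decoder
trained on likely-correct trials tests whether the cue representation
generalizes to likely-swap trials; and a cross-validated dot-product
estimator gives unbiased squared distances between the three hypothesized
representations, embedded in 2-D by classical MDS.

## Worked example

```python
import numpy as np
from swapmix import (GeneratorSpec, HierarchicalBehaviorModel,
                     NeuralMixtureModel, SpikePreprocessor)
from swapmix.behavior import type_posteriors_from_params
from swapmix.synth import generate_session

# one synthetic session: 500 trials, 60 units, 70% selection errors and
# 30% cue-misinterpretation errors among swap trials
spec = GeneratorSpec(n_sessions=1, trials_per_session=500, n_units=60,
                     seed=42, mechanism_mix={"misselect": 0.7, "miscue": 0.3})
ses = generate_session(spec, np.random.default_rng(42), 0)

behav = type_posteriors_from_params(ses.trials, ses.truth.params)
activity = SpikePreprocessor(second_zscore=True, max_dims=24).fit_transform(
    ses.epochs["delay2"].summed())

model = NeuralMixtureModel(epoch="delay2", seed=5, max_leapfrog=48).fit(
    activity, ses.trials, behav)
print(model.weights_)
```

prints (exact draws depend on the sampler seed)

```
MixtureWeights(p_misbind=None, p_selection=0.59, p_cue=0.34, p_resp=0.56)
```

i.e. the model attributes ~0.59 of the swap-trial probability mass to a
selection-error representation and ~0.34 to a cue-misinterpretation one,
recovering the generating 0.7 / 0.3 mix from 37 swap trials within the
posterior uncertainty (SD ≈ 0.10). On a null generator whose swap trials
carry the nominal representation the same fit returns
p_selection + p_cue ≈ 0.25 or less.

A command-line interface mirrors the library:

```
swapmix simulate -s 2 -t 300 -u 40 --seed 0 --out data/
swapmix behavior --sessions data/session000_behavior.csv --out fit.json \
        --posteriors-out posteriors.csv
swapmix run --data data/ --tier ci --out results/
swapmix benchmark --tier ci
```

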
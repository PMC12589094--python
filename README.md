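# lifecourse

Generative transformer modelling of lifetime disease trajectories.

A person's health history — first-occurrence diagnoses, lifestyle
markers, "still healthy" padding and eventually death, each recorded
at a continuous age — is modelled autoregressively by a GPT-style
transformer whose per-token logits are log event rates per day.  The
competing-exponentials identity turns one logits vector into both the
next-event distribution (`λ_j/Σλ`, the softmax) and the waiting-time
law (`Exponential(Σλ)`), so the same model predicts *what* happens
next, *when* it happens, and absolute disease incidence — and can
simulate entire future health trajectories by sampling.

The package is aimed at methods work on event-stream health models
where registry data are access-restricted: it ships a ground-truth
hazard simulator (age-dependent, sex-specific, with decaying pairwise
comorbidity effects), the full training and sampling machinery, an
age/sex-stratified evaluation stack (DeLong-combined AUC, calibration,
incidence cross-entropy, Nelson–Aalen baselines), and masking-based
Shapley attribution of rate changes to past events.

## The model in brief

Events are pairs `(age, token)`.  Three changes adapt a standard
decoder-only transformer to continuous time:

* positional encodings are replaced by a sinusoidal **age encoding**
  (trainable linear mix of sin/cos at periods from 100 years to
  2 days);
* causal attention additionally **masks same-age events**, which carry
  no ordering information;
* the loss is the joint likelihood of the competing-exponentials
  model,

  `loss = −log softmax(logits)[next] − (logsumexp(logits) − Σ exp(logits) · T)`

  with `T` the waiting time in days, evaluated only on disease, death
  and no-event tokens; co-occurring events are predicted from the last
  strictly earlier token.

At the published hyperparameters (embedding 120, 12 layers, 12 heads,
1,270-token vocabulary, tied embeddings, bias-free layers) the
architecture counts 2.2 million trainable parameters.  Everything runs
on numpy; the package contains its own compact reverse-mode autodiff
engine and Adam loop (with the gradient clipping that the waiting-time
head makes essential — see `docs/methods.md`).

## Worked example

```python
import numpy as np
from lifecourse import (
    DiseaseTrajectoryModel, ModelConfig, TrainConfig,
    OracleRateModel, fixture_presets, prepare_cohort, simulate_cohort,
)

preset = fixture_presets()["tiny"]          # 5 diseases, known hazards
vocab = preset.hazard_model.vocab
cohort = simulate_cohort(200, preset.hazard_model, seed=11)
prepared = prepare_cohort(cohort, vocab, seed=12)   # death-truncate + padding

model = DiseaseTrajectoryModel(
    prepared, vocab, config=ModelConfig.desk_scale(len(vocab))
)
result = model.fit(TrainConfig.desk_scale(total_iters=300, warmup_iters=30, seed=4))
print(result.summary())
```

```
Disease trajectory transformer — fit summary
====================================================
vocabulary size      19
embedding dim        32
layers / heads       4 / 4
trainable params     51,072
weight tying         True
iterations           300 (batch 48)
learning rate        0.006 -> 0.0006 (cosine)
----------------------------------------------------
final token loss     0.7475 nats/event
final time loss      8.1554 nats/event
final total loss     8.9029 nats/event
```

The token loss is the categorical head in nats per predicted event —
already well below the ln 7 ≈ 1.95 of a uniform guess over this
preset's 7 predictable tokens; the time loss is the exponential
waiting-time negative log-likelihood (its scale is set by the typical
inter-event gap of a few hundred days).  The fitted object predicts
per-token rates and annual risks, samples future trajectories, and
attributes predictions:

```python
traj = prepared[0]
risks = result.predict_annual_risk(traj)        # P(token within 1 year)
future = result.sample(traj, stop_age_years=80, seed=1)
shap = result.shapley(traj, targets=vocab.death_index)
print(shap.for_target(vocab.death_index))       # per-event log-rate attributions
```

A command-line interface covers the same pipeline
(`lifecourse simulate | prepare | train | sample | evaluate`).

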
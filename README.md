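# gyrosde

Latent neural-SDE characterization of repetitive human motion from
smartphone gyroscope signals.

Wearable-sensor studies of walking, running, squats and similar
repetitive motions produce high-dimensional, noisy angular-velocity
streams whose scientifically interesting structure — tempo, cycle shape,
person-specific style, motion changes — lives on a low-dimensional
manifold. `gyrosde` fits that structure directly: a two-dimensional
latent stochastic differential equation

    dz = mu_theta(z) dt + sigma_theta dW

models the motion dynamics, an MLP decoder maps the latent state to the
mean of the observed 4-channel frame (three gyro axes plus magnitude,
z-scored), and a small causal GPT2-style transformer serves as the
amortized filtering posterior `q(z_t | x_{0:t})`. Generative and
inference parameters are trained jointly by maximizing the sequential
evidence lower bound

    ELBO = sum_t E_q[ log p(xbar_{t+1} | z_t) ]
         - KL(q(z_0|x_0) || p(z_0))
         - sum_t E_q[ KL(q(z_t|x_{0:t}) || p(z_t|z_{t-1})) ],

where `xbar_{t+1} = (x_t + x_{t+1})/2` and `p(z_0)` is a PCA-anchored
Gaussian prior. On top of the fitted model the package provides the
downstream analyses: latent-trajectory extraction (causal, online),
attention heat maps, contrastive user identification, initial-state
optimization from a pre-window of observations, kernel-density "normal
latent regions" per motion, and motion-switch detection. A synthetic
multi-subject, multi-motion generator with known ground truth (walking at
1/30 cycles per sample at 30 Hz, running at 1/20, ...) makes every stage
testable without recorded data.

It is aimed at researchers in wearable-sensor biomechanics and
biomedical time-series modelling who want an interpretable latent
dynamical account of periodic motion rather than a black-box activity
classifier. See `docs/methods.md` for the full model description and
design rationale. The package is pure Python on numpy/scipy (networks
train through a compact in-package reverse-mode autodiff engine — the
models are deliberately small).

## Worked example

```python
import gyrosde as g
from gyrosde.analysis import dominant_period

# one subject, walking (period 30 samples) and running (period 20)
subject = g.SubjectProfile("s01", phase_offsets=(0.3, 1.1, 2.2))
recs = [g.generate_recording(g.archetype(m), subject, 1500, seed=i)
        for i, m in enumerate(("walking", "running"))]

model = g.MotionSDE.from_recordings(recs, T=90, user_key="motion")
results = model.fit(g.TrainConfig(n_epochs=150, seed=0))
print(results.summary())

frames = results.normalize(recs[0])          # raw -> normalized frames
z = results.latent_trajectory(frames[1200:]) # held-out latent trajectory
print("walking latent period:",
      round(dominant_period(z[30:, 0]), 1), "samples")
```

Output from this exact script:

```
Latent neural-SDE motion model
======================================
window length T+1        : 91
latent dimension         : 2
transformer              : 2 layers, 1 head(s), embed 32
training windows         : 26
validation windows       : 6
diffusion sigma_theta    : 0.1073
observation sd           : 0.8301
posterior sd             : 0.0882
prior sigma_0            : 0.20
epochs                   : 150
final train loss (-ELBO) : 406.253
final validation loss    : 341.757
walking latent period: 30.0 samples
```

The summary reports the fitted scales: the latent diffusion
`sigma_theta`, the decoder's observation noise (in z-scored units), and
the posterior sd, alongside the negative-ELBO traces used to monitor
overfitting. The last line is the headline property: the latent
trajectory of held-out walking data oscillates at the same 30-sample
period as the input signal — the latent space preserves the motion's
time-domain frequency while compressing four channels into two
coordinates.

A command-line interface mirrors the pipeline
(`gyrosde simulate | preprocess | train | infer | analyze`); each
command logs its seed and configuration hash, and artifacts are plain
CSV/JSON.

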
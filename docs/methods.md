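# Methods

`gyrosde` characterizes repetitive human motion from smartphone gyroscope
signals by fitting a two-dimensional latent stochastic differential
equation to windowed sensor observations, with a causal transformer as
the amortized filtering posterior. This note records the model, its
assumptions, the numerical choices, what the synthetic data does and does
not emulate, and the package's known limitations.

## Generative model

Observations are 4-channel frames `x_t = (omega_x, omega_y, omega_z,
omega_T)`: the three angular-velocity axes plus their Euclidean magnitude,
each z-scored with statistics fit on the training split only. The latent
state `z_t` in R^2 follows the simplified neural SDE

    dz = mu_theta(z) dt + sigma_theta dW,

discretized by Euler–Maruyama with one substep per 30 Hz sample. We fix
`dt = 1`: the physical time unit is absorbed into the learned drift and
diffusion, so nothing is lost and one hyperparameter disappears. The
drift `mu_theta` is a tanh MLP (default 2→64→64→2) whose output layer is
zero-initialized, making the untrained transition an identity-mean random
walk — a neutral starting point for optimization. The diffusion is a
single positive scalar (softplus-parameterized), i.e. isotropic latent
noise; a state-dependent diffusion network adds nothing at k = 2 and
hurts interpretability.

The decoder maps `z_t` to the mean of an isotropic Gaussian over the
*midpoint target* `xbar_{t+1} = (x_t + x_{t+1})/2` — the compromise
between pure reconstruction (which over-oscillates the latents) and pure
one-step prediction (which over-smooths them). The observation noise is a
single learned scalar sd shared across channels; a Gaussian likelihood is
the natural choice for real-valued z-scored data and makes the
reconstruction term of the bound well defined.

The initial-state prior is `p(z_0) = N(mu_0, sigma_0^2 I)` with
`sigma_0 = 0.2` fixed (not trained) and `mu_0` the projection of `x_0`
onto the two leading principal components of the training frames (history
length m = 0: only the current frame enters). PCA's sign ambiguity is
removed by forcing the largest-magnitude loading of each component
positive.

## Inference model

The filtering posterior factorizes causally,

    q(z_{0:T} | x_{0:T}) = q(z_0|x_0) prod_t q(z_t | x_{0:t}),

each factor an isotropic Gaussian `N(mu_t, sigma_q^2 I)` whose means all
come from one forward pass of a small decoder-only (GPT2-style)
transformer: learned linear token embedding of the 4-channel frame,
learned positional embeddings, two pre-norm blocks with single-head
causal self-attention and a 4× GELU feed-forward, final layer norm, and
a linear head to R^2. Defaults: 2 layers, 1 head, embedding width 32,
maximum sequence length 91 tokens (so a full training window fits). The
causal mask makes `mu_t` a function of `x_{0:t}` only — the posterior is
a filter, usable online, in contrast to smoothing posteriors that
condition on future frames. The posterior scale `sigma_q` is one learned
global scalar; per-step variance heads add parameters without improving
the bound on these data. No dropout anywhere: the model is tiny and
overfitting is monitored through the validation trace instead.

## Objective and training

A training window holds `T + 1 = 91` frames and is self-contained: it
yields `T` reconstruction terms, one initial KL and `T - 1` transition
KLs,

    ELBO = sum_{t=0}^{T-1} E_q log p(xbar_{t+1} | z_t)
         - KL(q(z_0|x_0) || p(z_0))
         - sum_{t=1}^{T-1} E_q KL(q(z_t|x_{0:t}) || p(z_t|z_{t-1})),

with the transition prior `p(z_t|z_{t-1}) = N(z_{t-1} +
mu_theta(z_{t-1}), sigma_theta^2 I)` evaluated at a reparameterized
sample of `z_{t-1}`. All KLs are closed-form isotropic-Gaussian
expressions (asserted non-negative inside the loss); outer expectations
use one reparameterized sample per step by default (`mc_samples`
configurable). Training minimizes the mean negative ELBO per window with
AdamW (decoupled weight decay; defaults lr 1e-3, weight decay 1e-2,
batch size 128), gradients from a small in-package reverse-mode autodiff
engine (`gyrosde.autodiff`) — the networks are small enough that
vectorized numpy with taped gradients trains them in minutes on one CPU.
Validation loss is the deterministic (noise-free reparameterization)
negative ELBO on the held-out windows, recorded every epoch; the
overfitting check fires when the running best is at least `patience`
epochs old and the trace has risen above it since.

Degenerate inputs are rejected rather than silently handled: zero-variance
channels raise on z-score fitting, non-finite losses abort training with
the offending term named, and a non-convergent initial-state optimization
raises instead of returning garbage.

## Contrastive term

An optional discriminator `C_omega(x_t, z_t)` (MLP on the concatenated
pair, default hidden width 64) scores same-source pairs high and
cross-source pairs low:

    L_contrast = - mean over ordered pairs (a, b != a) and steps t of
        [ log sigma(C(x_t^a, z_t^a)) + log(1 - sigma(C(x_t^a, z_t^b))) ].

Negative pairs align users by step and drop trailing steps beyond the
shortest sequence. A variant evaluating `log sigma(1 - C)` on negatives
is available behind `literal_form=True`; the default is the standard
discriminator loss, which is a proper saturating objective (a perfect
discriminator drives it to zero, which the literal form does not). The
term's gradients reach the discriminator and the posterior but not the
generative parameters, which it never touches. "Users" are whatever the
grouping key says: subjects for identification, motions for multi-motion
runs — in the latter case the term separates the motions' latent regions
in the shared space.

The total loss is `-ELBO + w * L_contrast`. Because the ELBO sums ~90
step terms while the contrastive term is a per-pair-per-step mean, `w`
must be of order 10–100 for the term to shape the latent geometry at
all; the reference experiments use w = 300 (multi-motion separation) and
w = 100 (user identification).

## Post-training analyses

**Latent trajectories.** For sequences longer than the encoder's maximum
length, a dense stride-1 window slides along the sequence and the last
position of each window is kept, so every estimate is causal and uses at
most 91 past frames. The first ~30 steps are an encoder warm-up transient
and are dropped from spectral and region analyses.

**Initial-state optimization.** Given a pre-window `x_{-T0:0}`, the start
state `z_{-T0}` minimizing the squared discrepancy between the decoded
noise-free rollout (drift only — sampling noise would make the objective
stochastic) and the observed midpoint targets is found by adaptive-moment
gradient descent (500 iterations, step 1e-2, model weights frozen),
initialized at the PCA projection of `x_{-T0}`. The best iterate is
returned, so the result is never worse than the PCA initialization; the
trace reports the running best (monotone by construction).

**Latent regions.** Per-motion Gaussian KDE (scipy, Scott's-rule
bandwidth) over training latents; the membership threshold is the 5th
percentile of the density at the fitting points, so ~95% of them are
members by construction and membership is a binary test rather than a
visual judgment. A forced isotropic bandwidth is available for controlled
settings (including the single-point closed form `1/(2 pi h^2)`).

**Motion switching.** Trajectories are smoothed with a trailing moving
average (window 5 — trailing, not centered, to stay online), each step
labelled by the highest-density region or 'abnormal' below every
threshold. A motion becomes *active* after at least 5 consecutive steps
carry its label: inside the transition zone the encoder's window mixes
both motions and produces isolated one-step labels that are noise, not
activity. A switch is timed one step past the previous motion's last
confirmed run, because leaving the normal region is promptly observable
while settling into the next region lags by up to the encoder history.

## Synthetic data

The generator emulates thigh-worn gyroscope logs of repetitive motion:
each axis is a harmonic series (weights 1.0, 0.4, 0.15) of a
motion-specific fundamental — walking 30 samples/cycle at 30 Hz, running
20, squats 45, jumping jacks 25 — scaled by per-axis base amplitudes
(running ≈ 2× walking, in rad/s) and per-subject factors: tempo ~
U(0.85, 1.15), amplitude ~ U(0.7, 1.3), per-axis phases ~ U(0, 2π),
plus white Gaussian noise (default sd 0.05 rad/s). The walking/running
periods are the anchored quantities; squat and jumping-jack parameters
are fixture choices. Motion switches carry accumulated phase across the
switch so the fundamental is continuous and only frequency and
amplitude jump.

What this does *not* emulate: waveform asymmetry and impact transients of
real gait, sensor bias/drift, amplitude modulation, within-recording
tempo drift, and accelerometer channels. Passing tests therefore
demonstrate that the method recovers the latent structure of
band-limited, phase-continuous periodic signals with known ground truth —
necessary machinery checks, not evidence about any particular real
recording.

## Reference experiment sizes

The reference experiments (`gyrosde.experiments`) run the full pipeline
at sizes chosen so each completes in a few minutes on one CPU: recordings
of 1500 samples per motion (26 training windows of 91 frames after the
80/20 chronological split), compact networks (drift and decoder 32+32
hidden units, encoder width 32), 800 epochs for the multi-motion study
and 600 for the identification study. At ~26 windows a batch of 128 is
one full-batch step per epoch, so epoch counts here play the role of
optimizer steps. The identification study fixes the two users' tempo
scales at the cohort extremes (0.85 and 1.15) — the well-separated-tempo
condition — with phases drawn randomly.

## Known limitations

- The latent dimension is fixed at k = 2 by design; higher-dimensional
  variants would need a different visualization story.
- Frequency readout uses the dominant FFT bin of held-out latent
  trajectories; with ~300-sample held-out segments the bin granularity
  near period 20 is ±0.8 samples.
- The transition KL uses a single-sample outer expectation by default;
  gradient variance is visible at very small batch sizes.
- Switch timing inherits a lag of up to the encoder window when entering
  the *new* region; timing by departure from the previous region (as
  implemented) keeps the error within a few samples.
- Training is full-precision CPU numpy; it is fast for these model sizes
  but does not scale to large encoders.
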
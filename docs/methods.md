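# Methods

## Model

`prespike` simulates a discrete-time leaky integrate-and-fire neuron whose
synaptic weights evolve online so that the membrane potential becomes a
one-dimensional predictive summary of the synaptic input. The membrane
recursion on a timestep grid `h` is

    v_t = α v_{t−1} − v_th s_{t−1} + wᵀ x_t,     α = 1 − h/τ_m
    s_t = H(v_t − v_th),                          H(0) = 1

with resting potential 0, subtractive reset (one step after the spike, no
refractory period) and `x_t` the presynaptic spike trains convolved with a
causal exponential kernel of time constant `τ_x` (unit amplitude at the
spike step, decay `exp(−h/τ_x)` per step; coincident spikes sum).

The neuron's self-supervised objective is the cumulative squared error of
predicting each input from the previous voltage,

    L = Σ_t ½ ‖x_t − v_{t−1} w‖²,

and plasticity descends this objective. Per timestep the rule computes the
per-synapse prediction error `ε_t = x_t − v_{t−1} w_{t−1}`, the global
signal `E_t = ε_tᵀ w_{t−1}`, and the influence (eligibility) vector
`p_t = α p_{t−1} + x_t`, which is the forward-accumulated gradient of the
voltage with respect to the weights when the derivative through the spike
nonlinearity is dropped (surrogate scale γ = 0 — the voltage, not the spike
train, is the output variable of the objective, so the Jacobian of the
recursion is simply α at every step and `p` is not reset at spikes). The
weight update is

    w_t = w_{t−1} + η (ε_t v_{t−1} + E_t p_{t−1})           (online)
    w_t = w_{t−1} + η w_{t−1} ⊙ (ε_t v_{t−1} + E_t p_{t−1}) (online, scaled)

The first bracket term is a time-shifted Oja rule — Hebbian correlation
`x_t v_{t−1}` plus heterosynaptic decay `−v_{t−1}² w_{t−1}`; the second term
propagates errors between synapses through the eligibility traces. The
scaled variant premultiplies by the current weight, keeping weights
non-negative (zero is a fixed point). A batch mode computes the exact
epoch gradient `−Σ_t (ε_t v_{t−1} + E_t p_{t−1})` at fixed weights and
applies it once per epoch with plain gradient descent or Adam
(β₁ = 0.9, β₂ = 0.999, ε = 1e−8); for `η τ_m ≪ 1` the online rule tracks
this batch direction (timescale separation; asserted as a test property).

Within one timestep the order of operations is: error and global signal
from `(x_t, v_{t−1}, w_{t−1})`; loss accumulation; weight update; influence
update; membrane update **with the new weights** and spike emission. Each
epoch is an independent presentation: `v`, `s` and `p` restart from 0 and
only the weights persist.

## Parameters and defaults

Five physical hyperparameters determine the simulator. Defaults:

| parameter | default | unit | role |
|---|---|---|---|
| `h` | 0.05 | ms | integration step (all experiments) |
| `τ_m` | 10 | ms | membrane leak; sets the prediction horizon |
| `τ_x` | 2 | ms | input (and lateral) kernel; EPSC-like fast decay |
| `v_th` | 1.0 | — | spiking threshold |
| `η` | 1e−3 (scaled) / 1e−7 (plain, network) | per step | plasticity rate |

`v_th` and `η` are calibration choices (no canonical values exist): with
`v_th = 1` a lone presynaptic spike at unit weight peaks the membrane at
≈ 27 · w, and the two-spike protocol's weight plane splits into no-spike
(w ≲ 0.02 on the diagonal), single-spike, and multi-spike (w ≳ 0.035)
regions inside w ∈ [0, 0.06]. The scaled-rule `η = 1e−3` makes the
two-input protocol start spiking near epoch 60 and fire ahead of the later
input by epoch ≈ 80 — the anticipation timeline the protocol is defined by.
`η` is exposed everywhere; the online approximation requires the weight
drift per membrane time constant to be small (a test asserts the drift
scales linearly with η).

STDP protocols pin "subthreshold" and "suprathreshold" inputs by initial
weights whose lone-spike EPSP peaks at 0.5 and 1.5 × threshold; the burst
protocol uses a weaker probe (0.2 ×, 20 repetitions instead of 60) because
with a strong probe the heterosynaptic drag — which grows with the burst's
summed squared depolarization — masks the eligibility-trace potentiation
and inverts the frequency ordering of LTP. These factors are configuration,
exposed on every protocol function.

## Synthetic inputs

All data are generated internally; nothing is fitted to external
recordings.

* **Two-input pattern** — one spike each on two channels (2 and 6 ms
  defaults), T = 500 ms, noise-free and bit-reproducible.
* **Jittered sequence** — N = 100 channels firing once at 2 ms delays
  (200 ms nominal span = span plus one inter-spike interval), spike times
  jittered uniformly in ±2 ms, per-channel homogeneous Poisson background
  with rates drawn uniformly from 0–10 Hz, 100 distractor channels with the
  same rate law, sequence onset uniform in 0–200 ms per epoch, T = 400 ms.
  Poisson background is realized by per-timestep Bernoulli thinning
  (rate · h ≈ 5e−4 at 10 Hz, exact to grid resolution). Jitter that would
  leave the window is clipped to the boundary.
* **STDP schedules** — deterministic two-channel event times per protocol:
  pairing at delay Δt (Δt < 0 means the probe leads); bursts of three
  driver spikes at 1/f spacing with the probe 10 ms before/after; the
  post-pre-post 1-n motif at 100 Hz (10 ms spacings); five post-pre pairs
  (driver leading by 6 ms) repeated at the pairing frequency, with the
  epoch window extended automatically at low frequencies.
* **Network stimulus** — 10 neurons × 8 afferents; afferent block n starts
  at 4 ms × n, spikes at 2 ms delays (16 ms nominal sub-sequence), ±2 ms
  jitter, 10 Hz background on all 80 channels, T = 60 ms.

What the generators do *not* emulate: correlated background, rate
modulation, inhomogeneous Poisson statistics, conductance synapses,
dendritic structure. Passing tests therefore demonstrate properties of the
learning rule under idealized point-neuron drive, not fits to physiological
recordings.

## Recurrent network

Each of M = 10 neurons owns its afferent block plus one lateral input
channel per presynaptic network neighbor (nearest-neighbor chain by
default; all-to-all and random wiring are available). A spike of neuron j
at step t−1 enters neuron i's lateral channel at step t as an event of
amplitude `lateral_gain`, filtered with the same exponential kernel as the
afferents; plasticity treats lateral channels identically and no gradient
flows through the recurrence (each neuron's influence vector spans only its
own input channels), as the discontinuous recurrent contributions are
dropped alongside the spike nonlinearity.

Two properties of this system shaped the shipped experiment configuration:

1. **The silent state is the optimum.** The prediction objective is
   minimized when nothing fires; with all afferent *and* lateral weights
   plastic, long conditioning converges there (lateral weights settle at
   the self-prediction value, afferent weights are crushed by the
   heterosynaptic term). The functional circuit — potentiated earliest
   afferents plus a forward n−1→n lateral chain — is a structured *phase*
   of training, not its fixed point. The conditioning experiment therefore
   trains for 2000 epochs, measures the duration compression across the
   whole run, and takes the recall weights from a mid-training checkpoint
   (epoch 500), mirroring the practice of reporting trained weights at the
   middle of a longer conditioning schedule.
2. **Lateral gain.** With unit-amplitude lateral events the recurrent
   channels out-compete the afferents before any within-block structure
   forms, and reverberation drives the weights to the silent optimum within
   a single epoch. The lateral event amplitude is a free modeling choice
   (recurrent synaptic efficacy need not equal afferent efficacy);
   `lateral_gain = 0.15` slows recurrent takeover enough that the
   checkpoint network supports a cued forward wave. Conditioning defaults:
   `w0_aff = 0.012`, `w0_lat = 0.05`, plain online rule at `η = 1e−7`.

At the checkpoint, cueing only the first neuron's afferents launches a
forward wave that activates all ten neurons in most noise realizations;
*strict* first-spike ordering across all ten holds in roughly 25–55% of
noise seeds (background spikes occasionally fire a tail neuron before the
wave arrives), so the ordered-recall-in-majority property is not met by
this implementation and the corresponding acceptance test is expected to
fail; the compression and all-neuron-activation properties are robust.
Recall presentations run with frozen weights on a copy of the state.

## Loss bookkeeping on the sequence task

Per-epoch records hold the cumulative loss L, the loss normalized by its
epoch-0 value, and the cumulative membrane potential Σ_t v_t. Under online
scaled training from the fixed init (w0 = 0.02) the cumulative
depolarization falls to ≈ 15–20% of its initial value while the raw loss
stays near the irreducible floor ½‖x‖² set by unpredictable background
spikes (the converged solution even adds a small burst-mismatch term). The
declining normalized-loss curve is produced by the epoch-wise variant:
Adam (step 1e−3, 300 epochs) from a truncated-normal init (mean 0.05,
sd 0.3/√N, truncated at 0), which starts from a high-loss state and
descends to ≈ 0.91 of it. Both declines are asserted in the acceptance
suite.

## Numerical choices

* Threshold ties (`v == v_th`) count as spikes, for determinism.
* Spike times are reported as `t · h` of the step where `s_t = 1`.
* A divergence guard aborts any epoch where |v| exceeds 1e6 — the symptom
  of a misconfigured learning rate — with a diagnostic exception.
* ε and E use `w_{t−1}`; the membrane update uses the fresh `w_t`.
* The inner loops are numba kernels; pure-numpy step functions define the
  reference semantics and the test suite asserts the two routes agree to
  machine precision. Epoch-wise (batch) network updates accumulate the
  online bracket at fixed weights and apply it (plain or Adam) at epoch
  end.
* Problem sizes in the shipped tests: 10 training runs × 1000 epochs for
  the sequence task, 300 epochs for the 20×20 asymmetry grid, 2000
  conditioning epochs for the network, 60 (20 for bursts) repetitions per
  STDP point — each the smallest size at which the corresponding effect is
  stable across seeds.

## Known limitations

* The γ ≠ 0 surrogate branch is not implemented (no functional form is
  defined for it); requesting it raises.
* The "switch from potentiation to depotentiation with increasing initial
  synaptic strength" is reproduced only as a monotone *decline* of LTP with
  initial strength; no sign change occurs for probes up to 3.5 × threshold
  in this parameterization.
* Post-pre burst depression deepens with intra-burst frequency rather than
  staying flat; the emitted CSV curves make the deviation visible.
* The recurrent network's functional recall state is transient (see above)
  and strict ordered recall holds only in a minority of noise seeds.
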
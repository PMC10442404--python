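"""Executable experiment protocols.

Single-neuron experiments built on the predictive learning rule:

* two-input anticipation (a fixed pair of presynaptic spikes 4 ms apart;
  the neuron learns to fire ahead of the later input),
* the weight-space flow field and asymmetry-index grid over initial weights,
* the jittered-sequence anticipation task with its success criteria,
* the STDP battery: pairing window, burst-frequency, 1-n multi-spike and
  frequency-pairing protocols, plus the fixed-supra-weight and
  initial-strength-sweep variants.

All STDP protocols are deterministic (noise-free) and run the scaled online
rule; 'subthreshold' and 'suprathreshold' inputs are pinned by initial
weights whose lone-spike EPSP peaks at 0.5 and 1.5 times threshold
respectively (the protocols only require the threshold relation; the factors
are configurable).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import DEFAULT_ETA_SCALED, default_neuron_params
from .inputs import (
    InputTrace,
    SequenceSpec,
    filter_raster,
    generate_sequence_epoch,
    make_stdp_schedule,
    make_two_input_pattern,
)
from .metrics import output_latency, threshold_fraction_weight
from .neuron import NeuronParams
from .plasticity import (
    LossRecord,
    PlasticityParams,
    SynapseState,
    run_epoch_trained,
)

__all__ = [
    "ProtocolResult",
    "StdpCurve",
    "run_two_input",
    "flow_field",
    "asymmetry_index",
    "asymmetry_grid",
    "run_sequence_task",
    "evaluate_sequence_response",
    "stdp_pairing_curve",
    "stdp_burst_curve",
    "stdp_one_n_curve",
    "stdp_freq_pairing_curve",
    "stdp_variants",
]


def _defaults(nparams, pparams):
    if nparams is None:
        nparams = default_neuron_params()
    if pparams is None:
        pparams = PlasticityParams(eta=DEFAULT_ETA_SCALED, mode="online_scaled")
    return nparams, pparams


@dataclass
class ProtocolResult:
    """Per-epoch records of one protocol run."""

    w_traj: np.ndarray                    # (n_epochs + 1, n_channels)
    spike_times: list                     # per-epoch arrays of output spike times (ms)
    losses: LossRecord
    summary: dict = field(default_factory=dict)

    @property
    def n_epochs(self) -> int:
        return self.w_traj.shape[0] - 1

    @property
    def first_spike_times(self) -> np.ndarray:
        return np.array(
            [st[0] if len(st) else np.nan for st in self.spike_times]
        )

    @property
    def spike_counts(self) -> np.ndarray:
        return np.array([len(st) for st in self.spike_times])


def _train_on_trace(
    trace: InputTrace,
    w0: np.ndarray,
    n_epochs: int,
    nparams: NeuronParams,
    pparams: PlasticityParams,
    freeze_channel: int | None = None,
) -> ProtocolResult:
    """Repeat one fixed trace for ``n_epochs`` of online training."""
    syn = SynapseState(np.asarray(w0, dtype=float))
    w_traj = np.empty((n_epochs + 1, syn.n_channels))
    w_traj[0] = syn.w
    spike_times = []
    loss = np.empty(n_epochs)
    cum_v = np.empty(n_epochs)
    for k in range(n_epochs):
        res = run_epoch_trained(trace, syn, nparams, pparams)
        syn = res.syn
        if freeze_channel is not None:
            syn.w[freeze_channel] = w0[freeze_channel]
        w_traj[k + 1] = syn.w
        spike_times.append(res.spike_times)
        loss[k] = res.loss
        cum_v[k] = res.cum_v
    return ProtocolResult(w_traj, spike_times, LossRecord(loss=loss, cum_v=cum_v))


# ---------------------------------------------------------------------------
# Two-input anticipation (deterministic pair of presynaptic spikes)
# ---------------------------------------------------------------------------

def run_two_input(
    w0=(0.005, 0.005),
    delay: float = 4.0,
    t_first: float = 2.0,
    T: float = 500.0,
    n_epochs: int = 300,
    nparams: NeuronParams | None = None,
    pparams: PlasticityParams | None = None,
) -> ProtocolResult:
    """Train on two presynaptic spikes ``delay`` ms apart (defaults 2 and 6 ms).

    The earlier input predicts the later one; across epochs its weight is
    potentiated, the later input is depressed, and the output spike migrates
    ahead of the second input's arrival time.
    """
    if delay < 0:
        raise ValueError("delay must be non-negative")
    nparams, pparams = _defaults(nparams, pparams)
    trace = filter_raster(
        make_two_input_pattern(t_first, t_first + delay, T), nparams.h
    )
    res = _train_on_trace(trace, np.asarray(w0, float), n_epochs, nparams, pparams)
    res.summary["t_inputs"] = (t_first, t_first + delay)
    return res


def flow_field(
    w1_values: np.ndarray,
    w2_values: np.ndarray,
    n_epochs: int = 10,
    delay: float = 4.0,
    t_first: float = 2.0,
    T: float = 500.0,
    nparams: NeuronParams | None = None,
    pparams: PlasticityParams | None = None,
) -> dict:
    """Weight-space flow of the two-input protocol.

    For every initial pair on the grid, returns the weight displacement after
    ``n_epochs`` epochs and the number of output spikes in the first epoch
    (whose level sets partition the plane into no-spike / single-spike /
    multi-spike regions).
    """
    nparams, pparams = _defaults(nparams, pparams)
    trace = filter_raster(
        make_two_input_pattern(t_first, t_first + delay, T), nparams.h
    )
    G1, G2 = len(w1_values), len(w2_values)
    dw = np.empty((G1, G2, 2))
    spikes_first = np.empty((G1, G2), dtype=int)
    for i, w1 in enumerate(w1_values):
        for j, w2 in enumerate(w2_values):
            r = _train_on_trace(
                trace, np.array([w1, w2]), n_epochs, nparams, pparams
            )
            dw[i, j] = r.w_traj[-1] - r.w_traj[0]
            spikes_first[i, j] = len(r.spike_times[0])
    return {"w1": np.asarray(w1_values), "w2": np.asarray(w2_values),
            "dw": dw, "spikes_first_epoch": spikes_first}


def asymmetry_index(w_traj: np.ndarray, epoch: int) -> float:
    """``(w1_j - w1_0) - (w2_j - w2_0)`` at epoch ``j`` of a 2-channel trajectory.

    Positive values mean the earlier input's weight grew relative to the
    later input's.
    """
    w_traj = np.asarray(w_traj)
    if not (0 <= epoch < w_traj.shape[0]):
        raise IndexError("epoch outside trajectory")
    d = w_traj[epoch] - w_traj[0]
    return float(d[0] - d[1])


def asymmetry_grid(
    w1_values: np.ndarray,
    w2_values: np.ndarray,
    n_epochs: int = 300,
    delay: float = 4.0,
    t_first: float = 2.0,
    T: float = 500.0,
    nparams: NeuronParams | None = None,
    pparams: PlasticityParams | None = None,
) -> np.ndarray:
    """Asymmetry index per epoch over a grid of initial weights.

    Returns an array of shape (len(w1), len(w2), n_epochs) where entry
    ``[i, j, k]`` is the asymmetry index after ``k + 1`` training epochs from
    the initial pair ``(w1_values[i], w2_values[j])``.
    """
    nparams, pparams = _defaults(nparams, pparams)
    trace = filter_raster(
        make_two_input_pattern(t_first, t_first + delay, T), nparams.h
    )
    out = np.empty((len(w1_values), len(w2_values), n_epochs))
    for i, w1 in enumerate(w1_values):
        for j, w2 in enumerate(w2_values):
            r = _train_on_trace(trace, np.array([w1, w2]), n_epochs, nparams, pparams)
            d = r.w_traj[1:] - r.w_traj[0]
            out[i, j] = d[:, 0] - d[:, 1]
    return out


# ---------------------------------------------------------------------------
# Sequence anticipation task
# ---------------------------------------------------------------------------

@dataclass
class SequenceTaskResult:
    """Training record of the jittered-sequence task."""

    w0: np.ndarray
    w_final: np.ndarray
    latencies: np.ndarray        # per-epoch first-spike latency rel. onset (ms)
    spike_counts: np.ndarray
    losses: LossRecord
    onsets: np.ndarray
    eval_latency: float          # held-out evaluation epoch, plasticity off
    eval_spike_count: int
    selective: bool              # first sequence input's weight is the maximum
    n_seq: int

    @property
    def success(self) -> bool:
        """Selectivity AND held-out latency below 20 ms."""
        return bool(self.selective and np.isfinite(self.eval_latency)
                    and self.eval_latency < 20.0)

    @property
    def normalized_final_weights(self) -> np.ndarray:
        return self.w_final / self.w0


def evaluate_sequence_response(
    w: np.ndarray,
    spec: SequenceSpec,
    seed,
    nparams: NeuronParams,
) -> tuple[float, int]:
    """Latency (ms, rel. sequence onset) and spike count of a frozen-weight epoch."""
    raster = generate_sequence_epoch(spec, seed, nparams.h)
    trace = filter_raster(raster, nparams.h)
    res = run_epoch_trained(
        trace, SynapseState(w), nparams,
        PlasticityParams(eta=1.0, mode="online"), train=False,
    )
    lat = output_latency(res.spike_times, raster.meta["onset"])
    return lat, int(res.s.sum())


def run_sequence_task(
    spec: SequenceSpec | None = None,
    n_epochs: int = 1000,
    seed=0,
    w0: float | np.ndarray = 0.02,
    nparams: NeuronParams | None = None,
    pparams: PlasticityParams | None = None,
) -> SequenceTaskResult:
    """Train one neuron on fresh noisy sequence epochs.

    Defaults follow the study conditions: 100 sequence channels at 2 ms
    delays (200 ms nominal span), jitter +/-2 ms, per-channel Poisson
    background with rates uniform in 0-10 Hz, 100 distractor channels,
    onset uniform in [0, 200] ms, tau_m = 10 ms, fixed initial weights.
    A held-out evaluation epoch (plasticity off) provides the reported
    latency; selectivity means the first sequence input's weight is the
    global maximum.
    """
    if spec is None:
        spec = SequenceSpec()
    nparams, pparams = _defaults(nparams, pparams)
    rng = np.random.default_rng(seed)
    n_ch = spec.n_channels
    w0_vec = np.full(n_ch, w0, dtype=float) if np.isscalar(w0) else np.asarray(w0, float)
    syn = SynapseState(w0_vec.copy())
    latencies = np.empty(n_epochs)
    counts = np.empty(n_epochs, dtype=int)
    onsets = np.empty(n_epochs)
    loss = np.empty(n_epochs)
    cum_v = np.empty(n_epochs)
    for k in range(n_epochs):
        raster = generate_sequence_epoch(spec, rng.integers(2**31), nparams.h)
        trace = filter_raster(raster, nparams.h)
        res = run_epoch_trained(trace, syn, nparams, pparams)
        syn = res.syn
        onsets[k] = raster.meta["onset"]
        latencies[k] = output_latency(res.spike_times, onsets[k])
        counts[k] = res.s.sum()
        loss[k] = res.loss
        cum_v[k] = res.cum_v
    eval_lat, eval_n = evaluate_sequence_response(
        syn.w, spec, rng.integers(2**31), nparams
    )
    selective = bool(np.argmax(syn.w) == 0) if spec.n_seq > 0 else False
    return SequenceTaskResult(
        w0=w0_vec, w_final=syn.w, latencies=latencies, spike_counts=counts,
        losses=LossRecord(loss=loss, cum_v=cum_v), onsets=onsets,
        eval_latency=eval_lat, eval_spike_count=eval_n,
        selective=selective, n_seq=spec.n_seq,
    )


# ---------------------------------------------------------------------------
# STDP battery
# ---------------------------------------------------------------------------

@dataclass
class StdpCurve:
    """Weight change of the subthreshold probe vs. a protocol variable.

    ``pct_change`` is ``(w_after / w_before - 1) * 100`` for channel 1 at the
    end of the protocol.
    """

    x: np.ndarray
    pct_change: np.ndarray
    x_name: str
    branch: np.ndarray | None = None     # e.g. 'pre_post' / 'post_pre'
    group: np.ndarray | None = None      # e.g. tau_m per point

    def to_frame(self) -> pd.DataFrame:
        data = {self.x_name: self.x, "pct_change": self.pct_change}
        if self.branch is not None:
            data["branch"] = self.branch
        if self.group is not None:
            data["tau_m"] = self.group
        return pd.DataFrame(data)


def _stdp_run(
    raster,
    tau_m: float = 10.0,
    n_epochs: int = 60,
    sub_factor: float = 0.5,
    supra_factor: float = 1.5,
    eta: float = DEFAULT_ETA_SCALED,
    fixed_supra: bool = False,
    w1_init: float | None = None,
    v_th: float | None = None,
    h: float | None = None,
) -> float:
    """Run one STDP schedule; return % change of the probe (channel 1) weight."""
    base = default_neuron_params()
    nparams = NeuronParams(
        h=base.h if h is None else h,
        tau_m=tau_m,
        v_th=base.v_th if v_th is None else v_th,
    )
    w1 = threshold_fraction_weight(sub_factor, nparams) if w1_init is None else w1_init
    w2 = threshold_fraction_weight(supra_factor, nparams)
    pparams = PlasticityParams(eta=eta, mode="online_scaled")
    trace = filter_raster(raster, nparams.h)
    res = _train_on_trace(
        trace, np.array([w1, w2]), n_epochs, nparams, pparams,
        freeze_channel=1 if fixed_supra else None,
    )
    if w1 == 0.0:
        # a zero probe weight is a fixed point of the scaled rule
        return 0.0 if res.w_traj[-1, 0] == 0.0 else np.inf
    return float((res.w_traj[-1, 0] / w1 - 1.0) * 100.0)


def stdp_pairing_curve(
    delays,
    tau_m_list=(10.0, 20.0),
    n_epochs: int = 60,
    t_ref: float = 150.0,
    T: float = 500.0,
    **kwargs,
) -> StdpCurve:
    """Classic pairing window: probe weight change vs. delay, per tau_m.

    ``dt < 0`` (probe before the spike-evoking input) yields potentiation,
    ``dt > 0`` depression; the window widens with the membrane time constant.
    """
    xs, ys, gs = [], [], []
    for tau_m in np.atleast_1d(tau_m_list):
        for dt in delays:
            raster = make_stdp_schedule("pairing", T=T, dt=float(dt), t_ref=t_ref)
            ys.append(_stdp_run(raster, tau_m=tau_m, n_epochs=n_epochs, **kwargs))
            xs.append(dt)
            gs.append(tau_m)
    return StdpCurve(np.array(xs, float), np.array(ys), "dt_ms",
                     group=np.array(gs))


def stdp_burst_curve(
    freqs_hz,
    branches=("pre_post", "post_pre"),
    n_epochs: int = 20,
    sub_factor: float = 0.2,
    probe_gap: float = 10.0,
    t_ref: float = 150.0,
    T: float = 500.0,
    **kwargs,
) -> StdpCurve:
    """Probe weight change vs. intra-burst frequency of 3 spike-evoking inputs.

    The probe default is weaker here (0.2x threshold peak) than in the
    pairing window: with a strong probe the heterosynaptic drag, which grows
    with the burst's summed depolarization, masks the eligibility-trace
    potentiation and inverts the frequency ordering of LTP.
    """
    xs, ys, bs = [], [], []
    for branch in branches:
        for f in freqs_hz:
            raster = make_stdp_schedule(
                "burst", T=T, freq_hz=float(f), branch=branch,
                probe_gap=probe_gap, t_ref=t_ref,
            )
            ys.append(
                _stdp_run(raster, n_epochs=n_epochs, sub_factor=sub_factor, **kwargs)
            )
            xs.append(f)
            bs.append(branch)
    return StdpCurve(np.array(xs, float), np.array(ys), "intra_burst_hz",
                     branch=np.array(bs))


def stdp_one_n_curve(
    n_values,
    burst_freq_hz: float = 100.0,
    n_epochs: int = 60,
    t_ref: float = 150.0,
    T: float = 500.0,
    **kwargs,
) -> StdpCurve:
    """Post-pre-post motif: probe weight change vs. number of spike-evoking inputs.

    ``n = 1`` is a pure post-pre pairing (depression); adding further
    post-synaptic spikes after the pairing converts it to potentiation.
    """
    xs, ys = [], []
    for n in n_values:
        raster = make_stdp_schedule(
            "one_n", T=T, n=int(n), burst_freq_hz=burst_freq_hz, t_ref=t_ref
        )
        ys.append(_stdp_run(raster, n_epochs=n_epochs, **kwargs))
        xs.append(n)
    return StdpCurve(np.array(xs, float), np.array(ys), "n_supra_spikes")


def stdp_freq_pairing_curve(
    pairing_freqs_hz,
    n_pairs: int = 5,
    intra_dt: float = 6.0,
    n_epochs: int = 60,
    t_ref: float = 50.0,
    T: float = 500.0,
    **kwargs,
) -> StdpCurve:
    """Probe weight change vs. repetition frequency of 5 post-pre pairs.

    Within each pair the spike-evoking input leads the probe by ``intra_dt``
    ms; low pairing frequencies give depression, high frequencies
    potentiation.
    """
    xs, ys = [], []
    for f in pairing_freqs_hz:
        raster = make_stdp_schedule(
            "freq_pairing", T=T, pairing_freq_hz=float(f),
            n_pairs=n_pairs, intra_dt=intra_dt, t_ref=t_ref,
        )
        ys.append(_stdp_run(raster, n_epochs=n_epochs, **kwargs))
        xs.append(f)
    return StdpCurve(np.array(xs, float), np.array(ys), "pairing_freq_hz")


def stdp_variants(variant: str, **kwargs) -> StdpCurve:
    """Supplementary pairing variants.

    'fixed_supra_weight'
        Pairing window with the spike-evoking input's weight exempt from
        plasticity (keyword ``delays``; accepts the pairing-curve keywords).
    'initial_strength_sweep'
        Probe weight change at fixed ``dt`` (default -4 ms) as a function of
        the probe's initial weight, given as threshold fractions
        (``sub_factors``, default 0.1 .. 0.9).
    """
    if variant == "fixed_supra_weight":
        delays = kwargs.pop("delays")
        return stdp_pairing_curve(delays, fixed_supra=True, **kwargs)
    if variant == "initial_strength_sweep":
        sub_factors = np.asarray(kwargs.pop("sub_factors", np.linspace(0.1, 0.9, 9)))
        dt = float(kwargs.pop("dt", -4.0))
        t_ref = float(kwargs.pop("t_ref", 150.0))
        T = float(kwargs.pop("T", 500.0))
        n_epochs = int(kwargs.pop("n_epochs", 60))
        ys = []
        for f in sub_factors:
            raster = make_stdp_schedule("pairing", T=T, dt=dt, t_ref=t_ref)
            ys.append(
                _stdp_run(raster, n_epochs=n_epochs, sub_factor=float(f), **kwargs)
            )
        return StdpCurve(sub_factors, np.array(ys), "initial_threshold_fraction")
    raise ValueError(
        "variant must be 'fixed_supra_weight' or 'initial_strength_sweep'"
    )
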
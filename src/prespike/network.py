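"""Recurrently connected population of predictive neurons.

Ten (by default) neurons receive disjoint blocks of sequentially active
afferents and are laterally coupled (nearest-neighbor by default, all-to-all
or random optionally).  A lateral spike of neuron ``j`` at step ``t - 1``
enters neuron ``i``'s input at step ``t`` as a unit event filtered with the
same exponential kernel as the afferents, so afferent and lateral channels
are treated identically by the learning rule; no gradient flows through the
recurrence (each neuron's influence vector covers only its own input
channels).  Conditioning repeats the full staggered sequence; recall presents
only the first neuron's afferent block (plus background) to a trained,
frozen network.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .config import DEFAULT_ETA_ONLINE, DEFAULT_TAU_X, default_neuron_params
from .inputs import SpikeRaster, filter_raster
from .neuron import NeuronParams
from .plasticity import PlasticityParams

__all__ = [
    "NetworkSpec",
    "NetworkState",
    "build_network",
    "make_network_stimulus",
    "run_network_epoch",
    "run_conditioning",
    "run_recall",
    "run_recall_experiment",
    "conditioning_defaults",
    "measure_duration",
    "neurons_needed_for_recall",
    "first_spike_times",
]

CONNECTIVITIES = ("nearest_neighbor", "all_to_all", "random")


@dataclass
class NetworkSpec:
    """Architecture and stimulus geometry of the recurrent network.

    Each neuron owns ``afferents_per_neuron`` afferent channels firing
    sequentially at ``inter_spike_delay`` ms intervals (16 ms nominal
    sub-sequence at the defaults); the sub-sequence onset of neuron ``n + 1``
    starts ``onset_stagger`` ms after neuron ``n``'s.  All afferents carry
    homogeneous Poisson background at ``background_rate_hz`` and the sequence
    spikes are jittered by +/- ``jitter_range`` ms.
    """

    n_neurons: int = 10
    connectivity: str = "nearest_neighbor"
    p_connect: float = 0.5                 # 'random' connectivity only
    afferents_per_neuron: int = 8
    afferent_assignment: str = "sequential"   # or 'random'
    inter_spike_delay: float = 2.0
    onset_stagger: float = 4.0
    jitter_range: float = 2.0
    background_rate_hz: float = 10.0
    T: float = 100.0
    lateral_kernel_tau: float = DEFAULT_TAU_X
    lateral_gain: float = 1.0

    def __post_init__(self):
        if self.n_neurons < 1:
            raise ValueError("need at least one neuron")
        if self.connectivity not in CONNECTIVITIES:
            raise ValueError(f"connectivity must be one of {CONNECTIVITIES}")
        if not (0 <= self.p_connect <= 1):
            raise ValueError("p_connect must lie in [0, 1]")

    @property
    def n_afferents(self) -> int:
        return self.n_neurons * self.afferents_per_neuron


@dataclass
class NetworkState:
    """Weights, influence traces and wiring of the network.

    ``w_lat[j, i]`` is the weight of the lateral connection j -> i; entries
    where ``adj[j, i] == 0`` are structurally absent and stay 0.
    """

    spec: NetworkSpec
    adj: np.ndarray           # (M, M) uint8, zero diagonal
    aff_idx: np.ndarray       # (M, K) afferent channel indices per neuron
    w_aff: np.ndarray         # (M, K)
    w_lat: np.ndarray         # (M, M)
    p_aff: np.ndarray = None
    p_lat: np.ndarray = None

    def __post_init__(self):
        if np.any(np.diag(self.adj)):
            raise ValueError("self-connections are not allowed")
        if self.p_aff is None:
            self.p_aff = np.zeros_like(self.w_aff)
        if self.p_lat is None:
            self.p_lat = np.zeros_like(self.w_lat)

    @property
    def n_neurons(self) -> int:
        return self.spec.n_neurons

    def in_degree(self) -> np.ndarray:
        return self.adj.sum(axis=0)

    def copy(self) -> "NetworkState":
        return NetworkState(
            self.spec, self.adj.copy(), self.aff_idx.copy(),
            self.w_aff.copy(), self.w_lat.copy(),
            self.p_aff.copy(), self.p_lat.copy(),
        )


def _adjacency(spec: NetworkSpec, rng) -> np.ndarray:
    M = spec.n_neurons
    adj = np.zeros((M, M), dtype=np.uint8)
    if spec.connectivity == "nearest_neighbor":
        for n in range(M - 1):
            adj[n, n + 1] = 1
            adj[n + 1, n] = 1
    elif spec.connectivity == "all_to_all":
        adj[:] = 1
        np.fill_diagonal(adj, 0)
    else:
        adj[:] = (rng.random((M, M)) < spec.p_connect).astype(np.uint8)
        np.fill_diagonal(adj, 0)
    return adj


def build_network(
    spec: NetworkSpec,
    seed=0,
    w0_aff: float = 0.01,
    w0_lat: float = 0.01,
    scale_lateral_by_in_channels: bool = True,
) -> NetworkState:
    """Assemble a network with fixed initial weights.

    Initial lateral weights are divided by each neuron's total in-channel
    count (afferents + in-degree) when ``scale_lateral_by_in_channels`` so
    densely connected variants start with comparable recurrent drive.
    Deterministic under ``seed`` (which only matters for 'random' wiring).
    """
    rng = np.random.default_rng(seed)
    M, K = spec.n_neurons, spec.afferents_per_neuron
    adj = _adjacency(spec, rng)
    if spec.afferent_assignment == "sequential":
        aff_idx = np.arange(M * K, dtype=np.int64).reshape(M, K)
    elif spec.afferent_assignment == "random":
        aff_idx = np.empty((M, K), dtype=np.int64)
        for i in range(M):
            aff_idx[i] = rng.choice(spec.n_afferents, size=K, replace=False)
    else:
        raise ValueError("afferent_assignment must be 'sequential' or 'random'")
    w_aff = np.full((M, K), float(w0_aff))
    w_lat = np.zeros((M, M))
    indeg = adj.sum(axis=0)
    for i in range(M):
        if indeg[i] == 0:
            continue
        w = float(w0_lat)
        if scale_lateral_by_in_channels:
            w = w / (K + indeg[i]) * (K + 2)  # normalized to the 2-neighbor case
        w_lat[:, i] = adj[:, i] * w
    return NetworkState(spec, adj, aff_idx, w_aff, w_lat)


def make_network_stimulus(
    spec: NetworkSpec, mode: str, seed, h: float = 0.05
) -> SpikeRaster:
    """Afferent raster for one epoch.

    mode 'full'        : every neuron's afferent block carries its jittered
                         sub-sequence (conditioning stimulus);
         'cued'        : only neuron 1's block carries the sub-sequence;
         'spontaneous' : background only.
    All channels carry Poisson background in every mode.
    """
    if mode not in ("full", "cued", "spontaneous"):
        raise ValueError("mode must be 'full', 'cued' or 'spontaneous'")
    rng = np.random.default_rng(seed)
    M, K = spec.n_neurons, spec.afferents_per_neuron
    n_cued = {"full": M, "cued": 1, "spontaneous": 0}[mode]
    spikes = []
    eps = 1e-9
    for n in range(M):
        for k in range(K):
            ts = _poisson_times(rng, spec.background_rate_hz, spec.T, h)
            if n < n_cued:
                t = n * spec.onset_stagger + k * spec.inter_spike_delay
                if spec.jitter_range > 0:
                    t += rng.uniform(-spec.jitter_range, spec.jitter_range)
                t = min(max(t, 0.0), spec.T - h + eps)
                ts = np.sort(np.append(ts, t))
            spikes.append(ts)
    return SpikeRaster(M * K, spikes, spec.T, meta={"mode": mode})


def _poisson_times(rng, rate_hz, T, h):
    if rate_hz <= 0:
        return np.empty(0)
    n_steps = int(round(T / h))
    hits = rng.random(n_steps) < rate_hz * h / 1000.0
    return np.flatnonzero(hits) * h


def run_network_epoch(
    state: NetworkState,
    trace,
    nparams: NeuronParams | None = None,
    pparams: PlasticityParams | None = None,
    train: bool = True,
) -> dict:
    """Simulate one epoch, mutating ``state``'s weights when training.

    Returns a dict with the (T, M) spike matrix ``s``, the voltage matrix
    ``v`` and the summed prediction loss.  Influence traces restart from 0
    each epoch (epochs are independent presentations).
    """
    if nparams is None:
        nparams = default_neuron_params()
    if pparams is None:
        pparams = PlasticityParams(eta=DEFAULT_ETA_ONLINE, mode="online")
    mode_map = {
        "online": _kernels.MODE_ONLINE,
        "online_scaled": _kernels.MODE_SCALED,
        "batch": _kernels.MODE_EPOCH,
    }
    mode = mode_map[pparams.mode] if train else _kernels.MODE_FROZEN
    state.p_aff[:] = 0.0
    state.p_lat[:] = 0.0
    beta_x = float(np.exp(-nparams.h / state.spec.lateral_kernel_tau))
    s, v, loss, acc_aff, acc_lat, ok = _kernels.network_epoch_loop(
        np.ascontiguousarray(trace.values),
        state.aff_idx, state.adj,
        state.w_aff, state.p_aff, state.w_lat, state.p_lat,
        nparams.alpha, beta_x, nparams.v_th, pparams.eta, mode,
        state.spec.lateral_gain,
    )
    if not ok:
        raise FloatingPointError("network voltage diverged; reduce eta")
    # epoch-wise mode: the bracket was accumulated at fixed weights; the
    # epoch gradient is its negative, applied here (plain step or Adam)
    if train and pparams.mode == "batch":
        _apply_epoch_update(state, -acc_aff, -acc_lat, pparams)
    return {"s": s, "v": v, "loss": float(loss)}


def _apply_epoch_update(state, grad_aff, grad_lat, pparams):
    if pparams.batch_optimizer == "adam":
        if not hasattr(state, "_adam"):
            state._adam = {
                "t": 0,
                "m_aff": np.zeros_like(state.w_aff),
                "v_aff": np.zeros_like(state.w_aff),
                "m_lat": np.zeros_like(state.w_lat),
                "v_lat": np.zeros_like(state.w_lat),
            }
        a = state._adam
        a["t"] += 1
        b1, b2, eps = pparams.adam_beta1, pparams.adam_beta2, pparams.adam_eps
        for g, mk, vk, w in (
            (grad_aff, "m_aff", "v_aff", state.w_aff),
            (grad_lat, "m_lat", "v_lat", state.w_lat),
        ):
            a[mk] = b1 * a[mk] + (1 - b1) * g
            a[vk] = b2 * a[vk] + (1 - b2) * g**2
            mhat = a[mk] / (1 - b1 ** a["t"])
            vhat = a[vk] / (1 - b2 ** a["t"])
            w -= pparams.eta * mhat / (np.sqrt(vhat) + eps)
    else:
        state.w_aff -= pparams.eta * grad_aff
        state.w_lat -= pparams.eta * grad_lat
    state.w_lat *= state.adj  # absent connections stay absent


def first_spike_times(s: np.ndarray, h: float) -> np.ndarray:
    """Per-neuron first spike time in ms (NaN for silent neurons)."""
    T, M = s.shape
    out = np.full(M, np.nan)
    for i in range(M):
        idx = np.flatnonzero(s[:, i])
        if idx.size:
            out[i] = idx[0] * h
    return out


def measure_duration(s: np.ndarray, h: float) -> float:
    """Duration of network activity (ms): last spike of the last neuron minus
    first spike of the first neuron; NaN when either neuron is silent."""
    first = np.flatnonzero(s[:, 0])
    last = np.flatnonzero(s[:, -1])
    if first.size == 0 or last.size == 0:
        return np.nan
    return float((last[-1] - first[0]) * h)


@dataclass
class ConditioningHistory:
    """Per-epoch records of network conditioning."""

    durations: np.ndarray
    spike_counts: np.ndarray
    losses: np.ndarray
    snapshots: dict = field(default_factory=dict)  # epoch -> (w_aff, w_lat)
    rasters: dict = field(default_factory=dict)    # epoch -> (T, M) uint8


def run_conditioning(
    state: NetworkState,
    n_epochs: int,
    seed=0,
    nparams: NeuronParams | None = None,
    pparams: PlasticityParams | None = None,
    snapshot_every: int | None = None,
    keep_rasters: tuple = (),
) -> ConditioningHistory:
    """Train the network on the full staggered sequence, fresh noise per epoch.

    Mutates ``state``.  ``snapshot_every`` stores periodic weight copies;
    ``keep_rasters`` lists epoch indices whose full spike rasters to retain.
    """
    if nparams is None:
        nparams = default_neuron_params()
    rng = np.random.default_rng(seed)
    durations = np.full(n_epochs, np.nan)
    counts = np.zeros(n_epochs, dtype=int)
    losses = np.empty(n_epochs)
    hist = ConditioningHistory(durations, counts, losses)
    for k in range(n_epochs):
        raster = make_network_stimulus(state.spec, "full", rng.integers(2**31), nparams.h)
        trace = filter_raster(raster, nparams.h, state.spec.lateral_kernel_tau)
        out = run_network_epoch(state, trace, nparams, pparams, train=True)
        durations[k] = measure_duration(out["s"], nparams.h)
        counts[k] = int(out["s"].sum())
        losses[k] = out["loss"]
        if snapshot_every and (k + 1) % snapshot_every == 0:
            hist.snapshots[k + 1] = (state.w_aff.copy(), state.w_lat.copy())
        if k in keep_rasters:
            hist.rasters[k] = out["s"]
    return hist


def run_recall(
    state: NetworkState,
    mode: str = "cued",
    seed=0,
    nparams: NeuronParams | None = None,
) -> dict:
    """One frozen-weight test epoch: cue (first neuron's afferents) or
    background only.  Returns the epoch dict of :func:`run_network_epoch`
    plus per-neuron first-spike times and the activity duration."""
    if nparams is None:
        nparams = default_neuron_params()
    stim_mode = {"cued": "cued", "spontaneous": "spontaneous"}[mode]
    raster = make_network_stimulus(state.spec, stim_mode, seed, nparams.h)
    trace = filter_raster(raster, nparams.h, state.spec.lateral_kernel_tau)
    work = state.copy()  # recall must not perturb the trained weights
    out = run_network_epoch(work, trace, nparams, train=False)
    out["first_spikes"] = first_spike_times(out["s"], nparams.h)
    out["duration"] = measure_duration(out["s"], nparams.h)
    return out


def _ordered_recall(state, cued_neurons: int, seed, nparams) -> bool:
    """True when cueing afferents of neurons 1..k activates all neurons in order."""
    rng = np.random.default_rng(seed)
    spec = state.spec
    M, K = spec.n_neurons, spec.afferents_per_neuron
    raster = make_network_stimulus(spec, "spontaneous", rng.integers(2**31), nparams.h)
    eps = 1e-9
    spikes = [ts.copy() for ts in raster.spikes]
    for n in range(cued_neurons):
        for k in range(K):
            t = n * spec.onset_stagger + k * spec.inter_spike_delay
            if spec.jitter_range > 0:
                t += rng.uniform(-spec.jitter_range, spec.jitter_range)
            t = min(max(t, 0.0), spec.T - nparams.h + eps)
            ch = n * K + k
            spikes[ch] = np.sort(np.append(spikes[ch], t))
    stim = SpikeRaster(M * K, spikes, spec.T)
    trace = filter_raster(stim, nparams.h, spec.lateral_kernel_tau)
    work = state.copy()
    out = run_network_epoch(work, trace, nparams, train=False)
    fs = first_spike_times(out["s"], nparams.h)
    return bool(np.all(np.isfinite(fs)) and np.all(np.diff(fs) >= 0))


def conditioning_defaults() -> dict:
    """Reference configuration of the conditioning/recall experiment.

    The recurrent network with fully plastic afferent and lateral weights
    drifts, over long training, toward the silent optimum of the prediction
    loss (where nothing fires and nothing needs predicting); the functional
    sequence-recall circuit — potentiated earliest afferents plus a forward
    lateral chain — is a structured *phase* of training, so the recall
    evaluation is taken at a mid-training checkpoint while the duration
    compression is measured across the whole run.  The lateral event gain
    0.15 slows the growth of the recurrent channels relative to afferent
    reorganization; see the methods note for the calibration rationale.
    """
    return dict(
        spec=NetworkSpec(T=60.0, lateral_gain=0.15),
        w0_aff=0.012,
        w0_lat=0.05,
        scale_lateral_by_in_channels=False,
        eta=DEFAULT_ETA_ONLINE,
        n_epochs=2000,
        checkpoint=500,
    )


def run_recall_experiment(
    seed=0,
    n_epochs: int | None = None,
    checkpoint: int | None = None,
    n_recall_seeds: int = 10,
    nparams: NeuronParams | None = None,
) -> dict:
    """Condition the reference network and probe cued recall.

    Returns a dict with the conditioning history, the checkpoint and final
    states, per-recall-seed first-spike vectors at the checkpoint, and the
    ordered-recall and all-fire counts.
    """
    cfg = conditioning_defaults()
    if n_epochs is not None:
        cfg["n_epochs"] = n_epochs
    if checkpoint is not None:
        cfg["checkpoint"] = checkpoint
    cfg["checkpoint"] = min(cfg["checkpoint"], cfg["n_epochs"])
    if nparams is None:
        nparams = default_neuron_params()
    state = build_network(
        cfg["spec"], seed, w0_aff=cfg["w0_aff"], w0_lat=cfg["w0_lat"],
        scale_lateral_by_in_channels=cfg["scale_lateral_by_in_channels"],
    )
    pparams = PlasticityParams(eta=cfg["eta"], mode="online")
    rng = np.random.default_rng(seed)
    hist_a = run_conditioning(
        state, cfg["checkpoint"], seed=rng.integers(2**31),
        nparams=nparams, pparams=pparams,
    )
    ckpt_state = state.copy()
    hist_b = run_conditioning(
        state, cfg["n_epochs"] - cfg["checkpoint"], seed=rng.integers(2**31),
        nparams=nparams, pparams=pparams,
    )
    durations = np.concatenate([hist_a.durations, hist_b.durations])
    first_spikes = []
    n_ordered = 0
    n_allfire = 0
    for _ in range(n_recall_seeds):
        rec = run_recall(ckpt_state, "cued", rng.integers(2**31), nparams)
        fs = rec["first_spikes"]
        first_spikes.append(fs)
        all_fire = bool(np.all(np.isfinite(fs)))
        n_allfire += all_fire
        n_ordered += bool(all_fire and np.all(np.diff(fs) >= 0))
    return {
        "state_final": state,
        "state_checkpoint": ckpt_state,
        "durations": durations,
        "spike_counts": np.concatenate([hist_a.spike_counts, hist_b.spike_counts]),
        "recall_first_spikes": np.array(first_spikes),
        "n_ordered": n_ordered,
        "n_allfire": n_allfire,
        "n_recall_seeds": n_recall_seeds,
    }


def neurons_needed_for_recall(
    state: NetworkState,
    seed=0,
    n_trials: int = 5,
    nparams: NeuronParams | None = None,
) -> int:
    """Smallest k such that cueing neurons 1..k recalls the full ordered
    sequence in a majority of noise trials; M if recall never succeeds."""
    if nparams is None:
        nparams = default_neuron_params()
    rng = np.random.default_rng(seed)
    M = state.spec.n_neurons
    for k in range(1, M + 1):
        wins = sum(
            _ordered_recall(state, k, rng.integers(2**31), nparams)
            for _ in range(n_trials)
        )
        if wins > n_trials // 2:
            return k
    return M
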
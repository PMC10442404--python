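"""The predictive learning rule.

A neuron following this rule treats its membrane potential as a running,
low-rank summary of its inputs and learns to predict each incoming input
from that summary.  At every timestep the per-synapse prediction error

    eps_t = x_t - v_{t-1} * w_{t-1}

and the global signal (error weighted by synaptic strength)

    E_t = eps_t . w_{t-1}

drive the weight update

    w_t = w_{t-1} + eta * (eps_t * v_{t-1} + E_t * p_{t-1})

where ``p_t = alpha * p_{t-1} + x_t`` is the influence (eligibility) vector,
a forward-pass accumulation of the gradient of the voltage with respect to
the weights.  The first term is a time-shifted Oja rule — a Hebbian
correlation ``x_t v_{t-1}`` plus a heterosynaptic decay ``-v_{t-1}^2 w_{t-1}``
— and the second term propagates prediction errors between synapses via the
eligibility traces.  The gradient through the spike/reset nonlinearity is
neglected (surrogate scale gamma = 0), so the voltage Jacobian is simply
``alpha`` at every step.

Three training modes are available:

``online``
    The rule above, applied at every timestep.
``online_scaled``
    The update bracket premultiplied elementwise by ``w_{t-1}``; keeps the
    weights non-negative when initialized non-negative.
``batch``
    The exact epoch gradient (summed over the epoch at fixed weights,
    accumulated through ``p``) applied once per epoch with plain gradient
    descent or Adam.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from ._kernels import epoch_gradient_loop, epoch_loop
from .inputs import InputTrace
from .neuron import NeuronParams

__all__ = [
    "SynapseState",
    "PlasticityParams",
    "LossRecord",
    "EpochResult",
    "prediction_error",
    "global_signal",
    "update_influence",
    "online_step",
    "run_epoch_trained",
    "epoch_gradient",
    "batch_train",
]

MODES = ("online", "online_scaled", "batch")
_MODE_CODE = {"online": _kernels.MODE_ONLINE, "online_scaled": _kernels.MODE_SCALED}


@dataclass
class SynapseState:
    """Weight vector ``w`` and influence vector ``p = grad_w v`` (same length)."""

    w: np.ndarray
    p: np.ndarray = None

    def __post_init__(self):
        self.w = np.atleast_1d(np.asarray(self.w, dtype=np.float64)).copy()
        if self.p is None:
            self.p = np.zeros_like(self.w)
        else:
            self.p = np.atleast_1d(np.asarray(self.p, dtype=np.float64)).copy()
        if self.p.shape != self.w.shape:
            raise ValueError("w and p must have the same shape")

    @property
    def n_channels(self) -> int:
        return self.w.size

    def copy(self) -> "SynapseState":
        return SynapseState(self.w.copy(), self.p.copy())


@dataclass(frozen=True)
class PlasticityParams:
    """Learning-rule settings.

    eta : per-step learning rate (> 0); must satisfy eta * tau_m << 1 for the
        online approximation to track the batch gradient (timescale
        separation).  The defaults used by the shipped protocols live in
        :mod:`prespike.config`.
    mode : 'online', 'online_scaled' or 'batch'.
    gamma : surrogate scale for the spike nonlinearity; fixed at 0 (the
        functional form of a nonzero surrogate is deliberately not modeled).
    batch_optimizer : 'plain_gd' or 'adam' (batch mode only).
    """

    eta: float = 1e-4
    mode: str = "online_scaled"
    gamma: float = 0.0
    batch_optimizer: str = "plain_gd"
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8

    def __post_init__(self):
        if self.eta <= 0:
            raise ValueError("eta must be positive")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if self.gamma != 0.0:
            raise NotImplementedError(
                "only gamma = 0 is implemented (no surrogate gradient)"
            )
        if self.batch_optimizer not in ("plain_gd", "adam"):
            raise ValueError("batch_optimizer must be 'plain_gd' or 'adam'")


@dataclass
class LossRecord:
    """Per-epoch loss bookkeeping.

    loss : cumulative prediction loss L = sum_t 0.5 ||eps_t||^2 per epoch.
    loss_norm : loss normalized by its value at epoch 0.
    cum_v : cumulative membrane potential sum_t v_t per epoch.
    """

    loss: np.ndarray = field(default_factory=lambda: np.empty(0))
    cum_v: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def loss_norm(self) -> np.ndarray:
        if self.loss.size == 0:
            return self.loss
        return self.loss / self.loss[0]


@dataclass
class EpochResult:
    """Full record of one simulated epoch."""

    syn: SynapseState
    v: np.ndarray
    s: np.ndarray
    loss_steps: np.ndarray
    h: float

    @property
    def loss(self) -> float:
        return float(self.loss_steps.sum())

    @property
    def cum_v(self) -> float:
        return float(self.v.sum())

    @property
    def spike_times(self) -> np.ndarray:
        return np.flatnonzero(self.s) * self.h

    @property
    def first_spike(self) -> float:
        idx = np.flatnonzero(self.s)
        return float(idx[0] * self.h) if idx.size else np.nan


def prediction_error(x_t: np.ndarray, v_prev: float, w_prev: np.ndarray) -> np.ndarray:
    """Per-synapse prediction error ``eps_t = x_t - v_{t-1} * w_{t-1}``."""
    x_t = np.asarray(x_t, dtype=float)
    w_prev = np.asarray(w_prev, dtype=float)
    if x_t.shape != w_prev.shape:
        raise ValueError("x_t and w_prev must have the same shape")
    return x_t - v_prev * w_prev


def global_signal(eps: np.ndarray, w_prev: np.ndarray) -> float:
    """Weighted sum of the per-synapse prediction errors, ``eps . w``."""
    eps = np.asarray(eps, dtype=float)
    w_prev = np.asarray(w_prev, dtype=float)
    if eps.shape != w_prev.shape:
        raise ValueError("eps and w_prev must have the same shape")
    return float(eps @ w_prev)


def update_influence(
    p_prev: np.ndarray, x_t: np.ndarray, nparams: NeuronParams
) -> np.ndarray:
    """Influence-vector recursion ``p_t = alpha * p_{t-1} + x_t`` (gamma = 0)."""
    return nparams.alpha * np.asarray(p_prev, float) + np.asarray(x_t, float)


def online_step(
    syn: SynapseState,
    eps: np.ndarray,
    v_prev: float,
    glob: float,
    pparams: PlasticityParams,
) -> SynapseState:
    """One online weight update (``p`` is updated separately).

    'online' applies ``eta*(eps*v_prev + glob*p)``; 'online_scaled'
    premultiplies the bracket elementwise by the current weights, so a
    zero weight is a fixed point and non-negativity is preserved.
    """
    bracket = eps * v_prev + glob * syn.p
    if pparams.mode == "online":
        w_new = syn.w + pparams.eta * bracket
    elif pparams.mode == "online_scaled":
        w_new = syn.w + pparams.eta * syn.w * bracket
    else:
        raise ValueError("online_step requires mode 'online' or 'online_scaled'")
    return SynapseState(w_new, syn.p.copy())


def run_epoch_trained(
    trace: InputTrace,
    syn: SynapseState,
    nparams: NeuronParams,
    pparams: PlasticityParams,
    train: bool = True,
) -> EpochResult:
    """Simulate one epoch with online plasticity.

    Starts from rest with ``p = 0`` (epochs are independent presentations;
    only the weights persist).  Per timestep, in order: prediction error and
    global signal from ``(x_t, v_{t-1}, w_{t-1})``; loss accumulation; weight
    update; influence update; membrane update with the *new* weights and
    spike emission.  With ``train=False`` (or in batch mode) the weights stay
    frozen and only the records are produced.
    """
    if syn.n_channels != trace.n_channels:
        raise ValueError("synapse state and trace channel counts differ")
    mode = _MODE_CODE.get(pparams.mode, _kernels.MODE_FROZEN) if train else _kernels.MODE_FROZEN
    w = syn.w.copy()
    p = np.zeros_like(w)
    v, s, loss_steps, w, p, ok = epoch_loop(
        np.ascontiguousarray(trace.values, dtype=np.float64),
        w, p, nparams.alpha, nparams.v_th, pparams.eta, mode,
    )
    if not ok:
        raise FloatingPointError(
            "voltage or weights diverged (|v| > 1e6); reduce eta or check the input"
        )
    return EpochResult(SynapseState(w, p), v, s, loss_steps, trace.h)


def epoch_gradient(
    trace: InputTrace, w: np.ndarray, nparams: NeuronParams
) -> np.ndarray:
    """Exact gradient of the cumulative loss over one epoch at fixed ``w``.

    Computed by forward accumulation through the influence vector on the
    fixed-weight trajectory:  grad = -sum_t (eps_t v_{t-1} + E_t p_{t-1}).
    """
    w = np.ascontiguousarray(w, dtype=np.float64)
    if w.shape != (trace.n_channels,):
        raise ValueError("weight vector and trace channel counts differ")
    grad, _ = epoch_gradient_loop(
        np.ascontiguousarray(trace.values, dtype=np.float64),
        w, nparams.alpha, nparams.v_th,
    )
    return grad


def epoch_loss(trace: InputTrace, w: np.ndarray, nparams: NeuronParams) -> float:
    """Cumulative prediction loss of one epoch at fixed ``w``."""
    w = np.ascontiguousarray(w, dtype=np.float64)
    _, loss = epoch_gradient_loop(
        np.ascontiguousarray(trace.values, dtype=np.float64),
        w, nparams.alpha, nparams.v_th,
    )
    return float(loss)


def batch_train(
    traces,
    w0: np.ndarray,
    nparams: NeuronParams,
    pparams: PlasticityParams,
    n_epochs: int,
) -> tuple[np.ndarray, LossRecord]:
    """Epoch-wise gradient descent on the cumulative prediction loss.

    ``traces`` may be a single :class:`InputTrace` (repeated every epoch), a
    sequence of traces, or a callable ``epoch -> InputTrace`` (fresh noise
    per epoch).  Returns the weight trajectory (n_epochs+1, n_channels) and
    a :class:`LossRecord` of the loss/cumulative voltage evaluated at the
    pre-update weights of each epoch.
    """
    if callable(traces):
        get = traces
    elif isinstance(traces, InputTrace):
        get = lambda k: traces
    else:
        seq = list(traces)
        get = lambda k: seq[k % len(seq)]

    w = np.ascontiguousarray(w0, dtype=np.float64).copy()
    traj = np.empty((n_epochs + 1, w.size))
    traj[0] = w
    loss = np.empty(n_epochs)
    cum_v = np.empty(n_epochs)
    m = np.zeros_like(w)
    vhat = np.zeros_like(w)
    frozen = PlasticityParams(eta=pparams.eta, mode="online")  # records only
    for k in range(n_epochs):
        trace = get(k)
        res = run_epoch_trained(trace, SynapseState(w), nparams, frozen, train=False)
        loss[k] = res.loss
        cum_v[k] = res.cum_v
        grad = epoch_gradient(trace, w, nparams)
        if pparams.batch_optimizer == "adam":
            m = pparams.adam_beta1 * m + (1 - pparams.adam_beta1) * grad
            vhat = pparams.adam_beta2 * vhat + (1 - pparams.adam_beta2) * grad**2
            mhat = m / (1 - pparams.adam_beta1 ** (k + 1))
            vhat_c = vhat / (1 - pparams.adam_beta2 ** (k + 1))
            w = w - pparams.eta * mhat / (np.sqrt(vhat_c) + pparams.adam_eps)
        else:
            w = w - pparams.eta * grad
        if not np.all(np.isfinite(w)) or np.max(np.abs(w)) > _kernels.GUARD:
            raise FloatingPointError("weights diverged in batch training")
        traj[k + 1] = w
    return traj, LossRecord(loss=loss, cum_v=cum_v)
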
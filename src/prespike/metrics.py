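"""Weight initialization and summary metrics."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import truncnorm

from ._kernels import epoch_loop
from .inputs import filter_raster, make_two_input_pattern
from .neuron import NeuronParams

__all__ = [
    "InitScheme",
    "init_weights",
    "output_latency",
    "normalized_weights",
    "epsp_peak",
    "threshold_fraction_weight",
]


@dataclass(frozen=True)
class InitScheme:
    """Initial-weight scheme.

    'fixed' uses ``mean`` for every channel.  'truncated_normal' draws from a
    normal with sd ``sd_base`` (optionally scaled by 1/sqrt(n_channels)),
    truncated to ``[lower, upper]``; the default lower bound 0 enforces
    non-negative draws.
    """

    kind: str = "truncated_normal"
    mean: float = 0.02
    sd_base: float = 0.02
    lower: float = 0.0
    upper: float = np.inf
    scale_by_inverse_sqrt_n: bool = True

    def __post_init__(self):
        if self.kind not in ("fixed", "truncated_normal"):
            raise ValueError("kind must be 'fixed' or 'truncated_normal'")
        if self.lower >= self.upper:
            raise ValueError("infeasible truncation bounds")


def init_weights(scheme: InitScheme, n_channels: int, seed) -> np.ndarray:
    """Draw an initial weight vector under the given scheme."""
    if scheme.kind == "fixed":
        return np.full(n_channels, scheme.mean, dtype=float)
    sd = scheme.sd_base
    if scheme.scale_by_inverse_sqrt_n:
        sd = sd / np.sqrt(n_channels)
    a = (scheme.lower - scheme.mean) / sd
    b = (scheme.upper - scheme.mean) / sd
    rng = np.random.default_rng(seed)
    return truncnorm.rvs(a, b, loc=scheme.mean, scale=sd, size=n_channels,
                         random_state=rng)


def output_latency(spike_times_ms: np.ndarray, onset: float) -> float:
    """First output spike time minus the sequence onset (ms); NaN if silent."""
    spike_times_ms = np.asarray(spike_times_ms, dtype=float)
    if spike_times_ms.size == 0:
        return np.nan
    return float(spike_times_ms[0] - onset)


def normalized_weights(w_traj: np.ndarray) -> np.ndarray:
    """Elementwise ``w / w_0`` for a (epochs, channels) weight trajectory."""
    w_traj = np.asarray(w_traj, dtype=float)
    w0 = w_traj[0]
    if np.any(w0 <= 0):
        raise ValueError("normalized weights require strictly positive epoch-0 weights")
    return w_traj / w0


def epsp_peak(nparams: NeuronParams, tau_x: float = 2.0) -> float:
    """Peak subthreshold voltage response to one spike at unit weight.

    The membrane response to a single filtered spike is the discrete
    difference of exponentials ``(alpha^(k+1) - beta^(k+1)) / (alpha - beta)``
    with ``beta = exp(-h/tau_x)``; this returns its maximum over time.
    """
    alpha = nparams.alpha
    beta = np.exp(-nparams.h / tau_x)
    k = np.arange(int(round(10 * max(nparams.tau_m, tau_x) / nparams.h)) + 1)
    resp = (alpha ** (k + 1) - beta ** (k + 1)) / (alpha - beta)
    return float(resp.max())


def threshold_fraction_weight(
    fraction: float, nparams: NeuronParams, tau_x: float = 2.0
) -> float:
    """Weight at which a lone presynaptic spike peaks at ``fraction * v_th``.

    Used by the STDP protocols to pin down 'subthreshold' (fraction < 1) and
    'suprathreshold' (fraction > 1) inputs.
    """
    return fraction * nparams.v_th / epsp_peak(nparams, tau_x)
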
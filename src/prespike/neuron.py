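"""Discrete-time leaky integrate-and-fire membrane with subtractive reset.

The membrane recursion is

    v_t = alpha * v_{t-1} - v_th * s_{t-1} + w . x_t,     alpha = 1 - h/tau_m
    s_t = 1  if v_t >= v_th  else 0

i.e. the threshold crossing emits a spike and the membrane is lowered by
exactly ``v_th`` one step later (spike-response-model style reset, no
refractory period, resting potential 0).  The threshold comparison uses
``>=`` so a tie is a spike; ties are measure-zero but must be deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._kernels import epoch_loop
from .inputs import DEFAULT_H, InputTrace

__all__ = ["NeuronParams", "NeuronState", "step_voltage", "run_epoch_voltage"]


@dataclass(frozen=True)
class NeuronParams:
    """Membrane parameters.

    h : timestep (ms); tau_m : membrane time constant (ms); v_th : spiking
    threshold (dimensionless voltage, resting = 0).  Requires 0 < h < tau_m
    so that the leak factor ``alpha = 1 - h/tau_m`` lies in (0, 1).
    """

    h: float = DEFAULT_H
    tau_m: float = 10.0
    v_th: float = 1.0

    def __post_init__(self):
        if not (0 < self.h < self.tau_m):
            raise ValueError("need 0 < h < tau_m")
        if self.v_th <= 0:
            raise ValueError("v_th must be positive")

    @property
    def alpha(self) -> float:
        return 1.0 - self.h / self.tau_m


@dataclass
class NeuronState:
    """Membrane potential and binary spike indicator at one timestep."""

    v: float = 0.0
    s: int = 0


def step_voltage(state: NeuronState, drive: float, params: NeuronParams) -> NeuronState:
    """One membrane update given the scalar weighted input ``w . x_t``."""
    v_new = params.alpha * state.v - params.v_th * state.s + drive
    return NeuronState(v=v_new, s=int(v_new >= params.v_th))


def run_epoch_voltage(
    trace: InputTrace, w: np.ndarray, params: NeuronParams
) -> tuple[np.ndarray, np.ndarray]:
    """Iterate the membrane over a full epoch with fixed weights.

    Starts from rest (v0 = 0, s0 = 0); state is not carried across epochs.
    Returns the full ``v_t`` (float) and ``s_t`` (0/1 int) series.
    """
    w = np.ascontiguousarray(w, dtype=np.float64)
    if w.shape != (trace.n_channels,):
        raise ValueError(
            f"weight vector has {w.shape} entries, trace has {trace.n_channels} channels"
        )
    p0 = np.zeros_like(w)
    v, s, _, _, _, ok = epoch_loop(
        np.ascontiguousarray(trace.values), w.copy(), p0,
        params.alpha, params.v_th, 0.0, 0,
    )
    if not ok:
        raise FloatingPointError("membrane potential diverged")
    return v, s.astype(np.int64)


def spike_times(s: np.ndarray, h: float = DEFAULT_H) -> np.ndarray:
    """Spike times in ms: ``t*h`` for every step with ``s_t = 1``."""
    return np.flatnonzero(s) * h
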
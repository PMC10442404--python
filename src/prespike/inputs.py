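"""Synthetic presynaptic spike patterns and their filtered drive.

All experiments in this package run on internally generated spike rasters:
deterministic two-spike patterns, jittered sequential rasters embedded in
homogeneous-Poisson background with distractor channels, and the pairing
schedules used by the STDP protocols.  Rasters live in continuous time (ms);
:func:`filter_raster` bins them onto the simulation grid and convolves each
channel with a causal exponential kernel (time constant ``tau_x``), which
stands in for the fast dynamics of post-synaptic currents.

Conventions
-----------
* Spike times are in milliseconds within ``[0, T)``.
* The exponential kernel has unit amplitude at the spike timestep and decays
  by ``exp(-h/tau_x)`` per step; coincident spikes in one channel and bin sum.
* "Nominal sequence span" is ``n_seq * inter_spike_delay`` (a sequence of 100
  channels at 2 ms delays is booked as 200 ms, i.e. first-to-last delay span
  plus one inter-spike interval).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._kernels import exp_filter_inplace

__all__ = [
    "SpikeRaster",
    "SequenceSpec",
    "InputTrace",
    "generate_sequence_epoch",
    "make_two_input_pattern",
    "make_stdp_schedule",
    "filter_raster",
]

#: default simulation timestep (ms); every numerical experiment uses this grid
DEFAULT_H = 0.05


@dataclass
class SpikeRaster:
    """A set of per-channel ordered spike times within one epoch.

    Parameters
    ----------
    n_channels : int
        Number of presynaptic channels (fixed across the epoch).
    spikes : list of ndarray
        ``spikes[c]`` holds the sorted spike times (ms) of channel ``c``,
        each in ``[0, duration)``.
    duration : float
        Epoch duration ``T`` in ms.
    """

    n_channels: int
    spikes: list = field(default_factory=list)
    duration: float = 500.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.n_channels < 0:
            raise ValueError("n_channels must be non-negative")
        if len(self.spikes) != self.n_channels:
            raise ValueError("spikes must have one entry per channel")
        clean = []
        for c, ts in enumerate(self.spikes):
            ts = np.sort(np.asarray(ts, dtype=float))
            if ts.size and (ts[0] < 0 or ts[-1] >= self.duration):
                raise ValueError(
                    f"channel {c}: spike times must lie in [0, {self.duration})"
                )
            clean.append(ts)
        self.spikes = clean

    @property
    def n_spikes(self) -> int:
        return int(sum(len(ts) for ts in self.spikes))

    def __add__(self, other: "SpikeRaster") -> "SpikeRaster":
        """Channel-wise superposition of two rasters of equal shape."""
        if (self.n_channels, self.duration) != (other.n_channels, other.duration):
            raise ValueError("rasters must share channel count and duration")
        merged = [
            np.sort(np.concatenate([a, b]))
            for a, b in zip(self.spikes, other.spikes)
        ]
        return SpikeRaster(self.n_channels, merged, self.duration)


def _as_range(law) -> tuple[float, float]:
    """Normalize a fixed value or (lo, hi) pair to a (lo, hi) tuple."""
    if np.isscalar(law):
        return float(law), float(law)
    lo, hi = law
    if hi < lo:
        raise ValueError("range law must be (lo, hi) with hi >= lo")
    return float(lo), float(hi)


@dataclass
class SequenceSpec:
    """Generative description of one jittered-sequence input epoch.

    ``n_seq`` channels fire once each, channel ``k`` at
    ``onset + k * inter_spike_delay + jitter_k`` with jitter uniform in
    ``[-jitter_range, +jitter_range]``.  Every channel (sequence and
    distractor alike) additionally carries homogeneous-Poisson background
    spikes; rate laws and the onset law may be fixed values or uniform
    ranges sampled per epoch.
    """

    n_seq: int = 100
    inter_spike_delay: float = 2.0
    jitter_range: float = 2.0
    background_rate: object = (0.0, 10.0)  # Hz, fixed or (lo, hi)
    n_distractors: int = 100
    distractor_rate: object = None  # defaults to background_rate law
    onset: object = (0.0, 200.0)  # ms, fixed or (lo, hi)
    T: float = 400.0

    def __post_init__(self):
        if self.n_seq < 0 or self.n_distractors < 0:
            raise ValueError("channel counts must be non-negative")
        if self.jitter_range < 0:
            raise ValueError("jitter_range must be non-negative")
        lo, hi = _as_range(self.background_rate)
        if lo < 0:
            raise ValueError("background rates must be non-negative")
        if self.distractor_rate is not None and _as_range(self.distractor_rate)[0] < 0:
            raise ValueError("distractor rates must be non-negative")
        on_lo, on_hi = _as_range(self.onset)
        if on_lo < 0:
            raise ValueError("onset must be non-negative")
        if self.n_seq >= 1:
            span = on_hi + (self.n_seq - 1) * self.inter_spike_delay + self.jitter_range
            if span > self.T:
                raise ValueError(
                    "onset + (n_seq-1)*delay + jitter_range must be <= T "
                    f"(got {span} > {self.T}); spikes at exactly T are clipped "
                    "to the last timestep"
                )

    @property
    def n_channels(self) -> int:
        return self.n_seq + self.n_distractors

    @property
    def nominal_span(self) -> float:
        """Booked sequence length: ``n_seq * inter_spike_delay`` (ms)."""
        return self.n_seq * self.inter_spike_delay


@dataclass
class InputTrace:
    """Time-discretized, exponentially filtered presynaptic drive.

    ``values[t, c]`` is the dimensionless drive of channel ``c`` at step
    ``t``; between spikes each channel decays by ``exp(-h/tau_x)`` per step.
    """

    values: np.ndarray  # (n_steps, n_channels)
    h: float = DEFAULT_H
    tau_x: float = 2.0

    @property
    def n_steps(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    @property
    def duration(self) -> float:
        return self.n_steps * self.h


def _poisson_background(rng, rate_hz: float, T: float, h: float) -> np.ndarray:
    """Background spike times from Bernoulli thinning on the timestep grid.

    At ``h = 0.05`` ms and rates <= tens of Hz, ``rate*h`` is ~1e-3 so the
    per-bin Bernoulli approximation of the Poisson process is exact to the
    grid resolution, at O(T/h) cost.
    """
    if rate_hz <= 0:
        return np.empty(0)
    n_steps = int(round(T / h))
    p = rate_hz * h / 1000.0
    hits = rng.random(n_steps) < p
    return np.flatnonzero(hits) * h


def generate_sequence_epoch(
    spec: SequenceSpec, seed, h: float = DEFAULT_H
) -> SpikeRaster:
    """Draw one epoch of the jittered-sequence stimulus.

    Channels ``0 .. n_seq-1`` carry the sequence spike plus background;
    channels ``n_seq .. n_seq+n_distractors-1`` carry background only.
    Jitter that would move a spike out of ``[0, T)`` is clipped to the
    window boundary.  Identical ``(spec, seed)`` give identical rasters.
    """
    rng = np.random.default_rng(seed)
    on_lo, on_hi = _as_range(spec.onset)
    onset = rng.uniform(on_lo, on_hi) if on_hi > on_lo else on_lo

    bg_lo, bg_hi = _as_range(spec.background_rate)
    di_law = spec.background_rate if spec.distractor_rate is None else spec.distractor_rate
    di_lo, di_hi = _as_range(di_law)

    spikes = []
    nominal = []
    eps = 1e-9
    for k in range(spec.n_seq):
        nom = onset + k * spec.inter_spike_delay
        t = nom
        if spec.jitter_range > 0:
            t += rng.uniform(-spec.jitter_range, spec.jitter_range)
        t = min(max(t, 0.0), spec.T - h + eps)
        nominal.append(nom)
        rate = rng.uniform(bg_lo, bg_hi) if bg_hi > bg_lo else bg_lo
        bg = _poisson_background(rng, rate, spec.T, h)
        spikes.append(np.sort(np.append(bg, t)))
    for _ in range(spec.n_distractors):
        rate = rng.uniform(di_lo, di_hi) if di_hi > di_lo else di_lo
        spikes.append(_poisson_background(rng, rate, spec.T, h))
    meta = {"onset": onset, "nominal_sequence_times": np.array(nominal)}
    return SpikeRaster(spec.n_channels, spikes, spec.T, meta=meta)


def make_two_input_pattern(t1: float, t2: float, T: float = 500.0) -> SpikeRaster:
    """Deterministic 2-channel pattern: channel 1 at ``t1`` ms, channel 2 at ``t2`` ms."""
    for t in (t1, t2):
        if not (0 <= t < T):
            raise ValueError(f"spike time {t} outside [0, {T})")
    return SpikeRaster(2, [np.array([t1]), np.array([t2])], T)


STDP_PROTOCOLS = ("pairing", "burst", "one_n", "freq_pairing")


def make_stdp_schedule(protocol: str, T: float = 500.0, **params) -> SpikeRaster:
    """Presynaptic event times for one epoch of an STDP protocol.

    Channel 2 (index 1) is the suprathreshold-designated input — each of its
    spikes is meant to evoke a post-synaptic spike — and channel 1 (index 0)
    is the subthreshold probe whose weight change the protocols read out.
    The sign convention is that ``dt < 0`` means channel 1 precedes channel 2.

    Protocols
    ---------
    pairing(dt, t_ref=50.0)
        One spike per channel, channel 1 at ``t_ref + dt``.
    burst(freq_hz, branch='pre_post'|'post_pre', n_burst=3, probe_gap=10.0,
          t_ref=50.0)
        A burst of ``n_burst`` channel-2 spikes spaced ``1000/freq_hz`` ms;
        the probe fires ``probe_gap`` ms before the first (pre_post) or
        after the last (post_pre) burst spike.
    one_n(n, burst_freq_hz=100.0, t_ref=50.0)
        Post-pre-post motif: one channel-2 spike, the probe ``1/f`` later,
        then ``n - 1`` further channel-2 spikes at ``1/f`` intervals.
        ``n=1`` degenerates to a single post-pre pairing.
    freq_pairing(pairing_freq_hz, n_pairs=5, intra_dt=6.0, t_ref=50.0)
        ``n_pairs`` post-pre pairs (channel 2 leading the probe by
        ``intra_dt`` ms) whose onsets repeat at the pairing frequency; the
        window is extended automatically when the pairs do not fit in ``T``.
    """
    if protocol not in STDP_PROTOCOLS:
        raise ValueError(f"unknown protocol {protocol!r}; choose from {STDP_PROTOCOLS}")
    t_ref = float(params.pop("t_ref", 50.0))

    if protocol == "pairing":
        dt = float(params.pop("dt"))
        ch1, ch2 = [t_ref + dt], [t_ref]
    elif protocol == "burst":
        f = float(params.pop("freq_hz"))
        if f <= 0:
            raise ValueError("intra-burst frequency must be positive")
        branch = params.pop("branch", "pre_post")
        n_burst = int(params.pop("n_burst", 3))
        gap = float(params.pop("probe_gap", 10.0))
        isi = 1000.0 / f
        ch2 = [t_ref + i * isi for i in range(n_burst)]
        ch1 = [t_ref - gap] if branch == "pre_post" else [ch2[-1] + gap]
    elif protocol == "one_n":
        n = int(params.pop("n"))
        if n < 1:
            raise ValueError("n must be >= 1")
        f = float(params.pop("burst_freq_hz", 100.0))
        if f <= 0:
            raise ValueError("burst frequency must be positive")
        isi = 1000.0 / f
        ch1 = [t_ref + isi]
        ch2 = [t_ref] + [t_ref + (1 + i) * isi for i in range(1, n)]
    else:  # freq_pairing
        f = float(params.pop("pairing_freq_hz"))
        if f <= 0:
            raise ValueError("pairing frequency must be positive")
        n_pairs = int(params.pop("n_pairs", 5))
        intra = float(params.pop("intra_dt", 6.0))
        period = 1000.0 / f
        ch2 = [t_ref + i * period for i in range(n_pairs)]
        ch1 = [t + intra for t in ch2]
        needed = max(ch1[-1], ch2[-1]) + 100.0
        if needed > T:
            T = needed
    if params:
        raise TypeError(f"unused protocol parameters: {sorted(params)}")
    ts = np.concatenate([ch1, ch2])
    if ts.min() < 0 or ts.max() >= T:
        raise ValueError("protocol events fall outside the epoch window")
    return SpikeRaster(2, [np.array(ch1, float), np.array(ch2, float)], T)


def bin_raster(raster: SpikeRaster, h: float = DEFAULT_H) -> np.ndarray:
    """Spike counts on the timestep grid, shape (n_steps, n_channels).

    Spikes are assigned to the nearest grid point (sub-timestep jitter is
    rounded); multiple spikes in one channel and bin sum.
    """
    n_steps = int(round(raster.duration / h))
    counts = np.zeros((n_steps, raster.n_channels))
    for c, ts in enumerate(raster.spikes):
        if len(ts) == 0:
            continue
        idx = np.clip(np.rint(ts / h).astype(np.int64), 0, n_steps - 1)
        np.add.at(counts[:, c], idx, 1.0)
    return counts


def filter_raster(
    raster: SpikeRaster, h: float = DEFAULT_H, tau_x: float = 2.0
) -> InputTrace:
    """Causal exponential filtering of a raster onto the timestep grid.

    A lone spike at step ``t0`` contributes 1 at ``t0`` and
    ``exp(-h*k/tau_x)`` at ``t0 + k``; filtering is linear, so superposed
    rasters filter to the sum of the individual traces.
    """
    if h <= 0 or tau_x <= 0:
        raise ValueError("h and tau_x must be positive")
    counts = bin_raster(raster, h)
    values = exp_filter_inplace(counts, np.exp(-h / tau_x))
    return InputTrace(values=values, h=h, tau_x=tau_x)
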
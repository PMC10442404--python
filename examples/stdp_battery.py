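"""Emergent STDP: pairing window and nonlinear protocol variants.

Classic plasticity protocols are simulated with two inputs: channel 2 is
strong enough that each of its spikes evokes a post-synaptic spike (the
stand-in for experimental current injection), channel 1 is a subthreshold
probe.  No STDP kernel is built in — the timing dependence below emerges
from the predictive rule alone.
"""

from prespike import (
    stdp_burst_curve,
    stdp_freq_pairing_curve,
    stdp_one_n_curve,
    stdp_pairing_curve,
)

window = stdp_pairing_curve([-20, -10, -4, 4, 10, 20], tau_m_list=(10.0,))
print("pairing window (dt ms -> probe weight change %):")
for dt, pct in zip(window.x, window.pct_change):
    print(f"  {dt:+6.0f}  {pct:+8.1f}")

burst = stdp_burst_curve([20.0, 50.0, 100.0], branches=("pre_post",))
print("pre-post burst LTP vs intra-burst frequency (Hz -> %):",
      dict(zip(burst.x, burst.pct_change.round(1))))

one_n = stdp_one_n_curve([1, 2, 3])
print("post-pre-post 1-n protocol (n -> %):",
      dict(zip(one_n.x.astype(int), one_n.pct_change.round(1))))

fp = stdp_freq_pairing_curve([5.0, 100.0])
print("5 post-pre pairs at low/high pairing frequency (Hz -> %):",
      dict(zip(fp.x, fp.pct_change.round(1))))

# Read-out: probes arriving shortly BEFORE the spike-evoking input gain
# weight (LTP), shortly AFTER lose weight (LTD) — an antisymmetric window.
# Faster bursts boost LTP, extra post-synaptic spikes convert the post-pre
# depression into potentiation, and high-frequency pairing does the same.
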
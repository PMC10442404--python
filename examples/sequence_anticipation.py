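"""Sequence anticipation in noise: credit flows to the first input.

100 presynaptic neurons fire sequentially at 2 ms delays (a 200 ms
sequence), jittered by +/-2 ms, embedded in 0-10 Hz Poisson background with
100 pure-noise distractor channels, and the sequence onset moves uniformly
over 0-200 ms every epoch.  After training, the neuron fires within a few
ms of sequence onset and the first sequence channel holds the largest
weight.
"""

import numpy as np

from prespike import run_sequence_task

res = run_sequence_task(n_epochs=1000, seed=1)

w = res.w_final
print(f"held-out latency rel. onset : {res.eval_latency:.2f} ms (success < 20 ms)")
print(f"most potentiated channel    : {np.argmax(w)} (0 = first in sequence)")
print(f"w(first) / max w(others)    : {w[0] / w[1:].max():.1f}")
print(f"cumulative depolarization   : {res.losses.cum_v[0]:.0f} -> "
      f"{np.mean(res.losses.cum_v[-100:]):.0f} (epoch 0 -> final)")
print(f"success (selective & fast)  : {res.success}")

# The latency collapse and the weight concentration on channel 0 show that
# the neuron has learned the temporal structure: the earliest input predicts
# everything that follows, so it alone keeps (and grows) its synapse while
# the redundant later inputs and the distractors are depressed.  The drop in
# cumulative depolarization is the efficiency gain of anticipation.
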
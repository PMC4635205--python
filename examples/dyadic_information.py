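"""Information-theoretic contagion between two individuals.

Treats one individual's behavioral symbols as channel inputs and the
other's as outputs, and quantifies how much behavior "passes through".
"""

import math

import numpy as np

from behaviordyn.information import (
    channel_capacity,
    contagion,
    entropy,
    maxent_distribution,
    mutual_contagion,
)

# Surprisal of single events, in bits.
print(f"contagion of a sure event: I(1) = {contagion(1.0):.1f} bits")
print(f"contagion of a coin flip:  I(0.5) = {contagion(0.5):.1f} bit")
print(f"entropy of (0.5, 0.25, 0.25) = {entropy([0.5, 0.25, 0.25]):.2f} bits")

# A noisy dyad: the receiver mirrors the sender's behavior 89% of the time.
e = 0.11
channel = [[1 - e, e], [e, 1 - e]]
cap, p_opt = channel_capacity(channel)
h2 = -e * math.log2(e) - (1 - e) * math.log2(1 - e)
print(f"channel capacity with 11% mirroring error = {cap:.4f} bits "
      f"(closed form 1 - H2(0.11) = {1 - h2:.4f}), optimal input = {p_opt.round(3)}")

joint = np.array([[0.445, 0.055], [0.055, 0.445]])
res = mutual_contagion(joint)
print(f"mutual contagion at the uniform input: I(F;G) = {res.mutual:.4f} bits "
      f"= S(F) - S(F|G) = {res.h_f:.3f} - {res.h_f_given_g:.3f}")

# Maximum-entropy reconstruction of a behavior distribution from a
# macroscopic constraint (mean behavioral intensity 0.5 on levels 0/1/2).
me = maxent_distribution([[0.0, 1.0, 2.0]], [0.5])
print(f"max-ent distribution with mean 0.5: {me.dist.round(4)}, "
      f"ln(partition) = {me.log_partition:.4f}")
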
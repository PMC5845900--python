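"""Rank features by minimal-redundancy maximal-relevance (mRMR).

A perfectly informative feature is planted among correlated noise; mRMR
should rank it first, and rank its exact duplicate far below second place
because the duplicate's redundancy cancels its relevance (MID criterion).
"""

import numpy as np

import dcipred as dp

rng = np.random.default_rng(4)
n = 200
y = rng.integers(0, 2, n)
X = rng.normal(size=(n, 8))
X[:, 3] = y + rng.normal(0, 0.2, n)   # strongly informative
X[:, 5] = X[:, 3].copy()              # exact duplicate of it

for criterion in ("MID", "MIQ"):
    order = dp.mrmr_rank(X, y, criterion=criterion, k=4)
    print(f"{criterion} ranking (column indices): {order}")

# Relevance vs redundancy, quantified in nats:
from dcipred.selection import discretize, mutual_information
codes3 = discretize(X[:, 3])
print(f"I(x3, y)  = {mutual_information(codes3, y):.3f} nats (relevance)")
print(f"I(x3, x5) = {mutual_information(codes3, discretize(X[:, 5])):.3f} "
      "nats (redundancy of the duplicate)")
# Under MID the duplicate's criterion value is relevance - redundancy ~ 0,
# so it cannot be picked immediately after the original.
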
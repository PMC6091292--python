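"""The GeneRank random walk on a tiny hand-built pathway network.

Three pathways on a path graph 1-2-3 with all prior mass on node 1:
damping d controls how much score diffuses from the seeded node to its
neighbors versus staying with the prior.
"""

import numpy as np

from pathnet.ranking import generank

w = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], float)
ex = np.array([1.0, 0.0, 0.0])  # all mutual-information mass on pathway 1

for d in (0.0, 0.5, 0.85):
    res = generank(ex, w, w.sum(axis=1), d=d, epsilon=1e-12)
    print(f"d = {d:4.2f}: r = {np.round(res.r, 4)}  "
          f"({res.iterations_used} iterations)")

print()
print("At d = 0 the walk returns the prior itself.  As d grows, the hub")
print("(node 2, adjacent to the seeded node) accumulates score it relays")
print("onward — at d = 0.85 it overtakes the seed, which is exactly how a")
print("pathway with no direct phenotype signal can be promoted by its")
print("similarity to signal-bearing neighbors.")
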
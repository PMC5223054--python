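"""Independent brute-force oracles shared by the test modules.

These deliberately avoid the package's own data structures and algorithms:
cluster search is a breadth-first flood fill over an explicit neighbour
function, and recall scoring enumerates subsequences exhaustively.
"""

from collections import deque
from itertools import combinations

import numpy as np


def flood_fill_clusters(tmap, threshold, spatial=None, dims=None):
    """Brute-force clusters of |t| > threshold, split by polarity.

    Neighbours: +-1 along freq/time axes, explicit graph along a space
    axis.  Returns a set of (polarity, frozenset of flat indices, rounded
    t_sum) triples.
    """
    shape = tmap.shape
    dims = dims or ("freq", "time")[:len(shape)]

    def neighbours(idx):
        for ax, kind in enumerate(dims):
            if kind == "space":
                for j in range(shape[ax]):
                    if spatial[idx[ax], j]:
                        yield idx[:ax] + (j,) + idx[ax + 1:]
            else:
                for step in (-1, 1):
                    k = idx[ax] + step
                    if 0 <= k < shape[ax]:
                        yield idx[:ax] + (k,) + idx[ax + 1:]

    out = set()
    for pol, mask in (("pos", tmap > threshold), ("neg", tmap < -threshold)):
        seen = np.zeros(shape, dtype=bool)
        for start in zip(*np.nonzero(mask)):
            if seen[start]:
                continue
            comp = []
            q = deque([start])
            seen[start] = True
            while q:
                cur = q.popleft()
                comp.append(cur)
                for nb in neighbours(cur):
                    if mask[nb] and not seen[nb]:
                        seen[nb] = True
                        q.append(nb)
            flat = frozenset(np.ravel_multi_index(np.array(comp).T, shape).tolist())
            out.add((pol, flat, round(float(sum(tmap[c] for c in comp)), 9)))
    return out


def result_as_set(clusters, shape):
    """Canonical comparable form of the package's cluster list."""
    return {(c.polarity, frozenset(int(i) for i in c.members),
             round(c.t_sum, 9)) for c in clusters}


def brute_force_lis_length(seq):
    """Maximum increasing subsequence size by exhaustive enumeration."""
    for r in range(len(seq), 0, -1):
        for combo in combinations(range(len(seq)), r):
            vals = [seq[i] for i in combo]
            if all(a < b for a, b in zip(vals, vals[1:])):
                return r
    return 0
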
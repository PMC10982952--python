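"""Brute-force reference computations, independent of the library's
implementations, used by the acceptance script for oracle comparisons."""

import itertools

import numpy as np


def brute_force_betweenness(g):
    """Unnormalized betweenness by enumerating every shortest path."""
    n = g.n_nodes
    adj = g.adjacency
    result = np.zeros(n)
    for s, t in itertools.combinations(range(n), 2):
        paths, frontier = [], [[s]]
        found = False
        while frontier and not found:
            nxt = []
            for p in frontier:
                for v in np.nonzero(adj[p[-1]])[0]:
                    if v in p:
                        continue
                    q = p + [int(v)]
                    if v == t:
                        paths.append(q)
                        found = True
                    else:
                        nxt.append(q)
            frontier = nxt
        if not paths:
            continue
        for k in range(n):
            if k in (s, t):
                continue
            through = sum(1 for p in paths if k in p[1:-1])
            result[k] += through / len(paths)
    return result
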
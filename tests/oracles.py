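"""Independent brute-force oracles shared by test modules.

These deliberately use naive exhaustive algorithms (vertex enumeration,
permutation enumeration) so they stay independent of the solver paths
they check; they are exponential and only usable on tiny instances.
"""

import itertools

import numpy as np


def ot_bruteforce(cost, a, b, tol=1e-12):
    """Exact transport cost by enumerating all basic feasible solutions.

    Vertices of the transport polytope correspond to spanning trees of the
    complete bipartite supply/demand graph; for each candidate edge set the
    tree flows are solved by leaf elimination and feasible (non-negative)
    solutions are scored.  Exponential, hence only for tiny instances.
    """
    n, m = cost.shape
    edges = list(itertools.product(range(n), range(m)))
    best = np.inf
    for subset in itertools.combinations(edges, n + m - 1):
        supply = np.concatenate([a, -np.asarray(b)])  # nodes 0..n-1, n..n+m-1
        adj = {v: [] for v in range(n + m)}
        for k, (i, j) in enumerate(subset):
            adj[i].append((n + j, k))
            adj[n + j].append((i, k))
        flows = np.zeros(len(subset))
        degrees = {v: len(adj[v]) for v in adj}
        removed = [False] * len(subset)
        ok = True
        for _ in range(n + m - 1):
            leaf = next(
                (v for v in adj if degrees[v] == 1), None
            )
            if leaf is None:  # cycle -> not a tree
                ok = False
                break
            nbr, k = next((u, k) for u, k in adj[leaf] if not removed[k])
            f = supply[leaf] if leaf < n else -supply[leaf]
            flows[k] = f
            supply[nbr] += supply[leaf] if nbr >= n else supply[leaf]
            supply[leaf] = 0.0
            removed[k] = True
            degrees[leaf] -= 1
            degrees[nbr] -= 1
            adj[leaf] = [e for e in adj[leaf] if not removed[e[1]]]
            adj[nbr] = [e for e in adj[nbr] if not removed[e[1]]]
        if not ok or np.any(flows < -tol):
            continue
        c = sum(f * cost[i, j] for f, (i, j) in zip(flows, subset))
        best = min(best, c)
    return best


def gw_permutation_oracle(xs, xt):
    """Minimum square-loss GW objective over all assignment couplings."""
    n = len(xs)
    c1 = np.linalg.norm(xs[:, None] - xs[None, :], axis=-1)
    c2 = np.linalg.norm(xt[:, None] - xt[None, :], axis=-1)
    return min(
        float(np.sum((c1 - c2[np.ix_(p, p)]) ** 2)) / n**2
        for p in (np.asarray(pp) for pp in itertools.permutations(range(n)))
    )


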
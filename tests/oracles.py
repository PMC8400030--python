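"""Independent brute-force oracles used to validate the implementation.

Deliberately written in the plainest possible style (dict-based DP,
explicit loops, path enumeration) and kept free of any imports from the
modules they check.
"""

from __future__ import annotations

from itertools import combinations

NEG = float("-inf")


def gotoh_oracle(a: str, b: str, match=1.0, mismatch=0.0, gap_open=-10.0, gap_extend=-1.0):
    """Exhaustive three-state affine-gap global alignment DP.

    Returns (score, aligned_a, aligned_b).  Gap of length L costs
    gap_open + (L-1)*gap_extend; end gaps are penalised.  Traceback is
    backward with tie priority substitution > gap-in-b > gap-in-a,
    the documented canonical convention.
    """
    n, m = len(a), len(b)
    M = {}
    X = {}  # gap in b (consumes a)
    Y = {}  # gap in a (consumes b)
    for i in range(n + 1):
        for j in range(m + 1):
            M[i, j] = X[i, j] = Y[i, j] = NEG
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = gap_open + (i - 1) * gap_extend
    for j in range(1, m + 1):
        Y[0, j] = gap_open + (j - 1) * gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
            X[i, j] = max(
                M[i - 1, j] + gap_open,
                X[i - 1, j] + gap_extend,
                Y[i - 1, j] + gap_open,
            )
            Y[i, j] = max(
                M[i, j - 1] + gap_open,
                X[i, j - 1] + gap_open,
                Y[i, j - 1] + gap_extend,
            )
    score = max(M[n, m], X[n, m], Y[n, m])

    # backward traceback, priority M > X > Y on ties
    tol = 1e-9
    i, j = n, m
    if abs(M[i, j] - score) <= tol:
        state = "M"
    elif abs(X[i, j] - score) <= tol:
        state = "X"
    else:
        state = "Y"
    ra, rb = [], []
    while i > 0 or j > 0:
        if state == "M":
            s = match if a[i - 1] == b[j - 1] else mismatch
            target = M[i, j] - s
            ra.append(a[i - 1])
            rb.append(b[j - 1])
            i, j = i - 1, j - 1
            cand = [("M", M[i, j]), ("X", X[i, j]), ("Y", Y[i, j])]
        elif state == "X":
            target = X[i, j]
            ra.append(a[i - 1])
            rb.append("-")
            i -= 1
            cand = [
                ("M", M[i, j] + gap_open),
                ("X", X[i, j] + gap_extend),
                ("Y", Y[i, j] + gap_open),
            ]
        else:
            target = Y[i, j]
            ra.append("-")
            rb.append(b[j - 1])
            j -= 1
            cand = [
                ("M", M[i, j] + gap_open),
                ("X", X[i, j] + gap_open),
                ("Y", Y[i, j] + gap_extend),
            ]
        if i == 0 and j == 0:
            break
        for name, value in cand:
            if abs(value - target) <= tol:
                state = name
                break
        else:  # pragma: no cover
            raise RuntimeError("oracle traceback failed")
    return score, "".join(reversed(ra)), "".join(reversed(rb))


def identity_oracle(aligned_a: str, aligned_b: str):
    """(matches, columns) excluding terminal gap overhangs, by direct
    character comparison."""
    cols = list(zip(aligned_a, aligned_b))
    while cols and "-" in cols[0]:
        cols.pop(0)
    while cols and "-" in cols[-1]:
        cols.pop()
    matches = sum(1 for x, y in cols if x == y and x != "-")
    return matches, len(cols)


# ---------------------------------------------------------------------------
# phenotype oracles

CHAIN = ("nar", "nir", "nor", "nos")
PRODUCT = {"nar": "nitrite", "nir": "NO", "nor": "N2O", "nos": "N2"}


def end_product_oracle(present: frozenset) -> str:
    """Walk the chain and report the product of the last present step."""
    last = "none"
    for enzyme in CHAIN:
        if enzyme in present:
            last = PRODUCT[enzyme]
    return last


def consecutive_oracle(present: frozenset) -> bool:
    """Check that present steps occupy a contiguous interval by testing
    every interval of the chain."""
    if not present:
        return True
    for start in range(4):
        for end in range(start, 4):
            if set(CHAIN[start : end + 1]) == set(present):
                return True
    return False


def all_16_profiles():
    for size in range(5):
        for combo in combinations(CHAIN, size):
            yield frozenset(combo)


# ---------------------------------------------------------------------------
# additive-tree oracle for neighbour joining


def random_unrooted_tree(labels, rng, min_len=0.1, max_len=2.0):
    """Random unrooted binary tree as an adjacency map with edge lengths.

    Built by attaching each new leaf to a uniformly chosen existing
    edge; all edge lengths positive so the distance matrix is strictly
    additive.
    """
    adj: dict = {labels[0]: {}, labels[1]: {}}
    next_internal = [0]

    def connect(u, v, w):
        adj.setdefault(u, {})[v] = w
        adj.setdefault(v, {})[u] = w

    def disconnect(u, v):
        del adj[u][v]
        del adj[v][u]

    connect(labels[0], labels[1], float(rng.uniform(min_len, max_len)))
    for leaf in labels[2:]:
        edges = [(u, v) for u in adj for v in adj[u] if str(u) < str(v)]
        u, v = edges[int(rng.integers(len(edges)))]
        w = adj[u][v]
        hub = f"__h{next_internal[0]}"
        next_internal[0] += 1
        disconnect(u, v)
        split = float(rng.uniform(0.2, 0.8))
        connect(u, hub, w * split)
        connect(hub, v, w * (1 - split))
        connect(hub, leaf, float(rng.uniform(min_len, max_len)))
    return adj


def path_distance_matrix(adj, labels):
    """Leaf-to-leaf path-length matrix by breadth-first path summing."""
    import numpy as np

    n = len(labels)
    d = np.zeros((n, n))
    for i, src in enumerate(labels):
        dist = {src: 0.0}
        queue = [src]
        while queue:
            node = queue.pop()
            for nbr, w in adj[node].items():
                if nbr not in dist:
                    dist[nbr] = dist[node] + w
                    queue.append(nbr)
        for j, dst in enumerate(labels):
            d[i, j] = dist[dst]
    return d


def tree_splits_and_lengths(adj, labels):
    """Canonical {split: length} map over all edges of the adjacency tree.

    Pendant edges are keyed by the single leaf; internal edges by the
    canonicalised bipartition of leaf labels.
    """
    full = frozenset(labels)

    def side_of(u, v):
        # leaves reachable from v without crossing u
        seen = {u, v}
        queue = [v]
        leaves = set()
        while queue:
            node = queue.pop()
            if node in full:
                leaves.add(node)
            for nbr in adj[node]:
                if nbr not in seen:
                    seen.add(nbr)
                    queue.append(nbr)
        return frozenset(leaves)

    out = {}
    for u in adj:
        for v in adj[u]:
            if not str(u) < str(v):
                continue
            side = side_of(u, v)
            if len(side) == 1:
                key = ("leaf", next(iter(side)))
            elif len(full - side) == 1:
                key = ("leaf", next(iter(full - side)))
            else:
                a = tuple(sorted(side))
                b = tuple(sorted(full - side))
                key = ("split", min(a, b), max(a, b))
            out[key] = adj[u][v]
    return out
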
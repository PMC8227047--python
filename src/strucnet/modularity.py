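"""Newman modularity maximization by leading-eigenvector bisection.

Subdivides a binary network into nonoverlapping groups maximizing
Q = sum_c [ e_cc/E - (sum_{i in c} k_i / 2E)^2 ], i.e. within-group edge
excess over the degree-matched random expectation.

The optimizer recursively bisects along the sign of the leading eigenvector
of the (generalized) modularity matrix, refines each bisection with a
Kernighan-Lin single-node-swap pass, and finishes with greedy single-node
moves and community merges until no step increases Q.  Every tie is broken
toward the lower node (or community) index, so the result is deterministic:
no randomness is involved.
"""

from __future__ import annotations

import numpy as np

_TOL = 1e-12


def modularity_q(adjacency: np.ndarray, membership: np.ndarray) -> float:
    """Newman modularity Q of a node partition of a binary undirected graph."""
    a = np.asarray(adjacency, dtype=float)
    membership = np.asarray(membership)
    k = a.sum(axis=1)
    two_m = k.sum()
    if two_m == 0:
        raise ValueError("modularity undefined for a graph with no edges")
    q = 0.0
    for c in np.unique(membership):
        idx = membership == c
        e_cc = a[np.ix_(idx, idx)].sum() / two_m  # within-group edge fraction
        deg_c = k[idx].sum() / two_m
        q += e_cc - deg_c**2
    return float(q)


def _leading_eigenvector(b: np.ndarray) -> tuple[float, np.ndarray]:
    vals, vecs = np.linalg.eigh(b)
    v = vecs[:, -1]
    # fix the arbitrary overall sign: first nonzero component positive
    nz = np.flatnonzero(np.abs(v) > _TOL)
    if nz.size and v[nz[0]] < 0:
        v = -v
    return float(vals[-1]), v


#: communities up to this size are bisected exactly by sign-vector enumeration
_EXACT_BISECTION_MAX = 12

#: whole networks up to this size are solved by exhaustive partition search
#: (recursive bisection cannot represent every optimum; at this size
#: enumeration over all set partitions is cheap and removes the heuristic gap)
_EXACT_PARTITION_MAX = 10


def _restricted_growth_strings(n: int):
    """All set partitions of n items as canonical membership vectors."""
    mem = np.zeros(n, dtype=np.int64)

    def rec(i: int, n_used: int):
        if i == n:
            yield mem
            return
        for c in range(n_used + 1):
            mem[i] = c
            yield from rec(i + 1, max(n_used, c + 1))

    yield from rec(1, 1)


def _exact_partition(b: np.ndarray) -> np.ndarray:
    """Globally optimal partition of a tiny graph's modularity matrix."""
    n = b.shape[0]
    best_q = -np.inf
    best = np.zeros(n, dtype=np.int64)
    for mem in _restricted_growth_strings(n):
        q = b[mem[:, None] == mem[None, :]].sum()
        if q > best_q + _TOL:
            best_q = q
            best = mem.copy()
    return best


def _best_bisection_exact(b_g: np.ndarray) -> np.ndarray:
    """Optimal bisection of a small community: enumerate all sign vectors.

    Fixes the first node's sign (s and -s are the same split); on ties the
    enumeration order prefers the lexicographically earliest assignment.
    """
    n = b_g.shape[0]
    codes = np.arange(2 ** (n - 1))[:, None]
    bits = (codes >> np.arange(n - 1)[None, :]) & 1
    s_all = np.hstack([np.ones((len(codes), 1)), 1.0 - 2.0 * bits])
    vals = np.einsum("ij,jk,ik->i", s_all, b_g, s_all)
    return s_all[int(np.argmax(vals))]


def _split_q(b_g: np.ndarray, s: np.ndarray, two_m: float) -> float:
    return float(s @ b_g @ s) / (2.0 * two_m)


def _kl_refine(b_g: np.ndarray, s: np.ndarray, two_m: float) -> np.ndarray:
    """Kernighan-Lin style refinement of a bisection vector s in {-1, +1}.

    Repeated passes: each pass flips every node once, at each step the flip
    with the largest Q gain (ties toward the lower node index), and keeps the
    best intermediate state if it improves on the pass start.
    """
    n = len(s)
    s = s.copy()
    best_q = _split_q(b_g, s, two_m)
    improved = True
    while improved:
        improved = False
        s_pass = s.copy()
        bs = b_g @ s_pass
        moved = np.zeros(n, dtype=bool)
        trail_q = _split_q(b_g, s_pass, two_m)
        best_trail_q, best_trail_state = best_q, None
        for _ in range(n):
            # gain of flipping node i given current s_pass
            gains = -2.0 * s_pass * (bs - np.diag(b_g) * s_pass) / two_m
            gains[moved] = -np.inf
            i = int(np.argmax(gains))  # argmax takes the lowest index on ties
            trail_q += gains[i]
            bs += -2.0 * s_pass[i] * b_g[:, i]
            s_pass[i] = -s_pass[i]
            moved[i] = True
            if trail_q > best_trail_q + _TOL:
                best_trail_q = trail_q
                best_trail_state = s_pass.copy()
        if best_trail_state is not None:
            s = best_trail_state
            best_q = best_trail_q
            improved = True
    return s


def _bisect(a: np.ndarray, k: np.ndarray, two_m: float, nodes: np.ndarray):
    """Try to split the community ``nodes``; return (part1, part2) or None."""
    if len(nodes) < 2:
        return None
    b = a[np.ix_(nodes, nodes)] - np.outer(k[nodes], k[nodes]) / two_m
    b_g = b - np.diag(b.sum(axis=1))  # generalized modularity matrix
    if len(nodes) <= _EXACT_BISECTION_MAX:
        s = _best_bisection_exact(b_g)
    else:
        eigval, v = _leading_eigenvector(b_g)
        if eigval <= _TOL:
            s = np.ones(len(nodes))
        else:
            s = np.where(v > _TOL, 1.0, -1.0)
        s = _kl_refine(b_g, s, two_m)
    if np.all(s == s[0]):
        return None
    if _split_q(b_g, s, two_m) <= _TOL:
        return None
    return nodes[s > 0], nodes[s < 0]


def _local_moves(a: np.ndarray, k: np.ndarray, two_m: float,
                 membership: np.ndarray) -> np.ndarray:
    """Greedy single-node moves and community merges until Q is stable."""
    membership = membership.copy()
    n = len(membership)
    while True:
        changed = False
        # node moves (including moves into a fresh singleton community)
        for i in range(n):
            ci = membership[i]
            # edges from i to each community, and community total degrees
            comms, inv = np.unique(membership, return_inverse=True)
            e_ic = np.bincount(inv, weights=a[i], minlength=len(comms))
            k_c = np.bincount(inv, weights=k, minlength=len(comms))
            ci_pos = int(np.searchsorted(comms, ci))
            base = e_ic[ci_pos] / two_m * 2 - 2 * k[i] * (k_c[ci_pos] - k[i]) / two_m**2
            gains = (2 * e_ic / two_m
                     - 2 * k[i] * k_c / two_m**2) - base
            gains[ci_pos] = 0.0
            singleton_gain = -base  # move i into a new empty community
            j = int(np.argmax(gains))
            if singleton_gain > gains[j] + _TOL and singleton_gain > _TOL:
                membership[i] = membership.max() + 1
                changed = True
            elif gains[j] > _TOL:
                membership[i] = comms[j]
                changed = True
        # community merges
        comms, inv = np.unique(membership, return_inverse=True)
        if len(comms) > 1:
            k_c = np.bincount(inv, weights=k)
            onehot = np.eye(len(comms))[inv]
            e_cc = onehot.T @ a @ onehot  # inter-community edge counts
            merge_gain = 2 * e_cc / two_m - 2 * np.outer(k_c, k_c) / two_m**2
            np.fill_diagonal(merge_gain, -np.inf)
            best = np.unravel_index(np.argmax(merge_gain), merge_gain.shape)
            if merge_gain[best] > _TOL:
                lo, hi = sorted((comms[best[0]], comms[best[1]]))
                membership[membership == hi] = lo
                changed = True
        if not changed:
            break
    # relabel communities 0..n_comms-1 in order of first appearance
    seen: dict[int, int] = {}
    out = np.empty(n, dtype=np.int64)
    for i, c in enumerate(membership):
        if c not in seen:
            seen[c] = len(seen)
        out[i] = seen[c]
    return out


def modularity_newman(network) -> tuple[float, np.ndarray]:
    """Maximize Newman modularity; returns (Q, membership).

    ``membership[i]`` is the community index of node i (0-based, in order of
    first appearance).  Deterministic: repeated calls give identical output.
    """
    a = np.asarray(network.adjacency, dtype=float)
    k = a.sum(axis=1)
    two_m = k.sum()
    if two_m == 0:
        raise ValueError("modularity undefined for a graph with no edges")
    if a.shape[0] <= _EXACT_PARTITION_MAX:
        b = a - np.outer(k, k) / two_m
        membership = _exact_partition(b)
        return modularity_q(a, membership), membership
    queue = [np.arange(a.shape[0])]
    final: list[np.ndarray] = []
    while queue:
        nodes = queue.pop(0)
        split = _bisect(a, k, two_m, nodes)
        if split is None:
            final.append(nodes)
        else:
            queue.extend(split)
    membership = np.empty(a.shape[0], dtype=np.int64)
    for c, nodes in enumerate(final):
        membership[nodes] = c
    membership = _local_moves(a, k, two_m, membership)
    return modularity_q(a, membership), membership
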
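"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written from first principles (enumeration,
closed forms) and must stay independent of the package implementation it
checks. Only `AnatomicalNetwork` accessors are used to read graphs.
"""

from __future__ import annotations

from itertools import chain, combinations

import numpy as np


def quality_by_hand(net, members, gamma=1.0):
    """Cohesion score computed directly from the definition."""
    mset = set(members)
    adj = net.adjacency()
    deg = {n: len(adj[n]) for n in net.nodes}
    m = net.n_edges
    l_in = sum(1 for a, b in net.edges if a in mset and b in mset)
    if m == 0:
        return float(l_in)
    pair_sum = sum(
        deg[a] * deg[b] for a, b in combinations(sorted(mset), 2)
    )
    return l_in - gamma * pair_sum / (2 * m)


def component_by_hand(net, focal):
    adj = net.adjacency()
    seen = {focal}
    stack = [focal]
    while stack:
        u = stack.pop()
        for v in adj[u]:
            if v not in seen:
                seen.add(v)
                stack.append(v)
    return sorted(seen)


def best_local_module_by_enumeration(net, focal, gamma=1.0):
    """All maximizers of the cohesion score over subsets of the focal
    node's component that contain the focal node (component size <= 20)."""
    comp = component_by_hand(net, focal)
    others = [n for n in comp if n != focal]
    assert len(others) <= 20, "enumeration oracle is for small components"
    best_score = -np.inf
    best_sets = []
    for r in range(len(others) + 1):
        for extra in combinations(others, r):
            members = frozenset({focal, *extra})
            score = quality_by_hand(net, members, gamma)
            if score > best_score + 1e-9:
                best_score = score
                best_sets = [members]
            elif abs(score - best_score) <= 1e-9:
                best_sets.append(members)
    return best_sets, best_score


def wilcoxon_greater_by_enumeration(diffs):
    """Exact one-sided p for tie-free, zero-free paired differences by
    enumerating all 2^n sign assignments of the absolute values."""
    d = [x for x in diffs if x != 0]
    n = len(d)
    assert n <= 12
    absd = sorted(abs(x) for x in d)
    assert len(set(absd)) == n, "oracle requires tie-free magnitudes"
    ranks = {v: i + 1 for i, v in enumerate(absd)}
    w_obs = sum(ranks[abs(x)] for x in d if x > 0)
    count = 0
    for signs in range(2**n):
        w = sum(ranks[absd[i]] for i in range(n) if (signs >> i) & 1)
        if w >= w_obs - 1e-9:
            count += 1
    return w_obs, count / 2**n


def intersection_sizes_by_enumeration(universe_size, sizes):
    """Exact null pmf of the k-fold intersection size by enumerating every
    combination of fixed-size subsets of the universe."""
    universe = tuple(range(universe_size))
    counts = {}
    total = 0

    def rec(i, current):
        nonlocal total
        if i == len(sizes):
            counts[len(current)] = counts.get(len(current), 0) + 1
            total += 1
            return
        for subset in combinations(universe, sizes[i]):
            rec(i + 1, current & set(subset))

    rec(0, set(universe))
    return np.array(
        [counts.get(s, 0) / total for s in range(min(sizes) + 1)]
    )


def intersection_sizes_by_simulation(universe_size, sizes, n_draws, rng):
    """Monte-Carlo null distribution of the k-fold intersection size."""
    inter = np.ones((n_draws, universe_size), dtype=bool)
    for m in sizes:
        u = rng.random((n_draws, universe_size))
        kth = np.partition(u, m - 1, axis=1)[:, m - 1 : m]
        inter &= u <= kth
    hits = inter.sum(axis=1)
    return np.bincount(hits, minlength=min(sizes) + 1)[: min(sizes) + 1] / n_draws


def powerset_at_least_two(items):
    items = list(items)
    return chain.from_iterable(
        combinations(items, r) for r in range(2, len(items) + 1)
    )
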
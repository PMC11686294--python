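"""Shared helpers and independent oracles for the test suite."""

import numpy as np

from tfbscape import GenotypeSpace, build_network, make_hoc_landscape


def small_space(L: int) -> GenotypeSpace:
    return GenotypeSpace(length=L, context=None, wildtype=None)


def random_landscape(L: int, seed: int, frac: float = 1.0):
    """A (possibly subsampled) HoC landscape as a Landscape object."""
    sp = small_space(L)
    truth = make_hoc_landscape(sp, seed=seed)
    scores = truth.scores
    if frac < 1.0:
        keep = np.random.default_rng(seed + 1).random(len(scores)) < frac
        scores = scores[keep]
    return build_network(scores, sp)


def brute_force_peaks(landscape) -> set[str]:
    """Independent all-neighbor scan: peak iff no observed neighbor is
    strictly higher.  Used as an oracle against the graph-based method."""
    peaks = set()
    for g in landscape.genotypes:
        s = landscape.scores[landscape.index[g]]
        if all(
            landscape.scores[landscape.index[n]] <= s
            for n in landscape.space.neighbors(g)
            if n in landscape.index
        ):
            peaks.add(g)
    return peaks


def brute_force_accessible_paths(landscape, src: str, dst: str):
    """Explicitly enumerate every minimum-length undirected path src->dst
    and count the strictly score-increasing ones.  Exponential; tiny
    landscapes only."""
    idx = landscape.index
    target = idx[dst]
    # undirected BFS distance from every node to dst
    from collections import deque

    dist = {target: 0}
    q = deque([target])
    while q:
        v = q.popleft()
        for u in landscape.neighbors(v):
            if u not in dist:
                dist[u] = dist[v] + 1
                q.append(u)
    start = idx[src]
    total = dist[start]
    n_tot = 0
    n_acc = 0
    stack = [(start, [start])]
    while stack:
        v, path = stack.pop()
        if v == target:
            n_tot += 1
            scores = landscape.scores[path]
            if np.all(np.diff(scores) > 0):
                n_acc += 1
            continue
        for u in landscape.neighbors(v):
            if dist.get(u, -1) == dist[v] - 1 and len(path) - 1 + 1 + dist[u] == total:
                stack.append((u, path + [u]))
    return n_tot, n_acc
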
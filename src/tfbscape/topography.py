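"""Landscape topography: basins, paths, epistasis squares, distances, PCA.

All functions operate on a :class:`~tfbscape.landscape.Landscape`.  The
accessibility relation is the landscape's directed step relation: without a
noise model a step must strictly increase the score; with one, steps to
distinguishably higher or indistinguishable neighbors are permitted.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .exceptions import DataError
from .landscape import Landscape, find_peaks
from .space import DNA_ALPHABET

__all__ = [
    "Basin",
    "basin_of_attraction",
    "all_basins",
    "basin_overlap",
    "shortest_accessible_path_length",
    "enumerate_shortest_paths",
    "pairwise_distance_distribution",
    "EpistasisSquare",
    "orient_square",
    "classify_epistasis",
    "enumerate_squares",
    "epistasis_summary",
    "onehot_pca",
]


# ---------------------------------------------------------------------------
# basins of attraction
# ---------------------------------------------------------------------------


@dataclass
class Basin:
    """Non-peak genotypes with at least one accessible path to a peak."""

    peak: str
    members: frozenset
    n_nonpeak: int  # denominator: non-peak genotypes in the landscape

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def fraction(self) -> float:
        return self.size / self.n_nonpeak if self.n_nonpeak else float("nan")


def _require_peaks(landscape: Landscape) -> None:
    if landscape.is_peak_ is None:
        find_peaks(landscape)


def basin_of_attraction(landscape: Landscape, peak: str) -> Basin:
    """Members computed by reverse reachability from the peak over
    permitted steps; all peak-labeled nodes are excluded from the count."""
    _require_peaks(landscape)
    try:
        p = landscape.index[peak]
    except KeyError:
        raise DataError(f"genotype {peak!r} not in landscape") from None
    if not landscape.is_peak_[p]:
        raise DataError(f"genotype {peak!r} is not a peak")
    visited = np.zeros(len(landscape), dtype=bool)
    visited[p] = True
    frontier = deque([p])
    while frontier:
        v = frontier.popleft()
        for u in landscape.allowed_in(v):
            if not visited[u]:
                visited[u] = True
                frontier.append(u)
    member_mask = visited & ~landscape.is_peak_
    n_nonpeak = int((~landscape.is_peak_).sum())
    return Basin(
        peak=peak,
        members=frozenset(landscape.genotypes[member_mask]),
        n_nonpeak=n_nonpeak,
    )


def all_basins(landscape: Landscape, peaks=None) -> list[Basin]:
    _require_peaks(landscape)
    if peaks is None:
        peaks = landscape.genotypes[landscape.is_peak_]
    return [basin_of_attraction(landscape, p) for p in peaks]


def basin_overlap(b1: Basin, b2: Basin) -> float:
    """Jaccard index |B1 n B2| / |B1 u B2| of two basins' member sets."""
    union = b1.members | b2.members
    if not union:
        raise DataError("Jaccard overlap undefined: both basins are empty")
    return len(b1.members & b2.members) / len(union)


# ---------------------------------------------------------------------------
# paths
# ---------------------------------------------------------------------------


def _bfs_directed(landscape: Landscape, start: int) -> np.ndarray:
    """Distances over permitted directed steps; -1 where unreachable."""
    dist = np.full(len(landscape), -1, dtype=np.int64)
    dist[start] = 0
    frontier = deque([start])
    while frontier:
        v = frontier.popleft()
        for u in landscape.allowed_out(v):
            if dist[u] < 0:
                dist[u] = dist[v] + 1
                frontier.append(u)
    return dist


def _bfs_undirected(landscape: Landscape, start: int) -> np.ndarray:
    dist = np.full(len(landscape), -1, dtype=np.int64)
    dist[start] = 0
    frontier = deque([start])
    while frontier:
        v = frontier.popleft()
        for u in landscape.neighbors(v):
            if dist[u] < 0:
                dist[u] = dist[v] + 1
                frontier.append(u)
    return dist


def shortest_accessible_path_length(
    landscape: Landscape, src: str, peak: str
) -> int | None:
    """Length of the shortest monotonically uphill path src -> peak, in
    mutational steps, or None if the peak is not accessible from src."""
    if src == peak:
        raise DataError("src and peak must differ")
    for g in (src, peak):
        if g not in landscape.index:
            raise DataError(f"genotype {g!r} not in landscape")
    dist = _bfs_directed(landscape, landscape.index[src])
    d = dist[landscape.index[peak]]
    return None if d < 0 else int(d)


def enumerate_shortest_paths(
    landscape: Landscape, src: str, dst: str
) -> tuple[int, int]:
    """Count all minimum-length undirected paths src -> dst and how many of
    them are accessible (score increasing at every step toward dst).

    Counting runs by dynamic programming over the shortest-path DAG, which
    is exact because accessibility is a per-step property.  On a complete
    landscape the total count for endpoints at Hamming distance d is d!.
    """
    if src == dst:
        raise DataError("src and dst must differ")
    for g in (src, dst):
        if g not in landscape.index:
            raise DataError(f"genotype {g!r} not in landscape")
    s, t = landscape.index[src], landscape.index[dst]
    d_src = _bfs_undirected(landscape, s)
    if d_src[t] < 0:
        raise DataError(f"{src!r} and {dst!r} are in different components")
    d_dst = _bfs_undirected(landscape, t)
    total_len = d_src[t]

    on_path = (d_src >= 0) & (d_dst >= 0) & (d_src + d_dst == total_len)
    order = np.flatnonzero(on_path)
    order = order[np.argsort(d_src[order], kind="stable")]
    n_total = np.zeros(len(landscape), dtype=object)
    n_acc = np.zeros(len(landscape), dtype=object)
    n_total[s] = 1
    n_acc[s] = 1
    landscape._require_edges()
    for v in order:
        if v == s:
            continue
        sl = slice(landscape.indptr[v], landscape.indptr[v + 1])
        nbrs = landscape.indices[sl]
        into = landscape.edge_allowed_in[sl]  # permitted step nbr -> v
        for u, step_ok in zip(nbrs, into):
            if on_path[u] and d_src[u] + 1 == d_src[v]:
                n_total[v] += n_total[u]
                if step_ok:
                    n_acc[v] += n_acc[u]
    return int(n_total[t]), int(n_acc[t])


def pairwise_distance_distribution(genotypes, space=None):
    """Hamming distances over all unordered pairs.

    Returns ``(hist, mean)`` with ``hist`` a Series indexed by distance.
    On the complete space over a 4-letter alphabet the mean is 3L/4.
    """
    genotypes = list(genotypes)
    if len(genotypes) < 2:
        raise DataError("need at least 2 genotypes")
    L = len(genotypes[0])
    codes = np.array([[ord(c) for c in g] for g in genotypes], dtype=np.int32)
    counts = np.zeros(L + 1, dtype=np.int64)
    chunk = 512
    for i0 in range(0, len(genotypes), chunk):
        block = codes[i0 : i0 + chunk]
        # distances of block rows against every later genotype (incl. block)
        d = (block[:, None, :] != codes[None, i0:, :]).sum(axis=2)
        rows, cols = np.triu_indices(d.shape[0], k=1, m=d.shape[1])
        counts += np.bincount(d[rows, cols], minlength=L + 1)
    hist = pd.Series(counts, index=pd.RangeIndex(L + 1, name="distance"))
    hist = hist[hist > 0]
    mean = float((hist.index.to_numpy() * hist.to_numpy()).sum() / hist.sum())
    return hist, mean


# ---------------------------------------------------------------------------
# epistasis squares
# ---------------------------------------------------------------------------


@dataclass
class EpistasisSquare:
    """A mutational square oriented with the top-scoring corner as the
    double mutant: background g, single mutants g_a / g_b, double g_ab."""

    background: str
    single_a: str
    single_b: str
    double: str
    positions: tuple[int, int]
    scores: tuple[float, float, float, float] = field(repr=False)
    epistasis_class: str = ""


def orient_square(corners, scores) -> tuple[list[str], list[float]]:
    """Reorder four Hamming-square corners as (g, gA, gB, gAB) with the
    highest-scoring corner as the double mutant gAB."""
    corners = list(corners)
    scores = [float(x) for x in scores]
    if len(corners) != 4:
        raise DataError("a square has exactly four corners")
    top = int(np.argmax(scores))
    gab = corners[top]
    opposite = [c for c in corners if sum(x != y for x, y in zip(c, gab)) == 2]
    singles = [c for c in corners if sum(x != y for x, y in zip(c, gab)) == 1]
    if len(opposite) != 1 or len(singles) != 2:
        raise DataError("corners do not form a Hamming square")
    order = [opposite[0], singles[0], singles[1], gab]
    return order, [scores[corners.index(c)] for c in order]


def classify_epistasis(s_g, s_ga, s_gb, s_gab) -> str:
    """Classify an oriented square into no_sign / simple_sign /
    reciprocal_sign.

    Precondition: s_gab is the maximal corner score (reorient first with
    :func:`orient_square`).  Reciprocal sign: both single mutations lower
    the score below the background while the double lies above it.  Simple
    sign: exactly one single mutant lies strictly below both background and
    double, while the other is intermediate.  Everything else — additivity
    and magnitude epistasis — pools into no_sign.  Boundary ties resolve
    to no_sign.
    """
    if s_gab < max(s_g, s_ga, s_gb):
        raise DataError("square not oriented: the double mutant must score highest")
    if s_ga < s_g and s_gb < s_g and s_gab > s_g:
        return "reciprocal_sign"
    a_low = s_ga < s_g and s_ga < s_gab and s_g <= s_gb <= s_gab
    b_low = s_gb < s_g and s_gb < s_gab and s_g <= s_ga <= s_gab
    if a_low or b_low:
        return "simple_sign"
    return "no_sign"


def enumerate_squares(landscape: Landscape):
    """Yield every mutational square with all four corners observed.

    A square is the quadruple {g, gA, gB, gAB} differing at two fixed
    positions.  Each square is enumerated once (from the corner carrying
    the alphabetically smallest allele at both varying positions) and is
    yielded oriented and classified.  Squares with unobserved corners are
    skipped; ``enumerate_squares.n_skipped`` is not tracked per-call — use
    :func:`epistasis_summary` for counts.
    """
    present = landscape.index
    scores = landscape.scores
    alphabet = sorted(landscape.space.alphabet)
    L = landscape.space.length
    for g in landscape.genotypes:
        for i in range(L):
            for a in alphabet:
                if a <= g[i]:
                    continue
                gi = g[:i] + a + g[i + 1 :]
                if gi not in present:
                    continue
                for j in range(i + 1, L):
                    for b in alphabet:
                        if b <= g[j]:
                            continue
                        gj = g[:j] + b + g[j + 1 :]
                        if gj not in present:
                            continue
                        gij = gi[:j] + b + gi[j + 1 :]
                        if gij not in present:
                            continue
                        corners = [g, gi, gj, gij]
                        vals = [scores[present[c]] for c in corners]
                        (bg, sa, sb, db), (v0, v1, v2, v3) = orient_square(
                            corners, vals
                        )
                        yield EpistasisSquare(
                            background=bg,
                            single_a=sa,
                            single_b=sb,
                            double=db,
                            positions=(i, j),
                            scores=(v0, v1, v2, v3),
                            epistasis_class=classify_epistasis(v0, v1, v2, v3),
                        )


def epistasis_summary(landscape: Landscape) -> dict:
    """Class counts and proportions over all complete squares."""
    counts = {"no_sign": 0, "simple_sign": 0, "reciprocal_sign": 0}
    for sq in enumerate_squares(landscape):
        counts[sq.epistasis_class] += 1
    n = sum(counts.values())
    props = {k: (v / n if n else float("nan")) for k, v in counts.items()}
    return {"n_squares": n, "counts": counts, "proportions": props}


# ---------------------------------------------------------------------------
# one-hot PCA
# ---------------------------------------------------------------------------


def onehot_pca(genotypes, n_components: int | None = None, alphabet: str = DNA_ALPHABET):
    """PCA of genotypes one-hot encoded as 4L binary vectors.

    Returns ``(coords, explained_variance_ratio)`` where coords is a
    DataFrame (index genotype, columns PC1..PCk).  In a combinatorially
    diverse library no single component explains much variance.
    """
    genotypes = list(genotypes)
    if len(genotypes) < 2:
        raise DataError("PCA requires at least 2 genotypes")
    L = len(genotypes[0])
    if any(len(g) != L for g in genotypes):
        raise DataError("genotypes must have uniform length")
    idx = {c: i for i, c in enumerate(alphabet)}
    X = np.zeros((len(genotypes), L * len(alphabet)))
    for row, g in enumerate(genotypes):
        for pos, c in enumerate(g):
            X[row, pos * len(alphabet) + idx[c]] = 1.0
    if np.allclose(X.var(axis=0), 0):
        raise DataError("zero variance: all genotypes identical")
    k = n_components or min(len(genotypes) - 1, X.shape[1])
    pca = PCA(n_components=k)
    coords = pca.fit_transform(X)
    df = pd.DataFrame(
        coords,
        index=pd.Index(genotypes, name="genotype"),
        columns=[f"PC{i + 1}" for i in range(coords.shape[1])],
    )
    return df, pca.explained_variance_ratio_
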
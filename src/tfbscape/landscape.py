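"""Score-annotated genotype networks: peaks, plateaus, noise, shuffled nulls.

The landscape is the Hamming graph restricted to observed genotypes, each
node carrying a repression score S.  Every undirected edge joins genotypes
differing at exactly one variable position; the canonical directed ("uphill")
orientation points from the lower-scoring endpoint to the higher-scoring one.
A peak is a node with no strictly higher neighbor; adjacent equal-score peaks
form a plateau.

With a measurement-noise model, each node also carries tau, the standard
deviation of its normalized score across replicates.  Genotype A counts as
distinguishably higher than neighbor B iff

    S_A > S_B + tau_B   and   S_A - tau_A > S_B + tau_B

(with tau optionally inflated by a common scale factor).  A distinguishable
pair gets a single uphill edge; an indistinguishable pair gets directed
edges in both directions, and a node is a peak iff it has no distinguishably
higher neighbor.  Connected indistinguishable peaks form (broader) plateaus.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .exceptions import ConfigurationError, DataError
from .space import GenotypeSpace

__all__ = [
    "Landscape",
    "build_network",
    "giant_component",
    "find_peaks",
    "apply_noise_model",
    "shuffle_null",
    "ShuffleNullResult",
]


def _peak_mask(scores, indptr, indices, src, eps: float = 0.0) -> np.ndarray:
    """Local-maximum mask by direct all-neighbor scan (no directed edges)."""
    n = len(scores)
    if len(indices) == 0:
        return np.ones(n, dtype=bool)
    higher = scores[indices] > scores[src] + eps
    deg = np.diff(indptr)
    starts = np.minimum(indptr[:-1], len(indices) - 1)
    cnt = np.add.reduceat(higher.astype(np.int64), starts)
    cnt[deg == 0] = 0
    return cnt == 0


class Landscape:
    """An observed genotype network with scores and optional noise values.

    Not constructed directly in normal use — see :func:`build_network`.
    Node order is fixed at construction; all per-node attributes are numpy
    arrays in that order.  Fitted-style attributes (``is_peak_``,
    ``plateau_id_``) are computed lazily by :func:`find_peaks`.
    """

    def __init__(
        self,
        genotypes,
        scores,
        space: GenotypeSpace,
        tau=None,
        noise_scale: float | None = None,
        epsilon: float = 0.0,
        provenance: dict | None = None,
    ):
        self.genotypes = np.asarray(list(genotypes), dtype=object)
        self.scores = np.asarray(scores, dtype=float)
        if len(self.genotypes) != len(self.scores):
            raise DataError("genotypes and scores must have equal length")
        if len(self.genotypes) == 0:
            raise DataError("empty landscape")
        self.space = space
        self.tau = None if tau is None else np.asarray(tau, dtype=float)
        if self.tau is not None and len(self.tau) != len(self.genotypes):
            raise DataError("tau must align with genotypes")
        if noise_scale is not None:
            if noise_scale < 0:
                raise ConfigurationError("noise scale must be >= 0")
            if self.tau is None:
                raise DataError("a noise model requires tau for every node")
            if np.any(self.tau < 0) or np.any(~np.isfinite(self.tau)):
                raise DataError("tau values must be finite and >= 0")
        self.noise_scale = noise_scale
        self.epsilon = float(epsilon)
        self.provenance = dict(provenance or {})
        self.index = {g: i for i, g in enumerate(self.genotypes)}
        if len(self.index) != len(self.genotypes):
            raise DataError("duplicate genotypes in landscape")
        for g in self.genotypes:
            space.validate(g)
        self._build_adjacency()
        self._edges_computed = False
        self.is_peak_: np.ndarray | None = None
        self.plateau_id_: np.ndarray | None = None

    # -- construction ----------------------------------------------------

    def _build_adjacency(self) -> None:
        # vectorized path: encode genotypes as base-a integers and find
        # neighbors arithmetically (needs a lookup table over the full
        # space, fine up to 4^12)
        if self.space.size <= 4**12:
            self._build_adjacency_vectorized()
            return
        index = self.index
        indptr = np.zeros(len(self.genotypes) + 1, dtype=np.int64)
        cols: list[int] = []
        for i, g in enumerate(self.genotypes):
            row = [index[nbr] for nbr in self.space.neighbors(g) if nbr in index]
            row.sort()
            cols.extend(row)
            indptr[i + 1] = len(cols)
        self.indptr = indptr
        self.indices = np.asarray(cols, dtype=np.int64)
        self.src = np.repeat(
            np.arange(len(self.genotypes), dtype=np.int64), np.diff(indptr)
        )

    def _build_adjacency_vectorized(self) -> None:
        space = self.space
        n, L, a = len(self.genotypes), space.length, space.n_alleles
        codes = space.encode(self.genotypes).astype(np.int64)
        powers = a ** np.arange(L - 1, -1, -1, dtype=np.int64)
        ints = codes @ powers
        lookup = np.full(space.size, -1, dtype=np.int64)
        lookup[ints] = np.arange(n)
        srcs, dsts = [], []
        for p in range(L):
            for allele in range(a):
                delta = (allele - codes[:, p]) * powers[p]
                cand = lookup[ints + delta]
                sel = (codes[:, p] != allele) & (cand >= 0)
                srcs.append(np.flatnonzero(sel))
                dsts.append(cand[sel])
        src = np.concatenate(srcs)
        dst = np.concatenate(dsts)
        order = np.lexsort((dst, src))
        src, dst = src[order], dst[order]
        self.indices = dst
        self.indptr = np.concatenate(
            ([0], np.cumsum(np.bincount(src, minlength=n)))
        ).astype(np.int64)
        self.src = src

    def _compute_edges(self) -> None:
        """Classify every adjacency entry (i -> j) once.

        edge_strict_up: j is strictly/distinguishably higher than i
        edge_allowed:   the directed edge i -> j exists (uphill or, under a
                        noise model, an indistinguishable bidirectional link)
        edge_allowed_in: the directed edge j -> i exists
        edge_tie:       i and j are indistinguishable (plateau link)
        """
        s, i, j = self.scores, self.src, self.indices
        if self.noise_scale is None:
            eps = self.epsilon
            up = s[j] > s[i] + eps
            down = s[i] > s[j] + eps
            tie = ~up & ~down
            self.edge_strict_up = up
            self.edge_strict_down = down
            self.edge_allowed = up
            self.edge_allowed_in = down
            self.edge_tie = tie
        else:
            t = self.tau * self.noise_scale
            j_higher = (s[j] > s[i] + t[i]) & (s[j] - t[j] > s[i] + t[i])
            i_higher = (s[i] > s[j] + t[j]) & (s[i] - t[i] > s[j] + t[j])
            # exact ties between two zero-noise nodes stay undirected
            # (plateau link), matching the noise-free convention.
            zero_tie = (s[i] == s[j]) & (t[i] == 0) & (t[j] == 0)
            self.edge_strict_up = j_higher
            self.edge_strict_down = i_higher
            self.edge_allowed = ~i_higher & ~zero_tie
            self.edge_allowed_in = ~j_higher & ~zero_tie
            self.edge_tie = ~i_higher & ~j_higher
        self._edges_computed = True

    def _require_edges(self) -> None:
        if not self._edges_computed:
            self._compute_edges()

    # -- queries ---------------------------------------------------------

    def __len__(self) -> int:
        return len(self.genotypes)

    @property
    def n_edges(self) -> int:
        """Number of undirected edges."""
        return len(self.indices) // 2

    def neighbors(self, i: int) -> np.ndarray:
        return self.indices[self.indptr[i] : self.indptr[i + 1]]

    def _row_mask(self, i: int, mask: np.ndarray) -> np.ndarray:
        sl = slice(self.indptr[i], self.indptr[i + 1])
        return self.indices[sl][mask[sl]]

    def uphill_out(self, i: int) -> np.ndarray:
        """Strictly (distinguishably) higher neighbors of node i."""
        self._require_edges()
        return self._row_mask(i, self.edge_strict_up)

    def allowed_out(self, i: int) -> np.ndarray:
        """Neighbors reachable by a permitted (non-decreasing) step from i."""
        self._require_edges()
        return self._row_mask(i, self.edge_allowed)

    def allowed_in(self, i: int) -> np.ndarray:
        """Neighbors from which a permitted step leads into node i."""
        self._require_edges()
        return self._row_mask(i, self.edge_allowed_in)

    def relative_connectivity(self) -> np.ndarray:
        """Observed fraction of each genotype's (a-1)*L possible neighbors."""
        return np.diff(self.indptr) / self.space.max_degree

    def node_table(self) -> pd.DataFrame:
        """Per-node summary (genotype, S, tau, peak/plateau labels)."""
        if self.is_peak_ is None:
            find_peaks(self)
        df = pd.DataFrame(
            {
                "genotype": self.genotypes,
                "S": self.scores,
                "tau": self.tau if self.tau is not None else np.nan,
                "is_peak": self.is_peak_,
                "plateau_id": self.plateau_id_,
                "rel_connectivity": self.relative_connectivity(),
            }
        )
        return df

    def edge_table(self) -> pd.DataFrame:
        """Directed/undirected edge list (one row per ordered adjacent pair)."""
        self._require_edges()
        direction = np.where(
            self.edge_strict_up, "uphill", np.where(self.edge_tie, "tie", "downhill")
        )
        return pd.DataFrame(
            {
                "src": self.genotypes[self.src],
                "dst": self.genotypes[self.indices],
                "direction": direction,
            }
        )

    def to_networkx(self):
        """Export as a networkx DiGraph of permitted (uphill/tie) edges."""
        import networkx as nx

        self._require_edges()
        g = nx.DiGraph()
        for i, name in enumerate(self.genotypes):
            g.add_node(
                name,
                S=float(self.scores[i]),
                tau=float(self.tau[i]) if self.tau is not None else 0.0,
            )
        sel = self.edge_allowed
        for a, b in zip(self.genotypes[self.src[sel]], self.genotypes[self.indices[sel]]):
            g.add_edge(a, b)
        return g

    def subset(self, node_idx: np.ndarray) -> "Landscape":
        """A new landscape restricted to the given node indices."""
        node_idx = np.asarray(node_idx)
        return Landscape(
            self.genotypes[node_idx],
            self.scores[node_idx],
            self.space,
            tau=None if self.tau is None else self.tau[node_idx],
            noise_scale=self.noise_scale,
            epsilon=self.epsilon,
            provenance=self.provenance,
        )


def build_network(
    scores,
    space: GenotypeSpace,
    tau=None,
    epsilon: float = 0.0,
    provenance: dict | None = None,
) -> Landscape:
    """Build the genotype network from a score table.

    ``scores`` is a pandas Series (genotype -> S) or a score DataFrame with
    an ``S`` column (and optionally ``tau``) indexed by genotype, as produced
    by the scoring module.  Adjacency is exactly the Hamming-distance-1
    relation restricted to the given genotypes.
    """
    if isinstance(scores, pd.DataFrame):
        if "S" not in scores.columns:
            raise DataError("score table must have an 'S' column")
        if tau is None and "tau" in scores.columns:
            tau = scores["tau"].to_numpy()
        genotypes = scores.index
        values = scores["S"].to_numpy()
    else:
        ser = pd.Series(scores)
        genotypes = ser.index
        values = ser.to_numpy(dtype=float)
    if pd.Index(genotypes).duplicated().any():
        raise DataError("duplicate genotypes in score input")
    return Landscape(
        genotypes, values, space, tau=tau, epsilon=epsilon, provenance=provenance
    )


def _undirected_csr(landscape: Landscape) -> csr_matrix:
    n = len(landscape)
    return csr_matrix(
        (np.ones(len(landscape.indices), dtype=np.int8), landscape.indices, landscape.indptr),
        shape=(n, n),
    )


def giant_component(landscape: Landscape) -> Landscape:
    """Largest connected component; ties broken by the component containing
    the lexicographically smallest genotype among the tied components."""
    n_comp, labels = connected_components(_undirected_csr(landscape), directed=False)
    if n_comp == 1:
        return landscape
    sizes = np.bincount(labels, minlength=n_comp)
    best = sizes.max()
    tied = np.flatnonzero(sizes == best)
    if len(tied) == 1:
        winner = tied[0]
    else:
        winner = min(
            tied, key=lambda c: min(landscape.genotypes[labels == c])
        )
    keep = np.flatnonzero(labels == winner)
    out = landscape.subset(keep)
    out.provenance["giant_component_of"] = len(landscape)
    return out


def find_peaks(landscape: Landscape):
    """Identify local maxima and group adjacent indistinguishable ones.

    Returns ``(peaks, plateau_id)``: the peak genotypes (array) and a
    per-node plateau label (-1 for non-peaks).  Results are cached on the
    landscape as ``is_peak_`` and ``plateau_id_``.  A node is a peak iff it
    has no strictly (noise model: distinguishably) higher neighbor; plateaus
    are connected components of peaks joined by tie edges.
    """
    landscape._require_edges()
    n = len(landscape)
    if len(landscape.indices) == 0:
        is_peak = np.ones(n, dtype=bool)
        is_strict = np.ones(n, dtype=bool)
    else:
        deg = np.diff(landscape.indptr)
        starts = np.minimum(landscape.indptr[:-1], len(landscape.indices) - 1)
        cnt = np.add.reduceat(landscape.edge_strict_up.astype(np.int64), starts)
        cnt[deg == 0] = 0
        is_peak = cnt == 0
        # strict peaks: every neighbor distinguishably lower; the count of
        # these can only shrink as noise grows (the smoothing-sensitive
        # quantity), whereas the local-maximum set above can only grow
        not_down = np.add.reduceat(
            (~landscape.edge_strict_down).astype(np.int64), starts
        )
        not_down[deg == 0] = 0
        is_strict = not_down == 0

    # plateau components: peak-peak tie edges
    sel = landscape.edge_tie & is_peak[landscape.src] & is_peak[landscape.indices]
    peak_idx = np.flatnonzero(is_peak)
    remap = -np.ones(n, dtype=np.int64)
    remap[peak_idx] = np.arange(len(peak_idx))
    rows = remap[landscape.src[sel]]
    cols = remap[landscape.indices[sel]]
    sub = csr_matrix(
        (np.ones(len(rows), dtype=np.int8), (rows, cols)),
        shape=(len(peak_idx), len(peak_idx)),
    )
    n_plat, plat_labels = connected_components(sub, directed=False)
    plateau_id = -np.ones(n, dtype=np.int64)
    plateau_id[peak_idx] = plat_labels

    landscape.is_peak_ = is_peak
    landscape.is_strict_peak_ = is_strict
    landscape.plateau_id_ = plateau_id
    landscape.n_peaks_ = int(is_peak.sum())
    landscape.n_strict_peaks_ = int(is_strict.sum())
    landscape.n_plateaus_ = int(n_plat)
    landscape.mean_peak_breadth_ = (
        float(is_peak.sum() / n_plat) if n_plat else float("nan")
    )
    return landscape.genotypes[peak_idx], plateau_id


def apply_noise_model(
    landscape: Landscape, tau=None, scale: float = 1.0
) -> Landscape:
    """Re-orient edges under the measurement-noise model and recompute peaks.

    ``tau`` defaults to the landscape's stored per-node noise; ``scale``
    inflates it uniformly (1.0 = observed noise, 0.0 reproduces the
    noise-free landscape exactly).
    """
    t = landscape.tau if tau is None else np.asarray(tau, dtype=float)
    if t is None:
        raise DataError("a noise model requires tau for every node")
    out = Landscape(
        landscape.genotypes,
        landscape.scores,
        landscape.space,
        tau=t,
        noise_scale=scale,
        epsilon=landscape.epsilon,
        provenance={**landscape.provenance, "noise_scale": scale},
    )
    find_peaks(out)
    return out


@dataclass
class ShuffleNullResult:
    """Peak-count distribution over randomly score-shuffled landscapes."""

    peak_counts: np.ndarray
    mean: float
    sd: float
    upper95: float  # value below which 95% of shuffled peak counts fall
    n_shuffles: int
    score_samples: list | None = None  # permuted score vectors, if kept


def shuffle_null(
    landscape: Landscape,
    n_shuffles: int = 1000,
    seed: int | None = None,
    keep_samples: bool = False,
) -> ShuffleNullResult:
    """Null peak-count distribution from uniformly permuted scores.

    Each shuffle permutes the score multiset over the fixed node set and
    recounts local maxima with the noise-free definition, as for the
    original landscape.
    """
    if n_shuffles < 1:
        raise ConfigurationError("n_shuffles must be >= 1")
    rng = np.random.default_rng(seed)
    counts = np.empty(n_shuffles, dtype=np.int64)
    samples: list | None = [] if keep_samples else None
    for k in range(n_shuffles):
        perm = rng.permutation(landscape.scores)
        counts[k] = _peak_mask(
            perm, landscape.indptr, landscape.indices, landscape.src, landscape.epsilon
        ).sum()
        if samples is not None:
            samples.append(perm)
    return ShuffleNullResult(
        peak_counts=counts,
        mean=float(counts.mean()),
        sd=float(counts.std(ddof=1)) if n_shuffles > 1 else 0.0,
        upper95=float(np.percentile(counts, 95)),
        n_shuffles=n_shuffles,
        score_samples=samples,
    )
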
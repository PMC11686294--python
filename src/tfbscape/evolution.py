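"""Adaptive walks on a landscape: greedy, uniform (SSWM), and Kimura.

Greedy walks model clonal interference — the best available beneficial
mutation always fixes — and are deterministic up to tie-breaking.  Uniform
walks model the strong-selection weak-mutation regime: every beneficial
single mutation is equally likely to fix, the walk ends at a local peak.
Kimura walks allow drift: a proposed mutation j on background i fixes with
probability

    f_ij = (1 - exp(-2 s)) / (1 - exp(-2 N s)),

where s = S_j - S_i and N is the effective population size; neutral and
deleterious fixations are possible, so walks run for a fixed number of
proposal steps (1000 by default) and may visit several peaks.  Proposals
can be weighted by a 4x4 mutation-bias matrix of relative rates.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, DataError
from .landscape import Landscape, apply_noise_model, find_peaks

__all__ = [
    "WalkConfig",
    "WalkResult",
    "greedy_walk",
    "uniform_walk",
    "uniform_walk_endpoint_distribution",
    "kimura_fixation_probability",
    "kimura_walk",
    "run_walks",
    "walk_summary",
    "WalkSummary",
    "noise_sweep",
]


# ---------------------------------------------------------------------------
# configuration and results
# ---------------------------------------------------------------------------


@dataclass
class WalkConfig:
    """Parameters shared by the walk engines.

    ``starts`` is "all-nonpeak", ``("sample", K)`` for K random non-peak
    starts, or an explicit list of genotypes.  ``bias`` is a 4x4 matrix of
    relative mutation rates (rows = source base, columns = target base,
    diagonal ignored) in alphabet order; None means uniform.
    """

    mode: str = "uniform"  # greedy | uniform | kimura
    population_size: float = 1e8  # kimura only
    max_steps: int = 1000  # kimura only
    walks_per_start: int = 1000
    starts: object = "all-nonpeak"
    bias: np.ndarray | None = None
    tie_break: str = "lexicographic"  # greedy: lexicographic | random
    high_peak_threshold: float = 1.0

    def validate(self) -> None:
        if self.mode not in ("greedy", "uniform", "kimura"):
            raise ConfigurationError(f"unknown walk mode {self.mode!r}")
        if self.mode == "kimura":
            if self.population_size < 2:
                raise ConfigurationError("population size must be >= 2")
            if self.max_steps < 1:
                raise ConfigurationError("max_steps must be >= 1")
        if self.walks_per_start < 1:
            raise ConfigurationError("walks_per_start must be >= 1")
        if self.bias is not None:
            b = np.asarray(self.bias, dtype=float)
            if b.shape != (4, 4) or np.any(b < 0):
                raise ConfigurationError("bias must be a non-negative 4x4 matrix")
            if not np.any(b[~np.eye(4, dtype=bool)] > 0):
                raise ConfigurationError("bias needs a positive off-diagonal rate")


@dataclass
class WalkResult:
    """One adaptive walk: trajectory of fixed genotypes and bookkeeping."""

    start: str
    trajectory: list[str]
    selection_coefficients: list[float] = field(default_factory=list)
    visited_peaks: list[str] = field(default_factory=list)
    mode: str = ""

    @property
    def endpoint(self) -> str:
        return self.trajectory[-1]

    @property
    def steps(self) -> int:
        return len(self.trajectory) - 1


def _is_high_peak(landscape: Landscape, g: str, threshold: float) -> bool:
    i = landscape.index[g]
    return bool(landscape.is_peak_[i] and landscape.scores[i] > threshold)


# ---------------------------------------------------------------------------
# walk engines
# ---------------------------------------------------------------------------


def greedy_walk(
    landscape: Landscape,
    start: str,
    tie_break: str = "lexicographic",
    rng: np.random.Generator | None = None,
) -> WalkResult:
    """Step to the strictly best uphill neighbor until none exists.

    Deterministic with the default lexicographic tie-break; pass
    ``tie_break="random"`` (with an rng) to break ties at random.
    Starting on a peak yields a zero-step walk.
    """
    if start not in landscape.index:
        raise DataError(f"genotype {start!r} not in landscape")
    i = landscape.index[start]
    traj = [start]
    s_coefs: list[float] = []
    while True:
        up = landscape.uphill_out(i)
        if len(up) == 0:
            break
        gains = landscape.scores[up]
        best = np.flatnonzero(gains == gains.max())
        if len(best) == 1:
            nxt = up[best[0]]
        elif tie_break == "lexicographic":
            nxt = up[best[int(np.argmin(landscape.genotypes[up[best]]))]]
        elif tie_break == "random":
            if rng is None:
                raise ConfigurationError("random tie-break requires an rng")
            nxt = up[rng.choice(best)]
        else:
            raise ConfigurationError(f"unknown tie_break {tie_break!r}")
        s_coefs.append(float(landscape.scores[nxt] - landscape.scores[i]))
        i = int(nxt)
        traj.append(str(landscape.genotypes[i]))
    return WalkResult(start=start, trajectory=traj, selection_coefficients=s_coefs, mode="greedy")


def uniform_walk(
    landscape: Landscape, start: str, rng: np.random.Generator
) -> WalkResult:
    """Pick uniformly among strictly uphill neighbors until a peak."""
    if start not in landscape.index:
        raise DataError(f"genotype {start!r} not in landscape")
    i = landscape.index[start]
    traj = [start]
    s_coefs: list[float] = []
    while True:
        up = landscape.uphill_out(i)
        if len(up) == 0:
            break
        nxt = int(up[rng.integers(len(up))])
        s_coefs.append(float(landscape.scores[nxt] - landscape.scores[i]))
        i = nxt
        traj.append(str(landscape.genotypes[i]))
    return WalkResult(start=start, trajectory=traj, selection_coefficients=s_coefs, mode="uniform")


def uniform_walk_endpoint_distribution(
    landscape: Landscape, start: str
) -> dict[str, float]:
    """Exact endpoint distribution of the uniform walk from ``start``.

    Propagates probability mass through the acyclic uphill graph in
    increasing-score order; the support of the result is exactly the set
    of peaks reachable by monotonically uphill paths.
    """
    if start not in landscape.index:
        raise DataError(f"genotype {start!r} not in landscape")
    if landscape.is_peak_ is None:
        find_peaks(landscape)
    n = len(landscape)
    mass = np.zeros(n)
    mass[landscape.index[start]] = 1.0
    order = np.argsort(landscape.scores, kind="stable")
    out: dict[str, float] = {}
    for v in order:
        if mass[v] == 0:
            continue
        up = landscape.uphill_out(v)
        if len(up) == 0:
            out[str(landscape.genotypes[v])] = out.get(str(landscape.genotypes[v]), 0.0) + mass[v]
        else:
            mass[up] += mass[v] / len(up)
        mass[v] = 0.0
    return out


def kimura_fixation_probability(s, N):
    """Kimura's fixation probability f = (1 - e^(-2s)) / (1 - e^(-2Ns)).

    Vectorized and numerically guarded: the s -> 0 limit is 1/N, large
    positive N*s saturates the denominator at 1 (f -> 1 - e^(-2s)), and
    strongly deleterious s evaluates in log space and underflows cleanly
    to 0.  f is strictly increasing in s.
    """
    if N < 2:
        raise ConfigurationError("population size must be >= 2")
    s_arr = np.asarray(s, dtype=float)
    scalar = s_arr.ndim == 0
    s_arr = np.atleast_1d(s_arr)
    out = np.empty_like(s_arr)

    tiny = np.abs(s_arr) < 1e-12
    out[tiny] = 1.0 / N

    rest = ~tiny
    x = s_arr[rest]
    big_neg = -2.0 * N * x > 700.0  # denominator would overflow
    safe = ~big_neg
    with np.errstate(over="ignore"):
        vals = np.empty_like(x)
        vals[safe] = np.expm1(-2.0 * x[safe]) / np.expm1(-2.0 * N * x[safe])
        # log-space: f = expm1(-2s)/expm1(-2Ns) ~ exp(log(expm1(-2s)) + 2Ns)
        xb = x[big_neg]
        log_num = np.where(
            -2.0 * xb > 30.0, -2.0 * xb, np.log(np.expm1(-2.0 * np.minimum(xb, -1e-300)))
        )
        vals[big_neg] = np.exp(log_num + 2.0 * N * xb)
    out[rest] = vals
    return float(out[0]) if scalar else out


class _KimuraEngine:
    """Precomputed per-edge fixation probabilities and proposal weights."""

    def __init__(self, landscape: Landscape, N: float, bias=None):
        self.landscape = landscape
        s = landscape.scores
        self.f_edge = kimura_fixation_probability(
            s[landscape.indices] - s[landscape.src], N
        )
        if bias is None:
            self.weights = None
        else:
            b = np.asarray(bias, dtype=float)
            alpha = {c: i for i, c in enumerate(landscape.space.alphabet)}
            w = np.empty(len(landscape.indices))
            for k, (i, j) in enumerate(zip(landscape.src, landscape.indices)):
                gi, gj = landscape.genotypes[i], landscape.genotypes[j]
                pos = next(p for p in range(len(gi)) if gi[p] != gj[p])
                w[k] = b[alpha[gi[pos]], alpha[gj[pos]]]
            self.weights = w

    def step(self, i: int, rng: np.random.Generator) -> int | None:
        """Propose one mutation from node i; return the fixed neighbor
        index or None if the proposal did not fix (or i is isolated)."""
        land = self.landscape
        sl = slice(land.indptr[i], land.indptr[i + 1])
        nbrs = land.indices[sl]
        if len(nbrs) == 0:
            return None
        if self.weights is None:
            k = rng.integers(len(nbrs))
        else:
            w = self.weights[sl]
            tot = w.sum()
            if tot == 0:
                return None
            k = int(np.searchsorted(np.cumsum(w), rng.random() * tot))
        if rng.random() < self.f_edge[sl][k]:
            return int(nbrs[k])
        return None


def kimura_walk(
    landscape: Landscape,
    start: str,
    cfg: WalkConfig,
    rng: np.random.Generator,
    engine: _KimuraEngine | None = None,
) -> WalkResult:
    """Run ``cfg.max_steps`` mutation proposals from ``start``.

    Each step proposes one neighbor (bias-weighted) of the currently fixed
    genotype and fixes it with Kimura probability; steps without fixation
    still consume an iteration.  Every peak occupied along the way is
    recorded in ``visited_peaks``.
    """
    if start not in landscape.index:
        raise DataError(f"genotype {start!r} not in landscape")
    if landscape.is_peak_ is None:
        find_peaks(landscape)
    if engine is None:
        engine = _KimuraEngine(landscape, cfg.population_size, cfg.bias)
    i = landscape.index[start]
    traj = [start]
    s_coefs: list[float] = []
    visited: list[str] = []
    if landscape.is_peak_[i]:
        visited.append(start)
    for _ in range(cfg.max_steps):
        j = engine.step(i, rng)
        if j is None:
            continue
        s_coefs.append(float(landscape.scores[j] - landscape.scores[i]))
        i = j
        g = str(landscape.genotypes[i])
        traj.append(g)
        if landscape.is_peak_[i]:
            visited.append(g)
    return WalkResult(
        start=start,
        trajectory=traj,
        selection_coefficients=s_coefs,
        visited_peaks=visited,
        mode="kimura",
    )


# ---------------------------------------------------------------------------
# batch runner and summary
# ---------------------------------------------------------------------------


def _resolve_starts(landscape: Landscape, starts, rng) -> list[str]:
    if landscape.is_peak_ is None:
        find_peaks(landscape)
    nonpeak = landscape.genotypes[~landscape.is_peak_]
    if isinstance(starts, str) and starts == "all-nonpeak":
        return [str(g) for g in nonpeak]
    if isinstance(starts, tuple) and len(starts) == 2 and starts[0] == "sample":
        k = int(starts[1])
        if k > len(nonpeak):
            raise ConfigurationError(
                f"cannot sample {k} starts from {len(nonpeak)} non-peak genotypes"
            )
        return [str(g) for g in rng.choice(nonpeak, size=k, replace=False)]
    return [str(g) for g in starts]


def run_walks(
    landscape: Landscape, cfg: WalkConfig, seed: int | None = None
) -> list[WalkResult]:
    """Run the configured ensemble of walks; bit-reproducible given seed."""
    cfg.validate()
    rng = np.random.default_rng(seed)
    starts = _resolve_starts(landscape, cfg.starts, rng)
    results: list[WalkResult] = []
    if cfg.mode == "greedy":
        for g in starts:
            results.append(greedy_walk(landscape, g, cfg.tie_break, rng))
    elif cfg.mode == "uniform":
        for g in starts:
            for _ in range(cfg.walks_per_start):
                results.append(uniform_walk(landscape, g, rng))
    else:
        engine = _KimuraEngine(landscape, cfg.population_size, cfg.bias)
        for g in starts:
            for _ in range(cfg.walks_per_start):
                results.append(kimura_walk(landscape, g, cfg, rng, engine))
    return results


@dataclass
class WalkSummary:
    n_walks: int
    frac_end_on_peak: float
    frac_reaching_high_peak: float
    step_counts: np.ndarray
    per_start: pd.DataFrame  # start, n_walks, frac_high, n_distinct_high_peaks
    visitation: Counter  # genotype -> times occupied across all walks
    attainment: dict  # start -> Counter(high peak -> walks reaching it)


def walk_summary(
    results: list[WalkResult],
    landscape: Landscape,
    high_peak_threshold: float = 1.0,
) -> WalkSummary:
    """Aggregate an ensemble of walks into navigability statistics.

    A walk "reaches a high peak" if it ever occupies a peak whose score
    exceeds the threshold (for greedy/uniform walks only the endpoint can
    be a peak).
    """
    if not results:
        raise DataError("no walk results to summarize")
    if landscape.is_peak_ is None:
        find_peaks(landscape)
    for r in results:
        if r.start not in landscape.index or r.endpoint not in landscape.index:
            raise DataError("walk results do not match this landscape")

    visitation: Counter = Counter()
    attainment: dict[str, Counter] = {}
    per_start_rows: dict[str, list[int]] = {}
    n_end_peak = 0
    n_high = 0
    steps = np.empty(len(results), dtype=np.int64)
    for k, r in enumerate(results):
        steps[k] = r.steps
        visitation.update(r.trajectory)
        if landscape.is_peak_[landscape.index[r.endpoint]]:
            n_end_peak += 1
        peaks_seen = r.visited_peaks if r.visited_peaks else (
            [r.endpoint]
            if landscape.is_peak_[landscape.index[r.endpoint]]
            else []
        )
        high = {p for p in peaks_seen if _is_high_peak(landscape, p, high_peak_threshold)}
        if high:
            n_high += 1
        counter = attainment.setdefault(r.start, Counter())
        counter.update(high)
        row = per_start_rows.setdefault(r.start, [0, 0])
        row[0] += 1
        row[1] += bool(high)

    per_start = pd.DataFrame(
        [
            {
                "start": g,
                "n_walks": n,
                "frac_high": nh / n,
                "n_distinct_high_peaks": len(attainment.get(g, ())),
            }
            for g, (n, nh) in sorted(per_start_rows.items())
        ]
    )
    return WalkSummary(
        n_walks=len(results),
        frac_end_on_peak=n_end_peak / len(results),
        frac_reaching_high_peak=n_high / len(results),
        step_counts=steps,
        per_start=per_start,
        visitation=visitation,
        attainment=attainment,
    )


def noise_sweep(
    landscape: Landscape,
    scales,
    cfg: WalkConfig,
    seed: int | None = None,
) -> pd.DataFrame:
    """Rebuild the landscape at each noise scale and rerun the walks.

    The landscape must carry tau.  Starts are resolved once on the base
    (noise-free) landscape and reused, and each scale reuses the same walk
    seed, so differences across scales reflect the noise model alone.
    Returns one row per scale: peak/plateau counts, mean peak breadth, and
    the fraction of walks reaching a high peak.
    """
    if landscape.tau is None:
        raise DataError("noise_sweep requires tau on the landscape")
    scales = list(scales)
    if any(s < 0 for s in scales):
        raise ConfigurationError("noise scales must be >= 0")
    base = apply_noise_model(landscape, scale=0.0)
    rng = np.random.default_rng(seed)
    starts = _resolve_starts(base, cfg.starts, rng)
    rows = []
    for scale in scales:
        land = apply_noise_model(landscape, scale=scale)
        sub_cfg = WalkConfig(
            mode=cfg.mode,
            population_size=cfg.population_size,
            max_steps=cfg.max_steps,
            walks_per_start=cfg.walks_per_start,
            starts=[g for g in starts if not land.is_peak_[land.index[g]]],
            bias=cfg.bias,
            tie_break=cfg.tie_break,
            high_peak_threshold=cfg.high_peak_threshold,
        )
        if sub_cfg.starts:
            res = run_walks(land, sub_cfg, seed=seed)
            summ = walk_summary(res, land, cfg.high_peak_threshold)
            frac_high = summ.frac_reaching_high_peak
            n_walks = summ.n_walks
        else:
            frac_high, n_walks = float("nan"), 0
        rows.append(
            {
                "scale": scale,
                # strict peaks (all neighbors distinguishably lower): the
                # count noise smooths away, non-increasing in scale
                "n_peaks": land.n_strict_peaks_,
                # local maxima (no distinguishably higher neighbor): the
                # plateau members, non-decreasing in scale
                "n_local_maxima": land.n_peaks_,
                "n_plateaus": land.n_plateaus_,
                "mean_peak_breadth": land.mean_peak_breadth_,
                "n_walks": n_walks,
                "frac_reaching_high_peak": frac_high,
            }
        )
    return pd.DataFrame(rows)
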
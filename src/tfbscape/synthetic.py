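"""Ground-truth landscapes and a forward model of sort-seq experiments.

Two things live here:

1. Generators for ground-truth repression landscapes with tunable
   ruggedness — additive (single-peaked), NK (K interacting sites per
   locus), and House-of-Cards (i.i.d. scores, maximally rugged).  These
   serve as oracles: their topographic properties are known analytically
   or by brute force.

2. :func:`simulate_sortseq`, a forward model of the sorting-and-sequencing
   assay: each genotype's cells draw log-normal fluorescence around a
   monotone-decreasing map of its true repression, cells are binned into
   13 fluorescence gates (log2-equidistant interior boundaries, the lowest
   gate bounded by the autofluorescence median, the highest gate starting
   at the 95th percentile of the library's fluorescence distribution), and
   reads are sampled multinomially from the gate occupancies, independently
   for each of three replicates.

The simulator's defaults emulate the assay conditions the scoring module
expects: ~100 reads per genotype so the >=30-read depth filter bites only
in the lower tail, and between-replicate noise placed so that per-replicate
repression scores correlate at R ~ 0.84-0.92 across replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError
from .space import GenotypeSpace

__all__ = [
    "GroundTruthLandscape",
    "SortSeqSimConfig",
    "make_additive_landscape",
    "make_hoc_landscape",
    "make_nk_landscape",
    "simulate_sortseq",
    "rescale_repression",
    "bin_columns",
]


# ---------------------------------------------------------------------------
# ground-truth landscapes
# ---------------------------------------------------------------------------


@dataclass
class GroundTruthLandscape:
    """A genotype -> true repression map over a complete genotype space.

    ``scores`` is a pandas Series indexed by genotype string (the L variable
    characters), in wild-type-normalized-like units (non-negative).
    """

    scores: pd.Series
    space: GenotypeSpace
    model_kind: str
    model_params: dict
    seed: int | None = None

    def __post_init__(self):
        self.scores = self.scores.astype(float)
        self.scores.index.name = "genotype"
        self.scores.name = "true_repression"

    def __len__(self) -> int:
        return len(self.scores)

    def to_frame(self) -> pd.DataFrame:
        return self.scores.reset_index()


def _weight_matrix(space: GenotypeSpace, site_weights) -> np.ndarray:
    """Validate per-position, per-allele weights; return an (L, a) array."""
    L, alphabet = space.length, space.alphabet
    if len(site_weights) != L:
        raise ConfigurationError(
            f"site_weights has {len(site_weights)} positions, expected {L}"
        )
    mat = np.empty((L, len(alphabet)), dtype=float)
    for pos, wmap in enumerate(site_weights):
        for ai, allele in enumerate(alphabet):
            try:
                mat[pos, ai] = float(wmap[allele])
            except KeyError:
                raise ConfigurationError(
                    f"site_weights missing entry for position {pos}, allele {allele!r}"
                ) from None
    return mat


def make_additive_landscape(
    space: GenotypeSpace, site_weights, seed: int | None = None
) -> GroundTruthLandscape:
    """Additive landscape: score(g) = sum of per-position allele weights.

    ``site_weights`` is a sequence of L mappings allele -> weight.  With
    strictly distinct per-position weights the landscape has exactly one
    local maximum (the genotype of per-position best alleles).
    """
    mat = _weight_matrix(space, site_weights)
    genotypes = space.all_genotypes()
    codes = space.encode(genotypes)
    scores = mat[np.arange(space.length), codes].sum(axis=1)
    return GroundTruthLandscape(
        scores=pd.Series(scores, index=genotypes),
        space=space,
        model_kind="additive",
        model_params={"site_weights": [dict(w) for w in site_weights]},
        seed=seed,
    )


def make_hoc_landscape(
    space: GenotypeSpace,
    seed: int,
    distribution: str = "uniform",
    **dist_params,
) -> GroundTruthLandscape:
    """House-of-Cards landscape: i.i.d. scores, neighbors uncorrelated.

    On a complete Hamming graph with 4 alleles the expected number of local
    maxima is 4^L / (3L + 1).  ``distribution`` is one of ``uniform``,
    ``normal`` or ``exponential`` (continuous, so ties are almost surely
    absent); extra keyword arguments are passed to the numpy sampler.
    """
    rng = np.random.default_rng(seed)
    genotypes = space.all_genotypes()
    n = len(genotypes)
    samplers = {
        "uniform": rng.uniform,
        "normal": rng.normal,
        "exponential": rng.exponential,
    }
    if distribution not in samplers:
        raise ConfigurationError(f"unknown distribution {distribution!r}")
    scores = samplers[distribution](size=n, **dist_params)
    return GroundTruthLandscape(
        scores=pd.Series(scores, index=genotypes),
        space=space,
        model_kind="HoC",
        model_params={"distribution": distribution, **dist_params},
        seed=seed,
    )


def make_nk_landscape(
    space: GenotypeSpace, K: int, seed: int
) -> GroundTruthLandscape:
    """NK landscape: mean of per-site components, each depending on the
    site plus its K right-hand (circular) neighbors.

    K = 0 reduces to an additive landscape; K = L - 1 makes every component
    depend on the whole genotype, statistically matching House-of-Cards.
    """
    L, a = space.length, space.n_alleles
    if not 0 <= K <= L - 1:
        raise ConfigurationError(f"K must be in [0, {L - 1}], got {K}")
    rng = np.random.default_rng(seed)
    tables = rng.random((L, a ** (K + 1)))
    genotypes = space.all_genotypes()
    codes = space.encode(genotypes).astype(np.int64)
    # component index for site i: base-a number over sites i, i+1, ..., i+K (mod L)
    total = np.zeros(len(genotypes))
    for i in range(L):
        idx = np.zeros(len(genotypes), dtype=np.int64)
        for k in range(K + 1):
            idx = idx * a + codes[:, (i + k) % L]
        total += tables[i, idx]
    scores = total / L
    return GroundTruthLandscape(
        scores=pd.Series(scores, index=genotypes),
        space=space,
        model_kind="NK",
        model_params={"K": K},
        seed=seed,
    )


def rescale_repression(
    truth: GroundTruthLandscape, low: float = 0.0, high: float = 1.25
) -> GroundTruthLandscape:
    """Affinely rescale true scores onto a repression-like range.

    The observed, wild-type-normalized repression scale runs from 0 to
    about 1.25; generator outputs on arbitrary scales are mapped onto
    [low, high] before simulation so the fluorescence map's dynamic range
    is used consistently.
    """
    s = truth.scores
    span = s.max() - s.min()
    if span == 0:
        scaled = pd.Series(np.full(len(s), low), index=s.index)
    else:
        scaled = (s - s.min()) / span * (high - low) + low
    return GroundTruthLandscape(
        scores=scaled,
        space=truth.space,
        model_kind=truth.model_kind,
        model_params={**truth.model_params, "rescaled": (low, high)},
        seed=truth.seed,
    )


# ---------------------------------------------------------------------------
# sort-seq forward model
# ---------------------------------------------------------------------------


def bin_columns(n_bins: int = 13) -> list[str]:
    return [f"bin_{i:02d}" for i in range(1, n_bins + 1)]


@dataclass
class SortSeqSimConfig:
    """Parameters of the simulated sorting-and-sequencing experiment.

    Fluorescence model: F(r) = max(f_auto, f_max * 2**(-slope * r)), a
    log-linear decreasing map of true repression r with saturation at the
    autofluorescence floor of the promoterless control.  Single cells draw
    log-normal noise (sd ``cell_noise_sd`` on the natural-log scale) around
    F(r); each (genotype, replicate) additionally draws one multiplicative
    log-normal factor with sd ``replicate_noise_sd``.

    ``reads_total`` defaults to 100 reads per genotype, so median depth is
    approximately 100 and the 30-read filter removes only the tail.
    """

    n_bins: int = 13
    cells_per_genotype: int = 100
    reads_total: int | None = None  # default: 100 * number of genotypes
    n_replicates: int = 3
    cell_noise_sd: float = 0.35
    replicate_noise_sd: float = 0.30
    f_max: float = 8192.0
    f_auto: float = 64.0
    slope: float = 5.6  # log2 fluorescence decrease per repression unit
    dropout_fraction: float = 0.0
    seed: int | None = None
    gate_boundaries: np.ndarray | None = field(default=None, repr=False)

    def validate(self) -> None:
        if self.n_bins < 2:
            raise ConfigurationError("n_bins must be >= 2")
        if self.cells_per_genotype < 1:
            raise ConfigurationError("cells_per_genotype must be >= 1")
        if self.reads_total is not None and self.reads_total <= 0:
            raise ConfigurationError("reads_total must be positive")
        if self.n_replicates < 1:
            raise ConfigurationError("n_replicates must be >= 1")
        if self.cell_noise_sd < 0 or self.replicate_noise_sd < 0:
            raise ConfigurationError("noise standard deviations must be >= 0")
        if not (self.f_max > self.f_auto > 0):
            raise ConfigurationError("need f_max > f_auto > 0")
        if self.slope <= 0:
            raise ConfigurationError(
                "slope must be positive (fluorescence decreasing in repression)"
            )
        if not 0 <= self.dropout_fraction < 1:
            raise ConfigurationError("dropout_fraction must be in [0, 1)")
        if self.gate_boundaries is not None:
            b = np.asarray(self.gate_boundaries, float)
            if len(b) != self.n_bins - 1 or np.any(np.diff(b) <= 0):
                raise ConfigurationError(
                    "gate_boundaries must be strictly increasing with n_bins - 1 entries"
                )


def repression_to_fluorescence(r, cfg: SortSeqSimConfig) -> np.ndarray:
    """Monotone-decreasing map from repression to median fluorescence."""
    r = np.asarray(r, dtype=float)
    return np.maximum(cfg.f_auto, cfg.f_max * 2.0 ** (-cfg.slope * r))


def _gate_boundaries(median_f: np.ndarray, cfg: SortSeqSimConfig, rng) -> np.ndarray:
    """Derive the n_bins - 1 interior gate thresholds.

    Mirrors the sorting protocol: the lowest gate is bounded above by the
    median autofluorescence of the negative control; the highest gate starts
    at the 95th percentile of the recorded library fluorescence; interior
    boundaries are equidistant on a log2 scale.
    """
    t_low = cfg.f_auto  # median of the log-normal autofluorescence control
    cells = np.repeat(median_f, cfg.cells_per_genotype)
    if cfg.cell_noise_sd > 0:
        cells = cells * rng.lognormal(0.0, cfg.cell_noise_sd, size=cells.size)
    t_high = np.quantile(cells, 0.95)
    if t_high <= t_low:
        raise ConfigurationError(
            "95th fluorescence percentile does not exceed the autofluorescence "
            "median; the simulated library is entirely at the floor"
        )
    return 2.0 ** np.linspace(np.log2(t_low), np.log2(t_high), cfg.n_bins - 1)


def simulate_sortseq(
    truth: GroundTruthLandscape, cfg: SortSeqSimConfig
) -> pd.DataFrame:
    """Simulate per-replicate genotype x bin read counts.

    Returns a tidy DataFrame with columns ``genotype``, ``replicate`` and
    ``bin_01`` ... ``bin_{n_bins}``; per replicate the counts sum exactly to
    ``reads_total``.  The result carries the derived gate boundaries in
    ``df.attrs["gate_boundaries"]``.  Identical (truth, cfg) including the
    seed reproduce the table bit-identically.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    genotypes = np.asarray(truth.scores.index)
    n = len(genotypes)
    reads_total = cfg.reads_total if cfg.reads_total is not None else 100 * n
    if reads_total <= 0:
        raise ConfigurationError("reads_total must be positive")

    median_f = repression_to_fluorescence(truth.scores.to_numpy(), cfg)
    if cfg.gate_boundaries is not None:
        bounds = np.asarray(cfg.gate_boundaries, float)
    else:
        bounds = _gate_boundaries(median_f, cfg, rng)

    rows = []
    for rep in range(1, cfg.n_replicates + 1):
        rep_factor = (
            rng.lognormal(0.0, cfg.replicate_noise_sd, size=n)
            if cfg.replicate_noise_sd > 0
            else np.ones(n)
        )
        f = (median_f * rep_factor)[:, None] * np.ones(
            (n, cfg.cells_per_genotype)
        )
        if cfg.cell_noise_sd > 0:
            f = f * rng.lognormal(0.0, cfg.cell_noise_sd, size=f.shape)
        bins = np.digitize(f, bounds)  # 0 .. n_bins - 1
        # per-genotype gate occupancies
        flat = (np.arange(n)[:, None] * cfg.n_bins + bins).ravel()
        occupancy = np.bincount(flat, minlength=n * cfg.n_bins).reshape(
            n, cfg.n_bins
        )
        if cfg.dropout_fraction > 0:
            drop = rng.random(n) < cfg.dropout_fraction
            occupancy[drop] = 0
        total = occupancy.sum()
        if total == 0:
            raise ConfigurationError("no cells survived; dropout too aggressive")
        p = occupancy.ravel() / total
        counts = rng.multinomial(reads_total, p).reshape(n, cfg.n_bins)
        df = pd.DataFrame(counts, columns=bin_columns(cfg.n_bins))
        df.insert(0, "replicate", rep)
        df.insert(0, "genotype", genotypes)
        rows.append(df)

    out = pd.concat(rows, ignore_index=True)
    out.attrs["gate_boundaries"] = bounds
    out.attrs["reads_total"] = reads_total
    return out
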
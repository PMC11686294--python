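"""From genotype x bin x replicate read counts to repression scores.

The expression score of a genotype is the read-weighted mean bin index,

    e = sum_i x_i * w_i / sum_i x_i,        w_i = 1, 2, ..., n_bins,

which lies in [1, n_bins].  Because high fluorescence (high bins) means
weak repression, the scale is reversed,

    r = e_max + 1 - e,                      e_max = n_bins,

and finally normalized by the wild type so that S(wild type) = 1 and the
observed scores span roughly 0 to 1.25.

Replicates are combined after two quality filters: a genotype must be
present (reads > 0) in every replicate with at least ``min_reads`` reads
per replicate (summed over bins by default, or in every single bin with
``per_bin_threshold=True``), and its per-replicate repression scores must
have a coefficient of variation of at most ``max_cv``.  The per-genotype
noise estimate tau is the standard deviation of wild-type-normalized
per-replicate scores.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, DataError, UndefinedScoreError
from .space import DNA_ALPHABET
from .synthetic import bin_columns

__all__ = [
    "expression_score",
    "repression_score",
    "filter_variants",
    "normalize_by_wildtype",
    "score_pipeline",
    "frequency_matrix",
]


def expression_score(counts) -> np.ndarray | float:
    """Weighted-average bin index e of one or more bin-count vectors.

    ``counts`` is a length-n vector or an (m, n) matrix of non-negative
    integers; bin weights are 1..n.  Raises UndefinedScoreError if any
    vector is all zero.  e is invariant under rescaling all counts by a
    positive constant.
    """
    x = np.asarray(counts, dtype=float)
    scalar = x.ndim == 1
    x = np.atleast_2d(x)
    if np.any(x < 0):
        raise DataError("bin counts must be non-negative")
    totals = x.sum(axis=1)
    if np.any(totals == 0):
        raise UndefinedScoreError("expression score undefined for all-zero counts")
    w = np.arange(1, x.shape[1] + 1, dtype=float)
    e = (x * w).sum(axis=1) / totals
    return float(e[0]) if scalar else e


def repression_score(e, e_max: int = 13):
    """Reverse the expression scale: r = e_max + 1 - e, so that high r
    means strong repression.  e must lie in [1, e_max]."""
    e_arr = np.asarray(e, dtype=float)
    if np.any((e_arr < 1) | (e_arr > e_max)):
        raise DataError(f"expression score out of range [1, {e_max}]")
    r = e_max + 1 - e_arr
    return float(r) if np.isscalar(e) else r


def _count_matrices(table: pd.DataFrame, n_bins: int) -> dict[int, pd.DataFrame]:
    """Split a tidy count table into per-replicate genotype x bin matrices."""
    cols = bin_columns(n_bins)
    missing = [c for c in ("genotype", "replicate", *cols) if c not in table.columns]
    if missing:
        raise DataError(f"count table missing columns: {missing}")
    out = {}
    for rep, sub in table.groupby("replicate"):
        if sub["genotype"].duplicated().any():
            dup = sub.loc[sub["genotype"].duplicated(), "genotype"].iloc[0]
            raise DataError(f"replicate {rep} lists genotype {dup!r} more than once")
        out[rep] = sub.set_index("genotype")[cols]
    return out


def filter_variants(
    table: pd.DataFrame,
    min_reads: int = 30,
    max_cv: float = 0.5,
    per_bin_threshold: bool = False,
    n_bins: int = 13,
) -> pd.DataFrame:
    """Apply the replicate-presence, depth, and CV filters; score survivors.

    Returns a DataFrame indexed by genotype with columns ``r_mean``, ``cv``
    and per-replicate ``e_rep{k}``, ``r_rep{k}``, ``reads_rep{k}``.  The
    attrs carry the filter funnel (``attrs["funnel"]``) and, per filter,
    the set of genotypes it removed (``attrs["removed"]``), so downstream
    errors can name the responsible filter.

    The depth filter applies per replicate to the total reads summed over
    bins; ``per_bin_threshold=True`` instead demands ``min_reads`` in every
    single bin.  The CV is computed on pre-normalization r (normalizing by
    a common constant leaves it unchanged).
    """
    mats = _count_matrices(table, n_bins)
    reps = sorted(mats)
    if len(reps) < 2:
        raise DataError("filtering requires at least 2 replicates")

    observed = set().union(*(set(m.index) for m in mats.values()))
    funnel: dict[str, int] = {"observed": len(observed)}
    removed: dict[str, set] = {}

    # presence in all replicates (with at least one read)
    present = None
    for rep in reps:
        m = mats[rep]
        has_reads = set(m.index[m.sum(axis=1) > 0])
        present = has_reads if present is None else present & has_reads
    removed["not_in_all_replicates"] = observed - present
    funnel["in_all_replicates"] = len(present)

    # depth filter, per replicate
    deep = set(present)
    for rep in reps:
        m = mats[rep].loc[sorted(deep & set(mats[rep].index))]
        if per_bin_threshold:
            ok = m.index[(m >= min_reads).all(axis=1)]
        else:
            ok = m.index[m.sum(axis=1) >= min_reads]
        deep &= set(ok)
    removed["min_reads"] = present - deep
    funnel["min_reads"] = len(deep)

    keep = sorted(deep)
    e_mat = np.empty((len(keep), len(reps)))
    reads_mat = np.empty((len(keep), len(reps)), dtype=int)
    for j, rep in enumerate(reps):
        counts = mats[rep].loc[keep].to_numpy()
        reads_mat[:, j] = counts.sum(axis=1)
        if len(keep):
            e_mat[:, j] = expression_score(counts)
    r_mat = n_bins + 1 - e_mat

    mean_r = r_mat.mean(axis=1)
    sd_r = r_mat.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean_r > 0, sd_r / mean_r, np.inf)
    ok = cv <= max_cv
    removed["max_cv"] = set(np.asarray(keep)[~ok])
    funnel["max_cv"] = int(ok.sum())

    out = pd.DataFrame(index=pd.Index(np.asarray(keep)[ok], name="genotype"))
    out["r_mean"] = mean_r[ok]
    out["cv"] = cv[ok]
    for j, rep in enumerate(reps):
        out[f"e_rep{rep}"] = e_mat[ok, j]
        out[f"r_rep{rep}"] = r_mat[ok, j]
        out[f"reads_rep{rep}"] = reads_mat[ok, j]
    out.attrs["funnel"] = funnel
    out.attrs["removed"] = removed
    out.attrs["replicates"] = reps
    out.attrs["n_bins"] = n_bins
    if out.empty:
        warnings.warn("no genotypes survived filtering", stacklevel=2)
    return out


def normalize_by_wildtype(scores: pd.DataFrame, wildtype: str) -> pd.DataFrame:
    """Divide repression scores by the wild type's mean repression.

    Adds columns ``S`` (wild-type-normalized mean score, exactly 1 for the
    wild type), per-replicate ``S_rep{k}``, and ``tau`` (standard deviation
    of the normalized per-replicate scores).  Raises DataError naming the
    filter that removed the wild type if it is absent.
    """
    if wildtype not in scores.index:
        reason = "absent from the count table"
        for name, gone in scores.attrs.get("removed", {}).items():
            if wildtype in gone:
                reason = f"removed by the {name!r} filter"
                break
        raise DataError(f"wild type {wildtype!r} is not in the score table: {reason}")
    r_wt = scores.at[wildtype, "r_mean"]
    if r_wt <= 0:
        raise DataError(f"wild type {wildtype!r} has non-positive repression")
    out = scores.copy()
    out["S"] = out["r_mean"] / r_wt
    rep_cols = [c for c in scores.columns if c.startswith("r_rep")]
    for c in rep_cols:
        out[f"S_{c[2:]}"] = out[c] / r_wt
    s_reps = out[[f"S_{c[2:]}" for c in rep_cols]].to_numpy()
    out["tau"] = s_reps.std(axis=1, ddof=1)
    out.attrs = dict(scores.attrs)
    out.attrs["wildtype"] = wildtype
    return out


def score_pipeline(
    table: pd.DataFrame,
    wildtype: str,
    min_reads: int = 30,
    max_cv: float = 0.5,
    per_bin_threshold: bool = False,
    n_bins: int = 13,
) -> pd.DataFrame:
    """Filter, score and wild-type-normalize a count table in one call."""
    return normalize_by_wildtype(
        filter_variants(
            table,
            min_reads=min_reads,
            max_cv=max_cv,
            per_bin_threshold=per_bin_threshold,
            n_bins=n_bins,
        ),
        wildtype,
    )


def frequency_matrix(genotypes, alphabet: str = DNA_ALPHABET):
    """Per-position nucleotide frequencies and information content.

    Returns ``(freq, info)`` where ``freq`` is an (alphabet x L) DataFrame
    whose columns each sum to 1 and ``info`` is the per-position information
    content in bits, 2 - H(column) for the 4-letter alphabet, in [0, 2].
    """
    genotypes = list(genotypes)
    if not genotypes:
        raise DataError("frequency_matrix requires a non-empty genotype set")
    L = len(genotypes[0])
    if any(len(g) != L for g in genotypes):
        raise DataError("genotypes must have uniform length")
    counts = np.zeros((len(alphabet), L))
    idx = {c: i for i, c in enumerate(alphabet)}
    for g in genotypes:
        for pos, c in enumerate(g):
            try:
                counts[idx[c], pos] += 1
            except KeyError:
                raise DataError(f"character {c!r} outside alphabet {alphabet!r}") from None
    freq = counts / counts.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(freq > 0, freq * np.log2(freq), 0.0)
    entropy = -plogp.sum(axis=0)
    info = np.log2(len(alphabet)) - entropy
    positions = list(range(1, L + 1))
    return (
        pd.DataFrame(freq, index=list(alphabet), columns=positions),
        pd.Series(info, index=positions, name="information_bits"),
    )
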
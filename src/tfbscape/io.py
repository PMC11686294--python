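"""Readers and writers for the package's on-disk TSV dialects.

All tables are tab-separated with a header row; metadata (seeds, config
hash) travels as ``# key=value`` comment lines before the header and is
round-tripped into/out of ``DataFrame.attrs``.  Genotypes are stored as the
L variable characters only; the fixed context lives in the space definition.
"""

from __future__ import annotations

import io as _io
import re
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .exceptions import DataError
from .space import GenotypeSpace
from .synthetic import GroundTruthLandscape, bin_columns

__all__ = [
    "read_count_table",
    "write_count_table",
    "read_score_table",
    "write_score_table",
    "read_truth_table",
    "write_truth_table",
    "write_fasta",
    "write_node_table",
    "write_edge_table",
    "read_node_table",
    "load_config",
    "save_config",
]

_GENOTYPE_RE = re.compile(r"^[ACGT]+$")


def _write_tsv(df: pd.DataFrame, path, metadata: dict | None = None, index=False):
    path = Path(path)
    with path.open("w") as fh:
        for key, value in (metadata or {}).items():
            fh.write(f"# {key}={value}\n")
        df.to_csv(fh, sep="\t", index=index)


def _read_tsv(path) -> pd.DataFrame:
    path = Path(path)
    meta: dict[str, str] = {}
    lines = []
    with path.open() as fh:
        for line in fh:
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" in body:
                    key, _, value = body.partition("=")
                    meta[key.strip()] = value.strip()
            else:
                lines.append(line)
    df = pd.read_csv(_io.StringIO("".join(lines)), sep="\t")
    df.attrs["metadata"] = meta
    return df


def write_count_table(table: pd.DataFrame, path, metadata: dict | None = None):
    """Write a tidy genotype x replicate x bin count table."""
    _write_tsv(table, path, metadata)


def read_count_table(path, n_bins: int = 13) -> pd.DataFrame:
    """Read and validate a count table; malformed rows are reported with
    their (1-based, post-header) line numbers."""
    df = _read_tsv(path)
    expected = ["genotype", "replicate", *bin_columns(n_bins)]
    if list(df.columns) != expected:
        raise DataError(
            f"{path}: expected columns {expected}, found {list(df.columns)}"
        )
    for row_pos, genotype in enumerate(df["genotype"]):
        if not isinstance(genotype, str) or not _GENOTYPE_RE.match(genotype):
            raise DataError(f"{path}: line {row_pos + 2}: bad genotype {genotype!r}")
    counts = df[bin_columns(n_bins)]
    bad = np.flatnonzero((counts < 0).any(axis=1).to_numpy())
    if len(bad):
        raise DataError(f"{path}: line {bad[0] + 2}: negative count")
    if not np.issubdtype(counts.to_numpy().dtype, np.integer):
        frac = counts.to_numpy() % 1
        if np.any(frac != 0):
            row = int(np.argwhere(frac != 0)[0][0])
            raise DataError(f"{path}: line {row + 2}: non-integer count")
        df[bin_columns(n_bins)] = counts.astype(np.int64)
    return df


def write_score_table(scores: pd.DataFrame, path, metadata: dict | None = None):
    _write_tsv(scores.reset_index(), path, metadata)


def read_score_table(path) -> pd.DataFrame:
    df = _read_tsv(path)
    if "genotype" not in df.columns:
        raise DataError(f"{path}: score table must have a genotype column")
    meta = df.attrs.get("metadata", {})
    df = df.set_index("genotype")
    df.attrs["metadata"] = meta
    return df


def write_truth_table(truth: GroundTruthLandscape, path, metadata: dict | None = None):
    _write_tsv(truth.to_frame(), path, metadata)


def read_truth_table(path, space: GenotypeSpace) -> GroundTruthLandscape:
    df = _read_tsv(path)
    if list(df.columns) != ["genotype", "true_repression"]:
        raise DataError(f"{path}: expected columns genotype, true_repression")
    return GroundTruthLandscape(
        scores=df.set_index("genotype")["true_repression"],
        space=space,
        model_kind="from_file",
        model_params={"path": str(path)},
    )


def write_fasta(genotypes, space: GenotypeSpace, path):
    """Write full-context sequences (variable characters embedded) as FASTA."""
    with Path(path).open("w") as fh:
        for g in genotypes:
            fh.write(f">{g}\n{space.full_sequence(g)}\n")


def write_node_table(landscape, path, metadata: dict | None = None):
    _write_tsv(landscape.node_table(), path, metadata)


def write_edge_table(landscape, path, metadata: dict | None = None):
    _write_tsv(landscape.edge_table(), path, metadata)


def read_node_table(path) -> pd.DataFrame:
    df = _read_tsv(path)
    for col in ("genotype", "S"):
        if col not in df.columns:
            raise DataError(f"{path}: node table missing column {col!r}")
    meta = df.attrs.get("metadata", {})
    df = df.set_index("genotype")
    df.attrs["metadata"] = meta
    return df


def load_config(path) -> dict:
    with Path(path).open() as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise DataError(f"{path}: config must be a mapping")
    return cfg


def save_config(cfg: dict, path):
    with Path(path).open("w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
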
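"""Genotype spaces: fixed-length strings over {A,C,G,T} forming a Hamming graph.

A :class:`GenotypeSpace` describes the variable positions of a binding-site
library — the string length ``L``, the nucleotide alphabet, and (optionally)
the fixed flanking context the variable positions are embedded in.  Genotypes
are always handled as the ``L`` variable characters only; the context is
carried along so full-length sequences can be reconstructed for export.

The default space is the 8-position TetR operator (*tetO2*) library:
variable positions embedded in the 19-nt context ``TCCCNNNNAGTNNNNGAGA``
with wild type ``TATCGATA`` (i.e. full sequence ``TCCCTATCAGTGATAGAGA``),
giving a genotype space of :math:`4^8 = 65{,}536` sequences.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConfigurationError

DNA_ALPHABET = "ACGT"

#: fixed flanks of the tetO2-derived library; N marks the variable positions
TETO2_CONTEXT = "TCCCNNNNAGTNNNNGAGA"
#: wild-type alleles at the 8 variable positions of tetO2
TETO2_WILDTYPE = "TATCGATA"


@dataclass(frozen=True)
class GenotypeSpace:
    """Alphabet, length and (optional) sequence context of a TFBS library.

    Parameters
    ----------
    length:
        Number of variable positions, ``L``.
    alphabet:
        Allowed characters at each variable position.
    context:
        Full-length template with ``N`` at each variable position, or None.
        Must contain exactly ``length`` ``N`` characters when given.
    wildtype:
        The wild-type genotype (variable characters only), or None.
    """

    length: int = 8
    alphabet: str = DNA_ALPHABET
    context: str | None = TETO2_CONTEXT
    wildtype: str | None = TETO2_WILDTYPE
    _char_index: dict = field(init=False, repr=False, compare=False, default=None)

    def __post_init__(self):
        if self.length < 1:
            raise ConfigurationError("length must be >= 1")
        if len(set(self.alphabet)) != len(self.alphabet) or len(self.alphabet) < 2:
            raise ConfigurationError("alphabet must have >= 2 distinct characters")
        if self.context is not None and self.context.count("N") != self.length:
            raise ConfigurationError(
                f"context has {self.context.count('N')} variable positions, "
                f"expected {self.length}"
            )
        if self.wildtype is not None:
            self.validate(self.wildtype)
        object.__setattr__(
            self, "_char_index", {c: i for i, c in enumerate(self.alphabet)}
        )

    # -- basic queries ---------------------------------------------------

    @property
    def n_alleles(self) -> int:
        return len(self.alphabet)

    @property
    def size(self) -> int:
        """Number of genotypes in the complete space, ``|alphabet|^L``."""
        return self.n_alleles**self.length

    @property
    def max_degree(self) -> int:
        """Neighbors per genotype in the complete Hamming graph: (a-1)*L."""
        return (self.n_alleles - 1) * self.length

    def validate(self, genotype: str) -> str:
        if len(genotype) != self.length:
            raise ConfigurationError(
                f"genotype {genotype!r} has length {len(genotype)}, expected {self.length}"
            )
        bad = set(genotype) - set(self.alphabet)
        if bad:
            raise ConfigurationError(
                f"genotype {genotype!r} contains characters outside the alphabet: {sorted(bad)}"
            )
        return genotype

    # -- enumeration -----------------------------------------------------

    def all_genotypes(self) -> list[str]:
        """All genotypes of the complete space, in lexicographic order."""
        return [
            "".join(tup)
            for tup in itertools.product(sorted(self.alphabet), repeat=self.length)
        ]

    def neighbors(self, genotype: str):
        """Yield all single-substitution (Hamming distance 1) neighbors."""
        for pos in range(self.length):
            for allele in self.alphabet:
                if allele != genotype[pos]:
                    yield genotype[:pos] + allele + genotype[pos + 1 :]

    # -- arithmetic ------------------------------------------------------

    def hamming(self, a: str, b: str) -> int:
        return sum(x != y for x, y in zip(a, b, strict=True))

    def encode(self, genotypes) -> np.ndarray:
        """Encode genotypes as an (n, L) uint8 matrix of allele indices."""
        idx = self._char_index
        return np.array(
            [[idx[c] for c in g] for g in genotypes], dtype=np.uint8
        ).reshape(-1, self.length)

    def full_sequence(self, genotype: str) -> str:
        """Embed the variable characters into the fixed context."""
        if self.context is None:
            return genotype
        it = iter(genotype)
        return "".join(next(it) if c == "N" else c for c in self.context)


def teto2_space() -> GenotypeSpace:
    """The 8-position *tetO2* library space used throughout the package."""
    return GenotypeSpace()
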
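"""Exact arithmetic on IUPAC degenerate bases and codons.

A degenerate codon such as ``VRN`` is a compact description of a *mixture* of
concrete codons synthesized at one position of a combinatorial library: each
IUPAC ambiguity symbol stands for a set of nucleotides (``V`` = A/C/G,
``R`` = A/G, ``N`` = A/C/G/T), and the codon denotes the Cartesian product of
its three base sets.  Because oligo synthesis delivers each concrete codon of
the expansion in equal molar amounts, the amino-acid frequencies a degenerate
codon induces are exactly (codons encoding residue) / (expansion size).  This
module provides that arithmetic: expansion, translation under the standard
genetic code, amino-acid composition profiles, and forbidden-residue checks.

Residues are one-letter amino-acid codes; the stop signal is the dedicated
symbol ``*`` and is never merged with the amino acids (stop contamination of a
library is a distinct failure mode from an unwanted residue).
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Mapping, Set, Tuple

from Bio.Data.CodonTable import standard_dna_table
from Bio.Data.IUPACData import ambiguous_dna_values

__all__ = [
    "IUPAC_ALPHABET",
    "STOP",
    "AA_ALPHABET",
    "RESIDUE_ALPHABET",
    "THREE_LETTER",
    "DegenerateCodon",
    "AminoAcidProfile",
    "expand_base",
    "expand_codon",
    "translate_codon",
    "aa_profile",
    "check_forbidden",
]

# --------------------------------------------------------------------------
# Alphabets
# --------------------------------------------------------------------------

#: The 15 IUPAC nucleotide ambiguity symbols (concrete A/C/G/T included).
IUPAC_ALPHABET: str = "ACGTRYSWKMBDHVN"

#: Stop signal, kept as a distinct 21st residue symbol.
STOP: str = "*"

#: The 20 amino acids, one-letter.
AA_ALPHABET: str = "ACDEFGHIKLMNPQRSTVWY"

#: Full residue alphabet: 20 amino acids + stop.
RESIDUE_ALPHABET: str = AA_ALPHABET + STOP

#: One-letter -> three-letter residue names (stop -> "Stop"), for display.
THREE_LETTER: Dict[str, str] = {
    "A": "Ala", "C": "Cys", "D": "Asp", "E": "Glu", "F": "Phe",
    "G": "Gly", "H": "His", "I": "Ile", "K": "Lys", "L": "Leu",
    "M": "Met", "N": "Asn", "P": "Pro", "Q": "Gln", "R": "Arg",
    "S": "Ser", "T": "Thr", "V": "Val", "W": "Trp", "Y": "Tyr",
    STOP: "Stop",
}

# Concrete base sets per IUPAC symbol, sorted for byte-stable expansion order.
_EXPANSION: Dict[str, Tuple[str, ...]] = {
    sym: tuple(sorted(bases))
    for sym, bases in ambiguous_dna_values.items()
    if sym in IUPAC_ALPHABET
}

# Standard genetic code (translation table 1); stop codons map to STOP.
_CODE: Dict[str, str] = dict(standard_dna_table.forward_table)
_CODE.update({c: STOP for c in standard_dna_table.stop_codons})


def _normalize_base(symbol: str) -> str:
    """Uppercase a base symbol and map RNA U to T; reject non-IUPAC symbols."""
    s = symbol.upper().replace("U", "T")
    if len(s) != 1 or s not in IUPAC_ALPHABET:
        raise ValueError(
            f"invalid IUPAC nucleotide symbol {symbol!r}: "
            f"expected one of {IUPAC_ALPHABET}"
        )
    return s


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class DegenerateCodon:
    """An ordered triple of IUPAC ambiguity symbols, e.g. ``VRN``.

    Input is normalized to uppercase DNA (``U`` accepted and mapped to ``T``).
    """

    bases: str

    def __init__(self, bases: str) -> None:
        if len(bases) != 3:
            raise ValueError(
                f"a degenerate codon has exactly 3 bases, got {bases!r}"
            )
        norm = "".join(_normalize_base(b) for b in bases)
        object.__setattr__(self, "bases", norm)

    def __str__(self) -> str:  # pragma: no cover - trivial
        return self.bases

    @property
    def expansion_size(self) -> int:
        """Number of concrete codons in the expansion (product of degeneracies)."""
        n = 1
        for b in self.bases:
            n *= len(_EXPANSION[b])
        return n

    @property
    def is_concrete(self) -> bool:
        return all(b in "ACGT" for b in self.bases)

    def expand(self) -> List[str]:
        return expand_codon(self)

    def profile(self) -> "AminoAcidProfile":
        return aa_profile(self)


@dataclass(frozen=True)
class AminoAcidProfile:
    """Amino-acid (and stop) composition of a degenerate codon.

    ``counts[r]`` is the number of concrete codons in the expansion that
    translate to residue ``r``; counts sum to the expansion size, and
    ``frequencies`` are the induced per-residue probabilities under uniform
    codon sampling.
    """

    counts: Mapping[str, int]
    total_codons: int = field(default=0)

    def __post_init__(self) -> None:
        counts = dict(self.counts)
        object.__setattr__(self, "counts", counts)
        if self.total_codons == 0:
            object.__setattr__(self, "total_codons", sum(counts.values()))
        if sum(counts.values()) != self.total_codons:
            raise ValueError("profile counts do not sum to total_codons")

    @property
    def frequencies(self) -> Dict[str, float]:
        return {r: c / self.total_codons for r, c in sorted(self.counts.items())}

    @property
    def residues(self) -> FrozenSet[str]:
        """Distinct residues encoded (counts > 0)."""
        return frozenset(r for r, c in self.counts.items() if c > 0)

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    def encodes(self, residue: str) -> bool:
        return self.counts.get(residue, 0) > 0

    def as_three_letter(self) -> Dict[str, int]:
        """Counts keyed by three-letter residue names, as printed in design tables."""
        return {
            THREE_LETTER[r]: c
            for r, c in sorted(self.counts.items())
            if c > 0
        }

    def to_json(self) -> str:
        return json.dumps(
            {
                "counts": dict(sorted(self.counts.items())),
                "total_codons": self.total_codons,
                "frequencies": self.frequencies,
            }
        )


# --------------------------------------------------------------------------
# Operations
# --------------------------------------------------------------------------


def expand_base(symbol: str) -> Set[str]:
    """Concrete nucleotide set denoted by one IUPAC symbol.

    >>> sorted(expand_base("N"))
    ['A', 'C', 'G', 'T']
    """
    return set(_EXPANSION[_normalize_base(symbol)])


def expand_codon(codon: DegenerateCodon | str) -> List[str]:
    """All concrete codons of the expansion, lexicographically sorted.

    The length equals the product of the three base degeneracies; the sorted
    order makes every downstream output byte-stable.
    """
    c = codon if isinstance(codon, DegenerateCodon) else DegenerateCodon(codon)
    return [
        "".join(triple)
        for triple in itertools.product(*(_EXPANSION[b] for b in c.bases))
    ]


def translate_codon(codon: str) -> str:
    """Translate one concrete codon under the standard genetic code.

    Stop codons return ``*``.  Degenerate symbols are rejected: translation of
    a mixture is a profile, not a single residue (see :func:`aa_profile`).
    """
    c = "".join(_normalize_base(b) for b in codon)
    if len(codon) != 3:
        raise ValueError(f"a codon has exactly 3 bases, got {codon!r}")
    if any(b not in "ACGT" for b in c):
        raise ValueError(
            f"cannot translate degenerate codon {codon!r}; use aa_profile()"
        )
    return _CODE[c]


_PROFILE_CACHE: Dict[str, AminoAcidProfile] = {}


def aa_profile(codon: DegenerateCodon | str) -> AminoAcidProfile:
    """Amino-acid composition of a degenerate codon (expand, translate, tally).

    Profiles are memoized: there are only 3,375 degenerate codons and callers
    (exhaustive design searches, per-position tables) revisit them heavily.
    """
    c = codon if isinstance(codon, DegenerateCodon) else DegenerateCodon(codon)
    cached = _PROFILE_CACHE.get(c.bases)
    if cached is not None:
        return cached
    concrete = expand_codon(c)
    counts: Dict[str, int] = {}
    for cc in concrete:
        r = _CODE[cc]
        counts[r] = counts.get(r, 0) + 1
    prof = AminoAcidProfile(counts=counts, total_codons=len(concrete))
    _PROFILE_CACHE[c.bases] = prof
    return prof


def check_forbidden(
    codon: DegenerateCodon | str, forbidden: Iterable[str]
) -> List[str]:
    """Concrete codons in the expansion that encode a forbidden residue.

    Returns the (possibly empty) sorted list of offending concrete codons;
    an empty list means the codon is clean with respect to ``forbidden``.
    """
    bad = set(forbidden)
    unknown = bad - set(RESIDUE_ALPHABET)
    if unknown:
        raise ValueError(
            f"forbidden set contains unknown residue symbols: {sorted(unknown)}"
        )
    return [cc for cc in expand_codon(codon) if _CODE[cc] in bad]
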
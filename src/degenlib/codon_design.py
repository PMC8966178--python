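"""Reverse codon design: find degenerate codons for a residue specification.

Given the residues a library position must offer and the residues it must
never produce (by default cysteine and stop), the designer searches all
15^3 = 3,375 degenerate codons exhaustively and ranks the survivors.  The
default ranking prefers, in order: fewest off-target residues (specificity),
then the LARGEST expansion (among codons encoding the same residue set, the
maximal degenerate codon is the canonical IUPAC representation of that set —
e.g. TWY, not TWC, for {Phe, Tyr}), then the most uniform residue
distribution, then lexicographic order as a deterministic tie-break.

An optional frequency-target mode ranks instead by total variation distance
to a desired per-residue frequency vector, for positions designed to be
skewed (e.g. an arginine-rich polar position) rather than uniform.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Mapping, Optional, Tuple

from .codon_algebra import (
    IUPAC_ALPHABET,
    RESIDUE_ALPHABET,
    STOP,
    AminoAcidProfile,
    DegenerateCodon,
    aa_profile,
)

__all__ = [
    "CodonDesignQuery",
    "ScoredCandidate",
    "CodonDesignResult",
    "enumerate_degenerate_codons",
    "score_codon",
    "design_codon",
]


@dataclass(frozen=True)
class CodonDesignQuery:
    """What a randomized position must (and must not) encode.

    ``required`` residues must all be encodable; ``forbidden`` residues must
    be unreachable.  ``max_off_target`` optionally caps how many residues
    beyond the required set a candidate may encode (0 = exact-set designs).
    ``target_frequencies`` switches ranking to frequency matching
    (minimum total variation distance to the given residue distribution).
    """

    required: FrozenSet[str]
    forbidden: FrozenSet[str] = frozenset({"C", STOP})
    prefer_uniform: bool = False
    max_off_target: Optional[int] = None
    target_frequencies: Optional[Mapping[str, float]] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "required", frozenset(self.required))
        object.__setattr__(self, "forbidden", frozenset(self.forbidden))
        for r in self.required | self.forbidden:
            if r not in RESIDUE_ALPHABET:
                raise ValueError(f"unknown residue symbol {r!r}")
        if self.target_frequencies is not None:
            object.__setattr__(
                self, "target_frequencies", dict(self.target_frequencies)
            )

    @property
    def feasible_constraints(self) -> bool:
        return not (self.required & self.forbidden)


@dataclass(frozen=True)
class ScoredCandidate:
    codon: DegenerateCodon
    profile: AminoAcidProfile
    coverage: float          # fraction of required residues encoded
    off_target: int          # encoded residues beyond the required set
    uniformity: float        # normalized entropy of the encoded distribution
    expansion_size: int
    tvd: Optional[float] = None   # to target_frequencies, when given
    score: Tuple = ()             # ranking key, excluding the lexicographic tie-break


@dataclass(frozen=True)
class CodonDesignResult:
    query: CodonDesignQuery
    candidates: Tuple[ScoredCandidate, ...]
    feasible: bool
    reason: str = ""

    def top(self) -> Optional[ScoredCandidate]:
        return self.candidates[0] if self.candidates else None

    def rank1(self) -> List[ScoredCandidate]:
        """All candidates tied with the best score (excluding the tie-break)."""
        if not self.candidates:
            return []
        best = self.candidates[0].score
        return [c for c in self.candidates if c.score == best]


_ALL_CODONS: Optional[List[DegenerateCodon]] = None


def enumerate_degenerate_codons() -> List[DegenerateCodon]:
    """All 3,375 degenerate codons in lexicographic order (cached)."""
    global _ALL_CODONS
    if _ALL_CODONS is None:
        alphabet = sorted(IUPAC_ALPHABET)
        _ALL_CODONS = [
            DegenerateCodon("".join(t))
            for t in itertools.product(alphabet, repeat=3)
        ]
    return list(_ALL_CODONS)


def score_codon(
    codon: DegenerateCodon | str, query: CodonDesignQuery
) -> ScoredCandidate:
    """Score one codon against a query; pure and deterministic.

    coverage = |required ∩ encoded| / |required|; uniformity = Shannon entropy
    of the encoded-residue frequencies / log2(#encoded residues) (1.0 for a
    single-residue codon by convention).
    """
    c = codon if isinstance(codon, DegenerateCodon) else DegenerateCodon(codon)
    prof = aa_profile(c)
    encoded = prof.residues
    coverage = (
        len(query.required & encoded) / len(query.required)
        if query.required
        else 1.0
    )
    off_target = len(encoded - query.required)
    k = len(encoded)
    if k <= 1:
        uniformity = 1.0
    else:
        h = -sum(f * math.log2(f) for f in prof.frequencies.values() if f > 0)
        uniformity = h / math.log2(k)
    tvd = None
    if query.target_frequencies is not None:
        freqs = prof.frequencies
        support = set(freqs) | set(query.target_frequencies)
        tvd = 0.5 * sum(
            abs(freqs.get(r, 0.0) - query.target_frequencies.get(r, 0.0))
            for r in support
        )
    if tvd is not None:
        score: Tuple = (tvd, off_target, -prof.total_codons)
    elif query.prefer_uniform:
        score = (off_target, -uniformity, -prof.total_codons)
    else:
        score = (off_target, -prof.total_codons, -uniformity)
    return ScoredCandidate(
        codon=c,
        profile=prof,
        coverage=coverage,
        off_target=off_target,
        uniformity=uniformity,
        expansion_size=prof.total_codons,
        tvd=tvd,
        score=score,
    )


def design_codon(query: CodonDesignQuery, limit: int = 20) -> CodonDesignResult:
    """Exhaustive search over all 3,375 degenerate codons.

    Hard constraints: every required residue encodable, no forbidden residue
    reachable, and (if set) at most ``max_off_target`` extra residues.
    Survivors are ranked by :attr:`ScoredCandidate.score` with a final
    lexicographic tie-break, so the ordering is a deterministic total order.
    An infeasible query (required ∩ forbidden nonempty, or simply no codon
    satisfying the constraints) yields an empty candidate list, not an error.
    """
    if not query.required:
        raise ValueError("query.required must be non-empty")
    if not query.feasible_constraints:
        overlap = sorted(query.required & query.forbidden)
        return CodonDesignResult(
            query=query,
            candidates=(),
            feasible=False,
            reason=f"required and forbidden sets overlap: {overlap}",
        )
    scored: List[ScoredCandidate] = []
    for c in enumerate_degenerate_codons():
        cand = score_codon(c, query)
        encoded = cand.profile.residues
        if not (query.required <= encoded):
            continue
        if encoded & query.forbidden:
            continue
        if query.max_off_target is not None and cand.off_target > query.max_off_target:
            continue
        scored.append(cand)
    scored.sort(key=lambda cand: (cand.score, cand.codon.bases))
    if not scored:
        return CodonDesignResult(
            query=query,
            candidates=(),
            feasible=False,
            reason="no degenerate codon satisfies the constraints",
        )
    return CodonDesignResult(
        query=query, candidates=tuple(scored[:limit]), feasible=True
    )
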
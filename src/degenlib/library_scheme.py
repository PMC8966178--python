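"""Declarative model of a combinatorial protein library.

A :class:`LibraryScheme` is a template ORF in which most codons are concrete
(the framework) and a declared set of codon slots carry IUPAC degenerate
codons (the randomized positions).  From that declaration alone the module
derives everything the design promises: per-position theoretical amino-acid
frequency tables, DNA- and protein-level diversity, per-position Shannon
entropy, and sanity checks (no cysteine or stop codon reachable at any
randomized position, concrete framework, restriction-site risk).

The built-in fixture :func:`nanobody_cdr3_14_scheme` encodes a synthetic
single-domain-antibody (VHH / nanobody) library on a universal framework with
fixed-length CDR1/CDR2 and a 14-residue CDR3: 7 randomized CDR1 positions,
4 in CDR2 and 14 consecutive degenerate codons in CDR3, each position bound
to a degenerate codon tailored to the structural role of its side chain.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from .codon_algebra import (
    STOP,
    AminoAcidProfile,
    DegenerateCodon,
    aa_profile,
    check_forbidden,
    expand_base,
)

__all__ = [
    "RandomizedPosition",
    "LibraryScheme",
    "FrequencyRow",
    "FrequencyTable",
    "DiversityReport",
    "RestrictionHit",
    "nanobody_cdr3_14_scheme",
    "validate_scheme",
    "theoretical_frequencies",
    "diversity",
    "expected_distinct_variants",
    "restriction_site_risk",
]

DEFAULT_FORBIDDEN = frozenset({"C", STOP})

#: Cap above which the exact occupancy expectation is not attempted.
_OCCUPANCY_LIMIT = 10**6


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class RandomizedPosition:
    """One randomized codon slot of a library template.

    ``codon_index`` is the 0-based index into the template's codon sequence;
    ``label`` is the display label of the antibody numbering convention the
    design was written in (an opaque string — antibody numbering is not a
    contiguous template index); ``region`` names the hypervariable loop.
    """

    codon_index: int
    label: str
    codon: DegenerateCodon
    region: str
    note: str = ""

    @property
    def nt_interval(self) -> Tuple[int, int]:
        """Half-open nucleotide interval of this codon in the template."""
        return (3 * self.codon_index, 3 * self.codon_index + 3)


@dataclass(frozen=True)
class LibraryScheme:
    """Template ORF plus randomized positions: the full declarative design."""

    name: str
    template_nt: str
    positions: Tuple[RandomizedPosition, ...]
    annotations: Mapping[str, Tuple[int, int]] = field(default_factory=dict)
    forbidden: frozenset = DEFAULT_FORBIDDEN
    metadata: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "positions", tuple(self.positions))
        object.__setattr__(self, "annotations", dict(self.annotations))
        object.__setattr__(self, "forbidden", frozenset(self.forbidden))
        object.__setattr__(self, "metadata", dict(self.metadata))
        object.__setattr__(self, "template_nt", self.template_nt.upper())

    @property
    def n_codons(self) -> int:
        return len(self.template_nt) // 3

    @property
    def randomized_indices(self) -> Dict[int, RandomizedPosition]:
        return {p.codon_index: p for p in self.positions}

    def template_codon(self, codon_index: int) -> str:
        return self.template_nt[3 * codon_index : 3 * codon_index + 3]

    def position(self, label: str) -> RandomizedPosition:
        for p in self.positions:
            if p.label == label:
                return p
        raise KeyError(f"no randomized position labeled {label!r}")

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "template_nt": self.template_nt,
            "positions": [
                {
                    "codon_index": p.codon_index,
                    "label": p.label,
                    "codon": p.codon.bases,
                    "region": p.region,
                    "note": p.note,
                }
                for p in self.positions
            ],
            "annotations": {k: list(v) for k, v in self.annotations.items()},
            "forbidden": sorted(self.forbidden),
            "metadata": dict(self.metadata),
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_dict(cls, d: Mapping) -> "LibraryScheme":
        return cls(
            name=d["name"],
            template_nt=d["template_nt"],
            positions=tuple(
                RandomizedPosition(
                    codon_index=p["codon_index"],
                    label=p["label"],
                    codon=DegenerateCodon(p["codon"]),
                    region=p.get("region", ""),
                    note=p.get("note", ""),
                )
                for p in d["positions"]
            ),
            annotations={
                k: (int(v[0]), int(v[1]))
                for k, v in d.get("annotations", {}).items()
            },
            forbidden=frozenset(d.get("forbidden", DEFAULT_FORBIDDEN)),
            metadata=d.get("metadata", {}),
        )

    @classmethod
    def from_json(cls, source) -> "LibraryScheme":
        if hasattr(source, "read"):
            return cls.from_dict(json.load(source))
        text = str(source)
        if text.lstrip().startswith("{"):
            return cls.from_dict(json.loads(text))
        with open(text) as fh:
            return cls.from_dict(json.load(fh))

    def positions_tsv(self) -> str:
        lines = ["codon_index\tlabel\tregion\tcodon\tnote"]
        for p in self.positions:
            lines.append(
                f"{p.codon_index}\t{p.label}\t{p.region}\t{p.codon.bases}\t{p.note}"
            )
        return "\n".join(lines) + "\n"

    def template_fasta(self) -> str:
        """Degenerate template as FASTA (IUPAC symbols are legal in FASTA)."""
        seq = self.template_nt
        body = "\n".join(seq[i : i + 60] for i in range(0, len(seq), 60))
        return f">{self.name}\n{body}\n"


@dataclass(frozen=True)
class FrequencyRow:
    """Residue counts at one randomized position (codon counts or read tallies)."""

    label: str
    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        object.__setattr__(self, "counts", dict(self.counts))

    @property
    def n(self) -> int:
        return sum(self.counts.values())

    @property
    def frequencies(self) -> Dict[str, float]:
        n = self.n
        return {r: c / n for r, c in sorted(self.counts.items()) if c > 0}


@dataclass(frozen=True)
class FrequencyTable:
    """Per-position residue frequencies, theoretical (designed) or observed (NGS)."""

    kind: str  # "theoretical" | "observed"
    rows: Mapping[str, FrequencyRow]

    def __post_init__(self) -> None:
        if self.kind not in ("theoretical", "observed"):
            raise ValueError(f"kind must be theoretical|observed, got {self.kind!r}")
        object.__setattr__(self, "rows", dict(self.rows))

    @property
    def labels(self) -> List[str]:
        return list(self.rows)

    def frequencies(self, label: str) -> Dict[str, float]:
        return self.rows[label].frequencies

    def n_observations(self, label: str) -> int:
        return 0 if self.kind == "theoretical" else self.rows[label].n

    def to_tsv(self, theoretical: "FrequencyTable" = None) -> str:
        """TSV export; pass the designed table to add a theoretical_freq column."""
        header = "position\tresidue\tcount\tfrequency"
        if theoretical is not None:
            header += "\ttheoretical_freq"
        lines = [header]
        for label, row in self.rows.items():
            theo = theoretical.frequencies(label) if theoretical else {}
            residues = sorted(set(row.frequencies) | set(theo))
            for r in residues:
                line = (
                    f"{label}\t{r}\t{row.counts.get(r, 0)}"
                    f"\t{row.frequencies.get(r, 0.0):.6g}"
                )
                if theoretical is not None:
                    line += f"\t{theo.get(r, 0.0):.6g}"
                lines.append(line)
        return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class DiversityReport:
    """Theoretical size of the library's sequence space.

    Diversities are exact integers (they exceed 64-bit range for realistic
    schemes, hence Python arbitrary precision); entropies are in bits.
    """

    dna_diversity: int
    protein_diversity: int
    per_position_entropy: Mapping[str, float]
    transformants: Optional[int] = None
    expected_distinct: Optional[float] = None

    @property
    def sampling_ratio(self) -> Optional[float]:
        if self.transformants is None:
            return None
        return self.transformants / self.protein_diversity

    @property
    def log10_sampling_ratio(self) -> Optional[float]:
        # computed in log space: the ratio itself can underflow to 0.0
        if self.transformants is None:
            return None
        return math.log10(self.transformants) - math.log10(self.protein_diversity)

    @property
    def total_entropy_bits(self) -> float:
        return sum(self.per_position_entropy.values())


@dataclass(frozen=True)
class RestrictionHit:
    pattern: str
    offset: int
    guaranteed: bool


# --------------------------------------------------------------------------
# Built-in fixture
# --------------------------------------------------------------------------

# One concrete codon per amino acid for back-translating the synthetic
# framework (common E. coli codons; any concrete choice would do).
_BACK = {
    "A": "GCG", "C": "TGC", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGC", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG",
    "M": "ATG", "N": "AAC", "P": "CCG", "Q": "CAG", "R": "CGT",
    "S": "AGC", "T": "ACC", "V": "GTG", "W": "TGG", "Y": "TAT",
}

_FR1 = "QVQLVESGGGLVQAGGSLRLSCAAS"          # 25 codons, indices 0-24
_FR2 = "WFRQAPGKEREFVAGI"                   # 16 codons, indices 36-51
_FR3 = "DSVKGRFTISRDNAKNTVYLQMNSLKPEDTAVYYCAA"  # 37 codons, indices 60-96
_FR4 = "WGQGTQVTVSS"                        # 11 codons, indices 111-121

# CDR1 block, template codon indices 25-35, design labels "26"-"36".
# (label, codon-or-fixed-residue, randomized?)
_CDR1 = [
    ("26", "G", False),
    ("27", "DMY", True),
    ("28", "VRN", True),
    ("29", "E", False),
    ("30", "HWY", True),
    ("31", "VRN", True),
    ("32", "Y", False),
    ("33", "DMY", True),
    ("34", "VNN", True),
    ("35", "F", False),
    ("36", "KMY", True),
]
_CDR1_NOTES = {
    "27": "Ramachandran outlier; randomize but keep it small, Tyr included",
    "28": "surface-exposed side chain; variable but polar",
    "30": "packed against CDR1 extremes; mostly big hydrophobic/aromatic",
    "31": "surface-exposed side chain; variable but polar",
    "33": "alpha turn outside the binding site; mostly small",
    "34": "points upward at the base of CDR1; very variable",
    "36": "support for CDR3; small residues and Tyr",
}

# CDR2 block, template codon indices 52-59, labels "53"-"60".
_CDR2 = [
    ("53", "A", False),
    ("54", "I", False),
    ("55", "KMY", True),
    ("56", "WBG", True),
    ("57", "VRN", True),
    ("58", "G", False),
    ("59", "G", False),
    ("60", "ADM", True),
]
_CDR2_NOTES = {
    "55": "interacts with the bent CDR3; Ser/Tyr and small residues",
    "56": "small side chains stay partially buried; larger ones pack CDR1/CDR3",
    "57": "surface-exposed side chain; variable but polar",
    "60": "long charged residues protruding upward plus small polar ones",
}

# CDR3: 14 consecutive degenerate codons, indices 97-110. Interior positions
# are labeled by ordinal; the last three carry the design's n-2/n-1/n labels.
_CDR3_CODONS = [
    "VNN", "VRN", "WMY", "VRN", "WMY", "VNN", "WMY",
    "VRN", "WMY", "VNN", "WMY", "TWY", "VRN", "TMY",
]
_CDR3_LABELS = [f"cdr3_{i:02d}" for i in range(1, 12)] + ["115", "116", "117"]
_CDR3_NOTES = {
    "115": "n-2: buried against a hydrophobic patch; Phe/Tyr only (TWY)",
    "116": "n-1: solvent-exposed, holds the backbone turn; polar VRN",
    "117": "n: Ser/Tyr in equal proportions (TMY), Tyr most frequent",
}


def nanobody_cdr3_14_scheme() -> LibraryScheme:
    """The built-in CDR3-14 synthetic nanobody library scheme.

    25 randomized positions: 7 in CDR1 (27 DMY, 28 VRN, 30 HWY, 31 VRN,
    33 DMY, 34 VNN, 36 KMY), 4 in CDR2 (55 KMY, 56 WBG, 57 VRN, 60 ADM) and a
    14-codon CDR3 (VNN/VRN/WMY alternating, closed by TWY-VRN-TMY).  No codon
    can produce a cysteine or a stop.  The framework nucleotide sequence is a
    synthetic VHH-style framework constructed for this package (concrete
    codons only); the randomized codons and their labels are the library
    design itself.
    """
    codons: List[str] = []
    positions: List[RandomizedPosition] = []

    def emit_fixed(aa_seq: str) -> None:
        codons.extend(_BACK[a] for a in aa_seq)

    def emit_block(block, region: str, notes: Mapping[str, str]) -> None:
        for label, sym, randomized in block:
            idx = len(codons)
            if randomized:
                codons.append(sym)
                positions.append(
                    RandomizedPosition(
                        codon_index=idx,
                        label=label,
                        codon=DegenerateCodon(sym),
                        region=region,
                        note=notes.get(label, ""),
                    )
                )
            else:
                codons.append(_BACK[sym])

    emit_fixed(_FR1)
    emit_block(_CDR1, "CDR1", _CDR1_NOTES)
    emit_fixed(_FR2)
    emit_block(_CDR2, "CDR2", _CDR2_NOTES)
    emit_fixed(_FR3)
    cdr3_block = [
        (lab, cod, True) for lab, cod in zip(_CDR3_LABELS, _CDR3_CODONS)
    ]
    emit_block(cdr3_block, "CDR3", _CDR3_NOTES)
    emit_fixed(_FR4)

    template = "".join(codons)
    n = len(codons)
    annotations = {
        "FR1": (0, 75),
        "CDR1": (75, 108),
        "FR2": (108, 156),
        "CDR2": (156, 180),
        "FR3": (180, 291),
        "CDR3": (291, 333),
        "FR4": (333, 3 * n),
    }
    return LibraryScheme(
        name="nanobody-cdr3-14",
        template_nt=template,
        positions=tuple(positions),
        annotations=annotations,
        forbidden=DEFAULT_FORBIDDEN,
        metadata={
            "framework": (
                "synthetic VHH-style framework (concrete codons chosen by this "
                "package); randomized positions follow the published design"
            ),
            "position_29": "kept fixed (Glu): listed without a degenerate codon",
            "cdr3_length": "14",
        },
    )


# --------------------------------------------------------------------------
# Operations
# --------------------------------------------------------------------------


def validate_scheme(scheme: LibraryScheme) -> List[str]:
    """Check every scheme invariant; returns a list of violations (empty = valid).

    Checks: template length and alphabet; randomized template codons equal
    their declared degenerate codon; all other template positions concrete;
    label uniqueness and index bounds; and — the library-design core — that no
    randomized codon can realize a forbidden residue (default: Cys or stop).
    """
    v: List[str] = []
    t = scheme.template_nt
    if len(t) % 3 != 0:
        v.append(f"template length {len(t)} is not divisible by 3")
    try:
        for b in t:
            expand_base(b)
    except ValueError as e:
        v.append(f"template alphabet: {e}")
        return v

    labels = [p.label for p in scheme.positions]
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        v.append(f"duplicate position labels: {dupes}")

    randomized = set()
    for p in scheme.positions:
        if not (0 <= p.codon_index < scheme.n_codons):
            v.append(
                f"position {p.label}: codon_index {p.codon_index} outside "
                f"template ({scheme.n_codons} codons)"
            )
            continue
        randomized.add(p.codon_index)
        tc = scheme.template_codon(p.codon_index)
        if tc != p.codon.bases:
            v.append(
                f"position {p.label}: template codon {tc} differs from "
                f"declared degenerate codon {p.codon.bases}"
            )
        offending = check_forbidden(p.codon, scheme.forbidden)
        for residue in sorted({_residue_of(c) for c in offending}):
            name = "stop" if residue == STOP else residue
            v.append(f"position {p.label}: residue {name} reachable via {p.codon.bases}")

    for i in range(scheme.n_codons):
        if i in randomized:
            continue
        codon = scheme.template_codon(i)
        if any(b not in "ACGT" for b in codon):
            v.append(f"fixed codon {i} ({codon}) contains degenerate symbols")
    return v


def _residue_of(concrete_codon: str) -> str:
    from .codon_algebra import translate_codon

    return translate_codon(concrete_codon)


def theoretical_frequencies(scheme: LibraryScheme) -> FrequencyTable:
    """Designed per-position residue frequencies.

    At each randomized position the frequency of residue ``r`` is
    (concrete codons encoding ``r``) / (expansion size) — the distribution a
    perfectly synthesized, unbiased degenerate oligo induces.
    """
    problems = validate_scheme(scheme)
    if problems:
        raise ValueError(f"invalid scheme: {problems[0]} (+{len(problems) - 1} more)")
    rows = {
        p.label: FrequencyRow(label=p.label, counts=aa_profile(p.codon).counts)
        for p in scheme.positions
    }
    return FrequencyTable(kind="theoretical", rows=rows)


def diversity(
    scheme: LibraryScheme,
    transformants: Optional[int] = None,
) -> DiversityReport:
    """Exact DNA- and protein-level diversity and per-position entropy.

    ``dna_diversity`` is the product of codon expansion sizes over randomized
    positions; ``protein_diversity`` the product of distinct-residue counts
    (positions are independent, so the product is the exact count of distinct
    proteins).  When ``transformants`` is given (observed library size), the
    sampling ratio transformants / protein_diversity is derived.  For spaces
    up to 10^6 variants an exact occupancy expectation (expected number of
    distinct variants among the transformants) is included.
    """
    dna = 1
    protein = 1
    entropy: Dict[str, float] = {}
    for p in scheme.positions:
        prof = aa_profile(p.codon)
        dna *= prof.total_codons
        protein *= prof.n_residues
        h = -sum(
            f * math.log2(f) for f in prof.frequencies.values() if f > 0
        )
        entropy[p.label] = h
    expected = None
    if transformants is not None and protein <= _OCCUPANCY_LIMIT:
        expected = expected_distinct_variants(scheme, transformants)
    return DiversityReport(
        dna_diversity=dna,
        protein_diversity=protein,
        per_position_entropy=entropy,
        transformants=transformants,
        expected_distinct=expected,
    )


def expected_distinct_variants(scheme: LibraryScheme, n_samples: int) -> float:
    """Exact expected number of distinct protein variants in ``n_samples`` draws.

    E[distinct] = sum over variants v of 1 - (1 - p_v)^n, where p_v is the
    product of per-position residue frequencies.  Variants sharing the same
    probability are grouped (the per-position count spectra are tiny), so the
    computation is feasible whenever protein_diversity <= 10^6.
    """
    report_size = 1
    for p in scheme.positions:
        report_size *= aa_profile(p.codon).n_residues
    if report_size > _OCCUPANCY_LIMIT:
        raise ValueError(
            f"protein diversity {report_size} exceeds the exact-occupancy "
            f"limit {_OCCUPANCY_LIMIT}; only the sampling ratio is reported"
        )
    # spectrum: probability (exact Fraction) -> number of variants with it
    spectrum: Dict[Fraction, int] = {Fraction(1): 1}
    for p in scheme.positions:
        prof = aa_profile(p.codon)
        local: Dict[Fraction, int] = {}
        for count in prof.counts.values():
            f = Fraction(count, prof.total_codons)
            local[f] = local.get(f, 0) + 1
        new: Dict[Fraction, int] = {}
        for prob, mult in spectrum.items():
            for f, m in local.items():
                q = prob * f
                new[q] = new.get(q, 0) + mult * m
        spectrum = new
    return float(
        sum(
            mult * (1.0 - (1.0 - float(prob)) ** n_samples)
            for prob, mult in spectrum.items()
        )
    )


def restriction_site_risk(
    scheme: LibraryScheme, patterns: Sequence[str]
) -> List[RestrictionHit]:
    """Scan the degenerate template for restriction-site matches.

    A *guaranteed* hit is an offset where every concrete realization of the
    template contains the recognition sequence (template base set is a subset
    of the pattern base set at every position); a *possible* hit is one where
    at least one realization does (all base-set intersections non-empty).
    Randomized positions can create sites in a fraction of library members —
    a cloning hazard worth knowing before synthesis.
    """
    hits: List[RestrictionHit] = []
    t = scheme.template_nt
    for pat in patterns:
        if not pat:
            raise ValueError("empty restriction pattern")
        p = pat.upper()
        psets = [expand_base(b) for b in p]
        for off in range(len(t) - len(p) + 1):
            guaranteed = True
            possible = True
            for j, pset in enumerate(psets):
                tset = expand_base(t[off + j])
                if not (tset & pset):
                    possible = False
                    break
                if not tset <= pset:
                    guaranteed = False
            if possible:
                hits.append(RestrictionHit(pattern=p, offset=off, guaranteed=guaranteed))
    return hits
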
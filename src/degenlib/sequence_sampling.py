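"""Random library members and simulated amplicon reads.

Sampling draws each randomized position uniformly over the *concrete codons*
of its degenerate codon — the physical model of degenerate-oligo synthesis —
so the induced residue distribution is exactly the designed theoretical one,
including its deliberate skews (e.g. arginine at 6/24 under VRN).  Sampling
residues directly would erase those skews; the distinction matters and is the
reason this module samples at the codon level.

Read simulation layers a substitution-only error channel (optionally indels)
over sampled full-length ORFs and emits FASTQ, giving the verification module
an end-to-end test bench with known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List

import numpy as np
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .library_scheme import LibraryScheme, validate_scheme

__all__ = [
    "SamplingConfig",
    "ReadSimConfig",
    "sample_sequences",
    "simulate_reads",
    "write_fasta",
    "write_fastq",
]

_BASES = "ACGT"


@dataclass(frozen=True)
class SamplingConfig:
    """How many library members to draw, at which level, and with which seed."""

    n: int
    seed: int
    level: str = "dna"  # "dna" | "protein"
    id_prefix: str = "lib"

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("n must be >= 0")
        if self.level not in ("dna", "protein"):
            raise ValueError(f"level must be dna|protein, got {self.level!r}")


@dataclass(frozen=True)
class ReadSimConfig:
    """Amplicon read simulation: error rate, orientation mix, indels.

    Reads are full-ORF amplicons (as from long-read or merged paired-end
    amplicon sequencing).  ``substitution_rate`` is the per-base probability
    of an iid substitution to one of the three other bases;
    ``revcomp_fraction`` of reads are emitted reverse-complemented;
    ``indel_rate`` (default 0: frame always intact) is the per-base
    probability of a single-base insertion or deletion, for exercising
    frameshift detection downstream.
    """

    n_reads: int
    seed: int
    substitution_rate: float = 0.0
    revcomp_fraction: float = 0.0
    indel_rate: float = 0.0
    quality_char: str = "I"
    id_prefix: str = "read"

    def __post_init__(self) -> None:
        for name in ("substitution_rate", "revcomp_fraction", "indel_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if len(self.quality_char) != 1:
            raise ValueError("quality_char must be a single character")


def _require_valid(scheme: LibraryScheme) -> None:
    problems = validate_scheme(scheme)
    if problems:
        raise ValueError(f"invalid scheme: {problems[0]} (+{len(problems) - 1} more)")


def sample_sequences(
    scheme: LibraryScheme, cfg: SamplingConfig
) -> List[SeqRecord]:
    """Draw random library members from a scheme.

    Each randomized position is drawn uniformly over the lexicographically
    sorted expansion of its degenerate codon; fixed positions are copied
    verbatim.  ``level="protein"`` translates the full ORF.  A fixed seed
    gives byte-identical output across runs and platforms.
    """
    _require_valid(scheme)
    rng = np.random.default_rng(cfg.seed)
    expansions = [(p.codon_index, p.codon.expand()) for p in scheme.positions]
    template = list(
        scheme.template_nt[i : i + 3] for i in range(0, len(scheme.template_nt), 3)
    )
    records: List[SeqRecord] = []
    width = max(len(str(max(cfg.n - 1, 0))), 1)
    for k in range(cfg.n):
        codons = list(template)
        for idx, exp in expansions:
            codons[idx] = exp[rng.integers(0, len(exp))]
        nt = "".join(codons)
        seq = Seq(nt).translate() if cfg.level == "protein" else Seq(nt)
        records.append(
            SeqRecord(seq, id=f"{cfg.id_prefix}_{k:0{width}d}", description="")
        )
    return records


def simulate_reads(
    scheme: LibraryScheme, cfg: ReadSimConfig, return_molecules: bool = False
):
    """Simulate NGS amplicon reads with per-base substitution (and indel) errors.

    Ground-truth molecules are drawn exactly as :func:`sample_sequences` would
    draw them (same codon-level model); errors are then applied independently
    per base, and a ``revcomp_fraction`` subset is reverse-complemented.
    With zero error rates the reads decode back to the sampled molecules
    exactly.  FASTQ qualities are a constant placeholder.

    With ``return_molecules=True`` returns ``(reads, molecules)`` so callers
    can compare decoded reads against the error-free ground truth.
    """
    _require_valid(scheme)
    rng = np.random.default_rng(cfg.seed)
    molecules = sample_sequences(
        scheme,
        SamplingConfig(
            n=cfg.n_reads,
            seed=int(rng.integers(0, 2**31 - 1)),
            level="dna",
            id_prefix="mol",
        ),
    )
    reads: List[SeqRecord] = []
    width = max(len(str(max(cfg.n_reads - 1, 0))), 1)
    for k, mol in enumerate(molecules):
        bases = list(str(mol.seq))
        if cfg.substitution_rate > 0:
            hits = np.nonzero(rng.random(len(bases)) < cfg.substitution_rate)[0]
            for i in hits:
                alternatives = _BASES.replace(bases[i], "")
                bases[i] = alternatives[rng.integers(0, len(alternatives))]
        if cfg.indel_rate > 0:
            out: List[str] = []
            for b in bases:
                r = rng.random()
                if r < cfg.indel_rate / 2:
                    continue  # deletion
                if r < cfg.indel_rate:
                    out.append(_BASES[rng.integers(0, 4)])  # insertion before b
                out.append(b)
            bases = out
        seq = Seq("".join(bases))
        if rng.random() < cfg.revcomp_fraction:
            seq = seq.reverse_complement()
        rec = SeqRecord(seq, id=f"{cfg.id_prefix}_{k:0{width}d}", description="")
        rec.letter_annotations["phred_quality"] = [
            ord(cfg.quality_char) - 33
        ] * len(seq)
        reads.append(rec)
    if return_molecules:
        return reads, molecules
    return reads


def write_fasta(records: Iterable[SeqRecord], path) -> int:
    from Bio import SeqIO

    return SeqIO.write(records, path, "fasta")


def write_fastq(records: Iterable[SeqRecord], path) -> int:
    from Bio import SeqIO

    return SeqIO.write(records, path, "fastq")
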
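# Methods

## Model

A combinatorial library is modelled as a template ORF whose codons are either
*fixed* (concrete A/C/G/T) or *randomized* (an IUPAC degenerate codon). The
core assumption, taken from how degenerate oligos are physically synthesized,
is that a degenerate codon delivers each concrete codon of its expansion in
equal molar amounts. Every quantity in the package follows from that single
assumption:

- the theoretical residue frequency at a position with codon *c* is
  `count_c(a) / |expand(c)|`, where `count_c(a)` is the number of concrete
  codons of *c* translating to residue *a* under the standard genetic code
  (translation table 1, hard-coded; the expression host is E. coli);
- DNA diversity is the product of expansion sizes over randomized positions,
  protein diversity the product of distinct-residue counts (positions are
  independent, so both products are exact). Both are kept as exact Python
  integers — they exceed 64-bit range for realistic schemes — and the
  sampling ratio is additionally reported as a log10 to avoid float
  underflow;
- per-position Shannon entropy (bits) of the theoretical distribution
  summarizes how balanced a position is; a position with k equiprobable
  residues scores log2(k).

The stop signal is a dedicated 21st residue symbol `*`, never merged with
the amino acids: stop reachability is a distinct library failure mode
(truncated, non-displaying clones) and is tracked separately throughout.

## Built-in scheme

`nanobody_cdr3_14_scheme()` is a complete CDR3-14 synthetic nanobody design:
25 randomized positions — CDR1 27/DMY, 28/VRN, 30/HWY, 31/VRN, 33/DMY,
34/VNN, 36/KMY; CDR2 55/KMY, 56/WBG, 57/VRN, 60/ADM; and a 14-codon CDR3
alternating VNN/VRN/WMY and closing with TWY-VRN-TMY (labels 115/116/117).
Position 29 (Glu) is fixed, as are the buried packing residues 26, 32, 35,
53, 54, 58 and 59. No codon in the scheme can realize cysteine or a stop.
Position labels follow the antibody-numbering convention of the design and
are carried as opaque display strings; interior CDR3 positions, whose
numbering the convention does not pin down, are labelled by ordinal
(`cdr3_01`…`cdr3_11`). The framework nucleotide sequence is a synthetic
VHH-style framework constructed for this package (concrete codons chosen
from common E. coli usage); the randomized codons and their placement are
the design itself, and all scheme-level machinery is framework-agnostic.

## Reverse codon design

`design_codon` searches all 15³ = 3,375 degenerate codons exhaustively. Hard
constraints: every required residue encodable, no forbidden residue (default
{Cys, stop}) reachable, optional cap on off-target residues. Survivors are
ranked by:

1. fewest off-target residues (specificity),
2. **largest** expansion size,
3. highest uniformity (Shannon entropy of the encoded distribution divided
   by log2 of the number of encoded residues),
4. lexicographic codon, as a deterministic tie-break.

Preferring the largest expansion among equally specific candidates is a
deliberate choice: codons encoding the same residue set form families whose
maximal member is the canonical IUPAC description of that codon set (TWY,
not TWC or TWT, for {Phe, Tyr}), and it is the maximal codons that practical
designs use. Ranking by uniformity before expansion would instead promote
minimal two-codon representations and, for broad queries, near-uniform
subsets (e.g. VNB over VNN for the 16-residue query), neither of which
matches design practice. With `prefer_uniform` the uniformity and expansion
keys swap; with `target_frequencies` ranking switches to total variation
distance against the requested distribution, for positions designed to be
skewed rather than balanced. The search never raises on an unsatisfiable
query — it returns an explicitly infeasible result, since infeasibility is a
legitimate design answer.

There is no claim that this objective is the unique rationalization of any
particular published design; the ranking is validated by recovering the four
CDR3 codon choices (TWY, TMY, WMY, VNN) at rank 1 from their residue sets.

## Sampling and read simulation

`sample_sequences` draws each randomized position uniformly over the
*concrete codons* of its expansion — not over residues — which reproduces
the designed skews exactly (e.g. Arg at 6/24 under VRN). Sampling residues
uniformly would flatten those skews; the distinction is the reason the
sampler works at codon level. The RNG is NumPy's PCG64 (`default_rng`) with
an explicit seed per call; fixed seed implies byte-identical FASTA/FASTQ
output.

`simulate_reads` emits full-ORF amplicons (as from long-read or merged
paired-end amplicon sequencing) with iid per-base substitutions at a
configurable rate, an optional fraction of reverse-complemented reads, and
an optional indel rate (default 0, keeping reads in frame) used to exercise
frameshift detection. Qualities are a constant placeholder. The simulator
does not model platform-specific error profiles (quality-dependent error
rates, homopolymer indels), PCR bias, chimeras or synthesis bias — so
passing verification on simulated reads demonstrates correctness of the
recovery pipeline, not that any real sequencing run will be this clean.

## NGS verification

Reads are anchored by the 12-nt concrete framework segments flanking each
randomized region, matched in both orientations with at most 2 substitutions
per flank (Hamming matching; exact-width windows). The fast path checks both
flanks at their template offsets and falls back to a full scan only on
failure, so error-free data verifies in linear time. A right flank found at
an offset inconsistent with the template spacing marks the read
`frameshifted`; flanks not found anywhere mark it `unanchored`; an anchored
read whose extracted codons include a stop codon is `stop_containing` but is
still decoded and tallied (stop contamination is the key functional-fraction
QC metric). No read is silently dropped.

Observed vs designed comparison, per position: Pearson chi-square
goodness-of-fit of the observed counts against the designed proportions over
the designed support; observed residues outside the designed support
(sequencing errors, contamination) are reported as `unexpected_residues`,
excluded from the chi-square and flagged through the excluded count; total
variation distance TVD = ½·Σ|obs − design| is computed on the union support
as an effect size that does see the unexpected mass. P-values are
Benjamini–Hochberg corrected across positions (default FDR 0.05) — with 25
positions, uncorrected per-position testing at α = 0.01 would produce a
false alarm in roughly a fifth of perfectly clean runs, so the family-level
corrected decision is the one the report (and the test suite) acts on.
Positions with fewer than 50 decoded reads are reported descriptive-only:
below that the chi-square approximation and the test's power are both poor.

## Numerical and degenerate-input choices

- Expansions and all candidate lists are lexicographically sorted; every
  ranking ends in a lexicographic tie-break — outputs are byte-stable across
  runs and platforms.
- Inputs are normalized to uppercase; RNA `U` is accepted and mapped to `T`.
- Uniformity of a single-residue codon is defined as 1.0 (the zero-entropy /
  zero-log2 limit).
- A scheme with zero randomized positions is legal: diversities are the
  empty product, 1.
- The exact occupancy expectation E[distinct variants among n draws]
  = Σ_v (1 − (1 − p_v)^n) is computed by grouping variants by probability
  (exact `Fraction` arithmetic) and is offered only for protein spaces up to
  10⁶; beyond that only the sampling ratio is reported, which is all a
  realistic library comparison needs.

## Test and verification scales

The suite verifies the codon algebra exhaustively (all 3,375 codons against
a brute-force expand-translate-tally oracle), protein diversity against
brute-force enumeration on small schemes, and the verification pipeline
end-to-end with 10,000 simulated reads (error-free: 100% anchoring, bitwise
tally round-trip, no BH-corrected rejection; 0.5% substitutions: nonzero
unexpected-residue and stop fractions). Smaller read counts (300–2,000) are
used for the per-feature tests; all stochastic tests run with fixed seeds.

## Known limitations

- Single-codon designs only: one degenerate codon per position. Mixtures of
  oligos or trimer-phosphoramidite (codon-by-codon) synthesis, which can hit
  arbitrary residue distributions, are out of scope.
- Anchoring is substitution-tolerant but not indel-tolerant within a flank;
  indel-containing reads are flagged, not rescued. For substitution-dominated
  amplicon QC this is the right trade-off; for noisy long reads a proper
  aligner would be needed.
- No codon-usage optimization for the expression host, no mRNA secondary
  structure or codon-pair effects, no UMI handling, chimera detection or
  enrichment analysis.
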
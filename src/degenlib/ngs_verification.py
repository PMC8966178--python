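"""Verify a constructed library against its design from sequencing reads.

The question this module answers is the standard QC question for a synthetic
combinatorial library: *does the DNA that was actually synthesized and cloned
show, at every randomized position, the amino-acid diversity and frequencies
the degenerate codons were designed to produce?*

The pipeline is: anchor each amplicon read to the template by matching the
concrete framework segments flanking each randomized region (substitution-
tolerant Hamming matching, both orientations); extract the concrete codon at
every randomized position; translate and tally into an observed frequency
table; then compare observed against theoretical per position with a Pearson
chi-square goodness-of-fit test (Benjamini-Hochberg corrected across
positions) and total variation distance as an effect size.  Stop-codon
observations are tallied under the stop symbol, never discarded: the
stop-free ("functional") read fraction is itself a key QC number.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .codon_algebra import STOP, translate_codon
from .library_scheme import (
    FrequencyRow,
    FrequencyTable,
    LibraryScheme,
    theoretical_frequencies,
    validate_scheme,
)

__all__ = [
    "AnchoredRead",
    "PositionComparison",
    "ComparisonReport",
    "anchor_reads",
    "observed_frequencies",
    "compare_frequencies",
    "verify_reads",
]

#: Framework flank length used for anchoring, in nucleotides.
FLANK_LEN = 12

#: Positions with fewer decoded reads than this are reported descriptive-only.
MIN_COUNT_FOR_TEST = 50

_COMP = str.maketrans("ACGTN", "TGCAN")


def _revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


# --------------------------------------------------------------------------
# Anchoring
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class AnchoredRead:
    """One read after template anchoring.

    ``status`` is ``ok`` (all randomized codons extracted, no stop),
    ``stop_containing`` (extracted fine but at least one randomized codon is
    a stop codon — still decodable and still tallied), ``frameshifted``
    (flank spacing inconsistent with the template, i.e. an indel), or
    ``unanchored`` (framework flanks not found).
    """

    read_id: str
    orientation: str  # "forward" | "revcomp" | "unknown"
    extracted_codons: Mapping[str, str]
    status: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "extracted_codons", dict(self.extracted_codons))

    @property
    def decoded(self) -> bool:
        return self.status in ("ok", "stop_containing")


@dataclass(frozen=True)
class _Region:
    """A contiguous randomized span with its concrete flanks."""

    name: str
    nt_start: int            # first nt of the span (template coords)
    nt_end: int              # one past the last nt of the span
    left_flank: str          # FLANK_LEN concrete nt ending at nt_start
    right_flank: str         # FLANK_LEN concrete nt starting at nt_end
    codon_offsets: Tuple[Tuple[str, int], ...]  # (label, nt offset from nt_start)


def _build_regions(scheme: LibraryScheme) -> List[_Region]:
    by_region: Dict[str, List] = {}
    for p in scheme.positions:
        by_region.setdefault(p.region or p.label, []).append(p)
    regions: List[_Region] = []
    for name, positions in by_region.items():
        positions = sorted(positions, key=lambda p: p.codon_index)
        start = 3 * positions[0].codon_index
        end = 3 * positions[-1].codon_index + 3
        if start < FLANK_LEN or end + FLANK_LEN > len(scheme.template_nt):
            raise ValueError(
                f"region {name!r}: not enough template on both sides for "
                f"{FLANK_LEN}-nt anchoring flanks"
            )
        left = scheme.template_nt[start - FLANK_LEN : start]
        right = scheme.template_nt[end : end + FLANK_LEN]
        for flank, side in ((left, "left"), (right, "right")):
            if any(b not in "ACGT" for b in flank):
                raise ValueError(
                    f"region {name!r}: {side} flank {flank} is not fully "
                    f"concrete; cannot anchor"
                )
        regions.append(
            _Region(
                name=name,
                nt_start=start,
                nt_end=end,
                left_flank=left,
                right_flank=right,
                codon_offsets=tuple(
                    (p.label, 3 * p.codon_index - start) for p in positions
                ),
            )
        )
    regions.sort(key=lambda r: r.nt_start)
    return regions


def _hamming_at(read: str, offset: int, anchor: str) -> int:
    if offset < 0 or offset + len(anchor) > len(read):
        return len(anchor) + 1
    return sum(a != b for a, b in zip(read[offset : offset + len(anchor)], anchor))


def _scan(read_arr: np.ndarray, anchor: str, max_mm: int) -> Optional[int]:
    """Best-matching offset of anchor in read (Hamming <= max_mm), else None."""
    la = len(anchor)
    if len(read_arr) < la:
        return None
    anchor_arr = np.frombuffer(anchor.encode(), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(read_arr, la)
    mism = (windows != anchor_arr).sum(axis=1)
    best = int(mism.argmin())
    if mism[best] <= max_mm:
        return best
    return None


def _try_orientation(
    read: str, regions: Sequence[_Region], max_mm: int
) -> Tuple[Dict[str, str], int, bool]:
    """Anchor all regions in one orientation.

    Returns (extracted codons, number of anchored regions, frameshift seen).
    Fast path: check both flanks at their template offsets (no-indel reads);
    fall back to a full scan per flank only when that fails.
    """
    extracted: Dict[str, str] = {}
    anchored = 0
    frameshift = False
    read_arr: Optional[np.ndarray] = None
    for reg in regions:
        exp_left = reg.nt_start - FLANK_LEN
        exp_right = reg.nt_end
        left_off: Optional[int] = None
        if _hamming_at(read, exp_left, reg.left_flank) <= max_mm:
            left_off = exp_left
        else:
            if read_arr is None:
                read_arr = np.frombuffer(read.encode(), dtype=np.uint8)
            left_off = _scan(read_arr, reg.left_flank, max_mm)
        if left_off is None:
            continue
        span_start = left_off + FLANK_LEN
        span_len = reg.nt_end - reg.nt_start
        right_expected = span_start + span_len
        if _hamming_at(read, right_expected, reg.right_flank) <= max_mm:
            anchored += 1
            for label, delta in reg.codon_offsets:
                extracted[label] = read[span_start + delta : span_start + delta + 3]
        else:
            if read_arr is None:
                read_arr = np.frombuffer(read.encode(), dtype=np.uint8)
            elsewhere = _scan(read_arr, reg.right_flank, max_mm)
            if elsewhere is not None and elsewhere != right_expected:
                frameshift = True  # flank spacing inconsistent with the template
    return extracted, anchored, frameshift


def anchor_reads(
    reads: Iterable,
    scheme: LibraryScheme,
    max_mismatches: int = 2,
) -> List[AnchoredRead]:
    """Locate each read on the template and extract the randomized codons.

    Each read is tried in both orientations; the orientation anchoring more
    randomized regions wins (forward on ties).  Anchors are the
    ``FLANK_LEN``-nt concrete framework segments flanking each randomized
    region, matched with at most ``max_mismatches`` substitutions per flank.
    Reads that cannot be anchored are flagged, never silently dropped.

    ``reads`` may be Bio.SeqRecord objects or ``(id, sequence)`` pairs.
    """
    problems = validate_scheme(scheme)
    if problems:
        raise ValueError(f"invalid scheme: {problems[0]} (+{len(problems) - 1} more)")
    regions = _build_regions(scheme)
    n_regions = len(regions)
    results: List[AnchoredRead] = []
    for rec in reads:
        if hasattr(rec, "seq"):
            read_id, seq = rec.id, str(rec.seq).upper()
        else:
            read_id, seq = rec[0], str(rec[1]).upper()
        fwd = _try_orientation(seq, regions, max_mismatches)
        if fwd[1] == n_regions and not fwd[2]:
            chosen, orientation = fwd, "forward"
        else:
            rev = _try_orientation(_revcomp(seq), regions, max_mismatches)
            if rev[1] > fwd[1]:
                chosen, orientation = rev, "revcomp"
            elif fwd[1] > 0 or fwd[2]:
                chosen, orientation = fwd, "forward"
            elif rev[2]:
                chosen, orientation = rev, "revcomp"
            else:
                chosen, orientation = fwd, "unknown"
        extracted, anchored, frameshift = chosen
        if anchored == n_regions:
            has_stop = any(
                translate_codon(c) == STOP for c in extracted.values()
            )
            status = "stop_containing" if has_stop else "ok"
        elif frameshift:
            status = "frameshifted"
        else:
            status = "unanchored"
            orientation = orientation if anchored else "unknown"
        results.append(
            AnchoredRead(
                read_id=read_id,
                orientation=orientation,
                extracted_codons=extracted,
                status=status,
            )
        )
    return results


# --------------------------------------------------------------------------
# Frequency recovery and comparison
# --------------------------------------------------------------------------


def observed_frequencies(anchored: Sequence[AnchoredRead]) -> FrequencyTable:
    """Tally translated codons per randomized position over decoded reads.

    Decoded = status ``ok`` or ``stop_containing``; stop observations are
    counted under the stop symbol.  Raises if no read is decodable.
    """
    counts: Dict[str, Dict[str, int]] = {}
    usable = 0
    for ar in anchored:
        if not ar.decoded:
            continue
        usable += 1
        for label, codon in ar.extracted_codons.items():
            r = translate_codon(codon)
            row = counts.setdefault(label, {})
            row[r] = row.get(r, 0) + 1
    if usable == 0:
        raise ValueError("no read could be decoded (zero usable reads)")
    rows = {
        label: FrequencyRow(label=label, counts=c) for label, c in counts.items()
    }
    return FrequencyTable(kind="observed", rows=rows)


@dataclass(frozen=True)
class PositionComparison:
    """Observed vs designed residue distribution at one randomized position."""

    label: str
    observed_counts: Mapping[str, int]
    theoretical_freqs: Mapping[str, float]
    n: int                       # decoded reads at this position
    tvd: float                   # 0.5 * L1 distance, on the union support
    unexpected_residues: Tuple[str, ...]  # observed but designed frequency 0
    chi2: Optional[float] = None
    df: Optional[int] = None
    pvalue: Optional[float] = None
    tested: bool = False
    chi2_excluded_count: int = 0  # observations excluded from the chi-square

    def __post_init__(self) -> None:
        object.__setattr__(self, "observed_counts", dict(self.observed_counts))
        object.__setattr__(self, "theoretical_freqs", dict(self.theoretical_freqs))


@dataclass(frozen=True)
class ComparisonReport:
    """Per-position goodness-of-fit plus whole-run read accounting."""

    positions: Mapping[str, PositionComparison]
    status_fractions: Mapping[str, float]
    n_reads: int
    fdr: float
    rejected: Tuple[str, ...]    # labels rejected after BH correction

    def __post_init__(self) -> None:
        object.__setattr__(self, "positions", dict(self.positions))
        object.__setattr__(self, "status_fractions", dict(self.status_fractions))

    @property
    def functional_read_fraction(self) -> float:
        """Stop-free fraction among decoded reads."""
        ok = self.status_fractions.get("ok", 0.0)
        stop = self.status_fractions.get("stop_containing", 0.0)
        return ok / (ok + stop) if (ok + stop) > 0 else 0.0

    @property
    def max_tvd(self) -> float:
        return max(p.tvd for p in self.positions.values())

    def any_unexpected(self) -> bool:
        return any(p.unexpected_residues for p in self.positions.values())

    def to_dict(self) -> dict:
        return {
            "n_reads": self.n_reads,
            "status_fractions": dict(self.status_fractions),
            "functional_read_fraction": self.functional_read_fraction,
            "fdr": self.fdr,
            "rejected_positions": list(self.rejected),
            "positions": {
                label: {
                    "n": p.n,
                    "observed_counts": dict(sorted(p.observed_counts.items())),
                    "theoretical_freqs": dict(sorted(p.theoretical_freqs.items())),
                    "chi2": p.chi2,
                    "df": p.df,
                    "pvalue": p.pvalue,
                    "tested": p.tested,
                    "tvd": p.tvd,
                    "unexpected_residues": list(p.unexpected_residues),
                }
                for label, p in self.positions.items()
            },
        }


def compare_frequencies(
    observed: FrequencyTable,
    theoretical: FrequencyTable,
    fdr: float = 0.05,
    min_count: int = MIN_COUNT_FOR_TEST,
    status_counts: Optional[Mapping[str, int]] = None,
) -> ComparisonReport:
    """Per-position Pearson chi-square and TVD of observed vs designed.

    The chi-square is computed over the designed support; observed residues
    outside it (sequencing errors, contamination) are reported as
    ``unexpected_residues`` and excluded from the test, which is then flagged
    through ``chi2_excluded_count``.  TVD is computed on the union support,
    so unexpected residues do contribute to the effect size.  Positions with
    fewer than ``min_count`` decoded reads are descriptive-only.  P-values
    are Benjamini-Hochberg corrected across tested positions at ``fdr``.
    """
    if observed.kind != "observed" or theoretical.kind != "theoretical":
        raise ValueError("expected one observed and one theoretical table")
    obs_labels = set(observed.rows)
    theo_labels = set(theoretical.rows)
    if obs_labels != theo_labels:
        raise ValueError(
            f"position sets differ: only-observed={sorted(obs_labels - theo_labels)}, "
            f"only-theoretical={sorted(theo_labels - obs_labels)}"
        )

    comparisons: Dict[str, PositionComparison] = {}
    for label in theoretical.rows:
        theo = theoretical.frequencies(label)
        obs_row = observed.rows[label]
        n = obs_row.n
        if n == 0:
            raise ValueError(f"position {label}: zero observed counts")
        obs_freq = obs_row.frequencies
        support = sorted(set(theo) | set(obs_freq))
        tvd = 0.5 * sum(
            abs(obs_freq.get(r, 0.0) - theo.get(r, 0.0)) for r in support
        )
        unexpected = tuple(
            sorted(r for r in obs_freq if theo.get(r, 0.0) == 0.0)
        )
        in_support = {r: c for r, c in obs_row.counts.items() if r in theo}
        excluded = n - sum(in_support.values())
        n_used = sum(in_support.values())
        chi2 = df = pvalue = None
        tested = False
        if n_used >= min_count:
            cats = sorted(theo)
            f_obs = np.array([in_support.get(r, 0) for r in cats], dtype=float)
            f_exp = np.array([theo[r] * n_used for r in cats], dtype=float)
            chi2_stat, pvalue = stats.chisquare(f_obs, f_exp)
            chi2 = float(chi2_stat)
            pvalue = float(pvalue)
            df = len(cats) - 1
            tested = True
        comparisons[label] = PositionComparison(
            label=label,
            observed_counts=obs_row.counts,
            theoretical_freqs=theo,
            n=n,
            tvd=tvd,
            unexpected_residues=unexpected,
            chi2=chi2,
            df=df,
            pvalue=pvalue,
            tested=tested,
            chi2_excluded_count=excluded,
        )

    tested_labels = [l for l, p in comparisons.items() if p.tested]
    rejected: Tuple[str, ...] = ()
    if tested_labels:
        pvals = [comparisons[l].pvalue for l in tested_labels]
        reject, *_ = multipletests(pvals, alpha=fdr, method="fdr_bh")
        rejected = tuple(
            l for l, rej in zip(tested_labels, reject) if rej
        )

    counts = dict(status_counts or {})
    total = sum(counts.values())
    fractions = (
        {s: c / total for s, c in sorted(counts.items())} if total else {}
    )
    return ComparisonReport(
        positions=comparisons,
        status_fractions=fractions,
        n_reads=total,
        fdr=fdr,
        rejected=rejected,
    )


def verify_reads(
    reads: Iterable,
    scheme: LibraryScheme,
    max_mismatches: int = 2,
    fdr: float = 0.05,
    min_count: int = MIN_COUNT_FOR_TEST,
) -> Tuple[ComparisonReport, FrequencyTable]:
    """End-to-end verification: anchor, tally, compare against the design.

    Returns the comparison report and the observed frequency table.
    """
    anchored = anchor_reads(reads, scheme, max_mismatches=max_mismatches)
    status_counts: Dict[str, int] = {}
    for ar in anchored:
        status_counts[ar.status] = status_counts.get(ar.status, 0) + 1
    observed = observed_frequencies(anchored)
    theoretical = theoretical_frequencies(scheme)
    report = compare_frequencies(
        observed,
        theoretical,
        fdr=fdr,
        min_count=min_count,
        status_counts=status_counts,
    )
    return report, observed


def plot_frequency_comparison(
    observed: FrequencyTable,
    theoretical: FrequencyTable,
    path,
) -> None:
    """Paired-bar observed-vs-designed frequency plot, one panel per position.

    Requires matplotlib (optional dependency).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = list(theoretical.rows)
    ncols = 5
    nrows = (len(labels) + ncols - 1) // ncols
    fig, axes = plt.subplots(
        nrows, ncols, figsize=(4 * ncols, 2.5 * nrows), squeeze=False
    )
    for ax in axes.flat[len(labels):]:
        ax.axis("off")
    for ax, label in zip(axes.flat, labels):
        theo = theoretical.frequencies(label)
        obs = observed.frequencies(label)
        residues = sorted(set(theo) | set(obs))
        x = np.arange(len(residues))
        ax.bar(x - 0.2, [obs.get(r, 0) for r in residues], 0.4, label="observed")
        ax.bar(x + 0.2, [theo.get(r, 0) for r in residues], 0.4, label="designed")
        ax.set_xticks(x)
        ax.set_xticklabels(residues, fontsize=7)
        ax.set_title(f"position {label}", fontsize=9)
    axes.flat[0].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
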
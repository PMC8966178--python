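import pytest

from degenlib import (
    DegenerateCodon,
    LibraryScheme,
    RandomizedPosition,
    nanobody_cdr3_14_scheme,
)

# Concrete 15-nt flanks (>= 12 nt required for read anchoring).
LEFT_FLANK = "GCAGCTGCAACTGGT"
RIGHT_FLANK = "GGTACCGCTAGCACT"


def make_scheme(codon_strs, forbidden=("C", "*"), name="synthetic-test"):
    """Small synthetic scheme: one randomized block between concrete flanks."""
    template = LEFT_FLANK + "".join(codon_strs) + RIGHT_FLANK
    offset = len(LEFT_FLANK) // 3
    positions = tuple(
        RandomizedPosition(
            codon_index=offset + i,
            label=f"p{i + 1}",
            codon=DegenerateCodon(c),
            region="R1",
        )
        for i, c in enumerate(codon_strs)
    )
    return LibraryScheme(
        name=name,
        template_nt=template,
        positions=positions,
        annotations={"R1": (len(LEFT_FLANK), len(LEFT_FLANK) + 3 * len(codon_strs))},
        forbidden=frozenset(forbidden),
    )


@pytest.fixture(scope="session")
def builtin_scheme():
    return nanobody_cdr3_14_scheme()


@pytest.fixture()
def cdr2_scheme():
    """The CDR2 sub-design as a standalone scheme (KMY, WBG, VRN, ADM)."""
    return make_scheme(["KMY", "WBG", "VRN", "ADM"], name="cdr2-only")
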
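"""Kissing-loop and nanostar sequence arithmetic.

Single-stranded RNA nanostars interact through kissing loops (KLs):
hairpin loops whose exposed bases pair with the loop of a partner hairpin
without strand exchange. The design rules implemented here:

* A KL domain is nine nucleotides long: a six-nt interaction sequence
  flanked by three unpaired adenines, two upstream and one downstream
  (5'-AA<interaction>A-3').
* A palindromic interaction sequence (equal to its own reverse complement)
  binds itself — one nanostar species suffices. Non-palindromic sequences
  must be designed as complementary heterodimer pairs, which expands the
  usable design space: of the 4^6 = 4096 RNA 6-mers only 4^3 = 64 are
  palindromes, so allowing non-palindromes grows the space 64-fold.
* Heterodimer pairs for two-nanostar systems carry four G/C and two A/U
  bases per 6-mer so that all pairs have similar bond stability.
* A three-arm nanostar strand is stems joined by spacers: two inter-arm
  spacers are "AA", the third is a nick (the strand's own termini).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

from .errors import SequenceError

__all__ = [
    "RNA_ALPHABET",
    "reverse_complement_rna",
    "is_palindromic_kl",
    "kl_design_space",
    "validate_kl_pair",
    "KlPairReport",
    "Arm",
    "NanostarDesign",
    "assemble_single_stranded_nanostar",
    "dna_template",
    "KL_FLANK_5",
    "KL_FLANK_3",
    "WT_KL",
]

RNA_ALPHABET = frozenset("ACGU")
_RC = str.maketrans("ACGU", "UGCA")

KL_FLANK_5 = "AA"  # unpaired adenines upstream of the interaction sequence
KL_FLANK_3 = "A"  # unpaired adenine downstream
SPACER = "AA"  # inter-arm spacer (two unpaired adenines)
WT_KL = "GCGCGC"  # palindromic wild-type HIV-1 kissing-loop sequence

T7_PROMOTER = "TAATACGACTCACTATA"
SEALING_DOMAIN = "GCGC"  # 4-nt sealing domain closing the promoter duplex
_DNA_RC = str.maketrans("ACGT", "TGCA")


def _check_rna(seq: str) -> str:
    if not seq:
        raise SequenceError("empty sequence")
    bad = set(seq.upper()) - RNA_ALPHABET
    if bad:
        raise SequenceError(f"non-AUGC characters in RNA sequence: {sorted(bad)}")
    return seq.upper()


def reverse_complement_rna(seq: str) -> str:
    """Reverse complement of an RNA sequence (A<->U, G<->C), 5'->3'."""
    return _check_rna(seq).translate(_RC)[::-1]


def is_palindromic_kl(seq: str) -> bool:
    """True iff the sequence equals its own reverse complement.

    Such a sequence dimerizes with itself (homodimer); odd-length
    sequences can never be palindromic because the central base would
    have to pair with itself.
    """
    seq = _check_rna(seq)
    if len(seq) % 2 == 1:
        return False
    return seq == reverse_complement_rna(seq)


class DesignSpace(NamedTuple):
    total: int
    palindromic: int
    fold_expansion: float | None  # None when k is odd (no palindromes exist)


def kl_design_space(k: int) -> DesignSpace:
    """Count the k-mer interaction-sequence design space.

    ``total = 4^k`` sequences; a palindrome is fixed by its first k/2
    bases, so ``palindromic = 4^(k/2)`` for even k and 0 for odd k. The
    fold expansion gained by allowing non-palindromic (heterodimer)
    designs is total/palindromic = 4^(k/2); for k = 6 that is 64.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    total = 4**k
    if k % 2 == 0:
        palindromic = 4 ** (k // 2)
        return DesignSpace(total, palindromic, total / palindromic)
    return DesignSpace(total, 0, None)


@dataclass
class KlPairReport:
    """Checks for a candidate heterodimer KL interaction pair."""

    complementary: bool
    composition_ok: bool  # exactly 4 G/C and 2 A/U bases in each 6-mer
    palindromic_members: tuple[bool, bool]
    valid: bool


def _composition_ok(seq: str) -> bool:
    gc = sum(b in "GC" for b in seq)
    return gc == 4 and len(seq) - gc == 2


def validate_kl_pair(a: str, b: str) -> KlPairReport:
    """Validate a candidate two-nanostar KL heterodimer pair.

    The pair is valid when b is the reverse complement of a, each member
    carries exactly four G/C and two A/U bases (similar duplex stability
    across designs), and neither member is palindromic (a palindrome would
    homodimerize instead of pairing only with its partner). Wobble G.U
    pairs are not counted as complementary.
    """
    a, b = _check_rna(a), _check_rna(b)
    if len(a) != 6 or len(b) != 6:
        raise SequenceError("KL interaction sequences must be 6 nt")
    complementary = b == reverse_complement_rna(a)
    composition = _composition_ok(a) and _composition_ok(b)
    pal = (is_palindromic_kl(a), is_palindromic_kl(b))
    valid = complementary and composition and not any(pal)
    return KlPairReport(complementary, composition, pal, valid)


@dataclass
class Arm:
    """One stem arm as its two strand halves, 5' half and 3' half.

    A closed stem requires the 3' half to be the reverse complement of the
    5' half.
    """

    five_half: str
    three_half: str


@dataclass
class NanostarDesign:
    """Three-arm single-stranded nanostar: stems plus one KL sequence."""

    arms: list[Arm]
    kl_interaction: str

    def __post_init__(self) -> None:
        if len(self.arms) != 3:
            raise SequenceError("single-stranded nanostar designs have 3 arms")
        if len(_check_rna(self.kl_interaction)) != 6:
            raise SequenceError("KL interaction sequence must be 6 nt")


def kl_domain(interaction: str) -> str:
    """The 9-nt KL domain: 5'-AA + interaction + A-3'."""
    interaction = _check_rna(interaction)
    return KL_FLANK_5 + interaction + KL_FLANK_3


def assemble_single_stranded_nanostar(design: NanostarDesign) -> str:
    """Assemble the full nanostar strand, 5'->3'.

    Layout: arm1_5' KL arm1_3' AA arm2_5' KL arm2_3' AA arm3_5' KL arm3_3',
    where KL is the 9-nt kissing-loop domain closing each stem into a
    hairpin and AA are the two-adenine inter-arm spacers. The third spacer
    is a nick, realized as the strand's two ends. Raises if any stem would
    not close (arm halves not reverse-complementary).
    """
    domain = kl_domain(design.kl_interaction)
    parts = []
    for i, arm in enumerate(design.arms, start=1):
        five = _check_rna(arm.five_half)
        three = _check_rna(arm.three_half)
        if three != reverse_complement_rna(five):
            raise SequenceError(
                f"arm {i} stem does not close: 3' half is not the reverse "
                "complement of the 5' half"
            )
        parts.append(five + domain + three)
    return SPACER.join(parts)


def dna_template(rna_strand: str) -> dict[str, str]:
    """Non-coding DNA template and promoter-complement strand for a transcript.

    The template is the DNA reverse complement of the T7 promoter followed
    by the transcript; it is annealed to a 21-nt top strand consisting of
    the 17-nt promoter plus the 4-nt sealing domain 5'-GCGC that pairs
    with the first transcribed bases. A transcript that does not begin
    with GCGC will leave the sealing domain unpaired.
    """
    rna = _check_rna(rna_strand)
    coding_dna = T7_PROMOTER + rna.replace("U", "T")
    if not rna.startswith(SEALING_DOMAIN):
        import warnings

        warnings.warn(
            "transcript does not begin with the GCGC sealing domain; the "
            "21-nt promoter complement will not seal this template",
            stacklevel=2,
        )
    return {
        "noncoding_template": coding_dna.translate(_DNA_RC)[::-1],
        "promoter_complement": T7_PROMOTER + SEALING_DOMAIN,
    }
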
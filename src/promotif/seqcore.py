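"""Nucleic-acid alphabet handling and the partial-match motif model.

A :class:`NucSeq` stores residues over ``{A, C, G, T, N}`` after
normalization (uppercase, ``U`` mapped to ``T``) together with a tag
recording whether the source text was DNA or RNA.  A :class:`Motif` is a
DNA word plus a minimum contiguous match length; the screen it drives
considers every contiguous sub-word of the motif of at least that length,
in both the forward orientation and the reverse complement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

__all__ = [
    "NucSeq",
    "Motif",
    "SearchWord",
    "normalize",
    "uppercase_mask",
    "reverse_complement",
    "motif_from_rna",
    "enumerate_search_words",
]

#: IUPAC nucleotide one-letter codes accepted on input.
IUPAC_LETTERS = frozenset("ACGTUNRYSWKMBDHV")

#: Degenerate IUPAC codes collapse to N: the screen is exact-match only
#: and N never matches anything, so degeneracy cannot create hits.
_DEGENERATE = frozenset("RYSWKMBDHV")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class NucSeq:
    """An immutable normalized nucleotide sequence.

    Parameters
    ----------
    residues
        Uppercase residues over ``{A, C, G, T, N}``.
    alphabet_tag
        ``"DNA"`` or ``"RNA"``, recording the source alphabet.  The
        residues themselves are always stored in the DNA alphabet.
    """

    residues: str
    alphabet_tag: str = "DNA"

    def __post_init__(self) -> None:
        if self.alphabet_tag not in ("DNA", "RNA"):
            raise ValueError(f"alphabet_tag must be DNA or RNA, got {self.alphabet_tag!r}")
        bad = set(self.residues) - set("ACGTN")
        if bad:
            raise ValueError(f"non-normalized residues {sorted(bad)!r}; use normalize()")

    def __len__(self) -> int:
        return len(self.residues)

    def __str__(self) -> str:
        return self.residues


class SearchWord(NamedTuple):
    """A concrete word searched for during a scan, with its orientation tag."""

    word: str
    orientation: str  # "forward" | "reverse"


def normalize(raw: str, alphabet: str | None = None) -> NucSeq:
    """Normalize raw sequence text into a :class:`NucSeq`.

    Uppercases, strips whitespace, maps ``U``→``T`` and degenerate IUPAC
    codes to ``N``.  The alphabet tag is inferred (``RNA`` iff the text
    contains ``U``/``u``) unless *alphabet* is given explicitly.

    Raises
    ------
    ValueError
        If *raw* is empty after stripping, or contains a non-IUPAC
        character (the error names the offending 1-based position).
    """
    stripped = "".join(raw.split())
    if not stripped:
        raise ValueError("empty sequence")
    upper = stripped.upper()
    for pos, ch in enumerate(upper, start=1):
        if ch not in IUPAC_LETTERS:
            raise ValueError(f"non-IUPAC character {ch!r} at position {pos}")
    if alphabet is None:
        alphabet = "RNA" if "U" in upper else "DNA"
    residues = upper.replace("U", "T")
    residues = "".join("N" if c in _DEGENERATE else c for c in residues)
    return NucSeq(residues, alphabet_tag=alphabet)


def uppercase_mask(raw: str) -> tuple[bool, ...]:
    """Per-base flags recording which input characters were uppercase.

    Whitespace is stripped first, so the mask aligns with the residues of
    ``normalize(raw)``.  Kept separate from :func:`normalize` because case
    is annotation (e.g. promoter position relative to the TSS in some
    database exports), never matching semantics.
    """
    stripped = "".join(raw.split())
    return tuple(c.isupper() for c in stripped)


def reverse_complement(s: NucSeq) -> NucSeq:
    """Watson-Crick reverse complement, returned in the DNA alphabet.

    ``N`` maps to ``N``.  The operation is an involution.
    """
    return NucSeq(s.residues.translate(_COMPLEMENT)[::-1], alphabet_tag="DNA")


@dataclass(frozen=True)
class Motif:
    """A DNA search motif with a minimum contiguous match length.

    Invariants: ``1 <= min_match <= len(word)`` and the word contains no
    ``N`` (exact matching only).
    """

    word: NucSeq
    min_match: int = 10
    label: str = ""

    def __post_init__(self) -> None:
        if self.word.alphabet_tag != "DNA":
            raise ValueError("motif word must be DNA")
        if len(self.word) == 0:
            raise ValueError("motif word is empty")
        if "N" in self.word.residues:
            raise ValueError("motif word must not contain N")
        if not 1 <= self.min_match <= len(self.word):
            raise ValueError(
                f"min_match must be in [1, {len(self.word)}], got {self.min_match}"
            )


def motif_from_rna(rna: NucSeq, start: int, end: int, min_match: int = 10,
                   label: str = "") -> Motif:
    """Build the DNA motif complementary to an RNA sub-segment.

    *start* and *end* are 1-based inclusive positions within *rna*.  The
    motif word is the DNA reverse complement of the selected segment,
    i.e. the duplex DNA word the RNA segment would read along.
    """
    if rna.alphabet_tag != "RNA":
        raise ValueError("motif_from_rna expects an RNA-tagged sequence")
    if not (1 <= start <= end <= len(rna)):
        raise ValueError(
            f"coordinates [{start}, {end}] out of range for length {len(rna)}"
        )
    segment = NucSeq(rna.residues[start - 1:end], alphabet_tag="DNA")
    word = reverse_complement(segment)
    return Motif(word=word, min_match=min(min_match, len(word)), label=label)


def enumerate_search_words(m: Motif) -> set[SearchWord]:
    """All distinct contiguous sub-words of the motif at or above min_match.

    Sub-words of the motif word are tagged ``forward``; sub-words of its
    reverse complement are tagged ``reverse``.  Duplicates within one
    orientation collapse (hits are reported by position, so nothing is
    lost); the same word appearing in both orientations is kept once per
    orientation tag.
    """
    words: set[SearchWord] = set()
    for text, orientation in (
        (m.word.residues, "forward"),
        (reverse_complement(m.word).residues, "reverse"),
    ):
        for length in range(m.min_match, len(text) + 1):
            for i in range(len(text) - length + 1):
                words.add(SearchWord(text[i:i + length], orientation))
    return words
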
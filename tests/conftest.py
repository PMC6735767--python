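from __future__ import annotations

import random

import pytest

from promotif.promoter_io import load_panel_fixture
from promotif.seqcore import Motif, normalize

MOTIF_WORD = "GGCCACCACCCC"
MOTIF_RC = "GGGGTGGTGGCC"


@pytest.fixture(scope="session")
def screen_motif() -> Motif:
    """The 12-nt binding-motif query used throughout, min_match=10."""
    return Motif(word=normalize(MOTIF_WORD, alphabet="DNA"), min_match=10)


@pytest.fixture(scope="session")
def panel():
    """The bundled 30-promoter panel (checksummed fixture)."""
    return load_panel_fixture()


@pytest.fixture()
def rng() -> random.Random:
    return random.Random(20240917)


def brute_force_scan(text: str, word: str, min_match: int,
                     maximal_only: bool = True) -> set[tuple[int, int, str]]:
    """Independent window oracle for the motif scan.

    Tests every window of every length >= min_match for containment in
    the motif word (forward) or its reverse complement (reverse), then
    optionally removes windows properly contained in another window of
    the same orientation.
    """
    rc = word[::-1].translate(str.maketrans("ACGTN", "TGCAN"))
    found: set[tuple[int, int, str]] = set()
    for target, orientation in ((word, "forward"), (rc, "reverse")):
        for length in range(min_match, len(word) + 1):
            for i in range(len(text) - length + 1):
                if text[i:i + length] in target:
                    found.add((i, i + length, orientation))
    if not maximal_only:
        return found
    maximal = set()
    for a in found:
        contained = any(
            b != a and b[2] == a[2] and b[0] <= a[0] and a[1] <= b[1]
            for b in found
        )
        if not contained:
            maximal.add(a)
    return maximal
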
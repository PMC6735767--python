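"""The promoter screen: maximal partial-motif matches in promoter records.

The scan enumerates every contiguous sub-word of the motif (and of its
reverse complement) at or above the minimum match length, locates all
occurrences in each promoter, and keeps the maximal ones: a hit is
dropped only if its interval is properly contained in another hit of the
same orientation.  Overlapping hits of opposite orientation are both
reported.  The word set is tiny, so multi-pattern search plus a post-hoc
maximality filter is both fast and directly comparable to a brute-force
oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from promotif.promoter_io import MotifHit, PromoterRecord
from promotif.seqcore import Motif, NucSeq, enumerate_search_words

__all__ = ["ScanResult", "scan_promoter", "scan_database", "summarize_hits"]

_ORIENT_ORDER = {"forward": 0, "reverse": 1}


@dataclass(frozen=True)
class ScanResult:
    """Outcome of scanning a promoter collection with one motif."""

    hits: tuple[MotifHit, ...]
    promoters_scanned: int
    promoters_with_hit: int
    params: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        distinct = len({h.gene for h in self.hits})
        if self.promoters_with_hit != distinct:
            raise ValueError("promoters_with_hit inconsistent with hits")
        if self.promoters_with_hit > self.promoters_scanned:
            raise ValueError("more positive promoters than promoters scanned")


def _find_all(text: str, word: str) -> Iterable[int]:
    i = text.find(word)
    while i != -1:
        yield i
        i = text.find(word, i + 1)


def _maximal(intervals: list[tuple[int, int, str]]) -> list[tuple[int, int, str]]:
    """Drop intervals properly contained in a same-orientation interval."""
    out = []
    for a in intervals:
        contained = any(
            b is not a
            and b[2] == a[2]
            and b[0] <= a[0]
            and a[1] <= b[1]
            and (b[0], b[1]) != (a[0], a[1])
            for b in intervals
        )
        if not contained:
            out.append(a)
    return out


def scan_promoter(
    rec: PromoterRecord, m: Motif, *, maximal_only: bool = True
) -> list[MotifHit]:
    """All (maximal) motif sub-word occurrences in one promoter.

    Hits are ordered by (start, orientation forward-first, end) so output
    is deterministic.  With ``maximal_only=False`` every occurrence of
    every search word is reported, including nested ones.
    """
    text = rec.seq.residues
    occurrences: list[tuple[int, int, str]] = []
    for word, orientation in enumerate_search_words(m):
        for start in _find_all(text, word):
            occurrences.append((start, start + len(word), orientation))
    if maximal_only:
        occurrences = _maximal(occurrences)
    occurrences.sort(key=lambda t: (t[0], _ORIENT_ORDER[t[2]], t[1]))
    hits = []
    for start, end, orientation in occurrences:
        hits.append(
            MotifHit(
                gene=rec.gene,
                start=start,
                end=end,
                orientation=orientation,
                matched_word=NucSeq(text[start:end]),
                match_len=end - start,
                tss_rel_start=start - rec.tss_index,
                tss_rel_end=end - rec.tss_index,
            )
        )
    return hits


def scan_database(
    recs: Sequence[PromoterRecord], m: Motif, *, maximal_only: bool = True
) -> ScanResult:
    """Scan a promoter collection; hits concatenated in input order."""
    if not recs:
        raise ValueError("empty promoter record list")
    all_hits: list[MotifHit] = []
    positive = 0
    for rec in recs:
        hits = scan_promoter(rec, m, maximal_only=maximal_only)
        if hits:
            positive += 1
        all_hits.extend(hits)
    params = {
        "motif": m.word.residues,
        "min_match": m.min_match,
        "label": m.label,
        "maximal_only": maximal_only,
    }
    return ScanResult(
        hits=tuple(all_hits),
        promoters_scanned=len(recs),
        promoters_with_hit=positive,
        params=params,
    )


def summarize_hits(res: ScanResult) -> pd.DataFrame:
    """Per-gene summary table of a scan.

    One row per gene with a hit: hit count, the best (longest, then
    leftmost) match, its orientation and TSS-relative interval, and the
    set of orientations seen.  Row order follows first appearance in the
    hit list (i.e. scan input order).
    """
    columns = [
        "gene", "n_hits", "best_match", "best_len", "best_orientation",
        "best_tss_rel_start", "best_tss_rel_end", "orientations",
    ]
    by_gene: dict[str, list[MotifHit]] = {}
    for h in res.hits:
        by_gene.setdefault(h.gene, []).append(h)
    rows = []
    for gene, hits in by_gene.items():
        best = min(hits, key=lambda h: (-h.match_len, h.start, _ORIENT_ORDER[h.orientation]))
        orientations = ",".join(sorted({h.orientation for h in hits}))
        rows.append({
            "gene": gene,
            "n_hits": len(hits),
            "best_match": best.matched_word.residues,
            "best_len": best.match_len,
            "best_orientation": best.orientation,
            "best_tss_rel_start": best.tss_rel_start,
            "best_tss_rel_end": best.tss_rel_end,
            "orientations": orientations,
        })
    return pd.DataFrame(rows, columns=columns)
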
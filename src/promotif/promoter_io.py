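"""Promoter collection I/O: FASTA, gene/sequence tables and BED hit output.

Promoter records carry a TSS anchor (``tss_index``) assigned by a
configurable offset rule, because promoter-database extraction windows
vary.  The default rule assumes an EPD-style window ending 10 bp
downstream of the TSS, i.e. ``tss_index = len(seq) - 11``.

Lowercase in source sequences is preserved as a per-base annotation mask
(some database exports lowercase the portion upstream of the TSS); it is
never used for matching, since many real exports are fully uppercase.
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import TYPE_CHECKING, Callable, Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from promotif.seqcore import NucSeq, normalize, uppercase_mask

if TYPE_CHECKING:  # pragma: no cover
    pass

__all__ = [
    "PromoterRecord",
    "MotifHit",
    "default_tss_rule",
    "read_promoter_fasta",
    "write_promoter_fasta",
    "load_panel_fixture",
    "PANEL_SHA256",
    "write_hits_bed",
]

logger = logging.getLogger(__name__)

#: SHA-256 of the bundled promoter panel fixture; guards transcription drift.
PANEL_SHA256 = "c17d0663beb06fa70ba772b02955e9fd27a302ac67a506c015f6c60fbaef7cee"

_PANEL_RESOURCE = "promoter_panel.tsv"


@dataclass(frozen=True)
class PromoterRecord:
    """One promoter sequence anchored at a TSS position.

    ``upstream_mask[i]`` is True where the source text was lowercase
    (annotation only; conventionally "upstream of TSS" in some exports).
    """

    gene: str
    seq: NucSeq
    tss_index: int
    upstream_mask: tuple[bool, ...] = field(repr=False, default=())
    source: str = ""

    def __post_init__(self) -> None:
        if not 0 <= self.tss_index <= len(self.seq):
            raise ValueError(
                f"tss_index {self.tss_index} out of range for length {len(self.seq)}"
            )
        if self.upstream_mask and len(self.upstream_mask) != len(self.seq):
            raise ValueError("upstream_mask length must equal sequence length")


@dataclass(frozen=True)
class MotifHit:
    """A motif sub-word occurrence in a promoter.

    Coordinates are 0-based half-open relative to the promoter sequence;
    ``tss_rel_*`` are the same interval re-expressed relative to the
    record's ``tss_index`` (negative = upstream).
    """

    gene: str
    start: int
    end: int
    orientation: str
    matched_word: NucSeq
    match_len: int
    tss_rel_start: int
    tss_rel_end: int

    def __post_init__(self) -> None:
        if self.end - self.start != self.match_len or self.match_len < 1:
            raise ValueError("inconsistent hit interval")
        if self.orientation not in ("forward", "reverse"):
            raise ValueError(f"bad orientation {self.orientation!r}")


def default_tss_rule(length: int) -> int:
    """EPD-style anchor: window ends at +10 downstream, so TSS = L - 11.

    Clamped to 0 for records shorter than 11 nt (with a warning from the
    reader).
    """
    return max(0, length - 11)


def _unique_ids(ids: list[str]) -> list[str]:
    seen: dict[str, int] = {}
    out = []
    for name in ids:
        if name in seen:
            seen[name] += 1
            new = f"{name}.{seen[name]}"
            warnings.warn(f"duplicate promoter id {name!r}; renamed to {new!r}")
            out.append(new)
        else:
            seen[name] = 1
            out.append(name)
    return out


def read_promoter_fasta(
    path: str | Path,
    tss_offset_rule: Callable[[int], int] = default_tss_rule,
) -> list[PromoterRecord]:
    """Read a promoter FASTA into records with TSS anchors and case masks.

    One record per FASTA entry; sequences are normalized (uppercase,
    U→T); original case is kept in ``upstream_mask``.  Duplicate ids are
    suffixed with a warning; an empty file yields an empty list with a
    warning.
    """
    path = Path(path)
    raw_records = list(SeqIO.parse(str(path), "fasta"))
    if not raw_records:
        warnings.warn(f"no FASTA records in {path}")
        return []
    ids = _unique_ids([r.id for r in raw_records])
    records = []
    for name, rec in zip(ids, raw_records):
        raw = str(rec.seq)
        seq = normalize(raw)
        mask = tuple(not up for up in uppercase_mask(raw))  # True = lowercase
        tss = tss_offset_rule(len(seq))
        if not 0 <= tss <= len(seq):
            warnings.warn(
                f"tss rule gave {tss} for {name!r} (length {len(seq)}); clamping"
            )
            tss = min(max(tss, 0), len(seq))
        records.append(
            PromoterRecord(gene=name, seq=seq, tss_index=tss,
                           upstream_mask=mask, source=str(path))
        )
    return records


def write_promoter_fasta(records: Iterable[PromoterRecord], path: str | Path) -> None:
    """Write records to FASTA, restoring lowercase from the mask."""
    out = []
    for rec in records:
        text = rec.seq.residues
        if rec.upstream_mask:
            text = "".join(
                c.lower() if low else c for c, low in zip(text, rec.upstream_mask)
            )
        out.append(SeqRecord(Seq(text), id=rec.gene, description=""))
    SeqIO.write(out, str(path), "fasta")


def load_panel_fixture(
    tss_offset_rule: Callable[[int], int] = default_tss_rule,
) -> list[PromoterRecord]:
    """Load the bundled 30-promoter panel (EPD-derived 60-mers).

    The fixture ships read-only with the package; its SHA-256 is checked
    on every load and a mismatch is a hard failure, guarding against
    transcription drift.
    """
    content = (
        resources.files("promotif.data").joinpath(_PANEL_RESOURCE).read_text("ascii")
    )
    digest = hashlib.sha256(content.encode("ascii")).hexdigest()
    if digest != PANEL_SHA256:
        raise RuntimeError(
            f"promoter panel fixture checksum mismatch: {digest} != {PANEL_SHA256}"
        )
    records = []
    lines = content.strip().splitlines()
    header = lines[0].split("\t")
    if header != ["gene", "sequence"]:
        raise RuntimeError(f"unexpected panel header {header!r}")
    for line in lines[1:]:
        gene, raw = line.split("\t")
        seq = normalize(raw)
        mask = tuple(not up for up in uppercase_mask(raw))
        records.append(
            PromoterRecord(gene=gene, seq=seq,
                           tss_index=tss_offset_rule(len(seq)),
                           upstream_mask=mask, source="panel_fixture")
        )
    return records


def write_hits_bed(
    hits: Iterable[MotifHit],
    path: str | Path,
    name_template: str = "{gene}|{word}",
) -> None:
    """Write hits as BED6 with promoter-relative 0-based half-open coords.

    Columns: chrom = gene, start, end, name (from *name_template* with
    ``{gene}`` and ``{word}``), score = match length, strand from
    orientation (forward = ``+``).  Rows sorted by (gene, start, end,
    strand) for determinism.  An empty hit list produces a file holding
    only the header comment.
    """
    rows = sorted(
        hits, key=lambda h: (h.gene, h.start, h.end, h.orientation != "forward")
    )
    with open(path, "w") as fh:
        fh.write("# BED6: promoter-relative motif hits (chrom = promoter/gene id)\n")
        for h in rows:
            name = name_template.format(gene=h.gene, word=h.matched_word.residues)
            strand = "+" if h.orientation == "forward" else "-"
            fh.write(f"{h.gene}\t{h.start}\t{h.end}\t{name}\t{h.match_len}\t{strand}\n")
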
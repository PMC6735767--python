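"""Differential-expression thresholding and candidate-gene nomination.

The classifier applies literal boundary semantics: a gene is *up* iff
``log2fc >= fc_threshold`` and ``fdr < fdr_threshold``, *down* iff
``log2fc <= -fc_threshold`` and ``fdr < fdr_threshold``, otherwise
*unchanged* (inclusive on fold change, strict on FDR).  Nomination
intersects motif-positive genes from a scan with the DE table and ranks
by absolute fold change.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from promotif.motif_scan import ScanResult, summarize_hits

__all__ = [
    "ExpressionRecord",
    "CandidateGene",
    "classify_de",
    "nominate",
    "nominate_from_tables",
    "candidates_to_frame",
]

REQUIRED_COLUMNS = ("gene", "log2fc", "fdr")


@dataclass(frozen=True)
class ExpressionRecord:
    gene: str
    log2fc: float
    fdr: float
    status: str  # up | down | unchanged

    def __post_init__(self) -> None:
        if not 0.0 <= self.fdr <= 1.0:
            raise ValueError(f"fdr {self.fdr} outside [0, 1] for {self.gene}")
        if self.status not in ("up", "down", "unchanged"):
            raise ValueError(f"bad status {self.status!r}")


@dataclass(frozen=True)
class CandidateGene:
    gene: str
    n_hits: int
    best_match: str
    best_len: int
    best_orientation: str
    log2fc: float
    fdr: float
    status: str
    rank: int


def classify_de(
    table: pd.DataFrame,
    fc_threshold: float = 2.0,
    fdr_threshold: float = 0.01,
) -> list[ExpressionRecord]:
    """Classify every gene in a (gene, log2fc, fdr) table as up/down/unchanged.

    Raises on missing columns, duplicate genes (after uppercase
    normalization) and FDR values outside [0, 1].
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"missing column(s) {missing} in DE table")
    genes_upper = table["gene"].astype(str).str.upper()
    dup = genes_upper[genes_upper.duplicated()]
    if len(dup):
        raise ValueError(f"duplicate gene(s) in DE table: {sorted(set(dup))}")
    out = []
    for gene, log2fc, fdr in zip(table["gene"], table["log2fc"], table["fdr"]):
        log2fc = float(log2fc)
        fdr = float(fdr)
        if not 0.0 <= fdr <= 1.0:
            raise ValueError(f"fdr {fdr} outside [0, 1] for gene {gene}")
        if fdr < fdr_threshold and log2fc >= fc_threshold:
            status = "up"
        elif fdr < fdr_threshold and log2fc <= -fc_threshold:
            status = "down"
        else:
            status = "unchanged"
        out.append(ExpressionRecord(str(gene), log2fc, fdr, status))
    return out


def nominate(
    scan: ScanResult,
    de: Sequence[ExpressionRecord],
    require_de: bool = True,
    top_k: int | None = None,
) -> list[CandidateGene]:
    """Intersect motif-positive genes with the DE table and rank them.

    Gene identifiers are compared after uppercase normalization.  With
    *require_de* (default) only up/down genes survive; otherwise every
    motif-positive gene present in the table is kept.  Candidates are
    ranked by |log2fc| descending (ties by gene name) and optionally
    truncated to *top_k*.  An empty intersection warns and returns [].
    """
    summary = summarize_hits(scan)
    return nominate_from_tables(summary, de, require_de=require_de, top_k=top_k)


def nominate_from_tables(
    scan_summary: pd.DataFrame,
    de: Sequence[ExpressionRecord],
    require_de: bool = True,
    top_k: int | None = None,
) -> list[CandidateGene]:
    """Same as :func:`nominate` but starting from a per-gene scan summary."""
    de_by_gene = {rec.gene.upper(): rec for rec in de}
    picked = []
    for row in scan_summary.itertuples(index=False):
        rec = de_by_gene.get(str(row.gene).upper())
        if rec is None:
            continue
        if require_de and rec.status == "unchanged":
            continue
        picked.append((row, rec))
    if not picked:
        warnings.warn("no candidate genes: empty motif-positive/DE intersection")
        return []
    picked.sort(key=lambda pair: (-abs(pair[1].log2fc), pair[1].gene.upper()))
    if top_k is not None:
        picked = picked[:top_k]
    return [
        CandidateGene(
            gene=str(row.gene),
            n_hits=int(row.n_hits),
            best_match=str(row.best_match),
            best_len=int(row.best_len),
            best_orientation=str(row.best_orientation),
            log2fc=rec.log2fc,
            fdr=rec.fdr,
            status=rec.status,
            rank=rank,
        )
        for rank, (row, rec) in enumerate(picked, start=1)
    ]


def candidates_to_frame(candidates: Sequence[CandidateGene]) -> pd.DataFrame:
    columns = [
        "rank", "gene", "log2fc", "fdr", "status",
        "n_hits", "best_match", "best_len", "best_orientation",
    ]
    return pd.DataFrame(
        [{c: getattr(cand, c) for c in columns} for cand in candidates],
        columns=columns,
    )
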
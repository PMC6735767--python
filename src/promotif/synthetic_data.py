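"""Generators for every pipeline input, with recorded ground truth.

Each generator is deterministic given (parameters, seed), drives all
randomness from one ``numpy.random.default_rng(seed)``, and returns the
generated data together with a :class:`GroundTruth` object that records
exactly what was planted.  Promoter backgrounds that happen to contain a
chance motif search word are rejected and resampled, so scanner
sensitivity/specificity tests against the ground truth are exact.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from promotif.chirp_tss import GenomicInterval, TssSite
from promotif.melt_tm import MeltCurve
from promotif.motif_scan import scan_promoter
from promotif.promoter_io import PromoterRecord, default_tss_rule
from promotif.seqcore import Motif, NucSeq, enumerate_search_words, reverse_complement

__all__ = [
    "GroundTruth",
    "PlantSpec",
    "gen_promoters",
    "gen_de_table",
    "gen_fragments",
    "gen_melt_curve",
]

_BASES = np.array(list("ACGT"))
MAX_RESAMPLE_ATTEMPTS = 500


@dataclass(frozen=True)
class GroundTruth:
    """What a generator planted, plus the seed and parameters used."""

    kind: str
    seed: int
    params: dict = field(default_factory=dict)
    planted: tuple = ()

    def to_json(self) -> str:
        return json.dumps(
            {"kind": self.kind, "seed": self.seed, "params": self.params,
             "planted": list(self.planted)},
            indent=2, sort_keys=True,
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json() + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "GroundTruth":
        obj = json.loads(Path(path).read_text())
        planted = tuple(
            tuple(p) if isinstance(p, list) else p for p in obj["planted"]
        )
        return cls(kind=obj["kind"], seed=obj["seed"], params=obj["params"],
                   planted=planted)


@dataclass(frozen=True)
class PlantSpec:
    """One motif sub-word to plant: length, orientation and placement.

    ``promoter``/``position`` of None mean "choose randomly".  The
    planted word is a random contiguous window of the given length taken
    from the motif word (forward) or its reverse complement (reverse).
    """

    length: int
    orientation: str = "forward"
    promoter: int | None = None
    position: int | None = None

    def __post_init__(self) -> None:
        if self.orientation not in ("forward", "reverse"):
            raise ValueError(f"bad orientation {self.orientation!r}")
        if self.length < 1:
            raise ValueError("plant length must be >= 1")


def _random_background(rng: np.random.Generator, length: int,
                       gc_fraction: float) -> str:
    at = (1.0 - gc_fraction) / 2.0
    gc = gc_fraction / 2.0
    idx = rng.choice(4, size=length, p=[at, gc, gc, at])
    return "".join(_BASES[idx])


def gen_promoters(
    n: int,
    length: int,
    gc_fraction: float,
    motif: Motif,
    plant_spec: Sequence[PlantSpec],
    seed: int,
) -> tuple[list[PromoterRecord], GroundTruth]:
    """Background promoters with planted motif sub-words and exact truth.

    Backgrounds are i.i.d. with the requested GC fraction.  After
    planting, each sequence is rescanned with the motif: the maximal-hit
    set must equal exactly the planted intervals of length >= min_match
    (and be empty where only sub-threshold words were planted),
    otherwise the background is resampled.  Overlapping plants within
    one promoter are rejected as infeasible.
    """
    if not 0.0 <= gc_fraction <= 1.0:
        raise ValueError("gc_fraction must be in [0, 1]")
    for p in plant_spec:
        if p.length > len(motif.word):
            raise ValueError(f"plant length {p.length} exceeds motif length")
        if p.promoter is not None and not 0 <= p.promoter < n:
            raise ValueError(f"plant promoter index {p.promoter} out of range")
        if p.position is not None and p.position + p.length > length:
            raise ValueError("plant does not fit within sequence")
    rng = np.random.default_rng(seed)
    forward = motif.word.residues
    reverse = reverse_complement(motif.word).residues

    # Resolve plants: promoter index, position, concrete word.
    resolved: dict[int, list[tuple[int, int, str, str]]] = {i: [] for i in range(n)}
    for p in plant_spec:
        idx = int(rng.integers(n)) if p.promoter is None else p.promoter
        text = forward if p.orientation == "forward" else reverse
        w_start = int(rng.integers(len(text) - p.length + 1))
        word = text[w_start:w_start + p.length]
        taken = resolved[idx]
        if p.position is not None:
            pos = p.position
            if any(pos < e and s < pos + p.length for s, e, _, _ in taken):
                raise ValueError(f"overlapping plants in promoter {idx}")
        else:
            pos = None
            order = rng.permutation(length - p.length + 1)
            for cand in order:
                cand = int(cand)
                if not any(cand < e and s < cand + p.length for s, e, _, _ in taken):
                    pos = cand
                    break
            if pos is None:
                raise ValueError(f"no room to plant in promoter {idx}")
        taken.append((pos, pos + p.length, p.orientation, word))

    records = []
    planted_out = []
    for i in range(n):
        plants = sorted(resolved[i])
        expected = {
            (s, e, o) for s, e, o, _ in plants if e - s >= motif.min_match
        }
        for attempt in range(MAX_RESAMPLE_ATTEMPTS):
            chars = list(_random_background(rng, length, gc_fraction))
            for s, e, _, word in plants:
                chars[s:e] = word
            seq = "".join(chars)
            rec = PromoterRecord(
                gene=f"SYN{i:04d}", seq=NucSeq(seq),
                tss_index=default_tss_rule(length),
            )
            found = {(h.start, h.end, h.orientation)
                     for h in scan_promoter(rec, motif)}
            if found == expected:
                break
        else:
            raise RuntimeError(
                f"could not generate clean background for promoter {i} in "
                f"{MAX_RESAMPLE_ATTEMPTS} attempts"
            )
        records.append(rec)
        for s, e, o, word in plants:
            planted_out.append((rec.gene, s, e - s, o, word))

    truth = GroundTruth(
        kind="promoters", seed=seed,
        params={"n": n, "length": length, "gc_fraction": gc_fraction,
                "motif": forward, "min_match": motif.min_match},
        planted=tuple(planted_out),
    )
    return records, truth


def gen_de_table(
    genes: Sequence[str],
    n_up: int,
    n_down: int,
    fc_magnitude_range: tuple[float, float] = (2.0, 6.0),
    fdr_alt_range: tuple[float, float] = (1e-8, 0.009),
    fdr_null_range: tuple[float, float] = (0.02, 1.0),
    seed: int = 0,
    fc_threshold: float = 2.0,
    fdr_threshold: float = 0.01,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Expression table with planted up/down genes and unambiguous nulls.

    Planted genes draw |log2fc| from *fc_magnitude_range* (which must sit
    at or above *fc_threshold*) and FDR from *fdr_alt_range* (entirely
    below *fdr_threshold*); nulls get |log2fc| strictly below threshold
    and FDR from *fdr_null_range* (at or above threshold), so the planted
    classification is exact by construction.
    """
    genes = list(genes)
    if n_up + n_down > len(genes):
        raise ValueError("n_up + n_down exceeds number of genes")
    if fc_magnitude_range[0] < fc_threshold:
        raise ValueError("fc_magnitude_range straddles the fold-change threshold")
    if not (0 <= fdr_alt_range[0] <= fdr_alt_range[1] < fdr_threshold):
        raise ValueError("fdr_alt_range must lie strictly below fdr_threshold")
    if not (fdr_threshold <= fdr_null_range[0] <= fdr_null_range[1] <= 1.0):
        raise ValueError("fdr_null_range must lie at or above fdr_threshold")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(genes))
    status = {}
    for k, idx in enumerate(order):
        if k < n_up:
            status[genes[idx]] = "up"
        elif k < n_up + n_down:
            status[genes[idx]] = "down"
        else:
            status[genes[idx]] = "unchanged"
    rows = []
    for gene in genes:
        st = status[gene]
        if st == "unchanged":
            log2fc = float(rng.uniform(-0.9 * fc_threshold, 0.9 * fc_threshold))
            fdr = float(rng.uniform(*fdr_null_range))
        else:
            magnitude = float(rng.uniform(*fc_magnitude_range))
            log2fc = magnitude if st == "up" else -magnitude
            fdr = float(rng.uniform(*fdr_alt_range))
        rows.append({"gene": gene, "log2fc": log2fc, "fdr": fdr})
    table = pd.DataFrame(rows, columns=["gene", "log2fc", "fdr"])
    truth = GroundTruth(
        kind="de_table", seed=seed,
        params={"n_genes": len(genes), "n_up": n_up, "n_down": n_down,
                "fc_threshold": fc_threshold, "fdr_threshold": fdr_threshold},
        planted=tuple((g, status[g]) for g in genes),
    )
    return table, truth


def gen_fragments(
    tss_list: Sequence[TssSite],
    n: int,
    offset_sd_bp: float,
    fragment_len: int = 200,
    seed: int = 0,
) -> tuple[list[GenomicInterval], GroundTruth]:
    """Fragments centred at strand-signed Normal(0, sd) offsets from TSSs.

    Each fragment picks a TSS uniformly at random; the planted offset is
    recorded in the ground truth in the signed (strand-aware, upstream
    negative) convention, so the recovered midpoint distance equals the
    planted offset exactly when TSSs are well separated.
    """
    if not tss_list:
        raise ValueError("tss_list must be non-empty")
    if fragment_len < 1:
        raise ValueError("fragment_len must be >= 1")
    rng = np.random.default_rng(seed)
    intervals = []
    planted = []
    for i in range(n):
        site = tss_list[int(rng.integers(len(tss_list)))]
        offset = int(round(rng.normal(0.0, offset_sd_bp)))
        genomic_shift = offset if site.strand == "+" else -offset
        center = site.pos + genomic_shift
        start = center - fragment_len // 2
        end = start + fragment_len
        if start < 0:
            raise ValueError(
                f"fragment {i} would start at {start} < 0; place TSSs further "
                "from the chromosome origin or reduce offset_sd_bp"
            )
        frag_id = f"frag{i:05d}"
        intervals.append(GenomicInterval(site.chrom, start, end, frag_id))
        planted.append((frag_id, site.gene, offset))
    truth = GroundTruth(
        kind="fragments", seed=seed,
        params={"n": n, "offset_sd_bp": offset_sd_bp,
                "fragment_len": fragment_len},
        planted=tuple(planted),
    )
    return intervals, truth


def gen_melt_curve(
    tm: float,
    width: float,
    baseline: float,
    amplitude: float,
    noise_sd: float,
    t_lo: float = 60.0,
    t_hi: float = 95.0,
    dt: float = 0.2,
    seed: int = 0,
    condition: str = "",
) -> tuple[MeltCurve, GroundTruth]:
    """Two-state decreasing sigmoid melt profile with additive noise.

    ``F(T) = baseline + amplitude / (1 + exp((T - tm) / width)) + eps``,
    with eps i.i.d. Normal(0, noise_sd) on a uniform grid.
    """
    if width <= 0:
        raise ValueError("width must be positive")
    if not t_lo < tm < t_hi:
        raise ValueError("tm must lie inside the temperature range")
    rng = np.random.default_rng(seed)
    n_points = int(round((t_hi - t_lo) / dt)) + 1
    temps = t_lo + dt * np.arange(n_points)
    signal = baseline + amplitude / (1.0 + np.exp((temps - tm) / width))
    fluor = signal + rng.normal(0.0, noise_sd, n_points)
    curve = MeltCurve(temps=temps, fluor=fluor, condition=condition)
    truth = GroundTruth(
        kind="melt_curve", seed=seed,
        params={"tm": tm, "width": width, "baseline": baseline,
                "amplitude": amplitude, "noise_sd": noise_sd,
                "t_lo": t_lo, "t_hi": t_hi, "dt": dt},
        planted=((condition, tm),),
    )
    return curve, truth
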
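# promotif

Promoter motif screening and target-gene nomination toolkit for
lncRNA–chromatin studies.

`promotif` implements a small analysis pipeline around a partial-match
DNA motif screen:

- **seqcore** — alphabet normalization (uppercase, U→T, degenerate
  IUPAC→N), reverse complement, and the partial-match motif model: a DNA
  word plus a minimum contiguous match length (default 10). The search
  considers every contiguous sub-word of the motif at or above that
  length, in both the forward orientation and the reverse complement.
- **promoter_io** — promoter FASTA / gene-sequence-table reading with a
  configurable TSS-anchoring rule (default: EPD-style window ending
  +10 bp downstream of the TSS, i.e. `tss_index = length − 11`), case
  masks preserved as annotation, BED6 hit output, and a bundled,
  checksum-guarded panel of 30 human promoter 60-mers that all carry a
  partial site for the default motif `GGCCACCACCCC`.
- **motif_scan** — the screen itself: all maximal partial-motif matches
  per promoter (a hit is dropped only if properly contained in another
  hit of the same orientation), promoter-level positive counts, and a
  per-gene summary table.
- **chirp_tss** — signed distance from genomic fragments (BED) to the
  nearest TSS (BED6/GFF3), midpoint or nearest-edge measure, upstream
  negative, plus distance-bin histograms (default ±1/±5/±10 kb).
- **de_candidates** — differential-expression thresholding with literal
  boundary semantics (`log2fc ≥ 2` inclusive, `FDR < 0.01` strict, both
  configurable) and intersection/ranking of motif-positive genes into a
  candidate list.
- **melt_tm** — melting-temperature estimation from fluorescence melt
  profiles: centered smoothing, −dF/dT peak, quadratic sub-grid
  refinement; Tm shifts between paired conditions.
- **synthetic_data** — deterministic generators for every input
  (promoters with planted motif sub-words and certified-clean
  backgrounds, DE tables with planted up/down genes, fragments at
  Normal offsets around TSSs, two-state sigmoid melt curves), each with
  recorded ground truth.
- **pipeline_cli** — a `click` CLI exposing every stage and an
  end-to-end `run` that writes a JSON manifest with parameter and
  checksum records.

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (panel screen
positivity, motif derivation, Tm-shift recovery, and the property-based
replacements for genome-scale results).

## CLI

```sh
# screen the bundled 30-promoter panel with the default motif
promotif scan --panel-fixture --bed hits.bed --tsv summary.tsv

# screen your own promoter FASTA with a custom motif
promotif scan --fasta promoters.fa --motif GGCCACCACCCC --min-match 10

# fragment-to-TSS distances and binned histogram
promotif annotate-tss --fragments frags.bed --tss tss.bed \
    --out distances.tsv --hist bins.tsv

# DE thresholding and candidate nomination
promotif de-filter --table de.tsv --out classified.tsv
promotif nominate --scan-tsv summary.tsv --de-table de.tsv --top-k 6 \
    --out candidates.tsv

# melt-curve Tm and Tm shift between conditions a and b
promotif melt --csv melt.csv --pair a:b --out tm.tsv

# synthetic inputs with ground truth
promotif simulate promoters --n 30 --fasta syn.fa --truth truth.json
promotif simulate de-table --n-up 200 --n-down 231 --out de.tsv
promotif simulate fragments --n 2198 --fragments-out f.bed --tss-out t.bed
promotif simulate melt-curves --out melt.csv

# end-to-end with manifest
promotif run --panel-fixture --de-table de.tsv --top-k 6 --out-dir out/
```

## Conventions

- Coordinates are 0-based half-open everywhere (BED semantics).
- TSS distances are signed by gene strand, upstream negative.
- Tm is the peak of the negative first derivative of smoothed
  fluorescence, refined to sub-grid resolution.
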
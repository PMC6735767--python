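import math

import numpy as np
import pytest

from promotif.chirp_tss import (
    DEFAULT_BIN_EDGES,
    GenomicInterval,
    TssSite,
    bin_distances,
    distance_to_nearest_tss,
    read_intervals_bed,
    read_tss,
)
from promotif.synthetic_data import gen_fragments


def brute_force_nearest(frag, tsss, measure):
    """All-pairs oracle: minimize |distance|, ties to smaller TSS pos."""
    def absd(site):
        if measure == "midpoint":
            return abs(frag.midpoint - site.pos)
        if frag.start <= site.pos < frag.end:
            return 0
        return min(abs(frag.start - site.pos), abs(frag.end - 1 - site.pos))

    candidates = [t for t in tsss if t.chrom == frag.chrom]
    if not candidates:
        return None
    return min(candidates, key=lambda t: (absd(t), t.pos))


class TestReaders:
    def test_bed_interval(self, tmp_path):
        path = tmp_path / "f.bed"
        path.write_text("chr1\t100\t200\tf1\n")
        (iv,) = read_intervals_bed(path)
        assert (iv.chrom, iv.start, iv.end, iv.id) == ("chr1", 100, 200, "f1")

    def test_bed_malformed_line_number(self, tmp_path):
        path = tmp_path / "f.bed"
        path.write_text("chr1\t100\t200\tok\nchr1\tXX\t300\tbad\n")
        with pytest.raises(ValueError, match=":2"):
            read_intervals_bed(path)

    def test_bed_zero_length_rejected(self, tmp_path):
        path = tmp_path / "f.bed"
        path.write_text("chr1\t100\t100\tf1\n")
        with pytest.raises(ValueError):
            read_intervals_bed(path)

    def test_empty_file_warns(self, tmp_path):
        path = tmp_path / "f.bed"
        path.write_text("")
        with pytest.warns(UserWarning):
            assert read_intervals_bed(path) == []

    def test_gff_minus_strand_tss(self, tmp_path):
        path = tmp_path / "g.gff"
        # 1-based closed [501, 900] == 0-based half-open [500, 900)
        path.write_text(
            "chrX\tsrc\tgene\t501\t900\t.\t-\t.\tID=geneA;Name=GENEA\n"
        )
        (site,) = read_tss(path, format="gff")
        assert site.pos == 899
        assert site.strand == "-"
        assert site.gene == "GENEA"

    def test_gff_plus_strand_tss(self, tmp_path):
        path = tmp_path / "g.gff"
        path.write_text("chrX\tsrc\tgene\t501\t900\t.\t+\t.\tID=geneA\n")
        (site,) = read_tss(path, format="gff")
        assert site.pos == 500

    def test_bed_tss_strand(self, tmp_path):
        path = tmp_path / "t.bed"
        path.write_text("chr1\t500\t501\tG1\t0\t+\nchr1\t800\t801\tG2\t0\t-\n")
        sites = read_tss(path, format="bed")
        assert [(s.pos, s.strand) for s in sites] == [(500, "+"), (800, "-")]


class TestDistance:
    def test_midpoint_at_tss_is_zero(self):
        frag = GenomicInterval("chr1", 290, 310, "f")
        tss = [TssSite("chr1", 300, "+", "G")]
        (rec,) = distance_to_nearest_tss([frag], tss)
        assert rec.distance == 0
        assert rec.gene == "G"

    def test_sign_convention_both_strands(self):
        frag = GenomicInterval("chr1", 690, 710, "f")  # midpoint 700
        plus = [TssSite("chr1", 1000, "+", "G")]
        minus = [TssSite("chr1", 1000, "-", "G")]
        assert distance_to_nearest_tss([frag], plus)[0].distance == -300
        assert distance_to_nearest_tss([frag], minus)[0].distance == 300

    def test_tie_breaks_to_smaller_pos(self):
        frag = GenomicInterval("chr1", 495, 505, "f")  # midpoint 500
        tss = [TssSite("chr1", 400, "+", "L"), TssSite("chr1", 600, "+", "R")]
        (rec,) = distance_to_nearest_tss([frag], tss)
        assert rec.gene == "L"
        assert rec.distance == 100

    def test_unassigned_chromosome(self):
        frag = GenomicInterval("chr9", 0, 10, "f")
        tss = [TssSite("chr1", 5, "+", "G")]
        (rec,) = distance_to_nearest_tss([frag], tss)
        assert not rec.assigned
        assert rec.distance is None

    def test_edge_measure_zero_inside(self):
        frag = GenomicInterval("chr1", 100, 200, "f")
        tss = [TssSite("chr1", 150, "+", "G")]
        (rec,) = distance_to_nearest_tss([frag], tss, measure="edge")
        assert rec.distance == 0

    def test_generator_ground_truth_recovery(self):
        tss = [TssSite("chrZ", 500_000 * (i + 1), "+" if i % 2 else "-", f"G{i}")
               for i in range(25)]
        frags, truth = gen_fragments(tss, 300, 350.0, fragment_len=200, seed=42)
        recovered = {r.fragment_id: r.distance
                     for r in distance_to_nearest_tss(frags, tss)}
        for frag_id, _, offset in truth.planted:
            assert recovered[frag_id] == offset

    @pytest.mark.parametrize("measure", ["midpoint", "edge"])
    def test_brute_force_oracle(self, rng, measure):
        chroms = ["chr1", "chr2"]
        tss = [TssSite(rng.choice(chroms), rng.randint(0, 5000),
                       rng.choice("+-"), f"G{i}") for i in range(60)]
        frags = []
        for i in range(150):
            start = rng.randint(0, 4900)
            frags.append(GenomicInterval(rng.choice(chroms), start,
                                         start + rng.randint(1, 80), f"f{i}"))
        records = distance_to_nearest_tss(frags, tss, measure=measure)
        by_id = {f.id: f for f in frags}
        for rec in records:
            expected = brute_force_nearest(by_id[rec.fragment_id], tss, measure)
            assert rec.gene == expected.gene

    def test_translation_invariance(self, rng):
        tss = [TssSite("c", rng.randint(0, 10_000), rng.choice("+-"), f"G{i}")
               for i in range(30)]
        frags = []
        for i in range(50):
            start = rng.randint(0, 9_900)
            frags.append(GenomicInterval("c", start, start + 50, f"f{i}"))
        base = [r.distance for r in distance_to_nearest_tss(frags, tss)]
        shift = 12345
        tss2 = [TssSite(t.chrom, t.pos + shift, t.strand, t.gene) for t in tss]
        frags2 = [GenomicInterval(f.chrom, f.start + shift, f.end + shift, f.id)
                  for f in frags]
        shifted = [r.distance for r in distance_to_nearest_tss(frags2, tss2)]
        assert base == shifted

    def test_strand_flip_negates_distances(self, rng):
        tss = [TssSite("c", 1 + i * 700, rng.choice("+-"), f"G{i}")
               for i in range(20)]
        frags = []
        for i in range(40):
            start = rng.randint(0, 13_000)
            frags.append(GenomicInterval("c", start, start + 30, f"f{i}"))
        base = [r.distance for r in distance_to_nearest_tss(frags, tss)]
        flipped_tss = [
            TssSite(t.chrom, t.pos, "-" if t.strand == "+" else "+", t.gene)
            for t in tss
        ]
        flipped = [r.distance for r in distance_to_nearest_tss(frags, flipped_tss)]
        assert flipped == [-d for d in base]

    def test_input_validation(self):
        with pytest.raises(ValueError):
            distance_to_nearest_tss([], [TssSite("c", 0, "+")])
        frag = GenomicInterval("c", 0, 10)
        with pytest.raises(ValueError):
            distance_to_nearest_tss([frag], [TssSite("c", 0, "+")],
                                    measure="bogus")


class TestBinning:
    @staticmethod
    def _records(distances):
        from promotif.chirp_tss import TssDistanceRecord
        return [TssDistanceRecord(f"f{i}", "G", d) for i, d in enumerate(distances)]

    def test_all_zero_in_central_bin(self):
        table = bin_distances(self._records([0] * 10))
        central = table[table["bin"] == "[-1000, 1000)"]
        assert int(central["count"].iloc[0]) == 10
        assert float(central["fraction"].iloc[0]) == 1.0

    def test_fractions_sum_to_one(self, rng):
        distances = [rng.randint(-50_000, 50_000) for _ in range(500)]
        table = bin_distances(self._records(distances))
        assert math.isclose(table["fraction"].sum(), 1.0)
        assert table["count"].sum() == 500

    def test_half_open_boundaries(self):
        table = bin_distances(self._records([1000]))
        row = table[table["count"] == 1]
        assert row["bin"].iloc[0] == "[1000, 5000)"

    def test_non_monotone_edges_rejected(self):
        with pytest.raises(ValueError):
            bin_distances(self._records([0]), edges=[5, 1])

    def test_normal_offsets_match_closed_form(self):
        # fraction within +/-1000 of Normal(0, 400) ~= Phi(2.5) - Phi(-2.5)
        tss = [TssSite("c", 1_000_000 * (i + 1), "+", f"G{i}") for i in range(10)]
        frags, _ = gen_fragments(tss, 2198, 400.0, seed=7)
        records = distance_to_nearest_tss(frags, tss)
        table = bin_distances(records, DEFAULT_BIN_EDGES)
        central = float(
            table[table["bin"] == "[-1000, 1000)"]["fraction"].iloc[0]
        )
        expected = 0.98758  # Phi(2.5) - Phi(-2.5)
        # Monte-Carlo tolerance: ~4 binomial sigmas at n=2198
        sigma = math.sqrt(expected * (1 - expected) / 2198)
        assert abs(central - expected) < 4 * sigma

    def test_unassigned_excluded(self):
        from promotif.chirp_tss import TssDistanceRecord
        records = [TssDistanceRecord("a", "G", 0),
                   TssDistanceRecord("b", None, None, assigned=False)]
        table = bin_distances(records)
        assert table["count"].sum() == 1
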
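"""Annotation parsing, bedGraph expansion, window extraction, metagene."""

import numpy as np
import pytest

from exoscreen.annotation import GeneAnnotation, read_annotation, read_chrom_sizes
from exoscreen.signal import SignalTrack, average_tracks, read_signal_track
from exoscreen.windows import WindowSpec, extract_window, metagene_profile


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return str(p)


class TestReadAnnotation:
    def test_tsv_roundtrip(self, tmp_path):
        path = _write(tmp_path, "ann.tsv", "g1\tchrI\t+\t100\ng2\tchrI\t-\t900\n")
        genes = read_annotation(path)
        assert [g.gene_id for g in genes] == ["g1", "g2"]
        assert genes[1].strand == "-" and genes[1].tss == 900

    def test_gff3_minus_strand_tss_is_end(self, tmp_path):
        gff = (
            "##gff-version 3\n"
            "chrI\tsrc\tgene\t100\t500\t.\t-\t.\tID=gene1\n"
            "chrI\tsrc\tgene\t600\t800\t.\t+\t.\tID=gene2\n"
        )
        genes = read_annotation(_write(tmp_path, "ann.gff3", gff))
        by_id = {g.gene_id: g for g in genes}
        assert by_id["gene1"].tss == 500  # 5' end of a - strand gene
        assert by_id["gene2"].tss == 600

    def test_duplicate_gene_id_raises(self, tmp_path):
        path = _write(tmp_path, "dup.tsv", "g1\tchrI\t+\t100\ng1\tchrI\t+\t200\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_annotation(path)

    @pytest.mark.parametrize("row", ["g1\tchrI\t*\t100", "g1\tchrI\t+\t0"])
    def test_invalid_records_raise(self, tmp_path, row):
        with pytest.raises(ValueError):
            read_annotation(_write(tmp_path, "bad.tsv", row + "\n"))

    def test_chrom_sizes(self, tmp_path):
        sizes = read_chrom_sizes(_write(tmp_path, "cs", "chrI\t230218\nchrII\t813184\n"))
        assert sizes == {"chrI": 230218, "chrII": 813184}


class TestReadSignalTrack:
    def test_half_open_expansion(self, tmp_path):
        path = _write(tmp_path, "a.bedgraph", "chrI\t0\t5\t2.0\n")
        track = read_signal_track(path, {"chrI": 10})
        assert track.counts["chrI"].tolist() == [2, 2, 2, 2, 2, 0, 0, 0, 0, 0]

    def test_empty_file_is_all_zero(self, tmp_path):
        track = read_signal_track(_write(tmp_path, "e.bedgraph", ""), {"chrI": 4})
        assert track.counts["chrI"].tolist() == [0, 0, 0, 0]

    def test_overlapping_intervals_raise(self, tmp_path):
        path = _write(tmp_path, "o.bedgraph", "chrI\t0\t5\t1\nchrI\t3\t8\t2\n")
        with pytest.raises(ValueError, match="overlap"):
            read_signal_track(path, {"chrI": 10})

    def test_out_of_bounds_and_negative_raise(self, tmp_path):
        with pytest.raises(ValueError, match="bounds"):
            read_signal_track(_write(tmp_path, "b.bedgraph", "chrI\t5\t20\t1\n"), {"chrI": 10})
        with pytest.raises(ValueError, match="negative"):
            read_signal_track(_write(tmp_path, "n.bedgraph", "chrI\t0\t5\t-1\n"), {"chrI": 10})

    def test_replicates_average_basewise(self):
        t1 = SignalTrack(counts={"c": np.array([2.0, 4.0])})
        t2 = SignalTrack(counts={"c": np.array([4.0, 0.0])})
        assert average_tracks([t1, t2]).counts["c"].tolist() == [3.0, 2.0]


def _uniform_track(length=5000, value=2.0):
    return SignalTrack(counts={"chrI": np.full(length, value)})


class TestExtractWindow:
    def test_uniform_track_mean(self):
        gene = GeneAnnotation("g", "chrI", "+", 2500)
        prof = extract_window(_uniform_track(), gene, WindowSpec())
        assert prof.window_mean == 2.0
        assert len(prof.values) == 2001

    def test_single_count_upstream_plus_strand(self):
        counts = np.zeros(5000)
        tss0 = 2500 - 1
        counts[tss0 - 300] = 1.0
        track = SignalTrack(counts={"chrI": counts})
        prof = extract_window(track, GeneAnnotation("g", "chrI", "+", 2500), WindowSpec())
        assert prof.values[700] == 1.0  # index 700 = offset -300
        assert prof.offsets[700] == -300
        assert prof.window_mean == pytest.approx(1 / 2001)

    def test_single_count_upstream_minus_strand(self):
        # upstream of a - strand gene lies at larger genomic coordinates
        counts = np.zeros(5000)
        tss0 = 2500 - 1
        counts[tss0 + 300] = 1.0
        track = SignalTrack(counts={"chrI": counts})
        prof = extract_window(track, GeneAnnotation("g", "chrI", "-", 2500), WindowSpec())
        assert prof.values[700] == 1.0
        assert prof.offsets[700] == -300

    def test_chromosome_end_clipping(self):
        # tss=50 on a 1,000-bp chromosome: both arms clip, leaving the 49
        # upstream bases, the TSS, and the 950 downstream bases = 1,000
        gene = GeneAnnotation("g", "chrI", "+", 50)
        prof = extract_window(_uniform_track(length=1000), gene, WindowSpec())
        assert len(prof.values) == 1000
        assert prof.offsets[0] == -49 and prof.offsets[-1] == 950
        assert prof.window_mean == 2.0

    def test_window_mean_matches_bruteforce_loop(self, rng):
        counts = rng.integers(0, 20, size=4000).astype(float)
        track = SignalTrack(counts={"chrI": counts})
        for strand in "+-":
            gene = GeneAnnotation("g", "chrI", strand, 2000)
            prof = extract_window(track, gene, WindowSpec(300, 150))
            acc = []
            for rel in range(-300, 151):
                g = (2000 - 1) + rel if strand == "+" else (2000 - 1) - rel
                if 0 <= g < len(counts):
                    acc.append(counts[g])
            assert prof.window_mean == pytest.approx(sum(acc) / len(acc))
            assert prof.values.tolist() == acc

    def test_strand_flip_equivariance(self, rng):
        counts = rng.poisson(3.0, size=3000).astype(float)
        track = SignalTrack(counts={"chrI": counts})
        mirrored = SignalTrack(counts={"chrI": counts[::-1].copy()})
        gene = GeneAnnotation("g", "chrI", "+", 1200)
        flipped = GeneAnnotation("g", "chrI", "-", 3000 - 1200 + 1)
        a = extract_window(track, gene, WindowSpec())
        b = extract_window(mirrored, flipped, WindowSpec())
        assert np.array_equal(a.values, b.values)
        assert np.array_equal(a.offsets, b.offsets)

    def test_missing_chromosome_raises(self):
        gene = GeneAnnotation("g", "chrX", "+", 100)
        with pytest.raises(KeyError):
            extract_window(_uniform_track(), gene, WindowSpec())


class TestMetagene:
    def test_single_profile_identity(self):
        gene = GeneAnnotation("g", "chrI", "+", 2500)
        spec = WindowSpec(100, 100)
        prof = extract_window(_uniform_track(), gene, spec)
        meta = metagene_profile([prof], spec)
        assert np.array_equal(meta, prof.values)

    def test_two_flat_profiles_average(self):
        spec = WindowSpec(10, 10)
        genes = [GeneAnnotation("a", "chrI", "+", 100), GeneAnnotation("b", "chrI", "+", 200)]
        t1 = SignalTrack(counts={"chrI": np.full(400, 1.0)})
        t3 = SignalTrack(counts={"chrI": np.full(400, 3.0)})
        profs = [extract_window(t1, genes[0], spec), extract_window(t3, genes[1], spec)]
        assert np.allclose(metagene_profile(profs, spec), 2.0)

    def test_clipped_positions_excluded_positionwise(self):
        spec = WindowSpec(10, 10)
        track = SignalTrack(counts={"chrI": np.full(100, 4.0)})
        near_edge = extract_window(track, GeneAnnotation("e", "chrI", "+", 5), spec)
        interior = extract_window(track, GeneAnnotation("i", "chrI", "+", 50), spec)
        meta = metagene_profile([near_edge, interior], spec)
        assert np.allclose(meta, 4.0)  # not dragged down by the clipped gene
        assert len(meta) == spec.length

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            metagene_profile([], WindowSpec())

    def test_simulated_peak_position(self, small_chipexo):
        from exoscreen.windows import extract_all_windows

        config, sim = small_chipexo
        profs = extract_all_windows(sim.stress, sim.annotation, config.window)
        meta = metagene_profile(profs, config.window)
        peak_offset = int(config.window.offsets()[np.nanargmax(meta)])
        assert -300 <= peak_offset <= -200
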
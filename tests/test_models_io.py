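"""Domain types, coordinate conventions and format round trips."""

import numpy as np
import pandas as pd
import pytest

from primatesplice.models import (
    ExpressionMatrix,
    GenomeSet,
    SpliceJunction,
    TranscriptModel,
    ValidationError,
    reverse_complement,
)
from primatesplice import io as psio


def make_transcript(exons, strand="+", tid="t1", gene="g1", chrom="chr1"):
    return TranscriptModel(tid, gene, "H", chrom, strand, tuple(exons))


class TestTranscriptModel:
    def test_introns_are_gaps_between_exons(self):
        t = make_transcript([(100, 200), (300, 400)])
        assert t.introns == ((200, 300),)
        assert t.span == (100, 400)
        assert t.length == 200

    @pytest.mark.parametrize(
        "exons",
        [
            [],
            [(100, 100)],                     # empty exon
            [(100, 200), (150, 300)],         # overlap
            [(300, 400), (100, 200)],         # unsorted
            [(100, 200), (202, 300)],         # intron shorter than 4
        ],
    )
    def test_invalid_exon_chains_rejected(self, exons):
        with pytest.raises(ValidationError):
            make_transcript(exons)


class TestGtfIO:
    def test_coordinates_converted_to_half_open(self, tmp_path):
        gtf = tmp_path / "a.gtf"
        gtf.write_text(
            'chr1\t.\texon\t101\t200\t.\t+\t.\tgene_id "g1"; transcript_id "t1";\n'
            'chr1\t.\texon\t301\t400\t.\t+\t.\tgene_id "g1"; transcript_id "t1";\n'
        )
        ann = psio.read_annotation(gtf, "H")
        t = ann.transcripts["t1"]
        assert t.exons == ((100, 200), (300, 400))
        assert t.introns == ((200, 300),)

    def test_round_trip_is_byte_stable(self, tmp_path):
        ann_in = psio.read_annotation(_write_gtf(tmp_path), "H")
        out1 = tmp_path / "out1.gtf"
        out2 = tmp_path / "out2.gtf"
        psio.write_annotation(ann_in, out1)
        psio.write_annotation(psio.read_annotation(out1, "H"), out2)
        assert out1.read_bytes() == out2.read_bytes()
        t = psio.read_annotation(out2, "H").transcripts["t1"]
        assert t.exons == ann_in.transcripts["t1"].exons

    def test_overlapping_exons_in_transcript_rejected(self, tmp_path):
        gtf = tmp_path / "bad.gtf"
        gtf.write_text(
            'chr1\t.\texon\t101\t200\t.\t+\t.\tgene_id "g1"; transcript_id "t1";\n'
            'chr1\t.\texon\t150\t300\t.\t+\t.\tgene_id "g1"; transcript_id "t1";\n'
        )
        with pytest.raises(ValidationError):
            psio.read_annotation(gtf)

    def test_malformed_attributes_name_the_line(self, tmp_path):
        gtf = tmp_path / "bad.gtf"
        gtf.write_text("chr1\t.\texon\t101\t200\t.\t+\t.\tno_attrs_here\n")
        with pytest.raises(psio.GtfParseError, match=":1"):
            psio.read_annotation(gtf)


def _write_gtf(tmp_path):
    gtf = tmp_path / "in.gtf"
    gtf.write_text(
        'chr1\t.\texon\t101\t200\t.\t+\t.\tgene_id "g1"; transcript_id "t1";\n'
        'chr1\t.\texon\t301\t400\t.\t+\t.\tgene_id "g1"; transcript_id "t1";\n'
        'chr2\t.\texon\t51\t90\t.\t-\t.\tgene_id "g2"; transcript_id "t2";\n'
    )
    return gtf


class TestJunctionExtraction:
    def test_plus_strand_reads_forward_dinucleotides(self):
        seq = "A" * 100 + "GT" + "C" * 96 + "AG" + "A" * 100
        genome = GenomeSet("H", {"chr1": seq})
        t = make_transcript([(50, 100), (200, 250)])
        (j,) = psio.extract_junctions(t, genome)
        assert (j.donor, j.acceptor) == ("GT", "AG")

    def test_minus_strand_orientation(self):
        # genomic forward intron CT...AC reads GT-AG in transcript orientation
        seq = "A" * 100 + "CT" + "C" * 96 + "AC" + "A" * 100
        genome = GenomeSet("H", {"chr1": seq})
        t = make_transcript([(50, 100), (200, 250)], strand="-")
        (j,) = psio.extract_junctions(t, genome)
        assert (j.donor, j.acceptor) == ("GT", "AG")

    def test_monoexonic_yields_no_junctions(self):
        genome = GenomeSet("H", {"chr1": "A" * 300})
        assert psio.extract_junctions(make_transcript([(10, 50)]), genome) == []

    def test_strand_symmetry_under_reverse_complement(self):
        """Reverse-complementing the chromosome and flipping the strand must
        leave the oriented dinucleotides unchanged."""
        rng = np.random.default_rng(11)
        seq = "".join(rng.choice(list("ACGT"), size=400))
        genome = GenomeSet("H", {"chr1": seq})
        t = make_transcript([(30, 80), (140, 200), (260, 330)])
        fwd = psio.extract_junctions(t, genome)
        L = len(seq)
        rc_genome = GenomeSet("H", {"chr1": reverse_complement(seq)})
        rc_exons = sorted((L - e, L - s) for s, e in t.exons)
        rc_t = make_transcript(rc_exons, strand="-")
        rev = psio.extract_junctions(rc_t, rc_genome)
        assert [(j.donor, j.acceptor) for j in fwd] == [
            (j.donor, j.acceptor) for j in rev
        ]

    def test_intron_past_chromosome_end_errors(self):
        genome = GenomeSet("H", {"chr1": "A" * 120})
        t = make_transcript([(50, 100), (200, 250)])
        with pytest.raises(ValidationError):
            psio.extract_junctions(t, genome)


class TestExpressionIO:
    @staticmethod
    def _write(tmp_path, samples, transcripts, tpm):
        meta = tmp_path / "meta.tsv"
        rows = ["sample_id\tspecies\treplicate\tbatch"]
        paths = {}
        for i, s in enumerate(samples):
            rows.append(f"{s}\t{s[0]}\t{i + 1}\tb1")
            tab = tmp_path / f"ab_{s}.tsv"
            lines = ["target_id\test_counts\ttpm"]
            for t, v in zip(transcripts, tpm[s]):
                lines.append(f"{t}\t{v * 10}\t{v}")
            tab.write_text("\n".join(lines) + "\n")
            paths[s] = tab
        meta.write_text("\n".join(rows) + "\n")
        return paths, meta

    def test_matrix_assembled_from_abundance_files(self, tmp_path):
        paths, meta = self._write(
            tmp_path, ["H1"], ["tA", "tB"], {"H1": [5.0, 0.0]}
        )
        expr = psio.read_expression(paths, meta)
        assert expr.tpm.shape == (2, 1)
        assert expr.tpm.loc["tA", "H1"] == 5.0
        assert expr.counts.loc["tB", "H1"] == 0.0

    def test_duplicated_transcript_id_rejected(self, tmp_path):
        paths, meta = self._write(tmp_path, ["H1"], ["tA", "tA"], {"H1": [1.0, 2.0]})
        with pytest.raises(ValidationError, match="duplicated"):
            psio.read_expression(paths, meta)

    def test_sample_without_file_rejected(self, tmp_path):
        paths, meta = self._write(tmp_path, ["H1"], ["tA"], {"H1": [1.0]})
        meta.write_text(
            "sample_id\tspecies\treplicate\tbatch\nH1\tH\t1\tb1\nH2\tH\t2\tb1\n"
        )
        with pytest.raises(ValidationError, match="without abundance"):
            psio.read_expression(paths, meta)

    def test_negative_tpm_rejected(self, tmp_path):
        paths, meta = self._write(tmp_path, ["H1"], ["tA"], {"H1": [-1.0]})
        with pytest.raises(ValidationError):
            psio.read_expression(paths, meta)

    def test_column_sums_invariant_under_row_reordering(self):
        rng = np.random.default_rng(3)
        tpm = pd.DataFrame(rng.random((6, 4)), index=list("abcdef"),
                           columns=["H1", "H2", "C1", "C2"])
        meta = pd.DataFrame(
            {"sample_id": ["H1", "H2", "C1", "C2"],
             "species": ["H", "H", "C", "C"],
             "replicate": [1, 2, 1, 2]}
        )
        m1 = ExpressionMatrix(tpm=tpm, samples=meta)
        m2 = ExpressionMatrix(tpm=tpm.sample(frac=1, random_state=0), samples=meta)
        assert np.allclose(m1.tpm.sum(axis=0), m2.tpm.sum(axis=0))


class TestWriteTables:
    def test_round_trip_preserves_content(self, tmp_path):
        tab = pd.DataFrame(
            {"transcript_id": [f"t{i}" for i in range(10)],
             "value": np.arange(10) * 0.5}
        )
        psio.write_tables({"result": tab}, tmp_path)
        back = pd.read_csv(tmp_path / "result.tsv", sep="\t")
        pd.testing.assert_frame_equal(
            back.sort_values("transcript_id").reset_index(drop=True),
            tab.sort_values("transcript_id").reset_index(drop=True),
        )

    def test_empty_table_writes_header_only(self, tmp_path):
        tab = pd.DataFrame(columns=["a", "b"])
        psio.write_tables({"empty": tab}, tmp_path, allow_empty=True)
        assert (tmp_path / "empty.tsv").read_text().strip() == "a\tb"

    def test_empty_table_without_flag_errors(self, tmp_path):
        with pytest.raises(ValidationError):
            psio.write_tables({"x": pd.DataFrame(columns=["a"])}, tmp_path,
                              allow_empty=False)


class TestGenomeSet:
    def test_alphabet_enforced_and_uppercased(self):
        g = GenomeSet("H", {"chr1": "acgtn"})
        assert g.sequences["chr1"] == "ACGTN"
        with pytest.raises(ValidationError):
            GenomeSet("H", {"chr1": "ACGX"})

    def test_junction_requires_min_intron(self):
        with pytest.raises(ValidationError):
            SpliceJunction("chr1", "+", 100, 103)
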
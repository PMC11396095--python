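import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitocms.genome_io import (
    CircularGenome,
    GeneCategory,
    GeneModel,
    Interval,
    Topology,
    extract,
    gc_content,
    read_fasta,
    read_gff3,
    reverse_complement,
    write_gff3,
)


def _write(tmp_path, text, name="g.fasta"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadFasta:
    def test_single_record_counts(self, tmp_path):
        (g,) = read_fasta(_write(tmp_path, ">g\nACGT\n"))
        assert g.length == 4
        assert gc_content(g) == 0.5

    def test_lowercase_upcased(self, tmp_path):
        (g,) = read_fasta(_write(tmp_path, ">g\nacgtn\n"))
        assert g.sequence == "ACGTN"

    def test_two_records_in_order(self, tmp_path):
        gs = read_fasta(_write(tmp_path, ">a\nAAAA\n>b\nCCCC\n"))
        assert [g.id for g in gs] == ["a", "b"]

    def test_empty_file_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            read_fasta(_write(tmp_path, ""))

    def test_non_iupac_rejected_with_positions(self, tmp_path):
        with pytest.raises(ValueError, match="position"):
            read_fasta(_write(tmp_path, ">g\nACGTX\n"))


class TestGcContent:
    @pytest.mark.parametrize("seq,frac", [("ATAT", 0.0), ("GCGC", 1.0), ("ACGT", 0.5)])
    def test_examples(self, seq, frac):
        assert gc_content(seq) == frac

    def test_n_excluded_from_denominator(self):
        assert gc_content("GCNN") == 1.0

    def test_all_n_is_an_error(self):
        with pytest.raises(ValueError):
            gc_content("NNNN")

    def test_matches_independent_counter_on_random_sequence(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGTN"), size=10_000))
        expected = sum(c in "GC" for c in seq) / sum(c != "N" for c in seq)
        assert gc_content(seq) == pytest.approx(expected)

    def test_invariant_under_reverse_complement(self):
        rng = np.random.default_rng(1)
        seq = "".join(rng.choice(list("ACGT"), size=501))
        assert gc_content(seq) == pytest.approx(gc_content(reverse_complement(seq)))


class TestExtract:
    g = CircularGenome("g", "AAACCC")

    def test_plain_slice(self):
        assert extract(self.g, Interval(4, 6)) == "CC"

    def test_origin_crossing(self):
        assert extract(self.g, Interval(5, 1, wraps=True)) == "CA"

    def test_minus_strand_reverse_complements(self):
        assert extract(CircularGenome("g", "ATGAAA"), Interval(0, 3, "-")) == "CAT"

    def test_wrap_on_linear_genome_rejected(self):
        lin = CircularGenome("g", "AAACCC", Topology.LINEAR)
        with pytest.raises(ValueError):
            extract(lin, Interval(5, 1, wraps=True))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 59), st.integers(1, 59), st.integers(0, 59))
    def test_rotation_invariance(self, start, span, offset):
        rng = np.random.default_rng(3)
        seq = "".join(rng.choice(list("ACGT"), size=60))
        g = CircularGenome("g", seq)
        iv = Interval(start, start + span) if start + span <= 60 else Interval(
            start, (start + span) % 60, wraps=True
        )
        rotated = CircularGenome("g", seq[offset:] + seq[:offset])
        iv_rot = iv.shifted(-offset % 60, 60)
        assert extract(g, iv) == extract(rotated, iv_rot)

    def test_double_reverse_complement_is_identity(self):
        rng = np.random.default_rng(4)
        seq = "".join(rng.choice(list("ACGT"), size=100))
        assert reverse_complement(reverse_complement(seq)) == seq


class TestGff3RoundTrip:
    def test_fifty_gene_annotation_round_trips(self, tmp_path):
        rng = np.random.default_rng(5)
        L = 200_000
        genome = CircularGenome("chr", "".join(rng.choice(list("ACGT"), size=L)))
        cats = list(GeneCategory)
        models = []
        pos = 100
        for k in range(50):
            span = int(rng.integers(90, 900)) * 3
            strand = "+" if rng.random() < 0.5 else "-"
            name = f"g{k}" if k % 5 else f"g{k}-D2"
            models.append(
                GeneModel(
                    name,
                    cats[k % len(cats)],
                    [Interval(pos, pos + span, strand)],
                    coding=k % 3 != 0,
                )
            )
            pos += span + 120
        path = tmp_path / "ann.gff3"
        write_gff3(models, genome, path)
        back = read_gff3(path, genome)
        key = lambda m: (m.name, m.category, m.coding, [
            (iv.start, iv.end, iv.strand, iv.wraps) for iv in m.intervals
        ])
        assert [key(m) for m in back] == [key(m) for m in sorted(
            models, key=lambda m: (m.span_interval().start, m.name))]

    def test_wrapping_exon_round_trips(self, tmp_path):
        genome = CircularGenome("chr", "ACGT" * 300)
        m = GeneModel("wrapgene", GeneCategory.OTHER, [Interval(1100, 101, "+", wraps=True)])
        path = tmp_path / "w.gff3"
        write_gff3([m], genome, path)
        (back,) = read_gff3(path, genome)
        assert back.intervals[0] == Interval(1100, 101, "+", wraps=True)

    def test_disk_convention_is_one_based_inclusive(self, tmp_path):
        genome = CircularGenome("chr", "ACGTACGTACGT")
        m = GeneModel("x", GeneCategory.OTHER, [Interval(0, 3, "+")])
        path = tmp_path / "c.gff3"
        write_gff3([m], genome, path)
        line = [l for l in path.read_text().splitlines() if not l.startswith("#")][0]
        fields = line.split("\t")
        assert (fields[3], fields[4]) == ("1", "3")
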
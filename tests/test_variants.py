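import numpy as np
import pytest

from mitocms.annotate import translate
from mitocms.genome_io import CircularGenome, GeneCategory, GeneModel, Interval, extract
from mitocms.variants import (
    _left_normalize_deletion,
    _left_normalize_insertion,
    classify_snp_effect,
    summarize_variants,
    write_vcf,
)


def _genome_with_gene(strand="+"):
    rng = np.random.default_rng(31)
    bg = list("".join(rng.choice(list("ACGT"), size=3000)))
    cds = "ATG" + "GAT" * 50 + "TAA"  # M + 50x Asp
    from mitocms.genome_io import reverse_complement

    written = cds if strand == "+" else reverse_complement(cds)
    bg[1000 : 1000 + len(cds)] = list(written)
    g = CircularGenome("ref", "".join(bg))
    model = GeneModel(
        "dgene", GeneCategory.OTHER, [Interval(1000, 1000 + len(cds), strand)]
    )
    return g, model


class TestEffectClassification:
    def test_synonymous_third_position(self):
        g, m = _genome_with_gene("+")
        # codon 1 is GAT (Asp): position 1002+... codon index 1 starts at 1003
        pos = 1003 + 2  # third base of first GAT
        effect, cref, calt, aref, aalt = classify_snp_effect(g, m, pos, "C")
        assert (effect, cref, calt, aref, aalt) == ("synonymous", "GAT", "GAC", "D", "D")

    def test_nonsynonymous_second_position(self):
        g, m = _genome_with_gene("+")
        pos = 1003 + 1  # GAT -> GCT
        effect, cref, calt, aref, aalt = classify_snp_effect(g, m, pos, "C")
        assert (effect, aref, aalt) == ("nonsynonymous", "D", "A")

    def test_minus_strand_codon_arithmetic(self):
        g, m = _genome_with_gene("-")
        # third base of codon 1 in CDS coords = genome pos iv.end-1-5
        iv = m.intervals[0]
        pos = iv.end - 1 - 5
        alt_genome = "G"  # complements to C in CDS orientation -> GAC
        effect, cref, calt, aref, aalt = classify_snp_effect(g, m, pos, alt_genome)
        assert (effect, cref, calt) == ("synonymous", "GAT", "GAC")

    def test_every_called_cds_snp_agrees_with_whole_protein_oracle(self, default_run):
        """Codon-shortcut effects re-derived by translating the entire
        mutated CDS; all CDS SNP calls must agree."""
        ref = default_run.maintainer
        models = {m.name: m for m in default_run.maintainer_models}
        checked = 0
        for s in default_run.comparison.snps:
            if s.region != "CDS":
                continue
            m = models[s.gene]
            cds = "".join(extract(ref, iv) for iv in m.intervals)
            iv = m.intervals[0]
            if iv.strand == "+":
                off = s.ref_pos - iv.start
                alt = s.alt_base
            else:
                off = iv.end - 1 - s.ref_pos
                from mitocms.genome_io import reverse_complement

                alt = reverse_complement(s.alt_base)
            mutated = cds[:off] + alt + cds[off + 1 :]
            p0 = translate(cds, allow_internal_stop=True)
            p1 = translate(mutated, allow_internal_stop=True)
            assert (p0 == p1) == (s.effect == "synonymous")
            checked += 1
        assert checked == 24  # 5 synonymous + 19 non-synonymous planted


class TestIndelNormalization:
    def test_deletion_shifts_to_run_start(self):
        #        0123456789
        ref = "GGTAAAACTG"
        # deleting any single A in the run normalizes to position 3
        for pos in (3, 4, 5, 6):
            assert _left_normalize_deletion(ref, pos, 1) == 3

    def test_multibase_deletion_in_tandem_context(self):
        ref = "GACACACTT"
        assert _left_normalize_deletion(ref, 3, 2) == 1

    def test_insertion_normalizes_sequence_too(self):
        ref = "GGTAAAACTG"
        pos, seq = _left_normalize_insertion(ref, 7, "A")
        assert (pos, seq) == (3, "A")

    def test_normalization_idempotent(self):
        ref = "GGTAAAACTG"
        p1 = _left_normalize_deletion(ref, 5, 1)
        assert _left_normalize_deletion(ref, p1, 1) == p1


class TestCallingOnSyntheticPair:
    def test_indel_records_match_truth_exactly(self, default_run):
        truth = {
            (i.ref_pos, i.type, i.length, i.seq) for i in default_run.pair.truth.indels
        }
        called = {
            (i.ref_pos, i.type, i.length, i.seq) for i in default_run.comparison.indels
        }
        assert called == truth

    def test_flanks_are_100bp_and_match_reference(self, default_run):
        ref = default_run.maintainer
        for s in default_run.comparison.snps[:20]:
            assert len(s.flank_left) == 100 and len(s.flank_right) == 100
            assert ref.sequence[s.ref_pos - 100 : s.ref_pos] == s.flank_left

    def test_summary_counts(self, default_run):
        df = summarize_variants(default_run.comparison.snps, default_run.comparison.indels)
        d = {(g, k): c for g, k, c in df.itertuples(index=False)}
        assert d[("snp_effect", "synonymous")] == 5
        assert d[("snp_effect", "nonsynonymous")] == 19
        assert d[("total", "snps")] == 58
        assert d[("indel_type", "insertion")] == 6
        assert d[("indel_type", "deletion")] == 12

    def test_summary_empty(self):
        df = summarize_variants([], [])
        assert df["count"].sum() == 0


class TestVcfRoundTrip:
    def test_pysam_reproduces_records(self, tmp_path, default_run):
        pysam = pytest.importorskip("pysam")
        path = tmp_path / "v.vcf"
        write_vcf(
            default_run.comparison.snps,
            default_run.comparison.indels,
            default_run.maintainer,
            path,
        )
        snps = {}
        indels = {}
        for rec in pysam.VariantFile(str(path)):
            info = dict(rec.info)
            if info["TYPE"] == "snp":
                snps[rec.pos - 1] = (rec.ref, rec.alts[0], info["EFFECT"], info["REGION"])
            else:
                indels[(rec.pos, info["TYPE"])] = (rec.ref, rec.alts[0], info["LEN"])
        for s in default_run.comparison.snps:
            assert snps[s.ref_pos] == (s.ref_base, s.alt_base, s.effect, s.region)
        for i in default_run.comparison.indels:
            got = indels[(i.ref_pos, i.type)]
            assert got[2] == i.length
            if i.type == "deletion":
                assert got[0][1:] == i.seq
            else:
                assert got[1][1:] == i.seq
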
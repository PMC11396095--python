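import numpy as np
import pytest

from mitocms.annotate import (
    RefProtein,
    annotate_known_genes,
    find_orfs,
    translate,
)
from mitocms.genome_io import (
    CircularGenome,
    GeneCategory,
    Topology,
    extract,
    reverse_complement,
)
from mitocms.simulate import SimConfig, generate_maintainer, reverse_translate
from mitocms import refs

from oracles import brute_force_orfs, translate_table

ISOLATOR = "CTAGCTAGCTAG"  # stops in all six frames, no ATG


def _random_seq(seed, n):
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list("ACGT"), size=n))


class TestFindOrfs:
    def test_exactly_100_codons_is_reported(self):
        g = CircularGenome("g", ISOLATOR * 3 + "ATG" + "AAA" * 99 + "TAA" + ISOLATOR * 3)
        orfs = find_orfs(g, min_aa=100)
        assert len(orfs) == 1
        assert orfs[0].aa_length == 100
        assert orfs[0].id == "orf100a"

    def test_99_codons_is_below_threshold(self):
        g = CircularGenome("g", ISOLATOR * 3 + "ATG" + "AAA" * 98 + "TAA" + ISOLATOR * 3)
        assert find_orfs(g, min_aa=100) == []

    def test_min_aa_must_be_positive(self):
        with pytest.raises(ValueError):
            find_orfs(CircularGenome("g", "ACGT" * 100), min_aa=0)

    def test_origin_crossing_orf_found_once(self):
        core = "ATG" + "GAA" * 120 + "TAG"
        seq = core[200:] + ISOLATOR * 4 + core[:200]
        g = CircularGenome("g", seq)
        orfs = find_orfs(g, min_aa=100)
        assert len(orfs) == 1
        assert orfs[0].wraps
        assert orfs[0].aa_length == 121

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_scanner_on_random_genomes(self, seed):
        seq = _random_seq(seed, 5000)
        g = CircularGenome("g", seq)
        got = {
            (o.interval.start, o.interval.span(g.length), o.interval.strand)
            for o in find_orfs(g, min_aa=50)
        }
        assert got == brute_force_orfs(seq, True, 50)

    def test_rotation_invariance_of_orf_set(self):
        seq = _random_seq(77, 4000)
        g = CircularGenome("g", seq)
        off = 1234
        rot = CircularGenome("g", seq[off:] + seq[:off])
        a = sorted(
            ((o.interval.start + off) % 4000, o.interval.span(4000), o.interval.strand, o.protein)
            for o in find_orfs(rot, min_aa=50)
        )
        b = sorted(
            (o.interval.start, o.interval.span(4000), o.interval.strand, o.protein)
            for o in find_orfs(g, min_aa=50)
        )
        assert a == b

    def test_every_orf_retranslates_to_its_protein(self):
        g = CircularGenome("g", _random_seq(9, 6000))
        for o in find_orfs(g, min_aa=50):
            assert translate(extract(g, o.interval)) == o.protein
            assert o.protein.startswith("M")
            assert "*" not in o.protein


class TestTranslate:
    @pytest.mark.parametrize("cds,prot", [("ATGTTTTAA", "MF"), ("ATGTAA", "M")])
    def test_examples(self, cds, prot):
        assert translate(cds) == prot

    def test_length_must_be_codon_multiple(self):
        with pytest.raises(ValueError):
            translate("ATGT")

    def test_ambiguity_codes_rejected(self):
        with pytest.raises(ValueError):
            translate("ATGNNN")

    def test_internal_stop_reported_not_truncated(self):
        with pytest.raises(ValueError, match="internal stop"):
            translate("ATGTAATTT")
        assert translate("ATGTAATTT", allow_internal_stop=True) == "M*F"

    def test_matches_independent_codon_table(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            n = int(rng.integers(2, 60)) * 3
            cds = "".join(rng.choice(list("ACGT"), size=n))
            expected = translate_table(cds)
            if expected.endswith("*"):
                expected = expected[:-1]
            assert translate(cds, allow_internal_stop=True) == expected


class TestAnnotateKnownGenes:
    def _embed(self, protein, seed=3, strand="+", copies=1):
        rng = np.random.default_rng(seed)
        bg = list(_random_seq(seed + 1, 9000))
        spots = []
        pos = 500
        for _ in range(copies):
            cds = reverse_translate(protein, rng)
            written = cds if strand == "+" else reverse_complement(cds)
            bg[pos : pos + len(cds)] = list(written)
            spots.append((pos, pos + len(cds)))
            pos += len(cds) + 1500
        return CircularGenome("g", "".join(bg)), spots

    def test_exact_copy_recovered_with_exact_coordinates(self):
        rp = refs.reference_proteins()[0]
        g, [(s, e)] = self._embed(rp.protein)
        models = [m for m in annotate_known_genes(g, [rp]) if m.base_name == rp.name]
        assert len(models) == 1
        iv = models[0].intervals[0]
        assert (iv.start, iv.end, iv.strand) == (s, e, "+")

    def test_minus_strand_copy_recovered(self):
        rp = refs.reference_proteins()[1]
        g, [(s, e)] = self._embed(rp.protein, strand="-")
        (m,) = [m for m in annotate_known_genes(g, [rp]) if m.base_name == rp.name]
        assert (m.intervals[0].start, m.intervals[0].end, m.strand) == (s, e, "-")

    def test_two_disjoint_copies_named_in_coordinate_order(self):
        rp = refs.reference_proteins()[2]
        g, spots = self._embed(rp.protein, copies=2)
        models = [m for m in annotate_known_genes(g, [rp]) if m.base_name == rp.name]
        assert [m.name for m in models] == [rp.name, f"{rp.name}-D2"]
        assert models[0].intervals[0].start == spots[0][0]

    def test_diverged_copy_still_recovered(self):
        rp = refs.reference_proteins()[3]
        rng = np.random.default_rng(21)
        prot = list(rp.protein)
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        for i in rng.choice(len(prot) - 1, size=len(prot) // 10, replace=False):
            prot[i + 1] = aas[int(rng.integers(20))]
        g, [(s, e)] = self._embed("".join(prot))
        hits = [m for m in annotate_known_genes(g, [rp]) if m.base_name == rp.name]
        assert len(hits) == 1

    def test_empty_reference_set_rejected(self):
        with pytest.raises(ValueError):
            annotate_known_genes(CircularGenome("g", "ACGT" * 100), [])

    def test_maintainer_complement_fully_recovered(self):
        """Primary recovery check: the full planted gene complement comes
        back with exact coordinates from translated homology alone."""
        genome, models = generate_maintainer(SimConfig(seed=2))
        coding = {
            m.name: m for m in models if m.coding
        }
        found = {
            m.name: m
            for m in annotate_known_genes(genome, refs.reference_proteins())
        }
        assert set(found) == set(coding)
        for name, m in coding.items():
            got = found[name].intervals[0]
            want = m.intervals[0]
            assert (got.start, got.end, got.strand) == (want.start, want.end, want.strand)
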
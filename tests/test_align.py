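import numpy as np
import pytest

from mitocms.align_core import (
    Anchor,
    align_gaps,
    align_pair_score,
    chain_anchors,
    find_anchors,
)
from mitocms.genome_io import CircularGenome, reverse_complement

from oracles import exhaustive_best_chain_score, gotoh_score


def _random_seq(seed, n):
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list("ACGT"), size=n))


class TestFindAnchors:
    def test_identical_genomes_give_one_full_length_anchor(self):
        seq = _random_seq(0, 2000)
        a, b = CircularGenome("a", seq), CircularGenome("b", seq)
        anchors = find_anchors(a, b)
        assert len(anchors) == 1
        assert (anchors[0].ref_start, anchors[0].qry_start, anchors[0].length) == (0, 0, 2000)
        assert anchors[0].strand == "+"

    def test_reverse_complement_gives_minus_anchor(self):
        seq = _random_seq(1, 1500)
        anchors = find_anchors(
            CircularGenome("a", seq), CircularGenome("b", reverse_complement(seq))
        )
        assert len(anchors) == 1
        assert anchors[0].strand == "-"
        assert anchors[0].length == 1500

    def test_min_anchor_guard(self):
        g = CircularGenome("a", _random_seq(2, 100))
        with pytest.raises(ValueError):
            find_anchors(g, g, min_anchor=4)

    def test_anchors_are_exact_and_unique(self):
        ref = _random_seq(3, 4000)
        # translocate a 1 kb slice
        qry = ref[:500] + ref[1500:2500] + ref[500:1500] + ref[2500:]
        A, B = CircularGenome("a", ref), CircularGenome("b", qry)
        for a in find_anchors(A, B, 20):
            pat = ref[a.ref_start : a.ref_end]
            seg = qry[a.qry_start : a.qry_end]
            if a.strand == "-":
                seg = reverse_complement(seg)
            assert pat == seg
            assert ref.count(pat) == 1
            assert (qry + reverse_complement(qry)).count(pat if a.strand == "+" else reverse_complement(pat)) == 1


class TestChaining:
    def test_identical_genomes_single_chain(self):
        seq = _random_seq(4, 3000)
        anchors = find_anchors(CircularGenome("a", seq), CircularGenome("b", seq))
        chains = chain_anchors(anchors)
        assert len(chains) == 1
        assert chains[0].score == 3000

    def test_no_anchor_shared_between_chains(self):
        ref = _random_seq(5, 8000)
        qry = ref[:2000] + ref[5000:6500] + ref[2000:5000] + ref[6500:]
        anchors = find_anchors(CircularGenome("a", ref), CircularGenome("b", qry))
        chains = chain_anchors(anchors, min_chain_bp=400)
        seen = set()
        for c in chains:
            for a in c.anchors:
                assert id(a) not in seen
                seen.add(id(a))

    @pytest.mark.parametrize("seed", range(8))
    def test_best_chain_score_matches_exhaustive_search(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 13))
        tuples = []
        for _ in range(n):
            r = int(rng.integers(0, 4000))
            q = int(rng.integers(0, 4000))
            l = int(rng.integers(20, 300))
            tuples.append((r, q, l))
        anchors = [Anchor(r, q, l, "+") for r, q, l in tuples]
        chains = chain_anchors(anchors, min_chain_bp=1)
        got = max(c.score for c in chains)
        want = exhaustive_best_chain_score(tuples)
        assert got == pytest.approx(want)


class TestGapAlignment:
    @pytest.mark.parametrize(
        "a,b,n_match,n_cols",
        [("ACGT", "ACGT", 4, 4), ("ACGT", "AGT", 3, 4)],
    )
    def test_tiny_examples(self, a, b, n_match, n_cols):
        ref = _random_seq(6, 600) + a + _random_seq(7, 600)
        qry = ref[:600] + b + ref[604:]
        A, B = CircularGenome("a", ref), CircularGenome("b", qry)
        chains = chain_anchors(find_anchors(A, B))
        ba = align_gaps(A, B, chains[0])
        assert sum(1 for c in ba.columns if c[2]) >= 1195 + n_match

    @pytest.mark.parametrize("seed", range(10))
    def test_scores_match_textbook_dynamic_programming(self, seed):
        rng = np.random.default_rng(200 + seed)
        for _ in range(20):
            la, lb = int(rng.integers(0, 51)), int(rng.integers(0, 51))
            a = "".join(rng.choice(list("ACGT"), size=la))
            b = "".join(rng.choice(list("ACGT"), size=lb))
            assert align_pair_score(a, b) == pytest.approx(gotoh_score(a, b))

    def test_projection_columns_match_genomes(self, default_run):
        ref = default_run.maintainer
        qry = default_run.sterile
        for ba in default_run.comparison.alignments:
            minus = ba.chain.strand == "-"
            for rp, qp, m in ba.columns[:5000]:
                if rp is None or qp is None:
                    continue
                qb = qry.sequence[qp]
                if minus:
                    qb = reverse_complement(qb)
                assert m == (ref.sequence[rp] == qb)

    def test_band_overflow_escalates_not_truncates(self):
        ref = _random_seq(8, 3000) + _random_seq(9, 2500) + _random_seq(10, 3000)
        qry = ref[:3000] + _random_seq(11, 2600) + ref[5500:]
        A, B = CircularGenome("a", ref), CircularGenome("b", qry)
        chains = chain_anchors(find_anchors(A, B))
        ba = align_gaps(A, B, chains[0], band=2000)
        assert any(e.reason in ("band", "complex") for e in ba.escalations)

    def test_snp_only_pair_covered_by_single_chain(self):
        seq = list(_random_seq(12, 30000))
        rng = np.random.default_rng(13)
        qry = list(seq)
        for p in rng.choice(30000, size=20, replace=False):
            qry[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[qry[p]]
        A = CircularGenome("a", "".join(seq))
        B = CircularGenome("b", "".join(qry))
        chains = chain_anchors(find_anchors(A, B))
        assert len(chains) == 1
        rs, re = chains[0].ref_span
        qs, qe = chains[0].qry_span
        assert (re - rs) >= 0.999 * 30000
        assert (qe - qs) >= 0.999 * 30000

    def test_swap_symmetry_of_chains(self):
        ref = _random_seq(14, 6000)
        qry = ref[:1000] + reverse_complement(ref[1000:2500]) + ref[2500:]
        A, B = CircularGenome("a", ref), CircularGenome("b", qry)
        fwd = chain_anchors(find_anchors(A, B), min_chain_bp=400)
        rev = chain_anchors(find_anchors(B, A), min_chain_bp=400)
        assert sorted((c.strand, c.ref_span) for c in fwd) == sorted(
            (c.strand, c.qry_span) for c in rev
        )
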
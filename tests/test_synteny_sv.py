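from collections import Counter

import pytest

from mitocms.config import PipelineConfig
from mitocms.pipeline import compare_genomes
from mitocms.simulate import build_pair
from mitocms.synteny_sv import aligned_intervals

from conftest import bare_sim_config


def _compare_pair(ref_pair, cfg=None):
    return compare_genomes(
        ref_pair.maintainer,
        ref_pair.sterile,
        ref_pair.maintainer_models,
        cfg or PipelineConfig(seed=1),
    )


class TestBlockClassification:
    def test_identical_genomes_one_collinear_block(self, plain_pair):
        comp = _compare_pair(plain_pair)
        assert [b.klass for b in comp.blocks] == ["collinear"]
        assert comp.coverage.pct_homologous_ref == pytest.approx(100.0)
        assert comp.coverage.pct_homologous_qry == pytest.approx(100.0)
        assert comp.coverage.qry_unique_intervals == []

    def test_single_inversion_labeled_with_collinear_flanks(self):
        pair = build_pair(bare_sim_config(sv_plan=[("inversion", 2000)], seed=6))
        ev = pair.truth.sv_events[0]
        # outside the inverted interval the genomes are identical
        st, mt = pair.sterile.sequence, pair.maintainer.sequence
        assert st[: ev.qry_start] == mt[: ev.ref_start]
        assert st[ev.qry_end :] == mt[ev.ref_end :]
        comp = _compare_pair(pair)
        assert Counter(b.klass for b in comp.blocks) == {"collinear": 1, "inversion": 1}
        inv = next(b for b in comp.blocks if b.klass == "inversion")
        assert abs(inv.ref_span[0] - ev.ref_start) <= 25
        assert abs(inv.ref_span[1] - ev.ref_end) <= 25

    def test_deletion_and_insertion_events(self):
        pair = build_pair(
            bare_sim_config(sv_plan=[("deletion", 300), ("insertion", 400)], seed=7)
        )
        comp = _compare_pair(pair)
        klasses = Counter(e.klass for e in comp.sv_events if e.klass != "residue")
        assert klasses == {"deletion": 1, "insertion": 1}
        dele = next(e for e in comp.sv_events if e.klass == "deletion")
        t = next(e for e in pair.truth.sv_events if e.type == "deletion")
        assert abs(dele.ref_span[0] - t.ref_start) <= 25
        assert abs(dele.size - 300) <= 25

    def test_complex_region_called_when_unrelated_sequences_face_off(self):
        pair = build_pair(bare_sim_config(sv_plan=[("complex", 300)], seed=8))
        comp = _compare_pair(pair)
        klasses = Counter(e.klass for e in comp.sv_events if e.klass != "residue")
        assert klasses == {"complex_indel": 1}

    def test_translocation_vs_trans_inver_labels(self):
        pair = build_pair(
            bare_sim_config(
                sv_plan=[("translocation", 2500), ("trans_inver", 2000)], seed=9
            )
        )
        comp = _compare_pair(pair)
        got = Counter(b.klass for b in comp.blocks)
        assert got == {"collinear": 1, "translocation": 1, "trans_inver": 1}

    def test_full_default_plan_recovers_truth_multiset(self, default_run):
        tr = default_run.pair.truth
        called = Counter(
            [e.klass for e in default_run.comparison.sv_events if e.klass != "residue"]
            + [b.klass for b in default_run.comparison.blocks if b.klass != "collinear"]
        )
        assert called == Counter(e.type for e in tr.sv_events)


class TestConservation:
    def test_every_query_base_is_accounted_for(self, default_run):
        """Partition check: aligned coverage + SV/residue holes == genome."""
        comp = default_run.comparison
        L = default_run.sterile.length
        _, qry_cov = aligned_intervals(comp.alignments)
        holes = [
            e.qry_span for e in comp.sv_events if e.qry_span[1] > e.qry_span[0]
        ]
        total = sum(e - s for s, e in qry_cov) + sum(e - s for s, e in holes)
        assert total == L

    def test_swap_maps_insertions_to_deletions(self):
        pair = build_pair(
            bare_sim_config(sv_plan=[("deletion", 300), ("insertion", 400)], seed=10)
        )
        cfg = PipelineConfig(seed=1)
        fwd = compare_genomes(pair.maintainer, pair.sterile, pair.maintainer_models, cfg)
        rev = compare_genomes(pair.sterile, pair.maintainer, [], cfg)
        f = Counter(e.klass for e in fwd.sv_events if e.klass != "residue")
        r = Counter(e.klass for e in rev.sv_events if e.klass != "residue")
        assert f == {"deletion": 1, "insertion": 1}
        assert r == {"deletion": 1, "insertion": 1}
        f_del = next(e for e in fwd.sv_events if e.klass == "deletion")
        r_ins = next(e for e in rev.sv_events if e.klass == "insertion")
        assert abs(f_del.size - r_ins.size) <= 2

    def test_coverage_percentages_bounded(self, default_run):
        cov = default_run.comparison.coverage
        assert 0 <= cov.pct_homologous_ref <= 100
        assert 0 <= cov.pct_homologous_qry <= 100
        ivs = cov.qry_unique_intervals
        assert ivs == sorted(ivs)
        assert all(a < b for a, b in ivs)
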
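import numpy as np
import pytest

from mitocms.annotate import translate
from mitocms.genome_io import extract, Interval, reverse_complement
from mitocms.simulate import (
    ChimeraPlan,
    SimConfig,
    build_pair,
    generate_maintainer,
)

from conftest import bare_sim_config


class TestGenerateMaintainer:
    def test_zero_gene_config(self):
        cfg = bare_sim_config(genome_length=1000, gene_complement=[], noncoding=[])
        genome, models = generate_maintainer(cfg)
        assert genome.length == 1000
        assert models == []

    def test_same_seed_is_byte_identical(self):
        a, _ = generate_maintainer(SimConfig(seed=4))
        b, _ = generate_maintainer(SimConfig(seed=4))
        assert a.sequence == b.sequence

    def test_different_seed_differs(self):
        a, _ = generate_maintainer(SimConfig(seed=4))
        b, _ = generate_maintainer(SimConfig(seed=5))
        assert a.sequence != b.sequence

    def test_gc_near_target(self):
        g, _ = generate_maintainer(SimConfig(seed=4))
        from mitocms.genome_io import gc_content

        assert abs(gc_content(g) - 0.446) < 0.02

    def test_duplicate_copies_named_in_coordinate_order(self):
        _, models = generate_maintainer(SimConfig(seed=4))
        by_base = {}
        for m in models:
            by_base.setdefault(m.base_name, []).append(m)
        for base, copies in by_base.items():
            copies.sort(key=lambda m: m.span_interval().start)
            for k, m in enumerate(copies):
                assert m.name == (base if k == 0 else f"{base}-D{k + 1}")

    def test_overfull_complement_rejected(self):
        cfg = bare_sim_config(genome_length=5000)
        with pytest.raises((ValueError, RuntimeError)):
            generate_maintainer(cfg)


class TestDeriveSterile:
    def test_determinism_across_builds(self):
        a = build_pair(SimConfig(seed=6))
        b = build_pair(SimConfig(seed=6))
        assert a.sterile.sequence == b.sterile.sequence
        assert a.truth.unique_orf_ids == b.truth.unique_orf_ids

    def test_truth_snps_verify_against_both_genomes(self, default_pair):
        for s in default_pair.truth.snps:
            assert default_pair.maintainer.sequence[s.ref_pos] == s.ref
            assert default_pair.sterile.sequence[s.qry_pos] == s.alt
            assert s.ref != s.alt

    def test_truth_indels_verify_against_genomes(self, default_pair):
        m, st = default_pair.maintainer.sequence, default_pair.sterile.sequence
        for i in default_pair.truth.indels:
            if i.type == "deletion":
                assert m[i.ref_pos : i.ref_pos + i.length] == i.seq
            else:
                assert st[i.qry_pos : i.qry_pos + i.length] == i.seq

    def test_planted_effects_verified_by_direct_translation(self, default_pair):
        models = {m.name: m for m in default_pair.maintainer_models}
        for s in default_pair.truth.snps:
            if s.effect not in ("synonymous", "nonsynonymous"):
                continue
            m = models[s.gene]
            iv = m.intervals[0]
            cds = extract(default_pair.maintainer, iv)
            off = s.ref_pos - iv.start if iv.strand == "+" else iv.end - 1 - s.ref_pos
            alt = s.alt if iv.strand == "+" else reverse_complement(s.alt)
            mutated = cds[:off] + alt + cds[off + 1 :]
            same = translate(cds) == translate(mutated, allow_internal_stop=True)
            assert same == (s.effect == "synonymous")

    def test_truth_orfs_extract_to_orfs(self, default_pair):
        for o in default_pair.truth.orfs:
            seq = default_pair.sterile.sequence[o.qry_start : o.qry_end]
            prot = translate(seq)
            assert prot.startswith("M")
            assert len(prot) == o.aa_length

    def test_unit_arithmetic(self, default_pair):
        unit = default_pair.truth.co_transcript_unit
        plan = ChimeraPlan()
        assert unit["unit_length"] == plan.unit_length(110) == 2996
        orf5 = next(o for o in default_pair.truth.orfs if o.kind == "chimera_5")
        orf3 = next(o for o in default_pair.truth.orfs if o.kind == "chimera_3")
        assert orf3.qry_end - orf5.qry_start == 2996

    def test_inversion_reverse_complements_interval(self):
        pair = build_pair(bare_sim_config(sv_plan=[("inversion", 1200)], seed=12))
        ev = pair.truth.sv_events[0]
        seg_ref = pair.maintainer.sequence[ev.ref_start : ev.ref_end]
        seg_qry = pair.sterile.sequence[ev.qry_start : ev.qry_end]
        assert seg_qry == reverse_complement(seg_ref)

    def test_conservation_edit_counts_match_config(self, default_pair):
        cfg = default_pair.config
        tr = default_pair.truth
        assert len(tr.snps) == cfg.n_snps
        assert len(tr.indels) == cfg.n_small_indels
        n_novel = 1 + 1 + len(cfg.extra_unique_orf_aa) + sum(
            1 for t, _ in cfg.sv_plan if t == "insertion"
        )
        expected = {t for t, _ in cfg.sv_plan} | {"insertion"}
        got_types = {e.type for e in tr.sv_events}
        assert got_types == {t if t != "complex" else "complex_indel" for t in expected}
        assert sum(1 for e in tr.sv_events if e.type == "insertion") == n_novel
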
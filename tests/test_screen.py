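import json

import numpy as np
import pytest

from mitocms.annotate import find_orfs
from mitocms.genome_io import CircularGenome
from mitocms.screen import find_unique_orfs, report, screen
from mitocms.tm_chimera import TmDomain


def _random_seq(seed, n):
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list("ACGT"), size=n))


class TestFindUniqueOrfs:
    def _orf_genome(self):
        cds = "ATG" + "GAA" * 150 + "TAA"
        iso = "CTAGCTAGCTAG"
        seq = _random_seq(51, 2000) + iso + cds + iso + _random_seq(52, 2000)
        sterile = CircularGenome("s", seq)
        (orf,) = find_orfs(sterile, 100)
        return sterile, orf, cds

    def test_exact_copy_in_maintainer_is_not_unique(self):
        sterile, orf, cds = self._orf_genome()
        maintainer = CircularGenome("m", _random_seq(53, 3000) + cds + _random_seq(54, 3000))
        ((_, unique),) = find_unique_orfs([orf], sterile, maintainer)
        assert not unique

    def test_half_copy_is_unique_at_default_thresholds(self):
        sterile, orf, cds = self._orf_genome()
        maintainer = CircularGenome(
            "m", _random_seq(55, 3000) + cds[: len(cds) // 2] + _random_seq(56, 3000)
        )
        ((_, unique),) = find_unique_orfs([orf], sterile, maintainer)
        assert unique

    def test_absent_sequence_is_unique(self):
        sterile, orf, _ = self._orf_genome()
        maintainer = CircularGenome("m", _random_seq(57, 6000))
        ((_, unique),) = find_unique_orfs([orf], sterile, maintainer)
        assert unique

    def test_unique_set_equals_truth(self, default_run):
        uniq = sorted(c.orf.id for c in default_run.candidates if c.unique_in_sterile)
        assert uniq == sorted(default_run.pair.truth.unique_orf_ids)


class TestScreenRule:
    def test_candidate_set_equals_truth(self, default_run):
        cands = sorted(
            c.orf.id for c in default_run.candidates if c.verdict == "candidate"
        )
        assert cands == sorted(default_run.pair.truth.candidate_orf_ids)

    def test_monotone_adding_tm_domain_flips_rejected_extra_orf(self, default_run):
        extra = next(o for o in default_run.pair.truth.orfs if o.kind == "extra")
        flags = [
            (c.orf, c.unique_in_sterile) for c in default_run.candidates
        ]
        fake_tm = [TmDomain(extra.id, 5, 25, 3.0)]
        redone = screen(
            flags,
            default_run.comparison.coverage.qry_unique_intervals,
            default_run.comparison.blocks,
            fake_tm,
            [],
            genome_length=default_run.sterile.length,
        )
        verdicts = {c.orf.id: c.verdict for c in redone}
        assert verdicts[extra.id] == "candidate"

    def test_removing_uniqueness_always_rejects(self, default_run):
        flags = [(c.orf, False) for c in default_run.candidates]
        redone = screen(
            flags,
            default_run.comparison.coverage.qry_unique_intervals,
            default_run.comparison.blocks,
            default_run.tm_domains,
            default_run.chimeras,
            genome_length=default_run.sterile.length,
        )
        assert all(c.verdict == "rejected" for c in redone)

    def test_evidence_is_exhaustive(self, default_run):
        for c in default_run.candidates:
            joined = " ".join(c.evidence)
            assert "unique_in_sterile=" in joined
            assert "in_sv_or_unique_region=" in joined
            assert "tm_domains=" in joined
            assert "chimera_with=" in joined

    def test_candidates_carry_expression_caveat(self, default_run):
        for c in default_run.candidates:
            if c.verdict == "candidate":
                assert any("expression validation" in e for e in c.evidence)


class TestReport:
    def test_empty_candidate_list_keeps_tables(self, tmp_path):
        doc = report([], {"genomes": {"a": 1}}, tmp_path / "r.json", tmp_path / "r.md")
        assert doc["n_candidates"] == 0
        assert "genomes" in doc
        md = (tmp_path / "r.md").read_text()
        assert "No candidate ORFs" in md
        assert "genomes" in md

    def test_report_is_deterministic(self, tmp_path, default_run):
        for name in ("a", "b"):
            report(
                default_run.candidates,
                {"x": 1},
                tmp_path / f"{name}.json",
                tmp_path / f"{name}.md",
            )
        assert (tmp_path / "a.json").read_bytes() == (tmp_path / "b.json").read_bytes()
        assert (tmp_path / "a.md").read_bytes() == (tmp_path / "b.md").read_bytes()

    def test_candidate_table_lists_truth_candidates(self, default_run):
        listed = [
            c["orf_id"]
            for c in default_run.report_doc["candidates"]
            if c["verdict"] == "candidate"
        ]
        assert sorted(listed) == sorted(default_run.pair.truth.candidate_orf_ids)
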
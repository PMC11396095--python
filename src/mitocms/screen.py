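"""The CMS candidate-ORF filter cascade.

A sterile-line ORF is a CMS candidate when it is (i) absent from the
maintainer genome (sterile-specific), (ii) located in a rearranged or
sterile-unique region, and (iii) either encodes at least one predicted
transmembrane domain or forms a chimera / co-transcription unit with a
known mitochondrial gene.  The expression criterion used in wet-lab
screens (RT-PCR/RT-qPCR) is outside computational scope; every reported
candidate carries a "requires expression validation" caveat.

Sequence uniqueness is decided by best infix alignment of the ORF's
nucleotide sequence against the maintainer (both strands, circular) using
edlib: identity = 1 - dist/|orf| folds the identity and coverage thresholds
into a single edit-similarity score (a full-identity match covering 90% of
the ORF scores exactly 0.9).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import edlib

from . import jsonutil
from .annotate import OrfRecord
from .genome_io import CircularGenome, extract, reverse_complement
from .synteny_sv import SyntenyBlock
from .tm_chimera import ChimeraRecord, TmDomain


@dataclass
class CandidateOrf:
    orf: OrfRecord
    unique_in_sterile: bool
    in_sv_or_unique_region: bool
    tm_count: int
    chimera: ChimeraRecord | None
    verdict: str  # candidate | rejected
    evidence: list[str] = field(default_factory=list)


def _best_infix_identity(query: str, target_fwd: str, target_rev: str) -> float:
    best = len(query) + 1
    for t in (target_fwd, target_rev):
        d = edlib.align(query, t, mode="HW", task="distance", k=best - 1)
        if d["editDistance"] != -1:
            best = min(best, d["editDistance"])
    return 1.0 - best / len(query)


def find_unique_orfs(
    orfs: list[OrfRecord],
    sterile: CircularGenome,
    maintainer: CircularGenome,
    min_identity: float = 0.9,
    min_coverage: float = 0.9,
) -> list[tuple[OrfRecord, bool]]:
    """Flag each sterile ORF as unique (True) or shared with the maintainer.

    An ORF is *not* unique when some alignment to the maintainer reaches the
    identity/coverage thresholds.  Both are applied as one edit-similarity
    floor, ``min(min_identity, min_coverage)``, on the best infix alignment:
    uncovered overhang is absorbed into the edit distance, so a full-identity
    match covering 90% of the ORF scores exactly 0.9.
    """
    floor = min(min_identity, min_coverage)
    tgt = maintainer.sequence + (
        maintainer.sequence if maintainer.is_circular else ""
    )
    tgt_rev = reverse_complement(tgt)
    out = []
    for o in sorted(orfs, key=lambda o: (o.interval.start, o.interval.strand)):
        seq = extract(sterile, o.interval)
        ident = _best_infix_identity(seq, tgt, tgt_rev)
        out.append((o, ident < floor))
    return out


def _spans_intersect(a_start: int, a_end: int, b_start: int, b_end: int) -> bool:
    return min(a_end, b_end) - max(a_start, b_start) > 0


def screen(
    unique_flags: list[tuple[OrfRecord, bool]],
    qry_unique_intervals: list[tuple[int, int]],
    blocks: list[SyntenyBlock],
    tm_domains: list[TmDomain],
    chimeras: list[ChimeraRecord],
    genome_length: int | None = None,
) -> list[CandidateOrf]:
    """Apply the candidate rule to every ORF and report exhaustive evidence.

    verdict == candidate  <=>  unique AND in a non-collinear/unique region
    AND (>=1 TM domain OR chimera with a known gene).
    """
    tm_by_orf: dict[str, int] = {}
    for d in tm_domains:
        tm_by_orf[d.orf_id] = tm_by_orf.get(d.orf_id, 0) + 1
    chim_by_orf: dict[str, ChimeraRecord] = {}
    for c in chimeras:
        chim_by_orf.setdefault(c.orf_id, c)
    noncollinear = [
        (b.qry_span[0], b.qry_span[1]) for b in blocks if b.klass != "collinear"
    ]

    results = []
    for orf, unique in unique_flags:
        iv = orf.interval
        L = genome_length or (iv.end if not iv.wraps else iv.start + 1)
        o_start = iv.start
        o_end = iv.start + iv.span(genome_length) if genome_length else iv.end
        in_region = any(
            _spans_intersect(o_start, o_end, s, e) for s, e in qry_unique_intervals
        ) or any(_spans_intersect(o_start, o_end, s, e) for s, e in noncollinear)
        tm_count = tm_by_orf.get(orf.id, 0)
        chimera = chim_by_orf.get(orf.id)
        is_candidate = unique and in_region and (tm_count >= 1 or chimera is not None)
        evidence = [
            f"unique_in_sterile={unique}",
            f"in_sv_or_unique_region={in_region}",
            f"tm_domains={tm_count}",
            "chimera_with=" + (chimera.partner_gene if chimera else "none"),
        ]
        if is_candidate:
            evidence.append("requires expression validation")
        else:
            misses = []
            if not unique:
                misses.append("not sterile-specific")
            if not in_region:
                misses.append("outside rearranged/unique regions")
            if tm_count == 0 and chimera is None:
                misses.append("no transmembrane domain and no chimera")
            evidence.append("rejected: " + "; ".join(misses))
        results.append(
            CandidateOrf(
                orf,
                unique,
                in_region,
                tm_count,
                chimera,
                "candidate" if is_candidate else "rejected",
                evidence,
            )
        )
    results.sort(
        key=lambda c: (
            c.verdict != "candidate",
            -(c.chimera is not None),
            -c.tm_count,
            -c.orf.aa_length,
            c.orf.id,
        )
    )
    return results


def report(
    candidates: list[CandidateOrf],
    all_stats: dict,
    json_path: str | Path | None = None,
    md_path: str | Path | None = None,
) -> dict:
    """Assemble the pipeline's structured analysis report (JSON + Markdown)."""
    doc = {
        "schema_version": 1,
        **all_stats,
        "n_candidates": sum(1 for c in candidates if c.verdict == "candidate"),
        "candidates": [
            {
                "orf_id": c.orf.id,
                "aa_length": c.orf.aa_length,
                "start": c.orf.interval.start,
                "end": c.orf.interval.end,
                "strand": c.orf.interval.strand,
                "verdict": c.verdict,
                "tm_domains": c.tm_count,
                "chimera_partner": c.chimera.partner_gene if c.chimera else None,
                "unit_length": c.chimera.unit_length if c.chimera else None,
                "evidence": c.evidence,
            }
            for c in candidates
        ],
    }
    if json_path:
        Path(json_path).write_text(jsonutil.dumps(doc, indent=1, sort_keys=False))
    if md_path:
        lines = ["# CMS candidate screen report", ""]
        if doc["n_candidates"] == 0:
            lines.append("No candidate ORFs passed the screen.")
        lines += ["", "| ORF | aa | verdict | TM | chimera | evidence |", "|---|---|---|---|---|---|"]
        for c in doc["candidates"]:
            lines.append(
                f"| {c['orf_id']} | {c['aa_length']} | {c['verdict']} | "
                f"{c['tm_domains']} | {c['chimera_partner'] or '-'} | "
                f"{'; '.join(c['evidence'])} |"
            )
        for key, val in all_stats.items():
            lines += ["", f"## {key}", "", "```json", jsonutil.dumps(val, indent=1), "```"]
        Path(md_path).write_text("\n".join(lines) + "\n")
    return doc
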
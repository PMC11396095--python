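"""Synteny-block classification and structural-variant taxonomy.

The genome pair is partitioned into the standard whole-genome-comparison
region classes: collinear blocks, translocations, inversions,
translocation+inversion, insertions/deletions of at least 50 bp, and
complex InDels (region pairs that correspond in location but do not
align).  The collinear backbone is the maximum-anchored-bp set of
forward-strand chains that is order-preserving in both genomes; a
strand-negative chain in a locally order-consistent position is an
inversion, and one that is also out of order is a translocation+inversion.
Unaligned remnants below the size floor are reported as residue, never
silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .align_core import BaseAlignment, Chain, Escalation


@dataclass
class SyntenyBlock:
    chain: Chain
    ref_span: tuple[int, int]
    qry_span: tuple[int, int]
    klass: str  # collinear | translocation | inversion | trans_inver
    identity: float = 1.0


@dataclass
class SvEvent:
    klass: str  # insertion | deletion | complex_indel | residue
    ref_span: tuple[int, int]  # empty when ref_span[0] == ref_span[1]
    qry_span: tuple[int, int]
    size: int = 0


@dataclass
class CoverageStats:
    n_blocks: int
    n_homologous_blocks: int
    pct_homologous_ref: float
    pct_homologous_qry: float
    qry_unique_intervals: list[tuple[int, int]] = field(default_factory=list)


def _block_identity(ba: BaseAlignment) -> float:
    matches = sum(1 for c in ba.columns if c[2])
    pairs = sum(1 for c in ba.columns if c[0] is not None and c[1] is not None)
    return matches / pairs if pairs else 0.0


def classify_blocks(
    alignments: list[BaseAlignment], ref_len: int, qry_len: int
) -> list[SyntenyBlock]:
    """Label every chain with its region class (see module docstring)."""
    blocks = [
        SyntenyBlock(
            ba.chain, ba.chain.ref_span, ba.chain.qry_span, "", _block_identity(ba)
        )
        for ba in alignments
    ]
    blocks.sort(key=lambda b: b.ref_span)
    _reject_shared_anchors(blocks)

    plus = [b for b in blocks if b.chain.strand == "+"]
    # weighted LIS over qry order -> collinear backbone
    n = len(plus)
    best = [0.0] * n
    back = [-1] * n
    for i in range(n):
        best[i] = float(plus[i].chain.anchored_bp)
        for j in range(i):
            if plus[j].qry_span[1] <= plus[i].qry_span[0] + 1 and best[j] + plus[i].chain.anchored_bp > best[i]:
                best[i] = best[j] + plus[i].chain.anchored_bp
                back[i] = j
    backbone: set[int] = set()
    if n:
        i = max(range(n), key=lambda x: (best[x], -plus[x].ref_span[0]))
        while i != -1:
            backbone.add(id(plus[i]))
            i = back[i]
    for b in plus:
        b.klass = "collinear" if id(b) in backbone else "translocation"

    # a chain is "in place" when its query span sits between the query
    # positions that the collinear backbone assigns to its reference flanks
    slack = 100

    def in_place(b: SyntenyBlock, spine_anchors) -> bool:
        prev = next(
            (a for a in reversed(spine_anchors) if a.ref_end <= b.ref_span[0] + slack),
            None,
        )
        nxt = next(
            (a for a in spine_anchors if a.ref_start >= b.ref_span[1] - slack), None
        )
        lo = prev.qry_end if prev else 0
        hi = nxt.qry_start if nxt else qry_len
        return lo - slack <= b.qry_span[0] and b.qry_span[1] <= hi + slack and lo < hi

    def spine() -> list:
        return sorted(
            (a for b in plus if b.klass == "collinear" for a in b.chain.anchors),
            key=lambda a: a.ref_start,
        )

    # forward chains the backbone DP skipped (e.g. short runs between two
    # adjacent events) are still collinear if order-consistent on both axes
    changed = True
    while changed:
        changed = False
        sp = spine()
        for b in sorted(plus, key=lambda b: -b.chain.anchored_bp):
            if b.klass == "translocation" and in_place(b, sp):
                b.klass = "collinear"
                changed = True
                break

    sp = spine()
    for b in blocks:
        if b.chain.strand != "-":
            continue
        b.klass = "inversion" if in_place(b, sp) else "trans_inver"
    return blocks


def _reject_shared_anchors(blocks: list[SyntenyBlock]) -> None:
    seen: set[int] = set()
    for b in blocks:
        for a in b.chain.anchors:
            if id(a) in seen:
                raise ValueError("chains share anchors; cannot classify")
            seen.add(id(a))


def _merge_intervals(ivs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[list[int]] = []
    for s, e in sorted(ivs):
        if out and s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


def _complement(ivs: list[tuple[int, int]], length: int) -> list[tuple[int, int]]:
    out = []
    cur = 0
    for s, e in _merge_intervals(ivs):
        if s > cur:
            out.append((cur, s))
        cur = max(cur, e)
    if cur < length:
        out.append((cur, length))
    return out


def aligned_intervals(
    alignments: list[BaseAlignment],
) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    """Merged (ref, qry) intervals actually covered by aligned columns."""
    ref_ivs, qry_ivs = [], []
    for ba in alignments:
        rs = [c[0] for c in ba.columns if c[0] is not None]
        qs = [c[1] for c in ba.columns if c[1] is not None]
        # columns are monotone runs broken only by escalation holes; record
        # contiguous stretches
        for vals, store in ((rs, ref_ivs), (qs, qry_ivs)):
            if not vals:
                continue
            vals = sorted(vals)
            s = prev = vals[0]
            for v in vals[1:]:
                if v == prev + 1:
                    prev = v
                    continue
                store.append((s, prev + 1))
                s = prev = v
            store.append((s, prev + 1))
    return _merge_intervals(ref_ivs), _merge_intervals(qry_ivs)


def call_sv_gaps(
    alignments: list[BaseAlignment],
    extra_escalations: list[Escalation],
    ref_len: int,
    qry_len: int,
    min_size: int = 50,
) -> list[SvEvent]:
    """Classify escalated gap pairs and unaligned remnants into SV events.

    Escalated ref-side segments that are in fact aligned by *another* block
    (translocation sources) are subtracted before deletion calling, and
    likewise for the query side, so rearranged material is never double-
    called as indel loss/gain.
    """
    ref_cov, qry_cov = aligned_intervals(alignments)
    events: list[SvEvent] = []

    all_esc = [e for ba in alignments for e in ba.escalations] + list(extra_escalations)
    esc_ref = [(e.ref_start, e.ref_end) for e in all_esc if e.ref_end > e.ref_start]
    esc_qry = [(e.qry_start, e.qry_end) for e in all_esc if e.qry_end > e.qry_start]

    def uncovered(span: tuple[int, int], cov: list[tuple[int, int]]) -> list[tuple[int, int]]:
        s, e = span
        holes = []
        cur = s
        for cs, ce in sorted(cov):
            if ce <= s or cs >= e:
                continue
            if cs > cur:
                holes.append((cur, cs))
            cur = max(cur, ce)
        if cur < e:
            holes.append((cur, e))
        return holes

    # escalations from different chains can overlap (a sparse rescued chain
    # may escalate across territory another chain already explains); process
    # tightest first and let each unaligned hole feed exactly one event
    consumed_ref: list[tuple[int, int]] = []
    consumed_qry: list[tuple[int, int]] = []
    all_esc = sorted(
        all_esc,
        key=lambda e: (
            (e.ref_end - e.ref_start) + (e.qry_end - e.qry_start),
            e.ref_start,
            e.qry_start,
        ),
    )

    for e in all_esc:
        ref_holes = (
            uncovered((e.ref_start, e.ref_end), ref_cov + consumed_ref)
            if e.ref_end > e.ref_start
            else []
        )
        qry_holes = (
            uncovered((e.qry_start, e.qry_end), qry_cov + consumed_qry)
            if e.qry_end > e.qry_start
            else []
        )
        consumed_ref.extend(ref_holes)
        consumed_qry.extend(qry_holes)
        rbp = sum(b - a for a, b in ref_holes)
        qbp = sum(b - a for a, b in qry_holes)
        # a true complex region is one unaligned ref segment facing one
        # unaligned qry segment, each filling essentially the whole gap
        # pair; anything else decomposes into per-hole events
        eps = 10
        full_ref = (
            len(ref_holes) == 1
            and rbp >= (e.ref_end - e.ref_start) - eps
        )
        full_qry = (
            len(qry_holes) == 1
            and qbp >= (e.qry_end - e.qry_start) - eps
        )
        if rbp >= min_size and qbp >= min_size and full_ref and full_qry:
            events.append(
                SvEvent("complex_indel", ref_holes[0], qry_holes[0], max(rbp, qbp))
            )
            continue
        for a, b in ref_holes:
            if b - a > 0:
                events.append(
                    SvEvent(
                        "deletion" if b - a >= min_size else "residue",
                        (a, b),
                        (e.qry_start, e.qry_start),
                        b - a,
                    )
                )
        for a, b in qry_holes:
            if b - a > 0:
                events.append(
                    SvEvent(
                        "insertion" if b - a >= min_size else "residue",
                        (e.ref_start, e.ref_start),
                        (a, b),
                        b - a,
                    )
                )

    # between-block remnants not part of any escalation
    esc_ref_m = _merge_intervals(esc_ref + ref_cov)
    esc_qry_m = _merge_intervals(esc_qry + qry_cov)
    for s, e in _complement(esc_ref_m, ref_len):
        events.append(
            SvEvent("deletion" if e - s >= min_size else "residue", (s, e), (0, 0), e - s)
        )
    for s, e in _complement(esc_qry_m, qry_len):
        events.append(
            SvEvent("insertion" if e - s >= min_size else "residue", (0, 0), (s, e), e - s)
        )
    events.sort(key=lambda ev: (ev.ref_span, ev.qry_span, ev.klass))
    return events


def coverage_stats(
    blocks: list[SyntenyBlock],
    alignments: list[BaseAlignment],
    ref_len: int,
    qry_len: int,
    homology_min_identity: float = 0.9,
) -> CoverageStats:
    """Homologous-block coverage percentages and sterile-unique intervals.

    A block is homologous when its aligned identity reaches the threshold;
    the query-unique intervals are the complement of all aligned query
    coverage (insertion holes inside chains included).
    """
    homologous = [b for b in blocks if b.identity >= homology_min_identity]
    ref_bp = sum(b.ref_span[1] - b.ref_span[0] for b in homologous)
    qry_bp = sum(b.qry_span[1] - b.qry_span[0] for b in homologous)
    # subtract escalation holes from homologous spans
    for b in homologous:
        ba = next(a for a in alignments if a.chain is b.chain)
        for e in ba.escalations:
            ref_bp -= max(0, e.ref_end - e.ref_start)
            qry_bp -= max(0, e.qry_end - e.qry_start)
    _, qry_cov = aligned_intervals(alignments)
    uniq = [(s, e) for s, e in _complement(qry_cov, qry_len)]
    return CoverageStats(
        n_blocks=len(blocks),
        n_homologous_blocks=len(homologous),
        pct_homologous_ref=100.0 * max(0, ref_bp) / ref_len,
        pct_homologous_qry=100.0 * max(0, qry_bp) / qry_len,
        qry_unique_intervals=uniq,
    )


def blocks_to_tsv(blocks: list[SyntenyBlock], path) -> None:
    rows = [
        {
            "ref_start": b.ref_span[0],
            "ref_end": b.ref_span[1],
            "qry_start": b.qry_span[0],
            "qry_end": b.qry_span[1],
            "strand": b.chain.strand,
            "klass": b.klass,
            "identity": round(b.identity, 6),
            "anchored_bp": b.chain.anchored_bp,
        }
        for b in sorted(blocks, key=lambda b: b.ref_span)
    ]
    pd.DataFrame(
        rows,
        columns=[
            "ref_start", "ref_end", "qry_start", "qry_end",
            "strand", "klass", "identity", "anchored_bp",
        ],
    ).to_csv(path, sep="\t", index=False)


def sv_to_tsv(events: list[SvEvent], path) -> None:
    rows = [
        {
            "klass": ev.klass,
            "ref_start": ev.ref_span[0],
            "ref_end": ev.ref_span[1],
            "qry_start": ev.qry_span[0],
            "qry_end": ev.qry_span[1],
            "size": ev.size,
        }
        for ev in events
    ]
    pd.DataFrame(
        rows,
        columns=["klass", "ref_start", "ref_end", "qry_start", "qry_end", "size"],
    ).to_csv(path, sep="\t", index=False)
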
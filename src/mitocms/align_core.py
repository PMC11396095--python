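"""Anchor-based pairwise whole-genome alignment.

The two mitogenomes are aligned MUMmer-style: maximal exact matches that
are unique in both genomes (MUMs) anchor the comparison, anchors are
chained into collinear runs per strand, and the inter-anchor gaps are
closed with affine-gap global alignment.  Uniqueness in both genomes is
deliberate: repeats at or above the anchor length produce anchor deserts,
which is exactly where structural variation is later called.

Gap pairs that cannot be base-aligned meaningfully are escalated as
structured events rather than silently truncated: one-sided gaps longer
than ``sv_min`` (candidate insertions/deletions), two-sided gaps whose
alignment identity falls below ``complex_identity`` (candidate complex
regions), and anything wider than the band.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Align import PairwiseAligner

from .genome_io import CircularGenome, reverse_complement


@dataclass(frozen=True)
class Anchor:
    """A maximal exact match unique in both genomes.

    ``qry_start`` is always a forward-strand coordinate; for strand "-"
    the query segment is the reverse complement of the reference segment.
    """

    ref_start: int
    qry_start: int
    length: int
    strand: str

    @property
    def ref_end(self) -> int:
        return self.ref_start + self.length

    @property
    def qry_end(self) -> int:
        return self.qry_start + self.length


@dataclass
class Chain:
    anchors: list[Anchor]
    strand: str
    score: float

    @property
    def ref_span(self) -> tuple[int, int]:
        return self.anchors[0].ref_start, self.anchors[-1].ref_end

    @property
    def qry_span(self) -> tuple[int, int]:
        starts = [a.qry_start for a in self.anchors]
        ends = [a.qry_end for a in self.anchors]
        return min(starts), max(ends)

    @property
    def anchored_bp(self) -> int:
        return sum(a.length for a in self.anchors)


@dataclass
class Escalation:
    """A gap pair handed to SV classification instead of base alignment."""

    ref_start: int
    ref_end: int
    qry_start: int
    qry_end: int
    reason: str  # indel | complex | band


@dataclass
class BaseAlignment:
    """Stitched per-chain base alignment.

    ``columns`` holds (ref_pos | None, qry_pos | None, match) triples in
    alignment order; anchors contribute all-match runs.
    """

    chain: Chain
    columns: list[tuple[int | None, int | None, bool]]
    escalations: list[Escalation] = field(default_factory=list)


# --------------------------------------------------------------------------
# anchors
# --------------------------------------------------------------------------

def _maximal_matches(ref: str, qry: str, k: int, strand: str, max_positions: int = 32):
    """Seeded maximal exact matches between two linear strings."""
    index: dict[str, list[int]] = {}
    for i in range(len(ref) - k + 1):
        index.setdefault(ref[i : i + k], []).append(i)
    covered: dict[int, int] = {}  # diagonal -> qry end of last extension
    seen = set()
    out = []
    for j in range(len(qry) - k + 1):
        kmer = qry[j : j + k]
        positions = index.get(kmer)
        if not positions or len(positions) > max_positions:
            continue
        for i in positions:
            d = i - j
            if covered.get(d, -1) >= j:
                continue
            lo = 0
            while i - lo - 1 >= 0 and j - lo - 1 >= 0 and ref[i - lo - 1] == qry[j - lo - 1]:
                lo += 1
            hi = k
            while i + hi < len(ref) and j + hi < len(qry) and ref[i + hi] == qry[j + hi]:
                hi += 1
            covered[d] = j + hi - k + 1
            key = (i - lo, j - lo, lo + hi)
            if key not in seen:
                seen.add(key)
                out.append(key)
    return [(i, j, length, strand) for i, j, length in out]


def find_anchors(ref: CircularGenome, qry: CircularGenome, min_anchor: int = 20) -> list[Anchor]:
    """All maximal exact matches unique in both genomes, both orientations."""
    if min_anchor < 8:
        raise ValueError("min_anchor below 8 is all noise")
    r, q = ref.sequence, qry.sequence
    qr = reverse_complement(q)
    cands = _maximal_matches(r, q, min_anchor, "+") + _maximal_matches(
        r, qr, min_anchor, "-"
    )
    rr = reverse_complement(r)
    anchors = []
    for i, j, length, strand in cands:
        if length < min_anchor:
            continue
        pattern = r[i : i + length]
        if r.count(pattern) != 1 or rr.count(pattern) != 0:
            continue
        if strand == "+":
            if q.count(pattern) != 1 or qr.count(pattern) != 0:
                continue
            qry_start = j
        else:
            if qr.count(pattern) != 1 or q.count(pattern) != 0:
                continue
            qry_start = len(q) - (j + length)
        anchors.append(Anchor(i, qry_start, length, strand))
    anchors.sort(key=lambda a: (a.ref_start, a.qry_start, a.strand))
    return anchors


def canonical_rotation(ref: CircularGenome, qry: CircularGenome, min_anchor: int = 20) -> int:
    """Rotation offset of the query's origin relative to the reference.

    The dominant (anchor-length-weighted) diagonal offset of the forward
    anchors; individual anchors drift from the true rotation by cumulative
    InDel/SV shifts, so the estimate pools all anchors in coarse bins and
    returns the weighted mean of the heaviest bin.  0 when the genomes
    already share an origin.
    """
    anchors = [a for a in find_anchors(ref, qry, min_anchor) if a.strand == "+"]
    if not anchors:
        return 0
    L = qry.length
    nbins = 64
    weight = [0.0] * nbins
    wsum = [0.0] * nbins
    for a in anchors:
        off = (a.qry_start - a.ref_start) % L
        b = min(nbins - 1, off * nbins // L)
        weight[b] += a.length
        wsum[b] += a.length * off
    best = max(range(nbins), key=lambda b: weight[b])
    return int(round(wsum[best] / weight[best])) % L


def rotate_genome(genome: CircularGenome, offset: int) -> CircularGenome:
    """Rotate a circular genome so old coordinate ``offset`` becomes 0."""
    if not genome.is_circular:
        raise ValueError("cannot rotate a linear genome")
    s = genome.sequence
    off = offset % len(s)
    return CircularGenome(genome.id, s[off:] + s[:off], genome.topology)


# --------------------------------------------------------------------------
# chaining
# --------------------------------------------------------------------------

# Penalty per bp of ref/qry gap-length disagreement between consecutive
# anchors.  Large enough that a relocated segment scores better as its own
# chain than absorbed into the backbone with two big asymmetric gaps, small
# enough that ordinary InDel gaps never break a chain.
GAP_DIFF_COST = 0.5


def chain_score(anchors: list[Anchor], gap_diff_cost: float = GAP_DIFF_COST) -> float:
    """Score of an ordered anchor run: anchored bp minus overlap and a small
    penalty on ref/qry gap-length disagreement (indels)."""
    total = 0.0
    prev = None
    for a in anchors:
        total += a.length
        if prev is not None:
            gr = a.ref_start - prev.ref_end
            gq = _qgap(prev, a)
            total -= max(0, -gr) + max(0, -gq)
            total -= gap_diff_cost * abs(gr - gq)
        prev = a
    return total


def _qgap(prev: Anchor, cur: Anchor) -> int:
    if prev.strand == "+":
        return cur.qry_start - prev.qry_end
    return prev.qry_start - cur.qry_end  # strand '-': qry runs backwards


def _compatible(prev: Anchor, cur: Anchor, max_gap: int) -> bool:
    gr = cur.ref_start - prev.ref_end
    gq = _qgap(prev, cur)
    if gr > max_gap or gq > max_gap:
        return False
    if gr < -(min(prev.length, cur.length) - 1):
        return False
    if gq < -(min(prev.length, cur.length) - 1):
        return False
    return cur.ref_end > prev.ref_end


def chain_anchors(
    anchors: list[Anchor],
    max_gap: int = 50_000,
    min_chain_bp: int = 500,
    gap_diff_cost: float = GAP_DIFF_COST,
) -> list[Chain]:
    """Greedy extraction of maximal-scoring collinear chains per strand.

    Repeated best-chain dynamic programming: the highest-scoring chain is
    taken, its anchors are claimed, and the search repeats on the remaining
    anchors (so relocated segments inside the backbone's span still form
    their own chains); chains below ``min_chain_bp`` anchored bp are
    dropped.  Tie-breaks (score, then leftmost ref, then leftmost qry) make
    the output deterministic.
    """
    chains: list[Chain] = []
    remaining = list(anchors)
    claimed_ref: list[tuple[int, int]] = []  # anchor intervals already used
    claimed_qry: list[tuple[int, int]] = []

    def mostly_claimed(a: Anchor) -> bool:
        # staggered duplicates of already-used anchors (e.g. alternative
        # maximal extensions around an indel) must not seed further chains
        for span, claimed in (
            ((a.ref_start, a.ref_end), claimed_ref),
            ((a.qry_start, a.qry_end), claimed_qry),
        ):
            ov = sum(
                max(0, min(span[1], ce) - max(span[0], cs)) for cs, ce in claimed
            )
            if ov > 0.5 * a.length:
                return True
        return False

    while True:
        best_chain = None
        for strand in "+-":
            pool = [a for a in remaining if a.strand == strand]
            pool.sort(key=lambda a: (a.ref_start, a.qry_start))
            n = len(pool)
            if n == 0:
                continue
            score = [float(a.length) for a in pool]
            back = [-1] * n
            for ii in range(n):
                for jj in range(ii):
                    if not _compatible(pool[jj], pool[ii], max_gap):
                        continue
                    a, b = pool[jj], pool[ii]
                    gr = b.ref_start - a.ref_end
                    gq = _qgap(a, b)
                    cand = (
                        score[jj]
                        + b.length
                        - max(0, -gr)
                        - max(0, -gq)
                        - gap_diff_cost * abs(gr - gq)
                    )
                    if cand > score[ii] + 1e-9:
                        score[ii] = cand
                        back[ii] = jj
            ii = max(
                range(n),
                key=lambda x: (score[x], -pool[x].ref_start, -pool[x].qry_start),
            )
            run = []
            while ii != -1:
                run.append(pool[ii])
                ii = back[ii]
            run.reverse()
            cand_chain = Chain(run, strand, chain_score(run, gap_diff_cost))
            if best_chain is None or (
                cand_chain.score,
                -cand_chain.ref_span[0],
                -cand_chain.qry_span[0],
            ) > (best_chain.score, -best_chain.ref_span[0], -best_chain.qry_span[0]):
                best_chain = cand_chain
        if best_chain is None or best_chain.anchored_bp < min_chain_bp:
            break
        chains.append(best_chain)
        used = set(id(a) for a in best_chain.anchors)
        claimed_ref.extend((a.ref_start, a.ref_end) for a in best_chain.anchors)
        claimed_qry.extend((a.qry_start, a.qry_end) for a in best_chain.anchors)
        remaining = [
            a for a in remaining if id(a) not in used and not mostly_claimed(a)
        ]
        if not remaining:
            break
    chains.sort(key=lambda c: c.ref_span)
    return chains


# --------------------------------------------------------------------------
# base-level gap alignment
# --------------------------------------------------------------------------

def _gap_aligner(match: float, mismatch: float, gap_open: float, gap_extend: float) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    # biopython's open_gap_score includes the first extension
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def align_pair_score(a: str, b: str, match=1.0, mismatch=-1.0, gap_open=4.0, gap_extend=1.0) -> float:
    """Global affine-gap alignment score of two short sequences (a gap of
    length g costs gap_open + g*gap_extend)."""
    if not a:
        return -(gap_open + gap_extend * len(b)) if b else 0.0
    if not b:
        return -(gap_open + gap_extend * len(a))
    return _gap_aligner(match, mismatch, gap_open, gap_extend).score(a, b)


def _aligned_columns(a: str, b: str, r0: int, q0: int, aligner: PairwiseAligner):
    """Columns of one optimal global alignment, offset to genome coords."""
    aln = aligner.align(a, b)[0]
    cols = []
    pa, pb = 0, 0
    for (as_, ae), (bs, be) in zip(*aln.aligned):
        while pa < as_:
            cols.append((r0 + pa, None, False))
            pa += 1
        while pb < bs:
            cols.append((None, q0 + pb, False))
            pb += 1
        for t in range(ae - as_):
            cols.append((r0 + pa, q0 + pb, a[pa] == b[pb]))
            pa += 1
            pb += 1
    while pa < len(a):
        cols.append((r0 + pa, None, False))
        pa += 1
    while pb < len(b):
        cols.append((None, q0 + pb, False))
        pb += 1
    return cols


def align_gaps(
    ref: CircularGenome,
    qry: CircularGenome,
    chain: Chain,
    band: int = 2000,
    sv_min: int = 50,
    complex_identity: float = 0.70,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = 4.0,
    gap_extend: float = 1.0,
) -> BaseAlignment:
    """Stitch anchors and aligned inter-anchor gaps into one BaseAlignment.

    Structured escalations replace base alignment for gap pairs that are
    one-sided and >= ``sv_min`` (indel-scale events), wider than ``band``,
    or so divergent that their alignment identity drops below
    ``complex_identity`` (complex-region candidates).
    """
    aligner = _gap_aligner(match, mismatch, gap_open, gap_extend)
    cols: list[tuple[int | None, int | None, bool]] = []
    escalations: list[Escalation] = []
    rs, qs = ref.sequence, qry.sequence
    minus = chain.strand == "-"

    def emit_anchor(a: Anchor) -> None:
        for t in range(a.length):
            if not minus:
                cols.append((a.ref_start + t, a.qry_start + t, True))
            else:
                cols.append((a.ref_start + t, a.qry_end - 1 - t, True))

    def qry_gap(prev: Anchor, cur: Anchor) -> tuple[int, int]:
        if not minus:
            return prev.qry_end, cur.qry_start
        return cur.qry_end, prev.qry_start

    prev = None
    for a in chain.anchors:
        if prev is not None:
            r1, r2 = prev.ref_end, a.ref_start
            q1, q2 = qry_gap(prev, a)
            rseq = rs[r1:r2]
            qfwd = qs[q1:q2]
            qseq = reverse_complement(qfwd) if minus else qfwd
            lr, lq = len(rseq), len(qseq)
            if lr == 0 and lq == 0:
                pass
            elif lr > band or lq > band:
                escalations.append(Escalation(r1, r2, q1, q2, "band"))
            elif min(lr, lq) == 0 and max(lr, lq) > sv_min:
                escalations.append(Escalation(r1, r2, q1, q2, "indel"))
            elif lq == 0:
                cols.extend((r1 + t, None, False) for t in range(lr))
            elif lr == 0:
                qcols = range(q1, q2) if not minus else range(q2 - 1, q1 - 1, -1)
                cols.extend((None, qp, False) for qp in qcols)
            else:
                sub = _aligned_columns(rseq, qseq, 0, 0, aligner)
                matches = sum(1 for c in sub if c[2])
                pairs = sum(1 for c in sub if c[0] is not None and c[1] is not None)
                if min(lr, lq) >= sv_min and (pairs == 0 or matches / max(1, pairs) < complex_identity):
                    escalations.append(Escalation(r1, r2, q1, q2, "complex"))
                else:
                    for rp, qp, m in sub:
                        gr = None if rp is None else r1 + rp
                        if qp is None:
                            gq = None
                        elif not minus:
                            gq = q1 + qp
                        else:
                            gq = q2 - 1 - qp
                        cols.append((gr, gq, m))
        emit_anchor(a)
        prev = a
    return BaseAlignment(chain, cols, escalations)


def align_chains(
    ref: CircularGenome, qry: CircularGenome, chains: list[Chain], **kwargs
) -> list[BaseAlignment]:
    return [align_gaps(ref, qry, c, **kwargs) for c in chains]
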
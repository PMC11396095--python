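"""Maximal exact repeat detection (direct and inverted) within one genome.

Plant mitogenomes recombine across repeat families, so the repeat content
of a sterile/maintainer pair is part of the structural-variation story.
Repeats are counted as *pairs of occurrences* (REPuter-style reporting):
one RepeatPair per maximal pair of matching copies.  Candidate pairs are
seeded by shared k-mers at the minimum length and extended to maximality;
circular genomes are scanned on the doubled sequence with modular
deduplication.  A quadratic brute-force comparer exists in the test suite
as the independent oracle; this implementation is the one meant for
full-size (hundreds of kb) genomes.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .genome_io import CircularGenome, Interval, reverse_complement


@dataclass(frozen=True)
class RepeatPair:
    length: int
    copy1: Interval  # forward strand, copy1.start < copy2.start
    copy2: Interval
    orientation: str  # direct | inverted
    tandem_overlap: bool = False


def find_repeats(genome: CircularGenome, min_len: int = 30) -> list[RepeatPair]:
    """All maximal exact repeat pairs of length >= ``min_len``.

    Copies are reported on the forward strand; an inverted pair means
    copy2 equals the reverse complement of copy1.  Identical intervals are
    excluded; overlapping (tandem-style) copies are allowed and flagged.
    """
    if min_len < 2:
        raise ValueError("min_len must be >= 2")
    L = genome.length
    if L < 2 * min_len:
        raise ValueError("genome shorter than twice min_len")
    seq = genome.sequence
    circ = genome.is_circular
    # T gives every position >= L of left/right context for circular scans
    T = seq * 3 if circ else seq
    off = L if circ else 0
    k = min_len

    pairs: dict[tuple[int, int, int, str], bool] = {}

    # --- direct pairs
    index: dict[str, list[int]] = {}
    for i in range(L if circ else L - k + 1):
        index.setdefault(T[off + i : off + i + k], []).append(i)

    def extend(i: int, j: int, inverted: bool) -> tuple[int, int, int] | None:
        """Maximal extension of a seeded match; positions are genome coords."""
        a, b = off + i, off + j
        if not inverted:
            lo = 0
            while a - lo - 1 >= (0 if not circ else a - L) and b - lo - 1 >= (0 if not circ else b - L) and T[a - lo - 1] == T[b - lo - 1]:
                lo += 1
                if lo >= L:
                    break
            hi = k
            amax = len(T) if circ else L
            while a + hi < amax and b + hi < amax and hi - (-lo) < L and T[a + hi] == T[b + hi]:
                hi += 1
            length = hi + lo
            if length > L:
                return None
            return (a - lo - off, b - lo - off, length)
        # inverted: copy1 left extension pairs with copy2 right extension
        comp = _COMP
        lo = 0
        while (
            a - lo - 1 >= (0 if not circ else a - L)
            and b + k + lo < (len(T) if circ else L)
            and T[a - lo - 1] == comp[T[b + k + lo]]
            and lo < L
        ):
            lo += 1
        hi = 0
        while (
            a + k + hi < (len(T) if circ else L)
            and b - hi - 1 >= (0 if not circ else b - L)
            and T[a + k + hi] == comp[T[b - hi - 1]]
            and hi < L
        ):
            hi += 1
        length = k + lo + hi
        if length > L:
            return None
        return (a - lo - off, b - hi - off, length)

    for positions in index.values():
        if len(positions) < 2:
            continue
        for x in range(len(positions)):
            for y in range(x + 1, len(positions)):
                ext = extend(positions[x], positions[y], inverted=False)
                if ext is None:
                    continue
                s1, s2, length = ext
                key = _canonical(s1, s2, length, "direct", L, circ)
                if key is not None:
                    pairs[key] = True

    # --- inverted pairs: match k-mers of seq against k-mers of revcomp(seq)
    rc = reverse_complement(seq)
    rc_scan = rc + rc[: k - 1] if circ else rc
    rc_index: dict[str, list[int]] = {}
    for i in range(L if circ else L - k + 1):
        rc_index.setdefault(rc_scan[i : i + k], []).append(i)
    for i in range(L):
        kmer = T[off + i : off + i + k]
        for p in rc_index.get(kmer, ()):
            # rc position p corresponds to forward interval [L-p-k, L-p)
            j = (L - p - k) % L if circ else L - p - k
            if j < 0:
                continue
            ext = extend(i, j, inverted=True)
            if ext is None:
                continue
            s1, s2, length = ext
            key = _canonical(s1, s2, length, "inverted", L, circ)
            if key is not None:
                pairs[key] = True

    out = []
    for (s1, s2, length, orientation) in sorted(pairs):
        if length < min_len:
            continue
        c1 = _mk_interval(s1, length, L, circ)
        c2 = _mk_interval(s2, length, L, circ)
        overlap = _intersect_mod(s1, s1 + length, s2, s2 + length, L) > 0
        out.append(RepeatPair(length, c1, c2, orientation, overlap))
    return out


_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def _canonical(s1: int, s2: int, length: int, orientation: str, L: int, circ: bool):
    if circ:
        s1 %= L
        s2 %= L
    if s1 == s2:
        return None  # identical interval: not a repeat pair
    if s2 < s1:
        s1, s2 = s2, s1
    return (s1, s2, length, orientation)


def _mk_interval(start: int, length: int, L: int, circ: bool) -> Interval:
    end = start + length
    if end <= L:
        return Interval(start, end, "+")
    return Interval(start, end - L, "+", wraps=True)


def _intersect_mod(a1: int, a2: int, b1: int, b2: int, L: int) -> int:
    best = 0
    for sh in (-L, 0, L):
        best = max(best, min(a2, b2 + sh) - max(a1, b1 + sh))
    return best


def bin_repeats(pairs: list[RepeatPair], bin_width: int = 5, start: int = 30) -> pd.DataFrame:
    """Histogram of repeat lengths in [30,34], [35,39], ... bins."""
    lengths = [p.length for p in pairs]
    max_len = max(lengths) if lengths else None
    top = max(lengths) if lengths else start
    rows = []
    lo = start
    while lo <= top:
        hi = lo + bin_width - 1
        rows.append(
            {
                "bin": f"{lo}-{hi}",
                "lo": lo,
                "hi": hi,
                "count": sum(1 for l in lengths if lo <= l <= hi),
            }
        )
        lo += bin_width
    df = pd.DataFrame(rows, columns=["bin", "lo", "hi", "count"])
    df.attrs["max_length"] = max_len
    df.attrs["n_pairs"] = len(pairs)
    df.attrs["n_occurrences"] = 2 * len(pairs)
    return df


def repeats_to_tsv(pairs: list[RepeatPair], path) -> None:
    rows = []
    for p in pairs:
        rows.append(
            {
                "length": p.length,
                "c1_start": p.copy1.start,
                "c1_end": p.copy1.end,
                "c2_start": p.copy2.start,
                "c2_end": p.copy2.end,
                "orientation": p.orientation,
                "tandem_overlap": int(p.tandem_overlap),
            }
        )
    pd.DataFrame(
        rows,
        columns=[
            "length", "c1_start", "c1_end", "c2_start", "c2_end",
            "orientation", "tandem_overlap",
        ],
    ).to_csv(path, sep="\t", index=False)
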
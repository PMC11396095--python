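"""Independent brute-force oracles used to cross-check the fast paths.

Each oracle re-derives its quantity from first principles (full scans,
textbook dynamic programming, exhaustive enumeration) without sharing code
with the implementation it checks.
"""

from __future__ import annotations

import itertools

import numpy as np

_COMP = str.maketrans("ACGT", "TGCA")
_STOPS = {"TAA", "TAG", "TGA"}

_CODON = {}
_B = "TCAG"
_AA = (
    "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
)
for i, (b1, b2, b3) in enumerate(itertools.product(_B, _B, _B)):
    _CODON[b1 + b2 + b3] = _AA[i]


def revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


def translate_table(cds: str) -> str:
    return "".join(_CODON[cds[i : i + 3]] for i in range(0, len(cds), 3))


# --- ORF oracle -----------------------------------------------------------

def brute_force_orfs(sequence: str, circular: bool, min_aa: int):
    """Every maximal (first-ATG-per-stop) ORF as (start, span, strand)."""
    L = len(sequence)
    results = {}
    for strand in "+-":
        work = sequence + sequence if circular else sequence
        if strand == "-":
            work = revcomp(work)
        n = len(work)
        for i in range(n - 2):
            if work[i : i + 3] != "ATG":
                continue
            j = i
            stop = None
            while j + 3 <= n:
                if work[j : j + 3] in _STOPS:
                    stop = j
                    break
                j += 3
            if stop is None:
                continue
            span = stop + 3 - i
            if span > L or span // 3 - 1 < min_aa:
                continue
            if strand == "+":
                fwd_start = i
                stop_key = stop % L if circular else stop
            else:
                fwd_start = n - (stop + 3)
                stop_key = fwd_start % L if circular else fwd_start
            key = (stop_key, strand)
            cand = (span, fwd_start % L if circular else fwd_start)
            if key not in results or cand[0] > results[key][0]:
                results[key] = cand
    return {(start, span, strand) for (sk, strand), (span, start) in results.items()}


# --- repeat oracle --------------------------------------------------------

def _runs(mask: np.ndarray):
    """(start, length) of maximal True runs in a boolean vector."""
    if not mask.any():
        return []
    padded = np.concatenate(([False], mask, [False]))
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return list(zip(starts.tolist(), (ends - starts).tolist()))


def brute_force_repeats(sequence: str, circular: bool, min_len: int):
    """All maximal repeat pairs as (s1, s2, length, orientation)."""
    L = len(sequence)
    A = np.frombuffer(sequence.encode(), dtype=np.uint8)
    comp = np.zeros(256, dtype=np.uint8)
    for a, b in zip(b"ACGTN", b"TGCAN"):
        comp[a] = b
    C = comp[A]
    pairs = set()

    def canonical(s1, s2, length, orient):
        if circular:
            s1 %= L
            s2 %= L
        if s1 == s2:
            return None
        if s2 < s1:
            s1, s2 = s2, s1
        return (s1, s2, length, orient)

    def add_runs(mask_doubled, to_pair, orient):
        # mask over a doubled index space for circular wrap; cap length at L
        for start, length in _runs(mask_doubled):
            if length >= 2 * L:
                length = L
            if start >= L:
                continue
            length = min(length, L)
            if length < min_len:
                continue
            key = to_pair(start, length)
            if key is not None:
                pairs.add(key)

    idx = np.arange(2 * L if circular else L)
    for d in range(1, L):
        if circular:
            m = A[idx % L] == A[(idx + d) % L]
        else:
            m = np.zeros(L, bool)
            m[: L - d] = A[: L - d] == A[d:]
        add_runs(m, lambda s, ln, d=d: canonical(s, s + d, ln, "direct"), "direct")

    # inverted: anti-diagonal c with A[x] == comp(A[(c - x) mod L])
    cs = range(0, L) if circular else range(0, 2 * L - 1)
    for c in cs:
        if circular:
            m = A[idx % L] == C[(c - idx) % L]
        else:
            m = np.zeros(L, bool)
            xs = np.arange(max(0, c - L + 1), min(L, c + 1))
            if len(xs) == 0:
                continue
            mm = A[xs] == C[c - xs]
            m[xs] = mm
        for start, length in _runs(m):
            length = min(length, L)
            if start >= L or length < min_len:
                continue
            # copy1 = [start, start+len); copy2 = [(c - (start+len-1)), ...)
            s2 = (c - (start + length - 1)) % L if circular else c - (start + length - 1)
            key = canonical(start, s2, length, "inverted")
            if key is not None:
                pairs.add(key)
    return pairs


# --- alignment oracles ----------------------------------------------------

def gotoh_score(a: str, b: str, match=1.0, mismatch=-1.0, gap_open=4.0, gap_extend=1.0):
    """Textbook affine-gap global alignment score (gap of k costs open+k*ext)."""
    NEG = -1e18
    n, m = len(a), len(b)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (deletion from a)
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = -(gap_open + gap_extend * i)
    for j in range(1, m + 1):
        Y[0][j] = -(gap_open + gap_extend * j)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(
                M[i - 1][j] - gap_open - gap_extend, X[i - 1][j] - gap_extend
            )
            Y[i][j] = max(
                M[i][j - 1] - gap_open - gap_extend, Y[i][j - 1] - gap_extend
            )
    return max(M[n][m], X[n][m], Y[n][m])


def exhaustive_best_chain_score(anchors, max_gap=50_000, gap_diff_cost=0.5):
    """Best chain score over all anchor subsets (documented scoring rule).

    Anchors are (ref_start, qry_start, length) on the forward strand.
    """
    n = len(anchors)
    order = sorted(range(n), key=lambda i: (anchors[i][0], anchors[i][1]))

    def compatible(p, c):
        pr, pq, pl = p
        cr, cq, cl = c
        gr = cr - (pr + pl)
        gq = cq - (pq + pl)
        if gr > max_gap or gq > max_gap:
            return False
        lim = -(min(pl, cl) - 1)
        if gr < lim or gq < lim:
            return False
        return cr + cl > pr + pl

    def score(chain):
        total = 0.0
        prev = None
        for a in chain:
            total += a[2]
            if prev is not None:
                gr = a[0] - (prev[0] + prev[2])
                gq = a[1] - (prev[1] + prev[2])
                total -= max(0, -gr) + max(0, -gq)
                total -= gap_diff_cost * abs(gr - gq)
            prev = a
        return total

    best = 0.0
    for bits in range(1, 1 << n):
        chain = [anchors[order[i]] for i in range(n) if bits >> i & 1]
        ok = all(
            compatible(chain[k], chain[k + 1]) for k in range(len(chain) - 1)
        )
        if ok:
            best = max(best, score(chain))
    return best
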
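"""Presence/absence PCR marker design and in-silico validation.

A CMS marker amplifies a sterile-specific sequence (here, a candidate
ORF's unique region) so that a single PCR distinguishes sterile from
fertile cytoplasm.  Primer melting temperatures use the Wallace rule
(2(A+T) + 4(G+C)), a deliberate simple deterministic choice; candidate
pairs must satisfy GC 40-60%, a 3'-terminal G/C clamp and a Tm spread of
at most 5 degC, and every returned pair is verified by exhaustive
in-silico PCR to yield exactly one product on the sterile genome and none
on the maintainer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .genome_io import CircularGenome, reverse_complement


@dataclass(frozen=True)
class PrimerPair:
    fwd: str
    rev: str
    fwd_start: int  # position of the fwd primer 5' end on the design template
    rev_start: int  # forward-strand start of the rev primer binding site
    tm_fwd: float
    tm_rev: float
    gc_fwd: float
    gc_rev: float
    target_amplicon: int


@dataclass
class AmpliconResult:
    genome_id: str
    products: list[tuple[int, int, int]] = field(default_factory=list)  # (fwd_site, rev_site, length)
    call: str = "absent"  # present | absent


@dataclass
class MarkerDesignFailure:
    reason: str
    longest_interval: int = 0


def wallace_tm(primer: str) -> float:
    at = primer.count("A") + primer.count("T")
    gc = primer.count("G") + primer.count("C")
    return 2.0 * at + 4.0 * gc


def gc_fraction(primer: str) -> float:
    return (primer.count("G") + primer.count("C")) / len(primer)


def _primer_ok(p: str, gc_min: float, gc_max: float) -> bool:
    return gc_min <= gc_fraction(p) <= gc_max and p[-1] in "GC"


def _find_sites(primer: str, seq: str, circular: bool, max_mismatch: int) -> list[int]:
    """Start positions (mod L) where the primer anneals 5'->3' on ``seq``.

    The 3'-terminal 3 nt must match exactly; up to ``max_mismatch``
    mismatches are tolerated elsewhere.
    """
    L = len(seq)
    scan = seq + seq[: len(primer) - 1] if circular else seq
    n = len(primer)
    if max_mismatch == 0:
        sites = set()
        start = scan.find(primer)
        while start != -1:
            sites.add(start % L)
            start = scan.find(primer, start + 1)
        return sorted(sites)
    sites = []
    for i in range(len(scan) - n + 1):
        window = scan[i : i + n]
        if window[-3:] != primer[-3:]:
            continue
        mism = sum(1 for a, b in zip(window[:-3], primer[:-3]) if a != b)
        if mism <= max_mismatch:
            sites.append(i % L)
    return sorted(set(sites))


def in_silico_pcr(
    pair: PrimerPair,
    genome: CircularGenome,
    max_mismatch: int = 0,
    max_amplicon: int = 6000,
) -> AmpliconResult:
    """Exhaustive primer-site scan and convergent-pair product prediction.

    Products are reported for every forward-strand fwd site paired with a
    reverse-strand rev site lying downstream (circularly) within
    ``max_amplicon``; product length includes both primers.
    """
    seq = genome.sequence
    L = genome.length
    circ = genome.is_circular
    fwd_sites = _find_sites(pair.fwd, seq, circ, max_mismatch)
    # rev primer anneals to the minus strand: its binding site on the
    # forward strand is the reverse complement of the primer
    rev_rc = reverse_complement(pair.rev)
    rev_sites = _find_sites_exact_rc(rev_rc, pair.rev, seq, circ, max_mismatch)
    products = []
    for f in fwd_sites:
        for r in rev_sites:
            rev_end = r + len(pair.rev)
            length = (rev_end - f) % L if circ else rev_end - f
            if length <= 0 or length > max_amplicon:
                continue
            if length < len(pair.fwd) + len(pair.rev):
                continue
            products.append((f, r, length))
    products.sort()
    return AmpliconResult(
        genome.id, products, "present" if products else "absent"
    )


def _find_sites_exact_rc(
    rev_rc: str, rev: str, seq: str, circular: bool, max_mismatch: int
) -> list[int]:
    """Sites of the reverse primer: match its reverse complement on the
    forward strand, with the primer's 3' end (the *start* of rev_rc's
    window... i.e. the leftmost 3 nt of rev_rc) exact."""
    L = len(seq)
    scan = seq + seq[: len(rev_rc) - 1] if circular else seq
    n = len(rev_rc)
    if max_mismatch == 0:
        sites = set()
        start = scan.find(rev_rc)
        while start != -1:
            sites.add(start % L)
            start = scan.find(rev_rc, start + 1)
        return sorted(sites)
    sites = []
    for i in range(len(scan) - n + 1):
        window = scan[i : i + n]
        if window[:3] != rev_rc[:3]:  # primer 3' end, exact
            continue
        mism = sum(1 for a, b in zip(window[3:], rev_rc[3:]) if a != b)
        if mism <= max_mismatch:
            sites.append(i % L)
    return sorted(set(sites))


def design_marker(
    unique_interval: tuple[int, int],
    sterile: CircularGenome,
    maintainer: CircularGenome,
    target_len: int = 3000,
    tolerance: float = 0.20,
    primer_min: int = 18,
    primer_max: int = 25,
    gc_min: float = 0.40,
    gc_max: float = 0.60,
    tm_max_diff: float = 5.0,
    max_candidates: int = 10,
    max_amplicon: int = 6000,
    search_window: int = 400,
) -> list[PrimerPair] | MarkerDesignFailure:
    """Enumerate validated primer pairs inside a sterile-unique interval.

    At least one primer must sit wholly inside the unique interval (both do,
    since the search is restricted to it); the predicted sterile amplicon
    must lie within ``tolerance`` of ``target_len``; every returned pair is
    checked to give exactly one sterile product and zero maintainer
    products.  Pairs are ranked by |amplicon - target_len|.
    """
    s, e = unique_interval
    span = e - s
    lo = int(target_len * (1 - tolerance))
    hi = int(target_len * (1 + tolerance))
    if target_len > sterile.length:
        return MarkerDesignFailure("target amplicon exceeds genome length", span)
    if span < max(2 * primer_min + 1, lo):
        return MarkerDesignFailure("unique interval too short", span)
    seq = sterile.sequence[s:e]

    fwd_cands = []
    for i in range(min(search_window, span)):
        for n in range(primer_min, primer_max + 1):
            if i + n > span:
                continue
            p = seq[i : i + n]
            if _primer_ok(p, gc_min, gc_max):
                fwd_cands.append((i, p))
    rev_cands = []
    for j in range(max(0, span - search_window), span):
        for n in range(primer_min, primer_max + 1):
            if j + n > span:
                continue
            site = seq[j : j + n]
            p = reverse_complement(site)
            if _primer_ok(p, gc_min, gc_max):
                rev_cands.append((j, p))

    scored = []
    for i, fp in fwd_cands:
        for j, rp in rev_cands:
            amp = (j + len(rp)) - i
            if not (lo <= amp <= hi):
                continue
            tf, tr = wallace_tm(fp), wallace_tm(rp)
            if abs(tf - tr) > tm_max_diff:
                continue
            scored.append(
                (
                    abs(amp - target_len),
                    i,
                    j,
                    PrimerPair(
                        fp, rp, s + i, s + j, tf, tr,
                        gc_fraction(fp), gc_fraction(rp), amp,
                    ),
                )
            )
    scored.sort(key=lambda t: (t[0], t[1], t[2]))

    validated: list[PrimerPair] = []
    for _, _, _, pair in scored:
        res_s = in_silico_pcr(pair, sterile, max_amplicon=max_amplicon)
        if len(res_s.products) != 1:
            continue
        res_m = in_silico_pcr(pair, maintainer, max_amplicon=max_amplicon)
        if res_m.products:
            continue
        validated.append(pair)
        if len(validated) >= max_candidates:
            break
    if not validated:
        return MarkerDesignFailure("no primer pair passed validation", span)
    return validated


def validate_panel(
    pair: PrimerPair,
    panel: list[tuple[CircularGenome, str]],
    max_mismatch: int = 0,
    max_amplicon: int = 6000,
) -> tuple[float, pd.DataFrame]:
    """Score the marker on a labeled panel: present predicts sterile."""
    if not panel:
        raise ValueError("empty panel")
    rows = []
    correct = 0
    for genome, label in panel:
        res = in_silico_pcr(pair, genome, max_mismatch, max_amplicon)
        predicted = "sterile" if res.call == "present" else "fertile"
        ok = predicted == label
        correct += ok
        rows.append(
            {
                "line": genome.id,
                "label": label,
                "call": res.call,
                "predicted": predicted,
                "n_products": len(res.products),
                "product_bp": res.products[0][2] if res.products else 0,
                "correct": bool(ok),
            }
        )
    table = pd.DataFrame(
        rows,
        columns=["line", "label", "call", "predicted", "n_products", "product_bp", "correct"],
    )
    return correct / len(panel), table
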
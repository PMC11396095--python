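"""ORF prediction and known-gene annotation for circular mitogenomes.

ORFs are ATG-initiated, stop-terminated and maximal per stop codon (the
first in-frame ATG after the previous stop), scanned in all six frames.
Circular genomes are scanned on the doubled sequence and duplicates removed
at identical modular coordinates, so origin-crossing ORFs are found exactly
once.  Known genes are annotated by translated homology: reference proteins
are seeded against six-frame translations by exact peptide k-mers and the
candidate regions are then locally aligned, keeping hits that cover at least
40% of the reference protein (the standard homology-annotation coverage
rule) above an identity floor.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq

from .genome_io import (
    CircularGenome,
    GeneCategory,
    GeneModel,
    Interval,
    reverse_complement,
)

STOP_CODONS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class OrfRecord:
    """A predicted open reading frame (interval includes the stop codon)."""

    id: str
    interval: Interval
    frame: int
    aa_length: int
    protein: str

    @property
    def wraps(self) -> bool:
        return self.interval.wraps


@dataclass(frozen=True)
class HomologyHit:
    subject_gene: str
    interval: Interval
    percent_identity: float
    coverage_fraction: float
    score: float


def translate(cds: str, allow_internal_stop: bool = False) -> str:
    """Translate a CDS with the standard code (table 1); trailing stop dropped.

    Internal stop codons are an error unless ``allow_internal_stop`` is set,
    in which case they appear as ``*`` — they are never silently truncated.
    """
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} not divisible by 3")
    if "N" in cds:
        raise ValueError("ambiguity code N in CDS")
    prot = str(Seq(cds).translate(table=1))
    if prot.endswith("*"):
        prot = prot[:-1]
    if "*" in prot and not allow_internal_stop:
        raise ValueError(f"internal stop codon at aa position {prot.index('*')}")
    return prot


def _scan_frame(seq: str, frame: int, min_aa: int):
    """Yield (atg_pos, stop_end) for maximal first-ATG ORFs in one frame."""
    first_atg = None
    n = len(seq)
    for i in range(frame, n - 2, 3):
        codon = seq[i : i + 3]
        if codon in STOP_CODONS:
            if first_atg is not None:
                aa = (i - first_atg) // 3
                if aa >= min_aa:
                    yield first_atg, i + 3
            first_atg = None
        elif first_atg is None and codon == "ATG":
            first_atg = i


def find_orfs(genome: CircularGenome, min_aa: int = 100) -> list[OrfRecord]:
    """All maximal ATG->stop ORFs with >= ``min_aa`` codons, both strands.

    Returned sorted by (start, strand); ids are assigned by
    :func:`name_orfs` naming (orf{aa_length}{letter} in coordinate order).
    """
    if min_aa < 1:
        raise ValueError("min_aa must be >= 1")
    L = genome.length
    scan = genome.sequence + genome.sequence if genome.is_circular else genome.sequence

    # stop-keyed candidates: (stop_mod, strand) -> best (span, fwd_start)
    best: dict[tuple[int, str], tuple[int, int, int]] = {}
    for strand in "+-":
        work = scan if strand == "+" else reverse_complement(scan)
        for frame in range(3):
            for atg, stop_end in _scan_frame(work, frame, min_aa):
                span = stop_end - atg
                if span > L:
                    continue
                if strand == "+":
                    fwd_start = atg
                    stop_key = (stop_end - 3) % L if genome.is_circular else stop_end - 3
                else:
                    # map from reverse-complement coordinates
                    fwd_start = len(work) - stop_end
                    stop_key = fwd_start % L if genome.is_circular else fwd_start
                key = (stop_key, strand)
                cand = (span, fwd_start % L if genome.is_circular else fwd_start, atg)
                prev = best.get(key)
                if prev is None or cand[0] > prev[0]:
                    best[key] = cand

    orfs = []
    for (stop_key, strand), (span, start, _) in best.items():
        end = start + span
        if end <= L:
            iv = Interval(start, end, strand)
        else:
            iv = Interval(start, end - L, strand, wraps=True)
        cds = _extract_oriented(genome, iv)
        prot = translate(cds)
        orfs.append(
            OrfRecord("", iv, start % 3, span // 3 - 1, prot)
        )
    orfs.sort(key=lambda o: (o.interval.start, o.interval.strand))
    return name_orfs(orfs)


def _extract_oriented(genome: CircularGenome, iv: Interval) -> str:
    from .genome_io import extract

    return extract(genome, iv)


def name_orfs(orfs: list[OrfRecord]) -> list[OrfRecord]:
    """Assign orf{aa_length}{a,b,...} ids in coordinate order."""
    counters: dict[int, int] = {}
    named = []
    for o in sorted(orfs, key=lambda o: (o.interval.start, o.interval.strand)):
        k = counters.get(o.aa_length, 0)
        counters[o.aa_length] = k + 1
        suffix = ""
        n = k
        while True:
            suffix = chr(ord("a") + n % 26) + suffix
            n = n // 26 - 1
            if n < 0:
                break
        named.append(OrfRecord(f"orf{o.aa_length}{suffix}", o.interval, o.frame, o.aa_length, o.protein))
    return named


# --- known-gene annotation -------------------------------------------------

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def _make_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = _BLOSUM62
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    return aligner


@dataclass(frozen=True)
class RefProtein:
    name: str
    category: GeneCategory
    protein: str


def load_reference_proteins(path: str | Path) -> list[RefProtein]:
    """Load a reference protein FASTA with ``name category`` headers."""
    refs = []
    for rec in SeqIO.parse(str(path), "fasta"):
        cat = GeneCategory(rec.description.split(maxsplit=1)[1].replace("_", " "))
        refs.append(RefProtein(rec.id, cat, str(rec.seq)))
    return refs


def _six_frames(genome: CircularGenome) -> list[tuple[str, int, str]]:
    """(strand, frame, aa_string) for six frames of the (doubled) genome."""
    scan = genome.sequence + genome.sequence if genome.is_circular else genome.sequence
    frames = []
    for strand in "+-":
        work = scan if strand == "+" else reverse_complement(scan)
        for frame in range(3):
            sub = work[frame : frame + 3 * ((len(work) - frame) // 3)]
            frames.append((strand, frame, str(Seq(sub).translate(table=1))))
    return frames


def annotate_known_genes(
    genome: CircularGenome,
    reference_proteins: list[RefProtein],
    min_coverage: float = 0.40,
    min_identity: float = 50.0,
    seed_k: int = 6,
) -> list[GeneModel]:
    """Annotate known genes by translated homology against six frames.

    A hit is kept when the aligned region covers at least ``min_coverage``
    of the reference protein at >= ``min_identity`` percent identity.
    Disjoint placements of the same gene are named with -D2, -D3 suffixes in
    coordinate order; when a full-length hit is followed by an in-frame stop
    codon the stop is included in the gene interval.
    """
    if not reference_proteins:
        raise ValueError("empty reference protein set")
    if not genome.sequence:
        raise ValueError("empty genome")
    L = genome.length
    scan_len = 2 * L if genome.is_circular else L
    aligner = _make_aligner()

    # seed index over reference peptides
    seeds: dict[str, list[tuple[int, int]]] = {}
    for pi, rp in enumerate(reference_proteins):
        for j in range(len(rp.protein) - seed_k + 1):
            seeds.setdefault(rp.protein[j : j + seed_k], []).append((pi, j))

    hits: dict[int, list[HomologyHit]] = {pi: [] for pi in range(len(reference_proteins))}
    for strand, frame, aa in _six_frames(genome):
        # diagonals with seed support, per protein
        diag_hits: dict[int, set[int]] = {}
        for i in range(len(aa) - seed_k + 1):
            for pi, j in seeds.get(aa[i : i + seed_k], ()):
                diag_hits.setdefault(pi, set()).add(i - j)
        for pi, diags in diag_hits.items():
            rp = reference_proteins[pi]
            plen = len(rp.protein)
            for d0 in _cluster_diagonals(sorted(diags), plen // 4 + 2):
                w_lo = max(0, d0 - 8)
                w_hi = min(len(aa), d0 + plen + 8)
                window = aa[w_lo:w_hi]
                if not window:
                    continue
                alns = aligner.align(rp.protein, window)
                if len(alns) == 0:
                    continue
                aln = alns[0]
                qa, ta = aln.aligned
                if len(qa) == 0:
                    continue
                ident = sum(
                    1
                    for (qs, qe), (ts, te) in zip(qa, ta)
                    for a, b in zip(rp.protein[qs:qe], window[ts:te])
                    if a == b
                )
                aligned_cols = sum(qe - qs for qs, qe in qa)
                coverage = (qa[-1][1] - qa[0][0]) / plen
                identity = 100.0 * ident / aligned_cols
                if coverage < min_coverage or identity < min_identity:
                    continue
                # aa coordinates in frame -> nt coordinates on the scan
                aa_s = w_lo + ta[0][0]
                aa_e = w_lo + ta[-1][1]
                nt_s = frame + 3 * aa_s
                nt_e = frame + 3 * aa_e
                if strand == "-":
                    nt_s, nt_e = scan_len - nt_e, scan_len - nt_s
                # include the trailing stop codon of full-length hits
                if coverage >= 0.999:
                    if strand == "+":
                        nxt = _codon_at(genome, nt_e)
                        if nxt in STOP_CODONS:
                            nt_e += 3
                    else:
                        nxt = reverse_complement(_codon_at(genome, nt_s - 3))
                        if nxt in STOP_CODONS:
                            nt_s -= 3
                if nt_s < 0 or nt_e - nt_s > L:
                    continue
                start = nt_s % L if genome.is_circular else nt_s
                end = start + (nt_e - nt_s)
                iv = (
                    Interval(start, end, strand)
                    if end <= L
                    else Interval(start, end - L, strand, wraps=True)
                )
                hits[pi].append(HomologyHit(rp.name, iv, identity, coverage, aln.score))

    models = []
    for pi, rp in enumerate(reference_proteins):
        placements = _merge_placements(hits[pi], L)
        placements.sort(key=lambda h: h.interval.start)
        for k, hit in enumerate(placements):
            name = rp.name if k == 0 else f"{rp.name}-D{k + 1}"
            models.append(GeneModel(name, rp.category, [hit.interval], coding=True))
    models.sort(key=lambda m: (m.span_interval().start, m.name))
    return models


def _codon_at(genome: CircularGenome, pos: int) -> str:
    from .genome_io import extract_circular

    if pos < 0:
        pos += genome.length
    if not genome.is_circular and pos + 3 > genome.length:
        return ""
    return extract_circular(genome, pos, 3)


def _cluster_diagonals(diags: list[int], tol: int) -> list[int]:
    """Collapse nearby diagonals; return one representative (min) each."""
    reps = []
    for d in diags:
        if not reps or d - reps[-1][-1] > tol:
            reps.append([d])
        else:
            reps[-1].append(d)
    return [min(group) for group in reps]


def _merge_placements(hs: list[HomologyHit], L: int) -> list[HomologyHit]:
    """Deduplicate/merge overlapping hits (incl. doubled-sequence aliases)."""
    uniq: dict[tuple[int, int, str], HomologyHit] = {}
    for h in hs:
        key = (h.interval.start % L, h.interval.span(L), h.interval.strand)
        prev = uniq.get(key)
        if prev is None or h.score > prev.score:
            uniq[key] = h
    merged: list[HomologyHit] = []
    for h in sorted(uniq.values(), key=lambda h: (-h.score, h.interval.start)):
        overlap = False
        for m in merged:
            if h.interval.strand != m.interval.strand:
                continue
            hs_, he_ = h.interval.start, h.interval.start + h.interval.span(L)
            ms_, me_ = m.interval.start, m.interval.start + m.interval.span(L)
            if min(he_, me_) - max(hs_, ms_) > 0 or min(he_ % L + L, me_) - max(hs_, ms_) > 0:
                overlap = True
                break
        if not overlap:
            merged.append(h)
    return merged


def write_orf_protein_fasta(orfs: list[OrfRecord], path: str | Path, tm_counts: dict[str, int] | None = None) -> None:
    with open(path, "w") as fh:
        for o in orfs:
            extra = f" tm_domains={tm_counts[o.id]}" if tm_counts and o.id in tm_counts else ""
            fh.write(f">{o.id} aa={o.aa_length}{extra}\n{o.protein}\n")
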
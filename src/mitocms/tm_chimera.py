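"""Transmembrane-domain prediction and chimeric / co-transcription detection.

CMS-associated mitochondrial ORFs typically either encode membrane-anchored
peptides or sit in a co-transcription unit with a standard mitochondrial
gene.  Transmembrane segments are predicted here with a windowed
Kyte–Doolittle hydropathy score: a full HMM topology model is deliberately
out of scope, and the hydropathy surrogate with its thresholds is exposed as
configuration.  Chimera/co-transcription detection is purely positional:
same-strand ORF/gene pairs that overlap or lie within a small gap are merged
into units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .genome_io import CircularGenome, GeneModel, Interval

# Kyte & Doolittle (1982) hydropathy index.
KYTE_DOOLITTLE = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5,
}


@dataclass(frozen=True)
class TmDomain:
    """A predicted membrane-spanning segment in protein coordinates."""

    orf_id: str
    aa_start: int  # 0-based inclusive
    aa_end: int    # exclusive
    mean_hydropathy: float

    @property
    def span(self) -> int:
        return self.aa_end - self.aa_start


@dataclass
class ChimeraRecord:
    """An ORF linked to a known gene by overlap or close same-strand adjacency."""

    orf_id: str
    partner_gene: str
    relation: str  # overlap_5prime | overlap_3prime | adjacent_upstream | adjacent_downstream
    shared_bp: int
    unit_members: list[str] = field(default_factory=list)
    unit_length: int = 0


def hydropathy_profile(protein: str, window: int = 19) -> list[float]:
    """Centered sliding-window mean hydropathy, one value per residue.

    Windows at the termini are truncated to the residues available, so the
    profile has exactly ``len(protein)`` entries.
    """
    if len(protein) < window:
        raise ValueError(f"protein shorter than window ({len(protein)} < {window})")
    try:
        scores = [KYTE_DOOLITTLE[aa] for aa in protein]
    except KeyError as exc:
        raise ValueError(f"unknown residue symbol {exc.args[0]!r}") from None
    half = window // 2
    prefix = [0.0]
    for s in scores:
        prefix.append(prefix[-1] + s)
    out = []
    n = len(scores)
    for i in range(n):
        lo = max(0, i - half)
        hi = min(n, i + half + 1)
        out.append((prefix[hi] - prefix[lo]) / (hi - lo))
    return out


def predict_tm(
    profile: list[float],
    orf_id: str = "",
    threshold: float = 1.6,
    min_len: int = 15,
    max_len: int = 35,
    min_gap: int = 5,
) -> list[TmDomain]:
    """Call transmembrane segments from a hydropathy profile.

    Maximal runs of residues with windowed hydropathy >= ``threshold`` are
    taken as candidate segments; runs separated by fewer than ``min_gap``
    residues are merged first, then the length bounds are enforced: runs
    shorter than ``min_len`` are dropped and runs longer than ``max_len``
    are split into equal near-``max_len`` pieces.
    """
    runs: list[list[int]] = []
    for i, v in enumerate(profile):
        if v >= threshold:
            if runs and i == runs[-1][1]:
                runs[-1][1] = i + 1
            else:
                runs.append([i, i + 1])
    # merge runs closer than min_gap
    merged: list[list[int]] = []
    for run in runs:
        if merged and run[0] - merged[-1][1] < min_gap:
            merged[-1][1] = run[1]
        else:
            merged.append(run)
    domains: list[TmDomain] = []
    for start, end in merged:
        length = end - start
        if length < min_len:
            continue
        if length <= max_len:
            pieces = [(start, end)]
        else:
            k = -(-length // max_len)  # ceil
            if length / k < min_len:
                k = 1
            step = length / k
            pieces = []
            for j in range(k):
                a = start + round(j * step)
                b = start + round((j + 1) * step) if j < k - 1 else end
                pieces.append((a, min(b, a + max_len)))
        for a, b in pieces:
            mean = sum(profile[a:b]) / (b - a)
            domains.append(TmDomain(orf_id, a, b, mean))
    return domains


def count_tm_domains(protein: str, orf_id: str = "", window: int = 19, **kwargs) -> int:
    if len(protein) < window:
        return 0
    return len(predict_tm(hydropathy_profile(protein, window), orf_id, **kwargs))


def _circular_gap(up_end: int, down_start: int, length: int) -> int:
    """Gap in bp from the end of one feature to the start of the next, mod L."""
    return (down_start - up_end) % length


def detect_chimera(orfs, gene_models: list[GeneModel], genome: CircularGenome, max_gap: int = 100) -> list[ChimeraRecord]:
    """Find ORF/known-gene overlaps and co-transcription adjacencies.

    Two same-strand features are linked when they overlap or when the gap
    between them is at most ``max_gap`` bp (co-transcription implies a single
    strand, so opposite-strand proximity is ignored).  Maximal runs of linked
    features form a unit; the unit length is the genomic span from the first
    member's start to the last member's end, measured circularly.
    """
    L = genome.length

    feats = []  # (start, end, strand, kind, name)
    for o in orfs:
        iv = o.interval
        end = iv.start + iv.span(L)
        feats.append((iv.start, end, iv.strand, "orf", o.id))
    for g in gene_models:
        iv = g.span_interval()
        end = iv.start + iv.span(L)
        feats.append((iv.start, end, iv.strand, "gene", g.name))
    feats.sort(key=lambda f: (f[0], f[1], f[4]))

    n = len(feats)
    # union-find over linked same-strand features
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    links: list[tuple[int, int, int]] = []  # (i, j, shared_bp) with i an ORF or gene
    for i in range(n):
        for j in range(i + 1, n):
            si, ei, sti, ki, _ = feats[i]
            sj, ej, stj, kj, _ = feats[j]
            if sj - ei > max_gap and not genome.is_circular:
                break
            if sti != stj:
                continue
            shared = min(ei, ej) - max(si, sj)
            linked = shared > 0 or _circular_gap(ei, sj, L) <= max_gap
            if not linked and genome.is_circular:
                linked = _circular_gap(ej, si, L) <= max_gap
            if linked:
                union(i, j)
                links.append((i, j, max(0, shared)))
            elif sj - ei > max_gap:
                break

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)

    records: list[ChimeraRecord] = []
    for members in groups.values():
        kinds = {feats[i][3] for i in members}
        if not ({"orf", "gene"} <= kinds):
            continue
        members.sort(key=lambda i: feats[i][0])
        names = [feats[i][4] for i in members]
        unit_len = feats[members[-1]][1] - feats[members[0]][0]
        if unit_len <= 0:
            unit_len += L
        for i in members:
            s, e, strand, kind, name = feats[i]
            if kind != "orf":
                continue
            # nearest same-unit gene partner
            best = None
            for j in members:
                if feats[j][3] != "gene":
                    continue
                gs, ge, _, _, gname = feats[j]
                shared = min(e, ge) - max(s, gs)
                if shared > 0:
                    dist = -shared
                else:
                    dist = min(_circular_gap(e, gs, L), _circular_gap(ge, s, L))
                if best is None or dist < best[0]:
                    best = (dist, j, max(0, shared))
            if best is None:
                continue
            _, j, shared_bp = best
            gs, ge, _, _, gname = feats[j]
            # relations are expressed relative to the partner gene's reading
            # direction: an ORF just 5' of the gene is "adjacent_upstream".
            if shared_bp > 0:
                covers_5p = s <= gs < e if strand == "+" else s < ge <= e
                relation = "overlap_5prime" if covers_5p else "overlap_3prime"
            else:
                orf_before = _circular_gap(e, gs, L) <= max_gap
                if strand == "+":
                    relation = "adjacent_upstream" if orf_before else "adjacent_downstream"
                else:
                    relation = "adjacent_downstream" if orf_before else "adjacent_upstream"
            records.append(
                ChimeraRecord(name, gname, relation, shared_bp, names, unit_len)
            )
    records.sort(key=lambda r: (r.orf_id, r.partner_gene))
    return records
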
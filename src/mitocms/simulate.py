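"""Synthetic maintainer/sterile mitogenome pairs with planted ground truth.

Real CMS studies compare a sterile line's mitogenome against its isonuclear
maintainer; assemblies for such pairs are frequently not deposited, so this
module builds the study system synthetically: a maintainer-like circular
genome carrying a standard plant-mito gene complement (with duplicated
"-D2"/"-D3" copies), repeat families and ncRNAs, and a sterile-like genome
derived from it by a fixed edit order — structural variants, then novel-ORF
insertions (a chimeric orf561a–rpl16–orf312a co-transcription unit and a
three-transmembrane-domain ORF), then small InDels, then SNPs with
engineered synonymous/non-synonymous effects.  Every edit is recorded in a
TruthSet whose coordinates refer to the final genomes, so each downstream
stage can be scored for recovery.

Randomness is drawn from named substreams of a single seed (background,
placement, codons, repeats, ORFs, SVs, indels, SNPs, panel), so extending
one plan does not reshuffle unrelated draws.  The generator audits itself:
after assembly it re-scans the sterile genome and re-draws any attempt in
which a chance junction ORF would make the set of sterile-unique ORFs differ
from the planted one.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.Data import CodonTable

from . import jsonutil, refs
from .annotate import OrfRecord, find_orfs, translate
from .genome_io import (
    CircularGenome,
    GeneCategory,
    GeneModel,
    Interval,
    Topology,
    reverse_complement,
)
from .tm_chimera import count_tm_domains

# 12-bp spacer flanking every novel block: carries a stop codon in all six
# frames (it is its own reverse complement) and no ATG, so no reading frame
# can run across a novel-block edge and no planted ORF can be extended by an
# upstream in-frame ATG from the background.
CASSETTE = "CTAGCTAGCTAG"

_TABLE = CodonTable.unambiguous_dna_by_id[1]
AA_TO_CODONS: dict[str, list[str]] = {}
for codon, aa in _TABLE.forward_table.items():
    AA_TO_CODONS.setdefault(aa, []).append(codon)
for aa in AA_TO_CODONS:
    AA_TO_CODONS[aa].sort()
STOPS = sorted(_TABLE.stop_codons)

_BASES = np.array(list("ACGT"))


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

@dataclass
class ChimeraPlan:
    """A planted co-transcription unit: orf5' - gap - gene copy - gap - orf3'."""

    gene: str = "rpl16"
    orf5_aa: int = 561
    orf3_aa: int = 312
    gap5: int = 20
    gap3: int = 18

    def unit_length(self, gene_aa: int) -> int:
        return 3 * (self.orf5_aa + 1) + self.gap5 + 3 * (gene_aa + 1) + self.gap3 + 3 * (self.orf3_aa + 1)


@dataclass
class TmOrfPlan:
    aa: int = 172
    n_domains: int = 3


@dataclass
class SimConfig:
    genome_length: int = 100_000
    gc_target: float = 0.446
    gene_complement: list[tuple[str, str, int, int]] = field(
        default_factory=refs.default_gene_complement
    )
    noncoding: list[tuple[str, str, int]] = field(
        default_factory=lambda: [(n, c.value, l) for n, c, l in refs.NONCODING_GENES]
    )
    repeat_plan: list[tuple[int, str, int]] = field(
        default_factory=lambda: [
            (32, "direct", 3),
            (33, "direct", 2),
            (45, "direct", 2),
            (35, "inverted", 2),
            (70, "direct", 1),
        ]
    )
    n_snps: int = 58
    # CDS SNP effects mirror the per-gene classes reported for a real
    # sterile/maintainer pair: 5 synonymous, 19 non-synonymous.
    snp_cds_plan: dict[str, dict[str, int]] = field(
        default_factory=lambda: {
            "synonymous": {"cox2": 2, "cob": 1, "rpl2": 1, "nad4L": 1},
            "nonsynonymous": {
                "sdh3": 3,
                "ccmFc": 3,
                "rpl10": 3,
                "rpl16": 3,
                "atp6": 4,
                "rps1": 3,
            },
        }
    )
    n_ncrna_snps: int = 4
    n_small_indels: int = 18
    indel_insertion_fraction: float = 1 / 3  # 6 insertions : 12 deletions
    sv_plan: list[tuple[str, int]] = field(
        default_factory=lambda: [
            ("translocation", 4000),
            ("translocation", 3000),
            ("inversion", 3000),
            ("trans_inver", 2500),
            ("insertion", 800),
            ("deletion", 700),
            ("deletion", 600),
            ("complex", 500),
        ]
    )
    complex_qry_size: int = 700
    chimera_plan: ChimeraPlan | None = field(default_factory=ChimeraPlan)
    tm_orf_plan: TmOrfPlan | None = field(default_factory=TmOrfPlan)
    extra_unique_orf_aa: list[int] = field(default_factory=lambda: [117, 133, 149])
    seed: int = 1


def full_scale_config(seed: int = 1) -> SimConfig:
    """A 500-kb pair with variant/SV counts at real mitogenome scale."""
    sv = (
        [("translocation", s) for s in [9000, 8000, 7000, 6500, 6000, 5500, 5000,
                                        4500, 4000, 3500, 3000, 2500, 2000, 1500, 1000]]
        + [("inversion", s) for s in [6000, 5000, 4000, 3000, 2000]]
        + [("trans_inver", s) for s in [5000, 4000, 3000, 2500, 2000, 1500, 1200, 1000, 800]]
        + [("insertion", s) for s in [900, 600]]
        + [("deletion", s) for s in [900, 700, 500, 300]]
        + [("complex", s) for s in [500, 400, 300]]
    )
    return SimConfig(
        genome_length=500_000,
        n_snps=288,
        n_ncrna_snps=8,
        n_small_indels=86,
        indel_insertion_fraction=28 / 86,
        sv_plan=sv,
        repeat_plan=[
            (32, "direct", 8),
            (33, "direct", 5),
            (38, "direct", 4),
            (45, "direct", 4),
            (35, "inverted", 4),
            (70, "direct", 2),
            (120, "direct", 1),
        ],
        seed=seed,
    )


# --------------------------------------------------------------------------
# truth records
# --------------------------------------------------------------------------

@dataclass
class SnpTruth:
    ref_pos: int
    qry_pos: int
    ref: str
    alt: str
    effect: str  # synonymous | nonsynonymous | noncoding | intergenic
    gene: str | None = None


@dataclass
class IndelTruth:
    ref_pos: int
    qry_pos: int
    type: str  # insertion | deletion (relative to the maintainer reference)
    length: int
    seq: str
    region_class: str = "intergenic"


@dataclass
class SvTruth:
    type: str
    ref_start: int
    ref_end: int
    qry_start: int
    qry_end: int


@dataclass
class OrfTruth:
    id: str
    aa_length: int
    qry_start: int
    qry_end: int
    strand: str
    kind: str  # chimera_5 | chimera_3 | tm | extra
    tm_domains: int = 0


@dataclass
class TruthSet:
    snps: list[SnpTruth] = field(default_factory=list)
    indels: list[IndelTruth] = field(default_factory=list)
    sv_events: list[SvTruth] = field(default_factory=list)
    orfs: list[OrfTruth] = field(default_factory=list)
    unique_orf_ids: list[str] = field(default_factory=list)
    candidate_orf_ids: list[str] = field(default_factory=list)
    co_transcript_unit: dict | None = None
    marker_locus: tuple[int, int] | None = None  # qry span of the chimera block
    orf561_maintainer_locus: tuple[int, int] | None = None

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            jsonutil.dumps(dataclasses.asdict(self), indent=1)
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthSet":
        d = json.loads(Path(path).read_text())
        return cls(
            snps=[SnpTruth(**x) for x in d["snps"]],
            indels=[IndelTruth(**x) for x in d["indels"]],
            sv_events=[SvTruth(**x) for x in d["sv_events"]],
            orfs=[OrfTruth(**x) for x in d["orfs"]],
            unique_orf_ids=d["unique_orf_ids"],
            candidate_orf_ids=d["candidate_orf_ids"],
            co_transcript_unit=d["co_transcript_unit"],
            marker_locus=tuple(d["marker_locus"]) if d["marker_locus"] else None,
            orf561_maintainer_locus=tuple(d["orf561_maintainer_locus"])
            if d["orf561_maintainer_locus"]
            else None,
        )


# --------------------------------------------------------------------------
# helpers
# --------------------------------------------------------------------------

def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([seed & 0x7FFFFFFF, stream])


def random_seq(rng: np.random.Generator, n: int, gc: float = 0.446) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(_BASES[rng.choice(4, size=n, p=p)])


# synonymous-codon weights biased toward A/T third positions, mirroring the
# AT-rich codon usage of plant organelle genomes (also keeps overall genome
# GC near the configured target despite GC-neutral amino-acid composition)
_CODON_WEIGHTS: dict[str, np.ndarray] = {}
for _aa, _codons in AA_TO_CODONS.items():
    w = np.array([1.60 ** sum(c in "AT" for c in codon) for codon in _codons])
    _CODON_WEIGHTS[_aa] = w / w.sum()
_STOP_W = np.array([1.60 ** sum(c in "AT" for c in codon) for codon in STOPS])
_STOP_W /= _STOP_W.sum()


def reverse_translate(protein: str, rng: np.random.Generator, stop: bool = True) -> str:
    codons = [
        AA_TO_CODONS[aa][rng.choice(len(AA_TO_CODONS[aa]), p=_CODON_WEIGHTS[aa])]
        for aa in protein
    ]
    if stop:
        codons.append(STOPS[rng.choice(len(STOPS), p=_STOP_W)])
    return "".join(codons)


_AA20 = list("ACDEFGHIKLMNPQRSTVWY")
_SOLUBLE_W = np.array(
    [3, 1, 7, 7, 1, 7, 3, 1, 7, 2, 1, 5, 5, 5, 6, 8, 6, 2, 1, 3], float
)
_SOLUBLE_W /= _SOLUBLE_W.sum()
_HYDRO = list("LIVFA")


def soluble_protein(rng: np.random.Generator, aa_len: int) -> str:
    """A random protein verified to carry no predicted TM domain."""
    for _ in range(200):
        prot = "M" + "".join(rng.choice(_AA20, size=aa_len - 1, p=_SOLUBLE_W))
        if count_tm_domains(prot) == 0:
            return prot
    raise RuntimeError("could not draw a soluble protein")


def tm_protein(rng: np.random.Generator, aa_len: int, n_domains: int) -> str:
    """A protein engineered to show exactly ``n_domains`` hydrophobic stretches."""
    tm_len, link_len = 25, 20
    core = n_domains * tm_len + (n_domains) * link_len
    lead = max(4, (aa_len - core) // 2)
    tail = aa_len - core - lead
    if tail < 0:
        raise ValueError("aa_len too short for requested domain count")
    hydrophil = [a for a in _AA20 if a not in _HYDRO]
    for _ in range(200):
        parts = ["M" + "".join(rng.choice(hydrophil, size=lead - 1))]
        for d in range(n_domains):
            parts.append("".join(rng.choice(_HYDRO, size=tm_len)))
            n_link = link_len if d < n_domains - 1 else link_len + tail
            parts.append("".join(rng.choice(hydrophil, size=n_link)))
        prot = "".join(parts)
        assert len(prot) == aa_len
        if count_tm_domains(prot) == n_domains:
            return prot
    raise RuntimeError("could not draw the requested TM architecture")


class _Occupancy:
    """Sorted occupied-interval bookkeeping for collision-free placement."""

    def __init__(self, length: int, margin: int):
        self.length = length
        self.taken: list[tuple[int, int]] = [(0, margin), (length - margin, length)]

    def free(self, start: int, end: int) -> bool:
        if start < 0 or end > self.length:
            return False
        return all(min(end, e) - max(start, s) <= 0 for s, e in self.taken)

    def claim(self, start: int, end: int) -> None:
        self.taken.append((start, end))
        self.taken.sort()

    def place(self, rng: np.random.Generator, size: int, pad: int, tries: int = 4000) -> int:
        for _ in range(tries):
            start = int(rng.integers(0, self.length - size))
            if self.free(start - pad, start + size + pad):
                self.claim(start - pad, start + size + pad)
                return start
        raise RuntimeError("placement collision budget exhausted: plan too dense")


# --------------------------------------------------------------------------
# the builder
# --------------------------------------------------------------------------

CATEGORY_BY_VALUE = {c.value: c for c in GeneCategory}


@dataclass
class SyntheticPair:
    config: SimConfig
    maintainer: CircularGenome
    maintainer_models: list[GeneModel]
    sterile: CircularGenome
    truth: TruthSet


def build_pair(config: SimConfig) -> SyntheticPair:
    """Build the maintainer/sterile pair plus its TruthSet."""
    mb = _MaintainerBuild(config)
    mb.build()
    last_err = None
    for salt in range(12):
        sb = _SterileBuild(config, mb, salt)
        try:
            ok = sb.build()
        except RuntimeError as err:
            last_err = err
            continue
        if ok:
            return SyntheticPair(config, mb.genome, mb.models, sb.genome, sb.truth)
    raise RuntimeError(f"sterile derivation failed audit repeatedly; plan too dense ({last_err})")


def generate_maintainer(config: SimConfig) -> tuple[CircularGenome, list[GeneModel]]:
    mb = _MaintainerBuild(config)
    mb.build()
    return mb.genome, mb.models


def derive_sterile(
    maintainer: CircularGenome, config: SimConfig
) -> tuple[CircularGenome, TruthSet]:
    pair = build_pair(config)
    if pair.maintainer.sequence != maintainer.sequence:
        raise ValueError("maintainer genome does not match this SimConfig/seed")
    return pair.sterile, pair.truth


class _MaintainerBuild:
    def __init__(self, config: SimConfig):
        self.cfg = config
        self.proteins: dict[str, tuple[str, str]] = {}  # name -> (category, protein)

    def build(self) -> None:
        cfg = self.cfg
        L = cfg.genome_length
        margin = max(50, min(1000, L // 50))
        bg = list(random_seq(_rng(cfg.seed, 0), L, cfg.gc_target))

        shipped = {rp.name: (rp.category.value, rp.protein) for rp in refs.reference_proteins()}
        place_rng = _rng(cfg.seed, 1)
        codon_rng = _rng(cfg.seed, 2)
        occ = _Occupancy(L, margin)
        models: list[GeneModel] = []

        # expand complement into copies and place them
        placements: dict[str, list[tuple[int, int, str]]] = {}
        feature_total = sum(3 * (aa + 1) * n for _, _, aa, n in cfg.gene_complement)
        feature_total += sum(l for _, _, l in cfg.noncoding)
        if feature_total > 0.7 * L:
            raise ValueError("gene complement does not fit in genome_length")
        for name, cat, aa, n_copies in cfg.gene_complement:
            if name in shipped:
                prot = shipped[name][1]
                if len(prot) != aa:
                    prot = _resize_protein(prot, aa)
            else:
                prot = soluble_protein(codon_rng, aa)
            self.proteins[name] = (cat, prot)
            for _ in range(n_copies):
                cds = reverse_translate(prot, codon_rng)
                start = occ.place(place_rng, len(cds), pad=150)
                strand = "+" if place_rng.random() < 0.5 else "-"
                written = cds if strand == "+" else reverse_complement(cds)
                bg[start : start + len(cds)] = list(written)
                placements.setdefault(name, []).append((start, start + len(cds), strand))

        for name, cat, length in cfg.noncoding:
            seq = random_seq(codon_rng, length, self.cfg.gc_target)
            start = occ.place(place_rng, length, pad=150)
            strand = "+" if place_rng.random() < 0.5 else "-"
            bg[start : start + length] = list(seq if strand == "+" else reverse_complement(seq))
            placements.setdefault(name, []).append((start, start + length, strand))

        # duplicate copies are named -D2/-D3 in coordinate order
        coding_names = {name for name, *_ in cfg.gene_complement}
        for name, spots in placements.items():
            cat = (
                self.proteins[name][0]
                if name in self.proteins
                else next(c for n, c, _ in cfg.noncoding if n == name)
            )
            for k, (s, e, strand) in enumerate(sorted(spots)):
                label = name if k == 0 else f"{name}-D{k + 1}"
                models.append(
                    GeneModel(
                        label,
                        CATEGORY_BY_VALUE[cat],
                        [Interval(s, e, strand)],
                        coding=name in coding_names,
                    )
                )
        models.sort(key=lambda m: (m.span_interval().start, m.name))

        # repeat families: copy planted content to a second (possibly
        # inverted) location, then enforce maximality at the copy edges
        rep_rng = _rng(cfg.seed, 3)
        self.repeats: list[tuple[int, int, int, str]] = []  # (c1, c2, len, orient)
        for length, orient, n in cfg.repeat_plan:
            for _ in range(n):
                c1 = occ.place(rep_rng, length, pad=40)
                c2 = occ.place(rep_rng, length, pad=40)
                if c2 < c1:
                    c1, c2 = c2, c1
                content = "".join(bg[c1 : c1 + length])
                bg[c2 : c2 + length] = list(
                    content if orient == "direct" else reverse_complement(content)
                )
                _break_extension(bg, c1, c2, length, orient)
                self.repeats.append((c1, c2, length, orient))

        # diverged full-length copy of the chimera 5' ORF: present in BOTH
        # genomes' shared backbone, so that ORF is not sterile-specific
        self.orf5_cds = None
        self.orf5_locus = None
        if cfg.chimera_plan is not None:
            orf_rng = _rng(cfg.seed, 4)
            self.orf5_cds = _clean_orf_cds(orf_rng, cfg.chimera_plan.orf5_aa)
            diverged = _diverge_every(self.orf5_cds, 13)
            start = occ.place(place_rng, len(diverged), pad=150)
            bg[start : start + len(diverged)] = list(diverged)
            self.orf5_locus = (start, start + len(diverged))

        self.genome = CircularGenome("mt_maintainer", "".join(bg))
        self.models = models
        self.occ = occ
        self.placements = placements


def _resize_protein(prot: str, aa: int) -> str:
    if len(prot) >= aa:
        return prot[:aa]
    reps = prot[1:] * (1 + (aa - len(prot)) // max(1, len(prot) - 1))
    return (prot + reps)[:aa]


def _clean_orf_cds(rng: np.random.Generator, aa_len: int) -> str:
    """CDS of a soluble protein whose cassette-flanked block contains exactly
    its own ORF and nothing else of >=100 codons (any frame, any strand)."""
    c = len(CASSETTE)
    for _ in range(200):
        prot = soluble_protein(rng, aa_len)
        cds = reverse_translate(prot, rng)
        probe = CircularGenome("probe", CASSETTE + cds + CASSETTE, Topology.LINEAR)
        found = {
            (o.interval.start, o.interval.end, o.interval.strand)
            for o in find_orfs(probe, min_aa=100)
        }
        if found == {(c, c + len(cds), "+")}:
            return cds
    raise RuntimeError("could not draw a clean ORF CDS")


def _diverge_gene_cds(cds: str, step: int = 12, phase: int = 0) -> str:
    """Silently diverge a CDS: one substitution about every ``step`` bp.

    Substitutions are synonymous wherever a degenerate site exists within a
    few bases of the target position (falling back to a conservative
    non-stop change), so the encoded protein is essentially unchanged while
    the longest exact nucleotide run stays below the alignment anchor
    length — the copy seeds no anchors against the original yet still
    annotates as the same gene.
    """
    out = list(cds)

    def try_sub(j: int, synonymous_only: bool) -> bool:
        if j < 3 or j >= len(cds) - 3:
            return False
        ci = (j // 3) * 3
        codon = "".join(out[ci : ci + 3])
        aa = _TABLE.forward_table.get(codon)
        if aa is None:
            return False
        for alt in "ACGT":
            if alt == out[j]:
                continue
            cand = codon[: j - ci] + alt + codon[j - ci + 1 :]
            if cand in STOPS:
                continue
            if synonymous_only and _TABLE.forward_table.get(cand) != aa:
                continue
            out[j] = alt
            return True
        return False

    for t in range(step + (phase % step), len(cds) - 3, step):
        done = False
        for off in (0, 1, -1, 2, -2, 3, -3):
            if try_sub(t + off, synonymous_only=True):
                done = True
                break
        if not done:
            try_sub(t, synonymous_only=False)
    return "".join(out)


def _diverge_every(seq: str, step: int) -> str:
    out = list(seq)
    order = {"A": "C", "C": "G", "G": "T", "T": "A"}
    for i in range(step - 1, len(out), step):
        out[i] = order[out[i]]
    return "".join(out)


def _break_extension(bg: list[str], c1: int, c2: int, length: int, orient: str) -> None:
    """Force mismatches just outside the planted copies so the maximal
    repeat length equals the planted length exactly."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}

    def differ(i: int, j: int, inverted_pairing: bool) -> None:
        if i < 0 or j < 0 or i >= len(bg) or j >= len(bg):
            return
        target = comp[bg[i]] if inverted_pairing else bg[i]
        if bg[j] == target:
            bg[j] = "ACGT"[("ACGT".index(bg[j]) + 1) % 4]
            if bg[j] == target:  # paranoid double-bump
                bg[j] = "ACGT"[("ACGT".index(bg[j]) + 1) % 4]

    if orient == "direct":
        differ(c1 - 1, c2 - 1, False)
        differ(c1 + length, c2 + length, False)
    else:
        # left edge of copy1 pairs with right edge of copy2 and vice versa
        differ(c1 - 1, c2 + length, True)
        differ(c1 + length, c2 - 1, True)


# --------------------------------------------------------------------------
# sterile derivation
# --------------------------------------------------------------------------

@dataclass
class _Block:
    kind: str          # "ref" | "novel"
    ref_start: int = 0
    ref_end: int = 0
    orient: str = "+"
    seq: str = ""
    label: str = ""
    moved: bool = False
    qry_start: int = -1
    qry_end: int = -1


class _SterileBuild:
    def __init__(self, config: SimConfig, mb: _MaintainerBuild, salt: int):
        self.cfg = config
        self.mb = mb
        self.salt = salt
        self.truth = TruthSet()

    # -- placement helpers --------------------------------------------------

    def _protected(self) -> list[tuple[int, int]]:
        """Intervals SV segments must not contain or cut (SNP hosts etc.)."""
        cfg = self.cfg
        hosts = set()
        for cls in cfg.snp_cds_plan.values():
            hosts.update(cls)
        hosts.update({"rrn26", "rrn18"})
        out = []
        for m in self.mb.models:
            if m.base_name in hosts:
                iv = m.span_interval()
                out.append((iv.start - 60, iv.end + 60))
        if self.mb.orf5_locus:
            s, e = self.mb.orf5_locus
            out.append((s - 60, e + 60))
        return out

    def _feature_spans(self) -> list[tuple[int, int]]:
        spans = [(m.span_interval().start, m.span_interval().end) for m in self.mb.models]
        spans += [(c1, c1 + l) for c1, c2, l, _ in self.mb.repeats]
        spans += [(c2, c2 + l) for c1, c2, l, _ in self.mb.repeats]
        if self.mb.orf5_locus:
            spans.append(self.mb.orf5_locus)
        return sorted(spans)

    def _cuttable(self, pos: int) -> bool:
        L = self.cfg.genome_length
        if pos < max(50, min(1000, L // 50)) or pos > L - max(50, min(1000, L // 50)):
            return False
        return all(not (s - 50 <= pos <= e + 50) for s, e in self._features)

    # -- main build ---------------------------------------------------------

    def build(self) -> bool:
        cfg = self.cfg
        L = cfg.genome_length
        self._features = self._feature_spans()
        protected = self._protected()
        sv_rng = _rng(cfg.seed, 5 + 101 * self.salt)
        novel_rng = _rng(cfg.seed, 6 + 101 * self.salt)

        chosen: list[tuple[int, int]] = []  # claimed ref intervals (pad applied)

        # events are kept >= 1 kb apart so the anchor run between any two
        # neighbouring events is long enough to stay in (or rejoin) the
        # collinear backbone instead of being skipped by the chain DP
        def clash(s: int, e: int) -> bool:
            return any(min(e, ce) - max(s, cs) > -1000 for cs, ce in chosen)

        def pick_segment(size: int) -> tuple[int, int]:
            for _ in range(4000):
                s = int(sv_rng.integers(0, L - size))
                e = s + size
                if not (self._cuttable(s) and self._cuttable(e)):
                    continue
                if clash(s, e):
                    continue
                # must not cut a feature (fully containing is fine) nor
                # contain a protected interval
                if any(s < fs < e < fe or fs < s < fe < e for fs, fe in self._features):
                    continue
                if any(s <= ps and pe <= e for ps, pe in protected):
                    continue
                chosen.append((s, e))
                return s, e
            raise RuntimeError("SV placement collision budget exhausted")

        gene_spans = [
            (m.span_interval().start, m.span_interval().end) for m in self.mb.models
        ]

        def pick_point(
            away_from: tuple[int, int] | None = None,
            min_dist: int = 0,
            gene_pad: int = 0,
            validate=None,
        ) -> int:
            for _ in range(4000):
                p = int(sv_rng.integers(0, L))
                if not (self._cuttable(p) and not clash(p, p)):
                    continue
                if away_from is not None:
                    s_, e_ = away_from
                    d = min((p - e_) % L, (s_ - p) % L)
                    if d < min_dist:
                        continue
                if gene_pad and any(
                    gs - gene_pad <= p <= ge + gene_pad for gs, ge in gene_spans
                ):
                    continue
                if validate is not None and not validate(p):
                    continue
                chosen.append((p, p))
                return p
            raise RuntimeError("SV placement collision budget exhausted")

        # registry of relocated/inverted segments per strand: a new
        # destination must differ from every existing member's geometry by
        # more than the chain DP could bridge, so two separate events can
        # never merge into one chain
        moved_registry: list[tuple[int, int, int, str]] = []  # (src, dest, size, strand)

        def dest_ok(p: int, src: int, size: int, strand: str) -> bool:
            for s2, d2, size2, st2 in moved_registry:
                if st2 != strand:
                    continue
                need = 2 * min(size, size2) + 6000
                dsrc = src - s2
                ddst = p - d2
                if min(abs(dsrc - ddst), abs(dsrc + ddst)) < need:
                    return False
            return True

        # 1. choose SV geometry
        seg_ops: list[tuple[str, int, int, dict]] = []
        point_ops: list[tuple[int, _Block]] = []
        for sv_type, size in cfg.sv_plan:
            if sv_type in {"translocation", "inversion", "trans_inver", "deletion", "complex"}:
                s, e = pick_segment(size)
                extra: dict = {}
                if sv_type in {"translocation", "trans_inver"}:
                    # keep destinations far from sources so a relocated
                    # segment can never be absorbed into the backbone chain
                    strand = "-" if sv_type == "trans_inver" else "+"
                    extra["dest"] = pick_point(
                        (s, e),
                        2 * size + 1000,
                        validate=lambda p, s=s, size=size, strand=strand: dest_ok(
                            p, s, size, strand
                        ),
                    )
                    moved_registry.append((s, extra["dest"], size, strand))
                if sv_type == "inversion":
                    moved_registry.append((s, s, size, "-"))
                if sv_type == "complex":
                    extra["novel"] = _novel_noncoding(
                        novel_rng, cfg.complex_qry_size, cfg.gc_target
                    )
                seg_ops.append((sv_type, s, e, extra))
            elif sv_type == "insertion":
                p = pick_point()
                seq = _novel_noncoding(novel_rng, size, cfg.gc_target)
                point_ops.append((p, _Block("novel", seq=seq, label="insertion")))
            else:
                raise ValueError(f"unknown SV type {sv_type}")

        # 2. planted ORF blocks
        self.planted_orfs: list[tuple[str, int, int, int]] = []  # (kind, offset_in_block, aa, block_idx)
        gene_aa = {name: aa for name, _, aa, _ in cfg.gene_complement}
        # ORF-bearing blocks stay well clear of annotated genes and of
        # chance background ORFs, so the only co-transcription partners and
        # unit members are the ones planted inside the block
        bg_orf_spans = [
            (o.interval.start, o.interval.end)
            for o in find_orfs(self.mb.genome, min_aa=100)
            if not o.interval.wraps
        ]

        def orf_clear(p: int, pad: int = 150) -> bool:
            return all(not (s_ - pad <= p <= e_ + pad) for s_, e_ in bg_orf_spans)

        if cfg.chimera_plan is not None:
            block, offsets = self._chimera_block(novel_rng)
            p = pick_point(gene_pad=300, validate=orf_clear)
            point_ops.append((p, _Block("novel", seq=block, label="chimera")))
            self._chimera_offsets = offsets
        if cfg.tm_orf_plan is not None:
            block = self._tm_block(novel_rng)
            p = pick_point(gene_pad=300, validate=orf_clear)
            point_ops.append((p, _Block("novel", seq=block, label="tm")))
        for k, aa in enumerate(cfg.extra_unique_orf_aa):
            block = self._plain_orf_block(novel_rng, aa)
            p = pick_point(gene_pad=300, validate=orf_clear)
            point_ops.append((p, _Block("novel", seq=block, label=f"extra{k}")))

        # 3. assemble block order
        blocks = self._assemble(seg_ops, point_ops)

        # 4. qry coordinates + SV truth (before indels/SNPs; shifted later)
        self._concatenate(blocks)
        self._record_sv_truth(seg_ops, point_ops, blocks)

        # 5. small indels and SNPs on unmoved backbone blocks
        edit_rng = _rng(cfg.seed, 7 + 101 * self.salt)
        self._plant_indels_and_snps(blocks, edit_rng)

        # 6. audit: ORF ids, uniqueness of planted ORFs only
        return self._audit()

    # -- novel blocks -------------------------------------------------------

    def _chimera_block(self, rng: np.random.Generator) -> tuple[str, dict]:
        cfg = self.cfg
        plan = cfg.chimera_plan
        gene_aa = {name: aa for name, _, aa, _ in cfg.gene_complement}[plan.gene]
        gene_model = next(m for m in self.mb.models if m.name == plan.gene)
        # the embedded gene copy is lightly diverged from the original so the
        # two copies share no exact run at or above the anchor length; the
        # copy still annotates as the same gene and stays non-unique
        gene_cds_raw = _oriented_seq(self.mb.genome, gene_model)
        orf5 = self.mb.orf5_cds
        for attempt in range(60):
            gene_cds = _diverge_gene_cds(gene_cds_raw, phase=attempt % 8)
            prot3 = soluble_protein(rng, plan.orf3_aa)
            cds3 = reverse_translate(prot3, rng)
            gap5 = _gap_seq(rng, plan.gap5, cfg.gc_target)
            gap3 = _gap_seq(rng, plan.gap3, cfg.gc_target)
            c = len(CASSETTE)
            block = CASSETTE + orf5 + gap5 + gene_cds + gap3 + cds3 + CASSETTE
            offsets = {
                "orf5": (c, c + len(orf5), plan.orf5_aa),
                "gene": (c + len(orf5) + len(gap5), c + len(orf5) + len(gap5) + len(gene_cds)),
                "orf3": (len(block) - c - len(cds3), len(block) - c, plan.orf3_aa),
            }
            expected = {
                (offsets["orf5"][0], offsets["orf5"][1], "+"),
                (offsets["gene"][0], offsets["gene"][1], "+"),
                (offsets["orf3"][0], offsets["orf3"][1], "+"),
            }
            if self._block_orfs_ok(block, expected):
                self.planted_orfs.append(("chimera_5", offsets["orf5"][0], plan.orf5_aa, -1))
                self.planted_orfs.append(("chimera_3", offsets["orf3"][0], plan.orf3_aa, -1))
                return block, offsets
        raise RuntimeError("could not build a clean chimera block")

    def _tm_block(self, rng: np.random.Generator) -> str:
        plan = self.cfg.tm_orf_plan
        c = len(CASSETTE)
        for _ in range(60):
            prot = tm_protein(rng, plan.aa, plan.n_domains)
            cds = reverse_translate(prot, rng)
            block = CASSETTE + cds + CASSETTE
            if self._block_orfs_ok(block, {(c, c + len(cds), "+")}):
                self.planted_orfs.append(("tm", c, plan.aa, -1))
                return block
        raise RuntimeError("could not build a clean TM-ORF block")

    def _plain_orf_block(self, rng: np.random.Generator, aa: int) -> str:
        c = len(CASSETTE)
        for _ in range(60):
            prot = soluble_protein(rng, aa)
            cds = reverse_translate(prot, rng)
            block = CASSETTE + cds + CASSETTE
            if self._block_orfs_ok(block, {(c, c + len(cds), "+")}):
                self.planted_orfs.append(("extra", c, aa, -1))
                return block
        raise RuntimeError("could not build a clean unique-ORF block")

    def _block_orfs_ok(self, block: str, expected: set[tuple[int, int, str]]) -> bool:
        """The isolated block must contain exactly the intended ORFs >=100 aa."""
        probe = CircularGenome("probe", block, Topology.LINEAR)
        found = {
            (o.interval.start, o.interval.end, o.interval.strand)
            for o in find_orfs(probe, min_aa=100)
        }
        return found == expected

    # -- assembly -----------------------------------------------------------

    def _assemble(self, seg_ops, point_ops) -> list[_Block]:
        L = self.cfg.genome_length
        cuts = {0, L}
        seg_by_start: dict[int, tuple[str, int, int, dict]] = {}
        for op in seg_ops:
            _, s, e, _ = op
            cuts.update((s, e))
            seg_by_start[s] = op
        events_at: dict[int, list[_Block]] = {}
        for p, blk in point_ops:
            cuts.add(p)
            events_at.setdefault(p, []).append(blk)
        for op in seg_ops:
            sv_type, s, e, extra = op
            if "dest" in extra:
                cuts.add(extra["dest"])
                moved = _Block(
                    "ref",
                    s,
                    e,
                    "-" if sv_type == "trans_inver" else "+",
                    label=sv_type,
                    moved=True,
                )
                events_at.setdefault(extra["dest"], []).append(moved)
            if sv_type == "complex":
                events_at.setdefault(s, []).append(
                    _Block("novel", seq=extra["novel"], label="complex")
                )

        bounds = sorted(cuts)
        out: list[_Block] = []
        for i in range(len(bounds) - 1):
            s, e = bounds[i], bounds[i + 1]
            for blk in events_at.get(s, []):
                out.append(blk)
            op = seg_by_start.get(s)
            if op is not None and op[2] == e:
                sv_type = op[0]
                if sv_type in {"deletion", "complex", "translocation", "trans_inver"}:
                    continue  # not emitted here
                if sv_type == "inversion":
                    out.append(_Block("ref", s, e, "-", label="inversion"))
                    continue
            out.append(_Block("ref", s, e, "+"))
        for blk in events_at.get(L, []):
            out.append(blk)
        return out

    def _concatenate(self, blocks: list[_Block]) -> None:
        parts = []
        cur = 0
        g = self.mb.genome.sequence
        for blk in blocks:
            if blk.kind == "ref":
                seq = g[blk.ref_start : blk.ref_end]
                if blk.orient == "-":
                    seq = reverse_complement(seq)
            else:
                seq = blk.seq
            blk.qry_start = cur
            blk.qry_end = cur + len(seq)
            parts.append(seq)
            cur = blk.qry_end
        self.pre_sequence = "".join(parts)
        self.blocks = blocks

    def _record_sv_truth(self, seg_ops, point_ops, blocks: list[_Block]) -> None:
        by_ref = {
            (b.ref_start, b.ref_end): b for b in blocks if b.kind == "ref"
        }
        next_ref_block = sorted(
            (b for b in blocks if b.kind == "ref" and not b.moved and b.orient == "+"),
            key=lambda b: b.ref_start,
        )
        self._sv_pre: list[SvTruth] = []
        for sv_type, s, e, extra in seg_ops:
            if sv_type in {"translocation", "trans_inver", "inversion"}:
                blk = by_ref[(s, e)]
                self._sv_pre.append(SvTruth(sv_type, s, e, blk.qry_start, blk.qry_end))
            elif sv_type == "deletion":
                nxt = next((b for b in next_ref_block if b.ref_start >= e), None)
                q = nxt.qry_start if nxt else len(self.pre_sequence)
                self._sv_pre.append(SvTruth("deletion", s, e, q, q))
            elif sv_type == "complex":
                blk = next(
                    b for b in blocks if b.kind == "novel" and b.label == "complex"
                    and b.seq == extra["novel"]
                )
                self._sv_pre.append(SvTruth("complex_indel", s, e, blk.qry_start, blk.qry_end))
        for blk in blocks:
            if blk.kind == "novel" and blk.label != "complex":
                # every novel block is, at the alignment level, an insertion
                nxt = next(
                    (b for b in self.blocks if b.kind == "ref" and b.qry_start >= blk.qry_end),
                    None,
                )
                r = nxt.ref_start if nxt is not None and nxt.orient == "+" and not nxt.moved else None
                if r is None:
                    prev = next(
                        (b for b in reversed(self.blocks)
                         if b.kind == "ref" and b.qry_end <= blk.qry_start and not b.moved and b.orient == "+"),
                        None,
                    )
                    r = prev.ref_end if prev is not None else 0
                self._sv_pre.append(SvTruth("insertion", r, r, blk.qry_start, blk.qry_end))

    # -- indels & SNPs ------------------------------------------------------

    def _backbone_blocks(self) -> list[_Block]:
        return [
            b for b in self.blocks if b.kind == "ref" and not b.moved and b.orient == "+"
        ]

    def _plant_indels_and_snps(self, blocks: list[_Block], rng: np.random.Generator) -> None:
        cfg = self.cfg
        g = self.mb.genome.sequence
        L = cfg.genome_length
        backbone = self._backbone_blocks()
        feature_pad = [(s - 30, e + 30) for s, e in self._features]
        edits: list[int] = []  # maintainer coords of all planned edits

        def far_enough(p: int, d: int = 40) -> bool:
            return all(abs(p - q) >= d for q in edits)

        def in_backbone(p: int, margin: int = 60) -> _Block | None:
            for b in backbone:
                if b.ref_start + margin <= p < b.ref_end - margin:
                    return b
            return None

        def intergenic(p: int, span: int = 1) -> bool:
            return all(not (s < p + span and p < e) for s, e in feature_pad)

        # --- small indels
        n_ins = round(cfg.n_small_indels * cfg.indel_insertion_fraction)
        plans = ["insertion"] * n_ins + ["deletion"] * (cfg.n_small_indels - n_ins)
        indels: list[IndelTruth] = []
        for typ in plans:
            length = int(rng.integers(1, 11))
            for _ in range(4000):
                p = int(rng.integers(0, L))
                b = in_backbone(p)
                if b is None or not intergenic(p, length) or not far_enough(p):
                    continue
                if typ == "deletion":
                    seq = g[p : p + length]
                    # reject ambiguous (shiftable) placements so the planted
                    # position is already left-normalized
                    if g[p - 1] == g[p + length - 1] or g[p + length] == g[p]:
                        continue
                    if len(set(seq)) == 1 and (g[p - 1] == seq[0] or g[p + length] == seq[0]):
                        continue
                else:
                    seq = random_seq(rng, length, cfg.gc_target)
                    if seq[-1] == g[p - 1] or seq[0] == g[p]:
                        continue
                edits.append(p)
                qpos = b.qry_start + (p - b.ref_start)
                indels.append(IndelTruth(p, qpos, typ, length, seq))
                break
            else:
                raise RuntimeError("indel placement collision budget exhausted")

        # --- SNPs: engineered CDS effects, ncRNA, then intergenic filler
        snps: list[SnpTruth] = []
        model_by_name = {m.name: m for m in self.mb.models}
        for effect, genes in cfg.snp_cds_plan.items():
            for gene, count in genes.items():
                m = model_by_name[gene]
                iv = m.span_interval()
                if in_backbone(iv.start, 0) is None:
                    raise RuntimeError(f"SNP host gene {gene} not on backbone")
                for _ in range(count):
                    snps.append(self._plant_cds_snp(m, effect, rng, edits))
        rrna = [model_by_name[n] for n in ("rrn26", "rrn18") if n in model_by_name]
        for k in range(cfg.n_ncrna_snps):
            m = rrna[k % len(rrna)]
            iv = m.span_interval()
            for _ in range(4000):
                p = int(rng.integers(iv.start + 20, iv.end - 20))
                if far_enough(p):
                    break
            else:
                raise RuntimeError("ncRNA SNP placement failed")
            edits.append(p)
            alt = _other_base(g[p], rng)
            snps.append(SnpTruth(p, -1, g[p], alt, "noncoding", m.name))
        n_cds = sum(sum(v.values()) for v in cfg.snp_cds_plan.values())
        n_intergenic = cfg.n_snps - n_cds - cfg.n_ncrna_snps
        if n_intergenic < 0:
            raise ValueError("n_snps smaller than planned CDS+ncRNA SNPs")
        for _ in range(n_intergenic):
            for _ in range(4000):
                p = int(rng.integers(0, L))
                if in_backbone(p) is not None and intergenic(p) and far_enough(p):
                    break
            else:
                raise RuntimeError("intergenic SNP placement failed")
            edits.append(p)
            alt = _other_base(g[p], rng)
            snps.append(SnpTruth(p, -1, g[p], alt, "intergenic", None))

        # fill qry positions (pre-indel coordinates) for all SNPs
        for s in snps:
            b = in_backbone(s.ref_pos, 0)
            s.qry_pos = b.qry_start + (s.ref_pos - b.ref_start)

        # --- apply indels right-to-left, then shift all qry coordinates
        seq = list(self.pre_sequence)
        indel_posdelta: list[tuple[int, int]] = []
        for ind in sorted(indels, key=lambda i: -i.qry_pos):
            if ind.type == "deletion":
                del seq[ind.qry_pos : ind.qry_pos + ind.length]
            else:
                seq[ind.qry_pos:ind.qry_pos] = list(ind.seq)
        for ind in indels:
            delta = ind.length if ind.type == "insertion" else -ind.length
            indel_posdelta.append((ind.qry_pos, delta))
        indel_posdelta.sort()

        def shift(q: int) -> int:
            return q + sum(d for p, d in indel_posdelta if p < q)

        for s in snps:
            s.qry_pos = shift(s.qry_pos)
            seq[s.qry_pos] = s.alt
        for ind in indels:
            ind.qry_pos = shift(ind.qry_pos)
        self.truth.snps = sorted(snps, key=lambda s: s.ref_pos)
        self.truth.indels = sorted(indels, key=lambda i: i.ref_pos)
        self.truth.sv_events = [
            SvTruth(t.type, t.ref_start, t.ref_end, shift(t.qry_start), shift(t.qry_end))
            for t in self._sv_pre
        ]
        for blk in self.blocks:
            blk.qry_start, blk.qry_end = shift(blk.qry_start), shift(blk.qry_end)
        self.genome = CircularGenome("mt_sterile", "".join(seq))

    def _plant_cds_snp(
        self, m: GeneModel, effect: str, rng: np.random.Generator, edits: list[int]
    ) -> SnpTruth:
        g = self.mb.genome.sequence
        iv = m.span_interval()
        cds = _oriented_seq(self.mb.genome, m)
        n_codons = len(cds) // 3 - 1  # excluding stop
        for _ in range(4000):
            ci = int(rng.integers(2, n_codons - 1))
            codon = cds[3 * ci : 3 * ci + 3]
            aa0 = _TABLE.forward_table.get(codon)
            if aa0 is None:
                continue
            choices = []
            if effect == "synonymous":
                b = 2
                for x in "ACGT":
                    if x != codon[2] and _TABLE.forward_table.get(codon[:2] + x) == aa0:
                        choices.append((b, x))
            else:
                for b in (0, 1):
                    for x in "ACGT":
                        cand = codon[:b] + x + codon[b + 1 :]
                        if x != codon[b] and cand not in _TABLE.stop_codons:
                            if _TABLE.forward_table[cand] != aa0:
                                choices.append((b, x))
            if not choices:
                continue
            b, x = choices[int(rng.integers(len(choices)))]
            off = 3 * ci + b
            if iv.strand == "+":
                pos = iv.start + off
                alt = x
            else:
                pos = iv.end - 1 - off
                alt = reverse_complement(x)
            if all(abs(pos - q) >= 40 for q in edits):
                edits.append(pos)
                return SnpTruth(pos, -1, g[pos], alt, effect, m.name)
        raise RuntimeError(f"could not plant {effect} SNP in {m.name}")

    # -- audit --------------------------------------------------------------

    def _audit(self) -> bool:
        """Locate planted ORFs, assign ids, and verify the unique set."""
        from .screen import find_unique_orfs

        cfg = self.cfg
        orfs = find_orfs(self.genome, min_aa=100)
        by_span = {
            (o.interval.start, o.interval.end - o.interval.start): o
            for o in orfs
            if not o.interval.wraps
        }

        planted: list[OrfTruth] = []
        chim_ids: dict[str, str] = {}
        for blk in self.blocks:
            if blk.kind != "novel":
                continue
            if blk.label == "chimera":
                offs = self._chimera_offsets
                for key, kind in (("orf5", "chimera_5"), ("orf3", "chimera_3")):
                    s, e, aa = offs[key]
                    o = by_span.get((blk.qry_start + s, e - s))
                    if o is None:
                        return False
                    planted.append(OrfTruth(o.id, aa, blk.qry_start + s, blk.qry_start + e, "+", kind))
                    chim_ids[kind] = o.id
            elif blk.label == "tm":
                c = len(CASSETTE)
                s_, e_ = blk.qry_start + c, blk.qry_end - c
                o = by_span.get((s_, e_ - s_))
                if o is None:
                    return False
                planted.append(
                    OrfTruth(o.id, cfg.tm_orf_plan.aa, s_, e_, "+",
                             "tm", cfg.tm_orf_plan.n_domains)
                )
            elif blk.label.startswith("extra"):
                c = len(CASSETTE)
                s_, e_ = blk.qry_start + c, blk.qry_end - c
                o = by_span.get((s_, e_ - s_))
                if o is None:
                    return False
                aa = (e_ - s_) // 3 - 1
                planted.append(OrfTruth(o.id, aa, s_, e_, "+", "extra"))

        self.truth.orfs = planted
        # unit isolation: no stray ORF within co-transcription distance of
        # the chimera block, or the planted unit geometry would change
        chim_blocks = [b for b in self.blocks if b.label == "chimera"]
        if chim_blocks:
            cb = chim_blocks[0]
            planted_spans = {(t.qry_start, t.qry_end) for t in planted}
            for o in orfs:
                if o.interval.wraps:
                    continue
                span = (o.interval.start, o.interval.end)
                if span in planted_spans:
                    continue
                if span[1] > cb.qry_start - 150 and span[0] < cb.qry_end + 150:
                    ok_inside = cb.qry_start <= span[0] and span[1] <= cb.qry_end
                    if not ok_inside:
                        return False
        expected_unique = {
            t.id for t in planted if t.kind in {"chimera_3", "tm", "extra"}
        }
        flags = find_unique_orfs(orfs, self.genome, self.mb.genome)
        found_unique = {o.id for o, uniq in flags if uniq}
        if found_unique != expected_unique:
            return False

        self.truth.unique_orf_ids = sorted(expected_unique)
        self.truth.candidate_orf_ids = sorted(
            t.id for t in planted if t.kind in {"chimera_3", "tm"}
        )
        if cfg.chimera_plan is not None:
            chim_blk = next(b for b in self.blocks if b.label == "chimera")
            gene_aa = {n: a for n, _, a, _ in cfg.gene_complement}[cfg.chimera_plan.gene]
            self.truth.co_transcript_unit = {
                "gene": cfg.chimera_plan.gene,
                "orf_ids": [chim_ids["chimera_5"], chim_ids["chimera_3"]],
                "unit_length": cfg.chimera_plan.unit_length(gene_aa),
                "qry_start": chim_blk.qry_start,
                "qry_end": chim_blk.qry_end,
            }
            self.truth.marker_locus = (chim_blk.qry_start, chim_blk.qry_end)
            self.truth.orf561_maintainer_locus = self.mb.orf5_locus
        return True


def _oriented_seq(genome: CircularGenome, m: GeneModel) -> str:
    from .genome_io import extract

    return "".join(extract(genome, iv) for iv in m.intervals)


def _gap_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    """Short intergenic spacer starting with in-frame-agnostic stop padding."""
    base = "CTAGCTAGCTAG"
    if n <= len(base):
        return base[:n]
    return base + random_seq(rng, n - len(base), gc)


def _novel_noncoding(rng: np.random.Generator, n: int, gc: float) -> str:
    """Cassette-flanked random sequence with no ORF of >=100 codons."""
    for _ in range(200):
        seq = CASSETTE + random_seq(rng, n, gc) + CASSETTE
        probe = CircularGenome("probe", seq, Topology.LINEAR)
        if not find_orfs(probe, min_aa=100):
            return seq
    raise RuntimeError("could not draw ORF-free novel sequence")


def _other_base(base: str, rng: np.random.Generator) -> str:
    options = [b for b in "ACGT" if b != base]
    return options[int(rng.integers(3))]


# --------------------------------------------------------------------------
# panel
# --------------------------------------------------------------------------

def generate_panel(
    sterile: CircularGenome,
    maintainer: CircularGenome,
    n_lines: int = 17,
    fraction_sterile: float = 4 / 17,
    seed: int = 1,
    n_line_snps: int = 25,
    exclude_sterile: tuple[int, int] | None = None,
    exclude_maintainer: tuple[int, int] | None = None,
) -> list[tuple[CircularGenome, str]]:
    """Inbred-line panel: each line is one cytoplasm plus private neutral SNPs.

    Returns (genome, label) with label in {"sterile", "fertile"}; sterile
    lines carry the sterile cytoplasm.  ``exclude_*`` intervals (e.g. the
    marker locus) are kept free of line SNPs so presence/absence genotyping
    stays a function of cytoplasm type only.
    """
    if n_lines < 2:
        raise ValueError("panel needs at least 2 lines")
    if not 0 < fraction_sterile < 1:
        raise ValueError("fraction_sterile must be in (0, 1)")
    rng = np.random.default_rng([seed & 0x7FFFFFFF, 9])
    n_sterile = max(1, round(n_lines * fraction_sterile))
    sterile_idx = set(rng.choice(n_lines, size=n_sterile, replace=False).tolist())
    panel = []
    for i in range(n_lines):
        is_sterile = i in sterile_idx
        base = sterile if is_sterile else maintainer
        excl = exclude_sterile if is_sterile else exclude_maintainer
        seq = list(base.sequence)
        placed = 0
        while placed < n_line_snps:
            p = int(rng.integers(0, len(seq)))
            if excl and excl[0] - 30 <= p < excl[1] + 30:
                continue
            seq[p] = _other_base(seq[p], rng)
            placed += 1
        panel.append(
            (
                CircularGenome(f"line{i + 1:02d}", "".join(seq)),
                "sterile" if is_sterile else "fertile",
            )
        )
    return panel
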
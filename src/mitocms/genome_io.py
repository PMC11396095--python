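"""Genome containers, circular-coordinate arithmetic, and FASTA/GFF3 I/O.

Plant mitochondrial genomes are conventionally assembled as single circular
"master circle" molecules, so the default topology here is circular and every
coordinate operation (extraction, flank retrieval, ORF scanning) must cope
with features that cross the origin.  Internally all coordinates are 0-based,
half-open, anchored on the forward strand; on-disk GFF3 uses the standard
1-based inclusive convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from gffutils.feature import feature_from_line

ALPHABET = set("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class Topology(str, Enum):
    CIRCULAR = "circular"
    LINEAR = "linear"


class GeneCategory(str, Enum):
    ATP_SYNTHASE = "ATP synthase"
    NADH_DEHYDROGENASE = "NADH dehydrogenase"
    CYTOCHROME = "cytochrome-related"
    RIBOSOMAL_PROTEIN = "ribosomal protein"
    SUCCINATE_DEHYDROGENASE = "succinate dehydrogenase"
    TRANSPORT_MATURATION = "transport/maturation"
    TRNA = "tRNA"
    RRNA = "rRNA"
    OTHER = "other"


@dataclass(frozen=True)
class Interval:
    """0-based half-open interval; ``wraps`` marks origin-crossing features.

    For a wrapping interval on a circular genome of length L the linear
    fields satisfy ``end < start`` and the span is ``L - start + end``.
    """

    start: int
    end: int
    strand: str = "+"
    wraps: bool = False

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if self.start < 0 or self.end < 0:
            raise ValueError("negative coordinate")
        if self.wraps:
            if self.end >= self.start:
                raise ValueError("wrapping interval requires end < start")
        elif self.end <= self.start:
            raise ValueError("empty interval")

    def span(self, genome_length: int | None = None) -> int:
        if self.wraps:
            if genome_length is None:
                raise ValueError("wrapping interval needs genome length")
            return genome_length - self.start + self.end
        return self.end - self.start

    def shifted(self, offset: int, genome_length: int) -> "Interval":
        """Rotate coordinates by ``offset`` on a circular genome."""
        span = self.span(genome_length)
        s = (self.start + offset) % genome_length
        e = s + span
        if e <= genome_length:
            return Interval(s, e, self.strand)
        return Interval(s, e % genome_length, self.strand, wraps=True)


@dataclass(frozen=True)
class CircularGenome:
    id: str
    sequence: str
    topology: Topology = Topology.CIRCULAR

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty sequence")
        bad = set(self.sequence) - ALPHABET
        if bad:
            positions = [i for i, c in enumerate(self.sequence) if c in bad][:10]
            raise ValueError(
                f"non-IUPAC characters {sorted(bad)} at positions {positions}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def is_circular(self) -> bool:
        return self.topology is Topology.CIRCULAR


@dataclass
class GeneModel:
    """A known mitochondrial gene; duplicate copies carry a ``-Dk`` suffix."""

    name: str
    category: GeneCategory
    intervals: list[Interval]
    coding: bool = True

    def __post_init__(self) -> None:
        if not self.intervals:
            raise ValueError("gene without exons")
        strands = {iv.strand for iv in self.intervals}
        if len(strands) > 1:
            raise ValueError(f"{self.name}: exons on mixed strands")

    @property
    def strand(self) -> str:
        return self.intervals[0].strand

    @property
    def base_name(self) -> str:
        name, _, suffix = self.name.rpartition("-")
        if suffix.startswith("D") and suffix[1:].isdigit():
            return name
        return self.name

    @property
    def copy_suffix(self) -> str:
        _, _, suffix = self.name.rpartition("-")
        if suffix.startswith("D") and suffix[1:].isdigit():
            return suffix
        return ""

    def span_interval(self) -> Interval:
        if len(self.intervals) == 1:
            return self.intervals[0]
        start = min(iv.start for iv in self.intervals)
        end = max(iv.end for iv in self.intervals)
        return Interval(start, end, self.strand)


def read_fasta(path: str | Path, topology: Topology = Topology.CIRCULAR) -> list[CircularGenome]:
    """Read a (multi-)FASTA into genomes, upcasing and validating the alphabet."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: empty or not FASTA")
    return [
        CircularGenome(rec.id, str(rec.seq).upper(), topology) for rec in records
    ]


def write_fasta(genomes: Iterable[CircularGenome], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for g in genomes:
            fh.write(f">{g.id}\n")
            for i in range(0, g.length, width):
                fh.write(g.sequence[i : i + width] + "\n")


def gc_content(genome: CircularGenome | str) -> float:
    """GC fraction with N excluded from the denominator."""
    seq = genome.sequence if isinstance(genome, CircularGenome) else genome
    gc = seq.count("G") + seq.count("C")
    denom = gc + seq.count("A") + seq.count("T")
    if denom == 0:
        raise ValueError("GC content undefined: no unambiguous bases")
    return gc / denom


def extract(genome: CircularGenome, interval: Interval) -> str:
    """Extract a sub-sequence; circular-aware and strand-aware.

    A wrapping interval concatenates the suffix from ``start`` with the
    prefix up to ``end``; minus-strand intervals return the reverse
    complement of the forward-strand slice.
    """
    if interval.wraps:
        if not genome.is_circular:
            raise ValueError("wrapping interval on a linear genome")
        seq = genome.sequence[interval.start :] + genome.sequence[: interval.end]
    else:
        if interval.end > genome.length:
            raise ValueError("interval beyond genome end")
        seq = genome.sequence[interval.start : interval.end]
    if interval.strand == "-":
        seq = reverse_complement(seq)
    return seq


def extract_circular(genome: CircularGenome, start: int, length: int) -> str:
    """Forward-strand slice of ``length`` bp starting at ``start`` mod L."""
    L = genome.length
    start %= L
    if start + length <= L:
        return genome.sequence[start : start + length]
    if not genome.is_circular:
        raise ValueError("slice beyond linear genome end")
    doubled = genome.sequence + genome.sequence
    return doubled[start : start + length]


# --- GFF3 -----------------------------------------------------------------


def write_gff3(models: Sequence[GeneModel], genome: CircularGenome, path: str | Path) -> None:
    """Write gene models as GFF3 (1-based inclusive on disk).

    Wrapping exons are written as two parts sharing one feature ID; ordering
    is deterministic (by start, then name).
    """
    lines = ["##gff-version 3", f"##sequence-region {genome.id} 1 {genome.length}"]
    ordered = sorted(models, key=lambda m: (m.span_interval().start, m.name))
    for m in ordered:
        attrs = f"ID={m.name};Name={m.name};gene_category={m.category.value.replace(' ', '_')};coding={int(m.coding)}"
        if m.copy_suffix:
            attrs += f";copy={m.copy_suffix}"
        for iv in m.intervals:
            if iv.wraps:
                parts = [(iv.start, genome.length), (0, iv.end)]
            else:
                parts = [(iv.start, iv.end)]
            for s, e in parts:
                lines.append(
                    "\t".join(
                        [
                            genome.id,
                            "mitocms",
                            "gene",
                            str(s + 1),
                            str(e),
                            ".",
                            iv.strand,
                            ".",
                            attrs + (";wraps=1" if iv.wraps else ""),
                        ]
                    )
                )
    Path(path).write_text("\n".join(lines) + "\n")


def read_gff3(path: str | Path, genome: CircularGenome) -> list[GeneModel]:
    """Read the GFF3 dialect written by :func:`write_gff3`."""
    by_id: dict[str, dict] = {}
    for raw in Path(path).read_text().splitlines():
        if not raw or raw.startswith("#"):
            continue
        feat = feature_from_line(raw)
        start0 = feat.start - 1
        end0 = feat.end
        if end0 > genome.length or start0 < 0:
            raise ValueError(f"{path}: coordinates outside genome: {raw}")
        if feat.strand not in "+-":
            raise ValueError(f"{path}: unknown strand {feat.strand!r}")
        fid = feat.attributes["ID"][0]
        entry = by_id.setdefault(
            fid,
            {
                "name": feat.attributes["Name"][0],
                "category": GeneCategory(
                    feat.attributes["gene_category"][0].replace("_", " ")
                ),
                "coding": feat.attributes.get("coding", ["1"])[0] == "1",
                "parts": [],
                "strand": feat.strand,
                "wraps": feat.attributes.get("wraps", ["0"])[0] == "1",
            },
        )
        entry["parts"].append((start0, end0))
    models = []
    for entry in by_id.values():
        parts = sorted(entry["parts"])
        if entry["wraps"]:
            # two linear parts: [s, L) and [0, e)
            (zs, ze), (ws, we) = parts
            assert zs == 0 and we == genome.length
            intervals = [Interval(ws, ze, entry["strand"], wraps=True)]
        else:
            intervals = [Interval(s, e, entry["strand"]) for s, e in parts]
        models.append(
            GeneModel(entry["name"], entry["category"], intervals, entry["coding"])
        )
    models.sort(key=lambda m: (m.span_interval().start, m.name))
    return models
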
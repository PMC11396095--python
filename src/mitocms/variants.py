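"""SNP and small-InDel calling from base alignments, with effect classes.

Every mismatch column of a chain becomes a SNP record with 100-bp flanks
from the reference (maintainer) genome; columns within a few bp of an
alignment gap are masked as a quality guard.  Gap-column runs up to
``max_len`` become InDel records, left-normalized so that any alignment of
the same two sequences yields identical records; longer runs are escalated
to SV classification.  Effects are classified by substituting the alternate
base into the host codon (strand-aware) and translating with the standard
code; insertion/deletion polarity is defined relative to the maintainer
reference.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .align_core import BaseAlignment, Escalation
from .annotate import translate
from .genome_io import (
    CircularGenome,
    GeneModel,
    extract,
    extract_circular,
    reverse_complement,
)


@dataclass
class SnpRecord:
    ref_pos: int
    qry_pos: int
    ref_base: str
    alt_base: str
    flank_left: str
    flank_right: str
    region: str  # CDS | ncRNA | intergenic
    gene: str | None
    effect: str  # synonymous | nonsynonymous | noncoding | intergenic
    codon_ref: str | None = None
    codon_alt: str | None = None
    aa_ref: str | None = None
    aa_alt: str | None = None


@dataclass
class IndelRecord:
    type: str  # insertion | deletion, relative to the maintainer reference
    ref_pos: int
    qry_pos: int
    length: int
    seq: str
    region: str  # genic | intergenic


def _gene_at(gene_models: list[GeneModel], pos: int) -> GeneModel | None:
    for m in gene_models:
        for iv in m.intervals:
            if iv.wraps:
                if pos >= iv.start or pos < iv.end:
                    return m
            elif iv.start <= pos < iv.end:
                return m
    return None


def classify_snp_effect(
    ref_genome: CircularGenome, gene: GeneModel, pos: int, alt: str
) -> tuple[str, str, str, str, str]:
    """(effect, codon_ref, codon_alt, aa_ref, aa_alt) for a CDS SNP."""
    cds = "".join(extract(ref_genome, iv) for iv in gene.intervals)
    if len(cds) % 3 != 0:
        return ("noncoding", None, None, None, None)
    iv = gene.intervals[0]
    if iv.strand == "+":
        off = pos - iv.start
        alt_c = alt
    else:
        off = (iv.end - 1) - pos
        alt_c = reverse_complement(alt)
    ci = off // 3
    codon = cds[3 * ci : 3 * ci + 3]
    b = off % 3
    codon_alt = codon[:b] + alt_c + codon[b + 1 :]
    aa_ref = translate(codon, allow_internal_stop=True) or "*"
    aa_alt = translate(codon_alt, allow_internal_stop=True) or "*"
    effect = "synonymous" if aa_ref == aa_alt else "nonsynonymous"
    return effect, codon, codon_alt, aa_ref, aa_alt


def call_snps(
    base_alignments: list[BaseAlignment],
    ref_genome: CircularGenome,
    qry_genome: CircularGenome,
    gene_models: list[GeneModel],
    flank: int = 100,
    gap_mask: int = 5,
) -> list[SnpRecord]:
    """One SnpRecord per mismatch column, gap-adjacent columns masked."""
    out: list[SnpRecord] = []
    L = ref_genome.length
    for ba in base_alignments:
        cols = ba.columns
        gap_idx = [k for k, c in enumerate(cols) if c[0] is None or c[1] is None]
        gap_set = set()
        for k in gap_idx:
            for d in range(-gap_mask, gap_mask + 1):
                gap_set.add(k + d)
        for k, (rp, qp, m) in enumerate(cols):
            if rp is None or qp is None or m:
                continue
            if k in gap_set:
                continue
            ref_base = ref_genome.sequence[rp]
            qb = qry_genome.sequence[qp]
            alt_base = reverse_complement(qb) if ba.chain.strand == "-" else qb
            if ref_base == alt_base:
                continue
            fl = extract_circular(ref_genome, rp - flank, flank)
            fr = extract_circular(ref_genome, rp + 1, flank)
            gene = _gene_at(gene_models, rp)
            if gene is None:
                region, effect = "intergenic", "intergenic"
                info = (None, None, None, None)
            elif not gene.coding:
                region, effect = "ncRNA", "noncoding"
                info = (None, None, None, None)
            else:
                region = "CDS"
                effect, *info = classify_snp_effect(ref_genome, gene, rp, alt_base)
            out.append(
                SnpRecord(
                    rp,
                    qp,
                    ref_base,
                    alt_base,
                    fl,
                    fr,
                    region,
                    gene.name if gene else None,
                    effect,
                    *info,
                )
            )
    out.sort(key=lambda s: s.ref_pos)
    return out


def _left_normalize_deletion(ref: str, pos: int, length: int) -> int:
    while pos > 0 and ref[pos - 1] == ref[pos + length - 1]:
        pos -= 1
    return pos


def _left_normalize_insertion(ref: str, pos: int, seq: str) -> tuple[int, str]:
    while pos > 0 and seq[-1] == ref[pos - 1]:
        seq = ref[pos - 1] + seq[:-1]
        pos -= 1
    return pos, seq


def call_small_indels(
    base_alignments: list[BaseAlignment],
    ref_genome: CircularGenome,
    qry_genome: CircularGenome,
    gene_models: list[GeneModel],
    max_len: int = 10,
) -> tuple[list[IndelRecord], list[Escalation]]:
    """Gap-column runs of length <= ``max_len`` as left-normalized InDels.

    Longer runs are returned as escalations for SV classification, never
    silently dropped.  Insertion positions name the reference base *before*
    which the query bases are inserted.
    """
    records: list[IndelRecord] = []
    escalations: list[Escalation] = []
    ref = ref_genome.sequence
    for ba in base_alignments:
        cols = ba.columns
        minus = ba.chain.strand == "-"
        k = 0
        n = len(cols)
        while k < n:
            rp, qp, _ = cols[k]
            if rp is not None and qp is not None:
                k += 1
                continue
            side = "del" if qp is None else "ins"
            j = k
            while j < n and (
                (cols[j][1] is None) if side == "del" else (cols[j][0] is None)
            ):
                j += 1
            run = cols[k:j]
            length = len(run)
            if length > max_len:
                r1 = next((c[0] for c in run if c[0] is not None), None)
                q1 = next((c[1] for c in run if c[1] is not None), None)
                if side == "del":
                    escalations.append(
                        Escalation(run[0][0], run[-1][0] + 1, _next_qry(cols, j, k), _next_qry(cols, j, k), "indel")
                    )
                else:
                    qs = [c[1] for c in run]
                    escalations.append(
                        Escalation(
                            _next_ref(cols, j, k), _next_ref(cols, j, k),
                            min(qs), max(qs) + 1, "indel",
                        )
                    )
                k = j
                continue
            if side == "del":
                pos = run[0][0]
                norm = _left_normalize_deletion(ref, pos, length)
                seq = ref[norm : norm + length]
                qpos = _next_qry(cols, j, k)
                rec = IndelRecord("deletion", norm, qpos, length, seq, "")
            else:
                qs = [c[1] for c in run]
                q_lo = min(qs)
                ins_fwd = qry_genome.sequence[q_lo : q_lo + length]
                ins = reverse_complement(ins_fwd) if minus else ins_fwd
                pos = _next_ref(cols, j, k)
                norm, ins = _left_normalize_insertion(ref, pos, ins)
                rec = IndelRecord("insertion", norm, q_lo, length, ins, "")
            span = rec.length if rec.type == "deletion" else 1
            gene = _gene_at(gene_models, rec.ref_pos)
            rec.region = "genic" if gene is not None else "intergenic"
            records.append(rec)
            k = j
    records.sort(key=lambda r: r.ref_pos)
    return records, escalations


def _next_ref(cols, j, k) -> int:
    for t in range(j, len(cols)):
        if cols[t][0] is not None:
            return cols[t][0]
    for t in range(k - 1, -1, -1):
        if cols[t][0] is not None:
            return cols[t][0] + 1
    return 0


def _next_qry(cols, j, k) -> int:
    for t in range(j, len(cols)):
        if cols[t][1] is not None:
            return cols[t][1]
    for t in range(k - 1, -1, -1):
        if cols[t][1] is not None:
            return cols[t][1] + 1
    return 0


def summarize_variants(snps: list[SnpRecord], indels: list[IndelRecord]) -> pd.DataFrame:
    """Deterministic tally by variant class / effect / region / gene."""
    rows = []
    for eff in ("synonymous", "nonsynonymous", "noncoding", "intergenic"):
        rows.append(("snp_effect", eff, sum(1 for s in snps if s.effect == eff)))
    for reg in ("CDS", "ncRNA", "intergenic"):
        rows.append(("snp_region", reg, sum(1 for s in snps if s.region == reg)))
    genes = sorted({s.gene for s in snps if s.gene})
    for g in genes:
        rows.append(("snp_gene", g, sum(1 for s in snps if s.gene == g)))
    for typ in ("insertion", "deletion"):
        rows.append(("indel_type", typ, sum(1 for i in indels if i.type == typ)))
    for reg in ("genic", "intergenic"):
        rows.append(("indel_region", reg, sum(1 for i in indels if i.region == reg)))
    rows.append(("total", "snps", len(snps)))
    rows.append(("total", "indels", len(indels)))
    return pd.DataFrame(rows, columns=["group", "key", "count"])


# --------------------------------------------------------------------------
# VCF 4.2 output (plain text; parse back with pysam/cyvcf2)
# --------------------------------------------------------------------------

def write_vcf(
    snps: list[SnpRecord],
    indels: list[IndelRecord],
    ref_genome: CircularGenome,
    path: str | Path,
) -> None:
    ref = ref_genome.sequence
    header = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={ref_genome.id},length={ref_genome.length}>",
        '##INFO=<ID=TYPE,Number=1,Type=String,Description="snp/insertion/deletion">',
        '##INFO=<ID=EFFECT,Number=1,Type=String,Description="effect class">',
        '##INFO=<ID=GENE,Number=1,Type=String,Description="host gene">',
        '##INFO=<ID=REGION,Number=1,Type=String,Description="region class">',
        '##INFO=<ID=QPOS,Number=1,Type=Integer,Description="0-based query position">',
        '##INFO=<ID=LEN,Number=1,Type=Integer,Description="indel length">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    body: list[tuple[int, str]] = []
    for s in snps:
        info = (
            f"TYPE=snp;EFFECT={s.effect};GENE={s.gene or '.'};"
            f"REGION={s.region};QPOS={s.qry_pos}"
        )
        body.append(
            (
                s.ref_pos,
                f"{ref_genome.id}\t{s.ref_pos + 1}\t.\t{s.ref_base}\t{s.alt_base}"
                f"\t.\tPASS\t{info}",
            )
        )
    for i in indels:
        anchor_pos = i.ref_pos - 1
        anchor = ref[anchor_pos] if anchor_pos >= 0 else ref[-1]
        if i.type == "deletion":
            ref_field = anchor + ref[i.ref_pos : i.ref_pos + i.length]
            alt_field = anchor
        else:
            ref_field = anchor
            alt_field = anchor + i.seq
        info = (
            f"TYPE={i.type};REGION={i.region};QPOS={i.qry_pos};LEN={i.length}"
        )
        body.append(
            (
                anchor_pos,
                f"{ref_genome.id}\t{anchor_pos + 1}\t.\t{ref_field}\t{alt_field}"
                f"\t.\tPASS\t{info}",
            )
        )
    body.sort(key=lambda r: (r[0], r[1]))
    Path(path).write_text("\n".join(header + [b for _, b in body]) + "\n")
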
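"""End-to-end orchestration: simulate -> annotate -> compare -> screen -> marker.

Every stage is a pure function of (inputs, config, seed); `run_full` writes
all stage outputs in standard formats plus a MANIFEST of content hashes, so
rerunning with the same config and seed reproduces the hashes byte for
byte.  No timestamps are embedded anywhere.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json

import numpy as np
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import jsonutil, refs
from .align_core import (
    BaseAlignment,
    align_chains,
    canonical_rotation,
    chain_anchors,
    find_anchors,
    rotate_genome,
)
from .annotate import (
    OrfRecord,
    annotate_known_genes,
    find_orfs,
    write_orf_protein_fasta,
)
from .config import PipelineConfig
from .genome_io import CircularGenome, GeneModel, gc_content, write_fasta, write_gff3
from .marker import MarkerDesignFailure, design_marker, validate_panel
from .repeats import bin_repeats, find_repeats, repeats_to_tsv
from .screen import CandidateOrf, find_unique_orfs, report, screen
from .simulate import SyntheticPair, TruthSet, build_pair, generate_panel
from .synteny_sv import (
    SvEvent,
    SyntenyBlock,
    blocks_to_tsv,
    call_sv_gaps,
    classify_blocks,
    coverage_stats,
    sv_to_tsv,
)
from .tm_chimera import detect_chimera, hydropathy_profile, predict_tm
from .variants import (
    call_small_indels,
    call_snps,
    summarize_variants,
    write_vcf,
)


@dataclass
class ComparisonResult:
    rotation_offset: int
    alignments: list[BaseAlignment]
    blocks: list[SyntenyBlock]
    sv_events: list[SvEvent]
    coverage: object
    snps: list
    indels: list


@dataclass
class PipelineResult:
    config: PipelineConfig
    pair: SyntheticPair | None
    maintainer: CircularGenome
    maintainer_models: list[GeneModel]
    sterile: CircularGenome
    sterile_genes: list[GeneModel]
    sterile_orfs: list[OrfRecord]
    comparison: ComparisonResult
    repeats: dict
    tm_domains: list
    chimeras: list
    candidates: list[CandidateOrf]
    marker_pairs: list | MarkerDesignFailure | None = None
    panel_accuracy: float | None = None
    panel_table: pd.DataFrame | None = None
    report_doc: dict | None = None


def detect_rotation(ref: CircularGenome, qry: CircularGenome, min_anchor: int) -> int:
    """Origin-shift offset, ignoring indel/SV-induced diagonal drift.

    Cumulative structural drift along a genome is bounded by the total SV
    size (a small fraction of the genome), whereas a genuine origin shift
    is typically arbitrary; offsets below a quarter genome length are
    treated as drift and left alone.
    """
    off = canonical_rotation(ref, qry, min_anchor)
    L = qry.length
    circ_dist = min(off, L - off)
    return off if circ_dist > L // 4 else 0


def compare_genomes(
    maintainer: CircularGenome,
    sterile: CircularGenome,
    maintainer_models: list[GeneModel],
    cfg: PipelineConfig,
) -> ComparisonResult:
    """Anchor, chain, base-align, then call variants, blocks and SVs."""
    al = cfg.align
    rot = detect_rotation(maintainer, sterile, al.min_anchor) if sterile.is_circular else 0
    qry = rotate_genome(sterile, rot) if rot else sterile
    anchors = find_anchors(maintainer, qry, al.min_anchor)
    chains = chain_anchors(anchors, al.max_gap, al.min_chain_bp, al.gap_diff_cost)
    alignments = align_chains(
        maintainer,
        qry,
        chains,
        band=al.band,
        sv_min=al.sv_min,
        complex_identity=al.complex_identity,
        match=al.match,
        mismatch=al.mismatch,
        gap_open=al.gap_open,
        gap_extend=al.gap_extend,
    )
    snps = call_snps(
        alignments, maintainer, qry, maintainer_models,
        flank=cfg.variants.flank, gap_mask=cfg.variants.gap_mask,
    )
    indels, indel_escalations = call_small_indels(
        alignments, maintainer, qry, maintainer_models, max_len=cfg.variants.max_indel_len
    )
    blocks = classify_blocks(alignments, maintainer.length, qry.length)
    sv_events = call_sv_gaps(
        alignments, indel_escalations, maintainer.length, qry.length,
        min_size=cfg.synteny.min_sv_size,
    )
    cov = coverage_stats(
        blocks, alignments, maintainer.length, qry.length,
        homology_min_identity=cfg.synteny.homology_min_identity,
    )
    return ComparisonResult(rot, alignments, blocks, sv_events, cov, snps, indels)


def run_full(cfg: PipelineConfig, outdir: str | Path | None = None) -> PipelineResult:
    """The full simulate-then-analyze pipeline at the configured scale."""
    pair = build_pair(cfg.simulate.to_sim_config(cfg.seed))
    res = analyze(
        pair.maintainer, pair.maintainer_models, pair.sterile, cfg, pair=pair
    )
    if outdir is not None:
        write_outputs(res, Path(outdir))
    return res


def analyze(
    maintainer: CircularGenome,
    maintainer_models: list[GeneModel],
    sterile: CircularGenome,
    cfg: PipelineConfig,
    pair: SyntheticPair | None = None,
) -> PipelineResult:
    an, tm = cfg.annotate, cfg.tm
    ref_prot = refs.reference_proteins()

    sterile_orfs = find_orfs(sterile, min_aa=an.min_aa)
    sterile_genes = annotate_known_genes(
        sterile, ref_prot, min_coverage=an.min_coverage, min_identity=an.min_identity
    )

    comparison = compare_genomes(maintainer, sterile, maintainer_models, cfg)

    rep = {}
    for g in (maintainer, sterile):
        pairs_g = find_repeats(g, min_len=cfg.repeats.min_len)
        rep[g.id] = {
            "pairs": pairs_g,
            "bins": bin_repeats(pairs_g, bin_width=cfg.repeats.bin_width, start=cfg.repeats.min_len),
        }

    tm_domains = []
    for o in sterile_orfs:
        if len(o.protein) < tm.window:
            continue
        tm_domains.extend(
            predict_tm(
                hydropathy_profile(o.protein, tm.window),
                o.id,
                threshold=tm.threshold,
                min_len=tm.min_len,
                max_len=tm.max_len,
                min_gap=tm.min_gap,
            )
        )
    chimeras = detect_chimera(sterile_orfs, sterile_genes, sterile, max_gap=tm.chimera_max_gap)

    unique_flags = find_unique_orfs(
        sterile_orfs, sterile, maintainer,
        min_identity=cfg.screen.min_identity, min_coverage=cfg.screen.min_coverage,
    )
    candidates = screen(
        unique_flags,
        comparison.coverage.qry_unique_intervals,
        comparison.blocks,
        tm_domains,
        chimeras,
        genome_length=sterile.length,
    )

    # marker design on the best candidate's largest unique interval
    marker_pairs = None
    panel_accuracy = None
    panel_table = None
    cand = [c for c in candidates if c.verdict == "candidate"]
    if cand:
        ivs = []
        for c in cand:
            o = c.orf
            for s, e in comparison.coverage.qry_unique_intervals:
                if min(e, o.interval.end) - max(s, o.interval.start) > 0:
                    ivs.append((e - s, s, e, c))
        if ivs:
            _, s, e, target_c = max(ivs, key=lambda t: (t[0], -t[1]))
            mk = cfg.marker
            marker_pairs = design_marker(
                (s, e),
                sterile,
                maintainer,
                target_len=mk.target_len,
                tolerance=mk.tolerance,
                primer_min=mk.primer_min,
                primer_max=mk.primer_max,
                gc_min=mk.gc_min,
                gc_max=mk.gc_max,
                tm_max_diff=mk.tm_max_diff,
                max_amplicon=mk.max_amplicon,
            )
            if not isinstance(marker_pairs, MarkerDesignFailure) and pair is not None:
                truth = pair.truth
                panel = generate_panel(
                    sterile,
                    maintainer,
                    n_lines=mk.panel_lines,
                    fraction_sterile=mk.panel_fraction_sterile,
                    seed=cfg.seed,
                    exclude_sterile=tuple(truth.marker_locus) if truth.marker_locus else None,
                    exclude_maintainer=tuple(truth.orf561_maintainer_locus)
                    if truth.orf561_maintainer_locus
                    else None,
                )
                panel_accuracy, panel_table = validate_panel(
                    marker_pairs[0], panel, mk.max_mismatch, mk.max_amplicon
                )

    stats = {
        "genomes": {
            maintainer.id: {"length": maintainer.length, "gc_pct": round(100 * gc_content(maintainer), 2)},
            sterile.id: {"length": sterile.length, "gc_pct": round(100 * gc_content(sterile), 2)},
        },
        "annotation": {
            "n_known_genes_sterile": len(sterile_genes),
            "n_orfs_sterile": len(sterile_orfs),
        },
        "variants": {
            "n_snps": len(comparison.snps),
            "n_indels": len(comparison.indels),
        },
        "synteny": {
            "n_blocks": len(comparison.blocks),
            "by_class": _count_by(b.klass for b in comparison.blocks),
            "sv_events": _count_by(e.klass for e in comparison.sv_events),
            "pct_homologous_ref": round(comparison.coverage.pct_homologous_ref, 2),
            "pct_homologous_qry": round(comparison.coverage.pct_homologous_qry, 2),
            "rotation_offset": comparison.rotation_offset,
        },
        "repeats": {
            gid: {
                "n_pairs": len(r["pairs"]),
                "max_length": r["bins"].attrs["max_length"],
            }
            for gid, r in rep.items()
        },
        "screen": {
            "n_unique_orfs": sum(1 for c in candidates if c.unique_in_sterile),
        },
    }
    doc = report(candidates, stats)

    return PipelineResult(
        cfg,
        pair,
        maintainer,
        maintainer_models,
        sterile,
        sterile_genes,
        sterile_orfs,
        comparison,
        rep,
        tm_domains,
        chimeras,
        candidates,
        marker_pairs,
        panel_accuracy,
        panel_table,
        doc,
    )


def _count_by(items) -> dict:
    out: dict[str, int] = {}
    for x in items:
        out[x] = out.get(x, 0) + 1
    return dict(sorted(out.items()))


# --------------------------------------------------------------------------
# output writing + manifest
# --------------------------------------------------------------------------

def write_outputs(res: PipelineResult, outdir: Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta([res.maintainer], outdir / "maintainer.fasta")
    write_fasta([res.sterile], outdir / "sterile.fasta")
    write_gff3(res.maintainer_models, res.maintainer, outdir / "maintainer.gff3")
    write_gff3(res.sterile_genes, res.sterile, outdir / "sterile_genes.gff3")
    _orfs_to_tsv(res.sterile_orfs, outdir / "sterile_orfs.tsv")
    tm_counts: dict[str, int] = {}
    for d in res.tm_domains:
        tm_counts[d.orf_id] = tm_counts.get(d.orf_id, 0) + 1
    write_orf_protein_fasta(res.sterile_orfs, outdir / "sterile_orf_proteins.faa", tm_counts)
    if res.pair is not None:
        res.pair.truth.to_json(outdir / "truth.json")

    for gid, r in res.repeats.items():
        repeats_to_tsv(r["pairs"], outdir / f"repeats_{gid}.tsv")
        bins = r["bins"]
        summary = {
            "genome": gid,
            "n_pairs": bins.attrs["n_pairs"],
            "n_occurrences": bins.attrs["n_occurrences"],
            "max_length": bins.attrs["max_length"],
            "bins": bins.to_dict(orient="records"),
        }
        (outdir / f"repeats_{gid}.json").write_text(jsonutil.dumps(summary, indent=1))

    _anchors_to_tsv(res.comparison.alignments, outdir / "chains.tsv")
    write_vcf(res.comparison.snps, res.comparison.indels, res.maintainer, outdir / "variants.vcf")
    summarize_variants(res.comparison.snps, res.comparison.indels).to_csv(
        outdir / "variant_summary.tsv", sep="\t", index=False
    )
    blocks_to_tsv(res.comparison.blocks, outdir / "blocks.tsv")
    sv_to_tsv(res.comparison.sv_events, outdir / "sv_events.tsv")
    cov = res.comparison.coverage
    (outdir / "coverage.json").write_text(
        jsonutil.dumps(
            {
                "n_blocks": cov.n_blocks,
                "n_homologous_blocks": cov.n_homologous_blocks,
                "pct_homologous_ref": round(cov.pct_homologous_ref, 4),
                "pct_homologous_qry": round(cov.pct_homologous_qry, 4),
                "qry_unique_intervals": cov.qry_unique_intervals,
            },
            indent=1,
        )
    )
    _tm_to_tsv(res.tm_domains, outdir / "tm_domains.tsv")
    (outdir / "chimeras.json").write_text(
        jsonutil.dumps([dataclasses.asdict(c) for c in res.chimeras], indent=1)
    )
    _candidates_to_tsv(res.candidates, outdir / "candidates.tsv")
    report(res.candidates, {k: v for k, v in res.report_doc.items() if k not in ("candidates", "n_candidates", "schema_version")},
           outdir / "report.json", outdir / "report.md")
    if res.marker_pairs is not None and not isinstance(res.marker_pairs, MarkerDesignFailure):
        _primers_to_tsv(res.marker_pairs, outdir / "marker_primers.tsv")
    if res.panel_table is not None:
        res.panel_table.to_csv(outdir / "panel_results.tsv", sep="\t", index=False)
    res.config.to_yaml(outdir / "config.yaml")

    manifest = {}
    for p in sorted(outdir.iterdir()):
        if p.name == "MANIFEST.json" or p.is_dir():
            continue
        manifest[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
    (outdir / "MANIFEST.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))


def _orfs_to_tsv(orfs, path):
    rows = [
        {
            "id": o.id,
            "start": o.interval.start,
            "end": o.interval.end,
            "strand": o.interval.strand,
            "wraps": int(o.interval.wraps),
            "aa_length": o.aa_length,
        }
        for o in orfs
    ]
    pd.DataFrame(rows, columns=["id", "start", "end", "strand", "wraps", "aa_length"]).to_csv(
        path, sep="\t", index=False
    )


def _anchors_to_tsv(alignments, path):
    rows = []
    for ci, ba in enumerate(alignments):
        for a in ba.chain.anchors:
            rows.append(
                {
                    "chain": ci,
                    "strand": ba.chain.strand,
                    "ref_start": a.ref_start,
                    "qry_start": a.qry_start,
                    "length": a.length,
                }
            )
    pd.DataFrame(rows, columns=["chain", "strand", "ref_start", "qry_start", "length"]).to_csv(
        path, sep="\t", index=False
    )


def _tm_to_tsv(domains, path):
    rows = [
        {
            "orf_id": d.orf_id,
            "aa_start": d.aa_start,
            "aa_end": d.aa_end,
            "mean_hydropathy": round(d.mean_hydropathy, 3),
        }
        for d in domains
    ]
    pd.DataFrame(rows, columns=["orf_id", "aa_start", "aa_end", "mean_hydropathy"]).to_csv(
        path, sep="\t", index=False
    )


def _candidates_to_tsv(candidates, path):
    rows = [
        {
            "orf_id": c.orf.id,
            "aa_length": c.orf.aa_length,
            "verdict": c.verdict,
            "unique": int(c.unique_in_sterile),
            "in_region": int(c.in_sv_or_unique_region),
            "tm_domains": c.tm_count,
            "chimera_partner": c.chimera.partner_gene if c.chimera else ".",
            "evidence": " | ".join(c.evidence),
        }
        for c in candidates
    ]
    pd.DataFrame(
        rows,
        columns=[
            "orf_id", "aa_length", "verdict", "unique", "in_region",
            "tm_domains", "chimera_partner", "evidence",
        ],
    ).to_csv(path, sep="\t", index=False)


def _primers_to_tsv(pairs, path):
    rows = [
        {
            "fwd": p.fwd,
            "rev": p.rev,
            "fwd_start": p.fwd_start,
            "rev_start": p.rev_start,
            "tm_fwd": p.tm_fwd,
            "tm_rev": p.tm_rev,
            "gc_fwd": round(p.gc_fwd, 3),
            "gc_rev": round(p.gc_rev, 3),
            "amplicon": p.target_amplicon,
        }
        for p in pairs
    ]
    pd.DataFrame(
        rows,
        columns=["fwd", "rev", "fwd_start", "rev_start", "tm_fwd", "tm_rev", "gc_fwd", "gc_rev", "amplicon"],
    ).to_csv(path, sep="\t", index=False)

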
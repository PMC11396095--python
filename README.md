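# mitocms

Comparative mitochondrial-genomics screening of cytoplasmic-male-sterility
(CMS) candidate ORFs.

## The problem

CMS is a maternally inherited pollen-abortion trait used to make hybrid
seed: a sterile line is kept isonuclear with its fertile *maintainer*
line, so any heritable difference between them lives in the cytoplasm —
in practice, the mitochondrial genome. Plant mitogenomes recombine across
repeat families, and rearrangement creates novel open reading frames; the
CMS-causing loci characterised to date are almost always such ORFs,
either chimeric/co-transcribed with a standard mitochondrial gene or
encoding a membrane-anchored peptide.

`mitocms` implements the full comparative workflow that screens for such
candidates in a sterile/maintainer mitogenome pair:

1. **annotate** — six-frame, circular-aware ORF prediction (ATG→stop,
   ≥100 codons, maximal per stop) and known-gene annotation by translated
   homology (coverage ≥ 40% of the reference protein above an identity
   floor, duplicate placements named `-D2`, `-D3`);
2. **repeats** — maximal exact repeat pairs ≥30 bp, direct and inverted,
   with the standard 5-bp length-bin summary;
3. **align** — MUM anchors (maximal exact matches unique in both genomes),
   weighted collinear chaining, and affine-gap base alignment of
   inter-anchor gaps (match +1, mismatch −1, gap open −4, extend −1);
4. **variants** — SNPs with synonymous / non-synonymous / non-coding
   classification (strand-aware codon substitution under the standard
   code), 100-bp reference flanks, and left-normalised 1–10 bp InDels;
   VCF 4.2 output;
5. **synteny/SV** — region classification into collinear, translocation,
   inversion, translocation+inversion, insertion ≥50 bp, deletion ≥50 bp
   and complex InDel, plus homologous-block coverage statistics;
6. **screen** — the candidate cascade: an ORF is a CMS candidate iff it is
   sterile-specific (no maintainer alignment at ≥0.9 edit similarity),
   lies in a rearranged or sterile-unique region, and carries ≥1 predicted
   transmembrane domain (windowed Kyte–Doolittle hydropathy) and/or forms
   a chimera / co-transcription unit with a known gene;
7. **marker** — presence/absence PCR marker design against the candidate's
   sterile-specific sequence (Wallace-rule Tm, GC 40–60%, 3′ G/C clamp)
   validated by exhaustive in-silico PCR across an inbred-line panel.

Real sterile/maintainer assemblies for such studies are frequently not
deposited, so the package ships a first-class synthetic-data module: it
generates a maintainer-like circular genome (standard plant-mito gene
complement with duplicated copies, rRNAs/tRNAs, repeat families) and
derives a sterile-like genome with fully recorded edits — structural
variants, a planted chimeric `orf561a–rpl16–orf312a` co-transcription
unit of exactly 2,996 bp, a three-transmembrane-domain `orf172a`, SNPs
with engineered effects, and small InDels. Every downstream stage is
scored against this planted truth.

## Worked example

```bash
mitocms run-all --seed 1 --out out/
```

runs simulate → annotate → compare → screen → marker on the default
100-kb pair and writes FASTA/GFF3/VCF/TSV/JSON outputs plus a `MANIFEST`
of content hashes. The candidate table (`out/candidates.tsv`, also in
`out/report.json`) ends with exactly two candidates:

```
orf_id    aa_length  verdict    unique  in_region  tm_domains  chimera_partner
orf312a   312        candidate  1       1          0           rpl16-D2
orf172a   172        candidate  1       1          3           .
```

`orf312a` is sterile-specific and sits 18 bp downstream of a `rpl16` copy
(annotated `rpl16-D2`, the second placement in coordinate order)
inside a co-transcription unit whose span (`unit_length` in
`out/chimeras.json`) is 2996 bp; `orf172a` is sterile-specific with 3
predicted transmembrane domains. Both carry a "requires expression
validation" caveat — the expression criterion is wet-lab territory. The
marker module then designs primer pairs inside the chimera insertion;
the top pair amplifies a single 3000-bp product on the sterile genome,
nothing on the maintainer, and classifies all 17 lines of the simulated
panel (4 sterile-cytoplasm) correctly (`out/panel_results.tsv`).

The same pipeline is callable as a library:

```python
from mitocms.config import PipelineConfig
from mitocms.pipeline import run_full

res = run_full(PipelineConfig(seed=1), "out/")
print(res.panel_accuracy)            # 1.0
print(res.comparison.coverage)       # homologous-block stats
```

and on real data via `mitocms compare --maintainer B.fasta --sterile
A.fasta --maintainer-gff B.gff3 --out out/`.

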
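# Methods

This note records the models, conventions and numerical choices behind
`mitocms`, in the spirit of a methods supplement: what each stage assumes,
which knobs matter, and what the synthetic study system does and does not
emulate.

## Coordinates and topology

Plant mitogenomes are treated as single circular molecules ("master
circles"); a `--linear` flag / `Topology.LINEAR` overrides. Internally all
coordinates are 0-based half-open on the forward strand; on-disk GFF3 and
VCF use the 1-based conventions of those formats. Origin-crossing features
carry a `wraps` flag (`end < start`), and circular scans (ORFs, repeats,
primer sites, flanks) operate on doubled sequence with modular
deduplication. GC content excludes `N` from the denominator.

## ORF prediction and gene annotation

ORFs are ATG-initiated, stop-terminated, maximal per stop codon (the first
in-frame ATG after the previous stop), ≥100 codons by default — the
"minsize 300 nt" convention with the stop codon counted in the 300 nt.
Alternative start codons and RNA editing are deliberately not modelled.
IDs follow the field's `orf{aa}{a,b,…}` style in coordinate order.

Known genes are annotated by translated homology: reference proteins are
seeded against six-frame translations by exact 6-mer peptide matches,
candidate diagonals are locally aligned (BLOSUM62, gap open −11 / extend
−1), and hits are kept at reference-protein coverage ≥ 0.40 above a 50%
identity floor. Database-size-dependent E-values are not reproducible
offline, so the identity floor replaces them; the 40% coverage rule is the
conventional one. Disjoint placements of one gene are named `-D2`, `-D3`
in coordinate order. The shipped reference proteins are synthetic
stand-ins of realistic lengths under standard plant-mito gene names
(`src/mitocms/data/synthetic_mito_proteins.faa`); they make the annotation
path hermetically testable but carry no real sequence information.

## Repeats

Repeats are counted as *pairs of occurrences* of maximal exact matches
≥30 bp (REPuter-style reporting), both orientations, identical intervals
excluded, tandem overlap allowed and flagged; a 5-bp length-bin histogram
(30–34, 35–39, …) and the maximum length summarise each genome. Candidate
pairs are seeded by shared k-mers at the minimum length and extended to
maximality; the test suite carries an O(n²) brute-force comparer as the
independent oracle.

## Whole-genome alignment

Anchors are MUMs: maximal exact matches, unique in both genomes on both
strands, ≥20 bp. Uniqueness is deliberate — repeats at or above the anchor
length produce anchor deserts exactly where rearrangement breakpoints are
expected. Chains are extracted greedily by repeated best-chain dynamic
programming per strand; the score is anchored bp minus overlap minus
0.5·|Δref−Δqry| per junction. The gap-disagreement penalty is the one
genuinely free constant: it is set high enough that a relocated segment
scores better as its own chain than absorbed into the backbone with two
large asymmetric gaps, and low enough that ordinary InDel gaps never
split a chain. Skipped forward chains that are order-consistent with the
collinear backbone on both axes are re-absorbed as collinear.

Inter-anchor gaps are closed by affine-gap global alignment (match +1,
mismatch −1, gap open −4, extend −1; configurable). Gap pairs that cannot
be meaningfully base-aligned are escalated as structured events rather
than silently truncated: one-sided gaps > 50 bp (InDel-scale), anything
wider than the 2000-bp band, and two-sided gaps whose alignment identity
falls below 0.70 (complex-region candidates; unrelated DNA aligns near
~0.55, genuine homology in this pipeline near 0.99, so the threshold sits
in a wide gap between the two regimes).

Circular origin shift is estimated as the anchor-length-weighted modal
diagonal offset of forward anchors; offsets under a quarter genome length
are treated as cumulative InDel/SV drift (which is bounded by total SV
size) rather than rotation.

## Variants

Reference = maintainer, query = sterile; insertion/deletion polarity is
relative to the maintainer. Every mismatch column becomes a SNP with
100-bp reference flanks; columns within 5 bp of an alignment gap are
masked (the classical quality guard; configurable). Effects are computed
by substituting the alternate base into the host codon, strand-aware,
under the standard genetic code — and the test suite re-derives every
effect by translating the entire mutated CDS. InDel runs ≤10 bp are
left-normalised (shifted to the leftmost equivalent placement) so that
any alignment of the same two sequences yields identical records; longer
runs are escalated to SV classification. Two haploid genomes cannot
produce multi-allelic sites.

## SV taxonomy

The collinear backbone is the maximum-anchored-bp, order-preserving set of
forward chains (weighted LIS). Remaining forward chains are
translocations. A reverse chain whose query span sits between the query
positions the backbone assigns to its reference flanks is an inversion;
one that has also moved is a translocation+inversion — the taxonomy's
"Tran+Inver" class is operationalised as strand-negative AND
order-breaking, since no formal definition is standard. Escalated gap
pairs become deletion (ref-only ≥50 bp), insertion (qry-only ≥50 bp) or
complex InDel (one ref segment facing one qry segment, each filling
essentially the whole gap pair); rearranged material aligned by another
chain is subtracted first so translocation sources are never double-called
as deletions, overlapping escalations are resolved smallest-first with
each unaligned hole feeding exactly one event, and sub-50-bp remnants are
reported as residue, never dropped. A conservation test asserts that
aligned coverage plus event holes tile the query genome exactly.

## Transmembrane prediction and chimera detection

Transmembrane segments are called from a centred 19-residue
Kyte–Doolittle window: maximal runs ≥1.6 mean hydropathy, runs closer
than 5 residues merged, then length bounds 15–35 enforced (long runs
split near-evenly). This is a transparent hydropathy surrogate for HMM
topology predictors — adequate for strongly hydrophobic synthetic
domains, and all thresholds are configuration.

Chimera/co-transcription detection is positional: same-strand ORF/gene
features that overlap or lie within 100 bp are linked; maximal linked runs
form units whose length is the genomic span from first member start to
last member end (circularly). Overlap and adjacency are recorded as
distinct relations, expressed relative to the partner gene (an ORF just 5′
of the gene is `adjacent_upstream`). The 100-bp gap default reproduces the
planted unit geometry and is configuration, since co-transcription
distance has no canonical cutoff.

## The candidate screen

`candidate ⇔ sterile-specific ∧ in a non-collinear or sterile-unique
region ∧ (≥1 TM domain ∨ chimera with a known gene)`. Sterile-specificity
is decided by the best infix (edlib) alignment of the ORF nucleotide
sequence against the maintainer, both strands, circularly: identity
= 1 − dist/|orf| folds the identity (0.9) and coverage (0.9) thresholds
into a single edit-similarity floor, since uncovered overhang is absorbed
into the edit distance. Every verdict carries exhaustive evidence strings,
and every candidate carries a "requires expression validation" caveat —
the expression criterion (RT-PCR/qPCR) is outside computational scope and
is represented in the synthetic system only by the planted-truth labels.

## Marker design

Primer pairs (18–25 nt, GC 40–60%, 3′ G/C clamp, Wallace-rule Tm
2(A+T)+4(G+C) with ≤5 °C spread) are enumerated inside the candidate's
sterile-unique interval, targeting a 3,000 bp ±20% amplicon. Wallace Tm
is a deliberate deterministic simplification of nearest-neighbour
thermodynamics. Every returned pair is verified by exhaustive in-silico
PCR — exact annealing by default with a hard 3′-terminal 3-nt match, all
convergent sites within 6 kb, circular template honoured — to yield
exactly one product on the sterile genome and none on the maintainer.
Panel validation calls `present ⇒ sterile cytoplasm` and reports accuracy
with a per-line table. Oligo secondary structure and multiplexing are out
of scope.

## The synthetic study system

The generator emulates the structure such comparative studies report, not
any particular organism's sequence. Defaults (the study conditions):

- 100-kb test pair (500-kb full scale), background GC targeted so the
  genome lands at ≈44.6%; synonymous codon choice is AT-biased (weight
  1.6 per A/T in the codon), mirroring organelle codon usage.
- gene complement: 25 coding genes of realistic lengths plus duplicated
  copies (atp8/atp9/cox3/mttB/nad1/nad2/nad7/sdh4 ×2, rps19 ×3), 3 rRNAs
  and 12 tRNAs carried as annotation; `rpl16` is set to 110 aa so the
  planted co-transcription unit closes at exactly
  1686 + 20 + 333 + 18 + 939 = 2996 bp.
- 58 SNPs at 100 kb (288 at 500 kb): 5 synonymous (cox2, cob, rpl2,
  nad4L), 19 non-synonymous (sdh3, ccmFc, rpl10, rpl16, atp6, rps1),
  4 in rRNA, the rest intergenic — the per-class CDS composition of a
  real sterile/maintainer comparison, scaled by genome length.
- 18 small InDels (86 full scale), 1–10 bp, intergenic, at sites chosen
  to be already left-normalised.
- SV plan: 2 translocations, 1 inversion, 1 translocation+inversion,
  1 plain insertion, 2 deletions, 1 complex region (15/5/9/2/4/3 at full
  scale), plus the chimera unit, the TM-ORF and three extra unique ORFs
  as insertions.
- panel: 17 lines, 4 with sterile cytoplasm, 25 private neutral SNPs per
  line outside the marker locus.

Mechanisms that make the truth exact rather than approximate:

- every novel block is flanked by a 12-bp spacer (`CTAGCTAGCTAG`: stop
  codons in all six frames, no ATG, its own reverse complement), so no
  reading frame crosses a block edge and no upstream ATG extends a
  planted ORF;
- the chimera's embedded `rpl16` copy and the maintainer's back-copy of
  the 5′ chimera ORF (which keeps `orf561a` non-sterile-specific, as in
  the motivating biology) are diverged by one substitution per ~12 bp,
  synonymous where possible and never creating stops — below the
  anchor length in exact-run terms, above the 0.9 uniqueness floor in
  identity, still annotatable by homology;
- edits keep ≥1 kb mutual spacing, translocation destinations sit far
  from their sources, and relocated segments obey a pairwise geometry
  separation so no two events can merge into one chain;
- after assembly the generator audits itself: it re-scans the sterile
  genome and re-draws the attempt (new placement salt) if any chance ORF
  would make the sterile-unique ORF set differ from the planted one or
  crowd the co-transcription unit.

Randomness is partitioned into named substreams of one seed (background,
placement, codons, repeats, ORFs, SVs, edits, panel), so changing one
plan does not reshuffle unrelated draws, and identical config + seed is
byte-identical across runs.

What passing tests on this system do *not* show: recovery under
sequencing error or assembly artefacts (inputs are exact assemblies),
heteroplasmy/substoichiometric molecules, real homology relationships
(reference proteins are synthetic), nucleotide-level realism of repeats
or intergenic DNA, or the behaviour of the TM surrogate on marginal
real-world topologies. The screen's expression criterion is not computed
at all.

## Problem sizes and known limitations

The default test scale is the 100-kb pair (seconds per stage); the
500-kb full-scale pair runs the complete pipeline in about a minute and
is exercised by `scripts/acceptance.py`. At full scale, with 43 planted
SVs, a translocation whose destination happens to fall order-consistent
with the backbone is occasionally (≤1 event in our runs) re-absorbed as
collinear — the price of the rule that rescues legitimately skipped
backbone fragments; all other stages recover their truth exactly at both
scales. Degenerate (mismatch-tolerant) repeats, read-level evidence,
quality scores and multi-genome comparison are out of scope.
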
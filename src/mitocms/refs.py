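"""Default plant-mitochondrial gene complement and reference proteins.

The shipped reference proteins are fixed synthetic stand-ins (see
``data/synthetic_mito_proteins.faa``): random peptide sequences of realistic
lengths under the standard plant-mito gene names, generated once with a fixed
seed.  They let homology annotation be tested hermetically; they are not real
plant sequences.
"""

from __future__ import annotations

from importlib import resources

from .annotate import RefProtein, load_reference_proteins
from .genome_io import GeneCategory as GC

# (name, category, aa_length) for single-copy coding genes.  Duplicated
# copies ("-D2"/"-D3") reuse the same protein with independent codon choices.
CODING_GENES: list[tuple[str, GC, int]] = [
    ("atp1", GC.ATP_SYNTHASE, 450),
    ("atp6", GC.ATP_SYNTHASE, 290),
    ("atp8", GC.ATP_SYNTHASE, 155),
    ("atp9", GC.ATP_SYNTHASE, 74),
    ("cox1", GC.CYTOCHROME, 520),
    ("cox2", GC.CYTOCHROME, 260),
    ("cox3", GC.CYTOCHROME, 265),
    ("cob", GC.CYTOCHROME, 390),
    ("ccmFc", GC.TRANSPORT_MATURATION, 440),
    ("mttB", GC.TRANSPORT_MATURATION, 250),
    ("nad1", GC.NADH_DEHYDROGENASE, 325),
    ("nad2", GC.NADH_DEHYDROGENASE, 480),
    ("nad3", GC.NADH_DEHYDROGENASE, 118),
    ("nad4", GC.NADH_DEHYDROGENASE, 490),
    ("nad4L", GC.NADH_DEHYDROGENASE, 101),
    ("nad5", GC.NADH_DEHYDROGENASE, 560),
    ("nad6", GC.NADH_DEHYDROGENASE, 205),
    ("nad7", GC.NADH_DEHYDROGENASE, 390),
    ("rpl2", GC.RIBOSOMAL_PROTEIN, 370),
    ("rpl10", GC.RIBOSOMAL_PROTEIN, 160),
    # rpl16 is kept short so the default co-transcription unit geometry
    # (orf561a - rpl16 - orf312a spanning 2996 bp) closes exactly.
    ("rpl16", GC.RIBOSOMAL_PROTEIN, 110),
    ("rps1", GC.RIBOSOMAL_PROTEIN, 200),
    ("rps19", GC.RIBOSOMAL_PROTEIN, 95),
    ("sdh3", GC.SUCCINATE_DEHYDROGENASE, 100),
    ("sdh4", GC.SUCCINATE_DEHYDROGENASE, 130),
]

# gene -> number of copies in the maintainer-like genome; duplicated
# copies are named -D2, -D3 in coordinate order.
DUPLICATED: dict[str, int] = {
    "atp8": 2,
    "atp9": 2,
    "cox3": 2,
    "mttB": 2,
    "nad1": 2,
    "nad2": 2,
    "nad7": 2,
    "rps19": 3,
    "sdh4": 2,
}

# non-coding complement: (name, category, nt_length)
NONCODING_GENES: list[tuple[str, GC, int]] = [
    ("rrn26", GC.RRNA, 3200),
    ("rrn18", GC.RRNA, 1900),
    ("rrn5", GC.RRNA, 120),
] + [(f"trn{aa}", GC.TRNA, 75) for aa in ["M", "E", "D", "F", "G", "H", "K", "N", "P", "Q", "S", "W"]]


def default_gene_complement() -> list[tuple[str, str, int, int]]:
    """(name, category, aa_length, n_copies) rows for SimConfig."""
    return [
        (name, cat.value, aa, DUPLICATED.get(name, 1)) for name, cat, aa in CODING_GENES
    ]


def reference_proteins() -> list[RefProtein]:
    """Load the shipped synthetic reference protein set."""
    with resources.as_file(
        resources.files("mitocms.data") / "synthetic_mito_proteins.faa"
    ) as p:
        return load_reference_proteins(p)
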
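"""Annotation of merged variants by reproducible table joins.

Instead of live database machinery, annotation consumes user-supplied
tables: a gene model (feature intervals), a known-variant table, a
deleteriousness-score table (SIFT-style, smaller = more damaging), and
protein-domain intervals pre-projected to genomic coordinates.  This keeps
every annotation a pure, versionable function of (variant, tables).

Region classes follow a fixed precedence when transcripts overlap:
exonic > ncRNA > UTR5 > UTR3 > intronic > upstream > downstream; a position
hitting nothing is intergenic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

from intervaltree import IntervalTree

from esnvkit.merge import MergedVariant, VariantKey

REGION_CLASSES = (
    "exonic",
    "ncRNA",
    "UTR5",
    "UTR3",
    "intronic",
    "upstream",
    "downstream",
)
_PRECEDENCE = {cls: rank for rank, cls in enumerate(REGION_CLASSES)}

DELETERIOUS_CUTOFF = 0.05  # strict: score < 0.05 flags a damaging change

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass(frozen=True)
class GeneModelInterval:
    """One feature interval of a transcript model (1-based, inclusive)."""

    chrom: str
    start: int
    end: int
    feature_class: str
    gene: str
    transcript: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"start {self.start} > end {self.end}")
        if self.feature_class not in REGION_CLASSES:
            raise ValueError(
                f"feature class {self.feature_class!r} not in {REGION_CLASSES}"
            )


class GeneModel:
    """Per-chromosome interval index over gene-model features."""

    def __init__(self, intervals: Iterable[GeneModelInterval] = ()):
        self._trees: dict[str, IntervalTree] = {}
        self.intervals: list[GeneModelInterval] = []
        for iv in intervals:
            self.add(iv)

    def add(self, iv: GeneModelInterval) -> None:
        self.intervals.append(iv)
        # intervaltree is half-open; store [start, end+1) for inclusive ends
        self._trees.setdefault(iv.chrom, IntervalTree()).addi(
            iv.start, iv.end + 1, iv
        )

    @classmethod
    def from_tsv(cls, handle: Iterable[str]) -> "GeneModel":
        """1-based inclusive TSV: chrom start end class gene [transcript]."""
        model = cls()
        for line in handle:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            model.add(
                GeneModelInterval(
                    chrom=f[0], start=int(f[1]), end=int(f[2]),
                    feature_class=f[3], gene=f[4],
                    transcript=f[5] if len(f) > 5 else "",
                )
            )
        return model

    @classmethod
    def from_bed(cls, handle: Iterable[str]) -> "GeneModel":
        """BED dialect: 0-based half-open, columns chrom start end class gene."""
        model = cls()
        for line in handle:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            model.add(
                GeneModelInterval(
                    chrom=f[0], start=int(f[1]) + 1, end=int(f[2]),
                    feature_class=f[3], gene=f[4],
                    transcript=f[5] if len(f) > 5 else "",
                )
            )
        return model

    def query(self, chrom: str, pos: int) -> list[GeneModelInterval]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return [hit.data for hit in tree.at(pos)]


def classify_region(key: VariantKey, model: GeneModel) -> tuple[str, Optional[str]]:
    """Resolve a variant position to a single region class and gene.

    Overlapping transcript features are resolved by precedence (a position
    exonic in any transcript is exonic); ties at equal precedence resolve to
    the lexicographically first gene for determinism.  No overlap at all
    means intergenic with no gene.
    """
    hits = model.query(key.chrom, key.pos)
    if not hits:
        return "intergenic", None
    best = min(hits, key=lambda iv: (_PRECEDENCE[iv.feature_class], iv.gene))
    return best.feature_class, best.gene


class KnownVariantTable:
    """Exact (chrom, pos, ref, alt) -> identifier lookup."""

    def __init__(self, entries: Mapping[VariantKey, str] | None = None):
        self._entries: dict[VariantKey, str] = dict(entries or {})

    def __len__(self) -> int:
        return len(self._entries)

    @classmethod
    def from_tsv(cls, handle: Iterable[str]) -> "KnownVariantTable":
        """Columns: chrom pos ref alt id (1-based)."""
        entries = {}
        for line in handle:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            entries[VariantKey(f[0], int(f[1]), f[2], f[3])] = f[4]
        return cls(entries)

    @classmethod
    def from_vcf(cls, path: str) -> "KnownVariantTable":
        from cyvcf2 import VCF

        entries = {}
        for var in VCF(path):
            for alt in var.ALT:
                key = VariantKey(var.CHROM, var.POS, var.REF, alt)
                entries[key] = var.ID or f"{var.CHROM}:{var.POS}{var.REF}>{alt}"
        return cls(entries)

    def lookup(self, key: VariantKey) -> Optional[str]:
        return self._entries.get(key)


def join_known(key: VariantKey, known: KnownVariantTable) -> Optional[str]:
    """Known identifier for the exact allele, or None for a novel variant."""
    return known.lookup(key)


class DomainTable:
    """Protein-domain intervals in genomic coordinates (1-based inclusive)."""

    def __init__(self) -> None:
        self._trees: dict[str, IntervalTree] = {}

    def add(self, chrom: str, start: int, end: int, name: str) -> None:
        self._trees.setdefault(chrom, IntervalTree()).addi(start, end + 1, name)

    @classmethod
    def from_tsv(cls, handle: Iterable[str]) -> "DomainTable":
        """Columns: chrom start end domain_name."""
        table = cls()
        for line in handle:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            table.add(f[0], int(f[1]), int(f[2]), f[3])
        return table

    def query(self, chrom: str, pos: int) -> list[str]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return sorted(hit.data for hit in tree.at(pos))


def join_domains(key: VariantKey, domains: DomainTable) -> list[str]:
    """All protein domains whose genomic projection covers the position."""
    return domains.query(key.chrom, key.pos)


def flag_deleterious(score: Optional[float]) -> bool:
    """Damaging iff a score is present and strictly below 0.05."""
    return score is not None and score < DELETERIOUS_CUTOFF


@dataclass(frozen=True)
class CodonContext:
    """Reference codon containing a variant, for synonymy calling.

    ``frame`` is the 0-based index of the variant base within the codon as
    written on the coding strand; ``strand`` is '+' or '-'.
    """

    codon: str
    frame: int
    strand: str = "+"


def call_synonymy(key: VariantKey, ctx: Optional[CodonContext]) -> str:
    """'synonymous' / 'nonsynonymous' given codon context, else 'noncoding'."""
    from Bio.Seq import Seq

    if ctx is None:
        return "noncoding"
    codon = ctx.codon.upper()
    if len(codon) != 3 or ctx.frame not in (0, 1, 2):
        raise ValueError(f"bad codon context {ctx}")
    alt = key.alt_base
    if ctx.strand == "-":
        alt = alt.translate(_COMPLEMENT)
    mutated = codon[: ctx.frame] + alt + codon[ctx.frame + 1 :]
    same = str(Seq(codon).translate()) == str(Seq(mutated).translate())
    return "synonymous" if same else "nonsynonymous"


@dataclass
class AnnotatedVariant:
    variant: MergedVariant
    region_class: str
    gene: Optional[str]
    known_id: Optional[str]
    domain_hits: list[str] = field(default_factory=list)
    deleterious: bool = False
    synonymy: str = "noncoding"

    @property
    def is_novel(self) -> bool:
        return self.known_id is None


def annotate_variants(
    variants: Iterable[MergedVariant],
    gene_model: GeneModel,
    known: KnownVariantTable | None = None,
    domains: DomainTable | None = None,
    scores: Mapping[VariantKey, float] | None = None,
    codon_contexts: Mapping[VariantKey, CodonContext] | None = None,
) -> list[AnnotatedVariant]:
    """Join every merged variant against the supplied annotation tables.

    Missing tables degrade gracefully: no known table means every variant is
    novel, no score table means nothing is flagged deleterious, and without
    codon context synonymy stays 'noncoding'.
    """
    out = []
    for mv in variants:
        region, gene = classify_region(mv.key, gene_model)
        out.append(
            AnnotatedVariant(
                variant=mv,
                region_class=region,
                gene=gene,
                known_id=known.lookup(mv.key) if known is not None else None,
                domain_hits=domains.query(mv.key.chrom, mv.key.pos)
                if domains is not None
                else [],
                deleterious=flag_deleterious(
                    scores.get(mv.key) if scores is not None else None
                ),
                synonymy=call_synonymy(
                    mv.key,
                    codon_contexts.get(mv.key) if codon_contexts is not None else None,
                ),
            )
        )
    return out
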
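"""Seeded synthetic fixtures with exhaustive ground truth.

The generator emulates the post-alignment inputs of a two-aligner eSNV
workflow on a small synthetic genome: per-aligner site evidence, a gene
model, a known-variant table, and a genotyping-chip truth set.  Every site
is planted as either a *clean* variant (het or hom-alt, balanced strands,
read positions uniform along the read) or as one of three artifact classes,
each engineered to fail exactly one filter criterion:

* ``strand_bias`` — all alternate reads on a single strand,
* ``end_clustered`` — alternate bases confined to the outermost read
  cycles while reference bases sit in the read interior (planted at high
  depth, because a rank-sum |Z| > 8 is unreachable in small samples),
* ``low_alt_depth`` — only 2-3 supporting reads.

A JSON-able ledger records, per site, the planted truth: category,
zygosity, region class, which aligners observed it and which criterion it
was designed to fail, so every downstream stage can be reconciled exactly.
Identical seeds yield byte-identical outputs.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np

from esnvkit.annotate import GeneModel, GeneModelInterval, KnownVariantTable
from esnvkit.evaluate import TruthRecord, TruthSet
from esnvkit.merge import VariantKey
from esnvkit.site_features import (
    SiteEvidence,
    read_pos_rank_sum,
    write_evidence_tsv,
)

_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_BASES = "ACGT"

CATEGORIES = ("clean", "strand_bias", "end_clustered", "low_alt_depth")


class SimConfigError(ValueError):
    pass


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic two-aligner experiment."""

    seed: int = 0
    n_sites: int = 10_000
    fraction_true_variants: float = 0.90
    strand_biased_fraction: float = 0.05
    end_clustered_fraction: float = 0.05
    low_alt_depth_fraction: float = 0.00
    depth_range: tuple[int, int] = (10, 120)
    artifact_depth_range: tuple[int, int] = (140, 220)  # end-clustered sites
    het_fraction_sd: float = 0.05  # het alt fraction ~ N(0.5, sd), clipped
    het_fraction_clip: tuple[float, float] = (0.35, 0.65)
    hom_fraction_range: tuple[float, float] = (0.95, 1.0)
    p_het: float = 2 / 3  # het vs hom-alt split among clean variants
    aligner_concordance: float = 0.95
    known_fraction: float = 0.5
    ts_fraction: float = 0.75  # transition probability => expected ts/tv 3.0
    read_length: int = 100
    min_clean_alt_depth: int = 4  # clean sites are planted above this floor
    dropout_fraction: float = 0.0  # single-cell allele dropout at het sites
    aligners: tuple[str, str] = ("tophat2", "bwa")
    region_mixture: tuple[tuple[str, float], ...] = (
        ("exonic", 0.369),
        ("UTR5", 0.130),
        ("UTR3", 0.254),
        ("intronic", 0.143),
        ("intergenic", 0.104),
    )

    def __post_init__(self) -> None:
        probs = [
            self.fraction_true_variants,
            self.strand_biased_fraction,
            self.end_clustered_fraction,
            self.low_alt_depth_fraction,
        ]
        if any(not (0 <= p <= 1) for p in probs):
            raise SimConfigError("category fractions must lie in [0, 1]")
        if abs(sum(probs) - 1.0) > 1e-9:
            raise SimConfigError(
                f"clean + artifact fractions must sum to 1, got {sum(probs)}"
            )
        if self.n_sites < 1:
            raise SimConfigError("n_sites must be >= 1")
        if not (0 <= self.aligner_concordance <= 1):
            raise SimConfigError("aligner_concordance must lie in [0, 1]")
        if not (0 <= self.known_fraction <= 1) or not (0 <= self.ts_fraction <= 1):
            raise SimConfigError("fractions must lie in [0, 1]")
        mix = dict(self.region_mixture)
        if abs(sum(mix.values()) - 1.0) > 1e-9:
            raise SimConfigError("region mixture must sum to 1")

    @classmethod
    def single_cell(cls, **overrides) -> "SimConfig":
        """Shallow single-cell preset: low depth, allele dropout at hets.

        Depth is shifted to a mean of ~7 reads and half of the het sites
        drop one allele, reproducing the zygosity discordance seen when a
        single cell is compared with a multicellular library.
        """
        overrides.setdefault("depth_range", (4, 12))
        overrides.setdefault("dropout_fraction", 0.5)
        overrides.setdefault("min_clean_alt_depth", 2)
        return cls(**overrides)


@dataclass
class PlantedSite:
    """One ledger entry: what was planted and what should come out."""

    chrom: str
    pos: int
    ref: str
    alt: str
    category: str
    zygosity: str  # het / hom_alt for clean sites, hom_ref for artifacts
    region_class: str
    observed_by: list[str]
    expected_fail: Optional[str]  # filter code the site is designed to fail
    known_id: Optional[str]

    @property
    def key(self) -> VariantKey:
        return VariantKey(self.chrom, self.pos, self.ref, self.alt)


@dataclass
class SimResult:
    config: SimConfig
    call_sets: dict[str, list[SiteEvidence]]
    truth: TruthSet
    gene_model: GeneModel
    known: KnownVariantTable
    rna_alt_depth: dict[tuple[str, int], int]
    ledger: list[PlantedSite]


# ---------------------------------------------------------------------------
# synthetic gene model
# ---------------------------------------------------------------------------


def build_gene_model(
    n_genes: int = 30, chroms: tuple[str, ...] = ("chr1", "chr2")
) -> tuple[GeneModel, dict[str, list[tuple[str, int, int]]]]:
    """Lay out non-overlapping transcript models along synthetic chromosomes.

    Each gene is upstream / UTR5 / exon / intron / exon / UTR3 / downstream
    with a 2 kb intergenic gap after it; every third gene is instead a
    single-interval ncRNA.  Because intervals never overlap, the region
    class of any position is unambiguous and region fractions over planted
    variants are exact.  Returns the model plus, per region class, the list
    of (chrom, start, end) intervals usable for placement (including the
    intergenic gaps, which carry no model interval).
    """
    model = GeneModel()
    placement: dict[str, list[tuple[str, int, int]]] = {}

    def _add(chrom: str, start: int, length: int, cls: str, gene: str, tx: str) -> int:
        end = start + length - 1
        model.add(GeneModelInterval(chrom, start, end, cls, gene, tx))
        placement.setdefault(cls, []).append((chrom, start, end))
        return end + 1

    cursors = {c: 1_000 for c in chroms}
    for g in range(n_genes):
        chrom = chroms[g % len(chroms)]
        cur = cursors[chrom]
        gene = f"GENE{g:03d}"
        tx = f"TX{g:03d}"
        if g % 3 == 2:
            cur = _add(chrom, cur, 600, "ncRNA", gene, tx)
        else:
            cur = _add(chrom, cur, 500, "upstream", gene, tx)
            cur = _add(chrom, cur, 200, "UTR5", gene, tx)
            cur = _add(chrom, cur, 400, "exonic", gene, tx)
            cur = _add(chrom, cur, 600, "intronic", gene, tx)
            cur = _add(chrom, cur, 400, "exonic", gene, tx)
            cur = _add(chrom, cur, 300, "UTR3", gene, tx)
            cur = _add(chrom, cur, 500, "downstream", gene, tx)
        placement.setdefault("intergenic", []).append((chrom, cur, cur + 1_999))
        cursors[chrom] = cur + 2_000
    return model, placement


# ---------------------------------------------------------------------------
# per-site evidence draws
# ---------------------------------------------------------------------------


def _near_even_split(aa: int, rng: np.random.Generator) -> tuple[int, int]:
    fwd = aa // 2 + (int(rng.integers(2)) if aa % 2 else 0)
    return fwd, aa - fwd


def _uniform_offsets(n: int, lo: int, hi: int, rng: np.random.Generator) -> list[int]:
    if n <= 0:
        return []
    return [int(x) for x in rng.integers(lo, hi + 1, size=n)]


def _draw_clean_counts(
    cfg: SimConfig, zygosity: str, rng: np.random.Generator
) -> tuple[int, int]:
    t = int(rng.integers(cfg.depth_range[0], cfg.depth_range[1] + 1))
    if zygosity == "het":
        f = float(
            np.clip(rng.normal(0.5, cfg.het_fraction_sd), *cfg.het_fraction_clip)
        )
        if cfg.dropout_fraction > 0 and rng.random() < cfg.dropout_fraction:
            # one allele drops out of the library; which one is a coin flip
            f = 0.02 if rng.random() < 0.5 else 0.98
    else:
        f = float(rng.uniform(*cfg.hom_fraction_range))
    aa = int(rng.binomial(t, f))
    if cfg.dropout_fraction == 0.0:
        # plant the site firmly inside the filter envelope
        aa = max(aa, cfg.min_clean_alt_depth, int(0.1 * t) + 1)
    aa = min(aa, t)
    return t, aa


def _evidence_for_site(
    site: PlantedSite, cfg: SimConfig, aligner: str, rng: np.random.Generator
) -> Optional[SiteEvidence]:
    """Draw one aligner's evidence consistent with the planted category."""
    half = (cfg.read_length - 1) // 2  # max nearer-end offset (49 for 100 bp)
    if site.category == "clean":
        t, aa = _draw_clean_counts(cfg, site.zygosity, rng)
        if aa == 0:
            return None  # total dropout of the alternate allele: no record
        fwd, rev = _near_even_split(aa, rng)
        ref_pos = _uniform_offsets(t - aa, 0, half, rng)
        alt_pos = _uniform_offsets(aa, 0, half, rng)
    elif site.category == "strand_bias":
        t = int(rng.integers(cfg.depth_range[0], cfg.depth_range[1] + 1))
        aa = max(int(rng.binomial(t, 0.45)), cfg.min_clean_alt_depth, int(0.1 * t) + 1)
        aa = min(aa, t)
        fwd, rev = (aa, 0) if rng.random() < 0.5 else (0, aa)
        ref_pos = _uniform_offsets(t - aa, 0, half, rng)
        alt_pos = _uniform_offsets(aa, 0, half, rng)
    elif site.category == "end_clustered":
        # high depth so that complete read-end separation drives |Z| past 8
        t = int(rng.integers(cfg.artifact_depth_range[0], cfg.artifact_depth_range[1] + 1))
        aa = int(np.clip(rng.binomial(t, 0.45), int(0.40 * t), int(0.50 * t)))
        fwd, rev = _near_even_split(aa, rng)
        alt_pos = _uniform_offsets(aa, 0, 4, rng)  # outermost decile of cycles
        ref_pos = _uniform_offsets(t - aa, 5, half, rng)
    elif site.category == "low_alt_depth":
        aa = int(rng.integers(2, 4))  # 2 or 3 supporting reads
        t = int(rng.integers(5, 10 * aa))  # keeps the alt fraction above 0.1
        fwd, rev = _near_even_split(aa, rng)
        ref_pos = _uniform_offsets(t - aa, 0, half, rng)
        alt_pos = _uniform_offsets(aa, 0, half, rng)
    else:  # pragma: no cover - guarded by CATEGORIES
        raise SimConfigError(f"unknown category {site.category!r}")

    return SiteEvidence(
        chrom=site.chrom,
        pos=site.pos,
        ref_base=site.ref,
        alt_base=site.alt,
        total_depth=t,
        alt_depth=aa,
        alt_fwd=fwd,
        alt_rev=rev,
        ref_read_positions=ref_pos,
        alt_read_positions=alt_pos,
        rrps=read_pos_rank_sum(ref_pos, alt_pos),
        aligner_id=aligner,
    )


_EXPECTED_FAIL = {
    "clean": None,
    "strand_bias": "strand_bias",
    "end_clustered": "rrps",
    "low_alt_depth": "alt_depth",
}


def simulate(cfg: SimConfig) -> SimResult:
    """Generate the full two-aligner fixture set for the given conditions."""
    rng = np.random.default_rng(cfg.seed)
    gene_model, placement = build_gene_model()
    classes = [c for c, _ in cfg.region_mixture]
    class_probs = np.array([p for _, p in cfg.region_mixture])
    cat_probs = np.array(
        [
            cfg.fraction_true_variants,
            cfg.strand_biased_fraction,
            cfg.end_clustered_fraction,
            cfg.low_alt_depth_fraction,
        ]
    )

    used_positions: set[tuple[str, int]] = set()
    ledger: list[PlantedSite] = []
    known_entries: dict[VariantKey, str] = {}
    n_known = 0

    for _ in range(cfg.n_sites):
        region = classes[int(rng.choice(len(classes), p=class_probs))]
        chrom = pos = None
        while True:
            iv = placement[region][int(rng.integers(len(placement[region])))]
            chrom = iv[0]
            pos = int(rng.integers(iv[1], iv[2] + 1))
            if (chrom, pos) not in used_positions:
                used_positions.add((chrom, pos))
                break
        ref = _BASES[int(rng.integers(4))]
        if rng.random() < cfg.ts_fraction:
            alt = _TRANSITION[ref]
        else:
            alt = rng.choice([b for b in _BASES if b != ref and b != _TRANSITION[ref]])
        category = CATEGORIES[int(rng.choice(len(CATEGORIES), p=cat_probs))]
        if category == "clean":
            zygosity = "het" if rng.random() < cfg.p_het else "hom_alt"
        else:
            zygosity = "hom_ref"
        if rng.random() < cfg.aligner_concordance:
            observed = list(cfg.aligners)
        else:
            observed = [cfg.aligners[int(rng.integers(2))]]
        known_id = None
        if category == "clean" and rng.random() < cfg.known_fraction:
            known_id = f"KV{n_known:06d}"
            n_known += 1
        site = PlantedSite(
            chrom=chrom,
            pos=pos,
            ref=ref,
            alt=str(alt),
            category=category,
            zygosity=zygosity,
            region_class=region,
            observed_by=observed,
            expected_fail=_EXPECTED_FAIL[category],
            known_id=known_id,
        )
        ledger.append(site)
        if known_id is not None:
            known_entries[site.key] = known_id

    ledger.sort(key=lambda s: (s.chrom, s.pos, s.alt))

    call_sets: dict[str, list[SiteEvidence]] = {a: [] for a in cfg.aligners}
    rna_alt_depth: dict[tuple[str, int], int] = {}
    truth = TruthSet(kind="chip")
    for site in ledger:
        truth.records[(site.chrom, site.pos)] = TruthRecord(
            site.ref, site.alt, site.zygosity
        )
        best_alt = 0
        for aligner in site.observed_by:
            ev = _evidence_for_site(site, cfg, aligner, rng)
            if ev is not None:
                call_sets[aligner].append(ev)
                best_alt = max(best_alt, ev.alt_depth)
        rna_alt_depth[(site.chrom, site.pos)] = best_alt

    return SimResult(
        config=cfg,
        call_sets=call_sets,
        truth=truth,
        gene_model=gene_model,
        known=KnownVariantTable(known_entries),
        rna_alt_depth=rna_alt_depth,
        ledger=ledger,
    )


# ---------------------------------------------------------------------------
# file emission (the TSV dialects the other modules consume)
# ---------------------------------------------------------------------------


def write_outputs(result: SimResult, outdir: str) -> dict[str, str]:
    """Write evidence TSVs, truth/known/gene-model tables and the ledger.

    Returns a name -> path map of everything written.  Same seed, same
    bytes.
    """
    os.makedirs(outdir, exist_ok=True)
    paths: dict[str, str] = {}

    for aligner, records in result.call_sets.items():
        p = os.path.join(outdir, f"evidence_{aligner}.tsv")
        with open(p, "w") as fh:
            write_evidence_tsv(records, fh)
        paths[f"evidence_{aligner}"] = p

    p = os.path.join(outdir, "truth_chip.tsv")
    with open(p, "w") as fh:
        fh.write("#chrom\tpos\tref\talt\tgenotype\n")
        for (chrom, pos), rec in sorted(result.truth.records.items()):
            fh.write(f"{chrom}\t{pos}\t{rec.ref_base}\t{rec.alt_base}\t{rec.genotype}\n")
    paths["truth"] = p

    p = os.path.join(outdir, "gene_model.tsv")
    with open(p, "w") as fh:
        fh.write("#chrom\tstart\tend\tclass\tgene\ttranscript\n")
        for iv in result.gene_model.intervals:
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.feature_class}\t"
                f"{iv.gene}\t{iv.transcript}\n"
            )
    paths["gene_model"] = p

    p = os.path.join(outdir, "known_variants.tsv")
    with open(p, "w") as fh:
        fh.write("#chrom\tpos\tref\talt\tid\n")
        for site in result.ledger:
            if site.known_id is not None:
                fh.write(
                    f"{site.chrom}\t{site.pos}\t{site.ref}\t{site.alt}\t{site.known_id}\n"
                )
    paths["known"] = p

    p = os.path.join(outdir, "ledger.json")
    with open(p, "w") as fh:
        json.dump([asdict(s) for s in result.ledger], fh, indent=1, sort_keys=True)
        fh.write("\n")
    paths["ledger"] = p
    return paths
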
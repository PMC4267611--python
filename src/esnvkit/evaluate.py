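"""Benchmarking of eSNV call sets against orthogonal truth.

Two truth flavours are supported:

* ``chip`` — genotyping-array genotypes.  The array assays a fixed panel of
  loci, so calls are judged only at assayed positions, and an array variant
  only counts as a recoverable positive when the locus is actually expressed
  in the RNA (more than 3 alternate-supporting RNA reads).
* ``wes`` — an exome-sequencing mutation list with per-position coverage.
  Calls at positions the exome covered below 4X are excluded from the
  precision denominator (the exome simply cannot adjudicate them) and
  reported separately.

From the gated sets: TP = calls matching a truth variant allele, FP = calls
the truth contradicts (absent, or genotyped hom-ref), FN = expressed truth
variants not called, then precision = TP/(TP+FP), recall = TP/(TP+FN),
F = 2PR/(P+R).  Also provided: transition/transversion ratio and
allele-fraction zygosity calls with a bulk-vs-cell concordance matrix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from esnvkit.merge import VariantKey
from esnvkit.site_features import SiteEvidence

GENOTYPES = ("hom_ref", "het", "hom_alt")
EXPRESSED_ALT_READS = 3  # a chip locus is "expressed" with > 3 alt reads
WES_MIN_COVERAGE = 4  # exome truth can adjudicate only at >= 4X

TRANSITIONS = frozenset({("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")})


def round_half_up(x: float, ndigits: int) -> float:
    """Decimal half-up rounding (0.05 at one digit -> 0.1)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class TruthRecord:
    ref_base: str
    alt_base: str
    genotype: str  # hom_ref / het / hom_alt

    def __post_init__(self) -> None:
        if self.genotype not in GENOTYPES:
            raise ValueError(f"genotype must be one of {GENOTYPES}")


@dataclass
class TruthSet:
    """Orthogonal truth: genotypes per assayed position, plus WES coverage."""

    kind: str  # "chip" or "wes"
    records: dict[tuple[str, int], TruthRecord] = field(default_factory=dict)
    wes_coverage: dict[tuple[str, int], int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("chip", "wes"):
            raise ValueError("truth kind must be 'chip' or 'wes'")
        if any(c < 0 for c in self.wes_coverage.values()):
            raise ValueError("WES coverage must be non-negative")

    def variant_positions(self) -> set[tuple[str, int]]:
        return {
            loc for loc, rec in self.records.items() if rec.genotype != "hom_ref"
        }

    @classmethod
    def from_tsv(cls, handle: Iterable[str], kind: str) -> "TruthSet":
        """Columns: chrom pos ref alt genotype [wes_depth]."""
        ts = cls(kind=kind)
        for line in handle:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            loc = (f[0], int(f[1]))
            ts.records[loc] = TruthRecord(f[2], f[3], f[4])
            if len(f) > 5 and f[5] != ".":
                ts.wes_coverage[loc] = int(f[5])
        return ts

    @classmethod
    def from_vcf(cls, path: str, kind: str) -> "TruthSet":
        """Truth from a VCF with a GT sample field (first sample used)."""
        from cyvcf2 import VCF

        ts = cls(kind=kind)
        for var in VCF(path):
            gt = var.genotypes[0][:2] if var.genotypes else [0, 0]
            n_alt = sum(1 for a in gt if a > 0)
            genotype = GENOTYPES[min(n_alt, 2)]
            alt = var.ALT[0] if var.ALT else var.REF
            loc = (var.CHROM, var.POS)
            ts.records[loc] = TruthRecord(var.REF, alt, genotype)
            dp = var.INFO.get("DP")
            if dp is not None:
                ts.wes_coverage[loc] = int(dp)
        return ts


@dataclass
class EvalResult:
    tp: int
    fp: int
    fn: int
    n_no_coverage: int = 0
    tstv: Optional[float] = None
    zygosity_matrix: Optional[np.ndarray] = None

    @property
    def precision(self) -> Optional[float]:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) > 0 else None

    @property
    def recall(self) -> Optional[float]:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) > 0 else None

    @property
    def f_score(self) -> Optional[float]:
        denom = (self.tp + self.fp) + (self.tp + self.fn)
        return 2 * self.tp / denom if denom > 0 else None

    def summary(self) -> str:
        def pct(x: Optional[float]) -> str:
            return "NA" if x is None else f"{round_half_up(100 * x, 1)}%"

        lines = [
            f"TP={self.tp} FP={self.fp} FN={self.fn}"
            + (f" no_coverage={self.n_no_coverage}" if self.n_no_coverage else ""),
            f"precision={pct(self.precision)} recall={pct(self.recall)} "
            f"F={'NA' if self.f_score is None else round_half_up(self.f_score, 3)}",
        ]
        if self.tstv is not None:
            lines.append(f"ts/tv={'inf' if math.isinf(self.tstv) else round(self.tstv, 2)}")
        return "\n".join(lines)


def precision_recall_from_counts(
    validated: int, total_calls: int, no_coverage: int, expressed_truth: int
) -> tuple[float, float, float]:
    """Benchmark metrics from summary counts alone.

    precision = validated / (total_calls - no_coverage);
    recall = validated / expressed_truth; F is their harmonic mean.  This is
    the arithmetic used when only a published count table is available.
    """
    assayable = total_calls - no_coverage
    precision = validated / assayable
    recall = validated / expressed_truth
    f = 2 * precision * recall / (precision + recall)
    return precision, recall, f


def gate_assayable(
    calls: Sequence[VariantKey],
    truth: TruthSet,
    rna_alt_depth: Mapping[tuple[str, int], int] | None = None,
    wes_coverage: Mapping[tuple[str, int], int] | None = None,
) -> tuple[list[VariantKey], set[tuple[str, int]], int]:
    """Restrict calls and truth to what the truth platform can adjudicate.

    chip: calls are kept only at array-assayed positions; the recoverable
    truth set is array variant loci with RNA alt depth > 3 ("expressed").
    wes: calls are kept only where exome coverage >= 4 (the rest are counted
    as ``n_no_coverage``); the recoverable truth set is the mutation-list
    loci, optionally restricted to RNA-expressed ones when ``rna_alt_depth``
    provides depths.

    Returns (assayable calls, expressed truth loci, n_no_coverage).
    """
    if truth.kind == "chip":
        if rna_alt_depth is None:
            raise ValueError("chip gating needs per-locus RNA alt depths")
        assayable = [k for k in calls if (k.chrom, k.pos) in truth.records]
        expressed = {
            loc
            for loc in truth.variant_positions()
            if rna_alt_depth.get(loc, 0) > EXPRESSED_ALT_READS
        }
        return assayable, expressed, 0
    # wes
    coverage = wes_coverage if wes_coverage is not None else truth.wes_coverage
    if not coverage:
        raise ValueError("wes gating needs per-position coverage data")
    assayable, no_cov = [], 0
    for k in calls:
        if coverage.get((k.chrom, k.pos), 0) >= WES_MIN_COVERAGE:
            assayable.append(k)
        else:
            no_cov += 1
    expressed = set(truth.variant_positions())
    if rna_alt_depth is not None:
        expressed = {loc for loc in expressed if rna_alt_depth.get(loc, 0) > 0}
    return assayable, expressed, no_cov


def score(
    assayable_calls: Sequence[VariantKey],
    truth: TruthSet,
    expressed_truth: set[tuple[str, int]],
    n_no_coverage: int = 0,
) -> EvalResult:
    """Tally TP/FP/FN over gated calls and compute the benchmark metrics.

    A call is TP when the truth set carries the same alternate allele at the
    position with a non-hom-ref genotype; a truth hom-ref genotype, or a
    different allele, at a called position is a contradiction, hence FP.
    FN counts expressed truth loci whose variant allele no assayable call
    recovered, so TP + FP == len(assayable_calls) and — whenever every
    allele-matched locus is expressed — TP + FN == len(expressed_truth).
    """
    tp = fp = 0
    matched_loci = set()
    for k in assayable_calls:
        loc = (k.chrom, k.pos)
        rec = truth.records.get(loc)
        if rec is not None and rec.genotype != "hom_ref" and rec.alt_base == k.alt_base:
            tp += 1
            matched_loci.add(loc)
        else:
            fp += 1
    fn = sum(1 for loc in expressed_truth if loc not in matched_loci)
    result = EvalResult(tp=tp, fp=fp, fn=fn, n_no_coverage=n_no_coverage)
    result.tstv = tstv_ratio(assayable_calls) if assayable_calls else None
    return result


def tstv_ratio(calls: Iterable[VariantKey | SiteEvidence]) -> float:
    """Transition/transversion count ratio of a call set.

    Transitions are A<->G and C<->T; the other eight substitution types are
    transversions.  Returns ``inf`` when no transversion is present.
    """
    n_ts = n_tv = 0
    for c in calls:
        pair = (
            (c.ref_base, c.alt_base)
            if isinstance(c, (VariantKey, SiteEvidence))
            else tuple(c)
        )
        if pair in TRANSITIONS:
            n_ts += 1
        else:
            n_tv += 1
    if n_tv == 0:
        return math.inf
    return n_ts / n_tv


def zygosity_call(
    e: SiteEvidence, het_lower: float = 0.1, het_upper: float = 0.9
) -> str:
    """Classify a site from its alt-allele read fraction.

    f < ``het_lower`` -> hom_ref; ``het_lower`` <= f <= ``het_upper`` -> het;
    f > ``het_upper`` -> hom_alt.
    """
    if e.total_depth == 0:
        raise ValueError(f"no-call at {e.chrom}:{e.pos}: zero depth")
    f = e.alt_depth / e.total_depth
    if f < het_lower:
        return "hom_ref"
    if f > het_upper:
        return "hom_alt"
    return "het"


def zygosity_concordance(
    cell_calls: Mapping[VariantKey, SiteEvidence],
    bulk_calls: Mapping[VariantKey, SiteEvidence],
    het_lower: float = 0.1,
    het_upper: float = 0.9,
) -> np.ndarray:
    """3x3 concordance matrix (bulk zygosity x per-cell zygosity).

    Rows index the bulk (multicellular) call, columns the single-cell call,
    both in order (hom_ref, het, hom_alt), over sites callable in both.
    A bulk-het site scattering across all three columns is the signature of
    cellular heterogeneity (or allele dropout at low depth).
    """
    matrix = np.zeros((3, 3), dtype=int)
    idx = {g: i for i, g in enumerate(GENOTYPES)}
    for key in sorted(set(cell_calls) & set(bulk_calls), key=VariantKey.sort_key):
        b = zygosity_call(bulk_calls[key], het_lower, het_upper)
        c = zygosity_call(cell_calls[key], het_lower, het_upper)
        matrix[idx[b], idx[c]] += 1
    return matrix
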
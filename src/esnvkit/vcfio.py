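"""VCF emission for filtered and merged call sets (pysam-backed).

Filtered per-aligner output carries the verdict in the FILTER column —
``PASS`` or a semicolon-joined list of failed criterion codes.  Merged
output carries INFO keys ``CONF`` (0/1/2), ``SUPP`` (supporting aligner
labels) and per-aligner depth/alt-depth mirrored into suffixed keys
(``DP_<aligner>``, ``AD_<aligner>``), plus the annotation keys ``REGION``,
``GENE``, ``KNOWN``, ``DOMAIN``, ``DELET`` when annotation is attached.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import pysam

from esnvkit.annotate import AnnotatedVariant
from esnvkit.filters import FILTER_CODES, FilterVerdict
from esnvkit.merge import MergedVariant
from esnvkit.site_features import SiteEvidence

_FILTER_DESCRIPTIONS = {
    "depth": "Total read depth below the minimum",
    "alt_depth": "Alternate-allele supporting reads below the minimum",
    "ratio": "Alternate-allele fraction at or below the coverage-dependent threshold",
    "strand_bias": "Strand-bias ratio at or below the coverage-dependent threshold",
    "rrps": "Read-position rank-sum outside the open (-8, 8) interval",
}


def _base_header(contigs: Sequence[str]) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for contig in contigs:
        header.contigs.add(contig)
    return header


def _contigs_of(chroms: Iterable[str]) -> list[str]:
    seen: dict[str, None] = {}
    for c in chroms:
        seen.setdefault(c)
    return list(seen)


def write_filtered_vcf(
    path: str, calls: Sequence[tuple[SiteEvidence, FilterVerdict]]
) -> None:
    """One record per site with verdict codes in FILTER and DP/AD in INFO."""
    header = _base_header(_contigs_of(e.chrom for e, _ in calls))
    for code in FILTER_CODES:
        header.filters.add(code, None, None, _FILTER_DESCRIPTIONS[code])
    header.info.add("DP", 1, "Integer", "Total read depth")
    header.info.add("AD", "R", "Integer", "Ref,alt supporting read counts")
    header.info.add("ALTF", 1, "Integer", "Forward-strand alt supporting reads")
    header.info.add("ALTR", 1, "Integer", "Reverse-strand alt supporting reads")
    header.info.add("ReadPosRankSum", 1, "Float", "Read-position rank-sum Z")
    with pysam.VariantFile(path, "w", header=header) as out:
        for ev, verdict in sorted(calls, key=lambda cv: (cv[0].chrom, cv[0].pos, cv[0].alt_base)):
            rec = out.new_record(
                contig=ev.chrom,
                start=ev.pos - 1,
                alleles=(ev.ref_base, ev.alt_base),
            )
            rec.info["DP"] = ev.total_depth
            rec.info["AD"] = (ev.total_depth - ev.alt_depth, ev.alt_depth)
            rec.info["ALTF"] = ev.alt_fwd
            rec.info["ALTR"] = ev.alt_rev
            if ev.rrps is not None:
                rec.info["ReadPosRankSum"] = ev.rrps
            failed = verdict.failed_codes()
            if failed:
                for code in failed:
                    rec.filter.add(code)
            else:
                rec.filter.add("PASS")
            out.write(rec)


def write_merged_vcf(
    path: str,
    merged: Sequence[MergedVariant],
    annotations: Sequence[AnnotatedVariant] | None = None,
) -> None:
    """Merged (optionally annotated) variants with confidence levels."""
    aligners = _contigs_of(
        label for mv in merged for label in mv.evidence
    )
    header = _base_header(_contigs_of(mv.key.chrom for mv in merged))
    header.info.add("CONF", 1, "Integer", "Confidence: 2 both aligners, 1 preferred only, 0 other only")
    header.info.add("SUPP", ".", "String", "Aligners whose evidence passed all filters")
    for aligner in aligners:
        header.info.add(f"DP_{aligner}", 1, "Integer", f"Total depth under {aligner}")
        header.info.add(f"AD_{aligner}", 1, "Integer", f"Alt depth under {aligner}")
    if annotations is not None:
        header.info.add("REGION", 1, "String", "Gene-model region class")
        header.info.add("GENE", 1, "String", "Gene symbol")
        header.info.add("KNOWN", 1, "String", "Known-variant identifier")
        header.info.add("DOMAIN", ".", "String", "Overlapping protein domains")
        header.info.add("DELET", 0, "Flag", "Deleteriousness score below 0.05")
        header.info.add("SYNONYMY", 1, "String", "synonymous/nonsynonymous/noncoding")
    ann_by_key = (
        {a.variant.key: a for a in annotations} if annotations is not None else {}
    )
    with pysam.VariantFile(path, "w", header=header) as out:
        for mv in merged:
            rec = out.new_record(
                contig=mv.key.chrom,
                start=mv.key.pos - 1,
                alleles=(mv.key.ref_base, mv.key.alt_base),
            )
            rec.info["CONF"] = mv.conf
            rec.info["SUPP"] = ",".join(mv.supporting_aligners)
            for aligner, (ev, _) in mv.evidence.items():
                rec.info[f"DP_{aligner}"] = ev.total_depth
                rec.info[f"AD_{aligner}"] = ev.alt_depth
            ann = ann_by_key.get(mv.key)
            if ann is not None:
                rec.info["REGION"] = ann.region_class
                if ann.gene:
                    rec.info["GENE"] = ann.gene
                rec.info["KNOWN"] = ann.known_id if ann.known_id else "novel"
                if ann.domain_hits:
                    rec.info["DOMAIN"] = ",".join(ann.domain_hits)
                if ann.deleterious:
                    rec.info["DELET"] = True
                rec.info["SYNONYMY"] = ann.synonymy
            out.write(rec)
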
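"""Per-site read evidence and the derived statistics consumed by the filters.

A *site* is one (chromosome, position, ref, alt) substitution observed in
RNA-Seq reads from one aligner.  Evidence is parsed either from samtools
``mpileup`` 6-column text (bases + qualities, with the usual ``^``/``$``/
indel/``*`` markers) or from VCF records carrying per-sample ``DP``/``AD``
(and ``ADF``/``ADR`` for the strand split).  Three statistics are derived:

* the alternate-allele fraction ``aa_i / t_i``,
* the strand-bias ratio ``min(aa_i+, aa_i-) / max(aa_i+, aa_i-)``,
* a Mann-Whitney rank-sum Z-score comparing within-read offsets of
  alt-supporting vs ref-supporting bases (extreme values flag alt bases
  clustered at read ends, a classic alignment-artifact signature).

Only single-nucleotide substitutions are emitted; indels present in pileup
text are consumed but never reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence, TextIO

import numpy as np
from scipy.stats import rankdata

VALID_BASES = frozenset("ACGT")


class PileupParseError(ValueError):
    """Raised when an mpileup line violates the pileup text format."""

    def __init__(self, message: str, line: str = "", column: int | None = None):
        loc = f" at column {column}" if column is not None else ""
        super().__init__(f"{message}{loc}: {line.rstrip()!r}")
        self.line = line
        self.column = column


class UndefinedRatioError(ZeroDivisionError):
    """A ratio was requested for a site with no qualifying reads."""


@dataclass
class SiteEvidence:
    """Read support for one candidate substitution under one aligner.

    ``total_depth`` (t_i) counts every surviving base call at the position —
    reference, the alternate under consideration, and any other alternate —
    while ``alt_depth`` (aa_i) counts only reads supporting ``alt_base``,
    split by strand into ``alt_fwd``/``alt_rev``.
    """

    chrom: str
    pos: int
    ref_base: str
    alt_base: str
    total_depth: int
    alt_depth: int
    alt_fwd: int
    alt_rev: int
    ref_read_positions: Optional[list[int]] = None
    alt_read_positions: Optional[list[int]] = None
    rrps: Optional[float] = None
    aligner_id: str = ""

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be 1-based positive, got {self.pos}")
        if self.ref_base not in VALID_BASES or self.alt_base not in VALID_BASES:
            raise ValueError(
                f"ref/alt must be one of A,C,G,T; got {self.ref_base}>{self.alt_base}"
            )
        if self.ref_base == self.alt_base:
            raise ValueError(f"ref and alt are identical ({self.ref_base})")
        if self.alt_fwd + self.alt_rev != self.alt_depth:
            raise ValueError(
                f"strand split {self.alt_fwd}+{self.alt_rev} != alt_depth {self.alt_depth}"
            )
        if self.alt_depth > self.total_depth:
            raise ValueError(
                f"alt_depth {self.alt_depth} exceeds total_depth {self.total_depth}"
            )
        if min(self.total_depth, self.alt_depth, self.alt_fwd, self.alt_rev) < 0:
            raise ValueError("read counts must be non-negative")


@dataclass
class PileupRecord:
    """One raw mpileup line, split into columns but not yet interpreted."""

    chrom: str
    pos: int
    ref_base: str
    depth_declared: int
    base_string: str
    quality_string: str


def allele_ratio(e: SiteEvidence) -> float:
    """Alternate-allele read fraction aa_i / t_i, in [0, 1]."""
    if e.total_depth == 0:
        raise UndefinedRatioError(
            f"allele ratio undefined at {e.chrom}:{e.pos} (total_depth == 0)"
        )
    return e.alt_depth / e.total_depth


def strand_bias_ratio(e: SiteEvidence) -> float:
    """min/max of forward- vs reverse-strand alt counts, in [0, 1].

    1.0 means perfectly balanced strands; 0.0 means one-sided support.
    """
    if e.alt_depth == 0:
        raise UndefinedRatioError(
            f"strand-bias ratio undefined at {e.chrom}:{e.pos} (alt_depth == 0)"
        )
    return min(e.alt_fwd, e.alt_rev) / max(e.alt_fwd, e.alt_rev)


def read_pos_rank_sum(
    ref_positions: Sequence[int], alt_positions: Sequence[int]
) -> Optional[float]:
    """Mann-Whitney rank-sum Z of alt vs ref within-read offsets.

    Midranks are used for ties and the variance carries the usual tie
    correction.  Returns ``None`` when either group is empty or the variance
    degenerates (all observations tied).  The sign is negative when the alt
    offsets rank lower than the ref offsets — with offsets measured from the
    nearer read end this means alt bases hug the read ends.
    """
    n_ref, n_alt = len(ref_positions), len(alt_positions)
    if n_ref == 0 or n_alt == 0:
        return None
    combined = np.concatenate(
        [np.asarray(ref_positions, dtype=float), np.asarray(alt_positions, dtype=float)]
    )
    ranks = rankdata(combined)
    rank_sum_alt = ranks[n_ref:].sum()
    u_alt = rank_sum_alt - n_alt * (n_alt + 1) / 2.0
    n = n_ref + n_alt
    mu = n_ref * n_alt / 2.0
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = float(((tie_counts**3) - tie_counts).sum())
    var = n_ref * n_alt / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return None
    return float((u_alt - mu) / math.sqrt(var))


def within_read_offset(cycle: int, read_length: int) -> int:
    """Distance of a base from the nearer read end.

    ``cycle`` is the 0-based position within the read.  Small offsets mean
    the base sits near the 5' or 3' end.
    """
    return min(cycle, read_length - 1 - cycle)


# ---------------------------------------------------------------------------
# samtools mpileup text parsing
# ---------------------------------------------------------------------------


def _scan_base_string(bases: str, line: str) -> list[tuple[str, bool]]:
    """Expand a pileup base column into (symbol, is_forward) pairs.

    Symbols returned: '.' for reference (either strand, strand encoded in the
    flag), 'A'/'C'/'G'/'T'/'N' for mismatches, '*' for a deletion
    placeholder.  Read-start (``^X``), read-end (``$``), indels
    (``+n<seq>``/``-n<seq>``) and reference skips (``<``/``>``) are consumed
    and do not produce a pair.
    """
    out: list[tuple[str, bool]] = []
    i = 0
    n = len(bases)
    while i < n:
        c = bases[i]
        if c == "^":
            if i + 1 >= n:
                raise PileupParseError("dangling '^' read-start marker", line, i)
            i += 2  # skip the encoded mapping quality
            continue
        if c == "$":
            i += 1
            continue
        if c in "+-":
            j = i + 1
            while j < n and bases[j].isdigit():
                j += 1
            if j == i + 1:
                raise PileupParseError("indel length not parseable", line, i)
            length = int(bases[i + 1 : j])
            if j + length > n:
                raise PileupParseError("indel sequence truncated", line, i)
            i = j + length
            continue
        if c == ".":
            out.append((".", True))
        elif c == ",":
            out.append((".", False))
        elif c in "<>":
            # reference skip (spliced alignment) — no base call, no quality?
            # samtools emits a quality char for these, so keep a placeholder
            out.append(("skip", c == ">"))
        elif c == "*" or c == "#":
            out.append(("*", c == "*"))
        elif c.upper() in "ACGTN":
            out.append((c.upper(), c.isupper()))
        else:
            raise PileupParseError(f"unrecognised pileup symbol {c!r}", line, i)
        i += 1
    return out


def parse_mpileup_line(
    line: str, min_base_quality: int = 13
) -> list[SiteEvidence]:
    """Parse one mpileup text line into per-alt-allele :class:`SiteEvidence`.

    Bases with quality <= ``min_base_quality`` are dropped from every count
    (the conventional screen retains quality strictly greater than 13).
    Mapping-quality filtering is the pileup producer's job, not ours.
    Deletion placeholders (``*``) and reference skips count toward nothing.
    One record is emitted per distinct A/C/G/T alternate with at least one
    surviving supporting read; records carry no read positions (mpileup text
    does not expose them), so ``rrps`` is left missing.
    """
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 6:
        raise PileupParseError(
            f"expected >=6 tab-separated columns, got {len(fields)}", line
        )
    chrom, pos_s, ref, depth_s, bases, quals = fields[:6]
    try:
        pos = int(pos_s)
        int(depth_s)
    except ValueError as exc:
        raise PileupParseError("position/depth column not an integer", line) from exc
    calls = _scan_base_string(bases, line)
    if len(calls) != len(quals):
        raise PileupParseError(
            f"{len(calls)} base symbols but {len(quals)} quality characters "
            "after marker stripping",
            line,
        )
    ref_u = ref.upper()
    total = 0
    # per-alt [fwd, rev]
    alt_counts: dict[str, list[int]] = {}
    for (symbol, is_fwd), qc in zip(calls, quals):
        if symbol in ("*", "skip"):
            continue
        if ord(qc) - 33 <= min_base_quality:
            continue
        total += 1
        if symbol == "." or symbol == "N" or symbol == ref_u:
            continue
        counts = alt_counts.setdefault(symbol, [0, 0])
        counts[0 if is_fwd else 1] += 1
    if ref_u not in VALID_BASES:
        return []  # cannot form substitution evidence on an N/ambiguous ref
    out = []
    for alt in sorted(alt_counts):
        fwd, rev = alt_counts[alt]
        out.append(
            SiteEvidence(
                chrom=chrom,
                pos=pos,
                ref_base=ref_u,
                alt_base=alt,
                total_depth=total,
                alt_depth=fwd + rev,
                alt_fwd=fwd,
                alt_rev=rev,
            )
        )
    return out


def parse_mpileup(
    handle: Iterable[str], min_base_quality: int = 13, aligner_id: str = ""
) -> Iterator[SiteEvidence]:
    """Stream :class:`SiteEvidence` records from mpileup text lines."""
    for line in handle:
        if not line.strip():
            continue
        for ev in parse_mpileup_line(line, min_base_quality=min_base_quality):
            ev.aligner_id = aligner_id
            yield ev


# ---------------------------------------------------------------------------
# VCF evidence
# ---------------------------------------------------------------------------


def read_vcf_evidence(path: str, aligner_id: str = "") -> list[SiteEvidence]:
    """Extract per-site evidence from a VCF produced by an upstream caller.

    Per-sample ``DP`` and ``AD`` (ref,alt) are required; the strand split is
    taken from ``ADF``/``ADR`` when present, otherwise the alt reads are
    split as evenly as possible (balanced assumption, never strand-biased).
    An INFO ``ReadPosRankSum`` is taken verbatim instead of recomputed.
    Multi-allelic records are decomposed into biallelic evidence.
    """
    from cyvcf2 import VCF

    out: list[SiteEvidence] = []
    vcf = VCF(path)
    for var in vcf:
        if var.REF not in VALID_BASES:
            continue
        ad = var.format("AD")
        adf = var.format("ADF")
        adr = var.format("ADR")
        dp = var.format("DP")
        rrps = var.INFO.get("ReadPosRankSum")
        for ai, alt in enumerate(var.ALT):
            if alt not in VALID_BASES:
                continue
            alt_col = ai + 1
            alt_depth = int(ad[0][alt_col]) if ad is not None else 0
            if dp is not None:
                total = int(np.asarray(dp).ravel()[0])
            elif ad is not None:
                total = int(sum(max(int(x), 0) for x in ad[0]))
            else:
                total = alt_depth
            if adf is not None and adr is not None:
                fwd = int(adf[0][alt_col])
                rev = int(adr[0][alt_col])
            else:
                fwd = alt_depth // 2
                rev = alt_depth - fwd
            out.append(
                SiteEvidence(
                    chrom=var.CHROM,
                    pos=var.POS,
                    ref_base=var.REF,
                    alt_base=alt,
                    total_depth=max(total, alt_depth),
                    alt_depth=alt_depth,
                    alt_fwd=fwd,
                    alt_rev=rev,
                    rrps=None if rrps is None else float(rrps),
                    aligner_id=aligner_id,
                )
            )
    return out


# ---------------------------------------------------------------------------
# site-evidence TSV dialect (the pipeline's internal interchange format)
# ---------------------------------------------------------------------------

TSV_COLUMNS = ("chrom", "pos", "ref", "alt", "t", "aa", "aa_fwd", "aa_rev", "rrps", "aligner_id")


def write_evidence_tsv(records: Iterable[SiteEvidence], handle: TextIO) -> None:
    """Write the documented 10-column tab-separated evidence table.

    Positions are 1-based; a missing rank-sum is written as ``.``.
    """
    handle.write("#" + "\t".join(TSV_COLUMNS) + "\n")
    for e in records:
        rrps = "." if e.rrps is None else f"{e.rrps:.4f}"
        handle.write(
            f"{e.chrom}\t{e.pos}\t{e.ref_base}\t{e.alt_base}\t{e.total_depth}\t"
            f"{e.alt_depth}\t{e.alt_fwd}\t{e.alt_rev}\t{rrps}\t{e.aligner_id}\n"
        )


def read_evidence_tsv(handle: Iterable[str]) -> list[SiteEvidence]:
    out = []
    for line in handle:
        if not line.strip() or line.startswith("#"):
            continue
        f = line.rstrip("\n").split("\t")
        if len(f) < 10:
            raise ValueError(f"evidence TSV needs 10 columns, got {len(f)}: {line!r}")
        out.append(
            SiteEvidence(
                chrom=f[0],
                pos=int(f[1]),
                ref_base=f[2],
                alt_base=f[3],
                total_depth=int(f[4]),
                alt_depth=int(f[5]),
                alt_fwd=int(f[6]),
                alt_rev=int(f[7]),
                rrps=None if f[8] == "." else float(f[8]),
                aligner_id=f[9],
            )
        )
    return out
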
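"""Pileup parsing and the per-site derived statistics."""

import math
import subprocess
from collections import Counter

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from esnvkit.site_features import (
    PileupParseError,
    SiteEvidence,
    UndefinedRatioError,
    allele_ratio,
    parse_mpileup_line,
    read_evidence_tsv,
    read_pos_rank_sum,
    strand_bias_ratio,
    within_read_offset,
    write_evidence_tsv,
)

from conftest import make_evidence


def rank_sum_oracle(ref, alt):
    """Brute-force Mann-Whitney Z: U by pairwise comparison, tie-corrected."""
    n1, n2 = len(ref), len(alt)
    if n1 == 0 or n2 == 0:
        return None
    u = sum(1.0 if a > r else 0.5 if a == r else 0.0 for a in alt for r in ref)
    n = n1 + n2
    mu = n1 * n2 / 2.0
    ties = Counter(list(ref) + list(alt))
    tie_term = sum(t**3 - t for t in ties.values())
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return None
    return (u - mu) / math.sqrt(var)


class TestPileupParsing:
    def line(self, bases, quals, ref="C", chrom="chr1", pos=42):
        return f"{chrom}\t{pos}\t{ref}\t{len(quals)}\t{bases}\t{quals}"

    def test_mixed_ref_and_alt_with_strand_split(self):
        out = parse_mpileup_line(self.line(".,.AAa", "IIIIII"))
        assert len(out) == 1
        e = out[0]
        assert (e.total_depth, e.alt_depth, e.alt_fwd, e.alt_rev) == (6, 3, 2, 1)
        assert (e.ref_base, e.alt_base) == ("C", "A")

    def test_markers_carry_no_base_calls(self):
        out = parse_mpileup_line(self.line("^~.$,", "II"))
        assert out == []  # two ref reads, no alt allele emitted
        # depth check via an alt on the same line
        out = parse_mpileup_line(self.line("^~.$,T", "III"))
        assert out[0].total_depth == 3

    def test_low_quality_ref_base_dropped(self):
        # '#' is Phred 2: the ref base is screened out, alt at Q40 survives
        (e,) = parse_mpileup_line(self.line(".A", "#I"))
        assert (e.total_depth, e.alt_depth) == (1, 1)

    def test_quality_screen_is_strict(self):
        # '.' is Phred 13 == threshold -> excluded; '/' is Phred 14 -> kept
        (e,) = parse_mpileup_line(self.line("AA", "./"))
        assert (e.total_depth, e.alt_depth) == (1, 1)

    def test_indels_consumed_never_reported(self):
        (e,) = parse_mpileup_line(self.line(".+2AC,G", "III"))
        assert (e.total_depth, e.alt_depth, e.alt_base) == (3, 1, "G")

    def test_deletion_placeholder_counts_toward_nothing(self):
        out = parse_mpileup_line(self.line(".*,", "III"))
        assert out == []
        (e,) = parse_mpileup_line(self.line(".*,t", "IIII"))
        assert (e.total_depth, e.alt_depth, e.alt_rev) == (3, 1, 1)

    def test_two_distinct_alt_alleles_two_records(self):
        out = parse_mpileup_line(self.line(".AaT", "IIII"))
        assert [(e.alt_base, e.alt_depth, e.alt_fwd) for e in out] == [
            ("A", 2, 1),
            ("T", 1, 1),
        ]
        assert all(e.total_depth == 4 for e in out)

    def test_other_alt_counts_toward_total_not_alt(self):
        out = parse_mpileup_line(self.line(".AAAAG", "IIIIII"))
        a = next(e for e in out if e.alt_base == "A")
        assert (a.total_depth, a.alt_depth) == (6, 4)

    @pytest.mark.parametrize(
        "bases,quals",
        [
            ("^", "I"),  # dangling read-start marker
            (".+xAC", "I"),  # indel length not parseable
            (".,", "I"),  # base/quality length mismatch
        ],
    )
    def test_malformed_lines_raise_parse_error(self, bases, quals):
        with pytest.raises(PileupParseError):
            parse_mpileup_line(self.line(bases, quals))

    def test_parsed_depth_bounded_by_declared_depth(self):
        line = self.line(".,.,AAa*", "IIIIIII#")
        (e,) = parse_mpileup_line(line)
        declared = int(line.split("\t")[3])
        assert e.total_depth <= declared


class TestSamtoolsRoundTrip:
    """Reconcile the parser against samtools mpileup on a constructed SAM."""

    def test_counts_match_known_read_layout(self, tmp_path):
        ref_seq = "A" * 60
        fasta = tmp_path / "ref.fa"
        fasta.write_text(">chr1\n" + ref_seq + "\n")
        reads = []
        # 4 forward ref reads, 2 forward alt-C reads, 3 reverse alt-C reads
        for i in range(4):
            reads.append((f"r{i}", 0, 21, "A" * 10))
        for i in range(2):
            reads.append((f"c{i}", 0, 21, "A" * 4 + "C" + "A" * 5))
        for i in range(3):
            reads.append((f"d{i}", 16, 21, "A" * 4 + "C" + "A" * 5))
        sam = tmp_path / "aln.sam"
        with open(sam, "w") as fh:
            fh.write("@HD\tVN:1.6\tSO:coordinate\n@SQ\tSN:chr1\tLN:60\n")
            for name, flag, pos, seq in reads:
                fh.write(
                    f"{name}\t{flag}\tchr1\t{pos}\t60\t10M\t*\t0\t0\t{seq}\t{'I'*10}\n"
                )
        out = subprocess.run(
            ["samtools", "mpileup", "-B", "-Q", "0", "-f", str(fasta), str(sam)],
            capture_output=True,
            text=True,
            check=True,
        )
        by_pos = {}
        for line in out.stdout.splitlines():
            for ev in parse_mpileup_line(line):
                by_pos[ev.pos] = ev
        e = by_pos[25]  # variant column: read offset 4 from pos 21
        assert (e.ref_base, e.alt_base) == ("A", "C")
        assert (e.total_depth, e.alt_depth, e.alt_fwd, e.alt_rev) == (9, 5, 2, 3)
        assert 24 not in by_pos  # all-reference columns emit no alt evidence


class TestDerivedStatistics:
    @pytest.mark.parametrize(
        "aa,t,expected", [(5, 50, 0.1), (0, 10, 0.0), (7, 7, 1.0)]
    )
    def test_allele_ratio(self, aa, t, expected):
        e = make_evidence(total_depth=t, alt_depth=aa, alt_fwd=aa, alt_rev=0)
        assert allele_ratio(e) == pytest.approx(expected)

    def test_allele_ratio_undefined_at_zero_depth(self):
        e = make_evidence(total_depth=0, alt_depth=0, alt_fwd=0, alt_rev=0)
        with pytest.raises(UndefinedRatioError):
            allele_ratio(e)

    @pytest.mark.parametrize(
        "fwd,rev,expected", [(4, 4, 1.0), (2, 8, 0.25), (0, 5, 0.0)]
    )
    def test_strand_bias_ratio(self, fwd, rev, expected):
        e = make_evidence(
            total_depth=50, alt_depth=fwd + rev, alt_fwd=fwd, alt_rev=rev
        )
        assert strand_bias_ratio(e) == pytest.approx(expected)

    def test_strand_bias_undefined_without_alt_reads(self):
        e = make_evidence(alt_depth=0, alt_fwd=0, alt_rev=0)
        with pytest.raises(UndefinedRatioError):
            strand_bias_ratio(e)

    @settings(max_examples=200, derandomize=True)
    @given(
        t=st.integers(min_value=1, max_value=500),
        aa=st.integers(min_value=0, max_value=500),
        fwd=st.integers(min_value=0, max_value=500),
    )
    def test_strand_bias_swap_invariance_and_ratio_monotonicity(self, t, aa, fwd):
        aa = min(aa, t)
        fwd = min(fwd, aa)
        e = make_evidence(total_depth=t, alt_depth=aa, alt_fwd=fwd, alt_rev=aa - fwd)
        swapped = make_evidence(
            total_depth=t, alt_depth=aa, alt_fwd=aa - fwd, alt_rev=fwd
        )
        if aa > 0:
            assert strand_bias_ratio(e) == pytest.approx(strand_bias_ratio(swapped))
        if aa < t:
            bumped = make_evidence(
                total_depth=t, alt_depth=aa + 1, alt_fwd=fwd + 1, alt_rev=aa - fwd
            )
            assert allele_ratio(bumped) >= allele_ratio(e)


class TestReadPosRankSum:
    def test_identical_distributions_give_zero(self):
        assert read_pos_rank_sum([10, 20, 30], [10, 20, 30]) == pytest.approx(0.0)

    def test_empty_group_is_missing(self):
        assert read_pos_rank_sum([], [5, 6]) is None
        assert read_pos_rank_sum([5, 6], []) is None

    def test_all_tied_is_missing(self):
        assert read_pos_rank_sum([7, 7], [7, 7, 7]) is None

    def test_separated_groups_match_enumeration_oracle(self):
        ref, alt = [30, 40, 50, 60], [1, 2, 3, 4]
        z = read_pos_rank_sum(ref, alt)
        assert z == pytest.approx(rank_sum_oracle(ref, alt), abs=1e-9)
        assert z < 0  # alt clustered low -> negative sign convention

    @settings(max_examples=300, derandomize=True)
    @given(
        ref=st.lists(st.integers(min_value=0, max_value=49), max_size=10),
        alt=st.lists(st.integers(min_value=0, max_value=49), max_size=10),
    )
    def test_agrees_with_oracle_on_small_lists(self, ref, alt):
        z = read_pos_rank_sum(ref, alt)
        expected = rank_sum_oracle(ref, alt)
        if expected is None:
            assert z is None
        else:
            assert z == pytest.approx(expected, abs=1e-9)

    @settings(max_examples=100, derandomize=True)
    @given(
        ref=st.lists(st.integers(min_value=0, max_value=30), min_size=1, max_size=8),
        alt=st.lists(st.integers(min_value=0, max_value=30), min_size=1, max_size=8),
    )
    def test_u_statistic_agrees_with_scipy(self, ref, alt):
        from scipy.stats import mannwhitneyu

        u_brute = sum(
            1.0 if a > r else 0.5 if a == r else 0.0 for a in alt for r in ref
        )
        u_scipy = mannwhitneyu(alt, ref, alternative="two-sided").statistic
        assert u_brute == pytest.approx(u_scipy)

    def test_within_read_offset_folds_both_ends(self):
        assert within_read_offset(0, 100) == 0
        assert within_read_offset(99, 100) == 0
        assert within_read_offset(49, 100) == 49
        assert within_read_offset(95, 100) == 4


class TestEvidenceTsvRoundTrip:
    def test_round_trip_preserves_records(self, tmp_path):
        records = [
            make_evidence(pos=10, rrps=None),
            make_evidence(pos=11, alt_base="T", rrps=-2.5),
        ]
        p = tmp_path / "ev.tsv"
        with open(p, "w") as fh:
            write_evidence_tsv(records, fh)
        with open(p) as fh:
            back = read_evidence_tsv(fh)
        assert [(e.chrom, e.pos, e.alt_base, e.total_depth, e.rrps) for e in back] == [
            ("chr1", 10, "G", 50, None),
            ("chr1", 11, "T", 50, -2.5),
        ]


class TestEvidenceInvariants:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(alt_fwd=3, alt_rev=3, alt_depth=5),  # strand split mismatch
            dict(alt_depth=60),  # alt exceeds total
            dict(pos=0),
            dict(ref_base="G"),  # ref == alt
            dict(ref_base="N"),
        ],
    )
    def test_invalid_evidence_rejected(self, kwargs):
        with pytest.raises(ValueError):
            make_evidence(**kwargs)
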
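# Methods

## Evidence model

The unit of analysis is a per-site, per-aligner evidence record for a
single-nucleotide substitution: chromosome, 1-based position, reference and
alternate base (both in {A, C, G, T}), total surviving read depth
*t<sub>i</sub>*, alternate-supporting depth *aa<sub>i</sub>* with its
forward/reverse strand split, optional within-read offset lists for ref-
and alt-supporting bases, and an optional precomputed read-position
rank-sum. Evidence comes from samtools-mpileup text, from VCF records
carrying per-sample DP/AD (ADF/ADR for the strand split, INFO
ReadPosRankSum taken verbatim when present), or from the package's own
10-column TSV interchange format. Mapping-quality screening is the pileup
producer's responsibility; the parser applies only the base-quality screen.

Pileup interpretation rules: bases with Phred quality ≤ 13 are dropped from
every count (strictly greater than 13 is retained); `^X`/`$` read
boundaries and `+n…/-n…` indels are consumed without producing base calls;
the `*` deletion placeholder and `<`/`>` reference skips count toward
nothing; `N` calls count toward total depth but can never be an alternate
allele; reads supporting a third allele count toward *t<sub>i</sub>* but
not *aa<sub>i</sub>*, since *t<sub>i</sub>* is the total read count at the
position. Only substitutions are emitted — indels are out of scope.

## Read-position rank-sum

The statistic is a Mann–Whitney Z-score comparing alt- vs ref-supporting
within-read offsets, with midranks for ties and the tie-corrected
variance:

Z = (U_alt − n₁n₂/2) / √( n₁n₂/12 · [ (n+1) − Σ(tₖ³−tₖ)/(n(n−1)) ] )

It is *missing* (never a number) when either group is empty or every
observation is tied; a missing value passes the filter, because upstream
callers omit the statistic exactly at such sites and rejecting them would
discard legitimate homozygous calls. Offsets are measured from the
*nearer* read end (min(cycle, L−1−cycle) for read length L), since
end-clustering is the artifact the filter targets; the sign is therefore
negative when alt bases hug the read ends. Tests verify agreement to
1e−9 with a brute-force U-statistic enumeration, and the U statistic
itself against `scipy.stats.mannwhitneyu`; the production path uses only
`scipy.stats.rankdata` for midranks.

## Filter battery

Five criteria, all evaluated unconditionally so verdicts are fully
reportable: t ≥ 4; aa ≥ 4 (single-cell preset: 2); allele fraction
aa/t > 0.1, or > 0.05 once t ≥ 100; strand-bias ratio
min/max(aa⁺, aa⁻) above the same coverage-switched thresholds; rank-sum
inside the open interval (−8, 8). Choices worth stating:

* The allele-fraction formula is alt/total (the definition of
  Ratio<sub>i</sub>), not alt/ref.
* The coverage regime switches at t ≥ 100 for both the allele-fraction and
  the strand-bias thresholds; the descriptions of the two criteria differ
  on whether 100 itself is "high", and a unified boundary keeps the
  battery internally consistent, with negligible effect at the boundary.
* All fraction comparisons are strict (a ratio of exactly 0.1 at low
  coverage fails); the depth minima t ≥ 4 and aa ≥ 4 are the ≥-form of the
  "< 4 eliminated" / "d_alt > 3" phrasing.
* aa = 0 is treated as total strand bias (the criterion fails), and t = 0
  fails the depth criterion, so degenerate records never pass.

Monotonicity (tightening any threshold never admits a site) is enforced by
a property test.

## Two-aligner merge

Calls are matched on the exact biallelic key (chrom, pos, ref, alt);
multi-allelic VCF records are decomposed before matching. CONF = 2
requires the evidence to pass all filters under *both* aligners — a site
called by both but surviving filters under one counts as single-aligner
support (CONF = 1 if that aligner is the preferred one, else CONF = 0).
Evidence from a non-supporting aligner is attached to the merged record
for reporting but never averaged; per-aligner depths are emitted side by
side because no combination rule is defined for them. For N > 2 aligners
a plain supporter count per key replaces the three-level code.

## Annotation

Annotation is deliberately reduced to pure joins against user-supplied
tables — gene model (1-based TSV or BED accepted), known-variant table,
deleteriousness scores, domain intervals pre-projected to genomic
coordinates — so results are a function of explicit inputs rather than of
live database versions. Region precedence follows the convention of
widely used annotators (exonic > ncRNA > UTR5 > UTR3 > intronic >
upstream > downstream); ties at equal precedence resolve to the
lexicographically first gene for determinism. The deleterious flag is
strict (score < 0.05). Synonymy is called only when a codon context
(codon, in-codon frame, strand) is supplied; without it the label is
"noncoding" rather than a guess. Splice-site categories are not modelled.

## Benchmarking

Chip truth assays a fixed locus panel, so calls are judged only at
assayed positions and a chip variant counts as recoverable only when
expressed (> 3 alternate RNA reads at the locus). Exome (WES) truth can
only adjudicate positions it covered at ≥ 4X; calls below that are
excluded from the precision denominator and reported as a separate
no-coverage count. TP requires the exact alternate allele at a
non-hom-ref truth locus; a call at a hom-ref or allele-discordant locus
is FP, and an expressed truth locus whose allele no call recovered is FN.
This keeps the conservation identities TP + FP = assayable calls and
TP + FN = expressed truth exact, which the scorer's tests assert, along
with the closed form F = 2TP/((TP+FP)+(TP+FN)).

Zygosity is called from the alt-read fraction f: hom-ref below 0.1, het
in [0.1, 0.9], hom-alt above 0.9. The 0.1/0.9 bounds are a package
choice aligned with the low-coverage allele-fraction threshold, and are
configurable. Reported percentages round half-up to one decimal and
fractions to three decimals, matching conventional reporting granularity.

## Synthetic fixtures

The generator plants `n_sites` (default 10,000) sites on a synthetic
two-chromosome genome with a programmatically laid-out, non-overlapping
gene model, so region classification has exact ground truth. Default
conditions: 90% clean variants (2/3 het with alt fraction ~N(0.5, 0.05)
clipped to [0.35, 0.65], 1/3 hom-alt with fraction in [0.95, 1]) at
10–120X depth, 5% strand-biased artifacts, 5% end-clustered artifacts,
two aligners observing each site concordantly with probability 0.95
(otherwise one aligner chosen by coin flip), half of the clean variants
carrying a known-variant identifier, and transitions drawn with
probability 0.75 so the expected ts/tv of a planted call set is 3.0 —
the value typical of validated human call sets.

Each artifact class is engineered to fail exactly one criterion while
passing the other four, which is what makes ledger reconciliation exact:

* strand-biased sites put every alternate read on one strand;
* end-clustered sites draw alternate offsets from the outermost read
  decile (nearer-end offsets 0–4 of a 100 bp read) and reference offsets
  from the read interior (5–49), giving complete separation; they are
  planted at 140–220X with alt fraction clipped to [0.40, 0.50] because a
  rank-sum |Z| > 8 is mathematically unreachable in small samples (for
  equal group sizes m the maximum |Z| is ≈ √(1.5 m), requiring m > 42 per
  group) — under complete separation Z = −√(3·n₁n₂/(n+1)), which at these
  depths is ≤ −10 deterministically;
* low-alt-depth sites (off by default) carry 2–3 supporting reads with
  total depth below 10·aa so the allele fraction still clears 0.1, and
  balanced strands, failing only the alt-depth minimum.

Clean sites are planted firmly inside the filter envelope (alt depth at
least max(4, ⌊0.1t⌋+1), near-even strand splits, uniform read offsets), so
every clean record passes all filters and every artifact record fails its
intended one — the end-to-end acceptance run reconciles both statements
against the ledger at 10,000 sites.

The single-cell preset lowers depth to 4–12X (mean ≈ 7), lowers the
planted alt-depth floor to 2, and drops one allele (coin flip which) at
half of the het sites, reproducing the bulk-het → {hom-ref, het, hom-alt}
scatter characteristic of single-cell libraries.

What the generator does *not* emulate — and hence what passing tests do
not establish about real data: alignment-dependent evidence divergence
between aligners (per-aligner draws are independent but share the planted
category, so an artifact never fails different filters under different
aligners), sequencing-error alternate reads at true hom-ref sites,
RNA editing, allele-specific expression, splice-junction artifacts, and
reference bias. Benchmark metrics on synthetic data are therefore
generator-relative, not estimates of performance on real libraries.

## Problem sizes and determinism

All randomness flows through `numpy.random.default_rng` seeded from a
single integer; identical seeds give byte-identical fixture files. The
test suite runs the full pipeline at 10,000 sites (seconds on one core)
and the acceptance script repeats it at the same size with the
caller-supplied seed; unit and property tests use hundreds of sites,
which is ample for the exact (non-stochastic) reconciliation checks that
dominate the suite.
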
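"""Coverage-dependent hard filters for candidate expressed SNVs.

Five criteria are evaluated per site, all unconditionally so a verdict is
fully reportable:

==============  ==============================================================
depth           total read depth t_i >= ``min_total_depth`` (default 4)
alt_depth       alt-supporting reads aa_i >= ``min_alt_depth`` (default 4;
                the single-cell preset lowers this to 2)
ratio           alt fraction aa_i/t_i strictly > 0.1 below the coverage
                switch, strictly > 0.05 at high coverage (t_i >= 100)
strand_bias     min/max strand split of alt reads strictly > the same
                regime-dependent thresholds
rrps            read-position rank-sum Z strictly inside (-8, +8); a missing
                value passes (upstream callers omit the statistic at sites
                lacking ref or alt reads)
==============  ==============================================================

The high-coverage relaxation of the allele-fraction threshold exists to keep
low-frequency (subclonal) events detectable where coverage supports them.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace
from typing import Mapping

from esnvkit.site_features import SiteEvidence

FILTER_CODES = ("depth", "alt_depth", "ratio", "strand_bias", "rrps")


@dataclass(frozen=True)
class FilterConfig:
    min_total_depth: int = 4
    min_alt_depth: int = 4
    depth_switch: int = 100
    ratio_low_cov: float = 0.1
    ratio_high_cov: float = 0.05
    sbs_low_cov: float = 0.1
    sbs_high_cov: float = 0.05
    rrps_lower: float = -8.0
    rrps_upper: float = 8.0

    def __post_init__(self) -> None:
        if not (0 < self.ratio_high_cov <= self.ratio_low_cov <= 1):
            raise ValueError("require 0 < ratio_high_cov <= ratio_low_cov <= 1")
        if not (0 < self.sbs_high_cov <= self.sbs_low_cov <= 1):
            raise ValueError("require 0 < sbs_high_cov <= sbs_low_cov <= 1")
        if not self.rrps_lower < self.rrps_upper:
            raise ValueError("require rrps_lower < rrps_upper")

    @classmethod
    def single_cell(cls, **overrides) -> "FilterConfig":
        """Preset for shallow single-cell libraries: alt-depth minimum of 2.

        Differs from the default configuration only in ``min_alt_depth``.
        """
        overrides.setdefault("min_alt_depth", 2)
        return cls(**overrides)

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, object]) -> "FilterConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown filter config keys: {sorted(unknown)}")
        int_fields = {"min_total_depth", "min_alt_depth", "depth_switch"}
        kwargs = {
            name: (int(value) if name in int_fields else float(value))
            for name, value in mapping.items()
        }
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str) -> "FilterConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"filter config {path} must be a key: value mapping")
        return cls.from_mapping(data)

    def with_overrides(self, **kwargs) -> "FilterConfig":
        kwargs = {k: v for k, v in kwargs.items() if v is not None}
        return replace(self, **kwargs)


@dataclass(frozen=True)
class FilterVerdict:
    pass_depth: bool
    pass_alt_depth: bool
    pass_ratio: bool
    pass_strand_bias: bool
    pass_rrps: bool

    @property
    def pass_all(self) -> bool:
        return (
            self.pass_depth
            and self.pass_alt_depth
            and self.pass_ratio
            and self.pass_strand_bias
            and self.pass_rrps
        )

    def failed_codes(self) -> list[str]:
        """Criterion codes that failed, for a VCF FILTER column."""
        flags = (
            self.pass_depth,
            self.pass_alt_depth,
            self.pass_ratio,
            self.pass_strand_bias,
            self.pass_rrps,
        )
        return [code for code, ok in zip(FILTER_CODES, flags) if not ok]

    def filter_field(self) -> str:
        codes = self.failed_codes()
        return "PASS" if not codes else ";".join(codes)


def apply_filters(e: SiteEvidence, cfg: FilterConfig | None = None) -> FilterVerdict:
    """Evaluate all five criteria on one site's evidence.

    The ratio and strand-bias thresholds switch to their high-coverage
    values when t_i >= ``depth_switch``; the comparison itself is strict
    (a ratio exactly at the threshold fails).  Degenerate evidence with
    t_i == 0 fails the depth criterion (and the ratio criterion, which it
    cannot satisfy); aa_i == 0 is treated as total strand bias.
    """
    cfg = cfg or FilterConfig()
    high_cov = e.total_depth >= cfg.depth_switch
    ratio_thr = cfg.ratio_high_cov if high_cov else cfg.ratio_low_cov
    sbs_thr = cfg.sbs_high_cov if high_cov else cfg.sbs_low_cov

    pass_depth = e.total_depth >= cfg.min_total_depth
    pass_alt_depth = e.alt_depth >= cfg.min_alt_depth
    if e.total_depth > 0:
        pass_ratio = (e.alt_depth / e.total_depth) > ratio_thr
    else:
        pass_ratio = False
    if e.alt_depth > 0:
        sbs = min(e.alt_fwd, e.alt_rev) / max(e.alt_fwd, e.alt_rev)
    else:
        sbs = 0.0
    pass_strand_bias = sbs > sbs_thr
    pass_rrps = e.rrps is None or (cfg.rrps_lower < e.rrps < cfg.rrps_upper)

    return FilterVerdict(
        pass_depth=pass_depth,
        pass_alt_depth=pass_alt_depth,
        pass_ratio=pass_ratio,
        pass_strand_bias=pass_strand_bias,
        pass_rrps=pass_rrps,
    )


def filter_call_set(
    records: list[SiteEvidence], cfg: FilterConfig | None = None
) -> list[tuple[SiteEvidence, FilterVerdict]]:
    """Apply the battery to a whole per-aligner call set."""
    cfg = cfg or FilterConfig()
    return [(e, apply_filters(e, cfg)) for e in records]
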
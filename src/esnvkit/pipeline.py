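"""End-to-end convenience wrappers: evidence -> filters -> merge."""

from __future__ import annotations

from typing import Mapping, Sequence

from esnvkit.filters import FilterConfig, filter_call_set
from esnvkit.merge import MergedVariant, merge_call_sets
from esnvkit.site_features import SiteEvidence


def call_variants(
    evidence_by_aligner: Mapping[str, Sequence[SiteEvidence]],
    preferred: str,
    filter_config: FilterConfig | None = None,
) -> list[MergedVariant]:
    """Filter each aligner's evidence and merge into confidence levels."""
    cfg = filter_config or FilterConfig()
    filtered = {
        label: filter_call_set(list(records), cfg)
        for label, records in evidence_by_aligner.items()
    }
    return merge_call_sets(filtered, preferred=preferred)
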
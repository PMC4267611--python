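"""Cross-aligner merging of filtered call sets into confidence levels.

RNA-Seq aligners disagree most where it matters — spliced reads, repeats,
pseudogenes — so agreement between two independent aligners is the strongest
single signal that a candidate eSNV is not a mapping artifact.  A merged
variant carries:

* ``conf = 2`` — passed every filter under both aligners,
* ``conf = 1`` — passed only under the user-designated *preferred* aligner,
* ``conf = 0`` — passed only under the other aligner.

Evidence from an aligner that called the site but failed filters is attached
for reporting and does not count as support.  For more than two aligners a
plain supporter count is reported instead of the three-level code.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

from esnvkit.filters import FilterVerdict
from esnvkit.site_features import SiteEvidence


class VariantKey(NamedTuple):
    """Biallelic variant identity; totally ordered by (chrom, pos, alt)."""

    chrom: str
    pos: int
    ref_base: str
    alt_base: str

    @classmethod
    def of(cls, e: SiteEvidence) -> "VariantKey":
        return cls(e.chrom, e.pos, e.ref_base, e.alt_base)

    def sort_key(self) -> tuple[str, int, str]:
        return (self.chrom, self.pos, self.alt_base)


# one aligner's view of one site: evidence plus its filter verdict
FilteredCall = tuple[SiteEvidence, FilterVerdict]
CallSet = Sequence[FilteredCall]


@dataclass
class MergedVariant:
    key: VariantKey
    conf: int
    supporting_aligners: list[str]
    evidence: dict[str, FilteredCall] = field(default_factory=dict)

    @property
    def concordance_count(self) -> int:
        return len(self.supporting_aligners)


class MergeInputError(ValueError):
    pass


def _index_call_set(label: str, calls: CallSet) -> dict[VariantKey, FilteredCall]:
    index: dict[VariantKey, FilteredCall] = {}
    for ev, verdict in calls:
        key = VariantKey.of(ev)
        if key in index:
            raise MergeInputError(f"duplicate key {key} in call set {label!r}")
        index[key] = (ev, verdict)
    return index


def merge_call_sets(
    call_sets: Mapping[str, CallSet], preferred: str
) -> list[MergedVariant]:
    """Merge exactly two per-aligner filtered call sets.

    The output contains every (chrom, pos, ref, alt) key that passes all
    filters in at least one set, each exactly once, sorted by key.  A site
    present in both inputs but filter-passing in only one counts as
    single-aligner support.
    """
    if len(call_sets) != 2:
        raise MergeInputError(
            f"two-aligner merge needs exactly 2 call sets, got {len(call_sets)}"
        )
    if preferred not in call_sets:
        raise MergeInputError(
            f"preferred aligner {preferred!r} not among inputs {sorted(call_sets)}"
        )
    indexed = {label: _index_call_set(label, cs) for label, cs in call_sets.items()}
    other = next(label for label in call_sets if label != preferred)

    merged: list[MergedVariant] = []
    all_keys = set().union(*(idx.keys() for idx in indexed.values()))
    for key in sorted(all_keys, key=VariantKey.sort_key):
        per_aligner = {
            label: idx[key] for label, idx in indexed.items() if key in idx
        }
        supporters = sorted(
            label for label, (_, verdict) in per_aligner.items() if verdict.pass_all
        )
        if not supporters:
            continue
        if len(supporters) == 2:
            conf = 2
        elif supporters[0] == preferred:
            conf = 1
        else:
            conf = 0
        merged.append(
            MergedVariant(
                key=key, conf=conf, supporting_aligners=supporters, evidence=per_aligner
            )
        )
    # deterministic tie-break already enforced by sort; keep preferred/other
    # labels reachable for writers
    for mv in merged:
        mv.evidence = dict(sorted(mv.evidence.items(), key=lambda kv: kv[0] != preferred))
    return merged


def concordance_summary(
    call_sets: Mapping[str, CallSet]
) -> tuple[dict[VariantKey, int], Counter]:
    """Supporter counts for N >= 2 aligners.

    Returns the per-key number of aligners whose evidence passed all
    filters, plus totals per count level (how many keys had exactly k
    supporters, k = 1..N).
    """
    if len(call_sets) < 2:
        raise MergeInputError("concordance summary needs at least 2 call sets")
    indexed = {label: _index_call_set(label, cs) for label, cs in call_sets.items()}
    counts: dict[VariantKey, int] = {}
    for label, idx in indexed.items():
        for key, (_, verdict) in idx.items():
            if verdict.pass_all:
                counts[key] = counts.get(key, 0) + 1
    level_totals = Counter(counts.values())
    return counts, level_totals
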
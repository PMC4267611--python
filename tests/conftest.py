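import pytest

from esnvkit.simulate import SimConfig, simulate


@pytest.fixture(scope="session")
def sim_small():
    """A modest synthetic experiment shared across read-only tests."""
    cfg = SimConfig(seed=11, n_sites=800, low_alt_depth_fraction=0.04,
                    fraction_true_variants=0.86)
    return simulate(cfg)


def make_evidence(**kwargs):
    """SiteEvidence with sensible defaults, overridable per test."""
    from esnvkit.site_features import SiteEvidence

    defaults = dict(
        chrom="chr1",
        pos=100,
        ref_base="A",
        alt_base="G",
        total_depth=50,
        alt_depth=10,
        alt_fwd=5,
        alt_rev=5,
        rrps=0.0,
        aligner_id="tophat2",
    )
    defaults.update(kwargs)
    return SiteEvidence(**defaults)
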
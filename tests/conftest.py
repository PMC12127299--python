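import pytest
from hypothesis import settings

from phasecascade import SimConfig, TriggerSite, build_locus

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture
def one_hit_locus():
    """One-hit locus: a single cleavable 22-nt trigger, phasing toward 3'."""
    return build_locus(
        "one_hit",
        transcript_length=700,
        triggers=[TriggerSite(scissile_coord=140, trigger_length=22, cleavable=True)],
        locus_id="TAS_one",
    )


@pytest.fixture
def two_hit_locus():
    """Two-hit locus: dual 21-nt triggers, only the 3' site cleavable."""
    return build_locus(
        "two_hit",
        transcript_length=700,
        triggers=[
            TriggerSite(scissile_coord=60, trigger_length=21, cleavable=False),
            TriggerSite(scissile_coord=500, trigger_length=21, cleavable=True),
        ],
        locus_id="TAS_two",
    )


@pytest.fixture
def clean_cfg():
    """Noise-free, secondary-only configuration: every read is phased."""
    return SimConfig(
        srna_depth=5000,
        phased_fraction=1.0,
        dcl2_fraction=0.0,
        tertiary_fraction=0.0,
        cleaved_fraction=0.2,
        decay_background=0.0,
        seed=11,
    )
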
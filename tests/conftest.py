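import pytest

from dnmrate import PloidyMap, Sample, SampleManifest
from tests_helpers import make_record_for


@pytest.fixture
def manifest():
    """Minimal confirmed-father pedigree: 2 focal (one per sex), 2 bait."""
    return SampleManifest(
        [
            Sample("mother", "mother", "female"),
            Sample("dad", "candidate_father", "male"),
            Sample("focal1", "focal", "female"),
            Sample("focal2", "focal", "male"),
            Sample("bait1", "bait", "female"),
            Sample("bait2", "bait", "male"),
        ]
    )


@pytest.fixture
def ploidy_map():
    return PloidyMap({"2": ("autosome", 100_000), "X": ("X", 50_000)})


@pytest.fixture
def make_record(manifest):
    """Build a SiteRecord with per-sample (gt, dp, ad_alt) overrides;
    unmentioned samples default to hom-ref with zero alternate reads."""
    return make_record_for(manifest)
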
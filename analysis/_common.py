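"""Shared constants/loaders for the numbered analysis drivers."""

from pathlib import Path

from dnmrate import PloidyMap, SampleManifest, SimConfig, read_joint_vcf
from dnmrate.masks import DepthMask

STUDY_SEED = 7
RESULTS = Path(__file__).resolve().parent.parent / "results"
SIMDATA = RESULTS / "simdata"


def study_config() -> SimConfig:
    """The main synthetic study: default (study-like) conditions."""
    return SimConfig(seed=STUDY_SEED)


def load_dataset(manifest_name: str = "manifest.tsv"):
    manifest = SampleManifest.from_tsv(SIMDATA / manifest_name)
    ploidy = PloidyMap.from_yaml(SIMDATA / "ploidy.yaml")
    records = list(read_joint_vcf(SIMDATA / "joint.vcf", manifest, ploidy))
    return records, manifest, ploidy


def load_masks(manifest: SampleManifest) -> dict[str, DepthMask]:
    return {
        s.sample_id: DepthMask.from_bed(SIMDATA / "masks" / f"{s.sample_id}.bed")
        for s in manifest.samples
    }
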
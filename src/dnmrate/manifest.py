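"""Sample manifest and chromosome ploidy map.

The pedigree design has a single mother, one or more candidate fathers
(only one of whom is the true mate), high-coverage *focal* offspring in
which de novo mutations are sought, and lower-coverage *bait* offspring
used only to veto sites with shared spurious alternate reads.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import yaml

ROLES = ("mother", "candidate_father", "focal", "bait")
SEXES = ("female", "male")

MOTHER = "mother"
CANDIDATE_FATHER = "candidate_father"
FOCAL = "focal"
BAIT = "bait"


class ManifestError(ValueError):
    pass


@dataclass(frozen=True)
class Sample:
    sample_id: str
    role: str
    sex: str

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ManifestError(f"unknown role {self.role!r} for {self.sample_id}")
        if self.sex not in SEXES:
            raise ManifestError(f"unknown sex {self.sex!r} for {self.sample_id}")


class SampleManifest:
    """Ordered collection of pedigree samples.

    Invariants: exactly one mother, at least one candidate father, at
    least one focal offspring; bait may be empty; sample ids unique.
    The sample order is the canonical column order used by
    :class:`~dnmrate.records.SiteRecord` arrays.
    """

    def __init__(self, samples: Iterable[Sample]):
        self.samples: list[Sample] = list(samples)
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ManifestError("duplicate sample ids in manifest")
        if len(self.mothers) != 1:
            raise ManifestError("manifest must contain exactly one mother")
        if not self.candidate_fathers:
            raise ManifestError("manifest must contain at least one candidate father")
        if not self.focal:
            raise ManifestError("manifest must contain at least one focal offspring")
        self.index: dict[str, int] = {s.sample_id: i for i, s in enumerate(self.samples)}

    # -- role views ---------------------------------------------------
    @property
    def mothers(self) -> list[Sample]:
        return [s for s in self.samples if s.role == MOTHER]

    @property
    def mother(self) -> Sample:
        return self.mothers[0]

    @property
    def candidate_fathers(self) -> list[Sample]:
        return [s for s in self.samples if s.role == CANDIDATE_FATHER]

    @property
    def focal(self) -> list[Sample]:
        return [s for s in self.samples if s.role == FOCAL]

    @property
    def bait(self) -> list[Sample]:
        return [s for s in self.samples if s.role == BAIT]

    @property
    def offspring(self) -> list[Sample]:
        return [s for s in self.samples if s.role in (FOCAL, BAIT)]

    @property
    def father(self) -> Sample:
        """The confirmed father; defined only once paternity is resolved."""
        fathers = self.candidate_fathers
        if len(fathers) != 1:
            raise ManifestError(
                f"father is ambiguous: {len(fathers)} candidate fathers present; "
                "run paternity confirmation first"
            )
        return fathers[0]

    @property
    def has_confirmed_father(self) -> bool:
        return len(self.candidate_fathers) == 1

    def confirm_father(self, sample_id: str) -> "SampleManifest":
        """Return a new manifest with every other candidate father removed."""
        if sample_id not in self.index:
            raise ManifestError(f"unknown sample {sample_id!r}")
        if self.samples[self.index[sample_id]].role != CANDIDATE_FATHER:
            raise ManifestError(f"{sample_id!r} is not a candidate father")
        kept = [
            s
            for s in self.samples
            if s.role != CANDIDATE_FATHER or s.sample_id == sample_id
        ]
        return SampleManifest(kept)

    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def __len__(self) -> int:
        return len(self.samples)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, SampleManifest) and self.samples == other.samples

    # -- TSV I/O ------------------------------------------------------
    @classmethod
    def from_tsv(cls, path: str | Path) -> "SampleManifest":
        samples = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#") or line.startswith("sample_id\t"):
                    continue
                fields = line.split("\t")
                if len(fields) != 3:
                    raise ManifestError(f"malformed manifest line: {line!r}")
                samples.append(Sample(*fields))
        return cls(samples)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("sample_id\trole\tsex\n")
            for s in self.samples:
                fh.write(f"{s.sample_id}\t{s.role}\t{s.sex}\n")


AUTOSOME = "autosome"
X = "X"


class PloidyMap:
    """Chromosome universe with class (autosome / X) and length.

    Copy number is 2 on autosomes for everyone; on X it is 2 for females
    and 1 for males (hemizygous). Y and unplaced contigs are excluded
    from the analysis and must not appear in the map.
    """

    def __init__(self, entries: dict[str, tuple[str, int]]):
        for chrom, (cls, length) in entries.items():
            if cls not in (AUTOSOME, X):
                raise ValueError(f"chromosome {chrom}: unknown class {cls!r}")
            if length <= 0:
                raise ValueError(f"chromosome {chrom}: non-positive length {length}")
        self.entries = dict(entries)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.entries

    def chromosomes(self) -> list[str]:
        return list(self.entries)

    def chrom_class(self, chrom: str) -> str:
        return self.entries[chrom][0]

    def length(self, chrom: str) -> int:
        return self.entries[chrom][1]

    def is_autosome(self, chrom: str) -> bool:
        return self.chrom_class(chrom) == AUTOSOME

    def copy_number(self, chrom: str, sex: str) -> int:
        if self.chrom_class(chrom) == AUTOSOME:
            return 2
        return 2 if sex == "female" else 1

    def autosomes(self) -> list[str]:
        return [c for c in self.entries if self.is_autosome(c)]

    def total_length(self) -> int:
        return sum(length for _, length in self.entries.values())

    def __eq__(self, other: object) -> bool:
        return isinstance(other, PloidyMap) and self.entries == other.entries

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PloidyMap":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls({c: (v["class"], int(v["length"])) for c, v in raw.items()})

    def to_yaml(self, path: str | Path) -> None:
        raw = {
            c: {"class": cls, "length": length}
            for c, (cls, length) in self.entries.items()
        }
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)
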
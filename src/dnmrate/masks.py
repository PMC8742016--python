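"""Per-sample depth masks as sorted, disjoint, half-open intervals.

A mask records the genomic coordinates at which a sample's aligned
depth reached the threshold (default 10x). Intervals follow the BED
convention: 0-based, half-open [start, end). SiteRecord positions are
1-based; the single conversion point is :meth:`DepthMask.contains_pos`.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

log = logging.getLogger(__name__)


class MaskError(ValueError):
    pass


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> np.ndarray:
    """Sort and merge possibly-overlapping [start, end) intervals."""
    ivs = sorted((int(s), int(e)) for s, e in intervals if e > s)
    merged: list[list[int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return np.asarray(merged, dtype=np.int64).reshape(-1, 2)


def intersect_two(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Intersect two sorted merged interval arrays by linear sweep."""
    out: list[tuple[int, int]] = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i, 0], b[j, 0])
        e = min(a[i, 1], b[j, 1])
        if s < e:
            out.append((s, e))
        if a[i, 1] <= b[j, 1]:
            i += 1
        else:
            j += 1
    return np.asarray(out, dtype=np.int64).reshape(-1, 2)


class DepthMask:
    def __init__(
        self,
        sample_id: str,
        intervals: Mapping[str, Iterable[tuple[int, int]]],
        threshold: int = 10,
    ):
        self.sample_id = sample_id
        self.threshold = threshold
        self.intervals: dict[str, np.ndarray] = {}
        for chrom, ivs in intervals.items():
            arr = merge_intervals(ivs)
            if len(arr) and arr[0, 0] < 0:
                raise MaskError(f"negative coordinate in mask for {sample_id}/{chrom}")
            self.intervals[chrom] = arr

    def chromosomes(self) -> list[str]:
        return list(self.intervals)

    def total_length(self) -> int:
        return int(
            sum((arr[:, 1] - arr[:, 0]).sum() for arr in self.intervals.values())
        )

    def contains(self, chrom: str, coord0: int) -> bool:
        """Membership of a 0-based coordinate."""
        arr = self.intervals.get(chrom)
        if arr is None or not len(arr):
            return False
        i = int(np.searchsorted(arr[:, 0], coord0, side="right")) - 1
        return i >= 0 and coord0 < arr[i, 1]

    def contains_pos(self, chrom: str, pos: int) -> bool:
        """Membership of a 1-based (VCF-style) position: pos_bed = pos - 1."""
        return self.contains(chrom, pos - 1)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DepthMask):
            return NotImplemented
        return (
            self.sample_id == other.sample_id
            and self.threshold == other.threshold
            and self.intervals.keys() == other.intervals.keys()
            and all(np.array_equal(self.intervals[c], other.intervals[c]) for c in self.intervals)
        )

    # -- BED I/O ------------------------------------------------------
    @classmethod
    def from_bed(
        cls, path: str | Path, sample_id: str | None = None, threshold: int = 10
    ) -> "DepthMask":
        """Read a BED3 mask. A ``#threshold=`` / ``#sample=`` header is
        honoured when present; unsorted input is sorted with a warning."""
        per_chrom: dict[str, list[tuple[int, int]]] = {}
        last: dict[str, int] = {}
        warned = False
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                if line.startswith("#"):
                    if line.startswith("#threshold="):
                        threshold = int(line.split("=", 1)[1])
                    elif line.startswith("#sample="):
                        sample_id = sample_id or line.split("=", 1)[1]
                    continue
                chrom, s, e = line.split("\t")[:3]
                s, e = int(s), int(e)
                if s < 0:
                    raise MaskError(f"negative coordinate in {path}: {line!r}")
                if not warned and chrom in last and s < last[chrom]:
                    log.warning("unsorted BED input %s; sorting", path)
                    warned = True
                last[chrom] = s
                per_chrom.setdefault(chrom, []).append((s, e))
        sid = sample_id if sample_id is not None else Path(path).stem
        return cls(sid, per_chrom, threshold)

    def to_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"#sample={self.sample_id}\n#threshold={self.threshold}\n")
            for chrom, arr in self.intervals.items():
                for s, e in arr:
                    fh.write(f"{chrom}\t{s}\t{e}\n")


def intersect_masks(masks: Iterable[DepthMask]) -> dict[str, np.ndarray]:
    """k-way interval intersection over the common chromosome universe.

    All masks must cover the same chromosome set (fatal otherwise):
    callable-site accounting is meaningless across mismatched universes.
    """
    masks = list(masks)
    universe = set(masks[0].chromosomes())
    for m in masks[1:]:
        if set(m.chromosomes()) != universe:
            raise MaskError(
                f"mask chromosome universes differ: {sorted(universe)} vs "
                f"{sorted(m.chromosomes())} ({m.sample_id})"
            )
    out: dict[str, np.ndarray] = {}
    for chrom in masks[0].chromosomes():
        arr = masks[0].intervals[chrom]
        for m in masks[1:]:
            arr = intersect_two(arr, m.intervals[chrom])
        out[chrom] = arr
    return out


def intervals_length(intervals: Mapping[str, np.ndarray]) -> int:
    return int(
        sum((arr[:, 1] - arr[:, 0]).sum() for arr in intervals.values() if len(arr))
    )
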
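"""Multi-sample VCF input/output via pysam.

Reading maps each VCF record onto a :class:`~dnmrate.records.SiteRecord`
with per-sample fields in manifest order; writing inverts the mapping.
Coordinates stay 1-based (VCF convention) inside ``SiteRecord``; the
0-based half-open convention is used only for BED depth masks (see
:mod:`dnmrate.masks`).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pysam

from .manifest import PloidyMap, SampleManifest
from .records import MISSING_DEPTH, SiteRecord

log = logging.getLogger(__name__)


class VcfError(ValueError):
    pass


def read_joint_vcf(
    path: str | Path,
    manifest: SampleManifest,
    ploidy_map: PloidyMap | None = None,
) -> Iterator[SiteRecord]:
    """Stream SiteRecords from a joint-called multi-sample VCF.

    Every manifest sample must be a column of the VCF (fatal otherwise).
    Records on contigs outside the ploidy map's chromosome universe are
    dropped with a summary count logged; pass ``ploidy_map=None`` to
    keep everything. Malformed DP/AD values degrade to missing with a
    warning rather than aborting the stream.
    """
    vcf = pysam.VariantFile(str(path))
    vcf_samples = set(vcf.header.samples)
    for s in manifest.sample_ids():
        if s not in vcf_samples:
            raise VcfError(f"sample {s!r} from manifest missing in VCF {path}")
    ids = manifest.sample_ids()
    n = len(ids)
    n_dropped = 0
    for rec in vcf:
        if ploidy_map is not None and rec.chrom not in ploidy_map:
            n_dropped += 1
            continue
        gts: list = [None] * n
        dp = np.full(n, MISSING_DEPTH, dtype=np.int64)
        ad_ref = np.full(n, MISSING_DEPTH, dtype=np.int64)
        ad_alt = np.full(n, MISSING_DEPTH, dtype=np.int64)
        for i, sid in enumerate(ids):
            call = rec.samples[sid]
            gt = call.get("GT")
            if gt is not None and None not in gt:
                gts[i] = tuple(sorted(gt))
            try:
                v = call.get("DP")
                if v is not None:
                    dp[i] = int(v)
                ad = call.get("AD")
                if ad is not None and ad[0] is not None:
                    ad_ref[i] = int(ad[0])
                    # at biallelic sites this is the single alt entry
                    ad_alt[i] = int(sum(a for a in ad[1:] if a is not None))
            except (TypeError, ValueError):
                log.warning(
                    "malformed DP/AD for %s at %s:%d; set missing", sid, rec.chrom, rec.pos
                )
                dp[i] = ad_ref[i] = ad_alt[i] = MISSING_DEPTH
        yield SiteRecord(
            chrom=rec.chrom,
            pos=rec.pos,
            ref=rec.ref,
            alts=tuple(rec.alts or ()),
            gts=gts,
            dp=dp,
            ad_ref=ad_ref,
            ad_alt=ad_alt,
        )
    if n_dropped:
        log.info("dropped %d records on contigs outside the ploidy map", n_dropped)


def write_joint_vcf(
    path: str | Path,
    records: Iterable[SiteRecord],
    manifest: SampleManifest,
    ploidy_map: PloidyMap,
) -> None:
    """Write SiteRecords as an uncompressed multi-sample VCF."""
    header = pysam.VariantHeader()
    for chrom in ploidy_map.chromosomes():
        header.contigs.add(chrom, length=ploidy_map.length(chrom))
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("DP", 1, "Integer", "Read depth")
    header.formats.add("AD", "R", "Integer", "Allele read depths (ref, alt...)")
    for sid in manifest.sample_ids():
        header.add_sample(sid)
    ids = manifest.sample_ids()
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for rec in records:
            vrec = out.new_record(
                contig=rec.chrom,
                start=rec.pos - 1,
                stop=rec.pos - 1 + len(rec.ref),
                alleles=(rec.ref, *rec.alts),
            )
            for i, sid in enumerate(ids):
                call = vrec.samples[sid]
                gt = rec.gts[i]
                call["GT"] = gt if gt is not None else (None,)
                if rec.dp[i] != MISSING_DEPTH:
                    call["DP"] = int(rec.dp[i])
                if rec.ad_ref[i] != MISSING_DEPTH:
                    # multi-allelic alt depths beyond the first are not
                    # resolvable from SiteRecord; only biallelic records
                    # round-trip AD exactly (the analysis uses only those)
                    ad = [int(rec.ad_ref[i]), int(rec.ad_alt[i])]
                    ad += [0] * (len(rec.alts) - 1)
                    call["AD"] = tuple(ad)
            out.write(vrec)
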
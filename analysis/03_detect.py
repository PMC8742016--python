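"""Detect candidate de novo mutations with the four filtering criteria.

Consumes the father-confirmed manifest from step 02. Writes the
candidate table and the filtering funnel (sites surviving each stage),
plus advisory co-mapping flags for sites with bait-shared alternate
reads nearby that lack a parental source.
"""

import pandas as pd
from _common import RESULTS, SIMDATA, load_dataset

from dnmrate import detect_candidates, flag_comapping_context
from dnmrate.detect import FUNNEL_STAGES, candidates_frame


def main() -> None:
    records, manifest, ploidy = load_dataset("manifest.confirmed.tsv")
    candidates, funnel = detect_candidates(records, manifest, ploidy)
    flag_comapping_context(candidates, records, manifest)

    out = RESULTS / "detect"
    out.mkdir(parents=True, exist_ok=True)
    candidates_frame(candidates).to_csv(out / "candidates.tsv", sep="\t", index=False)
    funnel.to_frame().to_csv(out / "funnel.tsv", sep="\t", index=False)

    truth = pd.read_csv(SIMDATA / "truth.tsv", sep="\t", comment="#")
    truth_keys = set(zip(truth.chrom.astype(str), truth.pos))
    n_true = sum(1 for c in candidates if (c.chrom, c.pos) in truth_keys)

    print("filtering funnel (sites surviving each stage):")
    for stage in FUNNEL_STAGES:
        print(f"  {stage}: {funnel.counts[stage]}")
    print(f"{len(candidates)} candidates, of which {n_true} are planted mutations "
          f"and {len(candidates) - n_true} would be false positives")
    print(f"co-mapping flags: {sum(c.comapping_flag for c in candidates)}")
    print(f"tables -> {out}")


if __name__ == "__main__":
    main()
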
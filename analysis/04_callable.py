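"""Count callable sites per parent-focal trio.

Intersects the mother/father/focal depth masks (DP >= 10), removes
joint-caller-reported coordinates that failed filtering (they proved
un-callable), sums across trios and doubles for diploidy.
"""

from _common import RESULTS, load_dataset, load_masks

from dnmrate import callable_summary, detect_candidates, flag_comapping_context


def main() -> None:
    records, manifest, ploidy = load_dataset("manifest.confirmed.tsv")
    candidates, _ = detect_candidates(records, manifest, ploidy)
    flag_comapping_context(candidates, records, manifest)
    summary = callable_summary(
        load_masks(manifest), manifest, records, candidates, ploidy
    )
    out = RESULTS / "callable"
    out.mkdir(parents=True, exist_ok=True)
    summary.per_trio.to_csv(out / "callable_per_trio.tsv", sep="\t", index=False)
    print(summary.per_trio.to_string(index=False))
    print(f"total callable sites C (x{summary.doubling_factor} for diploidy): "
          f"{summary.total:,}")
    print(f"table -> {out}")


if __name__ == "__main__":
    main()
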
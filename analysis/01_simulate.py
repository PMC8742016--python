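"""Generate the main synthetic pedigree dataset.

One mother, four candidate males (one the true mate), 10 focal and 19
bait offspring on a 1.2 Mb toy genome (two autosomes + X), with
planted de novo mutations at a known true rate. Writes the joint VCF,
per-sample depth masks, manifest, ploidy map and truth table that the
later stages consume.
"""

from _common import SIMDATA, study_config

from dnmrate import simulate_pedigree


def main() -> None:
    config = study_config()
    sim = simulate_pedigree(config)
    sim.write_outputs(SIMDATA)
    n_focal_planted = sum(
        1 for m in sim.truth.mutations if m.carrier_id.startswith("focal")
    )
    print(f"simulated {len(sim.records)} variant records on "
          f"{len(config.chromosomes)} chromosomes (seed {config.seed})")
    print(f"true father: {sim.truth.father_id} (hidden from the analysis stages)")
    print(f"planted de novo mutations: {len(sim.truth.mutations)} "
          f"({n_focal_planted} in focal offspring, the only detectable ones)")
    print(f"true rate mu = {config.mu_true:g} per site per generation")
    print(f"outputs -> {SIMDATA}")


if __name__ == "__main__":
    main()
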
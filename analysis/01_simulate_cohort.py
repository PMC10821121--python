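"""Generate the synthetic FMT cohort used by the downstream analyses.

54 recipient dogs served by 7 stool donors, each dog sampled before and
two weeks after a course of oral FMT capsules. Writes counts.tsv,
taxonomy.tsv, metadata.tsv, tree.nwk and truth.json to results/cohort/.
"""

from pathlib import Path

from fmt_engraft import SimulationConfig, simulate_cohort, write_cohort

OUT = Path(__file__).resolve().parent.parent / "results" / "cohort"
SEED = 20240119


def main() -> None:
    config = SimulationConfig(seed=SEED)
    cohort = simulate_cohort(config)
    paths = write_cohort(cohort, OUT)
    depths = cohort.table.data.sum(axis=1)
    print(
        f"simulated {config.n_triads} triads served by {config.n_donors} donors: "
        f"{cohort.table.n_samples} samples x {cohort.table.n_asvs} ASVs"
    )
    print(f"sequencing depth {depths.min()}-{depths.max()} reads per sample")
    print(f"wrote {', '.join(sorted(p.name for p in paths.values()))} to {OUT}")


if __name__ == "__main__":
    main()
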
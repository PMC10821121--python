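"""Priority-effect experiment: does donor-recipient overlap suppress
engraftment abundance?

Sweeps the donor-recipient taxon overlap from 0.1 to 0.9 at a fixed
per-ASV engraftment probability and correlates each triad's pre-FMT
weighted-UniFrac similarity to its donor with the donor-derived share of
its post-FMT microbiome. A negative correlation reproduces the priority
effect: established communities resist colonisation by similar
newcomers.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from fmt_engraft import SimulationConfig, simulate_cohort, spearman
from fmt_engraft.diversity import TreeBranches, _unifrac_from_fractions
from fmt_engraft.engraftment import provenance_fractions
from fmt_engraft.preprocess import remove_rare_asvs

ROOT = Path(__file__).resolve().parent.parent
OUT = ROOT / "results" / "priority_effect"
SEED = 20240119


def main() -> None:
    rows = []
    for i, overlap in enumerate(np.arange(0.1, 0.95, 0.1)):
        config = SimulationConfig(
            n_triads=6,
            n_donors=2,
            donor_richness=(40, 80),
            recipient_richness=(40, 80),
            overlap=float(overlap),
            engraft_prob=0.18,
            depth=30000,
            pool_size=300,
            seed=SEED + i,
        )
        cohort = simulate_cohort(config)
        filtered, _ = remove_rare_asvs(cohort.table)
        branches = TreeBranches(cohort.tree, filtered.asv_ids)
        for triad in cohort.triads:
            fd = branches.branch_fractions(filtered.counts(triad.donor_sample))
            fp = branches.branch_fractions(filtered.counts(triad.pre_sample))
            sim = 1.0 - _unifrac_from_fractions(branches.lengths, fd, fp, True)
            part = provenance_fractions(triad, filtered, "postFMT")
            rows.append(
                {
                    "overlap": round(float(overlap), 1),
                    "recipient_id": triad.recipient_id,
                    "unifrac_similarity": sim,
                    "donor_derived_fraction": part.fraction_donor_derived,
                }
            )
    df = pd.DataFrame(rows)
    OUT.mkdir(parents=True, exist_ok=True)
    df.to_csv(OUT / "overlap_sweep.tsv", sep="\t", index=False)

    by_overlap = df.groupby("overlap").mean(numeric_only=True)
    print("mean similarity and donor-derived fraction by overlap:")
    print(by_overlap.round(4).to_string())
    corr = spearman(
        df["unifrac_similarity"], df["donor_derived_fraction"],
        x_label="unifrac_similarity", y_label="donor_derived_fraction",
    )
    print(
        f"\nSpearman rho = {corr.rho:.3f}, p = {corr.p_value:.2g} (n = {corr.n}): "
        + (
            "negative, reproducing the priority effect"
            if corr.rho < 0
            else "no priority effect detected"
        )
    )
    print(f"wrote per-triad table to {OUT / 'overlap_sweep.tsv'}")


if __name__ == "__main__":
    main()
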
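"""Alpha- and beta-diversity of the cohort.

Alpha diversity (Chao1, Shannon, Gini-Simpson) is computed on samples
rarefied to 26,000 reads; beta diversity as Jaccard, Bray-Curtis,
Aitchison and weighted-UniFrac distance matrices on the unrarefied
table. Reads the cohort written by 01_simulate_cohort.py.
"""

from pathlib import Path

from fmt_engraft import (
    alpha_diversity_table,
    distance_matrix,
    rarefy,
    read_asv_table,
    read_metadata,
    read_newick,
)

ROOT = Path(__file__).resolve().parent.parent
COHORT = ROOT / "results" / "cohort"
OUT = ROOT / "results" / "diversity"
SEED = 20240119


def main() -> None:
    records = read_metadata(COHORT / "metadata.tsv")
    table = read_asv_table(COHORT / "counts.tsv", sample_ids=[r.sample_id for r in records])
    tree = read_newick(COHORT / "tree.nwk")
    OUT.mkdir(parents=True, exist_ok=True)

    rarefied = rarefy(table, depth=26000, seed=SEED)
    alpha = alpha_diversity_table(rarefied.table)
    alpha.to_csv(OUT / "alpha_diversity.tsv", sep="\t", index_label="sample_id")
    print(
        f"alpha diversity on {len(alpha)} samples rarefied to 26,000 reads "
        f"({len(rarefied.excluded_samples)} excluded as too shallow)"
    )
    roles = {r.sample_id: r.role for r in records}
    for role in ("donor", "preFMT", "postFMT"):
        sub = alpha.loc[[s for s in alpha.index if roles[s] == role]]
        print(
            f"  {role:8s} mean Chao1 {sub['chao1'].mean():7.1f}  "
            f"Shannon {sub['shannon'].mean():5.2f}  "
            f"Gini-Simpson {sub['gini_simpson'].mean():5.3f}"
        )

    for metric in ("jaccard", "bray_curtis", "aitchison", "weighted_unifrac"):
        dm = distance_matrix(table, metric, tree=tree)
        dm.to_csv(OUT / f"distance_{metric}.tsv", sep="\t", index_label="sample_id")
        tri = dm.to_numpy()[~(dm.to_numpy() == 0)]
        print(f"  {metric}: mean off-diagonal distance {tri.mean():.3f}")
    print(f"wrote tables to {OUT}")


if __name__ == "__main__":
    main()
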
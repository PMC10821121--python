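# fmt-engraft

Donor-bacteria engraftment analysis for fecal microbiota transplant
(FMT) cohorts profiled with 16S rRNA amplicon sequencing.

When a dog (or cat, or human) with chronic digestive disease receives
oral capsules of lyophilised donor stool, which of the donor's bacteria
actually *engraft*? This package answers that question from three
standard tables — an ASV count matrix, a taxonomy table, and sample
metadata linking each recipient's pre-FMT and post-FMT samples to a
stool donor — plus an optional phylogeny for UniFrac.

For each donor/pre/post **triad** with presence sets `D`, `P`, `Q` it
computes:

- the **engraftment rate** `100 · |(Q ∩ D) \ P| / |D \ P|` — the share
  of donor ASVs the recipient did not already carry that appear after
  FMT (singleton/doubleton ASVs are removed dataset-wide first);
- the **provenance partition** of every microbiome: each ASV is
  *always-shared* (`D ∩ P`), *donor-derived* (`D \ P`),
  *recipient-derived* (`P \ D`) or *environmental/stochastic*, with
  class abundance fractions summing to 1;
- **taxon engraftment frequencies** — which genera and families engraft
  most often across the cohort;
- the **priority-effect correlation**: Spearman's rho between each
  triad's donor–pre weighted-UniFrac similarity and its post-FMT
  donor-derived abundance fraction (negative rho = established
  communities resist similar newcomers).

Supporting modules provide the diversity computations these analyses
consume (Chao1, Shannon, Gini-Simpson on rarefied counts; Jaccard,
Bray–Curtis, Aitchison and weighted-UniFrac distances), nonparametric
statistics (Spearman, Wilcoxon rank-sum with both W and U conventions),
and a synthetic-cohort generator with known ground truth — every
simulated ASV carries its true provenance class and every triad its
realized engrafted set, so the whole pipeline is testable end to end.
See `docs/methods.md` for the model and its assumptions.

## Worked example

The `analysis/` scripts run the full chain on a synthetic 54-recipient,
7-donor cohort (sequencing depths 26,000–60,000 reads, per-ASV
engraftment probability 0.18):

```sh
python analysis/01_simulate_cohort.py   # writes results/cohort/
python analysis/02_diversity.py
python analysis/03_engraftment.py
python analysis/04_priority_effect.py
```

`03_engraftment.py` prints:

```
54/54 triads with a defined rate; engraftment mean 19.16%, median 18.28%, range 0.00-50.00%
post-FMT microbiome provenance (mean fractions): always-shared 52.9%, donor-derived 4.2%, recipient-derived 32.2%, environmental 10.7%
pre-FMT: always-shared 61.9%, recipient-derived 38.1%
pre vs post recipient-derived fraction: Wilcoxon W = 2041, p = 0.00034
most frequently engrafted taxon: Allobaculum (6.74% of all engraftment events)
donor-derived fraction vs donor-pre UniFrac similarity: Spearman rho = -0.36, p = 0.0079 (n = 54)
ground truth: realized mean rate 19.16% (generator engraftment probability 18%)
```

Reading: on average ~19% of each donor's eligible ASVs engrafted —
matching the generator's true 18% engraftment probability (the realized
mean of the binomial draws was exactly 19.16%). Before FMT, ASVs shared
with the donor made up 62% of the recipient microbiome; after FMT the
recipient-derived share shrank (W = 2041, p < 0.001) as donor and
environmental ASVs arrived. The negative Spearman correlation shows the
priority effect: recipients whose starting community already resembled
their donor gained less donor-derived abundance. `04_priority_effect.py`
sharpens this by sweeping overlap 0.1→0.9 at fixed engraftment
probability (rho = −0.46, p = 4e−4).

The same analysis runs from the shell on any cohort's files:

```sh
fmt-engraft simulate --out cohort/ --seed 7
fmt-engraft run --counts cohort/counts.tsv --metadata cohort/metadata.tsv \
    --taxonomy cohort/taxonomy.tsv --tree cohort/tree.nwk --out results/
```

writing `engraftment_rates.tsv`, `provenance_fractions.tsv`,
`engrafted_taxa.tsv`, `cohort_summary.tsv`, `alpha_diversity.tsv`,
`correlations.tsv` and a JSON run manifest.

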
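"""Synthetic FMT cohort generator with known ground truth.

Emulates the structure of an oral-capsule FMT study in dogs: ~7 stool
donors serving 54 recipients, each recipient contributing a pre-FMT and
a post-FMT fecal sample. Communities have long-tailed (log-normal) rank
abundances; the recipient's pre-FMT community shares a tunable fraction
of its taxa with its donor; post-FMT communities are assembled from
persisting recipient taxa, donor taxa engrafting independently with
probability ``engraft_prob``, and a small environmental influx; reads
are drawn multinomially at realistic sequencing depths. Every generated
ASV's true provenance class and the realized engrafted set are recorded
so pipeline outputs can be checked against ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode

from fmt_engraft.io import RANKS, AsvTable, SampleRecord, TaxonomyTable, Triad

# Canine gut lineages used for synthetic taxonomy labels. genus=None
# leaves the ASV unclassified below family.
_LINEAGES = [
    ("Firmicutes", "Clostridia", "Lachnospirales", "Lachnospiraceae", "Blautia"),
    ("Firmicutes", "Clostridia", "Lachnospirales", "Lachnospiraceae", "Lachnoclostridium"),
    ("Firmicutes", "Clostridia", "Lachnospirales", "Lachnospiraceae", None),
    ("Firmicutes", "Clostridia", "Oscillospirales", "Ruminococcaceae", "Faecalibacterium"),
    ("Firmicutes", "Clostridia", "Oscillospirales", "Ruminococcaceae", None),
    ("Firmicutes", "Clostridia", "Lachnospirales", "Lachnospiraceae", "Ruminococcus torques group"),
    ("Bacteroidota", "Bacteroidia", "Bacteroidales", "Bacteroidaceae", "Bacteroides"),
    ("Fusobacteriota", "Fusobacteriia", "Fusobacteriales", "Fusobacteriaceae", "Fusobacterium"),
    ("Bacteroidota", "Bacteroidia", "Bacteroidales", "Prevotellaceae", "Prevotella 9"),
    ("Bacteroidota", "Bacteroidia", "Bacteroidales", "Prevotellaceae", "Alloprevotella"),
    ("Firmicutes", "Negativicutes", "Selenomonadales", "Selenomonadaceae", "Megamonas"),
    ("Proteobacteria", "Gammaproteobacteria", "Burkholderiales", "Sutterellaceae", "Sutterella"),
    ("Firmicutes", "Bacilli", "Lactobacillales", "Streptococcaceae", "Streptococcus"),
    ("Proteobacteria", "Gammaproteobacteria", "Enterobacterales", "Enterobacteriaceae", "Escherichia-Shigella"),
    ("Firmicutes", "Clostridia", "Clostridiales", "Clostridiaceae", "Clostridium sensu stricto 1"),
    ("Firmicutes", "Clostridia", "Oscillospirales", "Butyricicoccaceae", "Butyricicoccus"),
    ("Firmicutes", "Clostridia", "Peptostreptococcales-Tissierellales", "Peptostreptococcaceae", "Peptoclostridium"),
    ("Firmicutes", "Bacilli", "Erysipelotrichales", "Erysipelotrichaceae", "Allobaculum"),
    ("Actinobacteriota", "Coriobacteriia", "Coriobacteriales", "Coriobacteriaceae", "Collinsella"),
    ("Firmicutes", "Negativicutes", "Veillonellales-Selenomonadales", "Veillonellaceae", "Megasphaera"),
]

_CLINICAL_SIGNS = ("diarrhea", "vomiting+diarrhea", "vomiting", "constipation")
_CLINICAL_PROBS = (0.48, 0.30, 0.13, 0.09)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror the cohort being emulated: 54 recipient triads served
    by 7 donors, donor richness 33-170 taxa, sequencing depth 26,000-
    60,000 reads, mean per-ASV engraftment probability 0.18, and a
    donor--recipient taxon overlap of 0.6 so that roughly three fifths of
    the pre-FMT community is shared with the donor.
    """

    n_triads: int = 54
    n_donors: int = 7
    donor_richness: tuple[int, int] = (33, 170)
    recipient_richness: tuple[int, int] = (40, 150)
    overlap: float = 0.6
    engraft_prob: float = 0.18
    persist_prob: float = 0.85
    n_env: int = 15
    env_mass: float = 0.12
    engraft_strength: float = 0.5
    lognormal_sigma: float = 1.5
    # lognormal noise linking a shared taxon's abundance in the recipient
    # to its abundance in the donor; smaller = stronger conservation
    abundance_conservation_sigma: float = 0.75
    depth: int | tuple[int, int] = (26000, 60000)
    pool_size: int = 800
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("overlap", "engraft_prob", "persist_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("donor_richness", "recipient_richness"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"{name} must be a positive range, got ({lo}, {hi})")
        lo, hi = self._depth_range()
        if lo <= 0 or hi < lo:
            raise ValueError(f"depth must be positive, got {self.depth}")
        if self.pool_size < self.donor_richness[1] + self.recipient_richness[1] + self.n_env:
            raise ValueError("pool_size too small for requested richness ranges")

    def _depth_range(self) -> tuple[int, int]:
        if isinstance(self.depth, (int, np.integer)):
            return int(self.depth), int(self.depth)
        lo, hi = self.depth
        return int(lo), int(hi)


@dataclass(frozen=True)
class TriadTruth:
    """Ground truth for one triad, recorded pre-sequencing."""

    recipient_id: str
    donor_id: str
    donor_taxa: frozenset[str]
    pre_taxa: frozenset[str]
    eligible_taxa: frozenset[str]  # donor_taxa - pre_taxa
    engrafted_taxa: frozenset[str]  # realized engraftment events
    post_classes: dict[str, str]  # every taxon in the post community
    engraft_prob: float


@dataclass
class SyntheticCohort:
    table: AsvTable
    records: list[SampleRecord]
    taxonomy: TaxonomyTable
    tree: TreeNode
    triads: list[Triad]
    truth: dict[str, TriadTruth]
    config: SimulationConfig


def simulate_community(richness: int, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Log-normal rank-abundance profile: p_i propto exp(N(0, sigma^2)), sum 1."""
    if richness < 1:
        raise ValueError(f"richness must be >= 1, got {richness}")
    if sigma == 0:
        return np.full(richness, 1.0 / richness)
    w = np.exp(rng.normal(0.0, sigma, richness))
    return w / w.sum()


def simulate_tree(asv_ids: list[str], rng: np.random.Generator) -> TreeNode:
    """Random rooted bifurcating topology with Exponential(1) branch lengths.

    Coalescent-style: repeatedly join two uniformly chosen lineages until
    one remains. Deterministic given the generator state.
    """
    if len(asv_ids) < 2:
        raise ValueError(f"need at least 2 taxa for a tree, got {len(asv_ids)}")
    nodes = [TreeNode(name=a) for a in asv_ids]
    for leaf in nodes:
        leaf.length = float(rng.exponential(1.0))
    while len(nodes) > 1:
        i, j = rng.choice(len(nodes), size=2, replace=False)
        i, j = (int(i), int(j)) if i < j else (int(j), int(i))
        b = nodes.pop(j)
        a = nodes.pop(i)
        parent = TreeNode(children=[a, b])
        parent.length = float(rng.exponential(1.0))
        nodes.append(parent)
    root = nodes[0]
    root.length = 0.0
    return root


def _draw_richness(rng: np.random.Generator, lo: int, hi: int) -> int:
    return int(rng.integers(lo, hi + 1))


def _simulate_recipient(
    config: SimulationConfig,
    rng: np.random.Generator,
    recipient_id: str,
    donor_id: str,
    donor_taxa: np.ndarray,
    donor_profile: np.ndarray,
    pool: np.ndarray,
) -> tuple[dict[str, float], dict[str, float], TriadTruth]:
    """Pre- and post-FMT abundance profiles plus ground truth for one triad."""
    richness = _draw_richness(rng, *config.recipient_richness)
    # at most 90% of the donor community may be pre-shared: no real triad
    # has its donor's entire community contained in the recipient, so the
    # eligible set (donor minus pre) is never empty by construction
    max_shared = int(0.9 * len(donor_taxa))
    n_shared = min(int(round(config.overlap * richness)), max_shared)
    shared = rng.choice(donor_taxa, size=n_shared, replace=False)
    donor_set = set(donor_taxa)
    outside = np.array([a for a in pool if a not in donor_set])
    unique = rng.choice(outside, size=richness - n_shared, replace=False)
    pre_taxa = np.concatenate([shared, unique])
    # shared taxa conserve their donor abundances up to lognormal noise;
    # recipient-specific taxa get fresh log-normal weights on the same
    # per-taxon abundance scale (mean donor abundance = 1/|donor|)
    donor_abund = dict(zip(donor_taxa, donor_profile))
    tau = config.abundance_conservation_sigma
    shared_w = np.array(
        [donor_abund[t] for t in shared]
    ) * np.exp(rng.normal(0.0, tau, size=n_shared))
    unique_w = np.exp(rng.normal(0.0, config.lognormal_sigma, size=len(unique)))
    if len(unique):
        unique_w = unique_w / unique_w.sum() * len(unique) / len(donor_taxa)
    weights = np.concatenate([shared_w, unique_w])
    weights = weights / weights.sum()
    pre_profile = dict(zip(pre_taxa, weights))

    pre_set = set(pre_taxa)
    eligible = [a for a in donor_taxa if a not in pre_set]

    post: dict[str, float] = {}
    for taxon, ab in pre_profile.items():
        if rng.random() < config.persist_prob:
            post[taxon] = ab
    engrafted = []
    for taxon in eligible:
        if rng.random() < config.engraft_prob:
            engrafted.append(taxon)
            post[taxon] = config.engraft_strength * donor_abund[taxon]
    base_mass = sum(post.values())
    if base_mass == 0:
        raise ValueError(
            f"triad {recipient_id!r}: empty post-FMT community "
            "(persist_prob and engraft_prob both too low)"
        )
    if config.n_env > 0:
        excluded = donor_set | pre_set
        candidates = np.array([a for a in pool if a not in excluded and a not in post])
        env_taxa = rng.choice(candidates, size=config.n_env, replace=False)
        env_w = np.exp(rng.normal(0.0, config.lognormal_sigma, config.n_env))
        env_w = env_w / env_w.sum() * config.env_mass * base_mass
        for taxon, w in zip(env_taxa, env_w):
            post[taxon] = float(w)
    total = sum(post.values())
    post = {t: v / total for t, v in post.items()}

    classes = {}
    for taxon in post:
        if taxon in donor_set and taxon in pre_set:
            classes[taxon] = "always_shared"
        elif taxon in donor_set:
            classes[taxon] = "donor_derived"
        elif taxon in pre_set:
            classes[taxon] = "recipient_derived"
        else:
            classes[taxon] = "environmental"

    truth = TriadTruth(
        recipient_id=recipient_id,
        donor_id=donor_id,
        donor_taxa=frozenset(donor_taxa),
        pre_taxa=frozenset(pre_taxa),
        eligible_taxa=frozenset(eligible),
        engrafted_taxa=frozenset(engrafted),
        post_classes=classes,
        engraft_prob=config.engraft_prob,
    )
    return pre_profile, post, truth


def _draw_counts(
    profile: dict[str, float], depth: int, rng: np.random.Generator
) -> dict[str, int]:
    taxa = sorted(profile)
    probs = np.array([profile[t] for t in taxa], dtype=float)
    probs = probs / probs.sum()
    counts = rng.multinomial(depth, probs)
    return {t: int(c) for t, c in zip(taxa, counts) if c > 0}


def simulate_triad(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[dict[str, int], dict[str, int], dict[str, int], TriadTruth]:
    """One standalone triad: donor, pre and post count vectors plus truth."""
    pool = np.array([f"ASV{i:04d}" for i in range(config.pool_size)])
    richness = _draw_richness(rng, *config.donor_richness)
    donor_taxa = rng.choice(pool, size=richness, replace=False)
    donor_profile = simulate_community(richness, config.lognormal_sigma, rng)
    pre_profile, post_profile, truth = _simulate_recipient(
        config, rng, "recipient", "donor", donor_taxa, donor_profile, pool
    )
    lo, hi = config._depth_range()
    depths = [int(rng.integers(lo, hi + 1)) for _ in range(3)]
    donor_counts = _draw_counts(dict(zip(donor_taxa, donor_profile)), depths[0], rng)
    pre_counts = _draw_counts(pre_profile, depths[1], rng)
    post_counts = _draw_counts(post_profile, depths[2], rng)
    return donor_counts, pre_counts, post_counts, truth


def simulate_cohort(config: SimulationConfig | None = None) -> SyntheticCohort:
    """Full cohort: donors shared across recipients, metadata, taxonomy, tree."""
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)
    pool = np.array([f"ASV{i:04d}" for i in range(config.pool_size)])
    lo_d, hi_d = config._depth_range()

    donors = {}
    for k in range(config.n_donors):
        donor_id = f"donor{k + 1:02d}"
        richness = _draw_richness(rng, *config.donor_richness)
        taxa = rng.choice(pool, size=richness, replace=False)
        profile = simulate_community(richness, config.lognormal_sigma, rng)
        donors[donor_id] = (taxa, profile)

    counts: dict[str, dict[str, int]] = {}
    records: list[SampleRecord] = []
    triads: list[Triad] = []
    truth: dict[str, TriadTruth] = {}

    for donor_id, (taxa, profile) in donors.items():
        sid = f"{donor_id}_stool"
        counts[sid] = _draw_counts(
            dict(zip(taxa, profile)), int(rng.integers(lo_d, hi_d + 1)), rng
        )
        records.append(
            SampleRecord(
                sample_id=sid,
                dog_id=donor_id,
                role="donor",
                body_condition_score=int(rng.integers(4, 7)),
            )
        )

    donor_ids = list(donors)
    for k in range(config.n_triads):
        dog_id = f"dog{k + 1:02d}"
        donor_id = donor_ids[k % len(donor_ids)]
        donor_taxa, donor_profile = donors[donor_id]
        pre_profile, post_profile, t = _simulate_recipient(
            config, rng, dog_id, donor_id, donor_taxa, donor_profile, pool
        )
        pre_sid, post_sid = f"{dog_id}_pre", f"{dog_id}_post"
        counts[pre_sid] = _draw_counts(pre_profile, int(rng.integers(lo_d, hi_d + 1)), rng)
        counts[post_sid] = _draw_counts(post_profile, int(rng.integers(lo_d, hi_d + 1)), rng)
        signs = str(rng.choice(_CLINICAL_SIGNS, p=_CLINICAL_PROBS))
        shared_covariates = dict(
            dog_id=dog_id,
            donor_id=donor_id,
            clinical_signs=signs,
            raw_food=bool(rng.random() < 0.46),
            kibble=bool(rng.random() < 0.39),
            prior_antibiotics=bool(rng.random() < 0.65),
            body_condition_score=int(rng.integers(2, 9)),
        )
        records.append(SampleRecord(sample_id=pre_sid, role="preFMT", **shared_covariates))
        records.append(SampleRecord(sample_id=post_sid, role="postFMT", **shared_covariates))
        triads.append(
            Triad(
                recipient_id=dog_id,
                donor_sample=f"{donor_id}_stool",
                pre_sample=pre_sid,
                post_sample=post_sid,
            )
        )
        truth[dog_id] = t

    all_taxa = sorted({t for row in counts.values() for t in row})
    df = pd.DataFrame.from_dict(counts, orient="index").reindex(columns=all_taxa)
    df = df.fillna(0).astype(np.int64)
    df = df.loc[[r.sample_id for r in records]]
    table = AsvTable(df)

    taxonomy = _synthetic_taxonomy(all_taxa, rng)
    tree = simulate_tree(all_taxa, rng)
    return SyntheticCohort(
        table=table,
        records=records,
        taxonomy=taxonomy,
        tree=tree,
        triads=triads,
        truth=truth,
        config=config,
    )


def _synthetic_taxonomy(asv_ids: list[str], rng: np.random.Generator) -> TaxonomyTable:
    rows = {}
    picks = rng.integers(0, len(_LINEAGES), size=len(asv_ids))
    for asv, k in zip(asv_ids, picks):
        phylum, class_, order, family, genus = _LINEAGES[int(k)]
        rows[asv] = {
            "domain": "Bacteria",
            "phylum": phylum,
            "class": class_,
            "order": order,
            "family": family,
            "genus": genus,
            "species": None,
        }
    return TaxonomyTable(pd.DataFrame.from_dict(rows, orient="index", columns=list(RANKS)))


def _truth_to_json(truth: dict[str, TriadTruth]) -> dict:
    return {
        rid: {
            "donor_id": t.donor_id,
            "donor_taxa": sorted(t.donor_taxa),
            "pre_taxa": sorted(t.pre_taxa),
            "eligible_taxa": sorted(t.eligible_taxa),
            "engrafted_taxa": sorted(t.engrafted_taxa),
            "post_classes": dict(sorted(t.post_classes.items())),
            "engraft_prob": t.engraft_prob,
        }
        for rid, t in truth.items()
    }


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> dict[str, Path]:
    """Write counts.tsv, taxonomy.tsv, metadata.tsv, tree.nwk and truth.json.

    The emitted files are directly consumable by the analysis entry
    points (and the ``fmt-engraft run`` CLI).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": out / "counts.tsv",
        "taxonomy": out / "taxonomy.tsv",
        "metadata": out / "metadata.tsv",
        "tree": out / "tree.nwk",
        "truth": out / "truth.json",
    }
    cohort.table.data.to_csv(paths["counts"], sep="\t", index_label="sample_id")
    cohort.taxonomy.data.to_csv(paths["taxonomy"], sep="\t", index_label="asv_id")
    meta = pd.DataFrame(
        [
            {
                "sample_id": r.sample_id,
                "dog_id": r.dog_id,
                "role": r.role,
                "donor_id": r.donor_id or "",
                "clinical_signs": r.clinical_signs or "",
                "raw_food": "" if r.raw_food is None else ("yes" if r.raw_food else "no"),
                "kibble": "" if r.kibble is None else ("yes" if r.kibble else "no"),
                "prior_antibiotics": ""
                if r.prior_antibiotics is None
                else ("yes" if r.prior_antibiotics else "no"),
                "body_condition_score": ""
                if r.body_condition_score is None
                else r.body_condition_score,
                "donor_primary": "yes" if r.donor_primary else "",
            }
            for r in cohort.records
        ]
    )
    meta.to_csv(paths["metadata"], sep="\t", index=False)
    cohort.tree.write(str(paths["tree"]))
    payload = {
        "seed": cohort.config.seed,
        "config": {
            k: list(v) if isinstance(v, tuple) else v
            for k, v in cohort.config.__dict__.items()
        },
        "triads": _truth_to_json(cohort.truth),
    }
    with open(paths["truth"], "w") as fh:
        json.dump(payload, fh, indent=1)
    return paths
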
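"""Donor-bacteria engraftment: the central per-triad computations.

For a triad with donor/pre/post presence sets D, P, Q (presence = at
least ``min_presence`` reads after the dataset-wide rare-ASV filter):

- engraftment rate = 100 * |(Q n D) \\ P| / |D \\ P|, i.e. the share of
  donor ASVs with the capacity to engraft (not already in the recipient)
  that appear in the recipient post-FMT;
- every ASV present at a stage is assigned a provenance class:
  always-shared (D n P), donor-derived (D \\ P), recipient-derived
  (P \\ D), or environmental/stochastic (neither);
- provenance abundance fractions sum each class's relative abundance
  within the stage's own sample;
- taxon engraftment frequency counts (triad, engrafted ASV) events per
  lowest-classified taxon label.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from fmt_engraft.io import AsvTable, TaxonomyTable, Triad

CLASSES = ("always_shared", "donor_derived", "recipient_derived", "environmental")


@dataclass(frozen=True)
class EngraftmentResult:
    recipient_id: str
    donor_set_size: int
    eligible_set: frozenset[str]
    engrafted_set: frozenset[str]
    rate_percent: float | None  # None when the eligible set is empty

    @property
    def defined(self) -> bool:
        return self.rate_percent is not None

    def __post_init__(self) -> None:
        assert self.engrafted_set <= self.eligible_set
        if self.rate_percent is not None:
            assert 0.0 <= self.rate_percent <= 100.0


@dataclass(frozen=True)
class ProvenancePartition:
    recipient_id: str
    stage: str  # preFMT | postFMT
    fraction_always_shared: float
    fraction_donor_derived: float
    fraction_recipient_derived: float
    fraction_environmental: float

    def as_dict(self) -> dict[str, float]:
        return {
            "always_shared": self.fraction_always_shared,
            "donor_derived": self.fraction_donor_derived,
            "recipient_derived": self.fraction_recipient_derived,
            "environmental": self.fraction_environmental,
        }


@dataclass(frozen=True)
class TaxonEngraftmentSummary:
    taxon: str
    n_engraftment_events: int
    percent_of_all_events: float


def presence_set(table: AsvTable, sample_id: str, min_presence: int = 1) -> set[str]:
    """ASVs with at least ``min_presence`` reads in a sample."""
    counts = table.counts(sample_id)
    present = {a for a, c in zip(table.asv_ids, counts) if c >= min_presence}
    if not present:
        warnings.warn(f"sample {sample_id!r} has no ASVs present", stacklevel=2)
    return present


def engraftment_rate(
    triad: Triad, table: AsvTable, min_presence: int = 1
) -> EngraftmentResult:
    """Per-triad donor-ASV engraftment rate.

    Assumes the dataset-wide singleton/doubleton filter has been applied.
    When no donor ASV is eligible (the recipient already carried the
    donor's entire community) the rate is undefined and flagged.
    """
    d = presence_set(table, triad.donor_sample, min_presence)
    p = presence_set(table, triad.pre_sample, min_presence)
    q = presence_set(table, triad.post_sample, min_presence)
    eligible = d - p
    engrafted = (q & d) - p
    rate = 100.0 * len(engrafted) / len(eligible) if eligible else None
    return EngraftmentResult(
        recipient_id=triad.recipient_id,
        donor_set_size=len(d),
        eligible_set=frozenset(eligible),
        engrafted_set=frozenset(engrafted),
        rate_percent=rate,
    )


def classify_provenance(
    triad: Triad, table: AsvTable, stage: str, min_presence: int = 1
) -> dict[str, str]:
    """Provenance class of every ASV present at a stage.

    At stage ``preFMT`` only always-shared and recipient-derived classes
    can occur (the stage sample *is* the recipient's pre-FMT community).
    """
    if stage not in ("preFMT", "postFMT"):
        raise ValueError(f"stage must be 'preFMT' or 'postFMT', got {stage!r}")
    d = presence_set(table, triad.donor_sample, min_presence)
    p = presence_set(table, triad.pre_sample, min_presence)
    stage_sample = triad.pre_sample if stage == "preFMT" else triad.post_sample
    present = presence_set(table, stage_sample, min_presence)
    classes = {}
    for asv in present:
        if asv in d and asv in p:
            classes[asv] = "always_shared"
        elif asv in d:
            classes[asv] = "donor_derived"
        elif asv in p:
            classes[asv] = "recipient_derived"
        else:
            classes[asv] = "environmental"
    return classes


def provenance_fractions(
    triad: Triad, table: AsvTable, stage: str, min_presence: int = 1
) -> ProvenancePartition:
    """Abundance fraction of each provenance class at a stage.

    Fractions are relative abundances within the stage's own sample,
    restricted to ASVs passing the presence threshold, and sum to 1.
    """
    classes = classify_provenance(triad, table, stage, min_presence)
    stage_sample = triad.pre_sample if stage == "preFMT" else triad.post_sample
    counts = dict(zip(table.asv_ids, table.counts(stage_sample)))
    total = float(sum(counts[a] for a in classes))
    if total == 0:
        raise ValueError(f"sample {stage_sample!r} has no reads at stage {stage}")
    sums = {c: 0.0 for c in CLASSES}
    for asv, cls in classes.items():
        sums[cls] += counts[asv]
    return ProvenancePartition(
        recipient_id=triad.recipient_id,
        stage=stage,
        fraction_always_shared=sums["always_shared"] / total,
        fraction_donor_derived=sums["donor_derived"] / total,
        fraction_recipient_derived=sums["recipient_derived"] / total,
        fraction_environmental=sums["environmental"] / total,
    )


def taxon_engraftment_frequency(
    results: list[EngraftmentResult], taxonomy: TaxonomyTable
) -> list[TaxonEngraftmentSummary]:
    """Engraftment events per taxon, sorted by descending frequency.

    Each (triad, engrafted ASV) pair is one event; events are grouped by
    the ASV's lowest classified taxon label and expressed as a percent
    of all events.
    """
    events: dict[str, int] = {}
    for result in results:
        for asv in result.engrafted_set:
            label = taxonomy.lowest_classified_label(asv)
            events[label] = events.get(label, 0) + 1
    total = sum(events.values())
    if total == 0:
        return []
    summaries = [
        TaxonEngraftmentSummary(
            taxon=taxon,
            n_engraftment_events=n,
            percent_of_all_events=100.0 * n / total,
        )
        for taxon, n in events.items()
    ]
    summaries.sort(key=lambda s: (-s.n_engraftment_events, s.taxon))
    return summaries


def results_table(results: list[EngraftmentResult]) -> pd.DataFrame:
    """Tabular view of per-triad engraftment results."""
    return pd.DataFrame(
        {
            "recipient_id": [r.recipient_id for r in results],
            "donor_set_size": [r.donor_set_size for r in results],
            "n_eligible": [len(r.eligible_set) for r in results],
            "n_engrafted": [len(r.engrafted_set) for r in results],
            "rate_percent": [
                np.nan if r.rate_percent is None else r.rate_percent for r in results
            ],
            "rate_defined": [r.defined for r in results],
        }
    ).set_index("recipient_id")


def partitions_table(partitions: list[ProvenancePartition]) -> pd.DataFrame:
    """Tabular view of provenance partitions (one row per triad x stage)."""
    return pd.DataFrame(
        {
            "recipient_id": [p.recipient_id for p in partitions],
            "stage": [p.stage for p in partitions],
            "always_shared": [p.fraction_always_shared for p in partitions],
            "donor_derived": [p.fraction_donor_derived for p in partitions],
            "recipient_derived": [p.fraction_recipient_derived for p in partitions],
            "environmental": [p.fraction_environmental for p in partitions],
        }
    )
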
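"""Count-table filtering and normalisation.

Two branches, kept deliberately separate: the dataset-wide
singleton/doubleton filter feeds the engraftment analyses (rare ASVs
would otherwise inflate presence/absence overlap), while rarefaction
feeds alpha diversity only. Proportion and centred log-ratio (CLR)
transforms serve Bray-Curtis and Aitchison distances respectively.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from fmt_engraft.io import AsvTable


@dataclass(frozen=True)
class FilterReport:
    n_asvs_before: int
    n_asvs_removed: int
    removed_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        assert self.n_asvs_removed == len(self.removed_ids) <= self.n_asvs_before


@dataclass(frozen=True)
class RarefiedTable:
    """An :class:`AsvTable` subsampled to fixed depth, plus provenance."""

    table: AsvTable
    depth: int
    seed: int
    excluded_samples: tuple[str, ...]


def remove_rare_asvs(table: AsvTable, max_total: int = 2) -> tuple[AsvTable, FilterReport]:
    """Drop ASVs whose summed count over the whole dataset is <= ``max_total``.

    The default of 2 removes singletons and doubletons. Idempotent; the
    sample set is unchanged.
    """
    totals = table.data.sum(axis=0)
    removed = tuple(totals.index[totals <= max_total])
    kept = totals.index[totals > max_total]
    report = FilterReport(
        n_asvs_before=table.n_asvs,
        n_asvs_removed=len(removed),
        removed_ids=removed,
    )
    if len(kept) == 0:
        warnings.warn("rare-ASV filter removed every ASV", stacklevel=2)
    return AsvTable(table.data[list(kept)].copy()), report


def rarefy(table: AsvTable, depth: int = 26000, seed: int | None = None) -> RarefiedTable:
    """Subsample every sample to ``depth`` reads without replacement.

    Each sample's counts are drawn from the multivariate hypergeometric
    law (equivalent to shuffling its reads and keeping the first
    ``depth``). Samples with fewer than ``depth`` reads are dropped and
    listed in ``excluded_samples``. Deterministic given ``seed``.
    """
    if depth <= 0:
        raise ValueError(f"rarefaction depth must be positive, got {depth}")
    if seed is None:
        raise ValueError("rarefy requires an explicit seed for reproducibility")
    rng = np.random.default_rng(seed)
    kept_rows = {}
    excluded = []
    for sid in table.sample_ids:
        counts = table.counts(sid)
        total = int(counts.sum())
        if total < depth:
            excluded.append(sid)
            continue
        if total == depth:
            kept_rows[sid] = counts
        else:
            kept_rows[sid] = rng.multivariate_hypergeometric(
                counts, depth, method="marginals"
            )
    sub = pd.DataFrame.from_dict(kept_rows, orient="index", columns=table.asv_ids)
    sub = sub.astype(np.int64) if len(sub) else sub.reindex(columns=table.asv_ids)
    return RarefiedTable(
        table=AsvTable(sub),
        depth=depth,
        seed=seed,
        excluded_samples=tuple(excluded),
    )


def to_proportions(table: AsvTable) -> pd.DataFrame:
    """Per-sample relative abundances; every row sums to 1."""
    totals = table.data.sum(axis=1)
    zero = totals.index[totals == 0].tolist()
    if zero:
        raise ValueError(f"all-zero samples cannot be normalised: {zero}")
    return table.data.div(totals, axis=0)


def clr_transform(table: AsvTable, pseudocount: float = 0.5) -> pd.DataFrame:
    """Centred log-ratio transform of counts.

    clr(x)_i = ln(x_i + c) - mean_j ln(x_j + c) with pseudocount c > 0;
    each output row sums to 0.
    """
    if pseudocount <= 0:
        raise ValueError(f"pseudocount must be positive, got {pseudocount}")
    logs = np.log(table.data.to_numpy(dtype=float) + pseudocount)
    clr = logs - logs.mean(axis=1, keepdims=True)
    return pd.DataFrame(clr, index=table.data.index, columns=table.data.columns)
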
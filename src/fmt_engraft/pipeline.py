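"""End-to-end cohort analysis: filtering, engraftment, provenance,
diversity, and the overlap-vs-engraftment correlation.

Two preprocessing branches are kept separate on purpose: the
singleton/doubleton filter applies only to the engraftment analyses,
and rarefaction applies only to alpha diversity.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

import fmt_engraft
from fmt_engraft.diversity import TreeBranches, _unifrac_from_fractions, alpha_diversity_table
from fmt_engraft.engraftment import (
    EngraftmentResult,
    ProvenancePartition,
    engraftment_rate,
    partitions_table,
    provenance_fractions,
    results_table,
    taxon_engraftment_frequency,
)
from fmt_engraft.io import AsvTable, SampleRecord, TaxonomyTable, Triad, assemble_triads
from fmt_engraft.preprocess import rarefy, remove_rare_asvs
from fmt_engraft.stats import CorrelationResult, spearman, summarize_cohort, summary_table


@dataclass
class AnalysisResult:
    triads: list[Triad]
    engraftment: list[EngraftmentResult]
    partitions: list[ProvenancePartition]
    taxon_summary: pd.DataFrame | None
    cohort_summary: dict
    similarity_correlation: CorrelationResult | None
    donor_similarity: pd.DataFrame | None  # per-triad donor-pre similarity
    alpha: pd.DataFrame | None
    alpha_excluded: tuple[str, ...]
    filter_report: object
    config: dict


def run_engraftment_analysis(
    table: AsvTable,
    records: Sequence[SampleRecord],
    taxonomy: TaxonomyTable | None = None,
    tree: TreeNode | None = None,
    *,
    donor_policy: str = "single",
    rare_max_total: int = 2,
    min_presence: int = 1,
    alpha_depth: int = 26000,
    seed: int = 0,
    compute_alpha: bool = True,
    out_dir: str | Path | None = None,
) -> AnalysisResult:
    """Run the full per-triad engraftment analysis over a cohort.

    Returns an :class:`AnalysisResult`; when ``out_dir`` is given, all
    result tables are also written there as TSV with a manifest.
    """
    config = {
        "donor_policy": donor_policy,
        "rare_max_total": rare_max_total,
        "min_presence": min_presence,
        "alpha_depth": alpha_depth,
        "seed": seed,
    }

    filtered, report = remove_rare_asvs(table, max_total=rare_max_total)
    triads, filtered = assemble_triads(filtered, records, donor_policy=donor_policy)

    engraftment = [engraftment_rate(t, filtered, min_presence) for t in triads]
    partitions = []
    for t in triads:
        partitions.append(provenance_fractions(t, filtered, "preFMT", min_presence))
        partitions.append(provenance_fractions(t, filtered, "postFMT", min_presence))
    cohort_summary = summarize_cohort(engraftment, partitions)

    taxon_summary = None
    if taxonomy is not None:
        freqs = taxon_engraftment_frequency(engraftment, taxonomy)
        taxon_summary = pd.DataFrame(
            {
                "taxon": [f.taxon for f in freqs],
                "n_engraftment_events": [f.n_engraftment_events for f in freqs],
                "percent_of_all_events": [f.percent_of_all_events for f in freqs],
            }
        )

    similarity_correlation = None
    donor_similarity = None
    if tree is not None:
        donor_similarity = donor_pre_similarity(filtered, triads, tree)
        post = {p.recipient_id: p for p in partitions if p.stage == "postFMT"}
        sims = donor_similarity["unifrac_similarity"]
        donor_frac = [post[rid].fraction_donor_derived for rid in donor_similarity.index]
        similarity_correlation = spearman(
            donor_frac,
            sims.to_numpy(),
            x_label="postFMT_donor_derived_fraction",
            y_label="donor_pre_unifrac_similarity",
        )

    alpha = None
    alpha_excluded: tuple[str, ...] = ()
    if compute_alpha:
        rarefied = rarefy(table, depth=alpha_depth, seed=seed)
        alpha_excluded = rarefied.excluded_samples
        if rarefied.table.n_samples:
            alpha = alpha_diversity_table(rarefied.table)

    result = AnalysisResult(
        triads=triads,
        engraftment=engraftment,
        partitions=partitions,
        taxon_summary=taxon_summary,
        cohort_summary=cohort_summary,
        similarity_correlation=similarity_correlation,
        donor_similarity=donor_similarity,
        alpha=alpha,
        alpha_excluded=alpha_excluded,
        filter_report=report,
        config=config,
    )
    if out_dir is not None:
        write_results(result, out_dir)
    return result


def donor_pre_similarity(
    table: AsvTable, triads: Sequence[Triad], tree: TreeNode
) -> pd.DataFrame:
    """Weighted UniFrac similarity (1 - normalised distance) between each
    recipient's pre-FMT sample and its donor sample."""
    branches = TreeBranches(tree, table.asv_ids)
    rows = {}
    for t in triads:
        pd_ = branches.branch_fractions(table.counts(t.donor_sample))
        pp = branches.branch_fractions(table.counts(t.pre_sample))
        dist = _unifrac_from_fractions(branches.lengths, pd_, pp, normalized=True)
        rows[t.recipient_id] = {"unifrac_similarity": 1.0 - dist}
    return pd.DataFrame.from_dict(rows, orient="index")


def _config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_results(result: AnalysisResult, out_dir: str | Path) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    header = f"fmt-engraft v{fmt_engraft.__version__} config={_config_hash(result.config)}"

    def _write(df: pd.DataFrame, name: str, index: bool = True, label: str | None = None):
        path = out / name
        with open(path, "w") as fh:
            fh.write(f"# {header}\n")
            df.to_csv(fh, sep="\t", index=index, index_label=label)
        return path

    paths = {}
    paths["rates"] = _write(results_table(result.engraftment), "engraftment_rates.tsv", label="recipient_id")
    paths["fractions"] = _write(
        partitions_table(result.partitions), "provenance_fractions.tsv", index=False
    )
    paths["summary"] = _write(summary_table(result.cohort_summary), "cohort_summary.tsv", label="statistic")
    if result.taxon_summary is not None:
        paths["taxa"] = _write(result.taxon_summary, "engrafted_taxa.tsv", index=False)
    if result.alpha is not None:
        paths["alpha"] = _write(result.alpha, "alpha_diversity.tsv", label="sample_id")
    report = result.filter_report
    pre_rows = [
        {"item": "n_asvs_before", "value": report.n_asvs_before},
        {"item": "n_asvs_removed", "value": report.n_asvs_removed},
        {"item": "removed_ids", "value": ";".join(report.removed_ids)},
        {"item": "alpha_excluded_samples", "value": ";".join(result.alpha_excluded)},
    ]
    paths["preprocess"] = _write(pd.DataFrame(pre_rows), "preprocess_report.tsv", index=False)
    corr_rows = []
    if result.similarity_correlation is not None:
        c = result.similarity_correlation
        corr_rows.append(
            {
                "x": c.x_label,
                "y": c.y_label,
                "rho": c.rho,
                "p_value": c.p_value,
                "n": c.n,
                "method": c.method,
            }
        )
    if corr_rows:
        paths["correlations"] = _write(pd.DataFrame(corr_rows), "correlations.tsv", index=False)
    if result.donor_similarity is not None:
        paths["similarity"] = _write(
            result.donor_similarity, "donor_pre_similarity.tsv", label="recipient_id"
        )
    manifest = {
        "package": "fmt-engraft",
        "version": fmt_engraft.__version__,
        "config": result.config,
        "config_hash": _config_hash(result.config),
        "n_triads": len(result.triads),
        "outputs": {k: str(v) for k, v in paths.items()},
    }
    manifest_path = out / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1)
    paths["manifest"] = manifest_path
    return paths
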
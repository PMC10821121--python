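"""Engraftment-rate and provenance-partition semantics."""

import numpy as np
import pandas as pd
import pytest

from fmt_engraft import (
    AsvTable,
    TaxonomyTable,
    Triad,
    classify_provenance,
    engraftment_rate,
    presence_set,
    provenance_fractions,
    taxon_engraftment_frequency,
)
from fmt_engraft.io import RANKS


def _table(rows: dict[str, dict[str, int]], asvs=None):
    df = pd.DataFrame.from_dict(rows, orient="index").fillna(0).astype(int)
    if asvs:
        df = df.reindex(columns=asvs, fill_value=0)
    return AsvTable(df)


class TestPresenceSet:
    def test_threshold_one(self):
        table = _table({"s": {"a": 0, "b": 3, "c": 1}})
        assert presence_set(table, "s") == {"b", "c"}

    def test_all_zero_sample_warns_empty(self):
        table = _table({"s": {"a": 0, "b": 0}})
        with pytest.warns(UserWarning, match="no ASVs"):
            assert presence_set(table, "s") == set()

    def test_min_presence_threshold(self):
        table = _table({"s": {"a": 0, "b": 3, "c": 1}})
        assert presence_set(table, "s", min_presence=2) == {"b"}

    def test_unknown_sample_errors(self):
        table = _table({"s": {"a": 1}})
        with pytest.raises(KeyError):
            presence_set(table, "nope")


class TestEngraftmentRate:
    def test_manual_set_enumeration(self, spec_triad):
        triad, table = spec_triad
        result = engraftment_rate(triad, table)
        assert result.eligible_set == {"b", "c", "d"}
        assert result.engrafted_set == {"b"}
        assert result.rate_percent == pytest.approx(100 / 3)

    def test_full_engraftment_hits_upper_bound(self):
        table = _table(
            {
                "d": {"a": 5, "b": 5},
                "p": {"x": 5},
                "q": {"a": 1, "b": 1, "x": 1},
            }
        )
        triad = Triad("r", "d", "p", "q")
        assert engraftment_rate(triad, table).rate_percent == 100.0

    def test_empty_eligible_set_flagged_undefined(self):
        table = _table({"d": {"a": 5}, "p": {"a": 5}, "q": {"a": 5}})
        result = engraftment_rate(Triad("r", "d", "p", "q"), table)
        assert not result.defined
        assert result.rate_percent is None

    def test_locality_unrelated_samples_do_not_change_result(self, spec_triad, rng):
        triad, table = spec_triad
        before = engraftment_rate(triad, table)
        extra = table.data.copy()
        extra.loc["other1"] = rng.integers(0, 9, size=table.n_asvs)
        extra["new_asv"] = [0, 0, 0, 5]
        after = engraftment_rate(triad, AsvTable(extra))
        assert after.eligible_set == before.eligible_set
        assert after.engrafted_set == before.engrafted_set
        assert after.rate_percent == before.rate_percent

    def test_rate_monotone_in_post_sample(self, spec_triad):
        triad, table = spec_triad
        base = engraftment_rate(triad, table).rate_percent
        grown = table.data.copy()
        grown.loc["post_s", "c"] = 4  # add another donor ASV to post
        assert engraftment_rate(triad, AsvTable(grown)).rate_percent >= base

    def test_matches_exhaustive_enumeration_on_random_tables(self, rng):
        """Brute-force oracle: classify every ASV by direct set membership."""
        for _ in range(50):
            n = int(rng.integers(3, 21))
            counts = rng.integers(0, 4, size=(3, n))
            table = _table(
                {
                    s: dict(zip([f"a{j}" for j in range(n)], row))
                    for s, row in zip(("d", "p", "q"), counts)
                }
            )
            result = engraftment_rate(Triad("r", "d", "p", "q"), table)
            elig, engr = set(), set()
            for j in range(n):
                in_d, in_p, in_q = (counts[k, j] >= 1 for k in range(3))
                if in_d and not in_p:
                    elig.add(f"a{j}")
                    if in_q:
                        engr.add(f"a{j}")
            assert result.eligible_set == elig
            assert result.engrafted_set == engr
            if elig:
                assert result.rate_percent == pytest.approx(100 * len(engr) / len(elig))
            else:
                assert result.rate_percent is None


class TestProvenance:
    def test_manual_classification(self, spec_triad):
        triad, table = spec_triad
        classes = classify_provenance(triad, table, "postFMT")
        assert classes == {
            "a": "always_shared",
            "b": "donor_derived",
            "e": "recipient_derived",
            "f": "environmental",
        }

    def test_prefmt_only_two_classes(self, spec_triad):
        triad, table = spec_triad
        classes = classify_provenance(triad, table, "preFMT")
        assert classes == {"a": "always_shared", "e": "recipient_derived"}

    def test_donor_equals_pre_forbids_donor_derived(self):
        table = _table(
            {"d": {"a": 5, "b": 5}, "p": {"a": 5, "b": 5}, "q": {"a": 1, "b": 1, "z": 3}}
        )
        classes = classify_provenance(Triad("r", "d", "p", "q"), table, "postFMT")
        assert "donor_derived" not in classes.values()

    def test_fraction_manual_sum(self, spec_triad):
        triad, table = spec_triad
        part = provenance_fractions(triad, table, "postFMT")
        assert part.fraction_always_shared == pytest.approx(0.4)
        assert part.fraction_donor_derived == pytest.approx(0.3)
        assert part.fraction_recipient_derived == pytest.approx(0.2)
        assert part.fraction_environmental == pytest.approx(0.1)

    def test_pre_subset_of_donor_all_always_shared(self):
        table = _table({"d": {"a": 5, "b": 5}, "p": {"a": 3}, "q": {"a": 1}})
        part = provenance_fractions(Triad("r", "d", "p", "q"), table, "preFMT")
        assert part.fraction_always_shared == pytest.approx(1.0)

    def test_partition_property_random_tables(self, rng):
        """Class map covers the stage presence set; fractions sum to 1."""
        for _ in range(25):
            n = int(rng.integers(4, 20))
            counts = rng.integers(0, 4, size=(3, n))
            counts[:, 0] += 1  # non-empty samples
            table = _table(
                {
                    s: dict(zip([f"a{j}" for j in range(n)], row))
                    for s, row in zip(("d", "p", "q"), counts)
                }
            )
            triad = Triad("r", "d", "p", "q")
            for stage, sample_row in (("preFMT", 1), ("postFMT", 2)):
                classes = classify_provenance(triad, table, stage)
                present = {f"a{j}" for j in range(n) if counts[sample_row, j] >= 1}
                assert set(classes) == present
                part = provenance_fractions(triad, table, stage)
                total = sum(part.as_dict().values())
                assert total == pytest.approx(1.0, abs=1e-9)
                if stage == "preFMT":
                    assert part.fraction_donor_derived == 0.0
                    assert part.fraction_environmental == 0.0


def _taxonomy(rows):
    df = pd.DataFrame.from_dict(rows, orient="index").reindex(columns=list(RANKS))
    return TaxonomyTable(df)


class TestTaxonFrequency:
    def test_single_genus_takes_all_events(self, spec_triad):
        triad, table = spec_triad
        result = engraftment_rate(triad, table)
        taxonomy = _taxonomy({"b": {"domain": "Bacteria", "genus": "Blautia"}})
        summary = taxon_engraftment_frequency([result, result], taxonomy)
        assert len(summary) == 1
        assert summary[0].taxon == "Blautia"
        assert summary[0].n_engraftment_events == 2
        assert summary[0].percent_of_all_events == pytest.approx(100.0)

    def test_unclassified_genus_grouped_under_family(self, spec_triad):
        triad, table = spec_triad
        result = engraftment_rate(triad, table)
        taxonomy = _taxonomy(
            {"b": {"domain": "Bacteria", "family": "Ruminococcaceae", "genus": None}}
        )
        summary = taxon_engraftment_frequency([result], taxonomy)
        assert summary[0].taxon == "unclassified Ruminococcaceae"

    def test_percents_sum_to_100(self, small_cohort):
        from fmt_engraft.preprocess import remove_rare_asvs

        filtered, _ = remove_rare_asvs(small_cohort.table)
        results = [engraftment_rate(t, filtered) for t in small_cohort.triads]
        summary = taxon_engraftment_frequency(results, small_cohort.taxonomy)
        assert sum(s.percent_of_all_events for s in summary) == pytest.approx(
            100.0, abs=1e-6
        )

    def test_empty_input_empty_summary(self):
        assert taxon_engraftment_frequency([], _taxonomy({})) == []
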
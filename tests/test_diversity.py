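"""Diversity metrics against hand computations, brute-force oracles, and
the scikit-bio reference implementations."""

import numpy as np
import pandas as pd
import pytest
from skbio.diversity import alpha as skbio_alpha
from skbio.diversity.beta import weighted_unifrac as skbio_weighted_unifrac

from fmt_engraft import (
    AsvTable,
    aitchison_distance,
    alpha_diversity_table,
    bray_curtis,
    chao1,
    clr_transform,
    distance_matrix,
    gini_simpson,
    jaccard_distance,
    shannon,
    simulate_tree,
    weighted_unifrac,
)
from fmt_engraft.io import parse_newick


class TestAlpha:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ((5, 3, 4), 3.0),  # no singletons: chao1 == observed richness
            ((5, 1, 1, 2), 4 + 4 / 2.0),  # F1=2, F2=1
            ((1, 1, 0), 2 + 2 * 1 / 2.0),  # F2=0 fallback branch
            ((), 0.0),
        ],
    )
    def test_chao1_examples(self, counts, expected):
        assert chao1(np.array(counts, dtype=int)) == pytest.approx(expected)

    def test_chao1_bias_corrected_variant(self):
        # S + F1(F1-1) / (2(F2+1)) = 4 + 2/4
        assert chao1([5, 1, 1, 2], bias_corrected=True) == pytest.approx(4.5)

    @pytest.mark.parametrize(
        "counts,expected",
        [
            ((1, 1, 1, 1), np.log(4)),
            ((7,), 0.0),
            ((1, 3), -(0.25 * np.log(0.25) + 0.75 * np.log(0.75))),
        ],
    )
    def test_shannon_examples(self, counts, expected):
        assert shannon(counts) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize(
        "counts,expected",
        [((9,), 0.0), ((1, 1, 1, 1), 0.75), ((1, 1, 2), 0.625)],
    )
    def test_gini_simpson_examples(self, counts, expected):
        assert gini_simpson(counts) == pytest.approx(expected, abs=1e-12)

    def test_chao1_at_least_observed_richness(self, rng):
        for _ in range(50):
            counts = rng.integers(0, 5, size=rng.integers(1, 30))
            assert chao1(counts) >= np.count_nonzero(counts)

    def test_alpha_agrees_with_skbio_on_random_vectors(self, rng):
        for _ in range(100):
            counts = rng.integers(0, 20, size=rng.integers(2, 40))
            if counts.sum() == 0:
                counts[0] = 1
            assert chao1(counts) == pytest.approx(
                skbio_alpha.chao1(counts, bias_corrected=False), abs=1e-8
            )
            assert shannon(counts) == pytest.approx(
                skbio_alpha.shannon(counts), abs=1e-8
            )
            assert gini_simpson(counts) == pytest.approx(
                skbio_alpha.simpson(counts), abs=1e-8
            )

    def test_alpha_table_columns(self, small_cohort):
        alpha = alpha_diversity_table(small_cohort.table)
        assert list(alpha.columns) == ["chao1", "shannon", "gini_simpson"]
        assert (alpha["chao1"] >= 0).all()
        assert ((alpha["gini_simpson"] >= 0) & (alpha["gini_simpson"] < 1)).all()


class TestPairwiseDistances:
    def test_jaccard_examples(self):
        assert jaccard_distance({"x"}, {"x"}) == 0.0
        assert jaccard_distance({"x"}, {"y"}) == 1.0
        assert jaccard_distance(set(), set()) == 0.0
        assert jaccard_distance({"x", "y", "z"}, {"y", "z", "w"}) == pytest.approx(0.5)

    def test_bray_curtis_examples(self):
        assert bray_curtis([0.2, 0.8], [0.2, 0.8]) == 0.0
        assert bray_curtis([1, 0], [0, 1]) == 1.0
        assert bray_curtis([0.5, 0.5, 0], [0.25, 0.25, 0.5]) == pytest.approx(0.5)

    def test_aitchison_examples(self):
        assert aitchison_distance([1.0, -1.0], [1.0, -1.0]) == 0.0
        assert aitchison_distance([0, 0], [1, -1]) == pytest.approx(np.sqrt(2))

    def test_mismatched_shapes_error(self):
        with pytest.raises(ValueError):
            bray_curtis([1, 0], [1, 0, 0])
        with pytest.raises(ValueError):
            aitchison_distance([1], [1, 2])

    def test_brute_force_oracle_equivalence(self, rng):
        """100 random instances per metric against naive summation loops."""
        for _ in range(100):
            n = int(rng.integers(2, 15))
            x = rng.random(n)
            y = rng.random(n)
            x, y = x / x.sum(), y / y.sum()
            bf_bc = sum(abs(a - b) for a, b in zip(x, y)) / sum(
                a + b for a, b in zip(x, y)
            )
            assert bray_curtis(x, y) == pytest.approx(bf_bc, abs=1e-8)
            u = rng.normal(size=n)
            v = rng.normal(size=n)
            bf_ait = np.sqrt(sum((a - b) ** 2 for a, b in zip(u, v)))
            assert aitchison_distance(u, v) == pytest.approx(bf_ait, abs=1e-8)
            sa = {f"t{i}" for i in np.flatnonzero(rng.random(n) < 0.5)}
            sb = {f"t{i}" for i in np.flatnonzero(rng.random(n) < 0.5)}
            bf_j = 1 - len(sa & sb) / len(sa | sb) if (sa | sb) else 0.0
            assert jaccard_distance(sa, sb) == pytest.approx(bf_j, abs=1e-12)

    def test_metric_axioms_on_random_tables(self, rng):
        from tests.conftest import random_count_table

        table = random_count_table(rng, 6, 20)
        for metric in ("jaccard", "bray_curtis", "aitchison"):
            dm = distance_matrix(table, metric)
            arr = dm.to_numpy()
            assert np.allclose(np.diag(arr), 0.0)
            assert np.allclose(arr, arr.T, atol=1e-12)
            assert (arr >= 0).all()
            if metric != "aitchison":
                assert (arr <= 1 + 1e-12).all()


def _brute_force_weighted_unifrac(tree, asv_ids, x, y, normalized):
    """Independent oracle: enumerate every branch's descendant leaf set."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    px, py = x / x.sum(), y / y.sum()
    idx = {a: i for i, a in enumerate(asv_ids)}
    raw = denom = 0.0
    for node in tree.traverse(include_self=False):
        leaves = [leaf.name for leaf in ([node] if node.is_tip() else node.tips())]
        fx = sum(px[idx[l]] for l in leaves if l in idx)
        fy = sum(py[idx[l]] for l in leaves if l in idx)
        raw += node.length * abs(fx - fy)
        denom += node.length * (fx + fy)
    if not normalized:
        return raw
    return raw / denom if denom else 0.0


class TestWeightedUnifrac:
    def test_identical_samples_distance_zero(self):
        tree = parse_newick("((a:1,b:1):1,c:2);")
        x = [3, 2, 1]
        assert weighted_unifrac(x, x, ["a", "b", "c"], tree) == pytest.approx(0.0)

    def test_two_leaf_complete_separation(self):
        tree = parse_newick("(a:1,b:1);")
        raw = weighted_unifrac([10, 0], [0, 10], ["a", "b"], tree, normalized=False)
        norm = weighted_unifrac([10, 0], [0, 10], ["a", "b"], tree, normalized=True)
        assert raw == pytest.approx(2.0)
        assert norm == pytest.approx(1.0)

    def test_taxon_absent_from_tree_errors(self):
        tree = parse_newick("(a:1,b:1);")
        with pytest.raises(ValueError, match="absent from tree"):
            weighted_unifrac([1, 1], [1, 2], ["a", "zzz"], tree)

    def test_random_instances_match_branch_set_oracle_and_skbio(self, rng):
        ids = [f"L{i}" for i in range(20)]
        for trial in range(25):
            tree = simulate_tree(ids, rng)
            x = rng.integers(0, 50, size=20)
            y = rng.integers(0, 50, size=20)
            x[0] += 1
            y[1] += 1
            for normalized in (False, True):
                mine = weighted_unifrac(x, y, ids, tree, normalized=normalized)
                oracle = _brute_force_weighted_unifrac(tree, ids, x, y, normalized)
                ref = skbio_weighted_unifrac(
                    x, y, taxa=ids, tree=tree, normalized=normalized
                )
                assert mine == pytest.approx(oracle, abs=1e-8)
                assert mine == pytest.approx(ref, abs=1e-8)

    def test_scale_invariance_and_range(self, rng):
        ids = [f"L{i}" for i in range(10)]
        tree = simulate_tree(ids, rng)
        x = rng.integers(1, 40, size=10)
        y = rng.integers(1, 40, size=10)
        d1 = weighted_unifrac(x, y, ids, tree)
        d2 = weighted_unifrac(7 * x, 3 * y, ids, tree)
        assert d1 == pytest.approx(d2, abs=1e-12)
        assert 0.0 <= d1 <= 1.0

    def test_unifrac_matrix_symmetry(self, small_cohort):
        sub = small_cohort.table.subset_samples(small_cohort.table.sample_ids[:5])
        dm = distance_matrix(sub, "weighted_unifrac", tree=small_cohort.tree)
        arr = dm.to_numpy()
        assert np.allclose(arr, arr.T, atol=1e-12)
        assert np.allclose(np.diag(arr), 0.0)
        assert ((arr >= 0) & (arr <= 1 + 1e-12)).all()
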
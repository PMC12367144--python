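"""Noise filtering, TMM normalization, replicate selection, correlations,
DEG overlap and Fisher species-bias tests.

The TMM implementation is checked against factors computed once with
Bioconductor edgeR's calcNormFactors on the same matrix (frozen below).
The Fisher test is checked against a full margin-fixed enumeration oracle.
"""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from twindiverge import expression as expr
from twindiverge.io_formats import CountMatrix, DifferentialResult
from twindiverge.orthology import OrthologPair
from twindiverge.simulate import CountSimParams, simulate_counts


def make_matrix(values: np.ndarray, samples=None, species=None,
                tissue=None, replicate=None) -> CountMatrix:
    n = values.shape[1]
    samples = samples or [f"s{i+1}" for i in range(n)]
    meta = pd.DataFrame(
        {
            "species": species or ["A"] * n,
            "tissue": tissue or ["head"] * n,
            "replicate": replicate or [str(i + 1) for i in range(n)],
        },
        index=samples,
    )
    vals = pd.DataFrame(values, columns=samples,
                        index=[f"g{i}" for i in range(values.shape[0])])
    return CountMatrix(vals.astype(float), meta)


class TestFilterLowExpectedCounts:
    def test_below_threshold_removed(self):
        m = make_matrix(np.array([[0.5, 0.4, 0.3], [1.0, 1.0, 1.0]]))
        out = expr.filter_low_expected_counts(m)
        assert out.gene_ids == ["g1"]

    def test_exactly_threshold_kept(self):
        m = make_matrix(np.array([[1.0, 1.0, 0.0]]))
        out = expr.filter_low_expected_counts(m)
        assert out.gene_ids == ["g0"]

    def test_all_zero_matrix_empties(self):
        m = make_matrix(np.zeros((3, 2)))
        assert expr.filter_low_expected_counts(m).gene_ids == []

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        m = make_matrix(rng.poisson(1.0, size=(50, 4)).astype(float))
        once = expr.filter_low_expected_counts(m)
        twice = expr.filter_low_expected_counts(once)
        assert once.gene_ids == twice.gene_ids


# matrix drawn once from a seeded generator; factors computed with
# Bioconductor edgeR 4.0.16: calcNormFactors(m, method="TMM")
EDGER_MATRIX = np.array([
    [345, 230, 3872, 133], [326, 455, 1640, 248], [185, 1032, 536, 498],
    [305, 930, 2352, 169], [127, 417, 2360, 166], [229, 410, 282, 97],
    [266, 117, 240, 188], [253, 650, 264, 191], [244, 120, 253, 230],
    [121, 750, 630, 305], [294, 717, 317, 112], [163, 335, 141, 105],
    [154, 552, 376, 186], [388, 757, 236, 118], [264, 535, 136, 205],
    [260, 397, 179, 196], [325, 555, 181, 235], [324, 437, 157, 240],
    [237, 455, 196, 339], [92, 157, 267, 264], [235, 382, 263, 353],
    [250, 545, 249, 336], [44, 475, 467, 623], [253, 495, 340, 535],
    [257, 800, 159, 258], [171, 272, 164, 369], [189, 1220, 375, 178],
    [203, 1037, 207, 124], [119, 287, 167, 83], [328, 1055, 120, 126],
], dtype=float)
EDGER_FACTORS = [1.388602, 1.168973, 0.545811, 1.128692]


class TestTmmFactors:
    def test_identical_samples_unit_factors(self):
        col = np.arange(1, 31, dtype=float)
        m = make_matrix(np.column_stack([col, col]))
        f = expr.tmm_factors(m)
        assert np.allclose(f.factors, [1.0, 1.0])

    def test_matches_edger_reference(self):
        m = make_matrix(EDGER_MATRIX)
        f = expr.tmm_factors(m)
        assert np.allclose(f.factors.values, EDGER_FACTORS, atol=1e-4)

    def test_factor_product_is_one(self):
        m = make_matrix(EDGER_MATRIX)
        f = expr.tmm_factors(m)
        assert math.prod(f.factors) == pytest.approx(1.0)

    def test_scale_invariance_of_normalized_expression(self):
        rng = np.random.default_rng(3)
        base = rng.negative_binomial(5, 0.05, size=(200, 1)).astype(float)
        m = make_matrix(np.column_stack([base[:, 0], 2.0 * base[:, 0]]))
        normalized = expr.log2_normalize(m, expr.tmm_factors(m))
        assert np.allclose(normalized["s1"], normalized["s2"])

    def test_gene_order_invariance(self):
        m = make_matrix(EDGER_MATRIX)
        perm = np.random.default_rng(1).permutation(EDGER_MATRIX.shape[0])
        m2 = make_matrix(EDGER_MATRIX[perm])
        assert np.allclose(expr.tmm_factors(m).factors,
                           expr.tmm_factors(m2).factors)

    def test_uniform_rescaling_invariance(self):
        m = make_matrix(EDGER_MATRIX)
        m2 = make_matrix(EDGER_MATRIX * 3.0)
        assert np.allclose(expr.tmm_factors(m).factors,
                           expr.tmm_factors(m2).factors)

    def test_all_zero_sample_rejected(self):
        m = make_matrix(np.array([[1.0, 0.0], [2.0, 0.0]]))
        with pytest.raises(ValueError, match="s2"):
            expr.tmm_factors(m)


class TestLog2Normalize:
    def test_zero_count_finite(self):
        m = make_matrix(np.array([[0.0, 5.0], [10.0, 10.0]]))
        out = expr.log2_normalize(m, expr.tmm_factors(m))
        assert np.isfinite(out.values).all()

    def test_monotone_in_counts(self):
        m = make_matrix(np.array([[1.0, 1.0], [2.0, 1.0], [50.0, 1.0]]))
        out = expr.log2_normalize(m, expr.tmm_factors(m))
        col = out["s1"].values
        assert col[0] < col[1] < col[2]

    def test_identical_samples_identical_columns(self):
        col = np.arange(1, 21, dtype=float)
        m = make_matrix(np.column_stack([col, col]))
        out = expr.log2_normalize(m, expr.tmm_factors(m))
        assert np.allclose(out["s1"], out["s2"])


class TestSelectConsistentReplicates:
    def test_most_correlated_pair_chosen(self):
        rng = np.random.default_rng(0)
        base = rng.normal(8, 2, 300)
        r1 = base + rng.normal(0, 0.05, 300)
        r2 = base + rng.normal(0, 0.05, 300)
        r3 = base + rng.normal(0, 2.0, 300)
        counts = np.power(2.0, np.column_stack([r1, r2, r3]))
        m = make_matrix(counts, replicate=["1", "2", "3"])
        chosen = expr.select_consistent_replicates(m)
        assert chosen[("A", "head")] == ("s1", "s2")

    def test_two_replicates_returned_as_is(self):
        m = make_matrix(np.abs(np.random.default_rng(0)
                               .normal(50, 10, (20, 2))))
        chosen = expr.select_consistent_replicates(m)
        assert chosen[("A", "head")] == ("s1", "s2")

    def test_single_replicate_rejected(self):
        m = make_matrix(np.ones((5, 1)) * 10)
        with pytest.raises(ValueError, match="fewer than 2"):
            expr.select_consistent_replicates(m)


class TestCrossSpeciesCorrelation:
    def _normalized(self, x, y):
        idx_a = [f"a{i}" for i in range(len(x))]
        idx_b = [f"b{i}" for i in range(len(y))]
        df = pd.DataFrame(
            np.concatenate([x, y]),
            index=idx_a + idx_b, columns=["sA"])
        df["sB"] = df["sA"]
        pairs = [OrthologPair(a, b, 1.0, 1.0)
                 for a, b in zip(idx_a, idx_b)]
        return df, pairs

    def test_identical_vectors_r_one(self):
        x = np.arange(10.0)
        df, pairs = self._normalized(x, x)
        r = expr.cross_species_correlation(df, ["sA"], ["sB"], pairs)
        assert r == pytest.approx(1.0)

    def test_decreasing_transform_spearman_minus_one(self):
        x = np.arange(10.0)
        df, pairs = self._normalized(x, -np.exp(x))
        rho = expr.cross_species_correlation(df, ["sA"], ["sB"], pairs,
                                             method="spearman")
        assert rho == pytest.approx(-1.0)

    def test_too_few_pairs_rejected(self):
        df, pairs = self._normalized(np.arange(2.0), np.arange(2.0))
        with pytest.raises(ValueError):
            expr.cross_species_correlation(df, ["sA"], ["sB"], pairs)

    def test_planted_correlation_recovered(self):
        params = CountSimParams(
            n_genes=2000, species_correlation=0.7,
            de_fraction={"head": 0.0, "leg": 0.0}, seed=8)
        matrix, _ = simulate_counts(params)
        matrix = expr.filter_low_expected_counts(matrix)
        normalized = expr.log2_normalize(matrix, expr.tmm_factors(matrix))
        chosen = expr.select_consistent_replicates(matrix, normalized)
        pairs = [OrthologPair(g, g, 1.0, 1.0) for g in matrix.gene_ids]
        r = expr.cross_species_correlation(
            normalized, list(chosen[("A", "head")]),
            list(chosen[("B", "head")]), pairs)
        assert r == pytest.approx(0.7, abs=0.05)


def de(gene, lfc, sig=True):
    return DifferentialResult(gene, lfc, 1e-4 if sig else 1.0, sig)


class TestDegOverlap:
    def test_shared_and_exclusive_counts(self):
        head = [de("a", 2.0), de("b", 1.0), de("c", 3.0)]
        leg = [de("b", 1.5), de("c", 2.0), de("d", 1.0)]
        out = expr.deg_overlap(head, leg)
        assert out["up_a"] == {"shared": 2, "head_only": 1, "leg_only": 1}

    def test_disjoint_sets(self):
        out = expr.deg_overlap([de("a", 1.0)], [de("b", 1.0)])
        assert out["up_a"]["shared"] == 0

    def test_identical_sets(self):
        head = [de(g, -1.0) for g in "abc"]
        out = expr.deg_overlap(head, head)
        assert out["up_b"] == {"shared": 3, "head_only": 0, "leg_only": 0}

    def test_conflicting_duplicates_rejected(self):
        with pytest.raises(ValueError, match="conflicting"):
            expr.deg_overlap([de("a", 1.0), de("a", 2.0)], [])


def fisher_oracle(table):
    """Two-sided Fisher p by full enumeration over margin-fixed tables."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x):
        return (math.comb(r1, x) * math.comb(r2, c1 - x)
                / math.comb(n, c1))

    p_obs = prob(a)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        p = prob(x)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return total


class TestFisherBiasTest:
    @pytest.mark.parametrize("cells,expected", [
        (((2, 0), (0, 2)), 1 / 3),
        (((5, 5), (5, 5)), 1.0),
        (((10, 0), (0, 10)), 2 / math.comb(20, 10)),
    ])
    def test_known_values(self, cells, expected):
        table = expr.ContingencyTable2x2(cells)
        assert expr.fisher_bias_test(table) == pytest.approx(expected,
                                                             rel=1e-6)

    def test_zero_margin_gives_one(self):
        table = expr.ContingencyTable2x2(((0, 0), (3, 5)))
        assert expr.fisher_bias_test(table) == 1.0

    def test_matches_enumeration_small_tables(self):
        rng = np.random.default_rng(5)
        for _ in range(60):
            cells = tuple(tuple(int(v) for v in row)
                          for row in rng.integers(0, 11, size=(2, 2)))
            table = expr.ContingencyTable2x2(cells)
            got = expr.fisher_bias_test(table)
            if min(sum(r) for r in cells) == 0 or \
                    min(cells[0][i] + cells[1][i] for i in range(2)) == 0:
                assert got == 1.0
            else:
                assert got == pytest.approx(fisher_oracle(cells), rel=1e-6)

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            expr.ContingencyTable2x2(((-1, 0), (0, 2)))


class TestSpeciesBiasPipeline:
    def test_planted_leg_bias_detected(self):
        params = CountSimParams(
            n_genes=2000,
            de_fraction={"head": 0.05, "leg": 0.1},
            up_in_a_bias={"head": 0.5, "leg": 0.8},
            seed=13)
        _, truth = simulate_counts(params)
        table = expr.direction_by_tissue_table(truth["head"], truth["leg"])
        assert expr.fisher_bias_test(table) < 0.05

    def test_null_not_detected(self):
        detections = 0
        for seed in range(10):
            params = CountSimParams(
                n_genes=2000,
                de_fraction={"head": 0.05, "leg": 0.05},
                up_in_a_bias={"head": 0.5, "leg": 0.5},
                seed=100 + seed)
            _, truth = simulate_counts(params)
            table = expr.direction_by_tissue_table(truth["head"],
                                                   truth["leg"])
            if expr.fisher_bias_test(table) < 0.05:
                detections += 1
        assert detections <= 1

    def test_membership_table_counts(self):
        deg = [de("a", 2.0), de("b", -1.0), de("c", 1.0),
               de("d", -2.0, sig=False)]
        table = expr.species_bias_table(deg, members={"a", "b"})
        assert table.cells == ((1, 1), (1, 0))
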
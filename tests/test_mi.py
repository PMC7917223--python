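"""Discretization, entropy and mutual-information unit/property tests."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from migenet.containers import AlignmentError
from migenet.mi import (
    DiscretizedVector,
    MIResult,
    default_nbins,
    discretize_equal_frequency,
    entropy_empirical,
    mutual_information,
    pairwise_mi,
)
from tests.conftest import make_matrix


def oracle_discretize(values, nbins):
    """Brute-force equal-frequency assignment: nearest-rank quantile edges,
    right-closed intervals, exhaustive interval-membership check."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    srt = sorted(values)
    edges = []
    for j in range(1, nbins):
        rank = math.ceil(n * j / nbins)  # smallest x with ECDF(x) >= j/nbins
        edges.append(srt[rank - 1])
    edges = sorted(set(edges))
    codes = []
    for v in values:
        code = len(edges)
        for b, e in enumerate(edges):
            if v <= e:
                code = b
                break
        codes.append(code)
    return codes


def oracle_entropy(codes):
    n = len(codes)
    out = 0.0
    for c in set(codes):
        p = codes.count(c) / n if isinstance(codes, list) else (
            np.sum(np.asarray(codes) == c) / n)
        out -= p * math.log(p)
    return out


def oracle_mi(x_codes, y_codes):
    """Plug-in MI from the explicit joint contingency table."""
    n = len(x_codes)
    joint = {}
    for a, b in zip(x_codes, y_codes):
        joint[(a, b)] = joint.get((a, b), 0) + 1
    px = {}
    py = {}
    for (a, b), c in joint.items():
        px[a] = px.get(a, 0) + c
        py[b] = py.get(b, 0) + c
    out = 0.0
    for (a, b), c in joint.items():
        p = c / n
        out += p * math.log(p * n * n / (px[a] * py[b]))
    return max(out, 0.0)


class TestDiscretize:
    def test_distinct_values_equal_bins(self):
        d = discretize_equal_frequency([1, 2, 3, 4, 5, 6], 3)
        assert d.codes.tolist() == [0, 0, 1, 1, 2, 2]
        assert d.effective_nbins == 3

    def test_constant_vector_collapses_to_one_bin(self):
        d = discretize_equal_frequency([7, 7, 7, 7], 3)
        assert d.codes.tolist() == [0, 0, 0, 0]
        assert d.effective_nbins == 1

    def test_zero_inflated_matches_interval_oracle(self):
        values = [0, 0, 0, 0, 1.2, 3.4, 0.5, 2.2]
        d = discretize_equal_frequency(values, 4)
        assert d.codes.tolist() == oracle_discretize(values, 4)

    @pytest.mark.parametrize("nbins", [2, 3, 4, 5])
    def test_random_vectors_match_oracle(self, nbins):
        rng = np.random.default_rng(42)
        for _ in range(50):
            n = int(rng.integers(nbins, 40))
            values = rng.choice([0.0, rng.normal()], size=n)  # heavy ties
            values = values + rng.normal(scale=0.5, size=n) * (rng.random(n) < 0.5)
            d = discretize_equal_frequency(values, nbins)
            assert d.codes.tolist() == oracle_discretize(values, nbins)

    def test_ties_share_a_bin(self):
        d = discretize_equal_frequency([0, 0, 0, 0, 0, 1, 2, 3], 4)
        zero_codes = set(d.codes[:5].tolist())
        assert len(zero_codes) == 1

    def test_input_validation(self):
        with pytest.raises(ValueError):
            discretize_equal_frequency([], 2)
        with pytest.raises(ValueError):
            discretize_equal_frequency([1.0, np.nan], 2)
        with pytest.raises(ValueError):
            discretize_equal_frequency([1.0, 2.0], 3)

    @given(st.lists(st.integers(-10**6, 10**6), min_size=4, max_size=60,
                    unique=True),
           st.integers(2, 4))
    @settings(deadline=None, max_examples=60, derandomize=True)
    def test_monotone_transform_invariance(self, values, nbins):
        """Strictly increasing transforms leave the codes unchanged."""
        values = np.asarray(values, dtype=float)
        base = discretize_equal_frequency(values, nbins).codes
        transformed = np.exp(values / 2e5)  # strictly increasing
        assert discretize_equal_frequency(transformed, nbins).codes.tolist() \
            == base.tolist()

    @given(st.lists(st.integers(-10**6, 10**6), min_size=6, max_size=60,
                    unique=True),
           st.integers(2, 5))
    @settings(deadline=None, max_examples=60, derandomize=True)
    def test_equal_frequency_property(self, values, nbins):
        """All-distinct values: bin sizes differ by at most 1... within the
        nearest-rank convention the spread can reach 1 extra per edge tie,
        so assert max - min <= 1 for n divisible by nbins and bounded
        occupancy otherwise."""
        d = discretize_equal_frequency(values, nbins)
        counts = np.bincount(d.codes, minlength=nbins)
        if len(values) % nbins == 0:
            assert counts.max() - counts.min() <= 1


class TestEntropy:
    def test_uniform_two_symbols(self):
        d = DiscretizedVector(np.array([0, 0, 1, 1]), 2)
        assert entropy_empirical(d) == pytest.approx(math.log(2), abs=1e-12)

    def test_single_symbol_zero(self):
        d = DiscretizedVector(np.array([0, 0, 0, 0]), 1)
        assert entropy_empirical(d) == 0.0

    def test_skewed_counts_match_formula_oracle(self):
        d = DiscretizedVector(np.array([0, 0, 1, 2]), 3)
        expected = -(0.5 * math.log(0.5) + 2 * 0.25 * math.log(0.25))
        assert entropy_empirical(d) == pytest.approx(expected, abs=1e-14)
        assert entropy_empirical(d) == pytest.approx(
            oracle_entropy([0, 0, 1, 2]), abs=1e-14)

    def test_bounded_by_log_effective_bins(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            codes = rng.integers(0, 5, size=int(rng.integers(2, 50)))
            d = DiscretizedVector(codes, 5)
            h = entropy_empirical(d)
            assert 0.0 <= h <= math.log(d.effective_nbins) + 1e-12


class TestMutualInformation:
    def test_self_information_is_entropy(self):
        d = DiscretizedVector(np.array([0, 0, 1, 1]), 2)
        assert mutual_information(d, d) == pytest.approx(math.log(2), abs=1e-12)

    def test_exact_independence_is_zero(self):
        x = DiscretizedVector(np.array([0, 0, 1, 1]), 2)
        y = DiscretizedVector(np.array([0, 1, 0, 1]), 2)
        assert mutual_information(x, y) == 0.0

    def test_contingency_table_oracle(self):
        # joint table [[2,1],[1,2]], n=6
        x = DiscretizedVector(np.array([0, 0, 0, 1, 1, 1]), 2)
        y = DiscretizedVector(np.array([0, 0, 1, 0, 1, 1]), 2)
        assert mutual_information(x, y) == pytest.approx(
            oracle_mi(x.codes.tolist(), y.codes.tolist()), abs=1e-14)

    def test_length_mismatch_raises(self):
        x = DiscretizedVector(np.array([0, 1]), 2)
        y = DiscretizedVector(np.array([0, 1, 0]), 2)
        with pytest.raises(AlignmentError):
            mutual_information(x, y)

    def test_random_pairs_match_oracle_and_symmetry(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            n = int(rng.integers(4, 50))
            x = DiscretizedVector(rng.integers(0, 4, n), 4)
            y = DiscretizedVector(rng.integers(0, 4, n), 4)
            got = mutual_information(x, y)
            assert got == pytest.approx(
                oracle_mi(x.codes.tolist(), y.codes.tolist()), abs=1e-12)
            assert got == pytest.approx(mutual_information(y, x), abs=0)
            assert got >= 0.0


class TestPairwiseMI:
    def test_single_pair_consistency(self):
        m = make_matrix([[1, 5, 2, 8, 3, 9]], "microbe", "m")
        g = make_matrix([[2, 6, 1, 9, 4, 7]], "gene", "g")
        res = pairwise_mi(m, g, nbins=3)
        dx = discretize_equal_frequency(m.values[0], 3)
        dy = discretize_equal_frequency(g.values[0], 3)
        assert res.mi.shape == (1, 1)
        assert res.mi[0, 0] == pytest.approx(mutual_information(dx, dy), abs=1e-12)

    def test_matches_naive_double_loop(self):
        rng = np.random.default_rng(5)
        m = make_matrix(rng.normal(size=(5, 30)), "microbe", "m")
        g = make_matrix(rng.normal(size=(8, 30)), "gene", "g")
        res = pairwise_mi(m, g, nbins=4)
        mx = [discretize_equal_frequency(r, 4) for r in m.values]
        gx = [discretize_equal_frequency(r, 4) for r in g.values]
        naive = np.array([[mutual_information(a, b) for b in gx] for a in mx])
        assert np.abs(res.mi - naive).max() <= 1e-12

    def test_information_bound(self):
        rng = np.random.default_rng(6)
        m = make_matrix(rng.normal(size=(4, 25)), "microbe", "m")
        g = make_matrix(rng.normal(size=(6, 25)), "gene", "g")
        res = pairwise_mi(m, g, nbins=3)
        hm = [entropy_empirical(discretize_equal_frequency(r, 3)) for r in m.values]
        hg = [entropy_empirical(discretize_equal_frequency(r, 3)) for r in g.values]
        for i in range(4):
            for j in range(6):
                assert 0.0 <= res.mi[i, j] <= min(hm[i], hg[j]) + 1e-12

    def test_unit_conversion_exact(self):
        rng = np.random.default_rng(7)
        m = make_matrix(rng.normal(size=(3, 20)), "microbe", "m")
        g = make_matrix(rng.normal(size=(3, 20)), "gene", "g")
        nats = pairwise_mi(m, g, nbins=3, unit="nats")
        bits = pairwise_mi(m, g, nbins=3, unit="bits")
        np.testing.assert_allclose(bits.mi, nats.mi / math.log(2), rtol=0, atol=0)

    def test_unaligned_samples_rejected(self):
        m = make_matrix(np.ones((2, 4)), "microbe", "m",
                        samples=["a", "b", "c", "d"])
        g = make_matrix(np.ones((2, 4)), "gene", "g",
                        samples=["a", "b", "d", "c"])
        with pytest.raises(AlignmentError):
            pairwise_mi(m, g, nbins=2)

    def test_chunking_does_not_change_result(self):
        rng = np.random.default_rng(8)
        m = make_matrix(rng.normal(size=(3, 30)), "microbe", "m")
        g = make_matrix(rng.normal(size=(10, 30)), "gene", "g")
        a = pairwise_mi(m, g, nbins=4, gene_chunk=3)
        b = pairwise_mi(m, g, nbins=4, gene_chunk=1000)
        np.testing.assert_array_equal(a.mi, b.mi)


def test_default_nbins_rules():
    assert default_nbins(60) == 4  # ceil(60^(1/3))
    assert default_nbins(8) == 2
    assert default_nbins(27) == 3
    assert default_nbins(50, rule="n-obs") == 50
    with pytest.raises(ValueError):
        default_nbins(10, rule="bogus")


def test_coupled_pairs_exceed_null_mi(small_dataset):
    """Planted monotone couplings carry more MI than never-coupled pairs."""
    ds = small_dataset
    cols = ds.samples_of("early")
    mi = pairwise_mi(ds.microbe_matrix.subset_samples(cols),
                     ds.gene_matrix.subset_samples(cols))
    idx = {m: i for i, m in enumerate(mi.microbe_ids)}
    jdx = {g: j for j, g in enumerate(mi.gene_ids)}
    truth = ds.truth_pairs("early")
    coupled = np.array([mi.mi[idx[m], jdx[g]] for m, g in truth])
    mask = np.ones(mi.mi.shape, dtype=bool)
    for m, g in truth | ds.truth_pairs("late"):
        mask[idx[m], jdx[g]] = False
    null = mi.mi[mask]
    assert coupled.mean() > null.mean()
    assert np.median(coupled) > np.quantile(null, 0.95)
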
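"""r^2, LD decay curves and AUC machinery, checked against brute force."""

import numpy as np
import pandas as pd
import pytest

from ildscan import ld_core as ld
from ildscan.errors import EmptyCurveError, InsufficientDataError, UndefinedLDError
from ildscan.types import HaplotypeAlignment, LDCurve, PairData, encode_sequence
from conftest import random_alignment


def brute_force_r2(g_i: np.ndarray, g_j: np.ndarray) -> float:
    """Haplotype-counting oracle: exhaustive counts of the four classes."""
    called = (g_i >= 0) & (g_j >= 0)
    a, b = g_i[called].astype(float), g_j[called].astype(float)
    n = len(a)
    if n < 2:
        return np.nan
    p_i, p_j = a.mean(), b.mean()
    p_ij = np.mean((a == 1) & (b == 1))
    denom = p_i * (1 - p_i) * p_j * (1 - p_j)
    if denom == 0:
        return np.nan
    return (p_ij - p_i * p_j) ** 2 / denom


def brute_force_curve(positions, G, bin_edges, max_distance, min_pairs):
    """O(n^2) double loop over all site pairs."""
    nb = len(bin_edges) - 1
    sums = np.zeros(nb)
    counts = np.zeros(nb, dtype=int)
    k = len(positions)
    for i in range(k):
        for j in range(i + 1, k):
            d = abs(positions[j] - positions[i])
            if d > max_distance:
                continue
            val = brute_force_r2(G[i], G[j])
            if np.isnan(val):
                continue
            for b in range(nb):
                lo, hi = bin_edges[b], bin_edges[b + 1]
                if lo <= d < hi or (b == nb - 1 and d == hi):
                    sums[b] += val
                    counts[b] += 1
                    break
    mean = np.where(counts >= min_pairs, sums / np.maximum(counts, 1), np.nan)
    return mean, counts


class TestR2:
    def test_perfect_association(self):
        m = np.vstack([encode_sequence(s) for s in ["AC", "AC", "GT", "GT"]])
        aln = HaplotypeAlignment("c", m, list("wxyz"))
        assert ld.r2(aln, 0, 1, ("A", "G"), ("C", "T")) == pytest.approx(1.0)

    def test_independence(self):
        m = np.vstack([encode_sequence(s) for s in ["AC", "AT", "GC", "GT"]])
        aln = HaplotypeAlignment("c", m, list("wxyz"))
        assert ld.r2(aln, 0, 1, ("A", "G"), ("C", "T")) == pytest.approx(0.0)

    def test_monomorphic_pair_raises(self):
        m = np.vstack([encode_sequence(s) for s in ["AC", "AC", "AT", "AT"]])
        aln = HaplotypeAlignment("c", m, list("wxyz"))
        with pytest.raises(UndefinedLDError):
            ld.r2(aln, 0, 1, ("A", "G"), ("C", "T"))

    def test_matches_brute_force_counting_on_random_fixtures(self, rng):
        """Vectorized r^2 equals exhaustive haplotype counting to 1e-12."""
        for _ in range(200):
            n = rng.integers(4, 30)
            G = rng.integers(0, 2, size=(2, n)).astype(np.int8)
            G[rng.random(G.shape) < 0.1] = -1  # sprinkle missingness
            expected = brute_force_r2(G[0], G[1])
            got = ld.r2_matrix(G)[0, 1]
            if np.isnan(expected):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(expected, abs=1e-12)

    def test_symmetry_and_allele_label_swap_invariance(self, rng):
        G = rng.integers(0, 2, size=(6, 20)).astype(np.int8)
        R = ld.r2_matrix(G)
        np.testing.assert_allclose(R, R.T, equal_nan=True)
        G2 = G.copy()
        G2[2] = 1 - G2[2]  # swap major/minor labels at one site
        R2 = ld.r2_matrix(G2)
        np.testing.assert_allclose(R, R2, equal_nan=True, atol=1e-12)


class TestDecayCurve:
    def test_single_pair_single_bin(self):
        m = np.vstack(
            [encode_sequence(s) for s in ["A" * 50 + "C", "A" * 50 + "C",
                                          "G" * 50 + "T", "G" * 50 + "T"]]
        )
        aln = HaplotypeAlignment("c", m, list("wxyz"))
        sites = pd.DataFrame(
            {"position": [0, 50], "major": ["A", "C"], "minor": ["G", "T"]}
        )
        curve = ld.ld_decay_curve(aln, sites, min_pairs_per_bin=1)
        assert curve.n_pairs.sum() == 1
        populated = curve.mean_r2[curve.populated]
        assert populated == pytest.approx([1.0])

    def test_input_order_invariance(self, rng):
        aln = random_alignment(rng, n_hap=10, length=400, n_snvs=25)
        from ildscan.io_annotation import call_snvs

        sites = call_snvs(aln, [])
        edges = ld.log_bin_edges(400, 8)
        c1 = ld.ld_decay_curve(aln, sites, bin_edges=edges, min_pairs_per_bin=1)
        shuffled = sites.sample(frac=1.0, random_state=0)
        c2 = ld.ld_decay_curve(aln, shuffled, bin_edges=edges, min_pairs_per_bin=1)
        np.testing.assert_allclose(c1.mean_r2, c2.mean_r2, equal_nan=True)
        np.testing.assert_array_equal(c1.n_pairs, c2.n_pairs)

    def test_matches_double_loop_reference_exactly(self, rng):
        """Binned curve equals the O(n^2) oracle on a 20-SNV fixture."""
        aln = random_alignment(rng, n_hap=12, length=500, n_snvs=20)
        from ildscan.io_annotation import call_snvs

        sites = call_snvs(aln, [])
        edges = ld.log_bin_edges(500, 7, min_distance=5.0)
        curve = ld.ld_decay_curve(
            aln, sites, bin_edges=edges, max_distance=500, min_pairs_per_bin=2
        )
        G = ld.genotype_matrix(aln, sites)
        mean, counts = brute_force_curve(
            sites.position.to_numpy(), G, edges, 500, 2
        )
        np.testing.assert_allclose(curve.mean_r2, mean, equal_nan=True, atol=1e-12)
        np.testing.assert_array_equal(curve.n_pairs, counts)

    def test_no_valid_pairs_raises(self):
        m = np.vstack([encode_sequence(s) for s in ["AC", "AC", "GT", "GT"]])
        aln = HaplotypeAlignment("c", m, list("wxyz"))
        sites = pd.DataFrame({"position": [0], "major": ["A"], "minor": ["G"]})
        with pytest.raises(EmptyCurveError):
            ld.ld_decay_curve(aln, sites)


def synthetic_curve(mids, values):
    mids = np.asarray(mids, float)
    edges = np.concatenate([[mids[0] - 1], (mids[:-1] + mids[1:]) / 2, [mids[-1] + 1]])
    return LDCurve(
        bin_edges=edges,
        bin_mid=mids,
        mean_r2=np.asarray(values, float),
        n_pairs=np.full(len(mids), 100),
    )


class TestAUC:
    def test_rectangle(self):
        curve = synthetic_curve([0, 250, 500, 750, 1000], [0.3] * 5)
        assert ld.auc(curve) == pytest.approx(0.3 * 1000)

    def test_triangle(self):
        w = 800.0
        curve = synthetic_curve([0, w / 4, w / 2, 3 * w / 4, w],
                                [1.0, 0.75, 0.5, 0.25, 0.0])
        assert ld.auc(curve) == pytest.approx(w / 2)

    def test_matches_fine_grid_quadrature(self, rng):
        """Trapezoid over bins equals numerical integration of the same
        piecewise-linear interpolant."""
        mids = np.sort(rng.uniform(0, 1000, size=12))
        vals = rng.uniform(0, 1, size=12)
        curve = synthetic_curve(mids, vals)
        grid = np.linspace(mids[0], mids[-1], 20001)
        expected = np.trapezoid(np.interp(grid, mids, vals), grid)
        assert ld.auc(curve) == pytest.approx(expected, rel=1e-6)

    def test_additive_over_disjoint_spans(self, rng):
        mids = np.arange(10, 1010, 100.0)
        vals = rng.uniform(0, 1, size=len(mids))
        curve = synthetic_curve(mids, vals)
        total = ld.auc(curve)
        left = ld.auc(curve, span=(0, 510))
        right = ld.auc(curve, span=(510, 1100))
        assert left + right == pytest.approx(total)

    def test_monotone_in_pointwise_order(self, rng):
        mids = np.arange(10, 510, 50.0)
        lo = rng.uniform(0, 0.5, size=len(mids))
        curve_lo = synthetic_curve(mids, lo)
        curve_hi = synthetic_curve(mids, lo + 0.1)
        assert ld.auc(curve_hi) > ld.auc(curve_lo)

    def test_insufficient_bins_raises(self):
        curve = synthetic_curve([0, 100], [0.5, np.nan])
        with pytest.raises(InsufficientDataError):
            ld.auc(curve)


class TestAUCDifference:
    def test_identity_is_exact_zero_with_ci_containing_zero(self, rng):
        aln = random_alignment(rng, n_hap=10, length=600, n_snvs=25)
        from ildscan.io_annotation import call_snvs

        sites = call_snvs(aln, [])
        edges = ld.log_bin_edges(600, 6)
        curve = ld.ld_decay_curve(aln, sites, bin_edges=edges, min_pairs_per_bin=2)
        res = ld.auc_difference(curve, curve, n_boot=300,
                                rng=np.random.default_rng(0))
        assert res.value == 0.0
        assert res.ci_low <= 0.0 <= res.ci_high
        assert not res.significant

    def test_constant_offset_gives_offset_times_width(self):
        mids = np.arange(10, 510, 50.0)
        base = np.linspace(0.8, 0.2, len(mids))
        c = 0.07
        a = synthetic_curve(mids, base + c)
        b = synthetic_curve(mids, base)
        res = ld.auc_difference(a, b, n_boot=0)
        assert res.value == pytest.approx(c * (mids[-1] - mids[0]))

    def test_masked_bins_excluded_from_both_curves(self):
        mids = np.arange(10, 510, 50.0)
        va = np.full(len(mids), 0.6)
        vb = np.full(len(mids), 0.4)
        va[3] = np.nan  # masked in a only -> dropped from both
        a = synthetic_curve(mids, va)
        b = synthetic_curve(mids, vb)
        res = ld.auc_difference(a, b, n_boot=0)
        assert res.value == pytest.approx(0.2 * (mids[-1] - mids[0]))
        assert res.n_bins_used == len(mids) - 1

    def test_mismatched_bins_rejected(self):
        a = synthetic_curve([0, 100, 200], [0.5, 0.4, 0.3])
        b = synthetic_curve([0, 150, 300], [0.5, 0.4, 0.3])
        with pytest.raises(ValueError):
            ld.auc_difference(a, b, n_boot=0)


class TestClassLabelPermutation:
    def test_no_signal_gives_uniformish_p(self, rng):
        """Under exchangeable labels the permutation p-value is not extreme."""
        ps = []
        for _ in range(20):
            G = rng.integers(0, 2, size=(14, 10)).astype(np.int8)
            pos = np.sort(rng.choice(2000, size=14, replace=False))
            pairs = ld.pair_data(pos, ld.r2_matrix(G), 2000)
            is_a = np.zeros(14, bool)
            is_a[:7] = True
            edges = ld.log_bin_edges(2000, 4, 10)
            try:
                _, p = ld.class_label_permutation_test(
                    pairs, is_a, edges, 1, 200, rng
                )
                ps.append(p)
            except InsufficientDataError:
                continue
        assert len(ps) >= 10
        assert 0.2 < np.mean(ps) < 0.8

    def test_planted_class_contrast_is_detected(self, rng):
        """Class A sites share one haplotype partition (r^2 = 1 among A),
        class B sites are independent noise."""
        n = 30
        block = (np.arange(n) < n // 2).astype(np.int8)
        G_a = np.tile(block, (8, 1))
        G_b = rng.integers(0, 2, size=(8, n)).astype(np.int8)
        G = np.vstack([G_a, G_b])
        pos = np.sort(rng.choice(3000, size=16, replace=False))
        pairs = ld.pair_data(pos, ld.r2_matrix(G), 3000)
        is_a = np.zeros(16, bool)
        is_a[:8] = True
        edges = ld.log_bin_edges(3000, 4, 10)
        _, p = ld.class_label_permutation_test(pairs, is_a, edges, 1, 400, rng)
        assert p < 0.05
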
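"""Diversity statistics, Fst estimators, distances, LD pruning, and PCA,
checked against hand calculations and independent per-site oracles."""
import numpy as np
import pytest

from pigpop import (
    DistanceMatrix, allele_frequency, diversity_stats, fst_per_snp,
    ibs_distance_matrix, ld_prune, nei_standard_distance,
    pairwise_fst_matrix, pca,
)
from pigpop.io import MISSING
from pigpop.simulate import SimulationConfig, simulate_populations

from conftest import make_dataset


class TestAlleleFrequency:
    def test_printed_counts_give_75_percent(self):
        # 89 diploids carrying 134 alt alleles of 178: 75% to the nearest percent
        dos = np.zeros((89, 1), dtype=np.int8)
        dos[:67, 0] = 2
        ds = make_dataset(dos)
        freq, alt, tot = allele_frequency(ds, ds.sample_ids)
        assert alt[0] == 134 and tot[0] == 178
        assert round(100 * freq[0]) == 75

    def test_all_reference_gives_zero(self):
        ds = make_dataset(np.zeros((5, 3), dtype=np.int8))
        freq, _, _ = allele_frequency(ds, ds.sample_ids)
        np.testing.assert_array_equal(freq, 0.0)

    def test_matches_hand_tally_with_missing(self, rng):
        dos = rng.integers(0, 3, size=(10, 8)).astype(np.int8)
        dos[rng.random((10, 8)) < 0.25] = MISSING
        ds = make_dataset(dos)
        freq, alt, tot = allele_frequency(ds, ds.sample_ids)
        for j in range(8):
            col = dos[:, j]
            called = col[col != MISSING]
            if called.size == 0:
                assert np.isnan(freq[j])
            else:
                assert alt[j] == called.sum()
                assert tot[j] == 2 * called.size
                assert freq[j] == pytest.approx(called.sum() / (2 * called.size))

    def test_empty_group_errors(self):
        ds = make_dataset(np.zeros((3, 2), dtype=np.int8))
        with pytest.raises(ValueError):
            allele_frequency(ds, [])


class TestDiversity:
    def test_two_heterozygotes_hand_value(self):
        # genotypes {0/1, 0/1}: Ho = 1, pi_s = (4/3)(1 - 0.25 - 0.25) = 2/3
        ds = make_dataset(np.array([[1], [1]], dtype=np.int8))
        s = diversity_stats(ds, ds.sample_ids)
        assert s.ho == pytest.approx(1.0)
        assert s.pi == pytest.approx(2.0 / 3.0)
        assert s.pn == 1.0 and s.n_snp_polymorphic == 1

    def test_monomorphic_group_all_zero(self):
        ds = make_dataset(np.full((4, 5), 2, dtype=np.int8))
        s = diversity_stats(ds, ds.sample_ids)
        assert (s.pn, s.ho, s.pi) == (0.0, 0.0, 0.0)

    def test_group_of_one_errors(self):
        ds = make_dataset(np.zeros((2, 3), dtype=np.int8))
        with pytest.raises(ValueError):
            diversity_stats(ds, ["S1"])

    def test_matches_per_site_oracle(self, rng):
        dos = rng.integers(0, 3, size=(12, 20)).astype(np.int8)
        dos[rng.random((12, 20)) < 0.1] = MISSING
        ds = make_dataset(dos)
        s = diversity_stats(ds, ds.sample_ids)
        # independent per-site recomputation
        pns, hos, pis = 0, [], []
        for j in range(20):
            col = dos[:, j]
            called = col[col != MISSING]
            if called.size:
                hos.append(np.mean(called == 1))
            n = 2 * called.size
            if n >= 2:
                p = called.sum() / n
                pis.append(n / (n - 1) * (1 - p**2 - (1 - p) ** 2))
                pns += 0 < called.sum() < n
        assert s.pn == pytest.approx(pns / 20)
        assert s.ho == pytest.approx(np.mean(hos))
        assert s.pi == pytest.approx(np.mean(pis))


def _two_group_ds(d1, d2):
    dos = np.vstack([d1, d2]).astype(np.int8)
    pops = ["A"] * len(d1) + ["B"] * len(d2)
    return make_dataset(dos, populations=pops)


class TestFst:
    @pytest.mark.parametrize("estimator", ["weir_cockerham", "hudson"])
    def test_fixed_difference_is_exactly_one(self, estimator):
        ds = _two_group_ds(np.full((5, 4), 2), np.zeros((5, 4)))
        pops = ds.populations()
        res = fst_per_snp(ds, pops["A"], pops["B"], estimator=estimator)
        np.testing.assert_allclose(res.per_snp, 1.0)
        assert res.mean_fst == pytest.approx(1.0)

    def test_hudson_hand_value(self):
        # p1 = 8/10, p2 = 2/10 -> 0.32444/0.68 = 0.47712
        d1 = np.array([[2], [2], [2], [2], [0]])   # 8 alt of 10
        d2 = np.array([[2], [0], [0], [0], [0]])   # 2 alt of 10
        ds = _two_group_ds(d1, d2)
        pops = ds.populations()
        res = fst_per_snp(ds, pops["A"], pops["B"], estimator="hudson")
        assert res.per_snp[0] == pytest.approx(0.47712, abs=1e-5)

    def test_monomorphic_union_is_undefined(self):
        ds = _two_group_ds(np.zeros((4, 1)), np.zeros((4, 1)))
        pops = ds.populations()
        for est in ("weir_cockerham", "hudson"):
            res = fst_per_snp(ds, pops["A"], pops["B"], estimator=est)
            assert np.isnan(res.per_snp[0])
            assert not res.defined[0]

    def test_wc_matches_component_equation_oracle(self, rng):
        dos = rng.integers(0, 3, size=(20, 30)).astype(np.int8)
        dos[rng.random((20, 30)) < 0.1] = MISSING
        ds = make_dataset(dos, populations=["A"] * 8 + ["B"] * 12)
        pops = ds.populations()
        res = fst_per_snp(ds, pops["A"], pops["B"])
        # independent scalar transcription of the 1984 a, b, c equations
        idx_a = [i for i, s in enumerate(ds.samples) if s.population == "A"]
        idx_b = [i for i, s in enumerate(ds.samples) if s.population == "B"]
        for j in range(30):
            groups = []
            for idx in (idx_a, idx_b):
                col = dos[idx, j]
                col = col[col != MISSING]
                groups.append(col)
            n1, n2 = len(groups[0]), len(groups[1])
            if min(n1, n2) < 1:
                continue
            p1 = groups[0].sum() / (2 * n1)
            p2 = groups[1].sum() / (2 * n2)
            h1 = np.mean(groups[0] == 1)
            h2 = np.mean(groups[1] == 1)
            r = 2
            nbar = (n1 + n2) / 2
            if nbar <= 1:
                continue
            nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
            pbar = (n1 * p1 + n2 * p2) / (r * nbar)
            s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
            hbar = (n1 * h1 + n2 * h2) / (r * nbar)
            a = (nbar / nc) * (
                s2 - 1 / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4)
            )
            b = (nbar / (nbar - 1)) * (
                pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
            )
            c = hbar / 2
            denom = a + b + c
            if denom == 0 or 2 * min(n1, n2) < 2:
                assert np.isnan(res.per_snp[j])
            else:
                assert res.per_snp[j] == pytest.approx(a / denom, abs=1e-12)

    def test_balding_nichols_recovery(self):
        """Ratio-of-sums WC mean within ±15% of the drift parameter."""
        for F in (0.05, 0.1, 0.2):
            cfg = SimulationConfig(
                n_pops=2, n_per_pop=50, n_snps=20000, drift_F=F,
                seed=1234 + int(F * 100), phased=False,
            )
            ds = simulate_populations(cfg)
            pops = ds.populations()
            res = fst_per_snp(ds, pops["POP1"], pops["POP2"])
            assert abs(res.mean_fst - F) / F < 0.15


class TestPairwiseFstMatrix:
    def test_three_simulated_levels_recover_ordering(self):
        cfg = SimulationConfig(
            n_pops=3, n_per_pop=30, n_snps=5000,
            drift_F=[0.02, 0.1, 0.3], seed=5, phased=False,
        )
        ds = simulate_populations(cfg)
        mat = pairwise_fst_matrix(ds, ds.population_grouping())
        f = mat.to_frame()
        # POP3 (strong drift) is farther from both others than they are
        # from each other
        assert f.loc["POP1", "POP3"] > f.loc["POP1", "POP2"]
        assert f.loc["POP2", "POP3"] > f.loc["POP1", "POP2"]
        assert np.all(np.diag(mat.values) == 0)

    def test_two_groups_match_fst_per_snp_mean(self):
        cfg = SimulationConfig(n_pops=2, n_per_pop=10, n_snps=500, drift_F=0.1,
                               seed=6, phased=False)
        ds = simulate_populations(cfg)
        pops = ds.populations()
        mat = pairwise_fst_matrix(ds, ds.population_grouping())
        res = fst_per_snp(ds, pops["POP1"], pops["POP2"])
        assert mat.to_frame().loc["POP1", "POP2"] == pytest.approx(
            max(res.mean_fst, 0.0)
        )

    def test_single_sample_group_errors(self):
        ds = make_dataset(np.zeros((3, 4), dtype=np.int8),
                          populations=["A", "A", "B"])
        with pytest.raises(ValueError, match="< 2 samples"):
            pairwise_fst_matrix(ds, ds.population_grouping())


class TestIBS:
    def test_identical_individuals_distance_zero(self, rng):
        row = rng.integers(0, 3, size=12)
        ds = make_dataset(np.vstack([row, row]))
        mat = ibs_distance_matrix(ds)
        assert mat.values[0, 1] == 0.0

    def test_opposite_homozygotes_distance_one(self):
        ds = make_dataset(np.vstack([np.zeros(10), np.full(10, 2)]))
        assert ibs_distance_matrix(ds).values[0, 1] == 1.0

    def test_matches_hand_computation(self, rng):
        dos = rng.integers(0, 3, size=(4, 10)).astype(np.int8)
        dos[0, 3] = MISSING
        ds = make_dataset(dos)
        mat = ibs_distance_matrix(ds)
        for i in range(4):
            for j in range(i + 1, 4):
                both = (dos[i] != MISSING) & (dos[j] != MISSING)
                sim = np.mean((2 - np.abs(dos[i][both] - dos[j][both])) / 2)
                assert mat.values[i, j] == pytest.approx(1 - sim)
        assert np.all((mat.values >= 0) & (mat.values <= 1))


class TestNeiDistance:
    def test_identity_is_zero(self, rng):
        x = rng.random(20)
        assert nei_standard_distance(x, x.copy()) == pytest.approx(0.0, abs=1e-12)

    def test_hand_value_single_snp(self):
        # x=(0.8,0.2), y=(0.6,0.4): D = -ln(0.56/sqrt(0.68*0.52)) = 0.06002
        assert nei_standard_distance(
            np.array([0.8]), np.array([0.6])
        ) == pytest.approx(0.06002, abs=1e-5)

    def test_disjoint_alleles_is_infinite(self):
        with pytest.warns(UserWarning):
            d = nei_standard_distance(np.array([1.0, 1.0]), np.array([0.0, 0.0]))
        assert d == np.inf

    def test_symmetry_exact(self, rng):
        x, y = rng.random(50), rng.random(50)
        assert nei_standard_distance(x, y) == nei_standard_distance(y, x)


class TestLDPrune:
    def test_duplicated_column_one_removed(self, rng):
        col = rng.integers(0, 3, size=20)
        other = rng.integers(0, 3, size=(20, 3))
        dos = np.column_stack([col, other[:, 0], col, other[:, 1], other[:, 2]])
        ds = make_dataset(dos)
        kept = ld_prune(ds, window_snps=5, step_snps=2, r2_max=0.1)
        assert not (0 in kept and 2 in kept)

    def test_independent_snps_all_kept(self):
        # orthogonal dosage columns with pairwise r2 = 0
        dos = np.array([
            [0, 0, 1], [2, 0, 1], [0, 2, 1], [2, 2, 1],
            [0, 0, 0], [2, 0, 2], [0, 2, 2], [2, 2, 0],
        ], dtype=np.int8)
        ds = make_dataset(dos)
        kept = ld_prune(ds, window_snps=3, step_snps=1, r2_max=0.1)
        assert list(kept) == [0, 1, 2]

    def test_no_surviving_window_pair_exceeds_threshold(self, rng):
        # correlated fixture: blocks of near-identical SNPs
        base = rng.integers(0, 3, size=(40, 12))
        cols = []
        for b in range(12):
            for _ in range(5):
                noisy = base[:, b].copy()
                flip = rng.random(40) < 0.05
                noisy[flip] = rng.integers(0, 3, size=flip.sum())
                cols.append(noisy)
        ds = make_dataset(np.column_stack(cols).astype(np.int8))
        w, s, r2max = 20, 5, 0.1
        kept = ld_prune(ds, window_snps=w, step_snps=s, r2_max=r2max)
        # exhaustive recheck over every window of kept SNPs
        from pigpop.popgen import _pair_r2

        kept = list(kept)
        start = 0
        while start < len(kept):
            window = kept[start : start + w]
            for ai in range(len(window)):
                for bi in range(ai + 1, len(window)):
                    r2 = _pair_r2(ds.dosages, window[ai], window[bi])
                    assert not (r2 > r2max), (window[ai], window[bi], r2)
            start += s


class TestPCA:
    def test_separates_two_populations(self):
        cfg = SimulationConfig(n_pops=2, n_per_pop=20, n_snps=2000, drift_F=0.2,
                               seed=9, phased=False)
        ds = simulate_populations(cfg)
        res = pca(ds, n_components=2)
        pc1 = res.scores[:, 0]
        a, b = pc1[:20], pc1[20:]
        assert max(a.max(), b.max()) > min(a.min(), b.min())  # sanity
        assert (a.max() < b.min()) or (b.max() < a.min())     # no overlap

    def test_duplicated_sample_identical_scores(self, rng):
        dos = rng.integers(0, 3, size=(6, 40)).astype(np.int8)
        dos[5] = dos[0]
        ds = make_dataset(dos)
        res = pca(ds, n_components=2)
        np.testing.assert_allclose(res.scores[0], res.scores[5], atol=1e-9)

    def test_matches_dense_eigendecomposition(self, rng):
        dos = rng.integers(0, 3, size=(8, 25)).astype(np.int8)
        ds = make_dataset(dos)
        res = pca(ds, n_components=3)
        # oracle: explicit standardized matrix and eigh
        d = dos.astype(float)
        p = d.mean(axis=0) / 2
        poly = (p > 0) & (p < 1)
        z = (d[:, poly] - 2 * p[poly]) / np.sqrt(2 * p[poly] * (1 - p[poly]))
        grm = z @ z.T / z.shape[1]
        vals, vecs = np.linalg.eigh(grm)
        order = np.argsort(vals)[::-1][:3]
        for k, o in enumerate(order):
            expected = vecs[:, o] * np.sqrt(max(vals[o], 0))
            got = res.scores[:, k]
            assert np.allclose(got, expected, atol=1e-8) or np.allclose(
                got, -expected, atol=1e-8
            )

    def test_monomorphic_only_errors(self):
        ds = make_dataset(np.zeros((5, 4), dtype=np.int8))
        with pytest.raises(ValueError):
            pca(ds, n_components=2)
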
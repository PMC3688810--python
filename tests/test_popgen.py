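"""F_st estimators, admixture clustering, delta-K, Mantel, diversity."""

import numpy as np
import pandas as pd
import pytest

from mhcdab import popgen, simulate
from mhcdab._rng import substream, spawn_seed
from mhcdab.errors import DataError


def _two_pop_binary(rng, n_per_pop, n_loci, fst):
    """Band data with per-population frequencies diverged at a target F
    (Balding-Nichols beta draws around a common ancestral frequency)."""
    anc = rng.uniform(0.2, 0.8, n_loci)
    mats = []
    for _pop in range(2):
        if fst == 0:
            p = anc
        else:
            c = (1 - fst) / fst
            p = rng.beta(anc * c, (1 - anc) * c)
        mats.append(rng.random((n_per_pop, n_loci)) < p)
    X = np.vstack(mats).astype(int)
    idx = [f"i{k}" for k in range(2 * n_per_pop)]
    pops = pd.Series(["a"] * n_per_pop + ["b"] * n_per_pop, index=idx)
    return pd.DataFrame(X, index=idx), pops


class TestFstBinary:
    def test_identical_frequencies_near_zero(self):
        rng = substream(1, "fst0")
        mat, pops = _two_pop_binary(rng, 50, 40, 0.0)
        est = popgen.fst_binary(mat, pops, bootstrap_reps=200, seed=0)
        assert abs(est.value) < 0.02

    def test_fixed_complementary_bands_give_one(self):
        mat = pd.DataFrame(np.vstack([np.tile([1, 0], (20, 5)),
                                      np.tile([0, 1], (20, 5))]).reshape(40, -1))
        pops = pd.Series(["a"] * 20 + ["b"] * 20, index=mat.index)
        est = popgen.fst_binary(mat, pops, bootstrap_reps=0)
        assert est.value == pytest.approx(1.0)

    def test_recovers_simulated_divergence(self):
        vals = []
        for seed in range(20):
            rng = substream(seed, "fst02")
            mat, pops = _two_pop_binary(rng, 50, 40, 0.2)
            vals.append(popgen.fst_binary(mat, pops, bootstrap_reps=0).value)
        assert 0.15 <= np.mean(vals) <= 0.25

    def test_ci_contains_point_estimate(self):
        rng = substream(3, "fstci")
        mat, pops = _two_pop_binary(rng, 40, 30, 0.1)
        est = popgen.fst_binary(mat, pops, bootstrap_reps=500, seed=1)
        assert est.ci_low <= est.value <= est.ci_high

    def test_monomorphic_matrix_errors(self):
        mat = pd.DataFrame(np.ones((10, 5), dtype=int))
        pops = pd.Series(["a"] * 5 + ["b"] * 5, index=mat.index)
        with pytest.raises(DataError):
            popgen.fst_binary(mat, pops, bootstrap_reps=0)


class TestFstHaplotype:
    def test_equal_vectors_zero(self):
        cnt = pd.DataFrame([[10, 10, 5], [10, 10, 5]], index=["a", "b"])
        assert popgen.fst_haplotype(cnt).value == pytest.approx(0.0)

    def test_disjoint_fixed_pops_one(self):
        cnt = pd.DataFrame([[20, 0], [0, 20]], index=["a", "b"])
        assert popgen.fst_haplotype(cnt).value == pytest.approx(1.0)

    def test_matches_direct_ht_hs_computation(self):
        rng = substream(5, "hap")
        for _ in range(10):
            cnt = pd.DataFrame(rng.integers(1, 30, (2, 6)), index=["a", "b"])
            got = popgen.fst_haplotype(cnt).value
            p = cnt.to_numpy() / cnt.to_numpy().sum(1, keepdims=True)
            h_s = np.mean([1 - (row ** 2).sum() for row in p])
            pbar = p.mean(0)
            h_t = 1 - (pbar ** 2).sum()
            assert got == pytest.approx((h_t - h_s) / h_t)

    def test_zero_observation_population_errors(self):
        cnt = pd.DataFrame([[5, 5], [0, 0]], index=["a", "b"])
        with pytest.raises(DataError):
            popgen.fst_haplotype(cnt)


class TestFstMicrosat:
    def test_panmixia_near_zero(self):
        panel = simulate.simulate_microsat_panel(25, (100, 100), fst=0.0,
                                                 seed=3)
        est = popgen.fst_microsat(panel.genotypes, panel.loci,
                                  bootstrap_reps=0)
        assert abs(est.value) < 0.02

    def test_estimates_increase_with_divergence(self):
        vals = []
        for F in (0.05, 0.2, 0.4):
            panel = simulate.simulate_microsat_panel(20, (60, 60), fst=F,
                                                     seed=8)
            vals.append(popgen.fst_microsat(panel.genotypes, panel.loci,
                                            bootstrap_reps=0).value)
        assert vals[0] < vals[1] < vals[2]


class TestAdmixture:
    def test_k1_degenerate(self):
        rng = substream(7, "k1")
        df = pd.DataFrame(rng.integers(0, 2, (20, 10)))
        qm = popgen.admixture_infer(df, 1, n_sweeps=120, burn_in=20, seed=0)
        assert np.allclose(qm.q.to_numpy(), 1.0)

    def test_q_rows_sum_to_one_and_reproducible(self):
        rng = substream(8, "rep")
        df = pd.DataFrame(rng.integers(0, 2, (30, 15)))
        q1 = popgen.admixture_infer(df, 2, n_sweeps=200, burn_in=50, seed=4)
        q2 = popgen.admixture_infer(df, 2, n_sweeps=200, burn_in=50, seed=4)
        assert np.allclose(q1.q.sum(axis=1), 1.0)
        assert q1.q.equals(q2.q)
        assert (q1.loglik_trace == q2.loglik_trace).all()

    def test_align_replicate_runs_undoes_label_swap(self):
        rng = substream(9, "swap")
        q = rng.dirichlet([1, 1], size=15)
        inds = [f"i{k}" for k in range(15)]
        qa = popgen.QMatrix(pd.DataFrame(q, index=inds,
                                         columns=["cluster1", "cluster2"]),
                            np.zeros(3), 2)
        qb = popgen.QMatrix(pd.DataFrame(q[:, ::-1], index=inds,
                                         columns=["cluster1", "cluster2"]),
                            np.zeros(3), 2)
        cons = popgen.align_replicate_runs([qa, qb])
        assert np.allclose(cons.q.to_numpy(), q, atol=1e-12)


class TestDeltaK:
    def test_flat_likelihood_gives_zero(self):
        runs = {1: [-100.0, -100.5], 2: [-100.2, -100.7],
                3: [-100.1, -100.6], 4: [-100.3, -100.8]}
        dk = popgen.evanno_delta_k(runs)
        inner = dk.table.dropna(subset=["delta_k"])
        assert (inner["delta_k"] < 1.5).all()

    def test_zero_sd_warns_infinite(self):
        runs = {1: [-10.0, -10.0], 2: [-8.0, -8.0], 3: [-7.9, -7.8]}
        with pytest.warns(UserWarning):
            dk = popgen.evanno_delta_k(runs)
        assert np.isinf(dk.table.loc[dk.table["K"] == 2, "delta_k"]).all()

    def test_needs_three_k_values(self):
        with pytest.raises(DataError):
            popgen.evanno_delta_k({1: [-1.0], 2: [-2.0]})


class TestMantel:
    @staticmethod
    def _sym(rng, n):
        a = rng.random((n, n))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0)
        return a

    def test_self_correlation_is_one(self):
        rng = substream(11, "mantel")
        d = self._sym(rng, 7)
        r, _p = popgen.mantel_test(d, d, [f"p{i}" for i in range(7)],
                                   n_perm=199, seed=0)
        assert r == pytest.approx(1.0)

    def test_null_p_values_super_uniform(self):
        """Independent random matrices: P(p <= t) must not exceed t by more
        than sampling noise."""
        rng = substream(12, "mantelnull")
        labels = [f"p{i}" for i in range(6)]
        ps = []
        for rep in range(200):
            d1, d2 = self._sym(rng, 6), self._sym(rng, 6)
            _r, p = popgen.mantel_test(d1, d2, labels, n_perm=99,
                                       seed=spawn_seed(rep, "mantel"))
            ps.append(p)
        ps = np.asarray(ps)
        assert (ps < 0.05).mean() <= 0.07
        for t in (0.1, 0.2, 0.5):
            assert (ps <= t).mean() <= t + 0.08

    def test_size_and_symmetry_validation(self):
        with pytest.raises(DataError):
            popgen.mantel_test(np.zeros((2, 2)), np.zeros((2, 2)), ["a", "b"])
        bad = np.array([[0, 1.0, 2], [1, 0, 3], [2, 3, 0.5]])
        with pytest.raises(DataError):
            popgen.mantel_test(bad, bad, list("abc"))


class TestDiversity:
    def test_spearman_of_identical_rankings(self):
        r, _p = popgen.spearman_correlation([1, 2, 3, 4], [10, 20, 30, 40])
        assert r == pytest.approx(1.0)

    def test_private_alleles_and_richness_floor(self):
        panel = simulate.simulate_microsat_panel(8, (20, 20), fst=0.4,
                                                 n_hybrids=3, seed=13)
        div = popgen.microsat_diversity(panel.genotypes, panel.loci, floor=9)
        assert set(div["population"]) == {"pop1", "pop2", "hybrid"}
        # hybrid sample of 3 is below the rarefaction floor
        hyb = div.set_index("population").loc["hybrid"]
        assert np.isnan(hyb["allelic_richness"])
        assert (div.set_index("population")["private_alleles"] >= 0).all()

    def test_coupled_diversity_gives_positive_correlation(self):
        """Populations richer in microsatellite alleles carry more MHC
        alleles per specimen: the built-in association is recovered."""
        rng = substream(14, "couple")
        frames = []
        pres_rows = []
        pops = []
        for k, (n_all, mhc_mean) in enumerate(
                [(2, 1.2), (3, 2.0), (4, 2.6), (5, 3.2), (6, 4.0)]):
            pop = f"pop{k}"
            for i in range(12):
                ind = f"{pop}-{i}"
                row = {"individual": ind, "population": pop}
                for l in range(6):
                    row[f"L{l:02d}_1"] = 100 + 2 * int(rng.integers(n_all))
                    row[f"L{l:02d}_2"] = 100 + 2 * int(rng.integers(n_all))
                frames.append(row)
                n_mhc = max(1, int(rng.poisson(mhc_mean)))
                pres_rows.append({"individual": ind,
                                  **{f"al{j}": 1 if j < n_mhc else 0
                                     for j in range(10)}})
                pops.append(pop)
        geno = pd.DataFrame(frames)
        pres = pd.DataFrame(pres_rows).set_index("individual")
        popser = pd.Series(pops, index=pres.index)
        loci = [f"L{l:02d}" for l in range(6)]
        _table, (r, _p) = popgen.diversity_and_correlation(
            pres, popser, geno, loci, floor=9)
        assert r > 0.5
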
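import numpy as np
import pytest

import driftwatch as dw

from conftest import make_matrix


def anova_fst(calls_by_pop):
    """Independent oracle: nested random-effects ANOVA on allele indicators
    (alleles within individuals within populations), ratio of summed
    variance components over loci and alleles."""
    n_loci = calls_by_pop[0].shape[1]
    A = D = 0.0
    for j in range(n_loci):
        pops = [c[:, j] for c in calls_by_pop]
        alleles = np.unique(np.concatenate([p.ravel() for p in pops]))
        n = np.array([len(p) for p in pops], float)
        r = len(pops)
        S1 = n.sum()
        S2 = (n**2).sum()
        nc = (S1 - S2 / S1) / (r - 1)
        for u in alleles:
            y_pops = [(p == u).astype(float) for p in pops]
            ybar_ind = [y.mean(axis=1) for y in y_pops]
            ybar_pop = [y.mean() for y in y_pops]
            ytot = np.concatenate([y.ravel() for y in y_pops]).mean()
            ssg = sum(((y - yb[:, None]) ** 2).sum() for y, yb in zip(y_pops, ybar_ind))
            ssi = sum(2 * ((yb - yp) ** 2).sum() for yb, yp in zip(ybar_ind, ybar_pop))
            ssp = sum(2 * ni * (yp - ytot) ** 2 for ni, yp in zip(n, ybar_pop))
            msg = ssg / S1
            msi = ssi / (S1 - r)
            msp = ssp / (r - 1)
            c = msg
            b = (msi - msg) / 2
            a = (msp - msi) / (2 * nc)
            A += a
            D += a + b + c
    return A / D


def _random_instance(rng, n_pops, max_alleles=3):
    calls, sids, assign = [], [], {}
    n_loci = int(rng.integers(2, 11))
    for p in range(n_pops):
        ni = int(rng.integers(2, 8))
        calls.append(rng.integers(0, max_alleles, size=(ni, n_loci, 2)).astype(np.int16))
        for i in range(ni):
            sid = f"p{p}i{i}"
            sids.append(sid)
            assign[sid] = f"P{p}"
    g = dw.GenotypeMatrix(sids, [f"L{j}" for j in range(n_loci)], np.concatenate(calls))
    return g, dw.PopulationMap(assign), calls


@pytest.mark.parametrize("n_pops", [2, 3, 4])
def test_wc84_matches_anova_oracle(n_pops):
    rng = np.random.default_rng(100 + n_pops)
    for _ in range(5):
        g, pm, calls = _random_instance(rng, n_pops)
        mine = dw.weir_cockerham_fst(g, pm).overall_fst
        oracle = anova_fst(calls)
        assert mine == pytest.approx(oracle, abs=1e-12)


def test_fixed_differences_give_fst_one():
    g = make_matrix([[(0, 0)] * 3] * 4 + [[(1, 1)] * 3] * 4)
    pm = dw.PopulationMap({f"s{i + 1}": ("A" if i < 4 else "B") for i in range(8)})
    res = dw.weir_cockerham_fst(g, pm)
    assert res.value("A", "B") == pytest.approx(1.0, abs=1e-12)
    assert res.overall_fst == pytest.approx(1.0, abs=1e-12)


def test_duplicated_population_gives_near_zero_fst(rng):
    calls = rng.integers(0, 2, size=(10, 50, 2)).astype(np.int16)
    both = np.concatenate([calls, calls])
    g = dw.GenotypeMatrix(
        [f"s{i}" for i in range(20)], [f"L{j}" for j in range(50)], both
    )
    pm = dw.PopulationMap({f"s{i}": ("A" if i < 10 else "B") for i in range(20)})
    res = dw.weir_cockerham_fst(g, pm)
    assert res.overall_fst <= 0.02  # estimator may be slightly negative


def test_single_individual_population_excluded(two_pop_toy):
    g, pm = two_pop_toy
    pm2 = dw.PopulationMap({**pm.assignments, "s6": "C"})
    with pytest.warns(UserWarning, match="excluded"):
        res = dw.weir_cockerham_fst(g, pm2)
    assert "C" not in res.populations


class TestMatrixCorrelation:
    def _matrix(self, vals, pops=("A", "B", "C", "D")):
        k = len(pops)
        m = np.zeros((k, k))
        iu = np.triu_indices(k, 1)
        m[iu] = vals
        m += m.T
        return dw.PairwiseFstMatrix(list(pops), m, float(np.mean(vals)))

    def test_self_correlation_is_one(self):
        a = self._matrix([0.1, 0.2, 0.3, 0.15, 0.25, 0.35])
        r, p, cv_a, cv_b = dw.fst_matrix_correlation(a, a)
        assert r == pytest.approx(1.0)
        assert cv_a == pytest.approx(cv_b)

    def test_linear_scaling_preserves_r(self):
        vals = np.array([0.1, 0.2, 0.3, 0.15, 0.25, 0.35])
        a = self._matrix(vals)
        b = self._matrix(2 * vals)
        r, *_ = dw.fst_matrix_correlation(a, b)
        assert r == pytest.approx(1.0)

    def test_matches_direct_pearson(self, rng):
        va = rng.random(6)
        vb = rng.random(6)
        a = self._matrix(va)
        b = self._matrix(vb)
        r, p, cv_a, cv_b = dw.fst_matrix_correlation(a, b)
        r_direct = np.corrcoef(va, vb)[0, 1]
        assert r == pytest.approx(r_direct, abs=1e-12)
        assert cv_a == pytest.approx(100 * va.std(ddof=1) / va.mean(), abs=1e-9)

    def test_mismatched_populations_dropped_with_warning(self):
        a = self._matrix([0.1, 0.2, 0.3, 0.15, 0.25, 0.35], ("A", "B", "C", "D"))
        b = self._matrix([0.1, 0.2, 0.3, 0.15, 0.25, 0.35], ("A", "B", "C", "E"))
        with pytest.warns(UserWarning, match="dropped"):
            r, *_ = dw.fst_matrix_correlation(a, b)
        assert np.isfinite(r)

    def test_too_few_shared_pairs_rejected(self):
        a = self._matrix([0.1], ("A", "B"))
        with pytest.raises(ValueError):
            dw.fst_matrix_correlation(a, a)


class TestRemoveTopFstLoci:
    def test_ceil_arithmetic(self, rng):
        for n_loci, frac, expected_removed in [(100, 0.05, 5), (40, 0.05, 2)]:
            calls = rng.integers(0, 2, size=(10, n_loci, 2)).astype(np.int16)
            g = dw.GenotypeMatrix(
                [f"s{i}" for i in range(10)], [f"L{j}" for j in range(n_loci)], calls
            )
            pm = dw.PopulationMap({f"s{i}": ("A" if i < 5 else "B") for i in range(10)})
            out = dw.remove_top_fst_loci(g, pm, ("A", "B"), frac)
            assert out.n_loci == n_loci - expected_removed

    def test_high_fst_loci_are_the_ones_removed(self):
        # loci 1-2 fixed differences (Fst 1), loci 3-20 identical in both pops
        calls = []
        for i in range(8):
            allele = 0 if i < 4 else 1
            row = [(allele, allele), (allele, allele)] + [(0, 1)] * 18
            calls.append(row)
        g = make_matrix(calls)
        pm = dw.PopulationMap({f"s{i + 1}": ("A" if i < 4 else "B") for i in range(8)})
        out = dw.remove_top_fst_loci(g, pm, ("A", "B"), 0.10)
        assert "L1" not in out.locus_ids and "L2" not in out.locus_ids
        assert out.n_loci == 18

    def test_ties_broken_by_input_order(self):
        # all loci identical -> identical Fst; first listed removed first
        g = make_matrix([[(0, 1)] * 10, [(0, 0)] * 10, [(1, 1)] * 10, [(0, 1)] * 10])
        pm = dw.PopulationMap({f"s{i + 1}": ("A" if i < 2 else "B") for i in range(4)})
        out = dw.remove_top_fst_loci(g, pm, ("A", "B"), 0.25)
        assert out.locus_ids == [f"L{j}" for j in range(4, 11)]

    def test_identical_pair_rejected(self, two_pop_toy):
        g, pm = two_pop_toy
        with pytest.raises(ValueError):
            dw.remove_top_fst_loci(g, pm, ("A", "A"), 0.05)


class TestSyntheticCalibration:
    def test_island_model_null_fst(self):
        g, pm, _ = dw.gen_structured_genotypes(
            "island_fst", n_pops=2, n_per_pop=25, n_loci=500, target_fst=0.0, seed=42
        )
        assert abs(dw.weir_cockerham_fst(g, pm).overall_fst) < 0.02

    def test_island_model_target_fst_recovered(self):
        ests = []
        for rep in range(10):
            g, pm, _ = dw.gen_structured_genotypes(
                "island_fst", n_pops=2, n_per_pop=25, n_loci=500,
                target_fst=0.25, seed=1000 + rep,
            )
            ests.append(dw.weir_cockerham_fst(g, pm).overall_fst)
        assert abs(np.mean(ests) - 0.25) < 0.05

    def test_divergence_zero_gives_zero_fst(self):
        g, pm, _ = dw.gen_structured_genotypes(
            "divergence_pair", n_pops=2, n_per_pop=25, n_loci=500,
            divergence_time=0, seed=3,
        )
        assert abs(dw.weir_cockerham_fst(g, pm).overall_fst) < 0.02

    def test_fst_increases_with_divergence_time(self):
        from scipy.stats import spearmanr

        times = [5, 20, 60, 150]
        rhos = []
        for rep in range(5):
            ests = []
            for t in times:
                g, pm, _ = dw.gen_structured_genotypes(
                    "divergence_pair", n_pops=2, n_per_pop=20, n_loci=300,
                    divergence_time=t, pop_size=100, seed=7000 + 13 * rep + t,
                )
                ests.append(dw.weir_cockerham_fst(g, pm).overall_fst)
            rhos.append(spearmanr(times, ests).statistic)
        assert np.mean(rhos) > 0.9
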
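import numpy as np
import pandas as pd
import pytest

from hydropop.differentiation import (
    Amova,
    AmovaResult,
    allele_size_permutation_test,
    amova,
    fst_matrix,
    fst_permutation_test,
    ibd_regression,
    mantel_test,
    pairwise_fst,
    pairwise_rst,
    rst,
)
from hydropop.io import GroupingScheme, ValidationError
from tests.conftest import table_from_genotypes


def wc_theta_oracle(gA, gB):
    """Independent symbolic evaluation of the Weir-Cockerham estimator
    (single locus, two samples)."""
    alleles = sorted({x for g in gA + gB for x in g})
    r = 2
    n1, n2 = len(gA), len(gB)
    nbar = (n1 + n2) / 2
    nc = (r * nbar - (n1 * n1 + n2 * n2) / (r * nbar)) / (r - 1)
    A = T = 0.0
    for al in alleles:
        p1 = sum(g.count(al) for g in gA) / (2 * n1)
        p2 = sum(g.count(al) for g in gB) / (2 * n2)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        h1 = sum(1 for g in gA if g.count(al) == 1) / n1
        h2 = sum(1 for g in gB if g.count(al) == 1) / n2
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (1 / (nbar - 1)) * (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - ((r - 1) / r) * s2 - ((2 * nbar - 1) / (4 * nbar)) * hbar
        )
        c = hbar / 2
        A += a
        T += a + b + c
    return A / T


class TestWeirCockerham:
    def test_fixed_difference_is_one(self):
        t = table_from_genotypes(
            {"A": [[(100, 100)]] * 10, "B": [[(102, 102)]] * 10}
        )
        assert pairwise_fst(t, "A", "B") == pytest.approx(1.0)

    def test_matches_symbolic_oracle(self):
        gA = [(100, 102), (100, 100), (102, 102), (100, 102), (100, 100)]
        gB = [(102, 102), (102, 104), (104, 104), (102, 104), (104, 104)]
        t = table_from_genotypes({"A": [[g] for g in gA], "B": [[g] for g in gB]})
        assert pairwise_fst(t, "A", "B") == pytest.approx(wc_theta_oracle(gA, gB))

    def test_panmictic_mean_near_zero(self):
        rng = np.random.default_rng(21)
        vals = []
        for _ in range(100):
            draws = rng.choice(4, size=(40, 3, 2), p=[0.4, 0.3, 0.2, 0.1]) * 2 + 100
            genos = {"A": [], "B": []}
            for i in range(40):
                row = [tuple(sorted(draws[i, j])) for j in range(3)]
                genos["A" if i < 20 else "B"].append(row)
            vals.append(pairwise_fst(table_from_genotypes(genos), "A", "B"))
        se = np.std(vals) / np.sqrt(len(vals))
        assert abs(np.mean(vals)) < 2 * se + 1e-6

    def test_allele_relabeling_invariance(self):
        rng = np.random.default_rng(3)
        draws = rng.choice([100, 102, 104], size=(30, 2, 2))
        relabel = {100: 140, 102: 100, 104: 120}
        genos1, genos2 = {"A": [], "B": []}, {"A": [], "B": []}
        for i in range(30):
            pop = "A" if i < 15 else "B"
            genos1[pop].append([tuple(sorted(draws[i, j])) for j in range(2)])
            genos2[pop].append(
                [tuple(sorted((relabel[a], relabel[b]))) for a, b in
                 (tuple(draws[i, j]) for j in range(2))]
            )
        t1, t2 = table_from_genotypes(genos1), table_from_genotypes(genos2)
        assert pairwise_fst(t1, "A", "B") == pytest.approx(pairwise_fst(t2, "A", "B"))


class TestFstPermutation:
    def test_fixed_difference_minimal_p(self):
        t = table_from_genotypes(
            {"A": [[(100, 100)]] * 10, "B": [[(102, 102)]] * 10}
        )
        theta, p = fst_permutation_test(t, "A", "B", n_perm=199, seed=5)
        assert theta == pytest.approx(1.0)
        assert p == pytest.approx(1 / 200)

    def test_deterministic_given_seed(self, two_pop_table):
        r1 = fst_permutation_test(two_pop_table, "A", "B", n_perm=99, seed=3)
        r2 = fst_permutation_test(two_pop_table, "A", "B", n_perm=99, seed=3)
        assert r1 == r2

    def test_matrix_shape(self, two_pop_table):
        m = fst_matrix(two_pop_table)
        assert m.shape == (2, 2) and m.loc["A", "A"] == 0


class TestRst:
    def test_identical_distributions_near_zero(self):
        genos = [[(100, 104)], [(102, 102)], [(104, 106)], [(100, 102)]]
        t = table_from_genotypes({"A": genos, "B": list(genos)})
        assert abs(pairwise_rst(t, "A", "B")) < 0.2

    def test_monomorphic_five_repeats_apart_is_one(self):
        t = table_from_genotypes(
            {"A": [[(100, 100)]] * 8, "B": [[(110, 110)]] * 8}
        )
        assert pairwise_rst(t, "A", "B") == pytest.approx(1.0)

    def test_matches_hand_anova_oracle(self):
        gA = [(100, 102), (100, 100), (102, 102), (100, 102), (100, 100)]
        gB = [(102, 102), (102, 104), (104, 104), (102, 104), (104, 104)]
        zA = [(v - 100) / 2 for g in gA for v in g]
        zB = [(v - 100) / 2 for g in gB for v in g]
        NA, NB = len(zA), len(zB)
        N, r = NA + NB, 2
        mA, mB, m = np.mean(zA), np.mean(zB), np.mean(zA + zB)
        ssb = NA * (mA - m) ** 2 + NB * (mB - m) ** 2
        ssw = sum((z - mA) ** 2 for z in zA) + sum((z - mB) ** 2 for z in zB)
        msb, msw = ssb / (r - 1), ssw / (N - r)
        n0 = (N - (NA**2 + NB**2) / N) / (r - 1)
        s2b = (msb - msw) / n0
        oracle = s2b / (s2b + msw)
        t = table_from_genotypes({"A": [[g] for g in gA], "B": [[g] for g in gB]})
        assert pairwise_rst(t, "A", "B") == pytest.approx(oracle)

    def test_size_translation_invariance(self):
        gA = [[(100, 104)], [(102, 102)], [(100, 100)]]
        gB = [[(104, 106)], [(106, 106)], [(104, 104)]]
        shift = lambda g: [[(a + 20, b + 20) for a, b in row] for row in g]
        t1 = table_from_genotypes({"A": gA, "B": gB})
        t2 = table_from_genotypes({"A": shift(gA), "B": shift(gB)})
        assert pairwise_rst(t1, "A", "B") == pytest.approx(pairwise_rst(t2, "A", "B"))


class TestAlleleSizePermutation:
    def test_equally_spaced_exchangeable_alleles_symmetric(self):
        # permuting sizes of equally-frequent, equally-spaced alleles leaves
        # the R_ST distribution unchanged: observed R_ST is a typical draw
        rng = np.random.default_rng(9)
        draws_a = rng.choice([100, 102, 104], size=(25, 2))
        draws_b = rng.choice([100, 102, 104], size=(25, 2))
        t = table_from_genotypes(
            {
                "A": [[tuple(sorted(d))] for d in draws_a],
                "B": [[tuple(sorted(d))] for d in draws_b],
            }
        )
        res = allele_size_permutation_test(t, n_perm=499, seed=2)
        assert 0.02 < res.p_value

    def test_mutation_driven_divergence_detected(self):
        from hydropop.simulate import MutationModel, SampledPop, Scenario, simulate_coalescent

        mut = MutationModel(mean_rate=1e-3, rate_shape=None, p_geom=0)
        hits = 0
        for rep in range(12):
            sc = Scenario(
                populations=[SampledPop("A", 25, 2000), SampledPop("B", 25, 2000)],
                ancestral={"anc": 2000},
            )
            sc.merge("A", "anc", 8000)
            sc.merge("B", "anc", 8000)
            tt = simulate_coalescent(sc, mut, 10, seed=300 + rep)
            res = allele_size_permutation_test(tt, n_perm=199, seed=rep)
            hits += res.p_value < 0.05
        assert hits >= 7

    def test_drift_only_divergence_mostly_nonsignificant(self):
        rng = np.random.default_rng(40)
        hits = 0
        n_rep = 30
        for rep in range(n_rep):
            # drift-only null: allele identities drift, sizes are arbitrary
            base = rng.dirichlet([1.5] * 5)
            sizes = 100 + 2 * rng.permutation(8)[:5]
            genos = {}
            for pop in ("A", "B"):
                p = rng.dirichlet(base * 30)
                draws = rng.choice(5, size=(20, 2), p=p)
                genos[pop] = [[tuple(sorted(sizes[d]))] for d in draws]
            res = allele_size_permutation_test(
                table_from_genotypes(genos), n_perm=199, seed=rep
            )
            hits += res.p_value < 0.05
        assert hits <= 0.1 * n_rep + 2

    def test_pairwise_mode_pair_count(self, study_fixture):
        from hydropop.differentiation import rst_pairwise_tests

        table, _, _ = study_fixture
        sub = table.subset(populations=["DAN1", "DAN2", "ELB1", "ODR1"])
        out = rst_pairwise_tests(sub, n_perm=29, seed=0)
        assert len(out) == 6  # 4 choose 2


class TestAmova:
    def test_disjoint_groups_fct_one(self):
        t = table_from_genotypes(
            {
                "P1": [[(100, 100)]] * 8,
                "P2": [[(100, 100)]] * 8,
                "P3": [[(104, 104)]] * 8,
                "P4": [[(104, 104)]] * 8,
            }
        )
        res = amova(t, {"P1": "g1", "P2": "g1", "P3": "g2", "P4": "g2"}, n_perm=0)
        assert res.f_ct == pytest.approx(1.0)

    def test_panmictic_fct_near_zero(self):
        rng = np.random.default_rng(17)
        vals = []
        for _ in range(40):
            genos = {}
            for p in range(4):
                draws = rng.choice(3, size=(12, 2), p=[0.5, 0.3, 0.2]) * 2 + 100
                genos[f"P{p}"] = [[tuple(sorted(d))] for d in draws]
            res = amova(
                table_from_genotypes(genos),
                {"P0": "g1", "P1": "g1", "P2": "g2", "P3": "g2"},
                n_perm=0,
            )
            vals.append(res.f_ct)
        se = np.std(vals) / np.sqrt(len(vals))
        assert abs(np.mean(vals)) < 2.5 * se + 1e-6

    def test_matches_brute_force_ssd_oracle(self):
        rng = np.random.default_rng(2)
        genos = {
            f"P{p}": [
                [tuple(sorted(rng.choice([100, 102, 104], 2)))] for _ in range(6)
            ]
            for p in range(4)
        }
        t = table_from_genotypes(genos)
        res = amova(t, {"P0": "g1", "P1": "g1", "P2": "g2", "P3": "g2"}, n_perm=0)
        copies, pop_of = [], []
        for p, g in enumerate(genos.values()):
            for (a,) in g:
                copies += [a[0], a[1]]
                pop_of += [p, p]
        copies, pop_of = np.array(copies), np.array(pop_of)
        D = (copies[:, None] != copies[None, :]).astype(float)
        N = len(copies)

        def ssd(idx):
            idx = list(idx)
            return D[np.ix_(idx, idx)].sum() / (2 * len(idx))

        ssd_t = ssd(range(N))
        ssd_wp = sum(ssd(np.where(pop_of == p)[0]) for p in range(4))
        ssd_wg = ssd(np.where(pop_of < 2)[0]) + ssd(np.where(pop_of >= 2)[0])
        G, P = 2, 4
        df_ag, df_ap, df_wp = G - 1, P - G, N - P
        ms_wp = ssd_wp / df_wp
        ms_ap = (ssd_wg - ssd_wp) / df_ap
        ms_ag = (ssd_t - ssd_wg) / df_ag
        n2 = np.full(4, N / 4)
        Ng = np.full(2, N / 2)
        s_within = (n2[:2] ** 2).sum() / Ng[0] + (n2[2:] ** 2).sum() / Ng[1]
        n_p = (N - s_within) / df_ap
        n_pp = (s_within - (n2**2).sum() / N) / df_ag
        n_ppp = (N - (Ng**2).sum() / N) / df_ag
        sc = ms_wp
        sb = (ms_ap - sc) / n_p
        sa = (ms_ag - sc - n_pp * sb) / n_ppp
        assert res.sigma_a == pytest.approx(sa)
        assert res.sigma_b == pytest.approx(sb)
        assert res.sigma_c == pytest.approx(sc)
        assert res.f_ct == pytest.approx(sa / (sa + sb + sc))

    def test_single_group_rejected(self, two_pop_table):
        with pytest.raises(ValidationError, match="2 groups"):
            Amova(two_pop_table, {"A": "g1", "B": "g1"})

    def test_summary_components_sum(self):
        rng = np.random.default_rng(33)
        genos = {
            f"P{p}": [
                [tuple(sorted(rng.choice([100, 102, 104, 106], 2)))]
                for _ in range(8)
            ]
            for p in range(4)
        }
        t = table_from_genotypes(genos)
        res = amova(t, {"P0": "g1", "P1": "g1", "P2": "g2", "P3": "g2"},
                    n_perm=50, seed=1)
        s = res.summary()
        assert s.loc["total", "variance"] == pytest.approx(
            res.sigma_a + res.sigma_b + res.sigma_c
        )
        assert 0 <= res.p_fct <= 1

    def test_fixture_translocation_signal(self, study_fixture):
        # the Czech Oder populations were founded from the northern Morava
        # stem, so they are closer to it than to the Polish Baltic rivers
        table, _, _ = study_fixture
        czoder = ["ODR1", "ODR2", "ODR3"]
        nmorav = ["DAN1", "DAN2", "DAN4"]
        polriv = ["ODR4", "VIS1", "VIS2"]
        to_nmorav = np.mean(
            [pairwise_fst(table, a, b) for a in czoder for b in nmorav]
        )
        to_polriv = np.mean(
            [pairwise_fst(table, a, b) for a in czoder for b in polriv]
        )
        assert to_nmorav < to_polriv

    def test_fixture_fct_increases_without_mismatched(self, study_fixture):
        from hydropop.fixture import MISMATCHED
        from hydropop.pipeline import _amova_subset_groups

        table, grouping, _ = study_fixture
        groups = _amova_subset_groups(grouping)
        res_all = Amova(table, groups).fit(n_perm=0)
        keep = {p: g for p, g in groups.items() if p not in MISMATCHED}
        res_red = Amova(table, keep).fit(n_perm=0)
        assert res_red.f_ct > res_all.f_ct


class TestIbd:
    def test_perfect_relationship(self):
        # distances built to be exactly exp(F/(1-F)) give Mantel r = 1
        n = 6
        rng = np.random.default_rng(8)
        F = np.zeros((n, n))
        iu = np.triu_indices(n, 1)
        F[iu] = rng.uniform(0.01, 0.3, size=len(iu[0]))
        F = F + F.T
        D = np.exp(F / (1 - F))
        np.fill_diagonal(D, 0)
        pops = [f"P{i}" for i in range(n)]
        fst = pd.DataFrame(F, index=pops, columns=pops)
        res = ibd_regression(fst, D, pops, n_perm=199, seed=1)
        assert res.mantel_r == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1 / 200)
        assert res.slope == pytest.approx(1.0)

    def test_population_order_invariance(self):
        n = 5
        rng = np.random.default_rng(10)
        F = np.zeros((n, n))
        iu = np.triu_indices(n, 1)
        F[iu] = rng.uniform(0.01, 0.3, size=len(iu[0]))
        F = F + F.T
        D = rng.uniform(1, 100, size=(n, n))
        D = (D + D.T) / 2
        np.fill_diagonal(D, 0)
        pops = [f"P{i}" for i in range(n)]
        fst = pd.DataFrame(F, index=pops, columns=pops)
        r1 = ibd_regression(fst, D, pops, n_perm=0 or 19, seed=3)
        order = [pops[i] for i in rng.permutation(n)]
        idx = [pops.index(p) for p in order]
        r2 = ibd_regression(
            fst.loc[order, order], D[np.ix_(idx, idx)], order, n_perm=19, seed=3
        )
        assert r1.slope == pytest.approx(r2.slope)
        assert r1.mantel_r == pytest.approx(r2.mantel_r)

    def test_fst_one_pair_excluded(self):
        pops = ["A", "B", "C", "D"]
        F = np.array(
            [
                [0, 1.0, 0.1, 0.2],
                [1.0, 0, 0.15, 0.25],
                [0.1, 0.15, 0, 0.05],
                [0.2, 0.25, 0.05, 0],
            ]
        )
        rng = np.random.default_rng(4)
        D = rng.uniform(10, 90, size=(4, 4))
        D = (D + D.T) / 2
        np.fill_diagonal(D, 0)
        fst = pd.DataFrame(F, index=pops, columns=pops)
        res = ibd_regression(fst, D, pops, n_perm=19, seed=0)
        assert ("A", "B") in res.excluded_pairs
        assert res.n_pairs == 5
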
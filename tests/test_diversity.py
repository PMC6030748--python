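import math
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hydropop.diversity import (
    allelic_richness,
    diversity_table,
    estimate_null_alleles,
    genotype_counts_from_table,
    heterozygosity,
    hwe_exact_test,
    hwe_test_population,
    null_allele_loglik,
    rarefaction_richness,
)
from hydropop.io import MISSING, ValidationError
from tests.conftest import table_from_genotypes


class TestHeterozygosity:
    def test_monomorphic_zero(self):
        t = table_from_genotypes({"P": [[(100, 100)] for _ in range(10)]})
        h = heterozygosity(t, "P")
        assert h.Ho.iloc[0] == 0.0 and h.He.iloc[0] == 0.0

    def test_all_heterozygote_two_alleles(self):
        t = table_from_genotypes({"P": [[(100, 102)] for _ in range(10)]})
        h = heterozygosity(t, "P")
        assert h.Ho.iloc[0] == 1.0
        assert h.He.iloc[0] == pytest.approx((20 / 19) * 0.5)

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(0)
        genos = [
            [tuple(sorted(100 + 2 * rng.integers(0, 4, 2)))] for _ in range(25)
        ]
        relabel = {100: 106, 102: 104, 104: 100, 106: 102}
        genos2 = [[tuple(sorted((relabel[a], relabel[b])))] for ((a, b),) in genos]
        h1 = heterozygosity(table_from_genotypes({"P": genos}), "P")
        h2 = heterozygosity(table_from_genotypes({"P": genos2}), "P")
        assert h1.He.iloc[0] == pytest.approx(h2.He.iloc[0])
        assert h1.Ho.iloc[0] == pytest.approx(h2.Ho.iloc[0])

    def test_zero_genotyped_flagged_nan(self):
        t = table_from_genotypes({"P": [[(MISSING, MISSING)] for _ in range(4)]})
        h = heterozygosity(t, "P")
        assert math.isnan(h.He.iloc[0])

    def test_he_unbiasedness(self):
        # mean He over replicate samples matches 1 - sum p^2 of the source
        rng = np.random.default_rng(5)
        p = np.array([0.5, 0.3, 0.2])
        target = 1 - (p**2).sum()
        vals = []
        for _ in range(400):
            draws = rng.choice(3, size=(12, 2), p=p) * 2 + 100
            t = table_from_genotypes({"P": [[tuple(sorted(d))] for d in draws]})
            vals.append(heterozygosity(t, "P").He.iloc[0])
        se = np.std(vals) / np.sqrt(len(vals))
        assert abs(np.mean(vals) - target) < 2 * se + 1e-9


class TestAllelicRichness:
    def test_monomorphic_is_one(self):
        assert rarefaction_richness([20], 6) == pytest.approx(1.0)

    def test_full_sample_equals_allele_count(self):
        assert rarefaction_richness([15, 3], 18) == pytest.approx(2.0)

    def test_exhaustive_enumeration_oracle(self):
        counts = [15, 3]
        g = 6
        allele = lambda i: 0 if i < 15 else 1
        mean = np.mean(
            [len({allele(i) for i in c}) for c in combinations(range(18), g)]
        )
        assert rarefaction_richness(counts, g) == pytest.approx(mean)

    def test_undefined_when_sample_too_small(self):
        t = table_from_genotypes({"P": [[(100, 102)] for _ in range(4)]})
        assert math.isnan(allelic_richness(t, "P", g=18).iloc[0])

    @given(
        counts=st.lists(st.integers(1, 12), min_size=1, max_size=5),
        g1=st.integers(2, 10),
    )
    @settings(max_examples=60, deadline=None)
    def test_monotone_in_g(self, counts, g1):
        total = sum(counts)
        g2 = g1 + 1
        if g2 > total:
            return
        a1 = rarefaction_richness(counts, g1)
        a2 = rarefaction_richness(counts, g2)
        assert a2 >= a1 - 1e-12
        assert rarefaction_richness(counts, total) == pytest.approx(len(counts))


class TestHweExact:
    def test_monomorphic_flagged(self):
        r = hwe_exact_test({(1, 1): 10})
        assert r.p_value == 1.0 and r.method == "no_test"

    def test_two_allele_enumeration_oracle(self):
        # independent oracle: enumerate heterozygote counts of Levene's law
        nAA, nAa, naa = 4, 2, 4
        n = 10
        cA, ca = 2 * nAA + nAa, 2 * naa + nAa
        lg = math.lgamma

        def logp(h):
            a, b = (cA - h) // 2, (ca - h) // 2
            if (cA - h) % 2 or a < 0 or b < 0:
                return None
            return (
                lg(n + 1) + lg(cA + 1) + lg(ca + 1) - lg(2 * n + 1)
                + h * math.log(2) - lg(a + 1) - lg(h + 1) - lg(b + 1)
            )
        lobs = logp(nAa)
        logs = [lp for h in range(min(cA, ca) + 1) if (lp := logp(h)) is not None]
        total = sum(math.exp(v) for v in logs)
        p_oracle = sum(math.exp(v) for v in logs if v <= lobs + 1e-12) / total
        r = hwe_exact_test({(1, 1): nAA, (1, 2): nAa, (2, 2): naa})
        assert r.method == "enumeration"
        assert r.p_value == pytest.approx(p_oracle, abs=1e-10)

    def test_mcmc_within_3se_of_enumeration(self):
        gc = {(1, 1): 3, (1, 2): 4, (2, 2): 2, (1, 3): 1, (2, 3): 3, (3, 3): 2}
        exact = hwe_exact_test(gc, method="enumeration").p_value
        est = hwe_exact_test(gc, method="mcmc", seed=4, n_burn=2000,
                             n_batches=40, batch_size=1500)
        assert abs(est.p_value - exact) < 3 * est.se

    def test_mcmc_deterministic_given_seed(self):
        gc = {(1, 1): 5, (1, 2): 6, (2, 2): 3, (1, 3): 2, (3, 3): 4}
        a = hwe_exact_test(gc, method="mcmc", seed=7, n_burn=500,
                           n_batches=10, batch_size=500)
        b = hwe_exact_test(gc, method="mcmc", seed=7, n_burn=500,
                           n_batches=10, batch_size=500)
        assert a.p_value == b.p_value

    def test_fixture_reduced_locus_set_flags_fewer_populations(self, study_fixture):
        # null-allele loci inflate homozygosity; dropping them (plus the
        # hyper-variable locus) should leave fewer HWE-deviant populations
        from hydropop.fixture import REDUCED_LOCUS_SET

        table, _, _ = study_fixture
        full_flags = reduced_flags = 0
        for pop in table.population_labels():
            pvals = {}
            for j, loc in enumerate(table.loci):
                counts = genotype_counts_from_table(table, pop, j)
                alleles = {x for pair in counts for x in pair}
                if len(alleles) < 2:
                    continue
                r = hwe_exact_test(counts, method="mcmc", seed=j + 1,
                                   n_burn=500, n_batches=10, batch_size=300)
                pvals[loc.name] = r.p_value
            if any(p < 0.05 / 12 for p in pvals.values()):
                full_flags += 1
            if any(p < 0.05 / 9 for nm, p in pvals.items()
                   if nm in REDUCED_LOCUS_SET):
                reduced_flags += 1
        assert full_flags > reduced_flags


class TestNullAlleleEM:
    def test_no_homozygote_excess_gives_zero(self):
        # genotype counts exactly at HW proportions, p = (0.5, 0.5), n = 100
        genos = (
            [[(100, 100)]] * 25 + [[(100, 102)]] * 50 + [[(102, 102)]] * 25
        )
        t = table_from_genotypes({"P": genos})
        assert estimate_null_alleles(t, "P", 0) < 1e-6

    def test_matches_grid_search_oracle(self):
        # crafted counts with inflated homozygosity
        genos = [[(100, 100)]] * 40 + [[(100, 102)]] * 30 + [[(102, 102)]] * 30
        t = table_from_genotypes({"P": genos})
        f_em = estimate_null_alleles(t, "P", 0, tol=1e-10)
        # grid search over (f, p1) of the same likelihood
        hom = np.array([40, 30])
        het = {(0, 1): 30}
        best, best_ll = None, -np.inf
        for f in np.linspace(0.0, 0.4, 801):
            for p1 in np.linspace(0.05, 0.95, 361):
                p = np.array([p1, 1 - f - p1])
                if p[1] <= 0:
                    continue
                ll = null_allele_loglik(hom, het, 0, p, f)
                if ll > best_ll:
                    best_ll, best = ll, f
        assert f_em == pytest.approx(best, abs=1e-3)

    def test_recovers_simulated_null_frequency(self):
        from hydropop.simulate import NuisanceModel, apply_nuisance

        rng = np.random.default_rng(12)
        estimates = []
        for rep in range(60):
            p = rng.dirichlet([2.0] * 5)
            draws = rng.choice(5, size=(50, 2), p=p) * 2 + 100
            t = table_from_genotypes({"P": [[tuple(sorted(d))] for d in draws]})
            t = apply_nuisance(t, NuisanceModel(null_freq={"L1": 0.08}),
                               seed=int(rng.integers(1, 2**31)))
            try:
                estimates.append(estimate_null_alleles(t, "P", 0))
            except ValidationError:
                continue
        assert abs(np.mean(estimates) - 0.08) < 0.03

    def test_too_few_individuals_rejected(self):
        t = table_from_genotypes({"P": [[(100, 102)]] * 3})
        with pytest.raises(ValidationError, match=">= 5"):
            estimate_null_alleles(t, "P", 0)


class TestDiversityReport:
    def test_fixture_report_shape_and_ranges(self, study_fixture):
        table, _, _ = study_fixture
        sub = table.subset(populations=["DAN1", "ELB3"])
        df = diversity_table(sub, estimate_nulls=False)
        assert len(df) == 2 * 12
        assert ((df.Ho.dropna() >= 0) & (df.Ho.dropna() <= 1)).all()
        assert ((df.He.dropna() >= 0) & (df.He.dropna() <= 1)).all()
        ar = df["AR_18"].dropna()
        assert (ar >= 1).all()
        assert (ar <= df.loc[ar.index, "A"] + 1e-9).all()
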
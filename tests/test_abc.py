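import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from hydropop.abc import (
    DEFAULT_MUT_PRIORS,
    ScenarioFamily,
    build_reference,
    default_fitting_stats,
    default_heldout_stats,
    estimate_parameters,
    model_check,
    model_choice,
    stat_names,
    summary_statistics,
    summary_stats_from_repeats,
    weighted_quantile,
)
from hydropop.io import ValidationError
from hydropop.simulate import (
    MutationModel,
    SampledPop,
    Scenario,
    simulate_repeat_counts,
)
from tests.conftest import table_from_genotypes


def two_pop_family(name, t_lo, t_hi, n=20, ne=1000):
    def builder(p):
        sc = Scenario(
            populations=[SampledPop("A", n, ne), SampledPop("B", n, ne)],
            ancestral={"anc": ne},
        )
        sc.merge("A", "anc", p["t"])
        sc.merge("B", "anc", p["t"])
        return sc

    return ScenarioFamily(name, {"t": (t_lo, t_hi)}, builder)


class TestSummaryStatistics:
    def test_monomorphic_data(self):
        reps = np.full((10, 3, 2), 7, dtype=np.int64)
        vec = summary_stats_from_repeats(reps, np.repeat([0, 1], 5), 2)
        names = stat_names(["A", "B"])
        s = pd.Series(vec, index=names)
        assert s["nal__A"] == 1 and s["nal__B"] == 1
        assert s["het__A"] == 0 and s["var__A"] == 0
        assert s["dmu2__A__B"] == 0

    def test_identical_groups_no_differentiation(self):
        rng = np.random.default_rng(1)
        block = rng.integers(0, 5, size=(30, 4, 2))
        reps = np.concatenate([block, block])
        vec = summary_stats_from_repeats(reps, np.repeat([0, 1], 30), 2)
        s = pd.Series(vec, index=stat_names(["A", "B"]))
        assert abs(s["fst__A__B"]) < 0.02
        assert s["dmu2__A__B"] == pytest.approx(0.0)

    def test_matches_hand_computed_vector(self):
        # 2 individuals per group, 1 locus, worked by hand
        reps = np.array(
            [
                [[0, 2]], [[0, 0]],  # group A: alleles 0,2,0,0
                [[2, 2]], [[2, 4]],  # group B: alleles 2,2,2,4
            ],
            dtype=np.int64,
        )
        vec = pd.Series(
            summary_stats_from_repeats(reps, np.array([0, 0, 1, 1]), 2),
            index=stat_names(["A", "B"]),
        )
        assert vec["nal__A"] == 2
        # unbiased gene diversity: (4/3) * (1 - (3/4)^2 - (1/4)^2) = 0.5
        assert vec["het__A"] == pytest.approx(0.5)
        assert vec["var__A"] == pytest.approx(np.var([0, 2, 0, 0], ddof=1))
        assert vec["dmu2__A__B"] == pytest.approx((0.5 - 2.5) ** 2)
        # DAS: cross pairs (02 vs 22) share 1, (02 vs 24) share 1,
        # (00 vs 22) share 0, (00 vs 24) share 0 -> mean ps = 0.25
        assert vec["das__A__B"] == pytest.approx(1 - 0.25)

    def test_table_and_repeats_paths_agree(self, two_pop_table):
        s = summary_statistics(two_pop_table)
        assert set(s.index) == set(stat_names(["A", "B"]))
        assert np.isfinite(s.to_numpy()).all()

    def test_fitting_and_heldout_sets_disjoint(self):
        groups = ["X", "Y", "Z"]
        fit = set(default_fitting_stats(groups))
        held = set(default_heldout_stats(groups))
        assert not (fit & held)
        assert fit | held == set(stat_names(groups))


class TestReferenceTable:
    def test_empty_reference(self):
        fam = two_pop_family("s1", 10, 100)
        ref = build_reference([fam], 0, {"A": 20, "B": 20}, n_loci=4, seed=1)
        assert len(ref.data) == 0

    def test_deterministic_given_seed(self):
        fam = two_pop_family("s1", 10, 100)
        r1 = build_reference([fam], 5, {"A": 20, "B": 20}, n_loci=4, seed=7)
        r2 = build_reference([fam], 5, {"A": 20, "B": 20}, n_loci=4, seed=7)
        pd.testing.assert_frame_equal(r1.data, r2.data)

    def test_parameter_marginals_match_priors(self):
        fam = two_pop_family("s1", 50, 500, n=8)
        ref = build_reference([fam], 300, {"A": 8, "B": 8}, n_loci=2, seed=3)
        t = ref.data["t"].to_numpy()
        ks = sps.kstest(t, sps.uniform(50, 450).cdf)
        assert ks.pvalue > 0.01

    def test_constraint_rejection(self):
        def builder(p):
            sc = Scenario(
                populations=[SampledPop("A", 5, 100), SampledPop("B", 5, 100)],
                ancestral={"anc": 100},
            )
            sc.merge("A", "anc", p["t1"])
            sc.merge("B", "anc", p["t2"])
            return sc

        fam = ScenarioFamily(
            "s", {"t1": (10, 100), "t2": (10, 100)}, builder,
            constraints=[lambda p: p["t1"] < p["t2"]],
        )
        rng = np.random.default_rng(0)
        for _ in range(50):
            p = fam.sample_params(rng)
            assert p["t1"] < p["t2"]

    def test_resume_by_extension_and_tsv_round_trip(self, tmp_path):
        from hydropop.abc import ReferenceTable

        fam = two_pop_family("s1", 10, 100, n=5)
        r1 = build_reference([fam], 4, {"A": 5, "B": 5}, n_loci=2, seed=1)
        r2 = build_reference([fam], 3, {"A": 5, "B": 5}, n_loci=2, seed=2)
        ext = r1.extend(r2)
        assert len(ext.data) == 7
        p = tmp_path / "ref.tsv"
        ext.to_tsv(p)
        back = ReferenceTable.from_tsv(p, ext.priors, ext.groups)
        assert back.stat_cols == ext.stat_cols
        pd.testing.assert_frame_equal(
            back.data[ext.data.columns], ext.data, check_dtype=False
        )

    def test_impossible_constraint_errors(self):
        fam = two_pop_family("s", 10, 100)
        fam.constraints = [lambda p: False]
        with pytest.raises(ValidationError, match="no valid"):
            fam.sample_params(np.random.default_rng(0))


@pytest.fixture(scope="module")
def separated_ref():
    fams = [two_pop_family("recent", 10, 100, n=15, ne=800),
            two_pop_family("old", 500, 2000, n=15, ne=800)]
    return fams, build_reference(
        fams, 400, {"A": 15, "B": 15}, n_loci=8, seed=13
    )


class TestModelChoice:

    def test_identical_scenarios_symmetric_posteriors(self):
        fams = [two_pop_family("s1", 100, 500, n=10, ne=500),
                two_pop_family("s2", 100, 500, n=10, ne=500)]
        ref = build_reference(fams, 250, {"A": 10, "B": 10}, n_loci=5, seed=5)
        sc = fams[0].builder({"t": 300})
        reps = simulate_repeat_counts(sc, MutationModel(rate_shape=None), 5, seed=99)
        obs = pd.Series(
            summary_stats_from_repeats(reps, np.repeat([0, 1], 10), 2),
            index=stat_names(["A", "B"]),
        )
        res = model_choice(ref, obs, tolerance=0.2)
        assert abs(res.posterior["prob"].iloc[0] - 0.5) < 0.25
        assert res.posterior["prob"].sum() == pytest.approx(1.0)

    def test_true_scenario_recovered(self, separated_ref):
        fams, ref = separated_ref
        wins = 0
        for rep in range(10):
            truth = fams[rep % 2]
            t_true = 50 if truth.name == "recent" else 1000
            reps = simulate_repeat_counts(
                truth.builder({"t": t_true}),
                MutationModel(rate_shape=None), 8, seed=500 + rep,
            )
            obs = pd.Series(
                summary_stats_from_repeats(reps, np.repeat([0, 1], 15), 2),
                index=stat_names(["A", "B"]),
            )
            res = model_choice(ref, obs, tolerance=0.1)
            wins += res.best() == truth.name
        assert wins >= 8

    def test_rejection_and_logistic_agree_when_separated(self, separated_ref):
        fams, ref = separated_ref
        reps = simulate_repeat_counts(
            fams[1].builder({"t": 1200}), MutationModel(rate_shape=None), 8,
            seed=321,
        )
        obs = pd.Series(
            summary_stats_from_repeats(reps, np.repeat([0, 1], 15), 2),
            index=stat_names(["A", "B"]),
        )
        logi = model_choice(ref, obs, tolerance=0.1)
        # direct rejection frequencies on the retained set
        X, _ = np.broadcast_arrays(0, 0), None
        from hydropop.abc import _standardize

        Xs, _ = _standardize(ref.data, obs, default_fitting_stats(ref.groups))
        d2 = (Xs**2).sum(axis=1)
        keep = np.argsort(d2)[: int(0.1 * len(d2))]
        frac_old = (ref.data["scenario"].to_numpy()[keep] == "old").mean()
        row = logi.posterior.set_index("scenario")
        assert abs(row.loc["old", "prob"] - frac_old) < 0.2

    def test_single_scenario_rejected(self):
        fam = two_pop_family("only", 10, 100, n=5)
        ref = build_reference([fam], 20, {"A": 5, "B": 5}, n_loci=2, seed=2)
        with pytest.raises(ValidationError, match=">= 2"):
            model_choice(ref, pd.Series(dtype=float))


@pytest.fixture(scope="module")
def ref_and_obs():
    fam = two_pop_family("s", 100, 2000, n=15, ne=800)
    ref = build_reference([fam], 600, {"A": 15, "B": 15}, n_loci=8, seed=17)
    reps = simulate_repeat_counts(
        fam.builder({"t": 800}), MutationModel(rate_shape=None), 8, seed=55
    )
    obs = pd.Series(
        summary_stats_from_repeats(reps, np.repeat([0, 1], 15), 2),
        index=stat_names(["A", "B"]),
    )
    return fam, ref, obs


class TestParameterEstimation:

    def test_tolerance_one_reproduces_prior(self, ref_and_obs):
        fam, ref, obs = ref_and_obs
        # keep everything and skip the regression: quantiles track the prior
        post = estimate_parameters(ref, "s", obs, tolerance=1.0, min_rows=100,
                                   stats=[])
        q = post.quantiles
        assert 100 < q.loc["t", "q2.5"] < 400
        assert 800 < q.loc["t", "median"] < 1300
        assert 1700 < q.loc["t", "q97.5"] < 2000

    def test_adjustment_reduces_posterior_spread(self, ref_and_obs):
        fam, ref, obs = ref_and_obs
        adj = estimate_parameters(ref, "s", obs, tolerance=0.2, min_rows=100)
        prior_sd = (2000 - 100) / np.sqrt(12)
        post_sd = adj.samples["t"].std()
        assert post_sd < prior_sd
        assert adj.adjusted

    def test_posterior_within_bounds(self, ref_and_obs):
        fam, ref, obs = ref_and_obs
        post = estimate_parameters(ref, "s", obs, tolerance=0.2, min_rows=100)
        assert (post.samples["t"] >= 100).all()
        assert (post.samples["t"] <= 2000).all()

    def test_too_few_rows_rejected(self, ref_and_obs):
        fam, ref, obs = ref_and_obs
        with pytest.raises(ValidationError, match="rows"):
            estimate_parameters(ref, "s", obs, tolerance=0.1, min_rows=10_000)

    def test_weighted_quantile_matches_plain_on_equal_weights(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=500)
        w = np.ones(500)
        assert weighted_quantile(x, 0.5, w) == pytest.approx(
            np.quantile(x, 0.5), abs=0.02
        )


class TestModelCheck:
    def test_zero_ppc_rejected(self, study_fixture):
        with pytest.raises(ValidationError, match="positive"):
            model_check(None, None, None, {"A": 5}, ["x"], ["y"], n_ppc=0)

    def test_overlapping_stat_sets_rejected(self):
        with pytest.raises(ValidationError, match="overlap"):
            model_check(None, None, None, {"A": 5}, ["x"], ["x", "y"], n_ppc=5)

    def test_well_specified_model_moderate_tails(self):
        fam = two_pop_family("s", 100, 1500, n=10, ne=600)
        ref = build_reference([fam], 300, {"A": 10, "B": 10}, n_loci=6, seed=23)
        reps = simulate_repeat_counts(
            fam.builder({"t": 600}), MutationModel(rate_shape=None), 6, seed=42
        )
        obs = pd.Series(
            summary_stats_from_repeats(reps, np.repeat([0, 1], 10), 2),
            index=stat_names(["A", "B"]),
        )
        post = estimate_parameters(ref, "s", obs, tolerance=0.3, min_rows=100)
        tails = model_check(
            post, fam, obs, {"A": 10, "B": 10},
            heldout_stats=default_heldout_stats(["A", "B"]),
            fitting_stats=default_fitting_stats(["A", "B"]),
            n_ppc=60, n_loci=6, seed=3,
        )
        assert (tails.dropna() > 0.01).all()

    def test_misspecified_scenario_extreme_tails(self):
        # posterior fitted to a deep split, checked against panmictic data
        deep = two_pop_family("deep", 4000, 8000, n=10, ne=400)
        ref = build_reference([deep], 300, {"A": 10, "B": 10}, n_loci=6, seed=29)
        reps = simulate_repeat_counts(
            deep.builder({"t": 6000}), MutationModel(rate_shape=None), 6, seed=77
        )
        obs_fit = pd.Series(
            summary_stats_from_repeats(reps, np.repeat([0, 1], 10), 2),
            index=stat_names(["A", "B"]),
        )
        post = estimate_parameters(ref, "deep", obs_fit, tolerance=0.3, min_rows=100)
        # "observed" data actually from a panmictic population
        pan = two_pop_family("pan", 1, 2, n=10, ne=400)
        reps0 = simulate_repeat_counts(
            pan.builder({"t": 1.5}), MutationModel(rate_shape=None), 6, seed=78
        )
        obs0 = pd.Series(
            summary_stats_from_repeats(reps0, np.repeat([0, 1], 10), 2),
            index=stat_names(["A", "B"]),
        )
        tails = model_check(
            post, deep, obs0, {"A": 10, "B": 10},
            heldout_stats=default_heldout_stats(["A", "B"]),
            fitting_stats=default_fitting_stats(["A", "B"]),
            n_ppc=60, n_loci=6, seed=5,
        )
        assert (tails.dropna() < 0.15).any()
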
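"""Approximate Bayesian computation for demographic model choice.

Candidate histories (scenario families with uniform priors) are compared by
simulating a large reference table of (scenario, parameters, summary
statistics), retaining the simulations closest to the observed statistics
(Euclidean distance on MAD-standardized statistics), and

* choosing among scenarios by multinomial logistic regression of the
  scenario indicator on statistic deviations, evaluated at the observed
  point (with 95% CIs from the regression covariance);
* estimating parameters of the chosen scenario by local-linear regression
  adjustment (Epanechnikov-weighted), with parameters logit-transformed to
  their prior bounds;
* model checking via posterior predictive simulation of statistics held
  out from the fitting step.

Summary statistics per group: mean allele number, mean gene diversity and
mean allele-size variance; per group pair: F_ST, the shared-allele distance
DAS and the (delta-mu)^2 distance.  By default all per-group statistics
plus F_ST and DAS enter the fitting steps while the (delta-mu)^2 family is
held out for model checking; the split is configurable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from hydropop.io import MISSING, GenotypeTable, ValidationError
from hydropop.simulate import MutationModel, simulate_repeat_counts

#: default priors for mutation hyper-parameters (loguniform rate, uniform P)
DEFAULT_MUT_PRIORS = {"mean_rate": (1e-4, 1e-3, "loguniform"), "p_geom": (0.1, 0.3, "uniform")}


# ---------------------------------------------------------------------------
# Summary statistics
# ---------------------------------------------------------------------------

def _pair_names(groups):
    return [(groups[i], groups[j]) for i in range(len(groups)) for j in range(i + 1, len(groups))]


def stat_names(groups):
    """Canonical, fixed statistic order for a group design."""
    names = []
    for g in groups:
        names += [f"nal__{g}", f"het__{g}", f"var__{g}"]
    for a, b in _pair_names(groups):
        names += [f"fst__{a}__{b}", f"das__{a}__{b}", f"dmu2__{a}__{b}"]
    return names


def one_sample_stats(groups):
    return [n for n in stat_names(groups) if n.split("__")[0] in ("nal", "het", "var")]


def two_sample_stats(groups):
    return [n for n in stat_names(groups) if n.split("__")[0] in ("fst", "das", "dmu2")]


def default_fitting_stats(groups):
    """Default fitting set: everything except the (delta-mu)^2 family."""
    return [n for n in stat_names(groups) if not n.startswith("dmu2")]


def default_heldout_stats(groups):
    return [n for n in stat_names(groups) if n.startswith("dmu2")]


def summary_stats_from_repeats(repeats: np.ndarray, group_idx: np.ndarray, n_groups: int):
    """Summary-statistic vector from a repeat-count genotype array.

    Parameters
    ----------
    repeats : (n, L, 2) int array, MISSING = -1
    group_idx : (n,) group index per individual
    n_groups : number of groups

    Returns a 1-D float array in :func:`stat_names` order.

    The mean proportion of shared alleles between cross-group individual
    pairs (for DAS) is computed in closed form from per-allele counts of
    individuals carrying 0, 1 or 2 copies, avoiding the quadratic pair loop.
    """
    from hydropop.differentiation import _wc_pair_components

    n, L, _ = repeats.shape
    G = n_groups
    pair_list = [(a, b) for a in range(G) for b in range(a + 1, G)]
    nal = np.full((G, L), np.nan)
    het = np.full((G, L), np.nan)
    var = np.full((G, L), np.nan)
    fst_num = np.zeros(len(pair_list))
    fst_den = np.zeros(len(pair_list))
    das_sum = np.zeros(len(pair_list))
    das_cnt = np.zeros(len(pair_list), dtype=int)
    dmu2_sum = np.zeros(len(pair_list))
    dmu2_cnt = np.zeros(len(pair_list), dtype=int)
    group_masks = [group_idx == k for k in range(G)]
    for l in range(L):
        g = repeats[:, l, :]
        scored = g[:, 0] != MISSING
        if not scored.any():
            continue
        vals = g[scored]
        m0 = int(vals.min())
        width = int(vals.max()) - m0 + 1
        codes = vals - m0  # (n_scored, 2)
        # per-individual copy counts per allele, scored individuals only
        X = np.zeros((len(codes), width))
        rows = np.repeat(np.arange(len(codes)), 2)
        np.add.at(X, (rows, codes.reshape(-1)), 1.0)
        sg = group_idx[scored]
        size = np.arange(width, dtype=float)
        C = np.zeros((G, width))   # allele copy counts
        H1 = np.zeros((G, width))  # individuals carrying exactly one copy
        H2 = np.zeros((G, width))  # individuals carrying two copies
        n_ind = np.zeros(G)
        for k in range(G):
            sel = sg == k
            n_ind[k] = sel.sum()
            if n_ind[k] == 0:
                continue
            Xk = X[sel]
            C[k] = Xk.sum(axis=0)
            H1[k] = (Xk == 1).sum(axis=0)
            H2[k] = (Xk == 2).sum(axis=0)
            tot = 2 * n_ind[k]
            p = C[k] / tot
            nal[k, l] = (C[k] > 0).sum()
            het[k, l] = (tot / (tot - 1)) * (1 - (p**2).sum()) if tot > 1 else 0.0
            mean_k = (C[k] @ size) / tot
            var[k, l] = ((C[k] @ size**2) - tot * mean_k**2) / (tot - 1) if tot > 1 else 0.0
        for pi, (a, b) in enumerate(pair_list):
            na, nb = n_ind[a], n_ind[b]
            if na == 0 or nb == 0:
                continue
            if na >= 2 and nb >= 2 and (C[a] + C[b] > 0).sum() >= 2:
                s_a, s_t = _wc_pair_components(na, nb, C[a], C[b], H1[a], H1[b])
                fst_num[pi] += s_a
                fst_den[pi] += s_t
            ma = (C[a] @ size) / (2 * na)
            mb = (C[b] @ size) / (2 * nb)
            dmu2_sum[pi] += (ma - mb) ** 2
            dmu2_cnt[pi] += 1
            # mean L1 distance between cross-pair copy-count vectors:
            # per allele, |x - y| summed over value combinations 0/1/2
            a0 = na - H1[a] - H2[a]
            b0 = nb - H1[b] - H2[b]
            l1 = (
                a0 * (H1[b] + 2 * H2[b])
                + H1[a] * (b0 + H2[b])
                + H2[a] * (2 * b0 + H1[b])
            ).sum() / (na * nb)
            das_sum[pi] += (2.0 - l1 / 2.0) / 2.0  # mean shared fraction
            das_cnt[pi] += 1
    out = []
    for k in range(G):
        row = [nal[k], het[k], var[k]]
        out += [float(np.nanmean(x)) if not np.all(np.isnan(x)) else np.nan
                for x in row]
    for pi in range(len(pair_list)):
        fst = fst_num[pi] / fst_den[pi] if fst_den[pi] else np.nan
        das = 1.0 - das_sum[pi] / das_cnt[pi] if das_cnt[pi] else np.nan
        dmu2 = dmu2_sum[pi] / dmu2_cnt[pi] if dmu2_cnt[pi] else np.nan
        out += [fst, das, dmu2]
    return np.array(out, dtype=float)


def summary_statistics(table: GenotypeTable, groups: dict | None = None) -> pd.Series:
    """Summary-statistic vector for an observed genotype table.

    ``groups`` maps group label -> population list; populations not listed
    are ignored.  When omitted every population is its own group.
    """
    if groups is None:
        groups = {p: [p] for p in table.population_labels()}
    labels = list(groups)
    pop_to_group = {}
    for gi, (glabel, members) in enumerate(groups.items()):
        for p in members:
            pop_to_group[p] = gi
    mask = np.array([p in pop_to_group for p in table.populations])
    sub = table.subset(individuals_mask=mask)
    gidx = np.array([pop_to_group[p] for p in sub.populations])
    reps = np.full((sub.n_individuals, sub.n_loci, 2), MISSING, dtype=np.int64)
    for j in range(sub.n_loci):
        codes, sizes = sub.locus_codes(j)
        units = sub.repeat_units(j, sizes) if len(sizes) else sizes
        scored = codes[:, 0] >= 0
        if len(sizes):
            reps[scored, j, :] = units[codes[scored]]
    vec = summary_stats_from_repeats(reps, gidx, len(labels))
    return pd.Series(vec, index=stat_names(labels))


# ---------------------------------------------------------------------------
# Scenario families and the reference table
# ---------------------------------------------------------------------------

@dataclass
class ScenarioFamily:
    """A demographic scenario with uniform priors over its parameters.

    ``builder(params)`` returns a concrete :class:`Scenario`; ``constraints``
    are predicates on the parameter dict (e.g. event-time orderings) enforced
    by rejection sampling.
    """

    name: str
    priors: dict  # param -> (low, high)
    builder: "callable"
    constraints: list = field(default_factory=list)

    def sample_params(self, rng, max_tries=1000):
        for _ in range(max_tries):
            params = {k: rng.uniform(lo, hi) for k, (lo, hi) in self.priors.items()}
            if all(c(params) for c in self.constraints):
                return params
        raise ValidationError(
            f"scenario {self.name}: priors admit no valid parameter combination "
            f"(constraints {self.constraints})"
        )


def _sample_mutation(rng, mut_priors, allele_range=40):
    lo, hi, kind = mut_priors.get("mean_rate", DEFAULT_MUT_PRIORS["mean_rate"])
    if kind == "loguniform":
        rate = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    else:
        rate = float(rng.uniform(lo, hi))
    plo, phi, _ = mut_priors.get("p_geom", DEFAULT_MUT_PRIORS["p_geom"])
    p = float(rng.uniform(plo, phi))
    return MutationModel(mean_rate=rate, rate_shape=None, p_geom=p, allele_range=allele_range)


@dataclass
class ReferenceTable:
    """Store of (scenario, parameter vector, summary statistics) rows."""

    data: pd.DataFrame
    stat_cols: list
    param_cols: list
    priors: dict  # scenario -> {param: (lo, hi)}
    groups: list  # group labels, fixing the statistic order

    def rows_for(self, scenario: str) -> pd.DataFrame:
        return self.data[self.data["scenario"] == scenario]

    def to_tsv(self, path):
        self.data.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, priors: dict, groups: list) -> "ReferenceTable":
        """Reload a stored reference table (columns infer the stat/param split)."""
        df = pd.read_csv(path, sep="\t")
        stat_cols = [c for c in stat_names(groups) if c in df.columns]
        param_cols = [c for c in df.columns if c not in stat_cols and c != "scenario"]
        return cls(df, stat_cols, param_cols, priors, list(groups))

    def extend(self, other: "ReferenceTable") -> "ReferenceTable":
        """Concatenate two reference tables over the same design (the resume
        path: build additional rows with a fresh seed, then extend)."""
        if other.groups != self.groups or other.stat_cols != self.stat_cols:
            raise ValidationError("reference tables built on different designs")
        priors = dict(self.priors)
        priors.update(other.priors)
        data = pd.concat([self.data, other.data], ignore_index=True)
        params = sorted(set(self.param_cols) | set(other.param_cols))
        return ReferenceTable(data, self.stat_cols, params, priors, self.groups)


def build_reference(
    families,
    n_per_scenario: int,
    group_sizes: dict,
    n_loci: int = 12,
    mut_priors: dict | None = None,
    motif_lengths=None,
    allele_range: int = 40,
    seed: int = 0,
) -> ReferenceTable:
    """Simulate the ABC reference table.

    ``group_sizes`` maps group label -> diploid sample size, matching the
    observed design.  Mutation hyper-parameters (mean rate, geometric step
    parameter) are drawn per simulated dataset from ``mut_priors``.
    Deterministic given ``seed``.
    """
    if n_per_scenario < 0:
        raise ValidationError("n_per_scenario must be >= 0")
    mut_priors = mut_priors or DEFAULT_MUT_PRIORS
    groups = list(group_sizes)
    gsizes = np.array([group_sizes[g] for g in groups])
    gidx = np.repeat(np.arange(len(groups)), gsizes)
    rng = np.random.default_rng(seed)
    param_cols = sorted({p for f in families for p in f.priors})
    rows = []
    for fam in families:
        for _ in range(n_per_scenario):
            params = fam.sample_params(rng)
            mut = _sample_mutation(rng, mut_priors, allele_range)
            sc = fam.builder(params)
            n_sim = sum(p.n for p in sc.populations)
            if n_sim != len(gidx):
                raise ValidationError(
                    f"scenario {fam.name} samples {n_sim} diploids but "
                    f"group_sizes sum to {len(gidx)}"
                )
            reps = simulate_repeat_counts(
                sc, mut, n_loci, int(rng.integers(1, 2**31 - 1))
            )
            vec = summary_stats_from_repeats(reps, gidx, len(groups))
            row = {"scenario": fam.name}
            row.update({p: params.get(p, np.nan) for p in param_cols})
            row.update(dict(zip(stat_names(groups), vec)))
            rows.append(row)
    df = pd.DataFrame(rows)
    return ReferenceTable(
        data=df,
        stat_cols=stat_names(groups),
        param_cols=param_cols,
        priors={f.name: dict(f.priors) for f in families},
        groups=groups,
    )


# ---------------------------------------------------------------------------
# Rejection, model choice, parameter estimation
# ---------------------------------------------------------------------------

def _standardize(ref_stats: pd.DataFrame, observed: pd.Series, stats: list):
    """MAD-standardized deviations of reference stats from the observed."""
    X = ref_stats[stats].to_numpy(dtype=float)
    obs = observed[stats].to_numpy(dtype=float)
    ok_col = np.isfinite(obs) & np.isfinite(X).all(axis=0)
    X = X[:, ok_col]
    obs = obs[ok_col]
    med = np.median(X, axis=0)
    mad = np.median(np.abs(X - med), axis=0)
    mad[mad == 0] = 1.0
    return (X - obs) / mad, [s for s, k in zip(stats, ok_col) if k]


@dataclass
class ModelChoiceResult:
    posterior: pd.DataFrame  # scenario, prob, ci_low, ci_high
    n_retained: int
    method: str  # "logistic" | "rejection"

    def best(self) -> str:
        return self.posterior.sort_values("prob", ascending=False).iloc[0]["scenario"]

    def summary(self) -> str:
        return (
            f"ABC model choice ({self.method}, {self.n_retained} retained)\n"
            + self.posterior.round(4).to_string(index=False)
        )


def model_choice(
    ref: ReferenceTable,
    observed: pd.Series,
    tolerance: float = 0.01,
    stats: list | None = None,
    ridge: float = 1.0,
) -> ModelChoiceResult:
    """Scenario posterior probabilities from the reference table.

    Statistics are MAD-standardized, the closest ``tolerance`` fraction of
    simulations is retained, and a multinomial logistic regression of the
    scenario indicator on statistic deviations is evaluated at the observed
    point (deviation zero).  Retained rows carry Epanechnikov weights in
    distance and the regression is L2-penalized (``ridge``), which keeps the
    local fit stable when the retained classes are nearly separable at
    desk-scale reference sizes.  95 % CIs come from the penalized
    regression's sandwich covariance by the delta method.  Falls back to
    weighted retained-set frequencies when the regression is degenerate.
    """
    scenarios = sorted(ref.data["scenario"].unique())
    if len(scenarios) < 2:
        raise ValidationError("model choice needs >= 2 scenarios")
    stats = stats or default_fitting_stats(ref.groups)
    X, used = _standardize(ref.data, observed, stats)
    d = np.sqrt((X**2).sum(axis=1))
    n_keep = max(len(scenarios) + 1, int(np.ceil(tolerance * len(d))))
    keep = np.argsort(d, kind="stable")[:n_keep]
    Xk = X[keep]
    dk = d[keep]
    dmax = dk.max() if dk.max() > 0 else 1.0
    w = np.maximum(1.0 - (dk / dmax) ** 2, 1e-6)
    yk = ref.data["scenario"].to_numpy()[keep]
    missing = [s for s in scenarios if s not in set(yk)]
    if missing:
        warnings.warn(f"scenarios absent from retained set, probability floored: {missing}")
    probs, ci, method = _logistic_probs(Xk, yk, w, scenarios, ridge)
    post = pd.DataFrame(
        {
            "scenario": scenarios,
            "prob": probs,
            "ci_low": ci[:, 0],
            "ci_high": ci[:, 1],
        }
    )
    return ModelChoiceResult(post, len(keep), method)


def _logistic_probs(Xk, yk, w, scenarios, ridge):
    from sklearn.linear_model import LogisticRegression

    J = len(scenarios)
    code = {s: i for i, s in enumerate(scenarios)}
    y = np.array([code[s] for s in yk])
    present = np.unique(y)
    if len(present) < 2:
        return _weighted_rejection(y, w, J)
    try:
        lr = LogisticRegression(C=1.0 / ridge, max_iter=2000)
        lr.fit(Xk, y, sample_weight=w)
        p_at_zero = lr.predict_proba(np.zeros((1, Xk.shape[1])))[0]
        # sandwich covariance of the penalized weighted fit
        P = lr.predict_proba(Xk)  # (n, Jp)
        Jp = P.shape[1]
        Z = np.column_stack([np.ones(len(Xk)), Xk])  # (n, p+1)
        k = Z.shape[1]
        H = np.zeros((Jp * k, Jp * k))
        for j in range(Jp):
            for m in range(Jp):
                wjm = w * (P[:, j] * ((j == m) - P[:, m]))
                H[j * k : (j + 1) * k, m * k : (m + 1) * k] = (Z * wjm[:, None]).T @ Z
        pen = np.zeros(Jp * k)
        for j in range(Jp):
            pen[j * k + 1 : (j + 1) * k] = ridge  # coefficients only
        Hp = H + np.diag(pen)
        Hp_inv = np.linalg.pinv(Hp)
        cov = Hp_inv @ H @ Hp_inv
        icpt = [j * k for j in range(Jp)]
        cov_b = cov[np.ix_(icpt, icpt)]
        ci_p = np.empty((Jp, 2))
        for j in range(Jp):
            grad = p_at_zero[j] * ((np.arange(Jp) == j) - p_at_zero)
            var = float(grad @ cov_b @ grad)
            half = 1.96 * np.sqrt(max(var, 0.0))
            ci_p[j] = (max(0.0, p_at_zero[j] - half), min(1.0, p_at_zero[j] + half))
        probs = np.zeros(J)
        ci = np.zeros((J, 2))
        for pos, cls in enumerate(lr.classes_):
            probs[cls] = p_at_zero[pos]
            ci[cls] = ci_p[pos]
        probs /= probs.sum()
        return probs, ci, "weighted_logistic"
    except Exception:
        return _weighted_rejection(y, w, J)


def _weighted_rejection(y, w, J):
    probs = np.zeros(J)
    np.add.at(probs, y, w)
    probs /= probs.sum()
    n_eff = float(w.sum() ** 2 / (w**2).sum())
    se = np.sqrt(probs * (1 - probs) / max(n_eff, 1.0))
    ci = np.stack(
        [np.clip(probs - 1.96 * se, 0, 1), np.clip(probs + 1.96 * se, 0, 1)], axis=1
    )
    return probs, ci, "rejection"


def _logit_to_bounds(x, lo, hi):
    z = np.clip((x - lo) / (hi - lo), 1e-9, 1 - 1e-9)
    return np.log(z / (1 - z))


def _inv_logit_from_bounds(t, lo, hi):
    return lo + (hi - lo) / (1 + np.exp(-t))


@dataclass
class ParameterPosterior:
    samples: pd.DataFrame  # adjusted posterior draws per parameter
    weights: np.ndarray
    quantiles: pd.DataFrame  # median and 95% CI per parameter
    adjusted: bool

    def summary(self) -> str:
        return "ABC parameter posterior\n" + self.quantiles.round(4).to_string()


def weighted_quantile(values, q, weights):
    order = np.argsort(values)
    v = np.asarray(values)[order]
    w = np.asarray(weights)[order]
    cw = np.cumsum(w)
    cw /= cw[-1]
    return np.interp(q, cw, v)


def estimate_parameters(
    ref: ReferenceTable,
    scenario: str,
    observed: pd.Series,
    tolerance: float = 0.01,
    stats: list | None = None,
    min_rows: int = 500,
) -> ParameterPosterior:
    """Posterior parameter distributions by local-linear ABC regression.

    The retained parameter draws of the chosen scenario are logit-mapped to
    their prior bounds, regression-adjusted on the standardized statistic
    deviations with Epanechnikov weights, back-transformed, and summarized
    by weighted quantiles.  With ``tolerance=1`` and a degenerate design the
    unadjusted (prior) sample is returned with a warning.
    """
    rows = ref.rows_for(scenario)
    if len(rows) < min_rows:
        raise ValidationError(
            f"scenario {scenario}: {len(rows)} rows < required {min_rows}"
        )
    stats = stats or default_fitting_stats(ref.groups)
    X, used = _standardize(rows, observed, stats)
    d = np.sqrt((X**2).sum(axis=1))
    n_keep = max(10, int(np.ceil(tolerance * len(d))))
    keep = np.argsort(d, kind="stable")[:n_keep]
    Xk = X[keep]
    dk = d[keep]
    dmax = dk.max() if dk.max() > 0 else 1.0
    w = 1.0 - (dk / dmax) ** 2
    w = np.maximum(w, 1e-6)
    priors = ref.priors[scenario]
    params = [p for p in ref.param_cols if p in priors]
    out = {}
    adjusted = True
    for p in params:
        lo, hi = priors[p]
        y = _logit_to_bounds(rows[p].to_numpy()[keep], lo, hi)
        A = np.column_stack([np.ones(len(Xk)), Xk])
        Aw = A * np.sqrt(w)[:, None]
        yw = y * np.sqrt(w)
        beta, *_ = np.linalg.lstsq(Aw, yw, rcond=None)
        if not np.all(np.isfinite(beta)):
            warnings.warn(f"singular regression for {p}; returning unadjusted sample")
            adjusted = False
            y_adj = y
        else:
            y_adj = y - Xk @ beta[1:]
        out[p] = _inv_logit_from_bounds(y_adj, lo, hi)
    samples = pd.DataFrame(out)
    quant = pd.DataFrame(
        {
            "q2.5": {p: weighted_quantile(samples[p], 0.025, w) for p in params},
            "median": {p: weighted_quantile(samples[p], 0.5, w) for p in params},
            "q97.5": {p: weighted_quantile(samples[p], 0.975, w) for p in params},
        }
    )
    return ParameterPosterior(samples, w, quant, adjusted)


# ---------------------------------------------------------------------------
# Model checking
# ---------------------------------------------------------------------------

def model_check(
    posterior: ParameterPosterior,
    family: ScenarioFamily,
    observed: pd.Series,
    group_sizes: dict,
    heldout_stats: list,
    fitting_stats: list,
    n_ppc: int = 200,
    n_loci: int = 12,
    mut_priors: dict | None = None,
    allele_range: int = 40,
    seed: int = 0,
) -> pd.Series:
    """Posterior predictive check on held-out summary statistics.

    Simulates ``n_ppc`` datasets from posterior parameter draws and reports,
    per held-out statistic, the two-sided tail probability of the observed
    value in the predictive distribution.  The held-out set must be disjoint
    from the fitting set.
    """
    if n_ppc <= 0:
        raise ValidationError("n_ppc must be positive")
    overlap = set(heldout_stats) & set(fitting_stats)
    if overlap:
        raise ValidationError(f"held-out statistics overlap the fitting set: {sorted(overlap)}")
    rng = np.random.default_rng(seed)
    groups = list(group_sizes)
    gsizes = np.array([group_sizes[g] for g in groups])
    gidx = np.repeat(np.arange(len(groups)), gsizes)
    mut_priors = mut_priors or DEFAULT_MUT_PRIORS
    draws = posterior.samples.sample(
        n=n_ppc, replace=True, weights=posterior.weights,
        random_state=int(rng.integers(1, 2**31 - 1)),
    )
    sims = []
    for _, row in draws.iterrows():
        sc = family.builder(row.to_dict())
        mut = _sample_mutation(rng, mut_priors, allele_range)
        reps = simulate_repeat_counts(sc, mut, n_loci, int(rng.integers(1, 2**31 - 1)))
        sims.append(summary_stats_from_repeats(reps, gidx, len(groups)))
    sim = pd.DataFrame(sims, columns=stat_names(groups))
    out = {}
    for s in heldout_stats:
        vals = sim[s].dropna().to_numpy()
        if len(vals) == 0 or not np.isfinite(observed[s]):
            out[s] = np.nan
            continue
        lo = (1 + (vals <= observed[s]).sum()) / (len(vals) + 1)
        hi = (1 + (vals >= observed[s]).sum()) / (len(vals) + 1)
        out[s] = min(1.0, 2 * min(lo, hi))
    return pd.Series(out)
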
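"""Individual-based clustering and ordination.

The centrepiece is a Bayesian admixture model with correlated allele
frequencies, in the statsmodels idiom: build an :class:`AdmixtureModel`
from a genotype table, call :meth:`~AdmixtureModel.fit` and get an
:class:`AdmixtureResults` carrying posterior mean membership (Q), cluster
allele frequencies (P), the model-evidence estimate ln Pr(X|K) and a
log-likelihood trace.

Model. Each individual i has membership proportions q_i ~ Dirichlet(alpha)
over K clusters; each allele copy picks a cluster of origin z from q_i and
then an allele from that cluster's frequency vector p_kl.  Cluster
frequencies are tied to ancestral frequencies p_Al ~ Dirichlet(lambda)
through the F-model: p_kl ~ Dirichlet(p_Al (1 - F_k) / F_k), so small F_k
means cluster k sits close to the ancestral pool.  alpha, F_k and p_A are
sampled by Metropolis steps; z, q and p by Gibbs.

Also here: the Evanno Delta-K diagnostic over a K scan, greedy label
alignment of replicate runs, and factorial correspondence analysis (FCA)
of allele-count profiles.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.special import gammaln

from hydropop.io import GenotypeTable, ValidationError


# ---------------------------------------------------------------------------
# Admixture model
# ---------------------------------------------------------------------------

class AdmixtureModel:
    """Bayesian admixture clustering of multilocus genotypes.

    Parameters
    ----------
    table : GenotypeTable
    K : int
        Number of clusters.
    lam : float
        Dirichlet parameter of the ancestral allele-frequency prior
        (lambda = 1 is the flat default).
    correlated : bool
        Use the correlated-frequencies F-model (default) or independent
        Dirichlet(lambda) frequencies per cluster.

    Individuals with no scored genotypes at all are excluded with a warning.
    """

    def __init__(self, table: GenotypeTable, K: int, lam: float = 1.0,
                 correlated: bool = True):
        if K < 1:
            raise ValidationError("K must be >= 1")
        self.K = int(K)
        self.lam = float(lam)
        self.correlated = correlated
        # flatten allele copies across loci
        copy_ind, copy_gid = [], []
        offsets = []
        total = 0
        self._locus_sizes = []
        for j in range(table.n_loci):
            codes, sizes = table.locus_codes(j)
            k = len(sizes)
            offsets.append(total)
            self._locus_sizes.append(k)
            if k == 0:
                continue
            flat = codes.reshape(-1)
            rows = np.repeat(np.arange(table.n_individuals), 2)
            ok = flat >= 0
            copy_ind.append(rows[ok])
            copy_gid.append(total + flat[ok])
            total += k
        self._offsets = np.array(offsets)
        self.n_alleles = total
        copy_ind = np.concatenate(copy_ind)
        copy_gid = np.concatenate(copy_gid)
        scored = np.bincount(copy_ind, minlength=table.n_individuals)
        keep = scored > 0
        if not keep.all():
            dropped = [table.individuals[i] for i in np.where(~keep)[0]]
            warnings.warn(f"excluding individuals with no scored genotypes: {dropped}")
            remap = np.cumsum(keep) - 1
            sel = keep[copy_ind]
            copy_ind = remap[copy_ind[sel]]
            copy_gid = copy_gid[sel]
        self.individuals = [ind for ind, m in zip(table.individuals, keep) if m]
        self.populations = table.populations[keep]
        self.n = len(self.individuals)
        self._copy_ind = copy_ind
        self._copy_gid = copy_gid
        # segment boundaries of locus blocks within the flat allele axis
        self._block_starts = np.array(
            [o for o, k in zip(offsets, self._locus_sizes) if k > 0]
        )
        self._block_sizes = np.array([k for k in self._locus_sizes if k > 0])
        self._block_of_allele = np.repeat(
            np.arange(len(self._block_sizes)), self._block_sizes
        )
        self.table = table

    def _normalize_blocks(self, M):
        """Normalize each locus block of a (K, n_alleles) matrix to sum 1."""
        sums = np.add.reduceat(M, self._block_starts, axis=1)
        return M / sums[:, self._block_of_allele]

    def fit(self, iters: int = 20_000, burnin: int = 5_000, seed: int = 0,
            thin: int = 1, alpha0: float = 1.0, f0: float = 0.05) -> "AdmixtureResults":
        """Run the Gibbs sampler and return posterior summaries.

        Desk-scale defaults (20 000 iterations, 5 000 burn-in) are far below
        production STRUCTURE settings but sufficient for strongly structured
        data; both are tunable.  Deterministic given ``seed``.
        """
        if iters <= burnin:
            raise ValidationError("iters must exceed burnin")
        rng = np.random.default_rng(seed)
        K, n, A = self.K, self.n, self.n_alleles
        ci, cg = self._copy_ind, self._copy_gid
        C = len(ci)
        lam = self.lam
        alpha = alpha0
        F = np.full(K, f0)
        PA = self._normalize_blocks(np.ones((1, A)))[0]
        P = np.tile(PA, (K, 1))
        Q = np.full((n, K), 1.0 / K)
        q_sum = np.zeros((n, K))
        p_sum = np.zeros((K, A))
        trace = np.empty(iters)
        n_kept = 0
        log2 = math.log(2)
        for it in range(iters):
            # 1. sample cluster of origin per allele copy
            probs = Q[ci] * P[:, cg].T  # (C, K)
            rowsum = probs.sum(axis=1)
            trace[it] = float(np.log(rowsum).sum())
            if K == 1:
                z = np.zeros(C, dtype=np.int64)
            else:
                u = rng.random(C) * rowsum
                z = (np.cumsum(probs, axis=1) < u[:, None]).sum(axis=1)
                np.clip(z, 0, K - 1, out=z)
            # 2. Q | z
            nik = np.zeros((n, K))
            np.add.at(nik, (ci, z), 1.0)
            G = np.maximum(rng.standard_gamma(alpha + nik), 1e-300)
            Q = G / G.sum(axis=1, keepdims=True)
            # 3. P | z
            m = np.zeros((K, A))
            np.add.at(m, (z, cg), 1.0)
            if self.correlated:
                prior = PA[None, :] * ((1 - F) / F)[:, None]
            else:
                prior = np.full((K, A), lam)
            GP = rng.standard_gamma(m + prior)
            GP = np.maximum(GP, 1e-300)
            P = self._normalize_blocks(GP)
            # 4. alpha (Metropolis, uniform(0, 10) prior)
            if K > 1:
                alpha_new = alpha + rng.normal(0, 0.025)
                if 0 < alpha_new < 10:
                    logq = np.log(Q).sum()
                    dl = n * (
                        gammaln(K * alpha_new) - K * gammaln(alpha_new)
                        - gammaln(K * alpha) + K * gammaln(alpha)
                    ) + (alpha_new - alpha) * logq
                    if math.log(rng.random()) < dl:
                        alpha = alpha_new
            if self.correlated and K >= 1:
                PA, F = self._update_fmodel(rng, P, PA, F, lam)
            if it >= burnin:
                q_sum += Q
                p_sum += P
                n_kept += 1
        post = trace[burnin:]
        ln_p = float(post.mean() - post.var() / 2.0)
        Qm = q_sum / n_kept
        if K == 1:
            Qm = np.ones((n, 1))
        return AdmixtureResults(
            model=self,
            K=K,
            Q=Qm,
            P=p_sum / n_kept,
            ln_p=ln_p,
            trace=trace,
            alpha=alpha,
            seed=seed,
        )

    def _update_fmodel(self, rng, P, PA, F, lam):
        """Metropolis updates of the ancestral frequencies and F_k."""
        K = self.K
        logP = np.log(np.maximum(P, 1e-300))

        def log_prior_blocks(PA_vec, c):
            # per (k, block) log Dirichlet density of P rows given PA, c=(1-F)/F
            a = PA_vec[None, :] * c[:, None]  # (K, A)
            t1 = gammaln(np.add.reduceat(a, self._block_starts, axis=1))
            t2 = np.add.reduceat(gammaln(a), self._block_starts, axis=1)
            t3 = np.add.reduceat((a - 1) * logP, self._block_starts, axis=1)
            return t1 - t2 + t3  # (K, n_blocks)

        c = (1 - F) / F
        cur = log_prior_blocks(PA, c)
        # ancestral frequencies: pairwise mass-transfer within a random block
        for _ in range(max(1, len(self._block_sizes) // 2)):
            b = rng.integers(0, len(self._block_sizes))
            k_b = self._block_sizes[b]
            if k_b < 2:
                continue
            s = self._block_starts[b]
            a1, a2 = rng.choice(k_b, size=2, replace=False) + s
            delta = rng.normal(0, 0.05)
            if not (0 < PA[a1] - delta < 1 and 0 < PA[a2] + delta < 1):
                continue
            PA_new = PA.copy()
            PA_new[a1] -= delta
            PA_new[a2] += delta
            new = log_prior_blocks(PA_new, c)
            # lambda = 1 ancestral prior is flat; proposal symmetric
            dl = new[:, b].sum() - cur[:, b].sum()
            if lam != 1.0:
                dl += (lam - 1) * (
                    math.log(PA_new[a1] / PA[a1]) + math.log(PA_new[a2] / PA[a2])
                )
            if math.log(rng.random()) < dl:
                PA = PA_new
                cur = new
        # F_k random-walk with truncated-normal prior (mean .01, sd .05)
        for k in range(K):
            f_new = F[k] + rng.normal(0, 0.01)
            if not (1e-4 < f_new < 1 - 1e-4):
                continue
            c_new = c.copy()
            c_new[k] = (1 - f_new) / f_new
            new_k = log_prior_blocks(PA, c_new)[k]
            dl = new_k.sum() - cur[k].sum()
            dl += (-((f_new - 0.01) ** 2) + (F[k] - 0.01) ** 2) / (2 * 0.05**2)
            if math.log(rng.random()) < dl:
                F[k] = f_new
                c = c_new
                cur[k] = new_k
        return PA, F


@dataclass
class AdmixtureResults:
    """Posterior summaries of an admixture fit."""

    model: AdmixtureModel
    K: int
    Q: np.ndarray  # (n, K) posterior mean memberships
    P: np.ndarray  # (K, n_alleles) posterior mean cluster frequencies
    ln_p: float  # estimated ln Pr(X | K)
    trace: np.ndarray  # per-iteration log-likelihood
    alpha: float
    seed: int

    def q_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.Q, index=self.model.individuals,
            columns=[f"cluster_{k + 1}" for k in range(self.K)],
        )
        df.insert(0, "population", self.model.populations)
        return df

    def population_q(self) -> pd.DataFrame:
        """Mean membership per population."""
        return self.q_frame().groupby("population", sort=False).mean()

    def summary(self) -> str:
        lines = [
            f"Admixture model fit: K = {self.K}, n = {self.model.n} individuals, "
            f"{self.model.table.n_loci} loci",
            f"ln Pr(X|K) = {self.ln_p:.2f}   alpha = {self.alpha:.3f}",
            "",
            "Mean membership by population:",
            self.population_q().round(3).to_string(),
        ]
        return "\n".join(lines)

    def barplot(self, ax=None, sort_by_population=True):
        """Stacked-bar membership plot (one bar per individual)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(12, 2.5))
        Q = self.Q
        order = np.argsort(self.model.populations, kind="stable") if sort_by_population \
            else np.arange(len(Q))
        bottom = np.zeros(len(Q))
        for k in range(self.K):
            ax.bar(np.arange(len(Q)), Q[order, k], bottom=bottom, width=1.0)
            bottom += Q[order, k]
        ax.set_xlim(-0.5, len(Q) - 0.5)
        ax.set_ylim(0, 1)
        ax.set_ylabel("membership")
        return ax


def admixture_gibbs(table, K, iters=20_000, burnin=5_000, lam=1.0, seed=0,
                    **kw) -> AdmixtureResults:
    """Functional wrapper: fit the admixture model once."""
    return AdmixtureModel(table, K, lam=lam).fit(iters=iters, burnin=burnin,
                                                 seed=seed, **kw)


# ---------------------------------------------------------------------------
# K selection (Evanno Delta-K)
# ---------------------------------------------------------------------------

@dataclass
class DeltaKSeries:
    ks: list
    ln_p: np.ndarray  # (n_K, n_replicates)
    mean: np.ndarray
    sd: np.ndarray
    delta_k: dict  # interior K -> Delta K (may be inf when SD == 0)

    def best_k(self):
        finite = {k: v for k, v in self.delta_k.items()}
        return max(finite, key=finite.get) if finite else None

    def to_frame(self):
        df = pd.DataFrame({"K": self.ks, "mean_lnP": self.mean, "sd_lnP": self.sd})
        df["delta_K"] = [self.delta_k.get(k, np.nan) for k in self.ks]
        return df


def delta_k_from_lnp(ks, ln_p: np.ndarray) -> DeltaKSeries:
    """Evanno Delta-K from a (n_K, n_replicates) matrix of ln Pr(X|K).

    ``Delta K = mean_r |lnP_r(K+1) - 2 lnP_r(K) + lnP_r(K-1)| / SD(lnP(K))``;
    undefined at the boundary K values; infinite (flagged) when the
    replicate SD is zero.
    """
    ks = list(ks)
    ln_p = np.asarray(ln_p, dtype=float)
    if ln_p.ndim != 2 or ln_p.shape[0] != len(ks):
        raise ValidationError("ln_p must be (n_K, n_replicates)")
    if ln_p.shape[1] < 2:
        raise ValidationError("Delta-K needs >= 2 replicates (SD undefined)")
    if ks != sorted(ks) or any(b - a != 1 for a, b in zip(ks, ks[1:])):
        raise ValidationError("K values must be contiguous and increasing")
    mean = ln_p.mean(axis=1)
    sd = ln_p.std(axis=1, ddof=1)
    delta = {}
    for i in range(1, len(ks) - 1):
        second = np.abs(ln_p[i + 1] - 2 * ln_p[i] + ln_p[i - 1]).mean()
        delta[ks[i]] = float(second / sd[i]) if sd[i] > 0 else float("inf")
    return DeltaKSeries(ks, ln_p, mean, sd, delta)


def scan_k(table, ks, replicates: int = 3, iters: int = 20_000,
           burnin: int = 5_000, seed: int = 0, **fit_kw) -> DeltaKSeries:
    """Fit the admixture model over a contiguous K range with replicates."""
    rng = np.random.default_rng(seed)
    ln_p = np.empty((len(ks), replicates))
    for i, K in enumerate(ks):
        for r in range(replicates):
            res = AdmixtureModel(table, K).fit(
                iters=iters, burnin=burnin,
                seed=int(rng.integers(1, 2**31 - 1)), **fit_kw,
            )
            ln_p[i, r] = res.ln_p
    return delta_k_from_lnp(list(ks), ln_p)


# ---------------------------------------------------------------------------
# Replicate-run label alignment (greedy, CLUMPP-style)
# ---------------------------------------------------------------------------

def _best_permutation(ref: np.ndarray, q: np.ndarray):
    """Column permutation of ``q`` minimizing Frobenius distance to ``ref``
    (solved exactly as an assignment problem)."""
    K = ref.shape[1]
    cost = np.zeros((K, K))
    for a in range(K):
        for b in range(K):
            cost[a, b] = ((ref[:, a] - q[:, b]) ** 2).sum()
    _, cols = linear_sum_assignment(cost)
    return cols


def similarity_g(q1: np.ndarray, q2: np.ndarray) -> float:
    """CLUMPP's pairwise similarity: 1 - ||Q1 - Q2||_F / sqrt(2 n)."""
    n = q1.shape[0]
    return 1.0 - float(np.linalg.norm(q1 - q2) / math.sqrt(2 * n))

def align_runs(runs):
    """Align cluster labels across replicate Q matrices and average.

    Runs are processed greedily: each run after the first is permuted to
    best match the running average (exact assignment solution per run).
    Returns (mean_Q, aligned_runs, permutations).
    """
    runs = [np.asarray(r, dtype=float) for r in runs]
    shapes = {r.shape for r in runs}
    if len(shapes) != 1:
        raise ValidationError("runs must share individuals and K")
    aligned = [runs[0]]
    perms = [np.arange(runs[0].shape[1])]
    running = runs[0].copy()
    for r, q in enumerate(runs[1:], start=2):
        perm = _best_permutation(running / (r - 1), q)
        qa = q[:, perm]
        aligned.append(qa)
        perms.append(perm)
        running += qa
    mean_q = running / len(runs)
    return mean_q, aligned, perms


# ---------------------------------------------------------------------------
# Factorial correspondence analysis
# ---------------------------------------------------------------------------

@dataclass
class FcaResult:
    coords: pd.DataFrame  # individual coordinates on leading axes
    centroids: pd.DataFrame  # population centroids
    inertia: np.ndarray  # explained inertia fraction per axis


def fca(table: GenotypeTable, n_axes: int = 2) -> FcaResult:
    """Factorial correspondence analysis of allele-count profiles.

    Individuals are coded 0/1/2 per allele column (missing genotypes
    mean-imputed per column); correspondence analysis is the SVD of the
    standardized profile matrix under the chi-square metric.  Duplicate
    genotypes map to identical coordinates.
    """
    cols = []
    poly = 0
    for j in range(table.n_loci):
        codes, sizes = table.locus_codes(j)
        k = len(sizes)
        if k < 2:
            continue
        poly += 1
        X = np.zeros((table.n_individuals, k))
        rows = np.repeat(np.arange(table.n_individuals), 2)
        flat = codes.reshape(-1)
        ok = flat >= 0
        np.add.at(X, (rows[ok], flat[ok]), 1.0)
        scored = codes[:, 0] >= 0
        if (~scored).any() and scored.any():
            X[~scored] = X[scored].mean(axis=0)
        cols.append(X)
    if poly < 2:
        raise ValidationError("FCA needs >= 2 polymorphic loci")
    X = np.concatenate(cols, axis=1)
    total = X.sum()
    N = X / total
    r = N.sum(axis=1)
    c = N.sum(axis=0)
    keep = c > 0
    N = N[:, keep]
    c = c[keep]
    S = (N - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    U, sv, Vt = np.linalg.svd(S, full_matrices=False)
    # drop numerically-zero axes
    nz = sv > 1e-12
    U, sv = U[:, nz], sv[nz]
    coords = (U * sv) / np.sqrt(r)[:, None]
    n_axes = min(n_axes, coords.shape[1])
    frame = pd.DataFrame(
        coords[:, :n_axes],
        index=table.individuals,
        columns=[f"axis_{i + 1}" for i in range(n_axes)],
    )
    frame.insert(0, "population", table.populations)
    cents = frame.groupby("population", sort=False).mean()
    inertia = sv**2 / (sv**2).sum()
    return FcaResult(frame, cents, inertia[:n_axes])
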
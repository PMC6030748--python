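"""Within-population genetic variability.

Observed and (Nei-unbiased) expected heterozygosity, rarefaction allelic
richness, exact Hardy-Weinberg tests on the Levene conditional distribution
(full enumeration or Markov-chain estimation), and EM maximum-likelihood
estimation of null-allele frequencies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from hydropop.io import MISSING, GenotypeTable, ValidationError

#: default rarefaction size: 18 genes = 9 diploid individuals
DEFAULT_RAREFACTION_GENES = 18


def heterozygosity(table: GenotypeTable, population: str):
    """Per-locus observed and expected heterozygosity for one population.

    ``Ho`` is the fraction of genotyped individuals that are heterozygous;
    ``He`` is Nei's unbiased gene diversity
    ``(2n / (2n - 1)) * (1 - sum p_a^2)``.  Loci with no genotyped
    individuals are reported as NaN.

    Returns
    -------
    DataFrame indexed by locus with columns n, A, Ho, He.
    """
    mask = table.pop_mask(population)
    rows = []
    for j, loc in enumerate(table.loci):
        g = table.calls[mask, j, :]
        genotyped = g[:, 0] != MISSING
        n = int(genotyped.sum())
        if n == 0:
            rows.append((loc.name, 0, 0, np.nan, np.nan))
            continue
        gg = g[genotyped]
        ho = float((gg[:, 0] != gg[:, 1]).mean())
        _, counts = np.unique(gg, return_counts=True)
        p = counts / counts.sum()
        he = (2 * n / (2 * n - 1)) * (1 - float((p**2).sum()))
        rows.append((loc.name, n, len(counts), ho, he))
    return pd.DataFrame(rows, columns=["locus", "n", "A", "Ho", "He"]).set_index("locus")


def rarefaction_richness(counts, g: int) -> float:
    """Expected allele count in a random subsample of ``g`` genes.

    ``AR = sum_a [1 - C(2n - c_a, g) / C(2n, g)]`` with ``c_a`` the observed
    allele counts (hypergeometric rarefaction).
    """
    counts = np.asarray(counts, dtype=np.int64)
    N = int(counts.sum())
    if N < g:
        return np.nan

    def log_choose(n, k):
        return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

    terms = np.where(
        N - counts >= g,
        np.exp(log_choose(N - counts, g) - log_choose(N, g)),
        0.0,
    )
    return float(np.sum(1.0 - terms))


def allelic_richness(table: GenotypeTable, population: str, g: int = DEFAULT_RAREFACTION_GENES):
    """Per-locus rarefaction allelic richness at ``g`` genes.

    Loci where fewer than ``g`` genes were scored are NaN (flagged
    undefined, not zero).
    """
    mask = table.pop_mask(population)
    out = {}
    for j, loc in enumerate(table.loci):
        _, counts = table.allele_counts(j, population)
        out[loc.name] = rarefaction_richness(counts, g) if counts.size else np.nan
    return pd.Series(out, name=f"AR_{g}")


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test (Levene conditional distribution)
# ---------------------------------------------------------------------------

def genotype_counts_from_table(table: GenotypeTable, population: str, j: int) -> dict:
    """Observed genotype counts {(a, b): n_ab} (a <= b, allele sizes)."""
    mask = table.pop_mask(population)
    g = table.calls[mask, j, :]
    g = g[g[:, 0] != MISSING]
    g = np.sort(g, axis=1)
    counts = {}
    for a, b in g:
        counts[(int(a), int(b))] = counts.get((int(a), int(b)), 0) + 1
    return counts


@dataclass
class HweResult:
    p_value: float
    se: float | None  # None for exact enumeration
    method: str  # "enumeration" | "mcmc" | "no_test"

    def __float__(self):
        return self.p_value


def hwe_exact_test(
    genotype_counts: dict,
    method: str = "auto",
    n_burn: int = 10_000,
    n_batches: int = 100,
    batch_size: int = 5_000,
    seed: int = 0,
) -> HweResult:
    """Exact probability test of Hardy-Weinberg proportions.

    Conditions on the observed allele counts (Levene's distribution); the
    p-value sums the probabilities of all genotypic configurations no more
    probable than the observed one.  Full enumeration is used for up to 3
    alleles and n <= 100; otherwise a Markov-chain (genotype-switching)
    estimate is returned with its standard error.

    Parameters
    ----------
    genotype_counts
        ``{(a, b): count}`` with ``a <= b`` allele labels.
    """
    alleles = sorted({x for pair in genotype_counts for x in pair})
    k = len(alleles)
    n = sum(genotype_counts.values())
    if k < 2:
        return HweResult(1.0, None, "no_test")
    idx = {a: i for i, a in enumerate(alleles)}
    obs = np.zeros((k, k), dtype=np.int64)
    for (a, b), c in genotype_counts.items():
        obs[idx[a], idx[b]] += c
    allele_counts = np.zeros(k, dtype=np.int64)
    for i in range(k):
        for j2 in range(i, k):
            allele_counts[i] += obs[i, j2]
            allele_counts[j2] += obs[i, j2]
    if method == "auto":
        method = "enumeration" if (k <= 3 and n <= 100) else "mcmc"
    log_obs = _config_log_prob(obs, allele_counts, n)
    if method == "enumeration":
        p = _hwe_enumerate(allele_counts, n, log_obs)
        return HweResult(p, None, "enumeration")
    p, se = _hwe_mcmc(obs, log_obs, n_burn, n_batches, batch_size, seed)
    return HweResult(p, se, "mcmc")


def _config_log_prob(mat, allele_counts, n):
    """Levene log-probability of a genotype configuration (upper-tri matrix)."""
    het = int(np.triu(mat, 1).sum())
    log_geno_fact = float(gammaln(mat[np.triu_indices_from(mat)] + 1).sum())
    const = (
        gammaln(n + 1)
        + float(gammaln(allele_counts + 1).sum())
        - gammaln(2 * n + 1)
    )
    return const + het * math.log(2) - log_geno_fact


def _hwe_enumerate(allele_counts, n, log_obs, tol=1e-12):
    """Sum Levene probabilities over all configurations with the given
    allele counts, accumulating those with Pr <= Pr(observed)."""
    k = len(allele_counts)
    p_le = 0.0
    total = 0.0
    mat = np.zeros((k, k), dtype=np.int64)
    # enumerate heterozygote cells of the strict upper triangle; homozygote
    # counts are then determined by the residual allele copies (must be even)
    cells = [(i, j) for i in range(k) for j in range(i + 1, k)]

    def close(remaining):
        nonlocal p_le, total
        if np.any(remaining < 0) or np.any(remaining % 2):
            return
        for r in range(k):
            mat[r, r] = remaining[r] // 2
        lp = _config_log_prob(mat, allele_counts, n)
        pr = math.exp(lp)
        total += pr
        if lp <= log_obs + tol:
            p_le += pr

    def go(ci, remaining):
        if ci == len(cells):
            close(remaining)
            return
        i, j = cells[ci]
        hi = min(remaining[i], remaining[j])
        for h in range(hi + 1):
            mat[i, j] = h
            new_rem = remaining.copy()
            new_rem[i] -= h
            new_rem[j] -= h
            go(ci + 1, new_rem)
        mat[i, j] = 0

    go(0, allele_counts.copy())
    # guard against numeric drift: probabilities must sum to ~1
    return min(1.0, p_le / total)


def _hwe_mcmc(obs, log_obs, n_burn, n_batches, batch_size, seed):
    """Genotype-switching Markov chain (Guo & Thompson style).

    A step picks two genotypes and swaps allele partners; the chain is
    reversible with respect to the Levene distribution.  The p-value is the
    stationary fraction of states with log-probability <= observed, with a
    batch-means standard error.
    """
    rng = np.random.default_rng(seed)
    k = obs.shape[0]
    mat = obs.copy()
    n = int(obs.sum())
    # The Levene distribution is the push-forward of the uniform distribution
    # over perfect matchings of the 2n allele copies, so a symmetric re-pairing
    # move (pick two genotypes, swap partners) is always accepted and needs no
    # Metropolis correction; the log-probability is tracked incrementally.
    genotypes = []
    for i in range(k):
        for j in range(i, k):
            genotypes.extend([(i, j)] * int(mat[i, j]))
    log_cur = log_obs
    tol = 1e-12

    def delta_remove(i, j):
        # removing one genotype: the -log(n_ab!) term gains +log(n_ab)
        d = math.log(mat[i, j])
        if i != j:
            d -= math.log(2)
        return d

    def delta_add(i, j):
        d = -math.log(mat[i, j] + 1)
        if i != j:
            d += math.log(2)
        return d

    batch_means = []
    count_in_batch = 0
    below_in_batch = 0
    total_steps = n_burn + n_batches * batch_size
    pair_idx = rng.integers(0, n, size=(total_steps, 2))
    coin = rng.random(total_steps)
    for step in range(total_steps):
        i1, i2 = pair_idx[step]
        if i1 != i2:
            (a, b), (c, d) = genotypes[i1], genotypes[i2]
            if coin[step] < 0.5:
                new1, new2 = tuple(sorted((a, d))), tuple(sorted((c, b)))
            else:
                new1, new2 = tuple(sorted((a, c))), tuple(sorted((b, d)))
            old1, old2 = (a, b), (c, d)
            if (new1, new2) != (old1, old2) and (new1, new2) != (old2, old1):
                dl = delta_remove(*old1)
                mat[old1] -= 1
                dl += delta_remove(*old2)
                mat[old2] -= 1
                dl += delta_add(*new1)
                mat[new1] += 1
                dl += delta_add(*new2)
                mat[new2] += 1
                log_cur += dl
                genotypes[i1], genotypes[i2] = new1, new2
        if step >= n_burn:
            below_in_batch += log_cur <= log_obs + tol
            count_in_batch += 1
            if count_in_batch == batch_size:
                batch_means.append(below_in_batch / batch_size)
                below_in_batch = 0
                count_in_batch = 0
    bm = np.array(batch_means)
    p = float(bm.mean())
    se = float(bm.std(ddof=1) / math.sqrt(len(bm))) if len(bm) > 1 else float("nan")
    return p, se


def hwe_test_population(table: GenotypeTable, population: str, j: int,
                        seed: int = 0, **kw) -> HweResult:
    counts = genotype_counts_from_table(table, population, j)
    return hwe_exact_test(counts, seed=seed, **kw)


# ---------------------------------------------------------------------------
# Null-allele EM estimation
# ---------------------------------------------------------------------------

def estimate_null_alleles(
    table: GenotypeTable,
    population: str,
    locus,
    tol: float = 1e-8,
    max_iter: int = 10_000,
    count_missing_as_null: bool = False,
) -> float:
    """EM maximum-likelihood estimate of the null-allele frequency.

    Assumes Hardy-Weinberg proportions with one non-amplifying allele:
    apparent homozygotes for allele ``a`` are a mixture of true ``a/a``
    homozygotes and ``a/null`` heterozygotes (Dempster-style EM, as in
    FreeNA's estimator).  Missing genotypes may optionally be treated as
    null/null homozygotes.
    """
    if isinstance(locus, str):
        j = table.locus_names.index(locus)
    else:
        j = locus
    mask = table.pop_mask(population)
    g = table.calls[mask, j, :]
    genotyped = g[:, 0] != MISSING
    n_missing = int((~genotyped).sum())
    gg = np.sort(g[genotyped], axis=1)
    if len(gg) < 5:
        raise ValidationError("need >= 5 genotyped individuals for null-allele EM")
    sizes = np.unique(gg)
    k = len(sizes)
    code = {int(s): i for i, s in enumerate(sizes)}
    hom_counts = np.zeros(k)
    het_counts = np.zeros(k)  # allele copies in unambiguous heterozygotes
    n_het = 0
    for a, b in gg:
        if a == b:
            hom_counts[code[int(a)]] += 1
        else:
            het_counts[code[int(a)]] += 1
            het_counts[code[int(b)]] += 1
            n_het += 1
    n_obs = len(gg)
    n_tot = n_obs + (n_missing if count_missing_as_null else 0)
    het_pairs = {}
    for a, b in gg:
        if a != b:
            key = (code[int(a)], code[int(b)])
            het_pairs[key] = het_pairs.get(key, 0) + 1

    def _finish(p_hat, f_hat):
        # EM converges sublinearly on the boundary f = 0; if the boundary
        # fits at least as well as the interior iterate, the MLE is 0
        copies0 = het_counts + 2 * hom_counts
        p0 = copies0 / copies0.sum()
        ll0 = null_allele_loglik(hom_counts, het_pairs, n_missing, p0, 0.0,
                                 count_missing_as_null=False)
        ll_hat = null_allele_loglik(hom_counts, het_pairs, n_missing, p_hat, f_hat,
                                    count_missing_as_null=False)
        # condition on the genotype being visible (null/null unobserved)
        ll_hat -= n_obs * math.log(max(1.0 - f_hat**2, 1e-12))
        if not count_missing_as_null and ll0 >= ll_hat - 1e-12:
            return 0.0
        return float(f_hat)

    # initialize
    p = np.full(k, (1 - 0.05) / k)
    f = 0.05
    for _ in range(max_iter):
        # E-step: split apparent homozygotes into true hom vs a/null
        denom = p**2 + 2 * p * f
        with np.errstate(invalid="ignore", divide="ignore"):
            w_null = np.where(denom > 0, (2 * p * f) / denom, 0.0)
        exp_null_from_hom = hom_counts * w_null
        # expected allele copy counts
        copies = het_counts + 2 * hom_counts * (1 - w_null) + exp_null_from_hom
        null_copies = exp_null_from_hom.sum()
        if count_missing_as_null:
            null_copies += 2 * n_missing
        total = copies.sum() + null_copies
        p_new = copies / total
        f_new = null_copies / total
        if abs(f_new - f) + np.abs(p_new - p).sum() < tol:
            return _finish(p_new, f_new)
        p, f = p_new, f_new
    raise ValidationError(
        f"null-allele EM did not converge in {max_iter} iterations (last f={f:.6g})"
    )


def null_allele_loglik(hom_counts, het_counts_pairs, n_missing, p, f,
                       count_missing_as_null=False):
    """Multinomial log-likelihood of apparent genotype classes given visible
    frequencies ``p`` and null frequency ``f`` (grid-search oracle helper)."""
    p = np.asarray(p, dtype=float)
    ll = 0.0
    for i, c in enumerate(hom_counts):
        if c:
            ll += c * math.log(p[i] ** 2 + 2 * p[i] * f)
    for (i, j2), c in het_counts_pairs.items():
        if c:
            ll += c * math.log(2 * p[i] * p[j2])
    if count_missing_as_null and n_missing:
        ll += n_missing * math.log(f**2)
    return ll


# ---------------------------------------------------------------------------
# Report
# ---------------------------------------------------------------------------

def diversity_table(
    table: GenotypeTable,
    g: int = DEFAULT_RAREFACTION_GENES,
    estimate_nulls: bool = True,
) -> pd.DataFrame:
    """Per-(population, locus) diversity report: n, A, Ho, He, AR_g, null_hat."""
    frames = []
    for pop in table.population_labels():
        het = heterozygosity(table, pop)
        ar = allelic_richness(table, pop, g)
        het[f"AR_{g}"] = ar
        nulls = []
        for j, loc in enumerate(table.loci):
            if not estimate_nulls or het.loc[loc.name, "n"] < 5 or het.loc[loc.name, "A"] < 2:
                nulls.append(np.nan)
                continue
            try:
                nulls.append(estimate_null_alleles(table, pop, j))
            except ValidationError:
                nulls.append(np.nan)
        het["null_hat"] = nulls
        het.insert(0, "population", pop)
        frames.append(het.reset_index())
    return pd.concat(frames, ignore_index=True)
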
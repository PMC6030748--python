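"""Between-population differentiation.

Weir-Cockerham theta (F_ST) with individual-permutation tests, the
allele-size analogue R_ST with the allele-size permutation (pR_ST) test,
three-level AMOVA with the among-group fixation index F_CT, and isolation
by distance (F_ST / (1 - F_ST) against ln distance, Mantel tests).

Variance components are reported as-is, so slightly negative estimates are
possible for undifferentiated pairs; permutation p-values use the add-one
convention (never exactly zero).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from hydropop.io import MISSING, GenotypeTable, GroupingScheme, ValidationError


# ---------------------------------------------------------------------------
# per-locus individual-level encodings (shared by F_ST and permutation tests)
# ---------------------------------------------------------------------------

def _locus_profiles(table: GenotypeTable, j: int, mask=None):
    """Per-individual allele-copy counts X (n, k), single-copy (heterozygote
    carrier) indicators Y (n, k) and genotyped flags g (n,) at locus j."""
    codes, sizes = table.locus_codes(j, mask=mask)
    n = codes.shape[0]
    k = len(sizes)
    X = np.zeros((n, k))
    Y = np.zeros((n, k))
    g = codes[:, 0] >= 0
    if k:
        rows = np.repeat(np.arange(n), 2)
        flat = codes.reshape(-1)
        ok = flat >= 0
        np.add.at(X, (rows[ok], flat[ok]), 1.0)
        Y = (X == 1).astype(float)
    return X, Y, g, sizes


def _wc_pair_components(n1, n2, C1, C2, H1, H2):
    """Weir-Cockerham a, b, c sums over alleles for two samples.

    All arguments broadcast; ``C``/``H`` carry the allele axis last.
    Returns (sum_a, sum_abc) with the allele axis reduced.
    """
    n1 = np.asarray(n1, dtype=float)[..., None]
    n2 = np.asarray(n2, dtype=float)[..., None]
    nbar = (n1 + n2) / 2.0
    nc = n1 + n2 - (n1**2 + n2**2) / (n1 + n2)
    with np.errstate(invalid="ignore", divide="ignore"):
        p1 = C1 / (2 * n1)
        p2 = C2 / (2 * n2)
        pbar = (C1 + C2) / (2 * (n1 + n2))
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / nbar
        hbar = (H1 + H2) / (n1 + n2)
        inner = pbar * (1 - pbar) - s2 / 2.0 - hbar / 4.0
        a = (nbar / nc) * (s2 - inner / (nbar - 1))
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - s2 / 2.0 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2.0
    valid = (n1 > 1) & (n2 > 1) & (nbar > 1)
    tot = np.where(valid, a + b + c, np.nan)
    a = np.where(valid, a, np.nan)
    return np.nansum(a, axis=-1), np.nansum(tot, axis=-1)


def pairwise_fst(table: GenotypeTable, pop_a: str, pop_b: str) -> float:
    """Multi-locus Weir-Cockerham theta between two populations.

    The ratio of summed among-population variance components to summed total
    components over loci and alleles; missing genotypes are excluded per
    locus.  Undefined (NaN) when no shared polymorphic locus exists.
    """
    mask = table.pop_mask([pop_a, pop_b])
    sub_pops = table.populations[mask]
    in_a = sub_pops == pop_a
    num = den = 0.0
    any_locus = False
    for j in range(table.n_loci):
        X, Y, g, sizes = _locus_profiles(table, j, mask=mask)
        if len(sizes) < 2:
            continue
        n1 = float((g & in_a).sum())
        n2 = float((g & ~in_a).sum())
        if n1 < 2 or n2 < 2:
            continue
        C1 = X[in_a].sum(axis=0)
        C2 = X[~in_a].sum(axis=0)
        H1 = Y[in_a].sum(axis=0)
        H2 = Y[~in_a].sum(axis=0)
        sa, st = _wc_pair_components(n1, n2, C1, C2, H1, H2)
        num += sa
        den += st
        any_locus = True
    if not any_locus or den == 0:
        return np.nan
    return float(num / den)


def fst_permutation_test(
    table: GenotypeTable, pop_a: str, pop_b: str, n_perm: int = 1000, seed: int = 0
) -> tuple[float, float]:
    """Permutation test of theta > 0 between two populations.

    Individuals are shuffled between the two samples holding sample sizes;
    ``p = (1 + #{theta_perm >= theta_obs}) / (n_perm + 1)``.

    Returns (theta_obs, p).
    """
    rng = np.random.default_rng(seed)
    mask = table.pop_mask([pop_a, pop_b])
    sub_pops = table.populations[mask]
    in_a = sub_pops == pop_a
    n = int(mask.sum())
    n_a = int(in_a.sum())
    # permutation membership matrices (n_perm + 1, n); row 0 = observed
    M = np.zeros((n_perm + 1, n))
    M[0, in_a] = 1.0
    for r in range(1, n_perm + 1):
        M[r, rng.permutation(n)[:n_a]] = 1.0
    num = np.zeros(n_perm + 1)
    den = np.zeros(n_perm + 1)
    for j in range(table.n_loci):
        X, Y, g, sizes = _locus_profiles(table, j, mask=mask)
        if len(sizes) < 2:
            continue
        gf = g.astype(float)
        n1 = M @ gf
        n2 = gf.sum() - n1
        ok = (n1 >= 2) & (n2 >= 2)
        C1 = M @ X
        C2 = X.sum(axis=0) - C1
        H1 = M @ Y
        H2 = Y.sum(axis=0) - H1
        sa, st = _wc_pair_components(n1, n2, C1, C2, H1, H2)
        num[ok] += sa[ok]
        den[ok] += st[ok]
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = num / den
    obs = theta[0]
    perm = theta[1:]
    perm = perm[np.isfinite(perm)]
    p = (1.0 + float((perm >= obs).sum())) / (len(perm) + 1.0)
    return float(obs), p


def fst_matrix(table: GenotypeTable, populations=None, n_perm: int = 0, seed: int = 0):
    """Pairwise theta matrix (and permutation p-values when n_perm > 0)."""
    pops = populations or table.population_labels()
    k = len(pops)
    vals = np.zeros((k, k))
    pvals = np.full((k, k), np.nan)
    rng = np.random.default_rng(seed)
    for i in range(k):
        for j in range(i + 1, k):
            if n_perm:
                th, p = fst_permutation_test(
                    table, pops[i], pops[j], n_perm=n_perm,
                    seed=int(rng.integers(1, 2**31 - 1)),
                )
                pvals[i, j] = pvals[j, i] = p
            else:
                th = pairwise_fst(table, pops[i], pops[j])
            vals[i, j] = vals[j, i] = th
    v = pd.DataFrame(vals, index=pops, columns=pops)
    p = pd.DataFrame(pvals, index=pops, columns=pops)
    return (v, p) if n_perm else v


# ---------------------------------------------------------------------------
# R_ST and the allele-size permutation test
# ---------------------------------------------------------------------------

def _rst_components_from_counts(counts, sizes2n, size_values):
    """ANOVA variance components on allele sizes from per-population allele
    counts.

    Parameters
    ----------
    counts : (r, k) per-population allele-copy counts at one locus
    sizes2n : (r,) gene copies per population (2 * genotyped individuals)
    size_values : (..., k) allele sizes in repeat units (leading axes allow
        permuted size vectors)

    Returns (sigma2_between, sigma2_within) broadcast over leading axes.
    """
    counts = np.asarray(counts, dtype=float)
    N = sizes2n.sum()
    r = (sizes2n > 0).sum()
    if r < 2 or N <= r:
        return np.nan, np.nan
    sv = np.asarray(size_values, dtype=float)
    totals = counts.sum(axis=0)  # (k,)
    gm = (sv @ totals) / N  # grand mean, (...,)
    means = (sv @ counts.T) / np.where(sizes2n > 0, sizes2n, 1)  # (..., r)
    ssb = ((means - gm[..., None]) ** 2 * sizes2n).sum(axis=-1)
    # SSW = sum(c * s^2) per pop - 2n_i * mean_i^2
    sq = (sv**2) @ counts.T  # (..., r)
    ssw = (sq - sizes2n * means**2).sum(axis=-1)
    msb = ssb / (r - 1)
    msw = ssw / (N - r)
    n0 = (N - (sizes2n**2).sum() / N) / (r - 1)
    s2b = (msb - msw) / n0
    return s2b, msw


def _locus_count_matrix(table, j, pops):
    codes, sizes = table.locus_codes(j)
    k = len(sizes)
    r = len(pops)
    counts = np.zeros((r, k))
    n2 = np.zeros(r)
    for i, p in enumerate(pops):
        pm = table.populations == p
        c = codes[pm]
        c = c[c >= 0]
        if k:
            counts[i] = np.bincount(c, minlength=k)
        n2[i] = len(c)
    return counts, n2, sizes


def pairwise_rst(table: GenotypeTable, pop_a: str, pop_b: str) -> float:
    """Multi-locus R_ST between two populations (allele sizes in repeat
    units; variance components pooled across loci by summation)."""
    return rst(table, [pop_a, pop_b])


def rst(table: GenotypeTable, populations=None) -> float:
    """Multi-locus R_ST over a set of populations."""
    pops = populations or table.population_labels()
    num = den = 0.0
    ok = False
    for j in range(table.n_loci):
        counts, n2, sizes = _locus_count_matrix(table, j, pops)
        if len(sizes) < 2:
            continue
        units = table.repeat_units(j, sizes).astype(float)
        s2b, s2w = _rst_components_from_counts(counts, n2, units)
        if np.isnan(s2b):
            continue
        num += s2b
        den += s2b + s2w
        ok = True
    if not ok or den == 0:
        return np.nan
    return float(num / den)


@dataclass
class RstTestResult:
    """Outcome of the allele-size permutation (pR_ST) test."""

    rst_obs: float
    prst_mean: float
    prst_ci: tuple  # (2.5%, 97.5%)
    p_value: float  # one-sided, R_ST > pR_ST
    n_perm: int

    def significant(self, alpha=0.05):
        return self.p_value < alpha


def allele_size_permutation_test(
    table: GenotypeTable, populations=None, n_perm: int = 9000, seed: int = 0
) -> RstTestResult:
    """Test whether stepwise mutations contribute to differentiation.

    Allele sizes are permuted among allelic states within each locus
    (allelic identities and their counts are kept; only the size labels
    move), R_ST is recomputed per permutation, and the observed R_ST is
    compared against this null (pR_ST) distribution.  A significant excess
    of R_ST over pR_ST indicates mutation (hence older divergence)
    contributes beyond drift; under pure drift R_ST is an F_ST analogue.
    """
    pops = populations or table.population_labels()
    if len(pops) < 2:
        raise ValidationError("need >= 2 populations")
    rng = np.random.default_rng(seed)
    num = np.zeros(n_perm + 1)
    den = np.zeros(n_perm + 1)
    for j in range(table.n_loci):
        counts, n2, sizes = _locus_count_matrix(table, j, pops)
        k = len(sizes)
        if k < 2:
            continue
        units = table.repeat_units(j, sizes).astype(float)
        # row 0: observed order; rows 1..: permuted size vectors
        S = np.empty((n_perm + 1, k))
        S[0] = units
        for r in range(1, n_perm + 1):
            S[r] = units[rng.permutation(k)]
        s2b, s2w = _rst_components_from_counts(counts, n2, S)
        if np.ndim(s2b) == 0 and np.isnan(s2b):
            continue
        num += s2b
        den += s2b + s2w
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = num / den
    obs = float(vals[0])
    null = vals[1:]
    null = null[np.isfinite(null)]
    p = (1.0 + float((null >= obs).sum())) / (len(null) + 1.0)
    lo, hi = np.percentile(null, [2.5, 97.5])
    return RstTestResult(obs, float(null.mean()), (float(lo), float(hi)), p, len(null))


def rst_pairwise_tests(table, populations=None, n_perm=9000, seed=0):
    """Pairwise allele-size permutation tests over all population pairs."""
    pops = populations or table.population_labels()
    rng = np.random.default_rng(seed)
    out = {}
    for i in range(len(pops)):
        for j in range(i + 1, len(pops)):
            out[(pops[i], pops[j])] = allele_size_permutation_test(
                table, [pops[i], pops[j]], n_perm=n_perm,
                seed=int(rng.integers(1, 2**31 - 1)),
            )
    return out


# ---------------------------------------------------------------------------
# AMOVA
# ---------------------------------------------------------------------------

@dataclass
class AmovaResult:
    """Three-level AMOVA decomposition.

    Variance components: among groups (``sigma_a``), among populations
    within groups (``sigma_b``), within populations (``sigma_c``); fixation
    indices F_CT = sigma_a / total, F_SC = sigma_b / (sigma_b + sigma_c),
    F_ST = (sigma_a + sigma_b) / total.
    """

    sigma_a: float
    sigma_b: float
    sigma_c: float
    f_ct: float
    f_sc: float
    f_st: float
    p_fct: float | None = None
    n_perm: int = 0
    groups: dict = field(default_factory=dict)

    @property
    def total(self):
        return self.sigma_a + self.sigma_b + self.sigma_c

    def summary(self) -> pd.DataFrame:
        tot = self.total if self.total else np.nan
        return pd.DataFrame(
            {
                "variance": [self.sigma_a, self.sigma_b, self.sigma_c, self.total],
                "pct_total": [
                    100 * self.sigma_a / tot,
                    100 * self.sigma_b / tot,
                    100 * self.sigma_c / tot,
                    100.0,
                ],
            },
            index=[
                "among groups",
                "among populations within groups",
                "within populations",
                "total",
            ],
        )


class Amova:
    """Hierarchical analysis of molecular variance (model object).

    Allele copies are the units; the distance metric is 0/1 (different
    allele or not), which makes the decomposition a function of allele
    counts only.  ``fit`` assesses the among-group index F_CT by permuting
    whole populations among groups.

    Parameters
    ----------
    table : GenotypeTable
    grouping : GroupingScheme or dict
        Population -> group mapping (only populations present in the table
        and mapped to a group enter the analysis).
    """

    def __init__(self, table: GenotypeTable, grouping):
        group_of = grouping.group_of if isinstance(grouping, GroupingScheme) else dict(grouping)
        pops = [p for p in table.population_labels() if p in group_of]
        groups = {}
        for p in pops:
            groups.setdefault(group_of[p], []).append(p)
        if len(groups) < 2:
            raise ValidationError("AMOVA needs >= 2 groups")
        if any(len(v) == 0 for v in groups.values()):
            raise ValidationError("every group needs >= 1 population")
        self.table = table
        self.groups = groups
        self.pops = pops
        self._group_sizes = [len(v) for v in groups.values()]
        # per-locus per-population allele counts, precomputed once
        self._per_locus = []
        for j in range(table.n_loci):
            counts, n2, sizes = _locus_count_matrix(table, j, pops)
            if len(sizes) >= 2:
                self._per_locus.append((counts, n2))

    @staticmethod
    def _ssd(counts, n_copies):
        """Sum of squared 0/1 differences within a set, from allele counts."""
        if n_copies <= 0:
            return 0.0
        return (n_copies - (counts**2).sum(-1) / n_copies) / 2.0

    def _components(self, assignment):
        """Variance components given ``assignment``: list of population-index
        lists, one per group.  Components are summed over loci."""
        sig_a = sig_b = sig_c = 0.0
        for counts, n2 in self._per_locus:
            present = n2 > 0
            P = int(present.sum())
            grp_idx = [
                [i for i in grp if present[i]] for grp in assignment
            ]
            grp_idx = [g for g in grp_idx if g]
            G = len(grp_idx)
            if G < 2 or P <= G:
                continue
            N = n2.sum()
            tot_counts = counts.sum(axis=0)
            ssd_t = self._ssd(tot_counts, N)
            ssd_wp = sum(self._ssd(counts[i], n2[i]) for i in range(len(n2)) if present[i])
            ssd_wg = sum(
                self._ssd(counts[g].sum(axis=0), n2[g].sum()) for g in map(list, grp_idx)
            )
            ssd_ag = ssd_t - ssd_wg
            ssd_ap = ssd_wg - ssd_wp
            df_ag = G - 1
            df_ap = P - G
            df_wp = N - P
            if df_wp <= 0 or df_ap <= 0:
                continue
            ms_wp = ssd_wp / df_wp
            ms_ap = ssd_ap / df_ap
            ms_ag = ssd_ag / df_ag
            Ng = np.array([n2[g].sum() for g in map(list, grp_idx)])
            sum_n2_within = np.array([(n2[g] ** 2).sum() for g in map(list, grp_idx)])
            n_p = (N - (sum_n2_within / Ng).sum()) / df_ap
            n_pp = ((sum_n2_within / Ng).sum() - (n2**2).sum() / N) / df_ag
            n_ppp = (N - (Ng**2).sum() / N) / df_ag
            s_c = ms_wp
            s_b = (ms_ap - s_c) / n_p
            s_a = (ms_ag - s_c - n_pp * s_b) / n_ppp
            sig_a += s_a
            sig_b += s_b
            sig_c += s_c
        return sig_a, sig_b, sig_c

    def fit(self, n_perm: int = 10_000, seed: int = 0) -> AmovaResult:
        pops = self.pops
        idx_of = {p: i for i, p in enumerate(pops)}
        base = [[idx_of[p] for p in members] for members in self.groups.values()]
        sa, sb, sc = self._components(base)
        tot = sa + sb + sc
        f_ct = sa / tot if tot else np.nan
        f_sc = sb / (sb + sc) if (sb + sc) else np.nan
        f_st = (sa + sb) / tot if tot else np.nan
        p = None
        if n_perm:
            rng = np.random.default_rng(seed)
            sizes = [len(g) for g in base]
            count_ge = 0
            n_pop = len(pops)
            for _ in range(n_perm):
                perm = rng.permutation(n_pop)
                shuffled = []
                pos = 0
                for s in sizes:
                    shuffled.append(list(perm[pos : pos + s]))
                    pos += s
                psa, psb, psc = self._components(shuffled)
                ptot = psa + psb + psc
                pfct = psa / ptot if ptot else -np.inf
                if pfct >= f_ct:
                    count_ge += 1
            p = (1.0 + count_ge) / (n_perm + 1.0)
        return AmovaResult(sa, sb, sc, f_ct, f_sc, f_st, p, n_perm, dict(self.groups))


def amova(table, grouping, n_perm: int = 10_000, seed: int = 0) -> AmovaResult:
    """Three-level AMOVA (convenience wrapper around :class:`Amova`)."""
    return Amova(table, grouping).fit(n_perm=n_perm, seed=seed)


# ---------------------------------------------------------------------------
# Isolation by distance
# ---------------------------------------------------------------------------

def mantel_test(x: np.ndarray, y: np.ndarray, n_perm: int = 1000, seed: int = 0,
                alternative: str = "greater"):
    """Mantel correlation between two symmetric matrices.

    ``r`` is the Pearson correlation of the off-diagonal upper-triangle
    entries; significance comes from permuting the population labels of one
    matrix.  Returns (r, p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.shape[0]
    iu = np.triu_indices(n, 1)
    finite = np.isfinite(x[iu]) & np.isfinite(y[iu])

    def corr(m):
        a, b = x[iu][finite], m[iu][finite]
        a = a - a.mean()
        b = b - b.mean()
        denom = np.sqrt((a**2).sum() * (b**2).sum())
        return float((a * b).sum() / denom) if denom else np.nan

    r_obs = corr(y)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        r_p = corr(y[np.ix_(perm, perm)])
        if alternative == "greater":
            count += r_p >= r_obs
        else:
            count += abs(r_p) >= abs(r_obs)
    p = (1.0 + count) / (n_perm + 1.0)
    return r_obs, p


@dataclass
class IbdResult:
    slope: float
    intercept: float
    mantel_r: float
    p_value: float
    n_pairs: int
    excluded_pairs: list

    def summary(self):
        return pd.Series(
            {
                "slope": self.slope,
                "intercept": self.intercept,
                "mantel_r": self.mantel_r,
                "p": self.p_value,
                "n_pairs": self.n_pairs,
            }
        )


def ibd_regression(
    fst: pd.DataFrame,
    distances: GroupingScheme | np.ndarray,
    populations=None,
    n_perm: int = 1000,
    seed: int = 0,
) -> IbdResult:
    """Isolation by distance: F_ST / (1 - F_ST) regressed on ln distance.

    Pairs with F_ST = 1 (transform undefined) or non-positive distance are
    excluded with a record in ``excluded_pairs``; the Mantel test permutes
    population labels of the genetic matrix.
    """
    pops = list(populations) if populations is not None else list(fst.index)
    F = fst.loc[pops, pops].to_numpy(dtype=float)
    if isinstance(distances, GroupingScheme):
        full = distances.distance_matrix()
        idx = [distances.populations.index(p) for p in pops]
        D = full[np.ix_(idx, idx)]
    else:
        D = np.asarray(distances, dtype=float)
    n = len(pops)
    iu = np.triu_indices(n, 1)
    excluded = []
    lin = np.full_like(F, np.nan)
    lnd = np.full_like(F, np.nan)
    for i, j in zip(*iu):
        if F[i, j] >= 1 or D[i, j] <= 0 or not np.isfinite(F[i, j]):
            excluded.append((pops[i], pops[j]))
            continue
        lin[i, j] = lin[j, i] = F[i, j] / (1 - F[i, j])
        lnd[i, j] = lnd[j, i] = np.log(D[i, j])
    y = lin[iu]
    x = lnd[iu]
    ok = np.isfinite(y) & np.isfinite(x)
    if ok.sum() < 3:
        raise ValidationError("fewer than 3 usable pairs for IBD regression")
    slope, intercept = np.polyfit(x[ok], y[ok], 1)
    r, p = mantel_test(lnd, lin, n_perm=n_perm, seed=seed)
    return IbdResult(float(slope), float(intercept), r, p, int(ok.sum()), excluded)
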
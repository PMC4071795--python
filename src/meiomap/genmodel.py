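"""Heritability and QTL mapping for the genome-wide recombination number.

Two estimators of heritability are provided: a pedigree repeatability model
(repeated GRN records per sire, additive + permanent-environment + residual
variance, Gibbs sampling with scaled-inverse-chi-square priors) and a
marker-based mixture model.  QTL mapping uses Bayesian whole-genome
regression -- BayesC (common SNP-effect variance) or BayesB (locus-specific
variances) with prior exclusion probability pi -- summarized per 1 Mb window
as the percentage of genetic variance and the window posterior probability
of association (WPPA).  Residuals of sire-mean phenotypes are weighted by
the family-size-dependent factor w_n.

The single-site Gibbs sampler is compiled with numba; chains are bit-for-bit
reproducible under a fixed seed in single-threaded execution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit
from scipy import linalg, stats


# ---------------------------------------------------------------------------
# pedigree relationship matrix
# ---------------------------------------------------------------------------

def pedigree_A(pedigree: pd.DataFrame, individuals: list[str] | None = None
               ) -> tuple[np.ndarray, list[str]]:
    """Numerator relationship matrix by the tabular method.

    ``pedigree`` needs ``offspring_id, sire_id`` columns (dam unknown in a
    sire/offspring design; '0', NaN or absence denotes an unknown parent,
    treated as an unrelated non-inbred founder).  Returns ``(A, order)``
    with parents placed before their offspring.
    """
    parent = {}
    for _, row in pedigree.iterrows():
        s = row["sire_id"]
        parent[str(row["offspring_id"])] = None if pd.isna(s) or str(s) == "0" \
            else str(s)
    if individuals is None:
        individuals = list(parent)
    ordered: list[str] = []
    seen: set[str] = set()

    def visit(ind: str, stack: tuple = ()) -> None:
        if ind in seen:
            return
        if ind in stack:
            raise ValueError(f"pedigree cycle involving {ind}")
        p = parent.get(ind)
        if p is not None:
            visit(p, stack + (ind,))
        seen.add(ind)
        ordered.append(ind)

    for ind in individuals:
        visit(ind)
    for ind in parent:
        visit(ind)

    n = len(ordered)
    idx = {ind: i for i, ind in enumerate(ordered)}
    A = np.zeros((n, n))
    for i, ind in enumerate(ordered):
        p = parent.get(ind)
        pi = idx[p] if p is not None else -1
        # single known parent; unknown dam contributes a founder gamete
        A[i, i] = 1.0
        for j in range(i):
            a = 0.5 * A[j, pi] if pi >= 0 else 0.0
            A[i, j] = A[j, i] = a
    keep = [idx[ind] for ind in individuals]
    return A[np.ix_(keep, keep)], list(individuals)


# ---------------------------------------------------------------------------
# repeatability model
# ---------------------------------------------------------------------------

@dataclass
class ChainSettings:
    iterations: int = 5000
    burn_in: int = 1000
    seed: int = 0
    prior_df: float = 4.0


@dataclass
class RepeatabilityFit:
    sigma2_a: float
    sigma2_p: float
    sigma2_e: float
    h2: float
    repeatability: float
    sd: dict
    ess: dict
    samples: pd.DataFrame


def _ess(x: np.ndarray) -> float:
    """Effective sample size via the initial-positive-sequence estimator."""
    x = np.asarray(x, dtype=float)
    n = x.size
    x = x - x.mean()
    v = x.var()
    if v == 0 or n < 10:
        return float(n)
    acf = np.correlate(x, x, mode="full")[n - 1:] / (v * n)
    s = 1.0
    for lag in range(1, n // 2):
        if acf[lag] <= 0:
            break
        s += 2.0 * acf[lag]
    return float(n / s)


def fit_repeatability(grn: pd.DataFrame, A: np.ndarray, sire_order: list[str],
                      chain: ChainSettings | None = None) -> RepeatabilityFit:
    """Gibbs sampler for the repeatability model ``y = 1 mu + Z u + Z p + e``.

    ``grn`` holds repeated records (columns ``sire_id, grn``); ``u`` are
    additive sire effects with Var(u) = A sigma2_a, ``p`` permanent-
    environment effects (one per sire, iid).  All three variances carry
    scaled-inverse-chi-square priors with ``prior_df`` degrees of belief,
    each centered (prior mean) on one third of the phenotypic variance --
    weakly informative and symmetric across the three components.

    Narrow-sense heritability h2 = sigma2_a / total; repeatability
    t = (sigma2_a + sigma2_p) / total.  Posterior means are reported.
    """
    chain = chain or ChainSettings()
    rng = np.random.default_rng(chain.seed)
    sire_idx = {s: i for i, s in enumerate(sire_order)}
    z = grn["sire_id"].map(sire_idx).to_numpy()
    if np.any(pd.isna(z)):
        raise ValueError("GRN table references sires absent from A")
    y = grn["grn"].to_numpy(dtype=float)
    n, q = y.size, len(sire_order)
    counts = np.bincount(z, minlength=q).astype(float)
    if (counts >= 2).sum() == 0:
        import warnings
        warnings.warn("no sire has repeated records; permanent-environment "
                      "variance is unidentifiable", stacklevel=2)

    try:
        Ainv = linalg.inv(linalg.cholesky(A, lower=True))
        Ainv = Ainv.T @ Ainv
    except linalg.LinAlgError as exc:
        raise ValueError("relationship matrix is not positive definite") from exc

    nu = chain.prior_df
    vy = y.var()
    # scale such that the prior mean nu*S/(nu-2) equals vy/3
    S_a = S_p = S_e = (vy / 3.0) * (nu - 2.0) / nu

    mu = y.mean()
    u = np.zeros(q)
    p_eff = np.zeros(q)
    s2a, s2p, s2e = vy / 3, vy / 3, vy / 3
    Z = np.zeros((n, q))
    Z[np.arange(n), z] = 1.0
    ZtZ = np.diag(counts)

    keep = chain.iterations - chain.burn_in
    out = np.zeros((keep, 5))
    for it in range(chain.iterations):
        resid = y - u[z] - p_eff[z]
        mu = rng.normal(resid.mean(), math.sqrt(s2e / n))
        # additive effects: joint multivariate-normal update
        rhs = Z.T @ (y - mu - p_eff[z]) / s2e
        M = ZtZ / s2e + Ainv / s2a
        L = linalg.cholesky(M, lower=True)
        mean = linalg.cho_solve((L, True), rhs)
        u = mean + linalg.solve_triangular(L, rng.standard_normal(q),
                                           lower=True, trans="T")
        # permanent environment: independent per sire
        r2 = y - mu - u[z]
        sums = np.bincount(z, weights=r2, minlength=q)
        var_p = 1.0 / (counts / s2e + 1.0 / s2p)
        p_eff = rng.normal(var_p * sums / s2e, np.sqrt(var_p))
        # variances
        e = r2 - p_eff[z]
        s2a = (u @ Ainv @ u + nu * S_a) / rng.chisquare(nu + q)
        s2p = (p_eff @ p_eff + nu * S_p) / rng.chisquare(nu + q)
        s2e = (e @ e + nu * S_e) / rng.chisquare(nu + n)
        if it >= chain.burn_in:
            tot = s2a + s2p + s2e
            out[it - chain.burn_in] = (s2a, s2p, s2e, s2a / tot,
                                       (s2a + s2p) / tot)

    samples = pd.DataFrame(out, columns=["sigma2_a", "sigma2_p", "sigma2_e",
                                         "h2", "t"])
    return RepeatabilityFit(
        sigma2_a=float(samples["sigma2_a"].mean()),
        sigma2_p=float(samples["sigma2_p"].mean()),
        sigma2_e=float(samples["sigma2_e"].mean()),
        h2=float(samples["h2"].mean()),
        repeatability=float(samples["t"].mean()),
        sd={c: float(samples[c].std()) for c in samples},
        ess={c: _ess(samples[c].to_numpy()) for c in ("h2", "t")},
        samples=samples,
    )


# ---------------------------------------------------------------------------
# residual weights for sire-mean phenotypes
# ---------------------------------------------------------------------------

def residual_weights(h2: float, c: float, t: float, n_offspring) -> np.ndarray:
    """Family-size weighting factor for sire-mean phenotypes.

    ``w_n = (1 - h2) / (c*h2 + (1 + (n - 1) t) / n - h2)`` where ``c`` is
    the proportion of genetic variance not captured by markers (0.40 by
    default in the fitting functions) and ``t`` the repeatability.  The
    residual variance of sire ``i`` is modeled as ``sigma2_e / w_i``: means
    of large families are less noisy and get larger weights.
    """
    if not 0.0 <= h2 <= t < 1.0:
        raise ValueError("need 0 <= h2 <= t < 1")
    n = np.asarray(n_offspring, dtype=float)
    if np.any(n < 1):
        raise ValueError("family sizes must be >= 1")
    denom = c * h2 + (1.0 + (n - 1.0) * t) / n - h2
    if np.any(denom <= 0):
        raise ValueError("non-positive weight denominator; check h2, c, t")
    w = (1.0 - h2) / denom
    return float(w) if np.ndim(n_offspring) == 0 else w


# ---------------------------------------------------------------------------
# BayesB / BayesC whole-genome regression
# ---------------------------------------------------------------------------

@njit(cache=True)
def _wgr_gibbs(Z, y, w, pi, bayesb, n_iter, burn_in, seed,
               nu_s, S_s, nu_e, S_e, win_of, n_win):  # pragma: no cover
    np.random.seed(seed)
    n, k = Z.shape
    Zw = Z * w.reshape(n, 1)
    C = np.zeros(k)
    for j in range(k):
        acc = 0.0
        for i in range(n):
            acc += Z[i, j] * Zw[i, j]
        C[j] = acc
    wsum = w.sum()

    mu = 0.0
    for i in range(n):
        mu += w[i] * y[i]
    mu /= wsum
    s = np.zeros(k)
    delta = np.zeros(k, dtype=np.int8)
    sigma2_j = np.full(k, S_s)
    common_s2 = S_s
    sigma2_e = S_e
    e = y - mu

    keep = n_iter - burn_in
    ppi = np.zeros(k)
    mean_s = np.zeros(k)
    snp_excl_diff = np.zeros(k)
    win_share = np.zeros(n_win)
    wppa = np.zeros(n_win)
    incl_frac = np.zeros(keep)
    var_g_tr = np.zeros(keep)
    s2e_tr = np.zeros(keep)
    h2_tr = np.zeros(keep)
    log_prior_odds = np.log((1.0 - pi) / pi) if pi > 0.0 else 1e30

    g = np.zeros(n)
    gw = np.zeros(n)
    inv_w_mean = 0.0
    for i in range(n):
        inv_w_mean += 1.0 / w[i]
    inv_w_mean /= n

    for it in range(n_iter):
        # intercept
        r = 0.0
        for i in range(n):
            r += w[i] * (e[i] + mu)
        mu_new = r / wsum + np.random.normal() * math.sqrt(sigma2_e / wsum)
        for i in range(n):
            e[i] += mu - mu_new
        mu = mu_new

        n_incl = 0
        for j in range(k):
            if C[j] <= 0.0:
                continue
            old = s[j]
            if delta[j] == 1:
                for i in range(n):
                    e[i] += Z[i, j] * old
            r = 0.0
            for i in range(n):
                r += Zw[i, j] * e[i]
            s2j = sigma2_j[j] if bayesb else common_s2
            v0 = C[j] * sigma2_e
            v1 = v0 + C[j] * C[j] * s2j
            if pi > 0.0:
                log_like = 0.5 * (math.log(v0 / v1) + r * r * (1.0 / v0 - 1.0 / v1))
                odds = log_prior_odds + log_like
                if odds > 35.0:
                    p1 = 1.0
                elif odds < -35.0:
                    p1 = 0.0
                else:
                    p1 = 1.0 / (1.0 + math.exp(-odds))
                inc = np.random.random() < p1
            else:
                inc = True
            if inc:
                lam = C[j] + sigma2_e / s2j
                mean_j = r / lam
                sd_j = math.sqrt(sigma2_e / lam)
                s[j] = mean_j + sd_j * np.random.normal()
                delta[j] = 1
                n_incl += 1
                for i in range(n):
                    e[i] -= Z[i, j] * s[j]
            else:
                s[j] = 0.0
                delta[j] = 0
            if bayesb:
                if delta[j] == 1:
                    sigma2_j[j] = (nu_s * S_s + s[j] * s[j]) / \
                        np.random.chisquare(nu_s + 1.0)
                else:
                    sigma2_j[j] = nu_s * S_s / np.random.chisquare(nu_s)

        if not bayesb:
            ssq = 0.0
            m = 0
            for j in range(k):
                if delta[j] == 1:
                    ssq += s[j] * s[j]
                    m += 1
            common_s2 = (nu_s * S_s + ssq) / np.random.chisquare(nu_s + m)

        sse = 0.0
        for i in range(n):
            sse += w[i] * e[i] * e[i]
        sigma2_e = (sse + nu_e * S_e) / np.random.chisquare(nu_e + n)

        if it >= burn_in:
            kk = it - burn_in
            incl_frac[kk] = n_incl / k
            # genome-wide genetic values and variance
            for i in range(n):
                g[i] = 0.0
            for j in range(k):
                if delta[j] == 1:
                    ppi[j] += 1.0
                    mean_s[j] += s[j]
                    for i in range(n):
                        g[i] += Z[i, j] * s[j]
            gm = 0.0
            for i in range(n):
                gm += g[i]
            gm /= n
            var_g = 0.0
            for i in range(n):
                var_g += (g[i] - gm) ** 2
            var_g /= n
            var_g_tr[kk] = var_g
            s2e_tr[kk] = sigma2_e
            resid_var = sigma2_e * inv_w_mean
            h2_tr[kk] = var_g / (var_g + resid_var) if var_g + resid_var > 0 else 0.0

            # window decomposition over included SNPs (win_of nondecreasing)
            if var_g > 0.0:
                j = 0
                while j < k:
                    if delta[j] == 0:
                        j += 1
                        continue
                    wcur = win_of[j]
                    for i in range(n):
                        gw[i] = 0.0
                    j0 = j
                    while j < k and win_of[j] == wcur:
                        if delta[j] == 1:
                            for i in range(n):
                                gw[i] += Z[i, j] * s[j]
                        j += 1
                    m1 = 0.0
                    for i in range(n):
                        m1 += gw[i]
                    m1 /= n
                    vw = 0.0
                    for i in range(n):
                        vw += (gw[i] - m1) ** 2
                    vw /= n
                    win_share[wcur] += vw / var_g
                    wppa[wcur] += 1.0
                    # leave-one-SNP-out shares for candidate-SNP attribution
                    for jj in range(j0, j):
                        if delta[jj] == 0:
                            continue
                        m2 = 0.0
                        for i in range(n):
                            m2 += gw[i] - Z[i, jj] * s[jj]
                        m2 /= n
                        v2 = 0.0
                        for i in range(n):
                            v2 += (gw[i] - Z[i, jj] * s[jj] - m2) ** 2
                        v2 /= n
                        snp_excl_diff[jj] += (vw - v2) / var_g

    ppi /= keep
    mean_s /= keep
    win_share /= keep
    wppa /= keep
    snp_excl_diff /= keep
    return (ppi, mean_s, win_share, wppa, snp_excl_diff,
            incl_frac, var_g_tr, s2e_tr, h2_tr)


@dataclass
class BayesFit:
    method: str
    pi: float
    ppi: np.ndarray
    effects: np.ndarray
    window_index: np.ndarray           # window id per SNP (genome-wide, dense)
    windows: pd.DataFrame              # chrom, window, pct_var, wppa
    snp_var_share: np.ndarray          # per-SNP window-variance-share drop (%)
    marker_h2: float
    marker_h2_sd: float
    mean_included_fraction: float
    included_fraction: np.ndarray
    var_g: np.ndarray
    sigma2_e: np.ndarray
    weights: np.ndarray
    chain: ChainSettings
    markers: pd.DataFrame | None = None


def _dense_windows(markers: pd.DataFrame) -> tuple[np.ndarray, pd.DataFrame]:
    """Map each SNP to a dense genome-wide window id (map order)."""
    from meiomap.haplotypes import WINDOW_BP

    win = markers["bp"].to_numpy() // WINDOW_BP
    key = pd.DataFrame({"chrom": markers["chrom"], "window": win})
    uniq = key.drop_duplicates().reset_index(drop=True)
    lut = {(c, w): i for i, (c, w) in enumerate(zip(uniq["chrom"], uniq["window"]))}
    dense = np.array([lut[(c, w)] for c, w in zip(key["chrom"], key["window"])],
                     dtype=np.int64)
    return dense, uniq


def fit_bayes(
    y: np.ndarray,
    genotypes: np.ndarray,
    markers: pd.DataFrame,
    weights: np.ndarray | None = None,
    method: str = "BayesB",
    pi: float = 0.995,
    chain: ChainSettings | None = None,
    genetic_proportion: float = 0.5,
    prior_spread: str = "all_snps",
) -> BayesFit:
    """Bayesian whole-genome regression of sire-mean GRN on SNP genotypes.

    ``y_i = mu + sum_j z_ij s_j + e_i`` with the mixture prior
    ``s_j ~ N(0, sigma2_s) w.p. 1 - pi; s_j = 0 w.p. pi``; SNP-effect
    variance common across loci (BayesC) or locus-specific (BayesB), both
    with scaled-inverse-chi-square priors; heterogeneous residuals
    ``e_i ~ N(0, sigma2_e / w_i)``.

    Genotypes are coded 0/1/2 and centered internally.  The SNP-effect
    variance prior scale spreads an assumed ``genetic_proportion`` of the
    phenotypic variance over the total genotypic variance of all markers
    (``prior_spread="all_snps"``, the default): the prior then stays weak
    relative to the likelihood, so under a signal-free phenotype the
    fraction of markers included per iteration sits at the prior rate
    ``1 - pi``, while the heavy tail of the scaled-inverse-chi-square still
    lets locus variances grow to capture large effects.
    ``prior_spread="included"`` concentrates the same variance into the
    expected ``(1 - pi) k`` included markers (a stronger prior that shrinks
    the null inclusion rate below ``1 - pi``).

    Per post-burn-in sample, the genetic variance is the variance across
    individuals of the genomic values and each 1 Mb window's variance is the
    variance of that window's partial sums; percentages, PPI and WPPA are
    tallied over samples.
    """
    if not 0.0 <= pi < 1.0:
        raise ValueError("pi must be in [0, 1)")
    if method not in ("BayesB", "BayesC"):
        raise ValueError(f"unknown method {method!r}")
    chain = chain or ChainSettings(iterations=5000, burn_in=1000)
    y = np.asarray(y, dtype=float)
    Z = np.asarray(genotypes, dtype=float)
    n, k = Z.shape
    if weights is None:
        weights = np.ones(n)
    weights = np.asarray(weights, dtype=float)
    if np.any(weights <= 0):
        raise ValueError("weights must be positive")
    Z = Z - Z.mean(axis=0)

    win_of, win_key = _dense_windows(markers)
    vy = float(np.var(y))
    mean_zvar = float(np.mean(Z.var(axis=0))) or 1.0
    if prior_spread == "all_snps":
        n_spread = float(k)
    elif prior_spread == "included":
        n_spread = max(1.0, (1.0 - pi) * k)
    else:
        raise ValueError(f"unknown prior_spread {prior_spread!r}")
    nu_s = 4.0
    S_s = genetic_proportion * vy / (n_spread * mean_zvar)
    nu_e = 4.0
    S_e = (1.0 - genetic_proportion) * vy

    res = _wgr_gibbs(
        np.ascontiguousarray(Z), y, weights, pi, method == "BayesB",
        chain.iterations, chain.burn_in, chain.seed,
        nu_s, S_s, nu_e, S_e, win_of, len(win_key))
    (ppi, mean_s, win_share, wppa, snp_excl, incl_frac,
     var_g, s2e, h2) = res
    if not np.all(np.isfinite(var_g)):
        raise RuntimeError(f"divergent chain (seed={chain.seed})")

    windows = win_key.copy()
    windows["pct_var"] = 100.0 * win_share
    windows["wppa"] = wppa
    return BayesFit(
        method=method, pi=pi, ppi=ppi, effects=mean_s, window_index=win_of,
        windows=windows, snp_var_share=100.0 * snp_excl,
        marker_h2=float(h2.mean()), marker_h2_sd=float(h2.std()),
        mean_included_fraction=float(incl_frac.mean()),
        included_fraction=incl_frac, var_g=var_g, sigma2_e=s2e,
        weights=weights, chain=chain, markers=markers.reset_index(drop=True),
    )


# ---------------------------------------------------------------------------
# QTL calling
# ---------------------------------------------------------------------------

@dataclass
class QtlReport:
    candidates: pd.DataFrame   # chrom, window, pct_var, wppa, flank windows,
    #                            candidate SNP, its variance share
    mean_wppa: float
    thresholds: dict = field(default_factory=dict)


def call_qtl(fit: BayesFit, min_pct_var: float = 0.2,
             wppa_fold: float = 1.5, flank_mb: int = 2) -> QtlReport:
    """Candidate windows and SNPs from a BayesFit.

    A window is a candidate when it explains at least ``min_pct_var`` % of
    the genetic variance AND its WPPA is at least ``wppa_fold`` times the
    genome-wide mean WPPA.  Each candidate window is reported with +-
    ``flank_mb`` Mb flanks and its candidate SNP: the SNP with the highest
    posterior probability of inclusion (ties -> larger variance share, then
    lowest bp), whose variance share is the posterior-mean drop in the
    window's variance when the SNP's contribution is removed.
    """
    mean_wppa = float(fit.windows["wppa"].mean())
    sel = (fit.windows["pct_var"] >= min_pct_var) & \
          (fit.windows["wppa"] >= wppa_fold * mean_wppa)
    rows = []
    for widx in np.nonzero(sel.to_numpy())[0]:
        wrow = fit.windows.iloc[widx]
        snps = np.nonzero(fit.window_index == widx)[0]
        order = sorted(
            snps,
            key=lambda j: (-fit.ppi[j], -fit.snp_var_share[j],
                           fit.markers["bp"].iloc[j] if fit.markers is not None else j),
        )
        best = order[0]
        rows.append({
            "chrom": wrow["chrom"], "window": int(wrow["window"]),
            "pct_var": float(wrow["pct_var"]), "wppa": float(wrow["wppa"]),
            "flank_lo": int(wrow["window"]) - flank_mb,
            "flank_hi": int(wrow["window"]) + flank_mb,
            "candidate_snp": (fit.markers["snp_id"].iloc[best]
                              if fit.markers is not None else str(best)),
            "snp_ppi": float(fit.ppi[best]),
            "snp_pct_var": float(fit.snp_var_share[best]),
        })
    return QtlReport(
        candidates=pd.DataFrame(rows, columns=[
            "chrom", "window", "pct_var", "wppa", "flank_lo", "flank_hi",
            "candidate_snp", "snp_ppi", "snp_pct_var"]),
        mean_wppa=mean_wppa,
        thresholds={"min_pct_var": min_pct_var, "wppa_fold": wppa_fold,
                    "flank_mb": flank_mb},
    )


# ---------------------------------------------------------------------------
# single-SNP confirmation test and multiple-testing correction
# ---------------------------------------------------------------------------

def effective_segments(Ne: float, L: float, k: int) -> float:
    """Effective number of independent chromosome segments
    ``Me = 2 Ne L k / ln(Ne L)`` (natural log), for Bonferroni correction of
    single-SNP tests; ``Ne`` effective population size, ``L`` mean
    chromosome length in Morgan, ``k`` the number of chromosomes."""
    if Ne * L <= 1:
        raise ValueError("need Ne * L > 1 for a positive log")
    return 2.0 * Ne * L * k / math.log(Ne * L)


def bonferroni(p: float, Me: float, alpha: float = 0.05) -> bool:
    """Genome-wide significance of a single-SNP p-value against alpha/Me."""
    return p < alpha / Me


def single_snp_test(y: np.ndarray, snp: np.ndarray, A: np.ndarray,
                    sigma2_a: float, sigma2_e: float) -> float:
    """GLS F-test of a SNP fitted as a fixed class effect in an animal model.

    Covariance ``V = sigma2_a A + sigma2_e I`` with plug-in components from
    the repeatability fit; the SNP enters as a 3-level class factor (fewer
    levels if a genotype class is absent).  Returns the F-test p-value; with
    ``A = I`` and one record per individual this reduces to the ordinary
    one-way ANOVA F-test.
    """
    y = np.asarray(y, dtype=float)
    snp = np.asarray(snp)
    levels = np.unique(snp)
    if levels.size < 2:
        raise ValueError("monomorphic SNP: class effect undefined")
    n = y.size
    V = sigma2_a * A + sigma2_e * np.eye(n)
    Lc = linalg.cholesky(V, lower=True)
    X = np.column_stack([np.ones(n)] +
                        [(snp == lv).astype(float) for lv in levels[1:]])
    Xw = linalg.solve_triangular(Lc, X, lower=True)
    yw = linalg.solve_triangular(Lc, y, lower=True)
    q = levels.size - 1
    beta, res_full, rank, _ = np.linalg.lstsq(Xw, yw, rcond=None)
    rss_full = float(((yw - Xw @ beta) ** 2).sum())
    X0 = Xw[:, :1]
    b0, *_ = np.linalg.lstsq(X0, yw, rcond=None)
    rss_0 = float(((yw - X0 @ b0) ** 2).sum())
    df2 = n - rank
    if df2 <= 0:
        raise ValueError("no residual degrees of freedom")
    F = ((rss_0 - rss_full) / q) / (rss_full / df2)
    return float(stats.f.sf(F, q, df2))
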
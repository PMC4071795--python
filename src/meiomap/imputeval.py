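"""Imputation-accuracy cross-validation and LD summaries.

Ties genotype-imputation quality to local recombination: relationship-based
K-means folds, a deliberately simple internal haplotype-matching imputer
(so the whole simulate -> mask -> impute -> evaluate loop runs without any
external tool; an externally imputed dataset can be evaluated instead),
identity-fraction accuracy aggregated per marker / animal / chromosome /
1 Mb window, and adjacent-SNP r-squared as the LD measure per window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats
from sklearn.cluster import KMeans

from meiomap.haplotypes import MISSING, WINDOW_BP, PhasedGenotypes


@dataclass
class FoldAssignment:
    folds: pd.Series           # individual -> fold in 1..K
    K: int
    inertia: float

    def members(self, k: int) -> list[str]:
        return list(self.folds.index[self.folds == k])


def kmeans_folds(A: np.ndarray, individuals: list[str], K: int = 5,
                 seed: int = 0, n_restarts: int = 50) -> FoldAssignment:
    """Cluster individuals into K cross-validation folds by K-means on the
    rows of the additive relationship matrix (k-means++ init, best of
    ``n_restarts``), maximizing within-fold and minimizing between-fold
    relatedness."""
    A = np.asarray(A, dtype=float)
    n = A.shape[0]
    if A.shape != (n, n) or len(individuals) != n:
        raise ValueError("A must be square and match the individual list")
    if K > n:
        raise ValueError("more folds than individuals")
    km = KMeans(n_clusters=K, n_init=n_restarts, random_state=seed)
    labels = km.fit_predict(A)
    return FoldAssignment(
        folds=pd.Series(labels + 1, index=list(individuals)),
        K=K, inertia=float(km.inertia_),
    )


# ---------------------------------------------------------------------------
# naive reference-haplotype imputer
# ---------------------------------------------------------------------------

def naive_impute(
    target: PhasedGenotypes,
    reference: PhasedGenotypes,
    panel_mask: dict[str, np.ndarray],
    window_bp: int = WINDOW_BP,
) -> PhasedGenotypes:
    """Fill masked markers of each target haplotype from its locally best-
    matching reference haplotype.

    ``panel_mask[chrom]`` is a boolean array over the chromosome's markers,
    True at observed (low-density panel) sites.  For every unobserved
    marker, the reference haplotype minimizing mismatches at observed
    markers within a sliding window of +- ``window_bp``/2 around it donates
    its allele; ties break to the more frequent reference haplotype, then
    the lower index.  This is a nearest-haplotype heuristic, not a
    reimplementation of HMM-based imputation: it exists so the pipeline is
    testable end to end, and it degrades near crossovers exactly because a
    single local donor cannot span a template switch.
    """
    if reference.n_samples == 0:
        raise ValueError("empty reference panel")
    out = target.copy()
    half = window_bp // 2
    for chrom in target.chromosomes:
        obs = np.asarray(panel_mask[chrom], dtype=bool)
        m = obs.size
        bp = target.chrom_markers(chrom)["bp"].to_numpy()
        if not np.array_equal(bp, reference.chrom_markers(chrom)["bp"].to_numpy()):
            raise ValueError("target markers must be a subset view of the "
                             "reference map (same chromosome marker grid)")
        R_all = reference.haplotypes[chrom].reshape(-1, m)  # (H, m)
        # score only distinct reference haplotypes; multiplicity doubles as
        # the frequency tie-break (index ties resolve to the first haplotype
        # in the lexicographic unique ordering -- deterministic)
        R, freq = np.unique(R_all, axis=0, return_counts=True)
        obs_idx = np.nonzero(obs)[0]
        fill_idx = np.nonzero(~obs)[0]
        if fill_idx.size == 0:
            continue
        lo = np.searchsorted(bp[obs_idx], bp[fill_idx] - half, side="left")
        hi = np.searchsorted(bp[obs_idx], bp[fill_idx] + half, side="right")
        empty = hi <= lo   # no observed marker nearby: use whole chromosome
        lo[empty], hi[empty] = 0, obs_idx.size

        # For binary alleles the window mismatch count between target t and
        # reference r is sum(t) + sum(r) - 2 t.r over the window's observed
        # markers; a missing allele encoded as 0.5 contributes a constant
        # independent of r, leaving the argmin untouched.
        T = out.haplotypes[chrom]
        nt = T.shape[0] * 2
        T_obs = T.reshape(nt, m)[:, obs_idx].astype(np.float32)
        T_obs[T_obs == MISSING] = 0.5
        R_obs = R[:, obs_idx].astype(np.float32)
        R_obs[R_obs == MISSING] = 0.5
        Pt = np.concatenate([np.zeros((nt, 1), np.float32),
                             np.cumsum(T_obs, axis=1)], axis=1)
        Pr = np.concatenate([np.zeros((R.shape[0], 1), np.float32),
                             np.cumsum(R_obs, axis=1)], axis=1)
        windows_key = lo.astype(np.int64) * (obs_idx.size + 1) + hi
        uniq_key, widx = np.unique(windows_key, return_inverse=True)
        tie = freq.astype(np.float32)
        tie /= tie.max() + 1.0       # < 1, so mismatch count dominates
        flat = T.reshape(nt, m)
        for w, key in enumerate(uniq_key):
            wlo, whi = int(key // (obs_idx.size + 1)), int(key % (obs_idx.size + 1))
            cross = T_obs[:, wlo:whi] @ R_obs[:, wlo:whi].T      # (nt, U)
            mism = (Pt[:, whi] - Pt[:, wlo])[:, None] \
                + (Pr[:, whi] - Pr[:, wlo])[None, :] - 2.0 * cross
            best = np.argmin(mism - tie[None, :], axis=1)
            cols = fill_idx[widx == w]
            flat[:, cols] = R[best][:, cols]
    return out


# ---------------------------------------------------------------------------
# accuracy
# ---------------------------------------------------------------------------

@dataclass
class AccuracyTrack:
    overall: float
    per_marker: pd.DataFrame       # snp_id, chrom, bp, accuracy, n
    per_animal: pd.DataFrame       # individual, accuracy, n
    per_chromosome: pd.DataFrame   # chrom, accuracy, n
    per_window: pd.DataFrame       # chrom, window, accuracy, n
    per_animal_chrom: pd.DataFrame  # individual, chrom, accuracy, n


def accuracy(imputed: PhasedGenotypes, original: PhasedGenotypes,
             panel_mask: dict[str, np.ndarray]) -> AccuracyTrack:
    """Fraction of imputed genotypes identical to the original genotypes.

    Only masked (imputed, not observed) entries enter; missing originals are
    excluded.  Aggregated overall and per marker, animal, chromosome and
    1 Mb window; the genome figure is the mask-weighted mean of the
    per-chromosome figures by construction.
    """
    if imputed.samples != original.samples:
        raise ValueError("sample sets differ")
    marker_rows, win_rows, chrom_rows, ac_rows = [], [], [], []
    hits_per_animal = np.zeros(len(imputed.samples))
    n_per_animal = np.zeros(len(imputed.samples))
    total_hits = total_n = 0
    any_masked = False
    for chrom in imputed.chromosomes:
        mask = ~np.asarray(panel_mask[chrom], dtype=bool)
        if not mask.any():
            continue
        any_masked = True
        gi = imputed.genotypes(chrom)[:, mask]
        go = original.genotypes(chrom)[:, mask]
        ok = go != MISSING
        same = (gi == go) & ok
        m = imputed.chrom_markers(chrom)
        bp = m["bp"].to_numpy()[mask]
        sid = m["snp_id"].to_numpy()[mask]
        n_col = ok.sum(axis=0)
        with np.errstate(invalid="ignore"):
            acc_col = np.divide(same.sum(axis=0), n_col,
                                out=np.full(mask.sum(), np.nan), where=n_col > 0)
        marker_rows.append(pd.DataFrame({
            "snp_id": sid, "chrom": chrom, "bp": bp,
            "accuracy": acc_col, "n": n_col}))
        win = bp // WINDOW_BP
        wdf = pd.DataFrame({"window": win, "hits": same.sum(axis=0), "n": n_col})
        agg = wdf.groupby("window").sum().reset_index()
        agg.insert(0, "chrom", chrom)
        win_rows.append(agg)
        hits_per_animal += same.sum(axis=1)
        n_per_animal += ok.sum(axis=1)
        chrom_rows.append((chrom, same.sum(), ok.sum()))
        ac_rows.append(pd.DataFrame({
            "individual": imputed.samples, "chrom": chrom,
            "hits": same.sum(axis=1), "n": ok.sum(axis=1)}))
        total_hits += int(same.sum())
        total_n += int(ok.sum())
    if not any_masked or total_n == 0:
        raise ValueError("empty imputation mask: nothing to score")

    per_marker = pd.concat(marker_rows, ignore_index=True)
    per_window = pd.concat(win_rows, ignore_index=True)
    per_window["accuracy"] = per_window["hits"] / per_window["n"].where(
        per_window["n"] > 0)
    per_chrom = pd.DataFrame(chrom_rows, columns=["chrom", "hits", "n"])
    per_chrom["accuracy"] = per_chrom["hits"] / per_chrom["n"]
    per_animal = pd.DataFrame({
        "individual": imputed.samples,
        "accuracy": np.divide(hits_per_animal, n_per_animal,
                              out=np.full_like(hits_per_animal, np.nan),
                              where=n_per_animal > 0),
        "n": n_per_animal.astype(int)})
    per_ac = pd.concat(ac_rows, ignore_index=True)
    per_ac["accuracy"] = per_ac["hits"] / per_ac["n"].where(per_ac["n"] > 0)
    return AccuracyTrack(
        overall=total_hits / total_n,
        per_marker=per_marker,
        per_animal=per_animal,
        per_chromosome=per_chrom[["chrom", "accuracy", "n"]],
        per_window=per_window[["chrom", "window", "accuracy", "n"]],
        per_animal_chrom=per_ac[["individual", "chrom", "accuracy", "n"]],
    )


# ---------------------------------------------------------------------------
# LD
# ---------------------------------------------------------------------------

def adjacent_r2(data: PhasedGenotypes) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Squared correlation of genotype codes for each physically adjacent
    SNP pair, plus the mean per 1 Mb window.

    Pairs straddling a window boundary count toward the left SNP's window;
    pairs involving a monomorphic SNP are excluded.  Returns
    ``(per-pair frame, per-window means)``.
    """
    pair_rows = []
    for chrom in data.chromosomes:
        g = data.genotypes(chrom).astype(float)
        g[g == MISSING] = np.nan
        bp = data.chrom_markers(chrom)["bp"].to_numpy()
        if g.shape[1] < 2:
            raise ValueError(f"chromosome {chrom} has fewer than 2 SNPs")
        for j in range(g.shape[1] - 1):
            a, b = g[:, j], g[:, j + 1]
            ok = ~np.isnan(a) & ~np.isnan(b)
            if ok.sum() < 2 or a[ok].std() == 0 or b[ok].std() == 0:
                continue
            r = np.corrcoef(a[ok], b[ok])[0, 1]
            pair_rows.append((chrom, int(bp[j]), int(bp[j + 1]),
                              int(bp[j]) // WINDOW_BP, r * r))
    pairs = pd.DataFrame(pair_rows,
                         columns=["chrom", "left_bp", "right_bp", "window", "r2"])
    window_means = pairs.groupby(["chrom", "window"])["r2"].mean().reset_index()
    return pairs, window_means


# ---------------------------------------------------------------------------
# accuracy vs recombination
# ---------------------------------------------------------------------------

def accuracy_vs_recombination(
    window_accuracy: pd.DataFrame,
    window_rates: pd.DataFrame,
    per_animal_chrom_accuracy: pd.DataFrame | None = None,
    crossover_counts: pd.DataFrame | None = None,
):
    """Relate imputation accuracy to recombination rate.

    Returns a dict with the product-moment correlation and least-squares
    regression slope of window accuracy on window rate (with a
    ``degenerate`` flag and correlation 0 when accuracy has no variance),
    the Spearman rank correlation, and -- when per-(animal, chromosome)
    accuracies and crossover counts are supplied -- mean accuracy in the
    0 / 1 / 2 / >2 crossovers-per-chromosome groups.
    """
    merged = window_accuracy[["chrom", "window", "accuracy"]].merge(
        window_rates[["chrom", "window", "c_w"]],
        on=["chrom", "window"]).dropna()
    if len(merged) < 3:
        raise ValueError("fewer than 3 shared windows")
    acc = merged["accuracy"].to_numpy()
    rate = merged["c_w"].to_numpy()
    degenerate = acc.std() == 0 or rate.std() == 0
    if degenerate:
        corr, slope, rank_corr = 0.0, 0.0, 0.0
    else:
        corr = float(np.corrcoef(acc, rate)[0, 1])
        slope = float(np.polyfit(rate, acc, 1)[0])
        rank_corr = float(sstats.spearmanr(acc, rate).statistic)
    result = {
        "correlation": corr, "slope": slope, "rank_correlation": rank_corr,
        "degenerate": bool(degenerate), "n_windows": len(merged),
    }
    if per_animal_chrom_accuracy is not None and crossover_counts is not None:
        m = per_animal_chrom_accuracy.merge(
            crossover_counts, on=["individual", "chrom"], how="left")
        m["n_xo"] = m["n_xo"].fillna(0)
        grp = np.select(
            [m["n_xo"] == 0, m["n_xo"] == 1, m["n_xo"] == 2],
            ["0", "1", "2"], default=">2")
        result["group_means"] = (
            m.assign(group=grp).groupby("group")["accuracy"].mean().to_dict())
    return result
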
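"""Marker- and individual-level quality control for sire/offspring genotypes.

Filters follow the usual SNP-array workflow for parent-offspring designs:
pairs are first verified by genome-wide Mendelian consistency and individual
call rate, then SNPs are screened on call rate, minor allele frequency,
Hardy-Weinberg equilibrium and per-SNP Mendelian inconsistency across
verified pairs, and finally half-sib families below a minimum size are
excluded from the recombination-phenotype (GRN) analyses while remaining
available for detection diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from meiomap.haplotypes import MISSING, PhasedGenotypes


@dataclass
class QcThresholds:
    """Filtering thresholds.

    ``mendel_rate_max`` may alternatively be derived from the observed
    distribution of per-pair rates (``mendel_rule="quantile"`` uses the
    ``mendel_quantile`` quantile as the cutoff); the fixed constant is the
    default.
    """

    individual_call_rate_min: float = 0.95
    snp_call_rate_min: float = 0.95
    maf_min: float = 0.01
    hwe_p_min: float = 0.001
    mendel_rate_max: float = 0.0024
    family_size_min: int = 3
    mendel_rule: str = "constant"   # or "quantile"
    mendel_quantile: float = 0.95

    def __post_init__(self) -> None:
        for name in ("individual_call_rate_min", "snp_call_rate_min",
                     "maf_min", "hwe_p_min", "mendel_rate_max"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.family_size_min < 1:
            raise ValueError("family_size_min must be >= 1")


@dataclass
class QcReport:
    removed_individuals: pd.DataFrame   # individual, reason
    removed_snps: pd.DataFrame          # snp_id, reason
    pair_mendel_rates: pd.DataFrame     # offspring_id, sire_id, mendel_rate
    counts: dict = field(default_factory=dict)

    def summary(self) -> str:
        lines = [f"{k}: {v}" for k, v in self.counts.items()]
        return "\n".join(lines)


def mendelian_inconsistency(sire: np.ndarray, offspring: np.ndarray) -> float:
    """Fraction of jointly non-missing sites at which sire and offspring are
    opposite homozygotes (the only parent-offspring impossibility for
    biallelic codes 0/1/2 when only one parent is genotyped)."""
    sire = np.asarray(sire)
    offspring = np.asarray(offspring)
    if sire.shape != offspring.shape:
        raise ValueError("genotype vectors differ in length")
    ok = (sire != MISSING) & (offspring != MISSING)
    n = int(ok.sum())
    if n == 0:
        raise ValueError("no jointly non-missing sites: rate undefined")
    opposite = ((sire == 0) & (offspring == 2)) | ((sire == 2) & (offspring == 0))
    return float((opposite & ok).sum()) / n


def hwe_test(genotype_counts: tuple[int, int, int]) -> float:
    """One-df chi-square Hardy-Weinberg test; upper-tail p-value.

    Allele frequencies are estimated from the sample.  Monomorphic sites are
    assigned p = 1 by convention (no test possible).
    """
    n_aa, n_ab, n_bb = (int(c) for c in genotype_counts)
    n = n_aa + n_ab + n_bb
    if n <= 0:
        raise ValueError("no genotypes")
    p = (2 * n_aa + n_ab) / (2 * n)
    if p in (0.0, 1.0):
        return 1.0
    exp = np.array([n * p * p, 2 * n * p * (1 - p), n * (1 - p) ** 2])
    obs = np.array([n_aa, n_ab, n_bb], dtype=float)
    chi2 = float(((obs - exp) ** 2 / exp).sum())
    return float(stats.chi2.sf(chi2, df=1))


def _pair_arrays(data: PhasedGenotypes, pedigree: pd.DataFrame):
    geno = data.all_genotypes()
    pairs = pedigree[pedigree["analysis_pair"]] if "analysis_pair" in pedigree \
        else pedigree
    si = np.array([data.sample_idx(s) for s in pairs["sire_id"]])
    oi = np.array([data.sample_idx(o) for o in pairs["offspring_id"]])
    return geno, pairs, si, oi


def apply_qc(data: PhasedGenotypes, pedigree: pd.DataFrame,
             thresholds: QcThresholds | None = None):
    """Run the full filter cascade.

    Order: (1) remove pairs failing Mendelian verification or individual call
    rate; (2) remove SNPs by call rate, MAF, HWE and per-SNP Mendelian rate
    over the verified pairs; (3) flag families below ``family_size_min``
    offspring as ineligible for GRN analyses (``grn_eligible`` column; the
    pairs stay in the pedigree for detection diagnostics).

    Returns ``(filtered PhasedGenotypes, pedigree, QcReport)``.
    """
    thr = thresholds or QcThresholds()
    geno, pairs, si, oi = _pair_arrays(data, pedigree)
    n_snps = geno.shape[1]

    # ---- individuals / pairs --------------------------------------------
    removed_ind = []
    rates = []
    nonmiss = (geno != MISSING)
    call_rate = nonmiss.mean(axis=1)
    sg, og = geno[si], geno[oi]
    joint = (sg != MISSING) & (og != MISSING)
    opp = (((sg == 0) & (og == 2)) | ((sg == 2) & (og == 0))) & joint
    denom = joint.sum(axis=1)
    pair_rate = np.divide(opp.sum(axis=1), denom, out=np.zeros(len(si)),
                          where=denom > 0)
    if thr.mendel_rule == "quantile":
        mendel_cut = float(np.quantile(pair_rate, thr.mendel_quantile))
    else:
        mendel_cut = thr.mendel_rate_max
    for k, (_, row) in enumerate(pairs.iterrows()):
        rates.append((row["offspring_id"], row["sire_id"], pair_rate[k]))
        if pair_rate[k] > mendel_cut:
            removed_ind.append((row["offspring_id"], "mendel_pair"))
        elif call_rate[oi[k]] < thr.individual_call_rate_min:
            removed_ind.append((row["offspring_id"], "call_rate"))
    low_cr_sires = {
        s for s in set(pairs["sire_id"])
        if call_rate[data.sample_idx(s)] < thr.individual_call_rate_min
    }
    removed_names = {r[0] for r in removed_ind}
    for s in sorted(low_cr_sires):
        if s not in removed_names:
            removed_ind.append((s, "call_rate"))
            removed_names.add(s)

    keep_samples = [s for s in data.samples if s not in removed_names]
    data1 = data.subset_samples(keep_samples) if removed_names else data
    ped1 = pedigree[~pedigree["offspring_id"].isin(removed_names)
                    & ~pedigree["sire_id"].isin(removed_names)].copy()

    # ---- SNPs ------------------------------------------------------------
    geno1, pairs1, si1, oi1 = _pair_arrays(data1, ped1)
    nonmiss1 = geno1 != MISSING
    snp_cr = nonmiss1.mean(axis=0)
    with np.errstate(invalid="ignore"):
        af = np.where(nonmiss1.sum(axis=0) > 0,
                      np.where(geno1 == MISSING, 0, geno1).sum(axis=0)
                      / (2 * np.maximum(nonmiss1.sum(axis=0), 1)), 0.5)
    maf = np.minimum(af, 1 - af)
    hwe_p = np.array([
        hwe_test(((geno1[:, j] == 0).sum(), (geno1[:, j] == 1).sum(),
                  (geno1[:, j] == 2).sum()))
        for j in range(n_snps)
    ])
    sg1, og1 = geno1[si1], geno1[oi1]
    joint1 = (sg1 != MISSING) & (og1 != MISSING)
    opp1 = (((sg1 == 0) & (og1 == 2)) | ((sg1 == 2) & (og1 == 0))) & joint1
    d1 = joint1.sum(axis=0)
    snp_mendel = np.divide(opp1.sum(axis=0), d1, out=np.zeros(n_snps),
                           where=d1 > 0)

    snp_ids = data1.markers["snp_id"].to_numpy()
    removed_snps = []
    drop = np.zeros(n_snps, dtype=bool)
    for j in range(n_snps):
        if snp_cr[j] < thr.snp_call_rate_min:
            removed_snps.append((snp_ids[j], "call_rate"))
        elif maf[j] < thr.maf_min:
            removed_snps.append((snp_ids[j], "maf"))
        elif hwe_p[j] < thr.hwe_p_min:
            removed_snps.append((snp_ids[j], "hwe"))
        elif snp_mendel[j] > thr.mendel_rate_max:
            removed_snps.append((snp_ids[j], "mendel_snp"))
        else:
            continue
        drop[j] = True
    data2 = data1.subset_markers(snp_ids[~drop]) if drop.any() else data1
    if data2.markers.empty or not any(
            ped1.get("analysis_pair", pd.Series(True, index=ped1.index))):
        raise ValueError("all data filtered out by QC thresholds")

    # ---- family size for GRN analyses -----------------------------------
    is_pair = ped1["analysis_pair"] if "analysis_pair" in ped1 \
        else pd.Series(True, index=ped1.index)
    fam_size = ped1[is_pair].groupby("sire_id")["offspring_id"].size()
    eligible = set(fam_size[fam_size >= thr.family_size_min].index)
    ped1["grn_eligible"] = is_pair & ped1["sire_id"].isin(eligible)

    report = QcReport(
        removed_individuals=pd.DataFrame(removed_ind,
                                         columns=["individual", "reason"]),
        removed_snps=pd.DataFrame(removed_snps, columns=["snp_id", "reason"]),
        pair_mendel_rates=pd.DataFrame(
            rates, columns=["offspring_id", "sire_id", "mendel_rate"]),
        counts={
            "input_snps": n_snps,
            "output_snps": int(len(data2.markers)),
            "removed_snps": int(drop.sum()),
            "input_pairs": len(pairs),
            "removed_individuals": len(removed_ind),
            "grn_eligible_pairs": int(ped1["grn_eligible"].sum()),
            "mendel_cutoff": mendel_cut,
        },
    )
    return data2, ped1, report
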
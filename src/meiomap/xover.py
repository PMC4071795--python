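"""Paternal crossover detection, the artefact-filter cascade, and GRN.

A crossover transmitted by a sire is visible as a change in which of the two
sire haplotypes the offspring's paternally inherited haplotype matches.
Only *informative* markers -- sites where the sire is heterozygous and
phased -- carry that signal, so each event is localized to a recombination
interval between consecutive informative markers.

Phase-switch errors, gene-conversion tracts, genotyping errors and map
errors all masquerade as crossovers; a fixed cascade of filters removes the
signatures of each.  The genome-wide recombination number (GRN) of a
sire/offspring pair is the count of retained events over all autosomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from meiomap.haplotypes import MISSING, WINDOW_BP, PhasedGenotypes

RETAINED = "retained"
REASONS = ("double_lt2Mb", "gt3_per_chrom", "pair_mismatch",
           "hot_window_excess", "snp_mismatch")


@dataclass
class FilterThresholds:
    double_tract_mb: float = 2.0       # double-crossover tract span
    max_events_per_chrom: int = 3      # "> 3 per chromosome" removes all
    pair_mismatch_max: float = 0.05    # haplotype mismatch rate per pair
    window_rate_null: float = 0.025    # null per-meiosis window rate
    window_rate_alpha: float = 0.05    # one-sided exact binomial test level
    snp_mismatch_max: float = 0.05     # per-SNP across-pair mismatch rate


@dataclass
class MatchProfile:
    """Per (pair, chromosome) record of which sire haplotype was transmitted.

    ``bp``/``labels`` cover the informative markers (sire heterozygous,
    everything non-missing); ``labels`` are 1 or 2 for the matched sire
    haplotype.  ``mismatch_bp`` lists sites where the putative paternal
    allele conflicts with the sire's genotype (sire homozygous for the other
    allele) -- impossible transmissions that indicate phasing or genotyping
    errors.
    """

    pair_id: str
    sire_id: str
    chrom: str
    bp: np.ndarray
    labels: np.ndarray
    mismatch_bp: np.ndarray
    n_nonmissing: int
    paternal_index: int = 0
    tie_break: bool = False

    @property
    def n_informative(self) -> int:
        return int(self.bp.size)

    @property
    def mismatch_rate(self) -> float:
        if self.n_nonmissing == 0:
            return 0.0
        return self.mismatch_bp.size / self.n_nonmissing


def assign_paternal_haplotype(offspring: np.ndarray, sire: np.ndarray):
    """Label the offspring haplotype transmitted by the sire.

    A truly paternal haplotype can never carry an allele the sire does not
    have, however many crossovers it contains, so the primary criterion is
    the conflict (mismatch) rate with the sire genotype: the fraction of
    non-missing sites where the haplotype's allele is impossible given the
    sire (sire homozygous for the other allele).  The offspring haplotype
    with the lower conflict rate is called paternal; equal rates fall back
    to the greater best-identity against either single sire haplotype, and
    exact ties break deterministically to offspring haplotype 0 (flagged).

    Returns ``(paternal_index, mismatch_rate, tie)`` for the chosen
    haplotype.
    """
    rates = np.zeros(2)
    for o in range(2):
        ok = (offspring[o] != MISSING) & (sire[0] != MISSING) & (sire[1] != MISSING)
        n = int(ok.sum())
        conflict = ok & (sire[0] == sire[1]) & (offspring[o] != sire[0])
        rates[o] = conflict.sum() / n if n else 0.0
    tie = False
    if rates[0] != rates[1]:
        pat = int(np.argmin(rates))
    else:
        ident = np.full((2, 2), -1.0)
        for o in range(2):
            for s in range(2):
                ok = (offspring[o] != MISSING) & (sire[s] != MISSING)
                if ok.any():
                    ident[o, s] = (offspring[o][ok] == sire[s][ok]).mean()
        best = ident.max(axis=1)
        tie = bool(best[0] == best[1])
        pat = 0 if tie else int(np.argmax(best))
    return pat, float(rates[pat]), tie


def build_match_profile(data: PhasedGenotypes, offspring_id: str, sire_id: str,
                        chrom: str) -> MatchProfile:
    """Construct the informative-marker match profile for one pair/chromosome."""
    off = data.haps(offspring_id, chrom)
    sire = data.haps(sire_id, chrom)
    bp = data.chrom_markers(chrom)["bp"].to_numpy()
    pat, rate, tie = assign_paternal_haplotype(off, sire)
    po = off[pat]
    ok = (po != MISSING) & (sire[0] != MISSING) & (sire[1] != MISSING)
    het = ok & (sire[0] != sire[1])
    informative = het & ((po == sire[0]) | (po == sire[1]))
    labels = np.where(po[informative] == sire[0][informative], 1, 2)
    conflict = ok & (sire[0] == sire[1]) & (po != sire[0])
    return MatchProfile(
        pair_id=offspring_id, sire_id=sire_id, chrom=chrom,
        bp=bp[informative], labels=labels.astype(np.int8),
        mismatch_bp=bp[conflict], n_nonmissing=int(ok.sum()),
        paternal_index=pat, tie_break=tie,
    )


def detect_crossovers(profile: MatchProfile) -> pd.DataFrame:
    """One event per change of matched sire haplotype between consecutive
    informative markers.

    Returns a DataFrame with columns ``pair_id, sire_id, chrom, left_bp,
    right_bp, status, reason`` (events initially retained).  With fewer than
    two informative markers no event can be seen and an empty frame is
    returned.
    """
    cols = ["pair_id", "sire_id", "chrom", "left_bp", "right_bp", "status", "reason"]
    if profile.n_informative < 2:
        return pd.DataFrame(columns=cols)
    changes = np.nonzero(np.diff(profile.labels) != 0)[0]
    rows = [
        (profile.pair_id, profile.sire_id, profile.chrom,
         int(profile.bp[i]), int(profile.bp[i + 1]), RETAINED, "")
        for i in changes
    ]
    return pd.DataFrame(rows, columns=cols)


def detect_all(data: PhasedGenotypes, pedigree: pd.DataFrame):
    """Detect crossovers for every analysis pair on every chromosome.

    Returns ``(events DataFrame, profiles dict keyed by (pair, chrom))``.
    """
    pairs = pedigree[pedigree["analysis_pair"]] if "analysis_pair" in pedigree \
        else pedigree
    frames, profiles = [], {}
    for _, row in pairs.iterrows():
        for chrom in data.chromosomes:
            prof = build_match_profile(data, row["offspring_id"],
                                       row["sire_id"], chrom)
            profiles[(row["offspring_id"], chrom)] = prof
            ev = detect_crossovers(prof)
            if len(ev):
                frames.append(ev)
    if frames:
        events = pd.concat(frames, ignore_index=True)
    else:
        events = detect_crossovers(
            MatchProfile("", "", "", np.empty(0), np.empty(0), np.empty(0), 0))
    return events, profiles


# ---------------------------------------------------------------------------
# filtering cascade
# ---------------------------------------------------------------------------

def _provisional_window_rates(events: pd.DataFrame, n_pairs: int) -> pd.DataFrame:
    from meiomap.recstats import window_rates
    return window_rates(events, n_pairs, classify=False)


def filter_events(
    events: pd.DataFrame,
    profiles: dict,
    n_pairs: int,
    thresholds: FilterThresholds | None = None,
    provisional_rates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Apply the artefact filters in fixed order; flag, never delete.

    1. *double_lt2Mb* -- both members of any consecutive event pair on the
       same (pair, chromosome) whose between-event tract (right bound of the
       first to left bound of the second) spans < 2 Mb; tight double
       crossovers are the signature of phase switches and gene conversion.
    2. *gt3_per_chrom* -- all events of a (pair, chromosome) carrying more
       than three events after step 1.
    3. *pair_mismatch* -- all events of pairs whose haplotype mismatch rate
       exceeds 0.05 (the putative paternal haplotype is not credibly a sire
       haplotype).
    4. *hot_window_excess* -- events overlapping windows whose provisional
       rate (computed from the unfiltered events: the two-pass scheme) is
       significantly above 0.025 by a one-sided exact binomial test at
       alpha = 0.05 over ``n_pairs`` meioses.
    5. *snp_mismatch* -- events overlapping windows containing a SNP whose
       across-pairs mismatch rate exceeds 0.05.

    Each removed event gets the first applicable reason.  Returns a new
    events frame with ``status``/``reason`` set.
    """
    thr = thresholds or FilterThresholds()
    ev = events.copy().reset_index(drop=True)
    if ev.empty:
        return ev
    status = np.array([RETAINED] * len(ev), dtype=object)
    reason = np.array([""] * len(ev), dtype=object)

    # (1) tight double crossovers
    tract_bp = thr.double_tract_mb * 1e6
    for (_, _), idx in ev.groupby(["pair_id", "chrom"]).groups.items():
        idx = ev.loc[idx].sort_values("left_bp").index.to_numpy()
        for a, b in zip(idx[:-1], idx[1:]):
            span = ev.at[b, "left_bp"] - ev.at[a, "right_bp"]
            if span < tract_bp:
                for k in (a, b):
                    if status[k] == RETAINED:
                        status[k] = "removed"
                        reason[k] = "double_lt2Mb"

    # (2) more than three events per chromosome after step 1
    alive = status == RETAINED
    for (_, _), idx in ev[alive].groupby(["pair_id", "chrom"]).groups.items():
        if len(idx) > thr.max_events_per_chrom:
            for k in idx:
                status[k] = "removed"
                reason[k] = "gt3_per_chrom"

    # (3) pairs with excessive haplotype mismatch rate
    pair_rate: dict[str, float] = {}
    pair_sites: dict[str, int] = {}
    for (pair, _), prof in profiles.items():
        pair_rate[pair] = pair_rate.get(pair, 0) + prof.mismatch_bp.size
        pair_sites[pair] = pair_sites.get(pair, 0) + prof.n_nonmissing
    bad_pairs = {p for p in pair_rate
                 if pair_sites[p] and pair_rate[p] / pair_sites[p] > thr.pair_mismatch_max}
    for k in np.nonzero(ev["pair_id"].isin(bad_pairs).to_numpy())[0]:
        if status[k] == RETAINED:
            status[k] = "removed"
            reason[k] = "pair_mismatch"

    # (4) windows with provisional rate significantly above the null
    if provisional_rates is None:
        provisional_rates = _provisional_window_rates(events, n_pairs)
    hot_windows = set()
    for _, row in provisional_rates.iterrows():
        k = int(round(row["c_w"] * n_pairs))
        if k > 0:
            p = stats.binomtest(k, n_pairs, thr.window_rate_null,
                                alternative="greater").pvalue
            if p < thr.window_rate_alpha:
                hot_windows.add((row["chrom"], int(row["window"])))

    # (5) windows containing a high-mismatch SNP
    snp_hits: dict[tuple, int] = {}
    snp_tot: dict[tuple, int] = {}
    for (pair, chrom), prof in profiles.items():
        for b in prof.mismatch_bp:
            snp_hits[(chrom, int(b))] = snp_hits.get((chrom, int(b)), 0) + 1
    n_pair_ids = len({p for (p, _) in profiles})
    bad_snp_windows = {
        (chrom, b // WINDOW_BP)
        for (chrom, b), hits in snp_hits.items()
        if n_pair_ids and hits / n_pair_ids > thr.snp_mismatch_max
    }

    for k in range(len(ev)):
        if status[k] != RETAINED:
            continue
        chrom = ev.at[k, "chrom"]
        w0 = int(ev.at[k, "left_bp"]) // WINDOW_BP
        w1 = (int(ev.at[k, "right_bp"]) - 1) // WINDOW_BP
        overlapped = {(chrom, w) for w in range(w0, w1 + 1)}
        if overlapped & hot_windows:
            status[k] = "removed"
            reason[k] = "hot_window_excess"
        elif overlapped & bad_snp_windows:
            status[k] = "removed"
            reason[k] = "snp_mismatch"

    ev["status"] = status
    ev["reason"] = reason
    return ev


def compute_grn(events: pd.DataFrame, pedigree: pd.DataFrame,
                grn_eligible_only: bool = True) -> pd.DataFrame:
    """Genome-wide recombination number per sire/offspring pair.

    GRN is the count of *retained* events summed over all autosomes; pairs
    without any retained event get GRN 0.  When the pedigree carries a
    ``grn_eligible`` column (small families excluded upstream), only
    eligible pairs are tabulated unless ``grn_eligible_only=False``.
    """
    pairs = pedigree[pedigree["analysis_pair"]] if "analysis_pair" in pedigree \
        else pedigree
    if grn_eligible_only and "grn_eligible" in pairs:
        pairs = pairs[pairs["grn_eligible"]]
    retained = events[events["status"] == RETAINED] if len(events) else events
    if len(retained):
        unknown = set(retained["pair_id"]) - set(pedigree["offspring_id"])
        if unknown:
            raise ValueError(f"events reference pairs absent from pedigree: "
                             f"{sorted(unknown)[:5]}")
        counts = retained.groupby("pair_id").size()
    else:
        counts = pd.Series(dtype=int)
    grn = pairs[["sire_id", "offspring_id"]].copy()
    grn["grn"] = counts.reindex(grn["offspring_id"]).fillna(0).astype(int).to_numpy()
    return grn.reset_index(drop=True)


def sire_mean_grn(grn: pd.DataFrame) -> pd.DataFrame:
    out = grn.groupby("sire_id").agg(mean_grn=("grn", "mean"),
                                     n_offspring=("grn", "size"))
    return out.reset_index()
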
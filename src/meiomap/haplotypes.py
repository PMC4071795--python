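"""Phased genotype container, marker-map handling and window haplotype counts.

Positions are 1-based base pairs as in VCF.  Analyses tile each chromosome
into non-overlapping 1 Mb windows; window ``w`` covers base pairs in the
half-open interval ``[w * 1e6, (w + 1) * 1e6)`` with a 0-based window index,
so the window of base pair ``b`` is ``b // 1_000_000``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

WINDOW_BP = 1_000_000

MISSING = -1


def window_of(bp) -> np.ndarray | int:
    """0-based 1 Mb window index of a (array of) base-pair position."""
    return np.asarray(bp, dtype=np.int64) // WINDOW_BP if np.ndim(bp) else int(bp) // WINDOW_BP


@dataclass
class PhasedGenotypes:
    """Marker map plus two phased haplotype allele sequences per individual.

    Attributes
    ----------
    markers:
        DataFrame with columns ``snp_id, chrom, bp, ref, alt``, sorted by
        (chrom, bp) with strictly increasing bp within each chromosome.
    samples:
        Individual identifiers, in haplotype-array row order.
    haplotypes:
        Mapping chromosome -> int8 array of shape ``(n_samples, 2, m_chrom)``
        holding 0/1 allele codes (-1 = missing).
    """

    markers: pd.DataFrame
    samples: list[str]
    haplotypes: dict[str, np.ndarray]
    _sample_index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._sample_index = {s: i for i, s in enumerate(self.samples)}
        for chrom, group in self.markers.groupby("chrom", sort=False):
            bp = group["bp"].to_numpy()
            if not np.all(np.diff(bp) > 0):
                raise ValueError(f"marker map not strictly increasing on {chrom}")
            if chrom not in self.haplotypes:
                raise ValueError(f"no haplotypes for chromosome {chrom}")
            if self.haplotypes[chrom].shape != (len(self.samples), 2, len(group)):
                raise ValueError(f"haplotype array shape mismatch on {chrom}")

    # -- basic accessors ---------------------------------------------------

    @property
    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.markers["chrom"]))

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_idx(self, sample: str) -> int:
        return self._sample_index[sample]

    def chrom_markers(self, chrom: str) -> pd.DataFrame:
        return self.markers[self.markers["chrom"] == chrom]

    def haps(self, sample: str, chrom: str) -> np.ndarray:
        """The (2, m) haplotype pair of one individual on one chromosome."""
        return self.haplotypes[chrom][self.sample_idx(sample)]

    def genotypes(self, chrom: str) -> np.ndarray:
        """(n_samples, m) genotype codes 0/1/2, -1 where either allele missing."""
        h = self.haplotypes[chrom]
        g = h.sum(axis=1, dtype=np.int8)
        g[(h[:, 0] == MISSING) | (h[:, 1] == MISSING)] = MISSING
        return g

    def all_genotypes(self) -> np.ndarray:
        """Genome-wide (n_samples, total m) genotype matrix, map order."""
        return np.concatenate([self.genotypes(c) for c in self.chromosomes], axis=1)

    # -- subsetting --------------------------------------------------------

    def subset_samples(self, keep: list[str]) -> "PhasedGenotypes":
        idx = np.array([self._sample_index[s] for s in keep])
        haps = {c: h[idx].copy() for c, h in self.haplotypes.items()}
        return PhasedGenotypes(self.markers.copy(), list(keep), haps)

    def subset_markers(self, keep_snp_ids) -> "PhasedGenotypes":
        keep = set(keep_snp_ids)
        mask = self.markers["snp_id"].isin(keep).to_numpy()
        new_markers = self.markers[mask].reset_index(drop=True)
        haps = {}
        for chrom, group in self.markers.groupby("chrom", sort=False):
            cmask = group["snp_id"].isin(keep).to_numpy()
            sub = self.haplotypes[chrom][:, :, cmask]
            if sub.shape[2]:
                haps[chrom] = sub.copy()
        new_markers = new_markers[new_markers["chrom"].isin(haps)].reset_index(drop=True)
        return PhasedGenotypes(new_markers, list(self.samples), haps)

    def copy(self) -> "PhasedGenotypes":
        return PhasedGenotypes(
            self.markers.copy(), list(self.samples),
            {c: h.copy() for c, h in self.haplotypes.items()},
        )


# ---------------------------------------------------------------------------
# alternate marker maps
# ---------------------------------------------------------------------------

def apply_marker_map(data: PhasedGenotypes, alt_map: pd.DataFrame) -> PhasedGenotypes:
    """Re-coordinate phased data onto an alternate marker map.

    ``alt_map`` needs columns ``snp_id, chrom, bp``; only SNPs shared with
    ``data`` are kept (the usual workflow when comparing assemblies or a
    linkage map against assembly coordinates).  Haplotype columns are
    permuted to follow the new (chrom, bp) order.

    Raises
    ------
    ValueError
        If the intersection of SNP ids is empty.
    """
    shared = set(data.markers["snp_id"]) & set(alt_map["snp_id"])
    if not shared:
        raise ValueError("alternate map shares no SNP ids with the data")
    dropped = len(data.markers) - len(shared)

    sub = data.subset_markers(shared)
    alt = alt_map[alt_map["snp_id"].isin(shared)].copy()
    alt = alt.sort_values(["chrom", "bp"], kind="stable").reset_index(drop=True)

    # per old chromosome, the column positions of each snp_id
    pos_of: dict[str, tuple[str, int]] = {}
    for chrom, group in sub.markers.groupby("chrom", sort=False):
        for j, sid in enumerate(group["snp_id"]):
            pos_of[sid] = (chrom, j)

    haps: dict[str, np.ndarray] = {}
    marker_rows = []
    for chrom, group in alt.groupby("chrom", sort=False):
        cols = []
        for _, row in group.iterrows():
            src_chrom, j = pos_of[row["snp_id"]]
            cols.append(sub.haplotypes[src_chrom][:, :, j])
        haps[chrom] = np.stack(cols, axis=2)
        g = group.copy()
        old = sub.markers.set_index("snp_id")
        g["ref"] = old.loc[g["snp_id"], "ref"].to_numpy()
        g["alt"] = old.loc[g["snp_id"], "alt"].to_numpy()
        marker_rows.append(g)
    markers = pd.concat(marker_rows, ignore_index=True)[
        ["snp_id", "chrom", "bp", "ref", "alt"]
    ]
    out = PhasedGenotypes(markers, list(sub.samples), haps)
    out.dropped_markers = dropped  # type: ignore[attr-defined]
    return out


# ---------------------------------------------------------------------------
# window haplotype counting
# ---------------------------------------------------------------------------

def count_window_haplotypes(
    data: PhasedGenotypes,
    frequency_rule: str = "quantile",
    quantile: float = 5.0,
    frequency_floor: float = 0.05,
) -> pd.DataFrame:
    """Count distinct haplotypes per 1 Mb window.

    Haplotype strings over each window's SNPs are tallied across all ``2n``
    haplotypes.  Phasing errors generate spurious rare haplotypes, so
    low-frequency haplotypes are dropped before counting survivors:

    * ``frequency_rule="quantile"`` (default): drop haplotypes whose
      frequency is strictly below the ``quantile``-th percentile of the
      window's haplotype-frequency distribution (ties at the threshold kept);
    * ``frequency_rule="floor"``: drop haplotypes with frequency at or below
      ``frequency_floor``.

    Windows containing no SNPs get count NaN.  Returns a DataFrame with
    columns ``chrom, window, count, n_snps``.
    """
    rows = []
    for chrom in data.chromosomes:
        m = data.chrom_markers(chrom)
        bp = m["bp"].to_numpy()
        win = bp // WINDOW_BP
        h = data.haplotypes[chrom].reshape(-1, len(m))  # (2n, m)
        for w in range(int(win.max()) + 1):
            cols = np.where(win == w)[0]
            if cols.size == 0:
                rows.append((chrom, w, np.nan, 0))
                continue
            sub = np.ascontiguousarray(h[:, cols])
            _, counts = np.unique(sub, axis=0, return_counts=True)
            freqs = counts / counts.sum()
            if frequency_rule == "quantile":
                thr = np.percentile(freqs, quantile)
                kept = int(np.sum(freqs >= thr))
            elif frequency_rule == "floor":
                kept = int(np.sum(freqs > frequency_floor))
            else:
                raise ValueError(f"unknown frequency_rule {frequency_rule!r}")
            rows.append((chrom, w, float(kept), cols.size))
    return pd.DataFrame(rows, columns=["chrom", "window", "count", "n_snps"])


def snp_adjusted_haplotype_means(
    counts: pd.DataFrame,
    snp_counts: pd.DataFrame,
    groups: pd.DataFrame,
) -> pd.DataFrame:
    """Hot/cold group means of window haplotype counts, adjusted for SNP number.

    Windows with more SNPs mechanically carry more distinct haplotypes, so the
    raw group comparison is confounded by SNP density.  The adjustment
    regresses count on SNP number across all windows (single-covariate least
    squares) and compares groups on residuals re-centred at the grand mean.

    Parameters are window tracks sharing ``chrom, window`` keys:  ``counts``
    with a ``count`` column, ``snp_counts`` with ``n_snps``, ``groups`` with a
    ``cls`` column (e.g. hot/cold/neither).  Returns per-group raw and
    adjusted means.
    """
    df = counts[["chrom", "window", "count"]].merge(
        snp_counts[["chrom", "window", "n_snps"]], on=["chrom", "window"])
    df = df.merge(groups[["chrom", "window", "cls"]], on=["chrom", "window"])
    df = df.dropna(subset=["count"])
    if len(df) < 3:
        raise ValueError("need at least 3 windows for SNP-count adjustment")
    x = df["n_snps"].to_numpy(dtype=float)
    y = df["count"].to_numpy(dtype=float)
    X = np.column_stack([np.ones_like(x), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    df = df.assign(adjusted=resid + y.mean())
    out = df.groupby("cls").agg(
        raw_mean=("count", "mean"),
        raw_sd=("count", "std"),
        adjusted_mean=("adjusted", "mean"),
        adjusted_sd=("adjusted", "std"),
        n_windows=("count", "size"),
    )
    return out.reset_index()
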
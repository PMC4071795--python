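"""Chromosome- and window-level recombination statistics.

Implements the truncated-binomial (Karlin) crossover model -- at most ``N``
crossovers per chromosome, count ~ Binomial(N, x/N) with ``x`` the length in
Morgan (100 Mb = 1 M) -- observed crossover-probability histograms, genetic
lengths and cM/Mb ratios, fractional 1 Mb-window recombination rates with
hot/cold classification, and the classical map functions (Haldane, Kosambi,
binomial) for comparison.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from meiomap.haplotypes import WINDOW_BP
from meiomap.xover import RETAINED

HOT_RATE = 0.02
COLD_RATE = 0.004


# ---------------------------------------------------------------------------
# binomial crossover model
# ---------------------------------------------------------------------------

def karlin_expected(x: float, N: int = 4):
    """Expected crossover-count probabilities under the binomial model.

    ``p(t) = C(N, t) (x/N)^t (1 - x/N)^(N-t)`` for t = 0..N, with ``x`` the
    chromosome length in Morgan.  The expected genetic length
    ``sum_i i * p(i)`` equals ``x`` identically (binomial mean).

    Returns ``(p, expected_length_morgan)`` with ``p`` of length N+1.
    """
    if x < 0 or x > N:
        raise ValueError(f"need 0 <= x <= N (x={x}, N={N}): "
                         "the binomial probability x/N must lie in [0, 1]")
    t = np.arange(N + 1)
    p = stats.binom.pmf(t, N, x / N)
    return p, float((t * p).sum())


def map_functions(x, N: int = 4):
    """Recombination fraction at genetic distance ``x`` Morgan under the
    Haldane (Poisson, no interference), Kosambi (strong interference) and
    binomial (at most N crossovers) map functions.

    Returns ``(r_haldane, r_kosambi, r_karlin)``; all approach 1/2 as x
    grows.  The binomial form is ``(1 - (1 - 2x/N)^N) / 2`` for x <= N/2 and
    1/2 beyond.
    """
    x = np.asarray(x, dtype=float)
    r_h = 0.5 * (1.0 - np.exp(-2.0 * x))
    r_k = 0.5 * np.tanh(2.0 * x)
    r_b = np.where(x <= N / 2.0, 0.5 * (1.0 - (1.0 - 2.0 * x / N) ** N), 0.5)
    if x.ndim == 0:
        return float(r_h), float(r_k), float(r_b)
    return r_h, r_k, r_b


# ---------------------------------------------------------------------------
# observed summaries
# ---------------------------------------------------------------------------

def _retained(events: pd.DataFrame) -> pd.DataFrame:
    if "status" in events.columns and len(events):
        return events[events["status"] == RETAINED]
    return events


def _pair_ids(pedigree: pd.DataFrame) -> pd.Series:
    pairs = pedigree[pedigree["analysis_pair"]] if "analysis_pair" in pedigree \
        else pedigree
    return pairs["offspring_id"]


def observed_probabilities(events: pd.DataFrame, pedigree: pd.DataFrame,
                           chrom: str) -> np.ndarray:
    """Observed probabilities of 0/1/2/3/>3 retained crossovers per pair on
    one chromosome (five-bin histogram normalized by the number of pairs)."""
    pair_ids = _pair_ids(pedigree)
    T = len(pair_ids)
    if T == 0:
        raise ValueError("no sire-offspring pairs")
    ev = _retained(events)
    counts = ev[ev["chrom"] == chrom].groupby("pair_id").size() if len(ev) \
        else pd.Series(dtype=int)
    per_pair = counts.reindex(pair_ids, fill_value=0).to_numpy()
    bins = np.array([
        (per_pair == 0).sum(), (per_pair == 1).sum(), (per_pair == 2).sum(),
        (per_pair == 3).sum(), (per_pair > 3).sum(),
    ], dtype=float)
    return bins / T


def genetic_length(events: pd.DataFrame, pedigree: pd.DataFrame, chrom: str,
                   physical_mb: float):
    """Estimated genetic length (cM) and cM/Mb for one chromosome.

    The estimator is 100 x the mean retained crossover count per meiosis --
    the natural companion of a GRN-based genome total.  Retained-event
    filtering biases it downward relative to the binomial expectation.
    """
    pair_ids = _pair_ids(pedigree)
    T = len(pair_ids)
    if T == 0:
        raise ValueError("no sire-offspring pairs")
    ev = _retained(events)
    n_events = int((ev["chrom"] == chrom).sum()) if len(ev) else 0
    cm = 100.0 * n_events / T
    return cm, cm / physical_mb


def chromosome_summary(events: pd.DataFrame, pedigree: pd.DataFrame,
                       chrom_lengths_mb: dict[str, float], N: int = 4
                       ) -> pd.DataFrame:
    """Per-chromosome table: observed/expected crossover probabilities,
    estimated and expected genetic length, cM/Mb; plus a Total row where the
    genome ratio is the ratio of the sums."""
    rows = []
    for chrom, mb in chrom_lengths_mb.items():
        p_obs = observed_probabilities(events, pedigree, chrom)
        x = mb / 100.0
        p_exp, exp_len = karlin_expected(x, N)
        cm, cm_per_mb = genetic_length(events, pedigree, chrom, mb)
        rows.append({
            "chrom": chrom, "physical_mb": mb,
            **{f"p_obs_{t}": p_obs[t] for t in range(4)}, "p_obs_gt3": p_obs[4],
            **{f"p_exp_{t}": p_exp[t] for t in range(min(N, 4) + 1)},
            "genetic_cm": cm, "expected_cm": 100.0 * exp_len,
            "cm_per_mb": cm_per_mb,
        })
    df = pd.DataFrame(rows)
    total = {
        "chrom": "Total",
        "physical_mb": df["physical_mb"].sum(),
        "genetic_cm": df["genetic_cm"].sum(),
        "expected_cm": df["expected_cm"].sum(),
        "cm_per_mb": df["genetic_cm"].sum() / df["physical_mb"].sum(),
    }
    return pd.concat([df, pd.DataFrame([total])], ignore_index=True)


# ---------------------------------------------------------------------------
# window rates
# ---------------------------------------------------------------------------

def window_rates(events: pd.DataFrame, n_pairs: int,
                 chrom_lengths_bp: dict[str, int] | None = None,
                 hot_rate: float = HOT_RATE, cold_rate: float = COLD_RATE,
                 classify: bool = True) -> pd.DataFrame:
    """Per-1 Mb-window recombination rate with fractional event attribution.

    Each event's unit mass is split over the windows its recombination
    interval ``[left_bp, right_bp)`` overlaps, proportionally to overlap
    (``x_k / r_k``), then divided by the number of meioses ``T``; a terminal
    partial window absorbs its overlap share.  With ``classify=True``
    windows are labeled hot (c_w >= 0.02), cold (c_w <= 0.004) or neither.

    When ``chrom_lengths_bp`` is given, every window of every chromosome is
    present (rate 0 where no event overlaps); otherwise only chromosomes
    with events appear, tiled up to their last event.
    """
    if n_pairs < 1:
        raise ValueError("need at least one sire-offspring pair")
    ev = _retained(events)
    acc: dict[str, np.ndarray] = {}

    def ensure(chrom: str, n_win: int) -> np.ndarray:
        cur = acc.get(chrom)
        if cur is None:
            acc[chrom] = np.zeros(n_win)
        elif cur.size < n_win:
            acc[chrom] = np.concatenate([cur, np.zeros(n_win - cur.size)])
        return acc[chrom]

    if chrom_lengths_bp:
        for chrom, L in chrom_lengths_bp.items():
            ensure(chrom, int(np.ceil(L / WINDOW_BP)))

    if len(ev):
        for chrom, left, right in zip(ev["chrom"], ev["left_bp"], ev["right_bp"]):
            left, right = int(left), int(right)
            r_k = right - left
            if r_k <= 0:
                raise ValueError("recombination interval of non-positive length")
            w0, w1 = left // WINDOW_BP, (right - 1) // WINDOW_BP
            arr = ensure(chrom, w1 + 1)
            for w in range(w0, w1 + 1):
                lo = max(left, w * WINDOW_BP)
                hi = min(right, (w + 1) * WINDOW_BP)
                arr[w] += (hi - lo) / r_k

    rows = []
    for chrom, arr in acc.items():
        for w, mass in enumerate(arr):
            rows.append((chrom, w, mass / n_pairs))
    out = pd.DataFrame(rows, columns=["chrom", "window", "c_w"])
    if classify:
        out["cls"] = np.select(
            [out["c_w"] >= hot_rate, out["c_w"] <= cold_rate],
            ["hot", "cold"], default="neither")
    return out


def load_bovine_autosome_table() -> pd.DataFrame:
    """Reference per-autosome genetic length (cM), physical length (Mb,
    UMD3.1 assembly) and cM/Mb ratio for the 29 *Bos taurus* autosomes, as
    published for the Angus sire/offspring map.  Used for arithmetic
    cross-checks of :func:`chromosome_summary`-style derived columns."""
    from importlib import resources

    with resources.files("meiomap.data").joinpath(
            "bovine_autosomes_umd31.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", dtype={"chrom": str})


def track_correlation(a: pd.DataFrame, b: pd.DataFrame,
                      value: str = "c_w") -> float:
    """Product-moment correlation of two window tracks over shared windows."""
    merged = a[["chrom", "window", value]].merge(
        b[["chrom", "window", value]], on=["chrom", "window"],
        suffixes=("_a", "_b")).dropna()
    if len(merged) < 3:
        raise ValueError("fewer than 3 shared windows")
    return float(np.corrcoef(merged[f"{value}_a"], merged[f"{value}_b"])[0, 1])
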
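"""Simulator for pedigreed, phased SNP-array data with known recombination.

The generator emulates the features of a half-sib beef-cattle design that
matter for crossover detection: multi-chromosome SNP maps (~1 SNP per 61 kb),
sires with many offspring, per-chromosome crossover counts following a
truncated-binomial model Binomial(N, x/N) with x the chromosome length in
Morgan (100 Mb = 1 M) and N the maximum crossover number, window-level
hot/cold heterogeneity in crossover placement, gene-conversion tracts,
genotyping errors, phase-switch errors, and a heritable sire-level expected
genome-wide recombination number (GRN) with optional planted QTL.

Every simulated event is recorded in :class:`TruthTables` so downstream
detection, filtering, heritability and imputation analyses can be validated
against ground truth.  All randomness flows from a single seeded
``numpy.random.Generator``; error processes are applied in the fixed order
gene conversion -> genotyping error -> switch error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from meiomap.haplotypes import MISSING, WINDOW_BP, PhasedGenotypes

__all__ = [
    "SimConfig", "TruthTables", "build_recomb_map", "draw_founder_haplotypes",
    "make_gamete", "simulate_population", "apply_gene_conversion",
    "apply_genotyping_error", "apply_switch_error",
]


@dataclass
class SimConfig:
    """Configuration of one simulated dataset.

    Rates are probabilities in [0, 1]; lengths are physical (Mb / kb).
    ``offspring_per_sire`` is either a fixed integer or an inclusive
    ``(min, max)`` range sampled uniformly per sire.  ``qtl_spec`` entries are
    ``(chrom, position_mb, effect)`` with the effect expressed per alternate
    allele on the expected GRN (crossover-count units).  ``n_grandsires > 0``
    arranges the sires into paternal half-sib families descending from a
    founder grandsire generation, which makes additive and permanent-
    environment variance separable in the pedigree analysis.
    """

    n_chromosomes: int = 5
    chrom_lengths_mb: tuple = (100.0,) * 5
    snp_spacing_kb: float = 61.0
    founder_pool_size: int = 4
    founder_mutation_rate: float = 0.002
    founder_segment_mb: float | None = 1.0
    n_sires: int = 200
    offspring_per_sire: object = (2, 6)
    max_crossovers_N: int = 4
    window_intensity: dict | None = None
    n_hot_windows: int = 0
    hot_multiplier: float = 5.0
    gene_conversion_rate: float = 0.0
    conversion_tract_kb: float = 2.0
    genotyping_error_rate: float = 0.0
    switch_error_rate: float = 0.0
    grn_h2: float = 0.26
    qtl_spec: tuple = ()
    n_background_qtl: int = 300
    n_grandsires: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.chrom_lengths_mb) != self.n_chromosomes:
            raise ValueError("chrom_lengths_mb must have one entry per chromosome")
        if any(l <= 0 for l in self.chrom_lengths_mb):
            raise ValueError("chromosome lengths must be positive")
        for name in ("founder_mutation_rate", "genotyping_error_rate",
                     "switch_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.gene_conversion_rate < 0:  # Poisson mean: tracts per gamete
            raise ValueError("gene_conversion_rate must be >= 0")
        if not 0.0 <= self.grn_h2 < 1.0:
            raise ValueError("grn_h2 must be in [0, 1)")
        if self.max_crossovers_N < 1:
            raise ValueError("max_crossovers_N must be >= 1")
        if self.founder_pool_size < 2:
            raise ValueError("founder pool needs >= 2 haplotypes for polymorphism")
        if self.window_intensity is not None:
            for c, w in self.window_intensity.items():
                need = n_windows_of(self._length_mb(c))
                if len(w) != need:
                    raise ValueError(
                        f"window_intensity for chromosome {c}: {len(w)} weights, "
                        f"expected {need}")
                if any(x < 0 for x in w):
                    raise ValueError("window_intensity weights must be non-negative")

    def _length_mb(self, chrom: str) -> float:
        return self.chrom_lengths_mb[self.chromosomes.index(chrom)]

    @property
    def chromosomes(self) -> list[str]:
        return [str(i + 1) for i in range(self.n_chromosomes)]

    def offspring_counts(self, rng: np.random.Generator) -> np.ndarray:
        if isinstance(self.offspring_per_sire, int):
            return np.full(self.n_sires, self.offspring_per_sire)
        lo, hi = self.offspring_per_sire
        return rng.integers(lo, hi + 1, size=self.n_sires)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "chrom_lengths_mb" in raw:
            raw["chrom_lengths_mb"] = tuple(raw["chrom_lengths_mb"])
        if "offspring_per_sire" in raw and isinstance(raw["offspring_per_sire"], list):
            raw["offspring_per_sire"] = tuple(raw["offspring_per_sire"])
        if "qtl_spec" in raw:
            raw["qtl_spec"] = tuple(tuple(q) for q in raw["qtl_spec"])
        return cls(**raw)


@dataclass
class TruthTables:
    """Ground truth recorded during simulation (one row per event)."""

    true_crossovers: pd.DataFrame          # gamete_id, chrom, bp
    true_sire_grn_value: dict              # sire -> expected GRN (genetic value)
    true_switch_errors: pd.DataFrame       # individual, chrom, bp
    true_conversion_tracts: pd.DataFrame   # gamete_id, chrom, start_bp, end_bp
    true_genotyping_errors: pd.DataFrame   # individual, chrom, bp
    recomb_map: pd.DataFrame = None        # chrom, window, weight
    chrom_lengths_bp: dict = field(default_factory=dict)
    sire_multiplier: dict = field(default_factory=dict)

    def crossover_counts(self, gamete_ids=None) -> pd.Series:
        """True genome-wide crossover count per gamete (0 for event-free)."""
        counts = self.true_crossovers.groupby("gamete_id").size()
        if gamete_ids is not None:
            counts = counts.reindex(gamete_ids, fill_value=0)
        return counts


def n_windows_of(length_mb: float) -> int:
    return int(math.ceil(length_mb))


# ---------------------------------------------------------------------------
# recombination intensity map
# ---------------------------------------------------------------------------

def build_recomb_map(config: SimConfig, rng: np.random.Generator | None = None
                     ) -> pd.DataFrame:
    """Per-1 Mb-window crossover sampling weights, normalized per chromosome.

    Uses ``config.window_intensity`` verbatim when given; otherwise applies
    the hot-window recipe: ``n_hot_windows`` windows chosen genome-wide (by
    the seeded generator) receive ``hot_multiplier`` times the baseline
    weight, remaining windows weight 1.
    """
    rng = rng or np.random.default_rng(config.seed)
    rows = []
    if config.window_intensity is not None:
        for chrom in config.chromosomes:
            w = np.asarray(config.window_intensity[chrom], dtype=float)
            w = w / w.sum()
            rows += [(chrom, i, wi) for i, wi in enumerate(w)]
    else:
        counts = [n_windows_of(l) for l in config.chrom_lengths_mb]
        total = sum(counts)
        hot = set(rng.choice(total, size=min(config.n_hot_windows, total),
                             replace=False)) if config.n_hot_windows else set()
        flat = 0
        for chrom, nw in zip(config.chromosomes, counts):
            w = np.ones(nw)
            for i in range(nw):
                if flat + i in hot:
                    w[i] = config.hot_multiplier
            flat += nw
            w = w / w.sum()
            rows += [(chrom, i, wi) for i, wi in enumerate(w)]
    return pd.DataFrame(rows, columns=["chrom", "window", "weight"])


# ---------------------------------------------------------------------------
# founders
# ---------------------------------------------------------------------------

def _make_marker_map(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for chrom, length_mb in zip(config.chromosomes, config.chrom_lengths_mb):
        length_bp = int(length_mb * 1e6)
        n = max(2, int(round(length_mb * 1000 / config.snp_spacing_kb)))
        pos = np.unique(rng.integers(1, length_bp + 1, size=int(n * 1.2)))
        while pos.size < n:
            pos = np.unique(np.concatenate(
                [pos, rng.integers(1, length_bp + 1, size=n)]))
        pos = np.sort(rng.choice(pos, size=n, replace=False))
        rows.append(pd.DataFrame({
            "snp_id": [f"snp_{chrom}_{i}" for i in range(n)],
            "chrom": chrom, "bp": pos, "ref": "A", "alt": "B",
        }))
    return pd.concat(rows, ignore_index=True)


def _draw_pool(config: SimConfig, markers: pd.DataFrame,
               rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Ancestral haplotype pool: per site an allele frequency ~ U(0.05, 0.95),
    pool haplotypes drawn independently at that frequency."""
    pool = {}
    for chrom, group in markers.groupby("chrom", sort=False):
        m = len(group)
        freq = rng.uniform(0.05, 0.95, size=m)
        pool[chrom] = (rng.random((config.founder_pool_size, m)) < freq
                       ).astype(np.int8)
    return pool


def draw_founder_haplotypes(
    config: SimConfig,
    n_haplotypes: int,
    markers: pd.DataFrame | None = None,
    pool: dict[str, np.ndarray] | None = None,
    rng: np.random.Generator | None = None,
):
    """Draw founder haplotypes as mutated (piecewise) copies of pool members.

    With ``founder_segment_mb`` set (the default), each founder haplotype is
    a mosaic of uniformly chosen pool haplotypes with template switches at a
    mean physical spacing of ``founder_segment_mb`` Mb, then per-site
    mutation at ``founder_mutation_rate``.  The small pool induces linkage
    disequilibrium between nearby SNPs and the segment length sets the
    physical scale over which it decays -- mimicking a real SNP panel
    instead of the unrealistic chromosome-length LD of whole-template
    copies.  With ``founder_segment_mb=None`` each founder haplotype copies
    a single pool member for the whole chromosome.  Raising the mutation
    rate erodes LD in either mode.

    Returns ``(haps, pool)`` where both map chromosome -> int8 array of shape
    ``(n_haplotypes, m)`` / ``(founder_pool_size, m)``.
    """
    rng = rng or np.random.default_rng(config.seed)
    if markers is None:
        markers = _make_marker_map(config, rng)
    if pool is None:
        pool = _draw_pool(config, markers, rng)
    haps = {}
    for chrom in config.chromosomes:
        p = pool[chrom]
        m = p.shape[1]
        if config.founder_segment_mb is None:
            picks = rng.integers(0, p.shape[0], size=n_haplotypes)
            h = p[picks].copy()
        else:
            bp = markers.loc[markers["chrom"] == chrom, "bp"].to_numpy()
            gaps = np.diff(bp, prepend=bp[0]).astype(float)
            switch_p = 1.0 - np.exp(-gaps / (config.founder_segment_mb * 1e6))
            h = np.empty((n_haplotypes, m), dtype=np.int8)
            for i in range(n_haplotypes):
                switches = rng.random(m) < switch_p
                switches[0] = True
                seg_id = np.cumsum(switches) - 1
                templates = rng.integers(0, p.shape[0], size=seg_id[-1] + 1)
                h[i] = p[templates[seg_id], np.arange(m)]
        if config.founder_mutation_rate > 0:
            flips = rng.random(h.shape) < config.founder_mutation_rate
            h[flips] = 1 - h[flips]
        haps[chrom] = h
    return haps, pool


# ---------------------------------------------------------------------------
# meiosis
# ---------------------------------------------------------------------------

def make_gamete(
    parent: np.ndarray,
    bp: np.ndarray,
    length_mb: float,
    window_weights: np.ndarray,
    config: SimConfig,
    multiplier: float,
    rng: np.random.Generator,
):
    """Simulate one gamete from a phased parent on one chromosome.

    The crossover count is drawn from ``Binomial(N, multiplier * x / N)``
    with ``x = length_mb / 100`` Morgan (no interference; placement is
    independent across events).  Each crossover lands in a window sampled
    proportional to ``window_weights`` and uniformly within the window; the
    gamete alternates parental origin at the sorted crossover positions,
    starting from a fair coin.

    Returns ``(gamete alleles, sorted crossover bp array)``.
    """
    if multiplier <= 0:
        raise ValueError("sire multiplier must be positive")
    x = length_mb / 100.0
    N = config.max_crossovers_N
    p = multiplier * x / N
    if p > 1.0:
        raise ValueError(
            f"multiplier*x/N = {p:.3f} > 1; raise max_crossovers_N to keep the "
            "binomial crossover model valid")
    t = int(rng.binomial(N, p)) if p > 0 else 0
    length_bp = int(length_mb * 1e6)
    if t:
        wins = rng.choice(window_weights.size, size=t, p=window_weights)
        starts = wins.astype(np.int64) * WINDOW_BP
        ends = np.minimum(starts + WINDOW_BP, length_bp)
        pos = np.sort(rng.integers(starts, ends) + 1)
    else:
        pos = np.empty(0, dtype=np.int64)
    start_hap = int(rng.integers(2))
    origin = (start_hap + np.searchsorted(pos, bp, side="left")) % 2
    gamete = parent[origin, np.arange(bp.size)]
    return gamete.copy(), pos, origin


def apply_gene_conversion(
    gamete: np.ndarray,
    parent: np.ndarray,
    origin: np.ndarray,
    bp: np.ndarray,
    length_bp: int,
    config: SimConfig,
    rng: np.random.Generator,
) -> list[tuple[int, int]]:
    """Overlay non-crossover gene-conversion tracts on a fresh gamete.

    Tract count is Poisson(``gene_conversion_rate``); tract length is
    geometric with mean ``conversion_tract_kb`` (in bp).  Within a tract the
    gamete carries the homologous (non-transmitted) parental sequence, with
    no exchange of flanking markers -- the signature that mimics a tightly
    spaced double crossover when the tract covers heterozygous markers.

    Mutates ``gamete`` in place; returns the list of (start_bp, end_bp) tracts.
    """
    tracts = []
    n_tracts = rng.poisson(config.gene_conversion_rate)
    mean_bp = max(1.0, config.conversion_tract_kb * 1000.0)
    for _ in range(int(n_tracts)):
        start = int(rng.integers(1, length_bp + 1))
        length = int(rng.geometric(1.0 / mean_bp))
        end = min(start + length, length_bp)
        sel = (bp >= start) & (bp < end)
        gamete[sel] = parent[1 - origin[sel], np.nonzero(sel)[0]]
        tracts.append((start, end))
    return tracts


# ---------------------------------------------------------------------------
# post-hoc error processes
# ---------------------------------------------------------------------------

def apply_genotyping_error(data: PhasedGenotypes, rate: float,
                           rng: np.random.Generator) -> pd.DataFrame:
    """Flip genotype calls to a uniformly chosen different code.

    Each (individual, site) call errs independently with probability
    ``rate``.  An erroneous heterozygote is stored with random allele order.
    Mutates ``data`` in place; returns a table (individual, chrom, bp).
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must be in [0, 1]")
    rows = []
    if rate == 0:
        return pd.DataFrame(rows, columns=["individual", "chrom", "bp"])
    for chrom in data.chromosomes:
        h = data.haplotypes[chrom]
        bp = data.chrom_markers(chrom)["bp"].to_numpy()
        hits = np.nonzero(rng.random((h.shape[0], h.shape[2])) < rate)
        for i, j in zip(*hits):
            g = int(h[i, 0, j]) + int(h[i, 1, j])
            new = int(rng.choice([c for c in (0, 1, 2) if c != g]))
            if new == 0:
                h[i, :, j] = 0
            elif new == 2:
                h[i, :, j] = 1
            else:
                a = int(rng.integers(2))
                h[i, 0, j], h[i, 1, j] = a, 1 - a
            rows.append((data.samples[i], chrom, int(bp[j])))
    return pd.DataFrame(rows, columns=["individual", "chrom", "bp"])


def switch_from(haps: np.ndarray, site: int) -> None:
    """Swap the two haplotype labels of one individual from ``site`` onward.

    ``haps`` has shape (2, m).  Applying the same switch twice restores the
    original phase (involution).
    """
    haps[:, site:] = haps[::-1, site:].copy()


def apply_switch_error(data: PhasedGenotypes, rate: float,
                       rng: np.random.Generator) -> pd.DataFrame:
    """Introduce phase-switch errors: at each heterozygous site, with
    probability ``rate``, haplotype labels swap from that site onward.

    This is the dominant artefact of statistical phasing; a single switch
    mimics a crossover, two nearby switches mimic a tight double crossover.
    Mutates ``data`` in place; returns a table (individual, chrom, bp).
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must be in [0, 1]")
    rows = []
    if rate == 0:
        return pd.DataFrame(rows, columns=["individual", "chrom", "bp"])
    for chrom in data.chromosomes:
        h = data.haplotypes[chrom]
        bp = data.chrom_markers(chrom)["bp"].to_numpy()
        het = (h[:, 0, :] != h[:, 1, :]) & (h[:, 0, :] != MISSING) & (h[:, 1, :] != MISSING)
        draws = (rng.random(het.shape) < rate) & het
        for i in np.nonzero(draws.any(axis=1))[0]:
            sites = np.nonzero(draws[i])[0]
            parity = np.zeros(h.shape[2], dtype=np.int8)
            for s in sites:
                parity[s:] ^= 1
                rows.append((data.samples[i], chrom, int(bp[s])))
            flip = parity.astype(bool)
            hi = h[i]
            hi[:, flip] = hi[::-1, flip]
    return pd.DataFrame(rows, columns=["individual", "chrom", "bp"])


# ---------------------------------------------------------------------------
# whole-population simulation
# ---------------------------------------------------------------------------

def _genetic_values(config: SimConfig, genotypes: np.ndarray,
                    markers: pd.DataFrame, rng: np.random.Generator,
                    total_morgan: float, within_var: float) -> np.ndarray:
    """Log-scale genetic values g such that sire multiplier = exp(g).

    The genetic architecture is genomic: planted QTL effects (``qtl_spec``)
    plus many small background SNP effects, jointly scaled so the between-
    sire variance of expected GRN yields the target heritability against the
    binomial within-sire sampling variance.  Genomic (rather than pedigree-
    drawn) values make genetic resemblance follow haplotype inheritance, so
    both pedigree- and marker-based heritability estimators see the intended
    signal.
    """
    n = genotypes.shape[0]
    if config.grn_h2 == 0:
        return np.zeros(n)
    h2 = config.grn_h2
    target_var = h2 / (1.0 - h2) * within_var / total_morgan ** 2

    q = np.zeros(n)
    qtl_cols = []
    for chrom, pos_mb, effect in config.qtl_spec:
        sub = markers.index[markers["chrom"] == str(chrom)]
        bps = markers.loc[sub, "bp"].to_numpy()
        col = sub[np.argmin(np.abs(bps - pos_mb * 1e6))]
        z = genotypes[:, col].astype(float)
        q += (z - z.mean()) * effect / total_morgan
        qtl_cols.append(col)

    bg = np.zeros(n)
    n_bg = min(config.n_background_qtl, genotypes.shape[1] - len(qtl_cols))
    if n_bg > 0:
        candidates = np.setdiff1d(np.arange(genotypes.shape[1]), np.array(qtl_cols, int))
        cols = rng.choice(candidates, size=n_bg, replace=False)
        eff = rng.normal(size=n_bg)
        z = genotypes[:, cols].astype(float)
        bg = (z - z.mean(axis=0)) @ eff
    var_q = q.var()
    bg_target = max(target_var - var_q, 0.0)
    if bg.var() > 0 and bg_target > 0:
        bg *= math.sqrt(bg_target / bg.var())
    else:
        bg = np.zeros(n)
    g = q + bg
    return g - g.mean()


def simulate_population(config: SimConfig):
    """Simulate a full dataset: phased genotypes, pedigree and truth tables.

    Returns ``(PhasedGenotypes, pedigree, TruthTables)``.  The pedigree has
    columns ``offspring_id, sire_id, analysis_pair``; rows with
    ``analysis_pair=True`` are the sire/offspring detection pairs, the
    remaining rows record sire ancestry (grandsire links, or '0' when
    unknown).  Error processes are applied to the assembled data in the fixed
    order gene conversion (during meiosis) -> genotyping error -> switch
    error; all events land in the truth tables.
    """
    rng = np.random.default_rng(config.seed)
    markers = _make_marker_map(config, rng)
    recomb = build_recomb_map(config, rng)
    weights = {c: g["weight"].to_numpy()
               for c, g in recomb.groupby("chrom", sort=False)}
    pool = _draw_pool(config, markers, rng)
    bp_of = {c: g["bp"].to_numpy() for c, g in markers.groupby("chrom", sort=False)}
    len_mb = dict(zip(config.chromosomes, config.chrom_lengths_mb))
    len_bp = {c: int(mb * 1e6) for c, mb in len_mb.items()}

    morgans = {c: mb / 100.0 for c, mb in len_mb.items()}
    total_morgan = sum(morgans.values())
    N = config.max_crossovers_N
    within_var = sum(N * (x / N) * (1 - x / N) for x in morgans.values())

    ped_rows = []
    hap_store: dict[str, dict[str, np.ndarray]] = {c: {} for c in config.chromosomes}

    def add_individual(name: str, haps_by_chrom: dict[str, np.ndarray]) -> None:
        for c in config.chromosomes:
            hap_store[c][name] = haps_by_chrom[c]

    # --- sire generation(s) ----------------------------------------------
    # With n_grandsires > 0 the first n_grandsires sires are founders and
    # every later sire is the son of a uniformly chosen earlier sire, giving
    # a deep multi-generation bull pedigree dense in parent-offspring (0.5)
    # and collateral (0.25, 0.125, ...) relationships -- the structure that
    # lets the repeatability model separate additive from permanent-
    # environment variance.  With n_grandsires == 0 all sires are unrelated
    # founders.
    sires = [f"S{i:04d}" for i in range(config.n_sires)]
    n_founder_sires = config.n_grandsires if config.n_grandsires > 0 \
        else config.n_sires
    n_founder_sires = min(n_founder_sires, config.n_sires)
    fh, _ = draw_founder_haplotypes(config, 2 * n_founder_sires, markers, pool, rng)
    dams, _ = draw_founder_haplotypes(config, len(sires), markers, pool, rng)
    for i, s in enumerate(sires):
        if i < n_founder_sires:
            add_individual(s, {c: fh[c][2 * i:2 * i + 2]
                               for c in config.chromosomes})
            ped_rows.append((s, "0", False))
        else:
            father = sires[int(rng.integers(0, i))]
            haps = {}
            for c in config.chromosomes:
                gam, _, _ = make_gamete(hap_store[c][father], bp_of[c],
                                        len_mb[c], weights[c], config, 1.0, rng)
                haps[c] = np.stack([gam, dams[c][i]])
            add_individual(s, haps)
            ped_rows.append((s, father, False))

    # --- sire genetic values ----------------------------------------------
    sire_geno = np.concatenate(
        [np.stack([hap_store[c][s].sum(axis=0) for s in sires]).astype(np.int8)
         for c in config.chromosomes], axis=1)
    g = _genetic_values(config, sire_geno, markers, rng, total_morgan, within_var)
    mult = {s: math.exp(gi) for s, gi in zip(sires, g)}
    true_grn_value = {s: mult[s] * total_morgan for s in sires}

    # --- offspring generation --------------------------------------------
    xover_rows, tract_rows = [], []
    n_off = config.offspring_counts(rng)
    off_counter = 0
    for i, s in enumerate(sires):
        mat, _ = draw_founder_haplotypes(config, int(n_off[i]), markers, pool, rng)
        for j in range(int(n_off[i])):
            oid = f"O{off_counter:05d}"
            off_counter += 1
            haps = {}
            for c in config.chromosomes:
                parent = hap_store[c][s]
                gam, pos, origin = make_gamete(parent, bp_of[c], len_mb[c],
                                               weights[c], config, mult[s], rng)
                xover_rows += [(oid, c, int(p)) for p in pos]
                tracts = apply_gene_conversion(gam, parent, origin, bp_of[c],
                                               len_bp[c], config, rng)
                tract_rows += [(oid, c, a, b) for a, b in tracts]
                haps[c] = np.stack([gam, mat[c][j]])
            add_individual(oid, haps)
            ped_rows.append((oid, s, True))

    samples = sires + [f"O{i:05d}" for i in range(off_counter)]
    haplotypes = {
        c: np.stack([hap_store[c][s] for s in samples]) for c in config.chromosomes
    }
    data = PhasedGenotypes(markers, samples, haplotypes)
    pedigree = pd.DataFrame(ped_rows, columns=["offspring_id", "sire_id",
                                               "analysis_pair"])

    geno_err = apply_genotyping_error(data, config.genotyping_error_rate, rng)
    switch_err = apply_switch_error(data, config.switch_error_rate, rng)

    truth = TruthTables(
        true_crossovers=pd.DataFrame(xover_rows, columns=["gamete_id", "chrom", "bp"]),
        true_sire_grn_value=true_grn_value,
        true_switch_errors=switch_err,
        true_conversion_tracts=pd.DataFrame(
            tract_rows, columns=["gamete_id", "chrom", "start_bp", "end_bp"]),
        true_genotyping_errors=geno_err,
        recomb_map=recomb,
        chrom_lengths_bp=len_bp,
        sire_multiplier=mult,
    )
    return data, pedigree, truth
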
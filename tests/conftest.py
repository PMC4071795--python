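import numpy as np
import pandas as pd
import pytest

from meiomap.simdata import SimConfig, simulate_population


@pytest.fixture(scope="session")
def small_sim():
    """Small clean dataset (no error processes) shared across tests."""
    cfg = SimConfig(n_chromosomes=2, chrom_lengths_mb=(50.0, 40.0), n_sires=20,
                    offspring_per_sire=4, seed=42)
    data, ped, truth = simulate_population(cfg)
    return cfg, data, ped, truth


@pytest.fixture(scope="session")
def noisy_sim():
    """Dataset with switch and genotyping errors plus gene conversion."""
    cfg = SimConfig(n_chromosomes=2, chrom_lengths_mb=(60.0, 50.0), n_sires=25,
                    offspring_per_sire=4, switch_error_rate=0.001,
                    genotyping_error_rate=0.0005, gene_conversion_rate=0.2,
                    seed=7)
    data, ped, truth = simulate_population(cfg)
    return cfg, data, ped, truth


def parity_expected_counts(truth, profiles, pairs, chromosomes):
    """Independent oracle: detectable crossover count per (pair, chromosome).

    Crossovers falling in the same gap between consecutive informative
    markers cancel pairwise, so the detectable count is the number of gaps
    holding an odd number of true crossovers.
    """
    out = {}
    tx = truth.true_crossovers
    for _, row in pairs.iterrows():
        for chrom in chromosomes:
            prof = profiles[(row["offspring_id"], chrom)]
            pos = tx[(tx["gamete_id"] == row["offspring_id"])
                     & (tx["chrom"] == chrom)]["bp"].to_numpy()
            if prof.bp.size < 2:
                out[(row["offspring_id"], chrom)] = None
                continue
            idx = np.searchsorted(prof.bp, pos, side="left")
            inside = idx[(idx > 0) & (idx < prof.bp.size)]
            counts = pd.Series(inside).value_counts()
            out[(row["offspring_id"], chrom)] = int((counts % 2).sum())
    return out
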
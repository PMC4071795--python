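"""Readers and writers for the pipeline's on-disk formats.

Phased genotypes travel as phased VCF (``GT`` with ``|`` separators, contigs
declared in the header); pedigrees, marker maps, window tracks and truth
tables are plain TSV.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from meiomap.haplotypes import MISSING, PhasedGenotypes


def write_phased_vcf(data: PhasedGenotypes, path: str | os.PathLike,
                     contig_lengths: dict[str, int] | None = None) -> None:
    """Write phased genotypes as an uncompressed VCF with ``|``-separated GT."""
    markers = data.markers
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=meiomap\n")
        for chrom in data.chromosomes:
            if contig_lengths and chrom in contig_lengths:
                fh.write(f"##contig=<ID={chrom},length={contig_lengths[chrom]}>\n")
            else:
                fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(data.samples) + "\n")
        for chrom in data.chromosomes:
            m = markers[markers["chrom"] == chrom]
            h = data.haplotypes[chrom]
            a = np.char.mod("%d", h[:, 0, :].T)  # (m, n)
            b = np.char.mod("%d", h[:, 1, :].T)
            a[h[:, 0, :].T == MISSING] = "."
            b[h[:, 1, :].T == MISSING] = "."
            gt = np.char.add(np.char.add(a, "|"), b)
            for j, (_, row) in enumerate(m.iterrows()):
                fixed = (f"{chrom}\t{row['bp']}\t{row['snp_id']}\t{row['ref']}\t"
                         f"{row['alt']}\t.\tPASS\t.\tGT\t")
                fh.write(fixed + "\t".join(gt[j]) + "\n")


def read_phased_vcf(path: str | os.PathLike) -> PhasedGenotypes:
    """Read a phased VCF into a :class:`PhasedGenotypes` container.

    Unphased heterozygotes and half-calls are stored as missing alleles.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows = []
    per_chrom: dict[str, list[np.ndarray]] = {}
    for var in vcf:
        rows.append((var.ID or f"{var.CHROM}:{var.POS}", var.CHROM, var.POS,
                     var.REF, var.ALT[0] if var.ALT else "."))
        gt = np.array(var.genotypes, dtype=np.int16)  # (n, 3): a, b, phased
        alleles = gt[:, :2].astype(np.int8)
        unphased_het = (gt[:, 2] == 0) & (alleles[:, 0] != alleles[:, 1])
        alleles[unphased_het] = MISSING
        alleles[alleles < 0] = MISSING
        per_chrom.setdefault(var.CHROM, []).append(alleles)
    markers = pd.DataFrame(rows, columns=["snp_id", "chrom", "bp", "ref", "alt"])
    haps = {
        chrom: np.stack(cols, axis=2)  # (n, 2, m)
        for chrom, cols in per_chrom.items()
    }
    return PhasedGenotypes(markers, samples, haps)


# -- flat tables -----------------------------------------------------------

def write_pedigree(pedigree: pd.DataFrame, path: str | os.PathLike) -> None:
    pedigree.to_csv(path, sep="\t", index=False)


def read_pedigree(path: str | os.PathLike) -> pd.DataFrame:
    ped = pd.read_csv(path, sep="\t", dtype={"offspring_id": str, "sire_id": str})
    if "analysis_pair" in ped.columns:
        ped["analysis_pair"] = ped["analysis_pair"].astype(bool)
    return ped


def write_marker_map(markers: pd.DataFrame, path: str | os.PathLike) -> None:
    markers[["snp_id", "chrom", "bp"]].to_csv(path, sep="\t", index=False)


def read_marker_map(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"snp_id": str, "chrom": str, "bp": np.int64})


def write_window_track(track: pd.DataFrame, path: str | os.PathLike,
                       value_cols: list[str] | None = None) -> None:
    """Write a window track as BED-compatible TSV (half-open 0-based intervals)."""
    from meiomap.haplotypes import WINDOW_BP

    cols = value_cols or [c for c in track.columns if c not in ("chrom", "window")]
    out = pd.DataFrame({
        "chrom": track["chrom"],
        "start": track["window"] * WINDOW_BP,
        "end": (track["window"] + 1) * WINDOW_BP,
    })
    for c in cols:
        out[c] = track[c].to_numpy()
    out.to_csv(path, sep="\t", index=False)
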
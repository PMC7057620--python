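"""Readers and writers for the standard on-disk formats.

* PennCNV-style per-sample signal files: tab-delimited with header
  ``Name  Chr  Position  <sample>.Log R Ratio  <sample>.B Allele Freq``.
* Genotypes as minimal uncompressed VCF 4.2 (GT field only).
* SNP map as BIM-like TSV; pedigree, truth tables and call sets as TSV.
* Calls additionally as BED (conversion from 1-based closed to 0-based
  half-open: ``bed_start = start_bp - 1``, ``bed_end = end_bp``).
"""

from __future__ import annotations

import pathlib
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .types import (
    CnvCall,
    ConfigurationError,
    Pedigree,
    SignalSet,
    SnpMap,
    calls_to_frame,
    frame_to_calls,
)

PathLike = Union[str, pathlib.Path]

GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
GT_CODES = {"0/0": 0, "0/1": 1, "1/0": 1, "1/1": 2, "./.": -1,
            "0|0": 0, "0|1": 1, "1|0": 1, "1|1": 2, ".|.": -1}


# ---------------------------------------------------------------------------
# PennCNV signal files
# ---------------------------------------------------------------------------

def write_signal_file(
    path: PathLike, sample: str, snp_map: SnpMap, lrr: np.ndarray, baf: np.ndarray
) -> None:
    """One sample's LRR/BAF track in the PennCNV text layout."""
    df = pd.DataFrame(
        {
            "Name": snp_map.snp_id,
            "Chr": snp_map.chrom,
            "Position": snp_map.pos_bp,
            f"{sample}.Log R Ratio": np.round(lrr, 4),
            f"{sample}.B Allele Freq": np.round(baf, 4),
        }
    )
    df.to_csv(path, sep="\t", index=False)


def write_signal_files(
    out_dir: PathLike, signals: SignalSet, snp_map: SnpMap
) -> list[pathlib.Path]:
    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, sample in enumerate(signals.animals):
        p = out / f"{sample}.signal.txt"
        write_signal_file(p, sample, snp_map, signals.lrr[i], signals.baf[i])
        paths.append(p)
    return paths


def read_signal_file(path: PathLike) -> tuple[str, pd.DataFrame]:
    """Parse one PennCNV-style signal file -> (sample name, frame).

    The frame has columns Name, Chr, Position, lrr, baf ordered as on disk.
    """
    df = pd.read_csv(path, sep="\t")
    lrr_cols = [c for c in df.columns if c.endswith(".Log R Ratio")]
    baf_cols = [c for c in df.columns if c.endswith(".B Allele Freq")]
    if len(lrr_cols) != 1 or len(baf_cols) != 1:
        raise ConfigurationError(f"{path}: expected exactly one LRR and one BAF column")
    sample = lrr_cols[0][: -len(".Log R Ratio")]
    out = df.rename(columns={lrr_cols[0]: "lrr", baf_cols[0]: "baf"})
    return sample, out[["Name", "Chr", "Position", "lrr", "baf"]]


def read_signal_files(
    paths: Sequence[PathLike], snp_map: SnpMap
) -> SignalSet:
    """Assemble a SignalSet from per-sample files, aligned to ``snp_map``.

    Genotype calls are derived from BAF by nearest-cluster assignment
    (<1/3 -> AA, >2/3 -> BB, else AB), matching how a caller would use such
    files when true calls were not exchanged.
    """
    animals, lrrs, bafs = [], [], []
    id_order = pd.Index(snp_map.snp_id)
    for p in paths:
        sample, df = read_signal_file(p)
        df = df.set_index("Name").reindex(id_order)
        if df["lrr"].isna().any():
            raise ConfigurationError(f"{p}: signal file does not cover the SNP map")
        animals.append(sample)
        lrrs.append(df["lrr"].values)
        bafs.append(df["baf"].values)
    lrr = np.vstack(lrrs)
    baf = np.vstack(bafs)
    geno = np.where(baf < 1 / 3, 0, np.where(baf > 2 / 3, 2, 1)).astype(np.int8)
    return SignalSet(animals=animals, lrr=lrr, baf=baf, genotypes=geno)


# ---------------------------------------------------------------------------
# VCF (GT only)
# ---------------------------------------------------------------------------

def write_vcf(path: PathLike, snp_map: SnpMap, signals: SignalSet) -> None:
    """Minimal uncompressed VCF 4.2 with GT genotypes (alleles A=REF, B=ALT)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(signals.animals)
            + "\n"
        )
        g = signals.genotypes
        for j in range(snp_map.n_snps):
            gts = "\t".join(GT_STRINGS[int(g[i, j])] for i in range(signals.n_animals))
            fh.write(
                f"{snp_map.chrom[j]}\t{snp_map.pos_bp[j]}\t{snp_map.snp_id[j]}"
                f"\tA\tB\t.\t.\t.\tGT\t{gts}\n"
            )


def read_vcf(path: PathLike) -> tuple[pd.DataFrame, list[str], np.ndarray]:
    """Read a GT-only VCF -> (site frame, sample names, genotype matrix).

    The site frame has columns snp_id, chrom, pos_bp; genotypes are dosage
    coded (-1 missing) with shape (n_samples, n_sites).
    """
    sites = []
    genos = []
    samples: list[str] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("##"):
                continue
            fields = line.rstrip("\n").split("\t")
            if line.startswith("#CHROM"):
                samples = fields[9:]
                continue
            chrom, pos, vid = fields[0], fields[1], fields[2]
            fmt = fields[8].split(":")
            gt_i = fmt.index("GT")
            row = [GT_CODES.get(s.split(":")[gt_i], -1) for s in fields[9:]]
            sites.append((vid, int(chrom), int(pos)))
            genos.append(row)
    site_df = pd.DataFrame(sites, columns=["snp_id", "chrom", "pos_bp"])
    g = np.asarray(genos, dtype=np.int8).T if genos else np.zeros((len(samples), 0), np.int8)
    return site_df, samples, g


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------

def write_snp_map(path: PathLike, snp_map: SnpMap) -> None:
    snp_map.table.to_csv(path, sep="\t", index=False)


def read_snp_map(path: PathLike) -> SnpMap:
    return SnpMap(pd.read_csv(path, sep="\t"))


def write_pedigree(path: PathLike, ped: Pedigree) -> None:
    ped.table.to_csv(path, sep="\t", index=False)


def read_pedigree(path: PathLike) -> Pedigree:
    return Pedigree(pd.read_csv(path, sep="\t", dtype={"animal_id": str, "sire_id": str, "dam_id": str}))


def write_calls_tsv(path: PathLike, calls: Sequence[CnvCall]) -> None:
    calls_to_frame(list(calls)).to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_calls_tsv(path: PathLike) -> list[CnvCall]:
    return frame_to_calls(pd.read_csv(path, sep="\t"))


def write_calls_bed(path: PathLike, calls: Sequence[CnvCall]) -> None:
    """Calls as BED: 0-based half-open, name = animal:cn:caller."""
    with open(path, "w") as fh:
        for c in sorted(calls, key=lambda x: (x.chrom, x.start_bp, x.end_bp, x.animal_id)):
            fh.write(
                f"{c.chrom}\t{c.start_bp - 1}\t{c.end_bp}\t"
                f"{c.animal_id}:cn{c.copy_number}:{c.caller}\n"
            )


def write_truth_table(path: PathLike, truth: pd.DataFrame) -> None:
    truth.to_csv(path, sep="\t", index=False)
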
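"""Core in-memory containers shared by every pipeline stage.

Conventions used throughout the package:

* Genomic coordinates are 1-based, closed intervals (the rawcnv convention);
  a segment from SNP *i* to SNP *j* has ``start_bp = pos[i]``,
  ``end_bp = pos[j]`` and length ``end_bp - start_bp + 1``.
* Genotypes are dosage-coded ``int8``: 0 = AA, 1 = AB, 2 = BB, -1 = missing.
* Haplotype alleles are 0 = A, 1 = B.
* CNV marker alleles are 0 = N (normal), 1 = D (deletion), 2 = P
  (duplication); each haplotype contributes 1, 0 or 2 copies respectively,
  so the diploid copy number is the sum of the two contributions (0..4).
* Unknown parents in pedigrees are coded ``"0"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

ALLELE_N = 0
ALLELE_D = 1
ALLELE_P = 2
ALLELE_NAMES = {ALLELE_N: "N", ALLELE_D: "D", ALLELE_P: "P"}
ALLELE_CODES = {v: k for k, v in ALLELE_NAMES.items()}
#: copies of the underlying sequence contributed by one haplotype carrying
#: each allele: normal 1, deletion 0, duplication 2
ALLELE_COPIES = np.array([1, 0, 2], dtype=np.int8)

UNKNOWN_PARENT = "0"


class HerdcnvError(Exception):
    """Base class for package errors."""


class ConfigurationError(HerdcnvError):
    """Invalid user-supplied parameters."""


class SimulationError(HerdcnvError):
    """A requested simulation target is unattainable (e.g. CNV frequency)."""


class PipelineError(HerdcnvError):
    """A pipeline stage produced an unusable result (e.g. all SNPs filtered)."""


@dataclass
class SnpMap:
    """Ordered autosomal SNP coordinates with panel flags and local GC content.

    Backed by a DataFrame with columns ``snp_id``, ``chrom``, ``pos_bp``,
    ``on_md_panel``, ``gc_frac``; rows sorted by (chrom, pos_bp) with
    strictly increasing positions within a chromosome. ``gc_frac`` is the GC
    fraction of the +/-500 kb window around the SNP (simulated here as a
    smooth track; only its correlation with LRR matters downstream).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"snp_id", "chrom", "pos_bp", "on_md_panel", "gc_frac"}
        missing = required - set(self.table.columns)
        if missing:
            raise ConfigurationError(f"SnpMap missing columns: {sorted(missing)}")
        t = self.table.reset_index(drop=True)
        if len(t) and not (
            t.sort_values(["chrom", "pos_bp"], kind="stable")["pos_bp"].values
            == t["pos_bp"].values
        ).all():
            t = t.sort_values(["chrom", "pos_bp"], kind="stable").reset_index(drop=True)
        for _, sub in t.groupby("chrom"):
            d = np.diff(sub["pos_bp"].values)
            if len(d) and (d <= 0).any():
                raise ConfigurationError("SNP positions must strictly increase within chromosome")
        if len(t) and (t["chrom"].values < 1).any():
            raise ConfigurationError("chromosomes must be integers >= 1 (autosomes only)")
        self.table = t

    # -- basic accessors -------------------------------------------------
    def __len__(self) -> int:
        return len(self.table)

    @property
    def n_snps(self) -> int:
        return len(self.table)

    @property
    def chrom(self) -> np.ndarray:
        return self.table["chrom"].values

    @property
    def pos_bp(self) -> np.ndarray:
        return self.table["pos_bp"].values

    @property
    def gc_frac(self) -> np.ndarray:
        return self.table["gc_frac"].values.astype(float)

    @property
    def on_md_panel(self) -> np.ndarray:
        return self.table["on_md_panel"].values.astype(bool)

    @property
    def snp_id(self) -> np.ndarray:
        return self.table["snp_id"].values

    def chroms(self) -> list[int]:
        return sorted(set(int(c) for c in self.table["chrom"].unique()))

    def chrom_indices(self, chrom: int) -> np.ndarray:
        return np.flatnonzero(self.chrom == chrom)

    def subset(self, idx: np.ndarray) -> "SnpMap":
        """New map containing only the rows ``idx`` (order preserved)."""
        return SnpMap(self.table.iloc[np.asarray(idx)].reset_index(drop=True))

    def md_subset(self) -> "SnpMap":
        """The medium-density panel as its own map (strict subset of HD)."""
        return self.subset(np.flatnonzero(self.on_md_panel))

    def md_indices(self) -> np.ndarray:
        return np.flatnonzero(self.on_md_panel)

    def snps_in_interval(self, chrom: int, start_bp: int, end_bp: int) -> np.ndarray:
        """Indices of SNPs with chrom == chrom and start_bp <= pos <= end_bp."""
        ci = self.chrom_indices(chrom)
        pos = self.pos_bp[ci]
        lo = np.searchsorted(pos, start_bp, side="left")
        hi = np.searchsorted(pos, end_bp, side="right")
        return ci[lo:hi]


@dataclass
class Pedigree:
    """Pedigree as a DataFrame: animal_id, sire_id, dam_id, birth_order, breed.

    ``birth_order`` is a total order (older = smaller); parents precede
    offspring. Unknown parents are ``"0"``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"animal_id", "sire_id", "dam_id", "birth_order", "breed"}
        missing = required - set(self.table.columns)
        if missing:
            raise ConfigurationError(f"Pedigree missing columns: {sorted(missing)}")
        t = self.table.reset_index(drop=True)
        if t["animal_id"].duplicated().any():
            raise ConfigurationError("duplicate animal ids in pedigree")
        order = dict(zip(t["animal_id"], t["birth_order"]))
        for _, row in t.iterrows():
            for par in (row["sire_id"], row["dam_id"]):
                if par != UNKNOWN_PARENT:
                    if par not in order:
                        raise ConfigurationError(f"parent {par!r} not in pedigree")
                    if order[par] >= row["birth_order"]:
                        raise ConfigurationError("parents must precede offspring in birth_order")
        self.table = t

    @property
    def animals(self) -> list[str]:
        return list(self.table["animal_id"])

    def __len__(self) -> int:
        return len(self.table)

    def breeds(self) -> list[str]:
        return sorted(set(self.table["breed"]))

    def parent_progeny_pairs(self) -> list[tuple[str, str]]:
        """All (parent, progeny) pairs with a known parent."""
        pairs = []
        for _, row in self.table.iterrows():
            if row["sire_id"] != UNKNOWN_PARENT:
                pairs.append((row["sire_id"], row["animal_id"]))
            if row["dam_id"] != UNKNOWN_PARENT:
                pairs.append((row["dam_id"], row["animal_id"]))
        return pairs

    def breed_animals(self, breed: str) -> list[str]:
        sub = self.table[self.table["breed"] == breed]
        return list(sub.sort_values("birth_order")["animal_id"])


@dataclass
class HaplotypeSet:
    """Phased haplotypes for every animal over a SnpMap.

    ``haps``: (n_animals, 2, n_snps) int8 of 0/1 (B allele = 1).
    ``origins``: matching array of founder-haplotype ids giving the local
    identity-by-descent lineage of every site (founder f, haplotype h has id
    2*f + h everywhere), used to construct CNV loci in perfect LD with the
    flanking haplotype.
    """

    animals: list[str]
    haps: np.ndarray
    origins: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.haps = np.asarray(self.haps, dtype=np.int8)
        if self.haps.ndim != 3 or self.haps.shape[1] != 2:
            raise ConfigurationError("haps must have shape (n_animals, 2, n_snps)")
        if self.haps.shape[0] != len(self.animals):
            raise ConfigurationError("animal list does not match haplotype array")

    @property
    def n_animals(self) -> int:
        return self.haps.shape[0]

    @property
    def n_snps(self) -> int:
        return self.haps.shape[2]

    def b_freq(self) -> np.ndarray:
        """Realized population B-allele frequency per SNP."""
        return self.haps.mean(axis=(0, 1))

    def genotype_dosage(self) -> np.ndarray:
        """(n_animals, n_snps) int8 dosage of the B allele (0/1/2)."""
        return self.haps.sum(axis=1, dtype=np.int8)

    def subset_snps(self, idx: np.ndarray) -> "HaplotypeSet":
        idx = np.asarray(idx)
        return HaplotypeSet(
            animals=list(self.animals),
            haps=self.haps[:, :, idx],
            origins=None if self.origins is None else self.origins[:, :, idx],
        )

    def animal_index(self) -> dict[str, int]:
        return {a: i for i, a in enumerate(self.animals)}


@dataclass
class SignalSet:
    """Per-animal, per-SNP array signals: LRR, BAF and called genotypes."""

    animals: list[str]
    lrr: np.ndarray
    baf: np.ndarray
    genotypes: np.ndarray

    def __post_init__(self) -> None:
        self.lrr = np.asarray(self.lrr, dtype=np.float64)
        self.baf = np.asarray(self.baf, dtype=np.float64)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        shapes = {self.lrr.shape, self.baf.shape, self.genotypes.shape}
        if len(shapes) != 1:
            raise ConfigurationError("lrr/baf/genotypes shapes differ")
        if self.lrr.shape[0] != len(self.animals):
            raise ConfigurationError("animal list does not match signal arrays")
        if np.nanmin(self.baf, initial=0.0) < 0 or np.nanmax(self.baf, initial=0.0) > 1:
            raise ConfigurationError("BAF outside [0, 1]")

    @property
    def n_animals(self) -> int:
        return self.lrr.shape[0]

    @property
    def n_snps(self) -> int:
        return self.lrr.shape[1]

    def subset_snps(self, idx: np.ndarray) -> "SignalSet":
        idx = np.asarray(idx)
        return SignalSet(
            animals=list(self.animals),
            lrr=self.lrr[:, idx],
            baf=self.baf[:, idx],
            genotypes=self.genotypes[:, idx],
        )

    def copy(self) -> "SignalSet":
        return SignalSet(
            animals=list(self.animals),
            lrr=self.lrr.copy(),
            baf=self.baf.copy(),
            genotypes=self.genotypes.copy(),
        )

    def animal_index(self) -> dict[str, int]:
        return {a: i for i, a in enumerate(self.animals)}

    def pop_b_freq(self) -> np.ndarray:
        """Population B-allele frequency estimated from called genotypes."""
        g = self.genotypes.astype(float)
        g[g < 0] = np.nan
        with np.errstate(invalid="ignore"):
            p = np.nanmean(g, axis=0) / 2.0
        p = np.where(np.isfinite(p), p, 0.5)
        return np.clip(p, 0.01, 0.99)


@dataclass(frozen=True)
class CnvLocus:
    """A planted CNV locus with its per-haplotype allele assignment.

    ``hap_alleles`` is (n_animals, 2) int8 over {N, D, P}; the diploid copy
    number of an animal is ``ALLELE_COPIES[a0] + ALLELE_COPIES[a1]``.
    """

    locus_id: str
    chrom: int
    start_bp: int
    end_bp: int
    hap_alleles: np.ndarray
    ld_mode: str
    snp_indices: tuple[int, ...] = ()

    def copy_numbers(self) -> np.ndarray:
        a = np.asarray(self.hap_alleles, dtype=np.int64)
        return ALLELE_COPIES[a[:, 0]].astype(int) + ALLELE_COPIES[a[:, 1]].astype(int)

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1

    def carrier_mask(self) -> np.ndarray:
        return self.copy_numbers() != 2


def truth_table(loci: Sequence[CnvLocus], animals: Sequence[str]) -> pd.DataFrame:
    """Long-format ground truth: one row per (animal, locus) with true copy number."""
    rows = []
    for loc in loci:
        cns = loc.copy_numbers()
        for a, cn in zip(animals, cns):
            rows.append((a, loc.locus_id, int(cn)))
    return pd.DataFrame(rows, columns=["animal_id", "locus_id", "true_copy_number"])


@dataclass(frozen=True)
class CnvCall:
    """One called CNV segment (1-based closed interval at SNP positions)."""

    animal_id: str
    chrom: int
    start_bp: int
    end_bp: int
    start_snp_index: int
    end_snp_index: int
    copy_number: int
    caller: str
    bayes_factor: Optional[float] = None

    def __post_init__(self) -> None:
        if self.copy_number == 2:
            raise ConfigurationError("a CNV call cannot have copy number 2")
        if self.n_snps < 1:
            raise ConfigurationError("invalid SNP index range in call")

    @property
    def n_snps(self) -> int:
        return self.end_snp_index - self.start_snp_index + 1

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1

    @property
    def length_kb(self) -> float:
        return self.length_bp / 1000.0


def calls_to_frame(calls: Sequence[CnvCall]) -> pd.DataFrame:
    """Tabular view of a call set (empty frame keeps the schema)."""
    cols = [
        "animal_id", "chrom", "start_bp", "end_bp", "start_snp_index",
        "end_snp_index", "copy_number", "n_snps", "caller", "bayes_factor",
    ]
    rows = [
        (
            c.animal_id, c.chrom, c.start_bp, c.end_bp, c.start_snp_index,
            c.end_snp_index, c.copy_number, c.n_snps, c.caller,
            np.nan if c.bayes_factor is None else c.bayes_factor,
        )
        for c in calls
    ]
    return pd.DataFrame(rows, columns=cols)


def frame_to_calls(df: pd.DataFrame) -> list[CnvCall]:
    calls = []
    for _, r in df.iterrows():
        bf = r.get("bayes_factor", np.nan)
        calls.append(
            CnvCall(
                animal_id=str(r["animal_id"]),
                chrom=int(r["chrom"]),
                start_bp=int(r["start_bp"]),
                end_bp=int(r["end_bp"]),
                start_snp_index=int(r["start_snp_index"]),
                end_snp_index=int(r["end_snp_index"]),
                copy_number=int(r["copy_number"]),
                caller=str(r["caller"]),
                bayes_factor=None if pd.isna(bf) else float(bf),
            )
        )
    return calls
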
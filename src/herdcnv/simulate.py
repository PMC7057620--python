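"""Synthetic pedigreed population, SNP panels, planted CNVs and array signals.

The generator emulates the data a SNP-array CNV study runs on: a pedigreed
(multi-)breed population genotyped on a high-density autosomal panel with a
nested medium-density subset, per-SNP LRR/BAF intensities with a
GC-correlated wave, planted deletion/duplication loci (diploid copy numbers
0..4, each spanning at least three HD SNPs) whose linkage with the flanking
haplotype is controllable, and genotype defects (missingness, Mendelian
inconsistencies) to exercise SNP quality control.

LRR is the log-ratio of observed to expected probe intensity (0 for two
copies); BAF is the proportion of B alleles at the SNP, so with copy number
``cn`` and ``b`` B copies the BAF clusters at ``b/cn`` (uniform when both
copies are deleted and no probe hybridizes).
"""

from __future__ import annotations

import logging
import math
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .types import (
    ALLELE_COPIES,
    ALLELE_D,
    ALLELE_N,
    ALLELE_P,
    ConfigurationError,
    CnvLocus,
    HaplotypeSet,
    Pedigree,
    PipelineError,
    SignalSet,
    SimulationError,
    SnpMap,
    UNKNOWN_PARENT,
    truth_table,
)

logger = logging.getLogger(__name__)

# PennCNV-convention per-state signal model (copy numbers 0..4); fully
# configurable, chosen for realistic separation between states.
DEFAULT_STATE_LRR_MEANS = (-3.5, -0.66, 0.0, 0.40, 0.68)
DEFAULT_STATE_LRR_SDS = (1.3, 0.28, 0.21, 0.21, 0.26)
DEFAULT_BAF_SD = 0.04


# ---------------------------------------------------------------------------
# pedigree
# ---------------------------------------------------------------------------

def simulate_pedigree(
    n_founders: int,
    n_generations: int,
    offspring_per_mating: int = 2,
    seed: int = 0,
    breed: str = "SIM",
) -> Pedigree:
    """Random-mating pedigree: founders plus ``n_generations`` cohorts.

    Each generation forms ``n_founders // 2`` sire x dam pairs sampled from
    the previous generation and produces ``offspring_per_mating`` offspring
    per pair. Founders have unknown parents; ``birth_order`` is a total
    order consistent with generations.
    """
    if n_founders < 2:
        raise ConfigurationError("need at least 2 founders to mate")
    if n_generations < 0:
        raise ConfigurationError("n_generations must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    counter = 0

    def new_id() -> str:
        nonlocal counter
        counter += 1
        return f"{breed}_{counter:05d}"

    birth = 0
    prev_gen: list[tuple[str, int]] = []  # (animal_id, sex) sex: 0 male 1 female
    for i in range(n_founders):
        aid = new_id()
        rows.append((aid, UNKNOWN_PARENT, UNKNOWN_PARENT, birth, breed))
        prev_gen.append((aid, i % 2))
        birth += 1

    n_matings = max(1, n_founders // 2)
    for _ in range(n_generations):
        males = [a for a, s in prev_gen if s == 0]
        females = [a for a, s in prev_gen if s == 1]
        if not males or not females:
            raise ConfigurationError("impossible mating structure: a generation lacks one sex")
        cur_gen: list[tuple[str, int]] = []
        for _ in range(n_matings):
            sire = males[rng.integers(len(males))]
            dam = females[rng.integers(len(females))]
            for _ in range(offspring_per_mating):
                aid = new_id()
                rows.append((aid, sire, dam, birth, breed))
                cur_gen.append((aid, int(rng.integers(2))))
                birth += 1
        if cur_gen:
            prev_gen = cur_gen
    return Pedigree(
        pd.DataFrame(rows, columns=["animal_id", "sire_id", "dam_id", "birth_order", "breed"])
    )


# ---------------------------------------------------------------------------
# SNP map
# ---------------------------------------------------------------------------

def simulate_snp_map(
    n_chrom: int = 3,
    snps_per_chrom: int = 5000,
    chrom_length_bp: int = 100_000_000,
    seed: int = 0,
    gc_range: tuple[float, float] = (0.30, 0.60),
    gc_autocorr: float = 0.995,
) -> SnpMap:
    """Autosomal SNP map with a smooth autocorrelated GC track.

    The GC fraction of the +/-500 kb window around each SNP is emulated as an
    AR(1) series squashed into ``gc_range``; only its correlation structure
    with LRR matters to the GC-wave adjustment, not real genome content.
    """
    if n_chrom < 1 or snps_per_chrom < 1:
        raise ConfigurationError("need at least one chromosome and one SNP")
    rng = np.random.default_rng(seed)
    frames = []
    for c in range(1, n_chrom + 1):
        n = snps_per_chrom
        u = np.sort(rng.random(n))
        pos = (u * (chrom_length_bp - n)).astype(np.int64) + np.arange(n) + 1
        x = np.empty(n)
        x[0] = rng.standard_normal()
        eps = rng.standard_normal(n) * math.sqrt(1 - gc_autocorr**2)
        for i in range(1, n):
            x[i] = gc_autocorr * x[i - 1] + eps[i]
        lo, hi = gc_range
        mid, amp = (lo + hi) / 2.0, (hi - lo) / 2.0
        gc = mid + amp * np.tanh(x / 2.0)
        frames.append(
            pd.DataFrame(
                {
                    "snp_id": [f"snp_{c}_{i:06d}" for i in range(n)],
                    "chrom": c,
                    "pos_bp": pos,
                    "on_md_panel": False,
                    "gc_frac": gc,
                }
            )
        )
    return SnpMap(pd.concat(frames, ignore_index=True))


# ---------------------------------------------------------------------------
# haplotypes
# ---------------------------------------------------------------------------

def _draw_freqs(maf_spectrum, n: int, rng: np.random.Generator) -> np.ndarray:
    kind = maf_spectrum[0]
    if kind == "uniform":
        lo, hi = maf_spectrum[1], maf_spectrum[2]
        maf = rng.uniform(lo, hi, size=n)
    elif kind == "point":
        maf = np.full(n, float(maf_spectrum[1]))
    elif kind == "beta":
        maf = rng.beta(maf_spectrum[1], maf_spectrum[2], size=n) * 0.5
    else:
        raise ConfigurationError(f"unknown maf_spectrum kind {kind!r}")
    # B allele is the minor allele with probability 1/2
    flip = rng.random(n) < 0.5
    return np.where(flip, maf, 1.0 - maf)


def simulate_haplotypes(
    ped: Pedigree,
    snp_map: SnpMap,
    recomb_rate_per_mb: float = 0.01,
    maf_spectrum=("uniform", 0.05, 0.5),
    seed: int = 0,
) -> HaplotypeSet:
    """Founder haplotypes from per-SNP frequencies; descent with crossovers.

    Founder haplotype alleles are independent Bernoulli draws from per-SNP
    B-allele frequencies sampled from ``maf_spectrum``; non-founder
    haplotypes are recombinant mosaics of the two parental haplotypes with
    Poisson crossovers at ``recomb_rate_per_mb`` per megabase. A parallel
    array of founder-haplotype origins is tracked so downstream code can
    place CNV alleles in perfect linkage with a local haplotype lineage.
    """
    if snp_map.n_snps == 0:
        raise ConfigurationError("empty SNP map")
    if recomb_rate_per_mb < 0:
        raise ConfigurationError("recomb_rate_per_mb must be >= 0")
    rng = np.random.default_rng(seed)
    n_snps = snp_map.n_snps
    freqs = _draw_freqs(maf_spectrum, n_snps, rng)

    order = ped.table.sort_values("birth_order")
    animals = list(order["animal_id"])
    idx_of = {a: i for i, a in enumerate(animals)}
    haps = np.zeros((len(animals), 2, n_snps), dtype=np.int8)
    origins = np.zeros((len(animals), 2, n_snps), dtype=np.int32)

    chrom_slices = []
    for c in snp_map.chroms():
        ci = snp_map.chrom_indices(c)
        chrom_slices.append((ci, snp_map.pos_bp[ci]))

    founder_count = 0
    for _, row in order.iterrows():
        i = idx_of[row["animal_id"]]
        if row["sire_id"] == UNKNOWN_PARENT or row["dam_id"] == UNKNOWN_PARENT:
            for h in range(2):
                haps[i, h] = (rng.random(n_snps) < freqs).astype(np.int8)
                origins[i, h] = 2 * founder_count + h
            founder_count += 1
        else:
            for h, parent in enumerate((row["sire_id"], row["dam_id"])):
                p = idx_of[parent]
                for ci, pos in chrom_slices:
                    length_mb = (pos[-1] - pos[0]) / 1e6 if len(pos) > 1 else 0.0
                    n_x = rng.poisson(recomb_rate_per_mb * length_mb)
                    start_hap = int(rng.integers(2))
                    if n_x == 0:
                        sel = np.full(len(ci), start_hap)
                    else:
                        breaks = np.sort(rng.uniform(pos[0], pos[-1], size=n_x))
                        sel = (start_hap + np.searchsorted(breaks, pos)) % 2
                    take0 = sel == 0
                    haps[i, h, ci] = np.where(take0, haps[p, 0, ci], haps[p, 1, ci])
                    origins[i, h, ci] = np.where(take0, origins[p, 0, ci], origins[p, 1, ci])
    return HaplotypeSet(animals=animals, haps=haps, origins=origins)


# ---------------------------------------------------------------------------
# CNV planting
# ---------------------------------------------------------------------------

def _draw_interval(snp_map: SnpMap, length_dist, min_snps: int, rng) -> Optional[tuple]:
    chroms = snp_map.chroms()
    c = chroms[int(rng.integers(len(chroms)))]
    ci = snp_map.chrom_indices(c)
    pos = snp_map.pos_bp[ci]
    kind = length_dist[0]
    if kind == "snps":
        n = int(length_dist[1])
        if n < min_snps or n > len(ci):
            return None
        i0 = int(rng.integers(len(ci) - n + 1))
        idx = ci[i0 : i0 + n]
        return c, int(pos[i0]), int(pos[i0 + n - 1]), idx
    if kind == "lognormal":
        length = int(rng.lognormal(length_dist[1], length_dist[2]))
    elif kind == "uniform":
        length = int(rng.uniform(length_dist[1], length_dist[2]))
    elif kind == "point":
        length = int(length_dist[1])
    else:
        raise ConfigurationError(f"unknown length_dist kind {kind!r}")
    length = max(length, 1)
    center = int(rng.uniform(pos[0], pos[-1]))
    start = max(1, center - length // 2)
    end = start + length - 1
    idx = snp_map.snps_in_interval(c, start, end)
    if len(idx) < min_snps:
        return None
    return c, start, end, idx


def _origin_carrier_fracs(origins_mid: np.ndarray) -> dict[int, float]:
    """Animal carrier fraction for each founder-haplotype origin at a site."""
    n_animals = origins_mid.shape[0]
    fracs = {}
    for o in np.unique(origins_mid):
        carrier = (origins_mid == o).any(axis=1)
        fracs[int(o)] = carrier.sum() / n_animals
    return fracs


def plant_cnv_loci(
    snp_map: SnpMap,
    haps: HaplotypeSet,
    n_loci: int,
    length_dist=("lognormal", math.log(50_000.0), 0.6),
    freq_range: tuple[float, float] = (0.05, 0.30),
    allele_set: Union[tuple, Sequence[tuple]] = ("N", "D"),
    ld_mode: Union[str, tuple, Sequence] = "perfect",
    min_snps: int = 3,
    seed: int = 0,
    max_tries: int = 500,
) -> tuple[list[CnvLocus], pd.DataFrame]:
    """Plant non-overlapping CNV loci with controllable frequency and LD.

    ``ld_mode`` per locus is ``"perfect"`` (the CNV allele rides exactly one
    founder-haplotype lineage, so the local flanking haplotype identifies
    carriers), ``"independent"`` (allele assigned independently of the
    flanking alleles) or ``("tagged", r)`` (carrier status correlates with a
    lineage indicator with correlation about ``r``). ``freq_range`` bounds
    the realized fraction of animals whose diploid copy number differs
    from 2. Intervals must span at least ``min_snps`` HD SNPs (redrawn
    otherwise). Returns the loci plus a long-format truth table.
    """
    if min_snps < 3:
        raise ConfigurationError("CNV loci must span at least 3 SNPs")
    rng = np.random.default_rng(seed)
    n_animals = haps.n_animals
    if haps.origins is None:
        raise ConfigurationError("haplotypes must carry origin tracking to plant CNVs")

    if allele_set and isinstance(allele_set[0], (tuple, list)):
        allele_sets = [tuple(a) for a in allele_set]
    else:
        allele_sets = [tuple(allele_set)] * n_loci
    if isinstance(ld_mode, (str, tuple)) and (
        isinstance(ld_mode, str) or (len(ld_mode) == 2 and ld_mode[0] == "tagged")
    ):
        ld_modes = [ld_mode] * n_loci
    else:
        ld_modes = list(ld_mode)
    if len(allele_sets) < n_loci:
        allele_sets = [allele_sets[i % len(allele_sets)] for i in range(n_loci)]
    if len(ld_modes) < n_loci:
        ld_modes = [ld_modes[i % len(ld_modes)] for i in range(n_loci)]

    loci: list[CnvLocus] = []
    used: list[tuple[int, int, int]] = []
    lo, hi = freq_range
    for li in range(n_loci):
        aset = tuple(allele_sets[li])
        mode = ld_modes[li]
        placed = False
        for _ in range(max_tries):
            drawn = _draw_interval(snp_map, length_dist, min_snps, rng)
            if drawn is None:
                continue
            c, start, end, idx = drawn
            if any(uc == c and not (end < us or start > ue) for uc, us, ue in used):
                continue
            mid_idx = idx[len(idx) // 2]
            hap_alleles = _assign_alleles(
                haps, mid_idx, aset, mode, (lo, hi), rng, n_animals
            )
            if hap_alleles is None:
                continue
            mode_name = mode if isinstance(mode, str) else f"tagged_r{mode[1]:g}"
            loci.append(
                CnvLocus(
                    locus_id=f"cnv{li:03d}",
                    chrom=c,
                    start_bp=start,
                    end_bp=end,
                    hap_alleles=hap_alleles,
                    ld_mode=mode_name,
                    snp_indices=tuple(int(j) for j in idx),
                )
            )
            used.append((c, start, end))
            placed = True
            break
        if not placed:
            raise SimulationError(
                f"could not place locus {li}: frequency range {freq_range} unattainable "
                f"with population size {n_animals} after {max_tries} tries"
            )
    return loci, truth_table(loci, haps.animals)


def _assign_alleles(haps, mid_idx, aset, mode, freq_range, rng, n_animals):
    """(n_animals, 2) allele codes for one locus, or None to redraw."""
    lo, hi = freq_range
    cnv_codes = [code for name, code in (("D", ALLELE_D), ("P", ALLELE_P)) if name in aset]
    if not cnv_codes or "N" not in aset:
        raise ConfigurationError("allele_set must contain N plus at least one of D, P")
    origins_mid = haps.origins[:, :, mid_idx]
    alleles = np.full((n_animals, 2), ALLELE_N, dtype=np.int8)

    def lineage_mask() -> Optional[np.ndarray]:
        fracs = _origin_carrier_fracs(origins_mid)
        target_lo, target_hi = (lo, hi) if len(cnv_codes) == 1 else (lo / 2, hi / 2)
        cands = [o for o, f in fracs.items() if target_lo <= f <= target_hi]
        if len(cands) < len(cnv_codes):
            return None
        chosen = rng.choice(cands, size=len(cnv_codes), replace=False)
        return np.stack([(origins_mid == o) for o in chosen])  # (n_codes, A, 2)

    if mode == "perfect":
        masks = lineage_mask()
        if masks is None:
            return None
        for code, m in zip(cnv_codes, masks):
            alleles[m] = code
    elif mode == "independent":
        f = rng.uniform(lo, hi)
        q = 1.0 - math.sqrt(max(0.0, 1.0 - f))
        n_hap = max(1, int(round(q * 2 * n_animals)))
        flat = rng.choice(2 * n_animals, size=min(n_hap, 2 * n_animals), replace=False)
        for k, j in enumerate(flat):
            alleles[j // 2, j % 2] = cnv_codes[k % len(cnv_codes)]
    elif isinstance(mode, tuple) and mode[0] == "tagged":
        r = float(mode[1])
        masks = lineage_mask()
        if masks is None:
            return None
        for code, m in zip(cnv_codes, masks):
            z = m.astype(float)
            p_base = z.mean()
            keep = rng.random(z.shape) < r
            rand = rng.random(z.shape) < p_base
            y = np.where(keep, z > 0.5, rand)
            alleles[y] = code
    else:
        raise ConfigurationError(f"unknown ld_mode {mode!r}")

    cn = ALLELE_COPIES[alleles[:, 0]].astype(int) + ALLELE_COPIES[alleles[:, 1]].astype(int)
    frac = (cn != 2).mean()
    if not (lo <= frac <= hi):
        return None
    return alleles


# ---------------------------------------------------------------------------
# signals
# ---------------------------------------------------------------------------

def render_signals(
    haps: HaplotypeSet,
    loci: Sequence[CnvLocus],
    snp_map: SnpMap,
    state_lrr_means: Sequence[float] = DEFAULT_STATE_LRR_MEANS,
    state_lrr_sds: Sequence[float] = DEFAULT_STATE_LRR_SDS,
    baf_sd: float = DEFAULT_BAF_SD,
    gc_wave_coef: float = 0.0,
    seed: int = 0,
) -> SignalSet:
    """Render LRR/BAF signals and genotype calls from haplotypes plus CNVs.

    LRR at SNP *i* for an animal with local copy number ``cn`` is
    ``state_lrr_means[cn] + gc_wave_coef * (gc_i - mean(gc)) + noise`` with
    per-state Gaussian noise; BAF concentrates at ``b/cn`` for ``b`` B-allele
    copies (uniform on [0,1] at cn = 0), truncated to [0,1]. Genotype calls
    come from the two underlying SNP alleles.
    """
    means = np.asarray(state_lrr_means, dtype=float)
    sds = np.asarray(state_lrr_sds, dtype=float)
    if means.shape != (5,) or sds.shape != (5,):
        raise ConfigurationError("state_lrr_means and state_lrr_sds must have 5 entries (cn 0..4)")
    if (sds <= 0).any() or baf_sd < 0:
        raise ConfigurationError("noise scales must be positive")
    rng = np.random.default_rng(seed)
    A, S = haps.n_animals, haps.n_snps

    copies0 = np.ones((A, S), dtype=np.int8)
    copies1 = np.ones((A, S), dtype=np.int8)
    for loc in loci:
        idx = np.asarray(loc.snp_indices)
        a = np.asarray(loc.hap_alleles)
        copies0[:, idx] = ALLELE_COPIES[a[:, 0]][:, None]
        copies1[:, idx] = ALLELE_COPIES[a[:, 1]][:, None]
    cn = (copies0 + copies1).astype(np.int8)
    b = copies0 * haps.haps[:, 0] + copies1 * haps.haps[:, 1]

    gc = snp_map.gc_frac
    lrr = means[cn] + gc_wave_coef * (gc - gc.mean())[None, :]
    lrr = lrr + rng.standard_normal((A, S)) * sds[cn]

    with np.errstate(divide="ignore", invalid="ignore"):
        mean_baf = np.where(cn > 0, b / np.maximum(cn, 1), 0.5)
    baf = mean_baf + rng.standard_normal((A, S)) * baf_sd
    zero = cn == 0
    if zero.any():
        baf[zero] = rng.random(int(zero.sum()))
    baf = np.clip(baf, 0.0, 1.0)

    genotypes = haps.genotype_dosage()
    return SignalSet(animals=list(haps.animals), lrr=lrr, baf=baf, genotypes=genotypes)


# ---------------------------------------------------------------------------
# defects and QC
# ---------------------------------------------------------------------------

def inject_defects(
    signals: SignalSet,
    ped: Pedigree,
    missing_rate: float = 0.0,
    mendel_error_rate: float = 0.0,
    mendel_pair_frac: float = 0.05,
    seed: int = 0,
) -> SignalSet:
    """Inject missing genotype calls and Mendelian inconsistencies.

    ``missing_rate`` is the per-cell probability a genotype call is set
    missing; ``mendel_error_rate`` is the fraction of SNPs that receive
    planted opposing-homozygote conflicts in ``mendel_pair_frac`` of the
    parent-progeny pairs (the default exceeds the 2% QC threshold so planted
    SNPs are removable by the filter).
    """
    if not (0 <= missing_rate <= 1 and 0 <= mendel_error_rate <= 1 and 0 <= mendel_pair_frac <= 1):
        raise ConfigurationError("rates must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    out = signals.copy()
    if mendel_error_rate > 0:
        pairs = ped.parent_progeny_pairs()
        aidx = out.animal_index()
        pairs_idx = [(aidx[p], aidx[c]) for p, c in pairs if p in aidx and c in aidx]
        if pairs_idx:
            n_bad = int(round(mendel_error_rate * out.n_snps))
            bad_snps = rng.choice(out.n_snps, size=n_bad, replace=False)
            n_pair = max(1, math.ceil(mendel_pair_frac * len(pairs_idx)))
            for j in bad_snps:
                sel = rng.choice(len(pairs_idx), size=min(n_pair, len(pairs_idx)), replace=False)
                for s in sel:
                    p, c = pairs_idx[s]
                    out.genotypes[p, j] = 0
                    out.genotypes[c, j] = 2
    if missing_rate > 0:
        mask = rng.random(out.genotypes.shape) < missing_rate
        out.genotypes[mask] = -1
    return out


def filter_snps(
    signals: SignalSet,
    snp_map: SnpMap,
    ped: Pedigree,
    min_call_rate: float = 0.95,
    max_mendel_pair_frac: float = 0.02,
) -> tuple[SnpMap, SignalSet]:
    """SNP quality control: call-rate and Mendelian-consistency filters.

    Removes SNPs with a call rate below ``min_call_rate`` and SNPs whose
    genotypes are opposing-homozygote inconsistent in more than
    ``max_mendel_pair_frac`` of the parent-progeny pairs (fraction over
    pairs where both members are genotyped). Ordering is preserved; the map
    is already restricted to placed autosomal SNPs by construction.
    """
    g = signals.genotypes
    call_rate = (g >= 0).mean(axis=0)
    keep = call_rate >= min_call_rate

    pairs = ped.parent_progeny_pairs()
    aidx = signals.animal_index()
    pairs_idx = [(aidx[p], aidx[c]) for p, c in pairs if p in aidx and c in aidx]
    if not pairs_idx:
        logger.warning("no parent-progeny pairs available; Mendelian filter skipped")
    else:
        opp = np.zeros(signals.n_snps, dtype=np.int64)
        valid = np.zeros(signals.n_snps, dtype=np.int64)
        for p, c in pairs_idx:
            gp, gc = g[p], g[c]
            both = (gp >= 0) & (gc >= 0)
            valid += both
            opp += both & (((gp == 0) & (gc == 2)) | ((gp == 2) & (gc == 0)))
        with np.errstate(invalid="ignore"):
            frac = np.where(valid > 0, opp / np.maximum(valid, 1), 0.0)
        keep &= frac <= max_mendel_pair_frac
    if not keep.any():
        raise PipelineError("all SNPs removed by QC filters")
    idx = np.flatnonzero(keep)
    return snp_map.subset(idx), signals.subset_snps(idx)


# ---------------------------------------------------------------------------
# MD panel
# ---------------------------------------------------------------------------

def make_md_subset(
    snp_map: SnpMap,
    md: Union[float, Sequence[str]] = 45_677 / 713_162,
    seed: int = 0,
) -> SnpMap:
    """Flag a nested medium-density subset of the HD map.

    ``md`` is either an explicit list of SNP ids (emulating a commercial
    medium-density manifest) or a target fraction, realized as a seeded
    even thinning keeping exactly ``floor(fraction * n)`` SNPs.
    """
    t = snp_map.table.copy()
    if isinstance(md, (float, int)):
        frac = float(md)
        if not (0 < frac <= 1):
            raise ConfigurationError("md fraction must be in (0, 1]")
        n = len(t)
        m = int(math.floor(frac * n))
        if m < 1:
            raise ConfigurationError("md fraction keeps no SNPs")
        rng = np.random.default_rng(seed)
        u = rng.random()
        idx = np.floor((np.arange(m) + u) * n / m).astype(np.int64)
        idx = np.clip(idx, 0, n - 1)
        flags = np.zeros(n, dtype=bool)
        flags[idx] = True
        t["on_md_panel"] = flags
    else:
        wanted = set(md)
        known = set(t["snp_id"])
        absent = sorted(wanted - known)
        if absent:
            raise ConfigurationError(f"SNP(s) not on the HD map: {absent[:5]}")
        t["on_md_panel"] = t["snp_id"].isin(wanted).values
    return SnpMap(t)
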
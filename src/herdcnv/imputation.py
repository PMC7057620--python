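"""CNV imputation from flanking SNP haplotypes.

The experiment follows the array-CNV imputation design: CNVs called by both
caller personalities on the same animal (endpoint SNP indices allowed to
differ by one) form the consensus set; consensus CNVs are grouped into
population-level loci and loci carried by at least ``min_carriers`` animals
in a breed are selected; each selected CNV is recoded as a variant at the
CNV midpoint -- tri-allelic (alleles normal/deletion/duplication, genotype
pairs mapping to copy numbers 0..4) or bi-allelic with deletions and
duplications imputed separately; the marker is imputed from the ``k``
nearest SNPs on each side of the midpoint using the oldest 80% of animals
(by birth order, within breed) as the reference population.

The imputer is an internal diploid haplotype-copying model evaluated on the
flank window with the marker as one extra, unobserved column. Two presets
share the contract: ``hmm`` computes the forward--backward posterior of a
Li--Stephens-style mosaic-copying model (switch rate per window SNP,
genotype error rate) and returns the posterior-mode allele pair;
``window`` scores every reference haplotype pair by squared dosage error
over the window and takes a softmax-weighted vote. Both are deterministic
given their inputs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .types import (
    ALLELE_COPIES,
    ALLELE_D,
    ALLELE_N,
    ALLELE_P,
    ConfigurationError,
    CnvCall,
    CnvLocus,
    HaplotypeSet,
    Pedigree,
    SnpMap,
)

logger = logging.getLogger(__name__)

MODES = ("triallelic", "biallelic_del", "biallelic_dup")
FLANK_K_GRID = (10, 25, 50, 100, 250, 500)

#: copy number -> unordered allele pair (codes ascending), tri-allelic mode
CN_TO_PAIR_TRIALLELIC = {
    0: (ALLELE_D, ALLELE_D),
    1: (ALLELE_N, ALLELE_D),
    2: (ALLELE_N, ALLELE_N),
    3: (ALLELE_N, ALLELE_P),
    4: (ALLELE_P, ALLELE_P),
}


def pair_to_cn(pair: Sequence[int]) -> int:
    """Diploid copy number implied by an allele pair."""
    return int(ALLELE_COPIES[pair[0]]) + int(ALLELE_COPIES[pair[1]])


def encode_pair(cn: int, mode: str = "triallelic") -> tuple[int, int]:
    """Copy number -> allele pair under the chosen encoding.

    ``biallelic_del`` sees only deletions (duplications collapse to
    normal/normal); ``biallelic_dup`` the reverse.
    """
    if cn not in (0, 1, 2, 3, 4):
        raise ConfigurationError(f"copy number {cn!r} outside 0..4")
    if mode == "triallelic":
        return CN_TO_PAIR_TRIALLELIC[cn]
    if mode == "biallelic_del":
        return {0: (ALLELE_D, ALLELE_D), 1: (ALLELE_N, ALLELE_D)}.get(cn, (ALLELE_N, ALLELE_N))
    if mode == "biallelic_dup":
        return {4: (ALLELE_P, ALLELE_P), 3: (ALLELE_N, ALLELE_P)}.get(cn, (ALLELE_N, ALLELE_N))
    raise ConfigurationError(f"unknown encoding mode {mode!r}")


def _project_allele(a: int, mode: str) -> int:
    if mode == "biallelic_del":
        return ALLELE_N if a == ALLELE_P else a
    if mode == "biallelic_dup":
        return ALLELE_N if a == ALLELE_D else a
    return a


# ---------------------------------------------------------------------------
# consensus
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConsensusCnv:
    """A CNV called by both callers on one animal (merged interval = union)."""

    animal_id: str
    chrom: int
    start_bp: int
    end_bp: int
    start_snp_index: int
    end_snp_index: int
    copy_number: int
    penn_call: CnvCall
    quanti_call: CnvCall

    @property
    def bayes_factor(self) -> Optional[float]:
        return self.quanti_call.bayes_factor

    @property
    def length_kb(self) -> float:
        return (self.end_bp - self.start_bp + 1) / 1000.0


def consensus_calls(
    penn_calls: Sequence[CnvCall],
    quanti_calls: Sequence[CnvCall],
    snp_tolerance: int = 1,
) -> list[ConsensusCnv]:
    """Match calls made by both callers on the same animal and chromosome.

    Two calls match when both endpoint SNP indices differ by at most
    ``snp_tolerance`` (default one SNP) and the copy numbers agree. Matching
    is greedy by start position (nearest candidate by total endpoint
    discrepancy, ties to the leftmost), each call used at most once; the
    merged interval is the union of the two. Symmetric in its inputs.
    """
    by_key: dict[tuple[str, int], list[CnvCall]] = {}
    for q in quanti_calls:
        by_key.setdefault((q.animal_id, q.chrom), []).append(q)
    for v in by_key.values():
        v.sort(key=lambda c: (c.start_bp, c.end_bp))

    out = []
    for p in sorted(penn_calls, key=lambda c: (c.animal_id, c.chrom, c.start_bp, c.end_bp)):
        cands = by_key.get((p.animal_id, p.chrom), [])
        best = None
        best_score = None
        for q in cands:
            ds = abs(q.start_snp_index - p.start_snp_index)
            de = abs(q.end_snp_index - p.end_snp_index)
            if ds <= snp_tolerance and de <= snp_tolerance and q.copy_number == p.copy_number:
                score = (ds + de, q.start_bp)
                if best_score is None or score < best_score:
                    best, best_score = q, score
        if best is not None:
            cands.remove(best)
            out.append(
                ConsensusCnv(
                    animal_id=p.animal_id,
                    chrom=p.chrom,
                    start_bp=min(p.start_bp, best.start_bp),
                    end_bp=max(p.end_bp, best.end_bp),
                    start_snp_index=min(p.start_snp_index, best.start_snp_index),
                    end_snp_index=max(p.end_snp_index, best.end_snp_index),
                    copy_number=p.copy_number,
                    penn_call=p,
                    quanti_call=best,
                )
            )
    return out


# ---------------------------------------------------------------------------
# locus grouping and selection
# ---------------------------------------------------------------------------

@dataclass
class GroupedLocus:
    """A population-level CNV locus: identical consensus region across animals."""

    locus_id: str
    chrom: int
    start_bp: int
    end_bp: int
    called_cn: dict[str, int]  # carriers only; everyone else is copy number 2
    bayes_factors: dict[str, float] = field(default_factory=dict)

    @property
    def length_kb(self) -> float:
        return (self.end_bp - self.start_bp + 1) / 1000.0

    @property
    def midpoint_bp(self) -> int:
        return (self.start_bp + self.end_bp) // 2

    def carrier_count(self, animals: Optional[Sequence[str]] = None) -> int:
        if animals is None:
            return len(self.called_cn)
        pool = set(animals)
        return sum(1 for a in self.called_cn if a in pool)

    def copy_number_of(self, animal: str) -> int:
        return self.called_cn.get(animal, 2)


def group_loci(
    consensus: Sequence[ConsensusCnv], bp_tolerance: int = 0
) -> list[GroupedLocus]:
    """Group consensus CNVs into loci by region.

    Default grouping is exact (chrom, start, end) identity; with
    ``bp_tolerance > 0`` regions whose endpoints each differ by at most the
    tolerance are chained into one locus (anchored at the first-seen region).
    """
    loci: list[GroupedLocus] = []
    for c in sorted(consensus, key=lambda x: (x.chrom, x.start_bp, x.end_bp, x.animal_id)):
        home = None
        for loc in loci:
            if (
                loc.chrom == c.chrom
                and abs(loc.start_bp - c.start_bp) <= bp_tolerance
                and abs(loc.end_bp - c.end_bp) <= bp_tolerance
            ):
                home = loc
                break
        if home is None:
            home = GroupedLocus(
                locus_id=f"locus_{len(loci):04d}",
                chrom=c.chrom,
                start_bp=c.start_bp,
                end_bp=c.end_bp,
                called_cn={},
            )
            loci.append(home)
        home.called_cn[c.animal_id] = c.copy_number
        if c.bayes_factor is not None:
            home.bayes_factors[c.animal_id] = c.bayes_factor
    return loci


def group_loci_and_select(
    consensus: Sequence[ConsensusCnv],
    ped: Pedigree,
    min_carriers: int = 30,
    bp_tolerance: int = 0,
) -> dict[str, list[GroupedLocus]]:
    """Per breed, the loci carried by at least ``min_carriers`` animals."""
    grouped = group_loci(consensus, bp_tolerance)
    out: dict[str, list[GroupedLocus]] = {}
    for breed in ped.breeds():
        animals = ped.breed_animals(breed)
        sel = [g for g in grouped if g.carrier_count(animals) >= min_carriers]
        if not sel:
            logger.warning("no locus reaches %d carriers in breed %s", min_carriers, breed)
        out[breed] = sel
    return out


# ---------------------------------------------------------------------------
# flanks and reference split
# ---------------------------------------------------------------------------

def extract_flanks(
    snp_map: SnpMap, chrom: int, midpoint_bp: int, k: int
) -> tuple[np.ndarray, int, int]:
    """The ``k`` nearest SNPs strictly left and right of the midpoint.

    Returns (sorted indices into the map, n_left, n_right). A chromosome
    end may truncate a side (logged); SNPs inside the CNV are eligible by
    design, since the window flanks the midpoint, not the endpoints.
    """
    if k < 1:
        raise ConfigurationError("k must be >= 1")
    ci = snp_map.chrom_indices(chrom)
    pos = snp_map.pos_bp[ci]
    split = int(np.searchsorted(pos, midpoint_bp, side="left"))
    # SNP exactly at the midpoint belongs to the right side
    left = ci[max(0, split - k) : split]
    right = ci[split : split + k]
    if len(left) < k or len(right) < k:
        logger.info(
            "flank window truncated at chromosome end: %d left, %d right (k=%d)",
            len(left), len(right), k,
        )
    return np.concatenate([left, right]), len(left), len(right)


def split_reference_validation(
    ped: Pedigree, breed: str, frac_reference: float = 0.8
) -> tuple[list[str], list[str]]:
    """Oldest 80% (by birth order, within breed) as reference, rest validation."""
    animals = ped.breed_animals(breed)
    n = len(animals)
    if n < 5:
        raise ConfigurationError(f"breed {breed!r} has {n} animals; need at least 5 to split")
    n_ref = math.ceil(frac_reference * n)
    return animals[:n_ref], animals[n_ref:]


# ---------------------------------------------------------------------------
# marker phasing for the reference panel
# ---------------------------------------------------------------------------

def phase_marker_alleles(
    called_cn: np.ndarray,
    mode: str = "triallelic",
    truth_locus: Optional[CnvLocus] = None,
) -> np.ndarray:
    """(n, 2) phased marker alleles for reference animals.

    The unordered pair comes from the called copy number under ``mode``;
    orientation onto haplotypes uses the simulator's true phase when it is
    consistent with the called pair, otherwise the non-normal allele goes
    deterministically on the first haplotype (orientation only matters for
    heterozygotes).
    """
    n = len(called_cn)
    out = np.zeros((n, 2), dtype=np.int8)
    truth = None if truth_locus is None else np.asarray(truth_locus.hap_alleles)
    for i, cn in enumerate(called_cn):
        pair = encode_pair(int(cn), mode)
        if truth is not None:
            t = (_project_allele(int(truth[i, 0]), mode), _project_allele(int(truth[i, 1]), mode))
            if tuple(sorted(t)) == tuple(sorted(pair)):
                out[i] = t
                continue
        out[i] = sorted(pair, reverse=True)  # non-N allele first
    return out


def flag_marker_conflicts(
    marker_pairs: dict[str, tuple[int, int]], ped: Pedigree
) -> list[tuple[str, str]]:
    """Parent-progeny pairs whose marker genotypes share no allele.

    Such opposing-homozygote conflicts cannot both be true under Mendelian
    inheritance and typically flag false CNV calls; they are reported, never
    auto-corrected.
    """
    conflicts = []
    for parent, child in ped.parent_progeny_pairs():
        if parent in marker_pairs and child in marker_pairs:
            if not set(marker_pairs[parent]) & set(marker_pairs[child]):
                conflicts.append((parent, child))
    return conflicts


# ---------------------------------------------------------------------------
# the imputer
# ---------------------------------------------------------------------------

def _subsample_haps(n_haps: int, max_haps: int) -> np.ndarray:
    if n_haps <= max_haps:
        return np.arange(n_haps)
    # deterministic even thinning keeps panel diversity without a seed
    return np.unique(np.linspace(0, n_haps - 1, max_haps).round().astype(int))


def _class_weights(P: np.ndarray, marker_alleles: np.ndarray) -> np.ndarray:
    """Aggregate a (V, H, H) pair weight array into (V, 3, 3) allele classes."""
    M = np.zeros((len(marker_alleles), 3))
    M[np.arange(len(marker_alleles)), marker_alleles] = 1.0
    return np.einsum("vjk,ja,kb->vab", P, M, M, optimize=True)


def _mode_pairs(W: np.ndarray) -> np.ndarray:
    """(V, 2) posterior-mode unordered allele pair from (V, 3, 3) weights."""
    V = W.shape[0]
    pairs = [(a, b) for a in range(3) for b in range(a, 3)]
    scores = np.stack(
        [W[:, a, b] + (W[:, b, a] if a != b else 0.0) for a, b in pairs], axis=1
    )
    best = scores.argmax(axis=1)
    return np.array([pairs[i] for i in best], dtype=np.int8)


def impute_marker(
    ref_flank_haps: np.ndarray,
    ref_marker_alleles: np.ndarray,
    val_flank_genotypes: np.ndarray,
    marker_insert_pos: int,
    method: str = "hmm",
    switch_rate: float = 0.01,
    error_rate: float = 0.002,
    max_ref_haps: int = 200,
    window_temp: float = 2.0,
) -> np.ndarray:
    """Impute the marker allele pair of every validation animal.

    ``ref_flank_haps``: (n_ref_haps, L) 0/1 flank alleles of the reference
    haplotypes (columns in genome order); ``ref_marker_alleles``:
    (n_ref_haps,) marker allele per reference haplotype; ``val_flank_genotypes``:
    (V, L) B-allele dosage (0/1/2, -1 missing) of the validation animals;
    ``marker_insert_pos``: the column index at which the (unobserved) marker
    sits among the flank columns. Returns (V, 2) allele codes, each row an
    unordered pair sorted ascending.
    """
    X = np.asarray(ref_flank_haps, dtype=np.int8)
    m = np.asarray(ref_marker_alleles, dtype=np.int8)
    G = np.asarray(val_flank_genotypes, dtype=np.int8)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ConfigurationError("empty reference haplotype panel")
    if m.shape[0] != X.shape[0]:
        raise ConfigurationError("marker alleles do not match reference panel")
    if G.ndim != 2 or G.shape[1] != X.shape[1]:
        raise ConfigurationError("validation genotypes do not match window width")
    keep = _subsample_haps(X.shape[0], max_ref_haps)
    X, m = X[keep], m[keep]
    H, L = X.shape
    V = G.shape[0]
    if len(np.unique(m)) == 1:
        logger.info("marker monomorphic in reference; imputing the single allele")
        return np.tile(np.sort(np.array([m[0], m[0]], dtype=np.int8)), (V, 1))

    if method == "hmm":
        P = _diploid_posterior(X, G, marker_insert_pos, switch_rate, error_rate)
    elif method == "window":
        P = _window_weights(X, G, window_temp)
    else:
        raise ConfigurationError(f"unknown imputer method {method!r}")
    W = _class_weights(P, m)
    return _mode_pairs(W)


def _emission(d: np.ndarray, g_col: np.ndarray, error_rate: float) -> np.ndarray:
    """(V, H, H) genotype emission at one column; missing genotypes emit 1."""
    E = np.where(d[None, :, :] == g_col[:, None, None], 1.0 - error_rate, error_rate)
    E[g_col < 0] = 1.0
    return E


def _ls_step(F: np.ndarray, rho: float, H: int) -> np.ndarray:
    """One diploid Li-Stephens transition: T' F T with T = (1-rho)I + rho/H J."""
    r = F.sum(axis=2)  # (V, H)
    c = F.sum(axis=1)  # (V, H)
    S = r.sum(axis=1)  # (V,)
    a = 1.0 - rho
    b = rho / H
    return (
        a * a * F
        + a * b * (r[:, :, None] + c[:, None, :])
        + b * b * S[:, None, None]
    )


def _diploid_posterior(
    X: np.ndarray, G: np.ndarray, insert_pos: int, switch_rate: float, error_rate: float
) -> np.ndarray:
    """Forward-backward posterior over reference haplotype pairs at the marker."""
    H, L = X.shape
    V = G.shape[0]
    # dosage of each haplotype pair per column, marker column emits 1
    cols = list(range(L))
    col_order = cols[:insert_pos] + [None] + cols[insert_pos:]
    n_cols = len(col_order)
    mi = insert_pos

    def emis(t: int) -> Optional[np.ndarray]:
        j = col_order[t]
        if j is None:
            return None
        d = X[:, j][:, None] + X[:, j][None, :]
        return _emission(d, G[:, j], error_rate)

    F = np.full((V, H, H), 1.0 / (H * H))
    e0 = emis(0)
    if e0 is not None:
        F = F * e0
    F /= F.sum(axis=(1, 2), keepdims=True)
    F_marker = None
    for t in range(1, n_cols):
        F = _ls_step(F, switch_rate, H)
        e = emis(t)
        if e is not None:
            F = F * e
        F /= F.sum(axis=(1, 2), keepdims=True)
        if t == mi:
            F_marker = F.copy()
    if mi == 0:
        F_marker = np.full((V, H, H), 1.0 / (H * H))

    B = np.ones((V, H, H))
    for t in range(n_cols - 1, mi, -1):
        e = emis(t)
        Gt = B if e is None else B * e
        B = _ls_step(Gt, switch_rate, H)
        B /= B.sum(axis=(1, 2), keepdims=True)
    P = F_marker * B
    P /= P.sum(axis=(1, 2), keepdims=True)
    return P


def _window_weights(X: np.ndarray, G: np.ndarray, temp: float) -> np.ndarray:
    """Softmax weights over haplotype pairs from squared dosage error."""
    H, L = X.shape
    Xf = X.astype(float)
    out = np.empty((G.shape[0], H, H))
    for v in range(G.shape[0]):
        g = G[v].astype(float)
        obs = g >= 0
        xo = Xf[:, obs]
        # 0/1 alleles: sum of squares equals the sum
        so = xo.sum(axis=1)
        Mo = xo @ xo.T
        t = Xf[:, obs] @ g[obs]
        score = so[:, None] + so[None, :] + 2 * Mo - 2 * t[:, None] - 2 * t[None, :] + float(g[obs] @ g[obs])
        w = np.exp(-(score - score.min()) / temp)
        out[v] = w / w.sum()
    return out


# ---------------------------------------------------------------------------
# the experiment
# ---------------------------------------------------------------------------

def run_imputation_experiment(
    selected: dict[str, list[GroupedLocus]],
    haps: HaplotypeSet,
    snp_map: SnpMap,
    ped: Pedigree,
    ks: Sequence[int] = (10, 25, 50),
    mode: str = "triallelic",
    method: str = "hmm",
    frac_reference: float = 0.8,
    max_ref_haps: int = 200,
    switch_rate: float = 0.01,
    error_rate: float = 0.002,
    truth_loci: Optional[Sequence[CnvLocus]] = None,
    report_conflicts: bool = True,
) -> pd.DataFrame:
    """Run the full imputation design over breeds, loci and flank sizes.

    ``selected`` maps breed -> loci (from :func:`group_loci_and_select`).
    ``mode="split"`` runs the two bi-allelic encodings and stacks their
    rows; otherwise ``mode`` is one encoding. ``truth_loci`` (matching loci
    by coordinates) supplies true phase for reference-marker orientation
    when available. Returns one row per
    (breed, locus, k, mode, validation animal) with called and imputed copy
    number plus locus metadata.
    """
    modes = ("biallelic_del", "biallelic_dup") if mode == "split" else (mode,)
    truth_by_region = {}
    if truth_loci:
        for t in truth_loci:
            truth_by_region[(t.chrom, t.start_bp, t.end_bp)] = t
    aidx = haps.animal_index()
    dosage = haps.genotype_dosage()
    rows = []
    for breed, loci in selected.items():
        if not loci:
            continue
        ref_ids, val_ids = split_reference_validation(ped, breed, frac_reference)
        ref_rows = [aidx[a] for a in ref_ids]
        val_rows = [aidx[a] for a in val_ids]
        for loc in loci:
            called_all = {a: loc.copy_number_of(a) for a in ped.breed_animals(breed)}
            truth = _match_truth(truth_by_region, loc)
            bf_vals = [loc.bayes_factors[a] for a in loc.bayes_factors]
            mean_bf = float(np.mean(bf_vals)) if bf_vals else np.nan
            pop_freq = loc.carrier_count(ped.breed_animals(breed))
            for enc in modes:
                ref_cn = np.array([called_all[a] for a in ref_ids])
                ref_pairs = phase_marker_alleles(
                    ref_cn, enc, _restrict_truth(truth, ref_rows)
                )
                if report_conflicts:
                    conf = flag_marker_conflicts(
                        {a: tuple(p) for a, p in zip(ref_ids, ref_pairs)}, ped
                    )
                    if conf:
                        logger.info(
                            "locus %s (%s): %d opposing-homozygote marker conflicts in pedigree",
                            loc.locus_id, enc, len(conf),
                        )
                for k in ks:
                    flank_idx, n_left, n_right = extract_flanks(
                        snp_map, loc.chrom, loc.midpoint_bp, k
                    )
                    if n_left == 0 or n_right == 0:
                        logger.warning(
                            "locus %s: empty flank side at k=%d; task skipped",
                            loc.locus_id, k,
                        )
                        continue
                    ref_haps = np.concatenate(
                        [haps.haps[ref_rows, 0][:, flank_idx], haps.haps[ref_rows, 1][:, flank_idx]]
                    )
                    ref_marker = np.concatenate([ref_pairs[:, 0], ref_pairs[:, 1]])
                    val_geno = dosage[val_rows][:, flank_idx]
                    imputed_pairs = impute_marker(
                        ref_haps,
                        ref_marker,
                        val_geno,
                        marker_insert_pos=n_left,
                        method=method,
                        switch_rate=switch_rate,
                        error_rate=error_rate,
                        max_ref_haps=max_ref_haps,
                    )
                    for animal, pair in zip(val_ids, imputed_pairs):
                        called = called_all[animal]
                        called_enc = pair_to_cn(encode_pair(called, enc))
                        rows.append(
                            {
                                "breed": breed,
                                "locus_id": loc.locus_id,
                                "chrom": loc.chrom,
                                "start_bp": loc.start_bp,
                                "end_bp": loc.end_bp,
                                "length_kb": loc.length_kb,
                                "population_frequency": pop_freq,
                                "mean_bayes_factor": mean_bf,
                                "k": k,
                                "mode": enc,
                                "method": method,
                                "animal_id": animal,
                                "called_cn": called_enc,
                                "imputed_cn": pair_to_cn(pair),
                            }
                        )
    cols = [
        "breed", "locus_id", "chrom", "start_bp", "end_bp", "length_kb",
        "population_frequency", "mean_bayes_factor", "k", "mode", "method",
        "animal_id", "called_cn", "imputed_cn",
    ]
    return pd.DataFrame(rows, columns=cols)


def _match_truth(truth_by_region: dict, loc: GroupedLocus) -> Optional[CnvLocus]:
    if not truth_by_region:
        return None
    exact = truth_by_region.get((loc.chrom, loc.start_bp, loc.end_bp))
    if exact is not None:
        return exact
    # fall back to the truth locus overlapping the grouped region, if unique
    hits = [
        t
        for t in truth_by_region.values()
        if t.chrom == loc.chrom and not (t.end_bp < loc.start_bp or t.start_bp > loc.end_bp)
    ]
    return hits[0] if len(hits) == 1 else None


def _restrict_truth(truth: Optional[CnvLocus], rows: Sequence[int]) -> Optional[CnvLocus]:
    if truth is None:
        return None
    return CnvLocus(
        locus_id=truth.locus_id,
        chrom=truth.chrom,
        start_bp=truth.start_bp,
        end_bp=truth.end_bp,
        hap_alleles=np.asarray(truth.hap_alleles)[list(rows)],
        ld_mode=truth.ld_mode,
        snp_indices=truth.snp_indices,
    )
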
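"""Five-state HMM CNV caller on LRR/BAF signals.

States are diploid copy numbers 0..4 with state 2 "normal". Emissions are a
Gaussian in LRR per state plus a BAF mixture over the ``b/cn`` cluster means
(clusters weighted by the binomial allele-count probabilities at the SNP's
population B-allele frequency, boundary clusters as half-normals, plus a
small uniform outlier component; copy number 0 emits uniform BAF).
Transitions are distance-dependent: the probability of leaving the current
state over an inter-SNP gap ``d`` is ``p_event * (1 - exp(-d / L))`` with
``L`` the expected CNV length, which encodes a geometric length prior with a
single scale parameter.

Two caller personalities share the decoder: ``penn_like`` (short length
scale, no Bayes factor) and ``quanti_like`` (longer length scale; each call
carries a log10 Bayes factor of the called state against the normal state).
Calls require at least ``min_snps`` consecutive SNPs (default 3); shorter
runs are discarded, not merged.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .types import CnvCall, ConfigurationError, SignalSet, SnpMap

logger = logging.getLogger(__name__)

N_STATES = 5
NORMAL_STATE = 2
#: argmax preference order: ties in Viterbi resolve toward the normal state
_TIE_ORDER = np.array([2, 0, 1, 3, 4])


@dataclass(frozen=True)
class HmmParams:
    """Emission and transition parameters of the 5-state caller."""

    state_lrr_means: tuple = (-3.5, -0.66, 0.0, 0.40, 0.68)
    state_lrr_sds: tuple = (1.3, 0.28, 0.21, 0.21, 0.26)
    baf_sd: float = 0.04
    baf_outlier_weight: float = 0.01
    expected_cnv_length_bp: float = 100_000.0
    p_event: float = 1e-4
    #: relative entry weights of the four CNV states (index 2 ignored)
    entry_probs: tuple = (0.05, 0.45, 0.0, 0.45, 0.05)
    #: when leaving a CNV state, probability of returning to normal rather
    #: than jumping to another CNV state
    back_to_normal: float = 0.95

    def __post_init__(self) -> None:
        if len(self.state_lrr_means) != N_STATES or len(self.state_lrr_sds) != N_STATES:
            raise ConfigurationError("state parameter vectors must have 5 entries")
        if any(s <= 0 for s in self.state_lrr_sds) or self.baf_sd <= 0:
            raise ConfigurationError("standard deviations must be > 0")
        if not (0 <= self.baf_outlier_weight <= 1):
            raise ConfigurationError("baf_outlier_weight must be in [0, 1]")
        e = np.asarray(self.entry_probs, dtype=float)
        if e.min() < 0 or e[np.arange(N_STATES) != NORMAL_STATE].sum() <= 0:
            raise ConfigurationError("entry_probs must be non-negative with mass off the normal state")


def penn_params(**overrides) -> HmmParams:
    """Short-length-scale caller preset (no Bayes factor)."""
    return HmmParams(**overrides)


def quanti_params(**overrides) -> HmmParams:
    """Longer-length-scale preset whose calls carry Bayes factors."""
    overrides.setdefault("expected_cnv_length_bp", 500_000.0)
    return HmmParams(**overrides)


# ---------------------------------------------------------------------------
# GC-wave adjustment
# ---------------------------------------------------------------------------

def gc_adjust_lrr(signals: SignalSet, snp_map: SnpMap) -> SignalSet:
    """Remove the GC wave by per-animal linear regression of LRR on GC.

    LRR is replaced by the residual of a least-squares fit against the GC
    fraction of the SNP's flanking window, with the animal's mean LRR added
    back, so the adjusted LRR is uncorrelated with GC but keeps its level.
    """
    gc = snp_map.gc_frac
    if len(gc) != signals.n_snps:
        raise ConfigurationError("map and signals disagree on SNP count")
    out = signals.copy()
    gc_c = gc - gc.mean()
    denom = float(gc_c @ gc_c)
    if denom == 0.0:
        logger.warning("constant GC track: GC adjustment is a no-op")
        return out
    # slope per animal via one matrix product; residual keeps the sample mean
    lrr = out.lrr
    means = lrr.mean(axis=1, keepdims=True)
    slopes = (lrr - means) @ gc_c / denom
    out.lrr = lrr - slopes[:, None] * gc_c[None, :]
    return out


# ---------------------------------------------------------------------------
# emissions
# ---------------------------------------------------------------------------

def _baf_cluster_logpdf(baf: np.ndarray, mean: float, sd: float) -> np.ndarray:
    """Log density of one BAF cluster; boundary clusters are half-normals."""
    z = (baf - mean) / sd
    log_norm = -0.5 * z * z - math.log(sd) - 0.5 * math.log(2 * math.pi)
    if mean in (0.0, 1.0):
        return log_norm + math.log(2.0)
    return log_norm


def emission_loglik_matrix(
    lrr: np.ndarray,
    baf: np.ndarray,
    pop_b_freq: np.ndarray,
    params: HmmParams,
) -> np.ndarray:
    """(..., n_snps, 5) log emission density for every state.

    ``lrr`` and ``baf`` may be (n_snps,) or (n_animals, n_snps);
    ``pop_b_freq`` is the per-SNP population B-allele frequency used to
    weight the BAF clusters.
    """
    lrr = np.asarray(lrr, dtype=float)
    baf = np.asarray(baf, dtype=float)
    p = np.asarray(pop_b_freq, dtype=float)
    squeeze = lrr.ndim == 1
    if squeeze:
        lrr, baf = lrr[None, :], baf[None, :]
    A, S = lrr.shape
    out = np.empty((A, S, N_STATES))
    means = np.asarray(params.state_lrr_means)
    sds = np.asarray(params.state_lrr_sds)
    w_out = params.baf_outlier_weight
    for state in range(N_STATES):
        z = (lrr - means[state]) / sds[state]
        lrr_log = -0.5 * z * z - math.log(sds[state]) - 0.5 * math.log(2 * math.pi)
        if state == 0:
            baf_density = np.ones((A, S))
        else:
            cn = state
            baf_density = np.zeros((A, S))
            for b in range(cn + 1):
                w = stats.binom.pmf(b, cn, p)  # (S,)
                clust = np.exp(_baf_cluster_logpdf(baf, b / cn, params.baf_sd))
                baf_density += w[None, :] * clust
        mix = (1 - w_out) * baf_density + w_out * 1.0
        out[:, :, state] = lrr_log + np.log(np.maximum(mix, 1e-300))
    return out[0] if squeeze else out


def emission_loglik(
    lrr: float, baf: float, pop_b_freq: float, state: int, params: HmmParams
) -> float:
    """Log emission density of a single SNP observation under one state."""
    if not (0.0 <= baf <= 1.0):
        raise ConfigurationError("BAF must lie in [0, 1]")
    m = emission_loglik_matrix(
        np.array([lrr]), np.array([baf]), np.array([pop_b_freq]), params
    )
    return float(m[0, state])


# ---------------------------------------------------------------------------
# transitions
# ---------------------------------------------------------------------------

def transition_log_matrix(distance_bp: float, params: HmmParams) -> np.ndarray:
    """(5, 5) log transition matrix for one inter-SNP gap."""
    rho = params.p_event * (1.0 - math.exp(-distance_bp / params.expected_cnv_length_bp))
    rho = min(max(rho, 1e-12), 0.2)
    e = np.asarray(params.entry_probs, dtype=float).copy()
    e[NORMAL_STATE] = 0.0
    e = e / e.sum()
    T = np.zeros((N_STATES, N_STATES))
    for s in range(N_STATES):
        if s == NORMAL_STATE:
            T[s] = rho * e
            T[s, s] = 1.0 - rho
        else:
            others = e.copy()
            others[s] = 0.0
            tot = others.sum()
            if tot > 0:
                T[s] = rho * (1.0 - params.back_to_normal) * others / tot
            T[s, NORMAL_STATE] = rho * params.back_to_normal + (
                rho * (1.0 - params.back_to_normal) if tot == 0 else 0.0
            )
            T[s, s] = 1.0 - rho
    return np.log(np.maximum(T, 1e-300))


def initial_log_probs(params: HmmParams) -> np.ndarray:
    """Stationary-ish start distribution: mostly normal, entry weights elsewhere."""
    e = np.asarray(params.entry_probs, dtype=float).copy()
    e[NORMAL_STATE] = 0.0
    e = e / e.sum()
    pi = params.p_event * e
    pi[NORMAL_STATE] = 1.0 - params.p_event
    return np.log(np.maximum(pi, 1e-300))


# ---------------------------------------------------------------------------
# decoding
# ---------------------------------------------------------------------------

def viterbi_paths(
    emissions: np.ndarray, positions: np.ndarray, params: HmmParams
) -> tuple[np.ndarray, np.ndarray]:
    """Batched exact Viterbi decode.

    ``emissions`` is (n_animals, n_snps, 5); ``positions`` the SNP bp
    coordinates of one chromosome. Returns (paths, scores): the
    maximum-probability state path per animal (ties resolved toward the
    normal state) and its log probability.
    """
    A, S, K = emissions.shape
    if K != N_STATES:
        raise ConfigurationError("emissions must have 5 states")
    if S == 0:
        return np.zeros((A, 0), dtype=np.int8), np.zeros(A)
    delta = initial_log_probs(params)[None, :] + emissions[:, 0, :]
    back = np.empty((A, S, K), dtype=np.int8)
    gaps = np.diff(positions.astype(float))
    # transition matrices depend only on the gap; cache by rounded distance
    cache: dict[float, np.ndarray] = {}
    for i in range(1, S):
        d = float(gaps[i - 1])
        tl = cache.get(d)
        if tl is None:
            tl = transition_log_matrix(d, params)
            cache[d] = tl
        # scores[a, prev, cur]; prefer normal-state predecessor on ties
        scores = delta[:, :, None] + tl[None, :, :]
        scores_p = scores[:, _TIE_ORDER, :]
        choice = scores_p.argmax(axis=1)
        best_prev = _TIE_ORDER[choice]
        delta = np.take_along_axis(scores_p, choice[:, None, :], axis=1)[:, 0, :]
        delta = delta + emissions[:, i, :]
        back[:, i, :] = best_prev
    final_p = delta[:, _TIE_ORDER]
    last_choice = final_p.argmax(axis=1)
    scores = np.take_along_axis(final_p, last_choice[:, None], axis=1)[:, 0]
    paths = np.empty((A, S), dtype=np.int8)
    paths[:, S - 1] = _TIE_ORDER[last_choice]
    for i in range(S - 1, 0, -1):
        paths[:, i - 1] = np.take_along_axis(
            back[:, i, :], paths[:, i][:, None].astype(np.int64), axis=1
        )[:, 0]
    return paths, scores


def _segments(path: np.ndarray, min_snps: int) -> list[tuple[int, int, int]]:
    """Maximal runs of a constant non-normal state with length >= min_snps."""
    segs = []
    S = len(path)
    i = 0
    while i < S:
        s = path[i]
        j = i
        while j + 1 < S and path[j + 1] == s:
            j += 1
        if s != NORMAL_STATE and (j - i + 1) >= min_snps:
            segs.append((i, j, int(s)))
        i = j + 1
    return segs


def viterbi_segment(
    lrr: np.ndarray,
    baf: np.ndarray,
    positions: np.ndarray,
    pop_b_freq: np.ndarray,
    params: HmmParams,
    animal_id: str = "animal",
    chrom: int = 1,
    caller: str = "penn_like",
    min_snps: int = 3,
    index_offset: int = 0,
) -> list[CnvCall]:
    """Decode one animal x chromosome and emit CNV calls.

    Runs shorter than ``min_snps`` are discarded (not merged); call
    boundaries sit on the first/last SNP of the run, SNP indices are offset
    by ``index_offset`` into the full map.
    """
    if len(positions) < 1:
        return []
    emis = emission_loglik_matrix(lrr, baf, pop_b_freq, params)[None, :, :]
    paths, _ = viterbi_paths(emis, np.asarray(positions), params)
    calls = []
    for i0, i1, s in _segments(paths[0], min_snps):
        calls.append(
            CnvCall(
                animal_id=animal_id,
                chrom=chrom,
                start_bp=int(positions[i0]),
                end_bp=int(positions[i1]),
                start_snp_index=index_offset + i0,
                end_snp_index=index_offset + i1,
                copy_number=s,
                caller=caller,
            )
        )
    return calls


# ---------------------------------------------------------------------------
# Bayes factor
# ---------------------------------------------------------------------------

def bayes_factor(
    call: CnvCall,
    emissions: np.ndarray,
    local_start_index: int = 0,
) -> float:
    """log10 likelihood ratio of the called state against the normal state.

    ``emissions`` is the (n_snps, 5) log emission matrix of the call's
    chromosome; the factor is additive over the segment's SNPs.
    """
    i0 = call.start_snp_index - local_start_index
    i1 = call.end_snp_index - local_start_index
    seg = emissions[i0 : i1 + 1]
    return float((seg[:, call.copy_number] - seg[:, NORMAL_STATE]).sum() / math.log(10))


# ---------------------------------------------------------------------------
# top level
# ---------------------------------------------------------------------------

def call_cnvs(
    signals: SignalSet,
    snp_map: SnpMap,
    panel: str = "hd",
    caller: str = "penn_like",
    params: Optional[HmmParams] = None,
    min_snps: int = 3,
    gc_adjust: bool = True,
    pop_b_freq: Optional[np.ndarray] = None,
) -> list[CnvCall]:
    """Call CNVs for every animal on the chosen panel.

    ``panel="md"`` restricts decoding to the medium-density subset before
    anything else, so regions with fewer than ``min_snps`` MD SNPs can never
    yield an MD call. GC adjustment runs first; ``quanti_like`` calls carry
    Bayes factors. SNP indices in the returned calls refer to rows of the
    panel's map (the HD map for ``panel="hd"``, the MD submap otherwise).
    """
    if panel not in ("hd", "md"):
        raise ConfigurationError(f"unknown panel {panel!r}")
    if caller not in ("penn_like", "quanti_like"):
        raise ConfigurationError(f"unknown caller {caller!r}")
    if params is None:
        params = penn_params() if caller == "penn_like" else quanti_params()

    if panel == "md":
        idx = snp_map.md_indices()
        if len(idx) == 0:
            raise ConfigurationError("MD panel is empty")
        snp_map = snp_map.subset(idx)
        signals = signals.subset_snps(idx)
        if pop_b_freq is not None:
            pop_b_freq = np.asarray(pop_b_freq)[idx]
    if pop_b_freq is None:
        pop_b_freq = signals.pop_b_freq()
    if gc_adjust:
        signals = gc_adjust_lrr(signals, snp_map)

    calls: list[CnvCall] = []
    for c in snp_map.chroms():
        ci = snp_map.chrom_indices(c)
        pos = snp_map.pos_bp[ci]
        emis = emission_loglik_matrix(
            signals.lrr[:, ci], signals.baf[:, ci], pop_b_freq[ci], params
        )
        paths, _ = viterbi_paths(emis, pos, params)
        for a_i, animal in enumerate(signals.animals):
            for i0, i1, s in _segments(paths[a_i], min_snps):
                call = CnvCall(
                    animal_id=animal,
                    chrom=c,
                    start_bp=int(pos[i0]),
                    end_bp=int(pos[i1]),
                    start_snp_index=int(ci[0]) + i0,
                    end_snp_index=int(ci[0]) + i1,
                    copy_number=s,
                    caller=caller,
                    bayes_factor=(
                        bayes_factor(
                            CnvCall(
                                animal_id=animal,
                                chrom=c,
                                start_bp=int(pos[i0]),
                                end_bp=int(pos[i1]),
                                start_snp_index=i0,
                                end_snp_index=i1,
                                copy_number=s,
                                caller=caller,
                            ),
                            emis[a_i],
                        )
                        if caller == "quanti_like"
                        else None
                    ),
                )
                calls.append(call)
    return calls
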
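"""Shared fixtures: a small population and a full study-scale simulation.

All fixtures are deterministic; the heavier ``study`` fixture is built once
per session and reused by the concordance/recovery checks.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from herdcnv import (
    calling,
    simulate_haplotypes,
    simulate_pedigree,
    simulate_snp_map,
    plant_cnv_loci,
    render_signals,
    make_md_subset,
    call_cnvs,
)
from herdcnv.calling import (
    HmmParams,
    emission_loglik_matrix,
    initial_log_probs,
    transition_log_matrix,
)


# ---------------------------------------------------------------------------
# brute-force Viterbi oracle (independent of the decoder implementation)
# ---------------------------------------------------------------------------

def brute_force_best_path(emissions: np.ndarray, positions: np.ndarray, params: HmmParams):
    """Enumerate all 5^L state paths; return (best score, set of argmax paths)."""
    L = emissions.shape[0]
    init = initial_log_probs(params)
    trans = [transition_log_matrix(float(d), params) for d in np.diff(positions)]
    best = -np.inf
    best_paths = []
    for path in itertools.product(range(5), repeat=L):
        s = init[path[0]] + emissions[0, path[0]]
        for i in range(1, L):
            s += trans[i - 1][path[i - 1], path[i]] + emissions[i, path[i]]
        if s > best + 1e-12:
            best, best_paths = s, [path]
        elif abs(s - best) <= 1e-12:
            best_paths.append(path)
    return best, best_paths


def random_hmm_instance(rng: np.random.Generator, max_len: int = 8):
    """A random short LRR/BAF sequence plus its emission matrix."""
    L = int(rng.integers(2, max_len + 1))
    params = HmmParams()
    lrr = rng.normal(0, 1.2, size=L)
    baf = rng.random(L)
    freq = rng.uniform(0.05, 0.95, size=L)
    pos = np.sort(rng.choice(np.arange(1, 10_000_000), size=L, replace=False))
    emis = emission_loglik_matrix(lrr, baf, freq, params)
    return emis, pos, params


# ---------------------------------------------------------------------------
# small population
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def small_pop():
    ped = simulate_pedigree(20, 3, 2, seed=11)
    snp_map = simulate_snp_map(2, 400, 40_000_000, seed=11)
    haps = simulate_haplotypes(ped, snp_map, recomb_rate_per_mb=0.01, seed=11)
    return ped, snp_map, haps


# ---------------------------------------------------------------------------
# study-scale run: 3 chr x 5,000 SNPs, 300 animals, 12 planted loci,
# HD calls plus a 6% MD thinning with MD calls
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def study():
    seed = 2024
    ped = simulate_pedigree(60, 4, 2, seed=seed)
    snp_map = simulate_snp_map(3, 5000, 100_000_000, seed=seed)
    haps = simulate_haplotypes(ped, snp_map, recomb_rate_per_mb=0.01, seed=seed)
    loci, truth = plant_cnv_loci(
        snp_map, haps, 12,
        length_dist=("snps", 15),
        freq_range=(0.10, 0.35),
        allele_set=[("N", "D"), ("N", "D"), ("N", "P")],
        ld_mode="perfect",
        seed=seed + 1,
    )
    signals = render_signals(haps, loci, snp_map, gc_wave_coef=0.2, seed=seed + 2)
    snp_map = make_md_subset(snp_map, 0.06, seed=seed + 3)
    hd_calls = call_cnvs(signals, snp_map, panel="hd", caller="penn_like")
    md_calls = call_cnvs(signals, snp_map, panel="md", caller="penn_like")
    return {
        "ped": ped,
        "snp_map": snp_map,
        "haps": haps,
        "loci": loci,
        "truth": truth,
        "signals": signals,
        "hd_calls": hd_calls,
        "md_calls": md_calls,
    }


# ---------------------------------------------------------------------------
# LD-extremes run: one breed, three loci (one per LD regime), imputed from
# truth copy numbers.  Conditions mirror the selected-CNV regime: rare loci
# (8-15% carrier frequency, near the 30-carrier selection threshold at this
# population size) in a livestock-like pedigree with large half-sib groups.
# ---------------------------------------------------------------------------

LD_MODES = ["perfect", ("tagged", float(np.sqrt(0.5))), "independent"]


@pytest.fixture(scope="session")
def ld_extremes():
    from herdcnv.imputation import GroupedLocus, run_imputation_experiment

    seed = 505
    ped = simulate_pedigree(30, 5, 3, seed=seed, breed="LD")
    snp_map = simulate_snp_map(1, 1500, 80_000_000, seed=seed)
    haps = simulate_haplotypes(ped, snp_map, recomb_rate_per_mb=0.01, seed=seed)
    loci, _ = plant_cnv_loci(
        snp_map, haps, 3,
        length_dist=("snps", 12),
        freq_range=(0.08, 0.15),
        allele_set=("N", "D"),
        ld_mode=LD_MODES,
        seed=seed + 1,
    )
    selected = {
        "LD": [
            GroupedLocus(
                locus_id=loc.locus_id,
                chrom=loc.chrom,
                start_bp=loc.start_bp,
                end_bp=loc.end_bp,
                called_cn={
                    a: int(cn)
                    for a, cn in zip(haps.animals, loc.copy_numbers())
                    if cn != 2
                },
            )
            for loc in loci
        ]
    }
    results = run_imputation_experiment(
        selected, haps, snp_map, ped, ks=(10,), mode="triallelic",
        method="hmm", truth_loci=loci,
    )
    mode_of = {loc.locus_id: loc.ld_mode for loc in loci}
    results["ld"] = results["locus_id"].map(mode_of)
    return ped, haps, snp_map, loci, selected, results


def reciprocal_overlap(a_start, a_end, b_start, b_end) -> float:
    ov = max(0, min(a_end, b_end) - max(a_start, b_start) + 1)
    if ov == 0:
        return 0.0
    return min(ov / (a_end - a_start + 1), ov / (b_end - b_start + 1))
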
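"""End-to-end orchestration: simulate -> call -> concord -> impute -> evaluate.

A run is a pure function of (config, seed): every stochastic stage draws a
named substream of the root seed, outputs are written with fixed float
formatting, and the manifest records a SHA-256 checksum of every artifact,
so re-running an identical config reproduces identical checksums.
"""

from __future__ import annotations

import contextlib
import dataclasses
import hashlib
import json
import logging
import pathlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import calling, concordance, imputation, io, simulate
from . import stats as evaluation
from .seeding import substream_seed
from .types import (
    ALLELE_N,
    CnvLocus,
    HaplotypeSet,
    Pedigree,
    PipelineError,
    SignalSet,
    SnpMap,
    truth_table,
)

logger = logging.getLogger(__name__)


@dataclass
class BreedSpec:
    name: str = "SIM"
    n_founders: int = 60
    n_generations: int = 4
    offspring_per_mating: int = 2


@dataclass
class RunConfig:
    """Everything a reproducible run needs; round-trips through YAML."""

    seed: int = 1
    breeds: list = field(default_factory=lambda: [BreedSpec()])
    # map
    n_chrom: int = 3
    snps_per_chrom: int = 5000
    chrom_length_bp: int = 100_000_000
    # haplotypes
    recomb_rate_per_mb: float = 0.01
    maf_spectrum: tuple = ("uniform", 0.05, 0.5)
    # CNV loci
    n_loci: int = 12
    cnv_length_dist: tuple = ("snps", 20)
    cnv_freq_range: tuple = (0.1, 0.35)
    cnv_allele_set: tuple = ("N", "D")
    cnv_ld_mode: object = "perfect"
    # signals
    gc_wave_coef: float = 0.2
    baf_sd: float = simulate.DEFAULT_BAF_SD
    state_lrr_means: tuple = simulate.DEFAULT_STATE_LRR_MEANS
    state_lrr_sds: tuple = simulate.DEFAULT_STATE_LRR_SDS
    # defects + QC
    missing_rate: float = 0.01
    mendel_error_rate: float = 0.002
    min_call_rate: float = 0.95
    max_mendel_pair_frac: float = 0.02
    # panels
    md_fraction: float = 45_677 / 713_162
    # caller
    min_snps_per_call: int = 3
    hmm_overrides: dict = field(default_factory=dict)
    # consensus + selection
    consensus_snp_tolerance: int = 1
    # call-boundary jitter splits recurrent loci when grouping is exact;
    # ~2-3 inter-SNP gaps at the demo SNP density keeps one locus per planted CNV
    locus_bp_tolerance: int = 50_000
    min_carriers: int = 30
    # imputation
    flank_k: tuple = (10, 25, 50)
    imputer_method: str = "hmm"
    encoding_mode: str = "triallelic"
    frac_reference: float = 0.8
    max_ref_haps: int = 200
    switch_rate: float = 0.01
    error_rate: float = 0.002
    # outputs
    write_signal_files: bool = False
    write_plots: bool = False

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["breeds"] = [
            dataclasses.asdict(b) if dataclasses.is_dataclass(b) else dict(b)
            for b in self.breeds
        ]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        breeds = d.pop("breeds", None)
        cfg = cls(**{k: _tuplify(v) for k, v in d.items()})
        if breeds is not None:
            cfg.breeds = [BreedSpec(**b) if isinstance(b, dict) else b for b in breeds]
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def _tuplify(v):
    return tuple(v) if isinstance(v, list) else v


def _sha256(path: pathlib.Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _expand_locus(loc: CnvLocus, rows: Sequence[int], total: int) -> CnvLocus:
    """Re-index a breed-local locus onto the combined animal set."""
    alleles = np.full((total, 2), ALLELE_N, dtype=np.int8)
    alleles[list(rows)] = np.asarray(loc.hap_alleles)
    return dataclasses.replace(loc, hap_alleles=alleles)


@contextlib.contextmanager
def _stage(name: str):
    """Abort with the failing stage named; partial outputs stay on disk."""
    try:
        yield
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage {name!r} failed: {exc}") from exc


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Execute the full pipeline; returns the manifest (also written as JSON)."""
    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.seed
    artifacts: dict[str, pathlib.Path] = {}

    def stage_seed(name: str) -> int:
        return substream_seed(seed, name)

    with _stage("simulate"):
        snp_map = simulate.simulate_snp_map(
            config.n_chrom, config.snps_per_chrom, config.chrom_length_bp,
            seed=stage_seed("snp_map"),
        )
        peds, hap_sets, loci_by_breed = [], {}, {}
        for spec in config.breeds:
            ped_b = simulate.simulate_pedigree(
                spec.n_founders, spec.n_generations, spec.offspring_per_mating,
                seed=stage_seed(f"pedigree:{spec.name}"), breed=spec.name,
            )
            haps_b = simulate.simulate_haplotypes(
                ped_b, snp_map, config.recomb_rate_per_mb, config.maf_spectrum,
                seed=stage_seed(f"haplotypes:{spec.name}"),
            )
            loci_b, _ = simulate.plant_cnv_loci(
                snp_map, haps_b, config.n_loci,
                length_dist=config.cnv_length_dist,
                freq_range=config.cnv_freq_range,
                allele_set=config.cnv_allele_set,
                ld_mode=config.cnv_ld_mode,
                seed=stage_seed(f"cnv_loci:{spec.name}"),
            )
            loci_b = [
                dataclasses.replace(l, locus_id=f"{spec.name}_{l.locus_id}")
                for l in loci_b
            ]
            peds.append(ped_b)
            hap_sets[spec.name] = haps_b
            loci_by_breed[spec.name] = loci_b

        ped = Pedigree(pd.concat([p.table for p in peds], ignore_index=True))
        combined_haps = HaplotypeSet(
            animals=[a for p in peds for a in p.animals],
            haps=np.concatenate([hap_sets[s.name].haps for s in config.breeds]),
            origins=None,
        )
        row_of = combined_haps.animal_index()
        all_loci: list[CnvLocus] = []
        for spec in config.breeds:
            rows = [row_of[a] for a in hap_sets[spec.name].animals]
            for loc in loci_by_breed[spec.name]:
                all_loci.append(_expand_locus(loc, rows, combined_haps.n_animals))

        sig_parts = [
            simulate.render_signals(
                hap_sets[spec.name], loci_by_breed[spec.name], snp_map,
                state_lrr_means=config.state_lrr_means,
                state_lrr_sds=config.state_lrr_sds,
                baf_sd=config.baf_sd,
                gc_wave_coef=config.gc_wave_coef,
                seed=stage_seed(f"signals:{spec.name}"),
            )
            for spec in config.breeds
        ]
        signals = SignalSet(
            animals=combined_haps.animals,
            lrr=np.concatenate([s.lrr for s in sig_parts]),
            baf=np.concatenate([s.baf for s in sig_parts]),
            genotypes=np.concatenate([s.genotypes for s in sig_parts]),
        )
        signals = simulate.inject_defects(
            signals, ped,
            missing_rate=config.missing_rate,
            mendel_error_rate=config.mendel_error_rate,
            seed=stage_seed("defects"),
        )

    with _stage("qc"):
        snp_map_qc, signals = simulate.filter_snps(
            signals, snp_map, ped,
            min_call_rate=config.min_call_rate,
            max_mendel_pair_frac=config.max_mendel_pair_frac,
        )
        kept = np.flatnonzero(pd.Index(snp_map.snp_id).isin(snp_map_qc.snp_id))
        combined_haps = combined_haps.subset_snps(kept)
        old_to_new = {int(o): n for n, o in enumerate(kept)}
        all_loci = [
            dataclasses.replace(
                loc,
                snp_indices=tuple(
                    old_to_new[i] for i in loc.snp_indices if i in old_to_new
                ),
            )
            for loc in all_loci
        ]
        snp_map_qc = simulate.make_md_subset(
            snp_map_qc, config.md_fraction, seed=stage_seed("md_panel")
        )

        io.write_snp_map(out / "snp_map.tsv", snp_map_qc)
        io.write_pedigree(out / "pedigree.tsv", ped)
        io.write_truth_table(
            out / "truth.tsv", truth_table(all_loci, combined_haps.animals)
        )
        io.write_vcf(out / "genotypes.vcf", snp_map_qc, signals)
        artifacts["snp_map"] = out / "snp_map.tsv"
        artifacts["pedigree"] = out / "pedigree.tsv"
        artifacts["truth"] = out / "truth.tsv"
        artifacts["genotypes"] = out / "genotypes.vcf"
        if config.write_signal_files:
            io.write_signal_files(out / "signals", signals, snp_map_qc)

    with _stage("call"):
        pop_freq = signals.pop_b_freq()
        overrides = dict(config.hmm_overrides)
        calls = {}
        for name, panel, caller, params in (
            ("hd_penn", "hd", "penn_like", calling.penn_params(**overrides)),
            ("hd_quanti", "hd", "quanti_like", calling.quanti_params(**overrides)),
            ("md_penn", "md", "penn_like", calling.penn_params(**overrides)),
        ):
            calls[name] = calling.call_cnvs(
                signals, snp_map_qc, panel=panel, caller=caller, params=params,
                min_snps=config.min_snps_per_call, pop_b_freq=pop_freq,
            )
            io.write_calls_tsv(out / f"calls_{name}.tsv", calls[name])
            io.write_calls_bed(out / f"calls_{name}.bed", calls[name])
            artifacts[f"calls_{name}"] = out / f"calls_{name}.tsv"

    with _stage("concord"):
        md_map = snp_map_qc.md_subset()
        records = concordance.classify_overlaps(
            calls["hd_penn"], calls["md_penn"], md_map
        )
        if records:
            summary = concordance.summarize_concordance(records)
            with open(out / "concordance_summary.json", "w") as fh:
                json.dump(summary.to_dict(), fh, indent=2, sort_keys=True, default=float)
            concordance.records_to_frame(records).to_csv(
                out / "concordance_records.tsv", sep="\t", index=False,
                float_format="%.6g",
            )
            artifacts["concordance_summary"] = out / "concordance_summary.json"
            artifacts["concordance_records"] = out / "concordance_records.tsv"

    with _stage("impute"):
        consensus = imputation.consensus_calls(
            calls["hd_penn"], calls["hd_quanti"], config.consensus_snp_tolerance
        )
        selected = imputation.group_loci_and_select(
            consensus, ped, config.min_carriers, config.locus_bp_tolerance
        )
        imputed = imputation.run_imputation_experiment(
            selected, combined_haps, snp_map_qc, ped,
            ks=config.flank_k,
            mode=config.encoding_mode,
            method=config.imputer_method,
            frac_reference=config.frac_reference,
            max_ref_haps=config.max_ref_haps,
            switch_rate=config.switch_rate,
            error_rate=config.error_rate,
            truth_loci=all_loci,
        )
        imputed.to_csv(out / "imputed.tsv", sep="\t", index=False, float_format="%.6g")
        artifacts["imputed"] = out / "imputed.tsv"

    with _stage("evaluate"):
        eval_summary: dict = {}
        if imputed.empty:
            logger.warning("imputation stage empty (no locus met the carrier threshold)")
        else:
            records = evaluation.imputation_accuracy(imputed)
            records.to_csv(
                out / "accuracy_records.tsv", sep="\t", index=False, float_format="%.6g"
            )
            artifacts["accuracy_records"] = out / "accuracy_records.tsv"
            agreement = evaluation.agreement_by_breed(imputed)
            evaluation.render_reports(
                records, agreement, out_dir=out / "report", plots=config.write_plots
            )
            for f in sorted((out / "report").iterdir()):
                if f.suffix in (".tsv", ".csv", ".txt"):
                    artifacts[f"report/{f.name}"] = f
            eval_summary["ari_by_breed"] = {
                r["breed"]: r["ari"] for _, r in agreement.iterrows()
            }
            for factor in ("k", "called_state", "breed"):
                groups = {
                    str(k): sub["accuracy"].values
                    for k, sub in records.groupby(factor)
                    if len(sub) >= 2
                }
                if len(groups) >= 2:
                    res = evaluation.anova_tukey(groups)
                    eval_summary[f"anova_{factor}"] = {
                        "f": res.f_stat,
                        "p": res.p_value,
                        "tukey": res.tukey.astype(str).to_dict(orient="records"),
                    }
            cnv_recs = records[records["called_state"] != 2]
            for xcol, label in (
                ("population_frequency", "frequency"),
                ("length_kb", "length"),
            ):
                if (
                    len(cnv_recs) >= 4
                    and cnv_recs[xcol].nunique() > 1
                    and cnv_recs["accuracy"].nunique() > 1
                ):
                    cr = evaluation.pearson_fisher_ci(
                        cnv_recs[xcol], cnv_recs["accuracy"]
                    )
                    eval_summary[f"correlation_accuracy_vs_{label}"] = {
                        "r": cr.r, "n": cr.n, "ci95": list(cr.ci95),
                        "significant": cr.significant,
                    }
            bf = evaluation.compare_bayes_factors(imputed)
            if not bf.empty:
                eval_summary["bayes_factor_comparison"] = bf.to_dict(orient="records")
            with open(out / "evaluation_summary.json", "w") as fh:
                json.dump(eval_summary, fh, indent=2, sort_keys=True, default=float)
            artifacts["evaluation_summary"] = out / "evaluation_summary.json"

    manifest = {
        "config": config.to_dict(),
        "artifacts": {k: _sha256(p) for k, p in sorted(artifacts.items())},
        "n_calls": {k: len(v) for k, v in calls.items()},
        "n_consensus": len(consensus),
        "n_selected_loci": {b: len(v) for b, v in selected.items()},
    }
    config.to_yaml(out / "config.yaml")
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
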
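"""Per-animal concordance of CNVs called from the HD versus the MD panel.

Each HD call is classified against the same animal's MD calls on the same
chromosome: ``direct`` (identical start and end coordinates), ``partial``
(intervals intersect) or ``none``. Intervals are 1-based closed, so the
overlap of [100,200] and [150,400] is 51 bp. When several MD calls
intersect one HD call, the one with the largest overlap wins (ties to the
leftmost start) and the multiplicity is logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .types import CnvCall, SnpMap, calls_to_frame

logger = logging.getLogger(__name__)

CATEGORIES = ("direct", "partial", "none")


@dataclass(frozen=True)
class OverlapRecord:
    hd_call: CnvCall
    md_call: Optional[CnvCall]
    category: str
    overlap_bp: int
    md_snps_in_region: int = 0


def _overlap_bp(a: CnvCall, b: CnvCall) -> int:
    lo = max(a.start_bp, b.start_bp)
    hi = min(a.end_bp, b.end_bp)
    return max(0, hi - lo + 1)


def md_snp_density(hd_call: CnvCall, md_map: SnpMap) -> int:
    """Number of MD SNPs inside the HD call's closed interval (binary search)."""
    ci = md_map.chrom_indices(hd_call.chrom)
    pos = md_map.pos_bp[ci]
    lo = np.searchsorted(pos, hd_call.start_bp, side="left")
    hi = np.searchsorted(pos, hd_call.end_bp, side="right")
    return int(hi - lo)


def classify_overlaps(
    hd_calls: Sequence[CnvCall],
    md_calls: Sequence[CnvCall],
    md_map: Optional[SnpMap] = None,
) -> list[OverlapRecord]:
    """One record per HD call, matched within the same animal and chromosome.

    Copy-number state is deliberately not required to match: the comparison
    is of genomic position only. If ``md_map`` is given, each record carries
    the count of MD SNPs in the HD call's region.
    """
    by_key: dict[tuple[str, int], list[CnvCall]] = {}
    for m in md_calls:
        by_key.setdefault((m.animal_id, m.chrom), []).append(m)
    for v in by_key.values():
        v.sort(key=lambda c: (c.start_bp, c.end_bp))

    records = []
    multi = 0
    for h in hd_calls:
        cands = by_key.get((h.animal_id, h.chrom), [])
        hits = [(m, _overlap_bp(h, m)) for m in cands]
        hits = [(m, o) for m, o in hits if o > 0]
        if len(hits) > 1:
            multi += 1
        if not hits:
            best, best_o = None, 0
            cat = "none"
        else:
            # largest overlap wins; ties to the leftmost start
            best, best_o = max(hits, key=lambda t: (t[1], -t[0].start_bp))
            cat = (
                "direct"
                if best.start_bp == h.start_bp and best.end_bp == h.end_bp
                else "partial"
            )
        density = md_snp_density(h, md_map) if md_map is not None else 0
        records.append(OverlapRecord(h, best, cat, best_o, density))
    if multi:
        logger.info("%d HD calls intersected more than one MD call", multi)
    return records


def records_to_frame(records: Sequence[OverlapRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        h = r.hd_call
        rows.append(
            {
                "animal_id": h.animal_id,
                "chrom": h.chrom,
                "start_bp": h.start_bp,
                "end_bp": h.end_bp,
                "length_kb": h.length_kb,
                "n_snps": h.n_snps,
                "copy_number": h.copy_number,
                "category": r.category,
                "overlap_bp": r.overlap_bp,
                "md_snps_in_region": r.md_snps_in_region,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "animal_id", "chrom", "start_bp", "end_bp", "length_kb", "n_snps",
            "copy_number", "category", "overlap_bp", "md_snps_in_region",
        ],
    )


def call_population_frequency(calls: Sequence[CnvCall]) -> pd.Series:
    """Number of animals sharing each exact call region (chrom, start, end)."""
    df = calls_to_frame(list(calls))
    if df.empty:
        return pd.Series(dtype=int)
    grp = df.groupby(["chrom", "start_bp", "end_bp"])["animal_id"].nunique()
    return grp


@dataclass
class ConcordanceSummary:
    """Table-style summary of the HD-vs-MD comparison."""

    per_category: pd.DataFrame  # count + quartiles of length and SNP count
    fraction_none: float
    fraction_lt3_md_snps: float
    anova_length_p: Optional[float]
    anova_frequency_p: Optional[float]

    def to_dict(self) -> dict:
        return {
            "per_category": self.per_category.to_dict(orient="index"),
            "fraction_none": self.fraction_none,
            "fraction_lt3_md_snps": self.fraction_lt3_md_snps,
            "anova_length_p": self.anova_length_p,
            "anova_frequency_p": self.anova_frequency_p,
        }


def summarize_concordance(records: Sequence[OverlapRecord]) -> ConcordanceSummary:
    """Per-category counts and quartiles; ANOVA across categories.

    Quartiles use the linear-interpolation convention. Population frequency
    of a call is the number of animals sharing its exact region among the HD
    calls. Categories with fewer than two records are kept in the summary
    but excluded from the tests.
    """
    if not records:
        raise ValueError("need at least one overlap record")
    df = records_to_frame(records)
    freq = call_population_frequency([r.hd_call for r in records])
    df["population_frequency"] = [
        int(freq.loc[(r.hd_call.chrom, r.hd_call.start_bp, r.hd_call.end_bp)])
        for r in records
    ]

    rows = {}
    for cat in CATEGORIES:
        sub = df[df["category"] == cat]
        if len(sub):
            q = lambda col, p: float(np.quantile(sub[col].values, p))  # noqa: E731
            rows[cat] = {
                "count": int(len(sub)),
                "q1_length_kb": q("length_kb", 0.25),
                "median_length_kb": q("length_kb", 0.5),
                "q3_length_kb": q("length_kb", 0.75),
                "q1_n_snps": q("n_snps", 0.25),
                "median_n_snps": q("n_snps", 0.5),
                "q3_n_snps": q("n_snps", 0.75),
                "mean_population_frequency": float(sub["population_frequency"].mean()),
            }
        else:
            rows[cat] = {
                "count": 0,
                "q1_length_kb": np.nan, "median_length_kb": np.nan, "q3_length_kb": np.nan,
                "q1_n_snps": np.nan, "median_n_snps": np.nan, "q3_n_snps": np.nan,
                "mean_population_frequency": np.nan,
            }
    per_cat = pd.DataFrame.from_dict(rows, orient="index")

    def _anova(col: str) -> Optional[float]:
        groups = [
            df[df["category"] == cat][col].values
            for cat in CATEGORIES
            if (df["category"] == cat).sum() >= 2
        ]
        if len(groups) < 2:
            return None
        if all(np.ptp(g) == 0 for g in groups) and len({g[0] for g in groups}) == 1:
            return 1.0
        return float(stats.f_oneway(*groups).pvalue)

    return ConcordanceSummary(
        per_category=per_cat,
        fraction_none=float((df["category"] == "none").mean()),
        fraction_lt3_md_snps=float((df["md_snps_in_region"] < 3).mean()),
        anova_length_p=_anova("length_kb"),
        anova_frequency_p=_anova("population_frequency"),
    )
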
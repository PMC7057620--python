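"""Evaluation statistics for the imputation experiment.

Covers per-CNV, per-called-state imputation accuracy; the Hubert--Arabie
adjusted Rand index between called and imputed copy numbers; one-way ANOVA
with Tukey's range test across factor groups; Pearson correlations with
Fisher r-to-z 95% confidence intervals; the Bayes-factor comparison between
correctly and incorrectly imputed CNVs; and table/figure-style report
rendering.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# accuracy
# ---------------------------------------------------------------------------

def imputation_accuracy(
    results: pd.DataFrame,
    denominator: str = "called",
    group_cols: Sequence[str] = ("breed", "locus_id", "k", "mode", "method"),
) -> pd.DataFrame:
    """Per-(locus, called state) imputation accuracy records.

    A CNV is correctly imputed when the imputed copy number equals the
    called copy number. With ``denominator="called"`` (default) the
    accuracy of a state at a locus is correct / times that state was called
    in the validation animals; ``denominator="all_validation"`` divides by
    all validation animals of the group instead. States never called in
    validation produce no record.
    """
    if denominator not in ("called", "all_validation"):
        raise ValueError(f"unknown denominator {denominator!r}")
    required = {"called_cn", "imputed_cn", "animal_id", *group_cols}
    missing = required - set(results.columns)
    if missing:
        raise ValueError(f"results missing columns: {sorted(missing)}")
    df = results.copy()
    df["correct"] = (df["called_cn"] == df["imputed_cn"]).astype(int)
    meta_cols = [
        c for c in ("population_frequency", "length_kb", "mean_bayes_factor", "chrom",
                    "start_bp", "end_bp")
        if c in df.columns
    ]
    group_total = df.groupby(list(group_cols), sort=True)["animal_id"].count()
    rows = []
    for key, sub in df.groupby(list(group_cols) + ["called_cn"], sort=True):
        *gkey, state = key
        n_called = len(sub)
        n_correct = int(sub["correct"].sum())
        denom = n_called if denominator == "called" else int(group_total.loc[tuple(gkey)])
        rec = dict(zip(group_cols, gkey))
        rec.update(
            called_state=int(state),
            n_called=n_called,
            n_correct=n_correct,
            accuracy=n_correct / denom,
        )
        for c in meta_cols:
            rec[c] = sub[c].iloc[0]
        rows.append(rec)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# adjusted Rand index
# ---------------------------------------------------------------------------

def adjusted_rand_index(labels_a: Sequence, labels_b: Sequence) -> float:
    """Hubert--Arabie adjusted Rand index of two labelings.

    Pair-counting agreement corrected for chance: 1 for identical
    partitions, about 0 for independent random labelings, negative for less
    agreement than expected by chance. When both labelings are a single
    cluster the chance-adjustment denominator vanishes and 0 is returned
    (with a log note).
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("labelings must be equal-length 1-D sequences")
    n = len(a)
    if n < 2:
        raise ValueError("need at least 2 items")
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    ct = np.zeros((ai.max() + 1, bi.max() + 1), dtype=np.int64)
    np.add.at(ct, (ai, bi), 1)

    def comb2(x):
        return x * (x - 1) / 2.0

    sum_cells = comb2(ct).sum()
    sum_rows = comb2(ct.sum(axis=1)).sum()
    sum_cols = comb2(ct.sum(axis=0)).sum()
    total = comb2(n)
    expected = sum_rows * sum_cols / total
    max_index = 0.5 * (sum_rows + sum_cols)
    if max_index == expected:
        logger.info("both labelings form a single cluster; ARI defined as 0")
        return 0.0
    return float((sum_cells - expected) / (max_index - expected))


def agreement_by_breed(results: pd.DataFrame) -> pd.DataFrame:
    """ARI between called and imputed copy number, per breed.

    Pools every (validation animal x selected locus) pair of the breed,
    states included as-is. Also returns the called x imputed contingency
    table flattened into counts.
    """
    rows = []
    for breed, sub in results.groupby("breed", sort=True):
        ari = adjusted_rand_index(sub["called_cn"].values, sub["imputed_cn"].values)
        rows.append({"breed": breed, "n_pairs": len(sub), "ari": ari})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# ANOVA + Tukey
# ---------------------------------------------------------------------------

@dataclass
class AnovaTukeyResult:
    f_stat: float
    p_value: float
    group_means: dict
    tukey: pd.DataFrame  # group1, group2, meandiff, p_adj, reject


def anova_tukey(groups: dict, alpha: float = 0.05) -> AnovaTukeyResult:
    """One-way ANOVA plus Tukey HSD pairwise comparisons.

    ``groups`` maps factor level -> accuracy values. Groups with fewer than
    two values are excluded with a warning. Pairs are declared different at
    adjusted p < alpha.
    """
    usable = {k: np.asarray(v, dtype=float) for k, v in groups.items() if len(v) >= 2}
    dropped = set(groups) - set(usable)
    if dropped:
        logger.warning("groups excluded from ANOVA (fewer than 2 values): %s", sorted(dropped))
    if len(usable) < 2:
        raise ValueError("need at least 2 groups with >= 2 values each")
    vals = list(usable.values())
    flat = np.concatenate(vals)
    labels = np.concatenate([[k] * len(v) for k, v in usable.items()])
    within_var = sum(((v - v.mean()) ** 2).sum() for v in vals)
    if within_var == 0.0:
        # degenerate spread: every group is constant, so the studentized
        # range is undefined; pairs differ exactly when their means differ
        keys = list(usable)
        pairs = [(a, b) for i, a in enumerate(keys) for b in keys[i + 1:]]
        rows = []
        for a, b in pairs:
            diff = float(usable[b].mean() - usable[a].mean())
            rows.append((a, b, diff, 1.0 if diff == 0 else 0.0, diff != 0))
        tk = pd.DataFrame(rows, columns=["group1", "group2", "meandiff", "p_adj", "reject"])
        f = 0.0 if np.ptp(flat) == 0 else math.inf
        return AnovaTukeyResult(
            f, 1.0 if f == 0.0 else 0.0,
            {k: float(v.mean()) for k, v in usable.items()}, tk,
        )
    f, p = sps.f_oneway(*vals)
    res = pairwise_tukeyhsd(flat, labels, alpha=alpha)
    tk = pd.DataFrame(
        res.summary().data[1:], columns=[c.replace("-", "_") for c in res.summary().data[0]]
    )
    tk = tk.rename(columns={"p_adj": "p_adj", "meandiff": "meandiff"})
    tk = tk[["group1", "group2", "meandiff", "p_adj", "reject"]]
    return AnovaTukeyResult(
        float(f), float(p), {k: float(v.mean()) for k, v in usable.items()}, tk
    )


# ---------------------------------------------------------------------------
# Pearson + Fisher CI
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int
    ci95: tuple[float, float]
    significant: bool  # CI excludes zero


def pearson_fisher_ci(
    x: Sequence[float], y: Sequence[float], alpha: float = 0.05
) -> CorrelationResult:
    """Pearson correlation with a Fisher r-to-z confidence interval.

    CI = tanh(atanh(r) +/- z_{1-alpha/2} / sqrt(n - 3)); the correlation is
    considered different from zero only when the CI excludes zero.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 4:
        raise ValueError("need equal-length x, y with n >= 4")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in input")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined: zero variance in x or y")
    n = len(x)
    r = float(np.corrcoef(x, y)[0, 1])
    z = sps.norm.ppf(1 - alpha / 2)
    if abs(r) >= 1.0:
        lo = hi = float(np.sign(r))
    else:
        zr = math.atanh(r)
        half = z / math.sqrt(n - 3)
        lo, hi = math.tanh(zr - half), math.tanh(zr + half)
    return CorrelationResult(r=r, n=n, ci95=(lo, hi), significant=not (lo <= 0.0 <= hi))


# ---------------------------------------------------------------------------
# Bayes-factor comparison
# ---------------------------------------------------------------------------

def compare_bayes_factors(results: pd.DataFrame) -> pd.DataFrame:
    """Does the Bayes factor differ between correctly and incorrectly imputed CNVs?

    One-way ANOVA (two levels: called == imputed vs not) on the per-instance
    mean Bayes factors of CNV (non-normal) calls, per breed and pooled; the
    direction of the mean difference (correct minus incorrect) is reported.
    Strata with an empty level are skipped.
    """
    df = results.dropna(subset=["mean_bayes_factor"])
    df = df[df["called_cn"] != 2]
    rows = []

    def one(name: str, sub: pd.DataFrame) -> None:
        correct = sub.loc[sub["called_cn"] == sub["imputed_cn"], "mean_bayes_factor"].values
        wrong = sub.loc[sub["called_cn"] != sub["imputed_cn"], "mean_bayes_factor"].values
        if len(correct) == 0 or len(wrong) == 0:
            logger.info("Bayes-factor test skipped for %s: one level empty", name)
            return
        if np.ptp(np.concatenate([correct, wrong])) == 0:
            f, p = 0.0, 1.0
        else:
            f, p = sps.f_oneway(correct, wrong)
        diff = float(correct.mean() - wrong.mean())
        rows.append(
            {
                "stratum": name,
                "n_correct": len(correct),
                "n_incorrect": len(wrong),
                "mean_diff": diff,
                "f_stat": float(f),
                "p_value": float(p),
                "direction": "none" if p >= 0.05 else ("positive" if diff > 0 else "negative"),
            }
        )

    for breed, sub in df.groupby("breed", sort=True):
        one(str(breed), sub)
    one("pooled", df)
    return pd.DataFrame(
        rows,
        columns=["stratum", "n_correct", "n_incorrect", "mean_diff", "f_stat", "p_value", "direction"],
    )


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

def accuracy_quartile_table(records: pd.DataFrame) -> pd.DataFrame:
    """Quartiles of accuracy grouped by called state and breed.

    Quantiles use linear interpolation; each row also carries the group
    size. Mirrors the per-state, per-breed accuracy summary table layout.
    """
    rows = []
    for (state, breed), sub in records.groupby(["called_state", "breed"], sort=True):
        acc = sub["accuracy"].values
        rows.append(
            {
                "called_state": int(state),
                "breed": breed,
                "q1": float(np.quantile(acc, 0.25)),
                "median": float(np.quantile(acc, 0.5)),
                "q3": float(np.quantile(acc, 0.75)),
                "n_cnvs": len(sub),
            }
        )
    return pd.DataFrame(rows, columns=["called_state", "breed", "q1", "median", "q3", "n_cnvs"])


def high_accuracy_table(records: pd.DataFrame, threshold: float = 0.85) -> pd.DataFrame:
    """Loci (CNV states excluded for the normal state) imputed with accuracy >= threshold.

    Lists genomic location, breed, population frequency and accuracy (as a
    percentage) for non-normal called states; an empty table is a valid
    outcome.
    """
    sub = records[(records["called_state"] != 2) & (records["accuracy"] >= threshold)]
    cols = ["locus_id", "breed", "called_state", "accuracy"]
    extra = [c for c in ("chrom", "start_bp", "end_bp", "population_frequency") if c in records.columns]
    out = sub[cols + extra].copy()
    out["accuracy_pct"] = out["accuracy"] * 100.0
    return out.reset_index(drop=True)


def scatter_data(records: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Plot-ready accuracy scatter data keyed by x-variable.

    ``frequency``: accuracy vs population frequency; ``length``: accuracy
    vs genomic length (kb); both state-coded. Row counts equal the record
    count whenever the metadata column exists.
    """
    out = {}
    if "population_frequency" in records.columns:
        out["frequency"] = records[
            ["locus_id", "breed", "called_state", "population_frequency", "accuracy"]
        ].copy()
    if "length_kb" in records.columns:
        out["length"] = records[
            ["locus_id", "breed", "called_state", "length_kb", "accuracy"]
        ].copy()
    return out


def render_reports(
    records: pd.DataFrame,
    agreement: Optional[pd.DataFrame] = None,
    correlations: Optional[dict[str, CorrelationResult]] = None,
    out_dir=None,
    plots: bool = False,
) -> dict:
    """Assemble (and optionally write) the evaluation tables and figures.

    Returns a dict with the quartile table, the high-accuracy listing, the
    scatter frames, and any agreement/correlation inputs. With ``out_dir``
    set the tables are written as TSV (footnoted with the linear-interpolation
    quantile convention) and, with ``plots=True``, PNG scatters.
    """
    if records.empty:
        raise ValueError("no accuracy records to report")
    report = {
        "quartiles": accuracy_quartile_table(records),
        "high_accuracy": high_accuracy_table(records),
        "scatter": scatter_data(records),
        "agreement": agreement,
        "correlations": correlations,
    }
    if out_dir is not None:
        import pathlib

        out = pathlib.Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        report["quartiles"].to_csv(out / "accuracy_quartiles.tsv", sep="\t", index=False)
        report["high_accuracy"].to_csv(out / "high_accuracy_loci.tsv", sep="\t", index=False)
        for name, df in report["scatter"].items():
            df.to_csv(out / f"scatter_accuracy_vs_{name}.csv", index=False)
        if agreement is not None:
            agreement.to_csv(out / "agreement_ari.tsv", sep="\t", index=False)
        with open(out / "README.txt", "w") as fh:
            fh.write("Quantiles use the linear-interpolation convention.\n")
        if plots:
            _write_scatter_plots(report["scatter"], out)
    return report


def _write_scatter_plots(scatter: dict[str, pd.DataFrame], out) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for name, df in scatter.items():
        xcol = "population_frequency" if name == "frequency" else "length_kb"
        fig, ax = plt.subplots(figsize=(5, 4))
        for state, sub in df.groupby("called_state"):
            ax.scatter(sub[xcol], sub["accuracy"] * 100, label=f"called cn {state}", s=18)
        ax.set_xlabel(xcol.replace("_", " "))
        ax.set_ylabel("imputation accuracy (%)")
        ax.legend(fontsize=7)
        fig.tight_layout()
        fig.savefig(out / f"scatter_accuracy_vs_{name}.png", dpi=120)
        plt.close(fig)
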
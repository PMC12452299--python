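"""Allele-specific expression around XCI status.

The allelic ratio AR = min(refCount, altCount) / (refCount + altCount) folds
the minor allele under 0.5, so AR = 0 is fully monoallelic and AR = 0.5 fully
biallelic; it is symmetric in ref/alt, and a minimum total read count (10 by
default) gates informativeness.  Per-gene AR aggregates SNPs by a
read-count-weighted mean of per-SNP ARs (pooling folded counts across SNPs
with opposite allelic skews would fabricate biallelic signal; count pooling
remains available as ``sum_counts``).  A gene's AR change on knockdown is
concordant-up only when AR rises in every knockdown clone, concordant-down
only when it falls in every clone; equality in any clone is discordant.

Testing layer: Fisher's exact test on the escape/inactive x up/down
contingency table (two-sided minimum-likelihood convention, sample odds
ratio ad/bc), Shapiro-Wilk normality per group and the Mann-Whitney U test
on escape vs inactive delta-AR.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "allelic_ratio",
    "gene_ar",
    "classify_ar_change",
    "build_ar_table",
    "xci_contingency",
    "delta_ar_test",
    "DeltaARTest",
]

MIN_TOTAL = 10


def allelic_ratio(ref_count: int, alt_count: int, min_total: int = MIN_TOTAL) -> float:
    """Folded allelic ratio of one SNP, NaN below the read-count cutoff."""
    if ref_count < 0 or alt_count < 0:
        raise ValueError("allele counts must be non-negative")
    total = ref_count + alt_count
    if total < min_total:
        return float("nan")
    return min(ref_count, alt_count) / total


def gene_ar(
    snp_records: pd.DataFrame,
    aggregation: str = "weighted_mean",
    min_total: int = MIN_TOTAL,
) -> float:
    """Aggregate the SNPs of one gene in one sample into a single AR.

    ``weighted_mean``: total-read-weighted mean of per-SNP ARs (default).
    ``sum_counts``: AR of ref/alt sums across SNPs — phase-blind, can read
    opposite skews as biallelic.  SNPs below ``min_total`` are ignored; NaN
    when none passes.
    """
    if aggregation not in ("weighted_mean", "sum_counts"):
        raise ValueError(f"unknown aggregation {aggregation!r}")
    ref = snp_records["refCount"].to_numpy(dtype=float)
    alt = snp_records["altCount"].to_numpy(dtype=float)
    if (ref < 0).any() or (alt < 0).any():
        raise ValueError("allele counts must be non-negative")
    total = ref + alt
    ok = total >= min_total
    if not ok.any():
        return float("nan")
    if aggregation == "sum_counts":
        r, a = ref[ok].sum(), alt[ok].sum()
        return min(r, a) / (r + a)
    ar = np.minimum(ref[ok], alt[ok]) / total[ok]
    return float(np.average(ar, weights=total[ok]))


def classify_ar_change(ar_ctrl: float, ar_kd: list[float] | np.ndarray) -> str:
    """Concordance class of a gene's AR change across knockdown clones.

    'up' iff AR increased in every clone, 'down' iff it decreased in every
    clone, 'discordant' otherwise (including any exact tie); any missing AR
    makes the gene 'incomplete'.
    """
    kd = np.asarray(ar_kd, dtype=float)
    if math.isnan(ar_ctrl) or np.isnan(kd).any() or kd.size == 0:
        return "incomplete"
    delta = kd - ar_ctrl
    if (delta > 0).all():
        return "up"
    if (delta < 0).all():
        return "down"
    return "discordant"


def build_ar_table(
    allele_counts: pd.DataFrame,
    xci_status: pd.Series,
    control: str,
    knockdowns: list[str],
    min_total: int = MIN_TOTAL,
    aggregation: str = "weighted_mean",
) -> pd.DataFrame:
    """Per-gene AR table across control and knockdown samples.

    Columns: AR_<sample> per sample, n_snps, total_reads, xci_status,
    dAR_<kd> = AR_kd - AR_control per knockdown clone, and ar_class.
    Genes without XCI annotation get status 'unknown'.
    """
    if not knockdowns:
        raise ValueError("need at least one knockdown sample")
    samples = [control, *knockdowns]
    present = set(allele_counts["sample_id"])
    missing = [s for s in samples if s not in present]
    if missing:
        raise ValueError(f"samples absent from allele counts: {missing}")
    rows = {}
    for gene, gdf in allele_counts.groupby("gene_id"):
        row: dict[str, float] = {}
        for s in samples:
            sdf = gdf[gdf["sample_id"] == s]
            row[f"AR_{s}"] = gene_ar(sdf, aggregation=aggregation, min_total=min_total) if len(sdf) else float("nan")
        sdf = gdf[gdf["sample_id"].isin(samples)]
        row["n_snps"] = int(sdf["pos"].nunique())
        row["total_reads"] = int((sdf["refCount"] + sdf["altCount"]).sum())
        rows[gene] = row
    tab = pd.DataFrame.from_dict(rows, orient="index").rename_axis("gene_id")
    tab["xci_status"] = xci_status.reindex(tab.index).fillna("unknown")
    for kd in knockdowns:
        tab[f"dAR_{kd}"] = tab[f"AR_{kd}"] - tab[f"AR_{control}"]
    tab["ar_class"] = [
        classify_ar_change(row[f"AR_{control}"], [row[f"AR_{kd}"] for kd in knockdowns])
        for _, row in tab.iterrows()
    ]
    return tab


@dataclass
class ContingencyResult:
    table: pd.DataFrame  # escape/inactive x up/down
    odds_ratio: float  # sample OR ad/bc; NaN when a margin cell is zero
    p: float  # Fisher's exact, two-sided


def xci_contingency(ar_table: pd.DataFrame) -> ContingencyResult:
    """Fisher's exact test of AR-change direction against XCI status.

    Only concordant genes (ar_class up/down) with escape or inactive status
    enter the 2x2.  The odds ratio is the unconditional sample estimate
    (a*d)/(b*c); the p value is the exact two-sided tail summing
    hypergeometric outcomes no more likely than the observed table.
    """
    sub = ar_table[
        ar_table["ar_class"].isin(["up", "down"])
        & ar_table["xci_status"].isin(["escape", "inactive"])
    ]
    tab = pd.crosstab(sub["xci_status"], sub["ar_class"]).reindex(
        index=["escape", "inactive"], columns=["up", "down"], fill_value=0
    )
    return contingency_fisher(tab)


def contingency_fisher(tab: pd.DataFrame) -> ContingencyResult:
    a, b = int(tab.iloc[0, 0]), int(tab.iloc[0, 1])
    c, d = int(tab.iloc[1, 0]), int(tab.iloc[1, 1])
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    odds = (a * d) / (b * c) if b * c > 0 else float("nan")
    return ContingencyResult(table=tab, odds_ratio=float(odds), p=float(p))


@dataclass
class DeltaARTest:
    shapiro_p_escape: float
    shapiro_p_inactive: float
    mannwhitney_u: float
    mannwhitney_p: float
    n_escape: int
    n_inactive: int


def delta_ar_test(delta_ar_escape, delta_ar_inactive) -> DeltaARTest:
    """Escape vs inactive delta-AR: Shapiro-Wilk per group, Mann-Whitney U.

    The rank test is two-sided, exact for small groups (n <= 8 per side,
    no ties) and tie-corrected normal otherwise.  Shapiro-Wilk is reported
    for both groups but never gates the rank test.
    """
    esc = np.asarray(delta_ar_escape, dtype=float)
    ina = np.asarray(delta_ar_inactive, dtype=float)
    esc, ina = esc[~np.isnan(esc)], ina[~np.isnan(ina)]
    if esc.size < 2 or ina.size < 2:
        raise ValueError("need at least two values per group")
    sw_e = stats.shapiro(esc).pvalue if esc.size >= 3 else float("nan")
    sw_i = stats.shapiro(ina).pvalue if ina.size >= 3 else float("nan")
    method = "exact" if max(esc.size, ina.size) <= 8 else "asymptotic"
    try:
        mw = stats.mannwhitneyu(esc, ina, alternative="two-sided", method=method)
    except ValueError:  # exact method refuses ties
        mw = stats.mannwhitneyu(esc, ina, alternative="two-sided", method="asymptotic")
    return DeltaARTest(
        shapiro_p_escape=float(sw_e),
        shapiro_p_inactive=float(sw_i),
        mannwhitney_u=float(mw.statistic),
        mannwhitney_p=float(mw.pvalue),
        n_escape=int(esc.size),
        n_inactive=int(ina.size),
    )
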
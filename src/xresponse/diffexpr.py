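"""Count normalization, expression summaries and a minimal NB Wald DE test.

The differential-expression test here is deliberately minimal: median-of-ratios
size factors, a fitted mean-dispersion trend on method-of-moments estimates,
a pseudocounted log2 fold change and a Wald p value from the delta-method
standard error, with Benjamini-Hochberg adjustment.  It exists so that
synthetic count matrices can be pushed end to end through the chromosome-level
analysis; real-data DE tables produced by dedicated tools are ingested as-is
(no shrinkage, no independent filtering is attempted here).

DEG classification uses strict cutoffs padj < alpha and |log2FC| > 0.58
(fold change 1.5x in either direction).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from xresponse.annotations_io import CountMatrix, DE_COLUMNS

__all__ = [
    "size_factors",
    "tpm",
    "fpkm",
    "percent_reduction",
    "benjamini_hochberg",
    "nb_wald_test",
    "classify_degs",
    "fc_from_fpkm",
    "filter_expressed",
]

UP_LFC = 0.58
DOWN_LFC = -0.58
ALPHA = 0.05


def size_factors(counts: pd.DataFrame, allow_pseudo_reference: bool = False) -> pd.Series:
    """Median-of-ratios size factors.

    For each gene with no zero count, the reference is the geometric mean
    across samples; the factor of sample j is the median over those genes of
    count_gj / reference_g.  When no all-nonzero gene exists the estimator is
    undefined; ``allow_pseudo_reference`` switches to a geometric mean over
    positive counts only.
    """
    mat = counts.to_numpy(dtype=float)
    eligible = (mat > 0).all(axis=1)
    if eligible.any():
        sub = mat[eligible]
        ref = np.exp(np.log(sub).mean(axis=1))
        factors = np.median(sub / ref[:, None], axis=0)
        return pd.Series(factors, index=counts.columns, name="size_factor")
    if not allow_pseudo_reference:
        raise ValueError(
            "no gene observed in every sample; re-run with "
            "allow_pseudo_reference=True to use a positive-count reference"
        )
    with np.errstate(divide="ignore"):
        logs = np.where(mat > 0, np.log(np.maximum(mat, 1e-300)), np.nan)
    ref = np.exp(np.nanmean(logs, axis=1))
    usable = np.isfinite(ref) & (ref > 0)
    if not usable.any():
        raise ValueError("count matrix is entirely zero; size factors undefined")
    ratios = mat[usable] / ref[usable, None]
    factors = np.nanmedian(np.where(ratios > 0, ratios, np.nan), axis=0)
    if np.isnan(factors).any() or (factors <= 0).any():
        raise ValueError("a sample has no positive count overlapping the reference")
    return pd.Series(factors, index=counts.columns, name="size_factor")


def tpm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Transcripts per million: length-rate normalized so columns sum to 1e6."""
    L = lengths.reindex(counts.index)
    if L.isna().any():
        raise ValueError("missing gene lengths for TPM")
    if (L <= 0).any():
        raise ValueError("gene lengths must be positive")
    rate = counts.div(L, axis=0)
    totals = rate.sum(axis=0)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise ValueError(f"all-zero samples have undefined TPM: {bad}")
    return rate.div(totals, axis=1) * 1e6


def fpkm(
    counts: pd.DataFrame,
    lengths: pd.Series,
    library_sizes: pd.Series | None = None,
) -> pd.DataFrame:
    """Fragments per kilobase per million mapped fragments."""
    L = lengths.reindex(counts.index)
    if (L <= 0).any() or L.isna().any():
        raise ValueError("gene lengths must be positive for FPKM")
    N = counts.sum(axis=0) if library_sizes is None else library_sizes.reindex(counts.columns)
    if (N <= 0).any():
        raise ValueError("library sizes must be positive")
    return counts.div(L, axis=0).div(N, axis=1) * 1e9


def percent_reduction(control_mean: float, deficient_mean: float) -> float:
    """Percentage reduction of expression relative to control.

    100 * (1 - deficient/control); negative values mean upregulation.
    """
    if control_mean <= 0:
        raise ValueError("percent reduction undefined for control mean <= 0")
    return 100.0 * (1.0 - deficient_mean / control_mean)


def benjamini_hochberg(pvalues: np.ndarray | pd.Series) -> np.ndarray:
    """BH-adjusted p values; NaN inputs yield NaN outputs."""
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def _fit_dispersion_trend(mu: np.ndarray, alpha_mom: np.ndarray) -> tuple[float, float]:
    """Fit alpha(mu) = a0 + a1/mu to method-of-moments dispersions.

    Weighted least squares on genes with a positive MoM estimate, iterated
    once with trimming of gross outliers (> 10x or < 0.1x the trend), in the
    spirit of parametric dispersion-trend fits for RNA-seq.
    """
    ok = (alpha_mom > 0) & (mu > 0) & np.isfinite(alpha_mom)
    if ok.sum() < 10:
        return float(np.median(alpha_mom[ok])) if ok.any() else 0.1, 0.0
    x = 1.0 / mu[ok]
    y = alpha_mom[ok]
    for _ in range(2):
        A = np.column_stack([np.ones_like(x), x])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        fit = A @ coef
        keep = (y < 10 * np.maximum(fit, 1e-8)) & (y > 0.1 * np.maximum(fit, 1e-8))
        if keep.sum() < 10 or keep.all():
            break
        x, y = x[keep], y[keep]
    a0, a1 = float(coef[0]), float(coef[1])
    return max(a0, 0.0), max(a1, 0.0)


def nb_wald_test(
    cm: CountMatrix,
    pseudocount: float = 0.5,
    dispersion_floor: float = 1e-8,
) -> pd.DataFrame:
    """Minimal negative-binomial Wald test, deficient vs control.

    Per gene: size-factor-normalized condition means; dispersion from the
    fitted mean-dispersion trend evaluated at the gene's overall mean
    (floored); log2 fold change of pseudocounted normalized means; Wald z
    from the delta-method standard error of the log ratio; two-sided normal
    p; BH adjustment over genes with non-missing p.  Genes with zero counts
    in every sample get missing p/padj.
    """
    ctrl = cm.samples("control")
    defi = cm.samples("deficient")
    if len(ctrl) < 2 or len(defi) < 2:
        raise ValueError("need >= 2 samples per condition for the Wald test")
    sf = size_factors(cm.counts, allow_pseudo_reference=True)
    norm = cm.counts.div(sf, axis=1).to_numpy(dtype=float)
    cols = list(cm.counts.columns)
    ia = np.array([cols.index(s) for s in ctrl])
    ib = np.array([cols.index(s) for s in defi])
    na, nb = len(ia), len(ib)
    mean_a = norm[:, ia].mean(axis=1)
    mean_b = norm[:, ib].mean(axis=1)
    mean_all = norm.mean(axis=1)

    # MoM dispersion on normalized counts, pooled within-condition:
    # Var(y) ~ mu/s + alpha mu^2; solve alpha per gene, then replace by trend.
    s_mean = 1.0 / np.mean(1.0 / sf.to_numpy())
    var_w = (
        norm[:, ia].var(axis=1, ddof=1) * (na - 1) + norm[:, ib].var(axis=1, ddof=1) * (nb - 1)
    ) / (na + nb - 2)
    mu_pool = (mean_a * na + mean_b * nb) / (na + nb)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_mom = (var_w - mu_pool / s_mean) / np.square(mu_pool)
    a0, a1 = _fit_dispersion_trend(mu_pool, alpha_mom)
    with np.errstate(divide="ignore"):
        alpha = np.maximum(a0 + a1 / np.maximum(mu_pool, 1e-12), dispersion_floor)

    log2fc = np.log2(mean_b + pseudocount) - np.log2(mean_a + pseudocount)

    inv_s_a = np.mean(1.0 / sf.to_numpy()[ia])
    inv_s_b = np.mean(1.0 / sf.to_numpy()[ib])
    var_mean_a = (mean_a * inv_s_a + alpha * mean_a**2) / na
    var_mean_b = (mean_b * inv_s_b + alpha * mean_b**2) / nb
    with np.errstate(divide="ignore", invalid="ignore"):
        var_log = var_mean_a / np.square(mean_a + pseudocount) + var_mean_b / np.square(
            mean_b + pseudocount
        )
        z = (np.log(2.0) * log2fc) / np.sqrt(var_log)
    p = 2.0 * stats.norm.sf(np.abs(z))
    allzero = (cm.counts.to_numpy() == 0).all(axis=1)
    p[allzero] = np.nan
    log2fc[allzero] = 0.0

    det = pd.DataFrame(
        {
            "log2fc": log2fc,
            "pvalue": p,
            "padj": benjamini_hochberg(p),
            "mean_expr": mean_all,
            "deg_class": "none",
        },
        index=cm.counts.index,
    )
    return classify_degs(det)


def classify_degs(
    det: pd.DataFrame,
    up_lfc: float = UP_LFC,
    down_lfc: float = DOWN_LFC,
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """Fill deg_class: up iff padj < alpha and log2fc > up_lfc (strict),
    down iff padj < alpha and log2fc < down_lfc; missing padj is never a DEG."""
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    padj = det["padj"].to_numpy(dtype=float)
    lfc = det["log2fc"].to_numpy(dtype=float)
    sig = ~np.isnan(padj) & (padj < alpha)
    cls = np.where(sig & (lfc > up_lfc), "up", np.where(sig & (lfc < down_lfc), "down", "none"))
    out = det.copy()
    out["deg_class"] = cls
    return out[[c for c in DE_COLUMNS if c in out.columns] + [c for c in out.columns if c not in DE_COLUMNS]]


def fc_from_fpkm(wt_fpkm: np.ndarray, ko_fpkm: np.ndarray) -> float:
    """Fold change as the mean over replicate pairs of KO/WT FPKM.

    Pairs with WT FPKM of zero are skipped (with a warning); if every pair is
    skipped the fold change is missing (NaN).
    """
    wt = np.asarray(wt_fpkm, dtype=float)
    ko = np.asarray(ko_fpkm, dtype=float)
    if wt.shape != ko.shape:
        raise ValueError("replicate FPKM vectors must be paired")
    ok = wt > 0
    if not ok.all():
        import warnings

        warnings.warn(f"skipping {int((~ok).sum())} replicate pair(s) with WT FPKM = 0", stacklevel=2)
    if not ok.any():
        return float("nan")
    return float(np.mean(ko[ok] / wt[ok]))


def filter_expressed(fpkm_table: pd.DataFrame, threshold: float = 1.0) -> pd.Index:
    """Genes whose mean FPKM is >= threshold (inclusive)."""
    if fpkm_table.empty:
        return fpkm_table.index
    return fpkm_table.index[fpkm_table.mean(axis=1) >= threshold]
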
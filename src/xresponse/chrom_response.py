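"""Chromosome-level transcriptional response.

Per-chromosome DEG percentages and descending ranks, two-proportion Z tests
of the X chromosome against pooled autosomes (and of the top-ranked
chromosome against the pooled rest), selection of a gene-count-matched
control autosome, and Kolmogorov-Smirnov comparisons of per-gene log2
fold-change distributions (the cumulative-distribution-shift analysis).

The ranking universe excludes the Y chromosome and unplaced scaffolds: the
human X is ranked among 23 chromosomes, the mouse X among 20.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from xresponse.annotations_io import GenomeAnnotation, normalize_chrom

__all__ = [
    "ChromosomeSummary",
    "DistributionComparison",
    "chrom_deg_percentages",
    "two_proportion_z",
    "x_vs_autosome_tests",
    "pick_control_chromosome",
    "compare_distributions",
    "cdf_comparison_suite",
]

DEG_CLASSES = ("up", "down", "deg")


def _chrom_sort_key(name: str):
    body = name[3:] if name.lower().startswith("chr") else name
    return (0, int(body)) if body.isdigit() else (1, body)


def sorted_chromosomes(names) -> list[str]:
    """Karyotype order: numeric chromosomes first, then lexicographic."""
    return sorted(names, key=_chrom_sort_key)


@dataclass
class ChromosomeSummary:
    """Per-chromosome DEG counts/percentages/ranks plus bookkeeping.

    ``table`` is indexed by chromosome with columns n_genes, n_up, n_down,
    n_deg, pct_up, pct_down, pct_deg, rank_up, rank_down, rank_deg.
    ``n_unmapped`` counts DE genes absent from the annotation (excluded).
    """

    table: pd.DataFrame
    n_unmapped: int = 0
    excluded_chroms: tuple[str, ...] = ()


@dataclass
class DistributionComparison:
    """Two-sample KS comparison of log2 fold-change distributions."""

    label_a: str
    label_b: str
    D: float
    p: float
    median_shift: float  # median(A) - median(B)
    direction: str  # right | left | none
    n_a: int = 0
    n_b: int = 0


def chrom_deg_percentages(
    det: pd.DataFrame,
    ann: GenomeAnnotation,
    exclude: tuple[str, ...] = ("chrY",),
) -> ChromosomeSummary:
    """Percentage of DEGs per chromosome = 100 * n_DEG / n_genes, per class.

    Ranks are descending (1 = highest percentage); ties break by karyotype
    chromosome-name order.  DE genes missing from the annotation are excluded
    and counted in ``n_unmapped``.
    """
    gene_chrom = pd.Series(
        ann.genes["chrom"].to_numpy(), index=ann.genes["gene_id"].to_numpy()
    )
    chroms = [c for c in sorted_chromosomes(ann.chromosomes) if c not in exclude]
    mapped = det.index.isin(gene_chrom.index)
    n_unmapped = int((~mapped).sum())
    det = det.loc[mapped]
    chrom_of = gene_chrom.loc[det.index]

    tab = pd.DataFrame(index=pd.Index(chroms, name="chrom"))
    tab["n_genes"] = ann.gene_counts().reindex(chroms, fill_value=0)
    cls = det["deg_class"]
    for name, mask in (("up", cls == "up"), ("down", cls == "down"), ("deg", cls != "none")):
        counts = chrom_of[mask.to_numpy()].value_counts()
        tab[f"n_{name}"] = counts.reindex(chroms, fill_value=0).astype(int)
        with np.errstate(invalid="ignore", divide="ignore"):
            tab[f"pct_{name}"] = np.where(
                tab["n_genes"] > 0, 100.0 * tab[f"n_{name}"] / tab["n_genes"], 0.0
            )
    # descending rank, name-order tie-break: stable sort over name-ordered rows
    for name in DEG_CLASSES:
        order = np.argsort(-tab[f"pct_{name}"].to_numpy(), kind="stable")
        ranks = np.empty(len(tab), dtype=int)
        ranks[order] = np.arange(1, len(tab) + 1)
        tab[f"rank_{name}"] = ranks
    return ChromosomeSummary(table=tab, n_unmapped=n_unmapped, excluded_chroms=tuple(exclude))


def two_proportion_z(k1: int, n1: int, k2: int, n2: int) -> tuple[float, float]:
    """Pooled-variance two-proportion z test, two-sided.

    z = (p1 - p2) / sqrt(p(1-p)(1/n1 + 1/n2)) with p the pooled proportion.
    Degenerate pooled proportions (0 or 1) carry no evidence: z = 0, p = 1.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("sample sizes must be positive")
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2):
        raise ValueError("successes must satisfy 0 <= k <= n")
    pooled = (k1 + k2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        return 0.0, 1.0
    se = np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    z = (k1 / n1 - k2 / n2) / se
    return float(z), float(2 * stats.norm.sf(abs(z)))


def x_vs_autosome_tests(summary: ChromosomeSummary, x_chrom: str = "chrX") -> pd.DataFrame:
    """Z tests per DEG class: X vs pooled autosomes, top-ranked vs pooled rest.

    Counts are pooled (summed DEGs over summed genes), so the comparison is
    of the X proportion against the aggregate autosomal proportion.
    """
    x_chrom = normalize_chrom(x_chrom)
    tab = summary.table
    if x_chrom not in tab.index:
        raise ValueError(f"{x_chrom} absent from the chromosome summary")
    rows = []
    for name in DEG_CLASSES:
        k_col, n_col = f"n_{name}", "n_genes"
        autosomes = tab.drop(index=x_chrom)
        z, p = two_proportion_z(
            int(tab.loc[x_chrom, k_col]),
            int(tab.loc[x_chrom, n_col]),
            int(autosomes[k_col].sum()),
            int(autosomes[n_col].sum()),
        )
        rows.append({"comparison": "x_vs_autosomes", "deg_class": name, "chrom": x_chrom, "z": z, "p": p})
        top = tab[f"rank_{name}"].idxmin()
        rest = tab.drop(index=top)
        z, p = two_proportion_z(
            int(tab.loc[top, k_col]),
            int(tab.loc[top, n_col]),
            int(rest[k_col].sum()),
            int(rest[n_col].sum()),
        )
        rows.append({"comparison": "top_vs_rest", "deg_class": name, "chrom": top, "z": z, "p": p})
    return pd.DataFrame(rows)


def pick_control_chromosome(ann: GenomeAnnotation, target: str = "chrX") -> str:
    """The autosome whose gene count is closest to the target chromosome's.

    In a human annotation this recovers chromosome 9, in mouse chromosome 10.
    Ties break toward the earlier chromosome in karyotype name order.
    """
    target = normalize_chrom(target)
    counts = ann.gene_counts()
    if target not in counts.index:
        raise ValueError(f"target chromosome {target} not in annotation")
    autosomes = [
        c
        for c in sorted_chromosomes(counts.index)
        if c not in (target, "chrX", "chrY")
    ]
    if not autosomes:
        raise ValueError("no autosomes available")
    t = counts[target]
    return min(autosomes, key=lambda c: (abs(int(counts[c]) - int(t)), _chrom_sort_key(c)))


def compare_distributions(
    values_a,
    values_b,
    label_a: str = "A",
    label_b: str = "B",
    alpha: float = 0.05,
) -> DistributionComparison:
    """Two-sample two-sided Kolmogorov-Smirnov comparison.

    ``direction`` is 'right' when the A distribution sits to the right of B
    (positive median shift) at KS significance, 'left' for the converse, else
    'none'.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    res = stats.ks_2samp(a, b, alternative="two-sided", method="asymp")
    shift = float(np.median(a) - np.median(b))
    if res.pvalue < alpha and shift > 0:
        direction = "right"
    elif res.pvalue < alpha and shift < 0:
        direction = "left"
    else:
        direction = "none"
    return DistributionComparison(
        label_a=label_a,
        label_b=label_b,
        D=float(res.statistic),
        p=float(res.pvalue),
        median_shift=shift,
        direction=direction,
        n_a=int(a.size),
        n_b=int(b.size),
    )


def cdf_comparison_suite(
    det: pd.DataFrame,
    ann: GenomeAnnotation,
    x_chrom: str = "chrX",
    control_chrom: str | None = None,
    expressed_only: bool = False,
    expressed_genes=None,
    exclude: tuple[str, ...] = ("chrY",),
) -> pd.DataFrame:
    """The three pairwise KS comparisons of log2 fold-change distributions:
    X vs autosomes, control chromosome vs autosomes, X vs control chromosome.

    The universe is every gene with a non-missing log2 fold change; with
    ``expressed_only`` it is restricted to ``expressed_genes`` (e.g. the
    FPKM >= 1 subset).  Autosome pools exclude the X, the control chromosome
    keeps its own genes, and excluded chromosomes never enter any pool.
    """
    x_chrom = normalize_chrom(x_chrom)
    if control_chrom is None:
        control_chrom = pick_control_chromosome(ann, target=x_chrom)
    control_chrom = normalize_chrom(control_chrom)
    gene_chrom = pd.Series(
        ann.genes["chrom"].to_numpy(), index=ann.genes["gene_id"].to_numpy()
    )
    sub = det[det["log2fc"].notna() & det.index.isin(gene_chrom.index)]
    if expressed_only:
        if expressed_genes is None:
            raise ValueError("expressed_only requires expressed_genes")
        sub = sub[sub.index.isin(pd.Index(expressed_genes))]
    chrom_of = gene_chrom.loc[sub.index]
    lfc = sub["log2fc"]
    x_vals = lfc[(chrom_of == x_chrom).to_numpy()]
    ctl_vals = lfc[(chrom_of == control_chrom).to_numpy()]
    auto_mask = (~chrom_of.isin([x_chrom, "chrY", *exclude])).to_numpy()
    auto_vals = lfc[auto_mask]
    comps = [
        compare_distributions(x_vals, auto_vals, x_chrom, "autosomes"),
        compare_distributions(ctl_vals, auto_vals, control_chrom, "autosomes"),
        compare_distributions(x_vals, ctl_vals, x_chrom, control_chrom),
    ]
    return pd.DataFrame([vars(c) for c in comps])
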
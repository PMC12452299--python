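"""Synthetic study generator with known ground truth.

Emulates the statistical structure of an XIST/Xist-loss RNA-seq study so
that every pipeline stage can be exercised without downloads:

* a genome of configurable autosomes plus an X chromosome, with gene
  midpoints drawn from a kernel-smoothed inhomogeneous intensity (clustered
  along each chromosome);
* SINE density positively coupled and LINE density negatively coupled to
  gene density through a Gaussian copula on the shared latent intensity
  field, calibrated so that the realized window-density correlations hit
  the configured targets (the lognormal transform and the Poisson sampling
  attenuation are both corrected for analytically);
* negative-binomial counts with lognormal gene means, a mean-dispersion
  trend, and lognormal sample-specific size factors; an "XIST" gene on the
  X is knocked down to a configurable residual in deficient samples;
* three scenarios — ``stem`` (a fraction f_x of X-linked genes upregulated
  by delta log2 units, the undifferentiated-cell response), ``differentiated``
  (the same number of affected genes placed genome-uniformly) and ``null``;
* binomial allelic counts: minor-allele fraction ~0.02 for XCI-inactive
  genes and ~0.25 for escape genes in control, shifted up (reactivation) or
  down (monoallelization) by dp_kd in knockdown clones for configured gene
  subsets.

Every stage derives its RNG deterministically from (seed, stage), so stages
regenerate independently and a fixed seed reproduces the study byte for
byte.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from xresponse.annotations_io import (
    CountMatrix,
    GenomeAnnotation,
    write_allele_counts,
    write_count_matrix,
    write_de_table,
    write_gene_annotation,
    write_xci_status,
)

__all__ = [
    "SimulationConfig",
    "SimulatedStudy",
    "simulate_annotation",
    "simulate_xci_status",
    "simulate_counts",
    "simulate_allele_counts",
    "simulate_bundle",
    "write_bundle",
]

_STAGE_ANNOTATION = 1
_STAGE_XCI = 2
_STAGE_COUNTS = 3
_STAGE_ALLELE = 4


@dataclass
class SimulationConfig:
    """Study conditions for the generator; defaults are the desk-scale
    scenario (a ~5,000-gene genome, 3 vs 3 replicates, f_x = 0.15 of
    X-linked genes shifted by one log2 unit in the stem scenario)."""

    seed: int = 0
    # genome
    n_autosomes: int = 22
    autosome_length: int = 100_000_000
    x_length: int = 155_000_000
    genes_per_chrom: int = 217  # per autosome_length; other chroms scale by length
    cluster_bandwidth: int = 500_000  # bp; smoothing of the latent intensity
    gene_intensity_sd: float = 0.7
    sine_per_mb: float = 60.0
    line_per_mb: float = 40.0
    sine_intensity_sd: float = 0.8
    line_intensity_sd: float = 0.5  # smaller sd keeps the negative coupling feasible
    rho_gene_sine: float = 0.6
    rho_gene_line: float = -0.4
    # expression
    scenario: str = "stem"  # stem | differentiated | null
    f_x: float = 0.15
    delta: float = 1.0
    n_reps: int = 3
    log_mu_mean: float = 4.7  # lognormal gene means, ~110 counts
    log_mu_sd: float = 1.2
    alpha0: float = 0.05  # asymptotic dispersion of the trend alpha0 + alpha1/mu
    alpha1: float = 2.0
    alpha_noise_sd: float = 0.2
    size_factor_sd: float = 0.15
    include_xist: bool = True
    xist_mu: float = 2000.0
    xist_residual: float = 0.08  # deficient/control expression ratio of XIST
    # XCI status of X-linked genes
    escape_frac: float = 0.2
    variable_frac: float = 0.05
    # allelic model
    p_inactive: float = 0.02
    p_escape: float = 0.25
    dp_kd: float = 0.2
    reads_per_snp: int = 60
    snps_per_gene: int = 3
    n_kd_clones: int = 2
    ar_gene_frac: float = 0.6  # X genes with informative SNPs
    react_frac: float = 0.15  # of informative genes, shifted +dp_kd on KD
    mono_frac: float = 0.15  # shifted -dp_kd on KD

    def __post_init__(self) -> None:
        for name in ("f_x", "escape_frac", "variable_frac", "ar_gene_frac", "react_frac", "mono_frac"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        for name in ("rho_gene_sine", "rho_gene_line"):
            if not -1 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [-1, 1]")
        if self.scenario not in ("stem", "differentiated", "null"):
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if min(self.autosome_length, self.x_length, self.cluster_bandwidth) <= 0:
            raise ValueError("lengths must be positive")

    def chrom_lengths(self) -> dict[str, int]:
        lengths = {f"chr{i}": self.autosome_length for i in range(1, self.n_autosomes + 1)}
        lengths["chrX"] = self.x_length
        return lengths

    def rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), int(stage)])


def _smooth_field(rng: np.random.Generator, n_bins: int, bandwidth_bins: float) -> np.ndarray:
    """Unit-variance smooth Gaussian field on a bin grid."""
    raw = rng.standard_normal(n_bins)
    if bandwidth_bins > 0 and n_bins > 3:
        sm = gaussian_filter1d(raw, sigma=bandwidth_bins, mode="wrap")
        sd = sm.std()
        if sd > 0:
            return sm / sd
    return raw


def _latent_rho(rho_target: float, sd_a: float, sd_b: float) -> float:
    """Latent Gaussian correlation whose lognormal-transformed fields have
    the target correlation: inverse of the lognormal correlation formula."""
    if rho_target == 0:
        return 0.0
    scale = np.sqrt(np.expm1(sd_a**2) * np.expm1(sd_b**2))
    arg = 1.0 + rho_target * scale
    if arg <= 0:
        return -0.999
    return float(np.log(arg) / (sd_a * sd_b))


def _window_smoothing_factor(bins_per_window: int, bandwidth_bins: float) -> float:
    """Mean pairwise latent correlation of the bins inside one window.

    Smoothed Gaussian fields decorrelate with lag d as exp(-d^2 / (4 s^2));
    averaging k partially correlated bins shrinks the window-level intensity
    variance by this factor.
    """
    k = max(int(bins_per_window), 1)
    if k == 1 or bandwidth_bins <= 0:
        return 1.0
    d = np.arange(k)
    corr = np.exp(-np.subtract.outer(d, d) ** 2 / (4.0 * bandwidth_bins**2))
    return float(corr.mean())


def _poisson_attenuation(lam_per_window: float, sd: float, smoothing: float = 1.0) -> float:
    """sqrt(share of window-count variance carried by the intensity)."""
    if lam_per_window <= 0:
        return 1.0
    v_int = lam_per_window * np.expm1(sd**2) * smoothing
    return float(np.sqrt(v_int / (v_int + 1.0)))


def _coupled_field(
    base: np.ndarray, indep: np.ndarray, rho_latent: float
) -> np.ndarray:
    rho_latent = float(np.clip(rho_latent, -0.999, 0.999))
    return rho_latent * base + np.sqrt(1 - rho_latent**2) * indep


def _place_features(
    rng: np.random.Generator,
    n: int,
    weights: np.ndarray,
    bin_size: int,
    chrom_length: int,
    lengths: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample feature intervals: a bin per feature (multinomial on the
    intensity), a uniform position inside the bin, the given lengths."""
    probs = weights / weights.sum()
    bins = rng.choice(len(weights), size=n, p=probs)
    offset = rng.uniform(0, bin_size, size=n)
    starts = np.minimum((bins * bin_size + offset).astype(np.int64), chrom_length - 1)
    ends = np.minimum(starts + np.maximum(lengths.astype(np.int64), 1), chrom_length)
    starts = np.minimum(starts, ends - 1)
    return starts, ends


def simulate_annotation(
    config: SimulationConfig, window: int = 1_000_000, step: int = 250_000
) -> tuple[GenomeAnnotation, pd.DataFrame, dict]:
    """Generate the genome annotation and repeat track.

    Returns (annotation, repeat track, truth) where truth records, per
    chromosome, the latent bin intensities of the three feature classes and
    the latent correlations actually used, so density-recovery tests can
    compare realized window correlations against the configured targets.
    """
    rng = config.rng(_STAGE_ANNOTATION)
    bin_size = step
    gene_rows = []
    repeat_rows = []
    truth: dict = {"latent": {}, "config_rho": (config.rho_gene_sine, config.rho_gene_line)}
    sd_g, sd_s, sd_l = (
        config.gene_intensity_sd,
        config.sine_intensity_sd,
        config.line_intensity_sd,
    )
    for chrom, L in config.chrom_lengths().items():
        n_bins = max(L // bin_size, 4)
        bw_bins = config.cluster_bandwidth / bin_size
        z_g = _smooth_field(rng, n_bins, bw_bins)
        e_s = _smooth_field(rng, n_bins, bw_bins)
        e_l = _smooth_field(rng, n_bins, bw_bins)

        n_genes = max(int(round(config.genes_per_chrom * L / config.autosome_length)), 2)
        n_sine = int(round(config.sine_per_mb * L / 1e6))
        n_line = int(round(config.line_per_mb * L / 1e6))

        # calibrate the latent coupling: undo the lognormal transform and the
        # Poisson count-sampling attenuation at the nominal window size
        wins_per = window / 1e6
        smooth = _window_smoothing_factor(window // bin_size, bw_bins)
        att_g = _poisson_attenuation(n_genes / L * 1e6 * wins_per, sd_g, smooth)
        att_s = _poisson_attenuation(config.sine_per_mb * wins_per, sd_s, smooth)
        att_l = _poisson_attenuation(config.line_per_mb * wins_per, sd_l, smooth)
        want_s = config.rho_gene_sine / max(att_g * att_s, 1e-6)
        want_l = config.rho_gene_line / max(att_g * att_l, 1e-6)
        rho_s = _latent_rho(np.clip(want_s, -0.999, 0.999), sd_g, sd_s)
        rho_l = _latent_rho(np.clip(want_l, -0.999, 0.999), sd_g, sd_l)
        for name, want, got in (("SINE", want_s, rho_s), ("LINE", want_l, rho_l)):
            if abs(want) > 0.999 or abs(got) > 0.999:
                warnings.warn(
                    f"{chrom}: gene-{name} coupling target infeasible; using latent rho "
                    f"{float(np.clip(got, -0.999, 0.999)):.3f}",
                    stacklevel=2,
                )
        z_s = _coupled_field(z_g, e_s, rho_s)
        z_l = _coupled_field(z_g, e_l, rho_l)
        w_g = np.exp(sd_g * z_g - sd_g**2 / 2)
        w_s = np.exp(sd_s * z_s - sd_s**2 / 2)
        w_l = np.exp(sd_l * z_l - sd_l**2 / 2)
        truth["latent"][chrom] = {
            "bin_size": bin_size,
            "gene_intensity": w_g,
            "sine_intensity": w_s,
            "line_intensity": w_l,
            "rho_latent_sine": rho_s,
            "rho_latent_line": rho_l,
        }

        glen = np.clip(rng.lognormal(np.log(2e4), 0.8, size=n_genes), 200, 2e5)
        gs, ge = _place_features(rng, n_genes, w_g, bin_size, L, glen)
        order = np.argsort(gs)
        for i, j in enumerate(order):
            gene_rows.append(
                {
                    "gene_id": f"{chrom}_g{i:04d}",
                    "chrom": chrom,
                    "start": int(gs[j]),
                    "end": int(ge[j]),
                    "strand": "+" if rng.random() < 0.5 else "-",
                    "length": int(ge[j] - gs[j]),
                }
            )
        slen = np.clip(rng.lognormal(np.log(300), 0.3, size=n_sine), 80, 1500)
        ss, se = _place_features(rng, n_sine, w_s, bin_size, L, slen)
        llen = np.clip(rng.lognormal(np.log(3000), 0.9, size=n_line), 200, 8000)
        ls, le = _place_features(rng, n_line, w_l, bin_size, L, llen)
        for cls, fs, fe in (("SINE", ss, se), ("LINE", ls, le)):
            for s, e in zip(fs, fe):
                repeat_rows.append({"chrom": chrom, "start": int(s), "end": int(e), "repeat_class": cls})

    genes = pd.DataFrame(gene_rows)
    if config.include_xist:
        # rename the X gene nearest the real XIST locus position
        x_genes = genes[genes["chrom"] == "chrX"]
        target = min(73_800_000, config.x_length // 2)
        mid = (x_genes["start"] + x_genes["end"]) // 2
        xist_row = (mid - target).abs().idxmin()
        genes.loc[xist_row, "gene_id"] = "XIST"
    ann = GenomeAnnotation(genes=genes, chrom_lengths=config.chrom_lengths())
    repeats = pd.DataFrame(repeat_rows, columns=["chrom", "start", "end", "repeat_class"])
    return ann, repeats, truth


def simulate_xci_status(ann: GenomeAnnotation, config: SimulationConfig) -> pd.Series:
    """Assign escape/variable/inactive status to X-linked genes."""
    rng = config.rng(_STAGE_XCI)
    x_genes = ann.genes.loc[ann.genes["chrom"] == "chrX", "gene_id"].to_numpy()
    u = rng.random(len(x_genes))
    status = np.where(
        u < config.escape_frac,
        "escape",
        np.where(u < config.escape_frac + config.variable_frac, "variable", "inactive"),
    )
    return pd.Series(status, index=x_genes, name="xci_status")


def simulate_counts(
    ann: GenomeAnnotation, config: SimulationConfig
) -> tuple[CountMatrix, pd.DataFrame]:
    """Negative-binomial count matrix plus the truth table of affected genes.

    ``stem``: round(f_x * n_X_genes) X-linked genes get a true log2 fold
    change of +delta in deficient samples; ``differentiated``: the same
    number of genes drawn genome-uniformly; ``null``: none.  The XIST gene
    (when present) is knocked down to ``xist_residual`` of its control mean
    in deficient samples.
    """
    rng = config.rng(_STAGE_COUNTS)
    gene_ids = ann.genes["gene_id"].to_numpy()
    chroms = ann.genes["chrom"].to_numpy()
    n_genes = len(gene_ids)
    mu = rng.lognormal(config.log_mu_mean, config.log_mu_sd, size=n_genes)
    alpha = (config.alpha0 + config.alpha1 / mu) * rng.lognormal(
        0.0, config.alpha_noise_sd, size=n_genes
    )

    is_x = chroms == "chrX"
    is_xist = gene_ids == "XIST"
    n_affect = int(round(config.f_x * int(is_x.sum())))
    true_lfc = np.zeros(n_genes)
    role = np.full(n_genes, "null", dtype=object)
    if config.scenario != "null" and n_affect > 0:
        pool = np.flatnonzero((is_x if config.scenario == "stem" else np.ones(n_genes, bool)) & ~is_xist)
        chosen = rng.choice(pool, size=min(n_affect, len(pool)), replace=False)
        true_lfc[chosen] = config.delta
        role[chosen] = "affected"
    if config.include_xist and is_xist.any():
        true_lfc[is_xist] = np.log2(config.xist_residual)
        role[is_xist] = "xist"
        mu[is_xist] = config.xist_mu

    samples = [f"control_{i + 1}" for i in range(config.n_reps)] + [
        f"deficient_{i + 1}" for i in range(config.n_reps)
    ]
    conditions = ["control"] * config.n_reps + ["deficient"] * config.n_reps
    sf = rng.lognormal(0.0, config.size_factor_sd, size=len(samples))
    counts = np.empty((n_genes, len(samples)), dtype=np.int64)
    for j, cond in enumerate(conditions):
        m = mu * (2.0**true_lfc if cond == "deficient" else 1.0) * sf[j]
        r = 1.0 / alpha
        p = r / (r + m)
        counts[:, j] = rng.negative_binomial(r, p)
    cm = CountMatrix(
        counts=pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene"), columns=samples),
        sample_meta=pd.DataFrame(
            {"condition": conditions, "replicate": [i % config.n_reps + 1 for i in range(len(samples))]},
            index=pd.Index(samples, name="sample"),
        ),
    )
    truth = pd.DataFrame(
        {
            "chrom": chroms,
            "true_log2fc": true_lfc,
            "affected": role == "affected",
            "role": role,
            "mu": mu,
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    return cm, truth


def simulate_allele_counts(
    ann: GenomeAnnotation, xci_status: pd.Series, config: SimulationConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Binomial per-SNP allelic counts for X-linked genes plus truth.

    In control samples, the minor-allele fraction p is ``p_inactive`` for
    XCI-inactive genes, ``p_escape`` for escape genes, and in between for
    variable genes.  In each knockdown clone, a reactivated subset shifts p
    by +dp_kd and a monoallelized subset by -dp_kd (clamped into [0, 0.5]).
    """
    rng = config.rng(_STAGE_ALLELE)
    genes = ann.genes.set_index("gene_id")
    x_genes = [g for g in xci_status.index if g in genes.index]
    n_pick = int(round(config.ar_gene_frac * len(x_genes)))
    picked = list(rng.choice(x_genes, size=n_pick, replace=False)) if n_pick else []
    shift = {}
    for g in picked:
        u = rng.random()
        shift[g] = "react" if u < config.react_frac else (
            "mono" if u < config.react_frac + config.mono_frac else "none"
        )
    samples = ["CTRL"] + [f"KD{i + 1}" for i in range(config.n_kd_clones)]
    base_p = {"inactive": config.p_inactive, "escape": config.p_escape}
    rows = []
    truth_rows = []
    for g in picked:
        status = xci_status[g]
        p0 = base_p.get(status, (config.p_inactive + config.p_escape) / 2)
        dp = {"react": config.dp_kd, "mono": -config.dp_kd, "none": 0.0}[shift[g]]
        p_kd = float(np.clip(p0 + dp, 0.0, 0.5))
        if shift[g] != "none" and p_kd in (0.0, 0.5) and p_kd == p0:
            warnings.warn(f"{g}: knockdown shift clamped to the [0, 0.5] boundary", stacklevel=2)
        start, end = int(genes.loc[g, "start"]), int(genes.loc[g, "end"])
        positions = np.sort(rng.integers(start, end, size=config.snps_per_gene))
        for sample in samples:
            p = p0 if sample == "CTRL" else p_kd
            minor = rng.binomial(config.reads_per_snp, p, size=config.snps_per_gene)
            for pos, alt in zip(positions, minor):
                rows.append(
                    {
                        "gene_id": g,
                        "chrom": "chrX",
                        "pos": int(pos),
                        "sample_id": sample,
                        "refCount": int(config.reads_per_snp - alt),
                        "altCount": int(alt),
                    }
                )
        truth_rows.append(
            {"gene_id": g, "xci_status": status, "p_control": p0, "p_kd": p_kd, "shift": shift[g]}
        )
    allele = pd.DataFrame(
        rows, columns=["gene_id", "chrom", "pos", "sample_id", "refCount", "altCount"]
    )
    truth = pd.DataFrame(
        truth_rows, columns=["gene_id", "xci_status", "p_control", "p_kd", "shift"]
    )
    return allele, truth


@dataclass
class SimulatedStudy:
    config: SimulationConfig
    annotation: GenomeAnnotation
    repeats: pd.DataFrame
    annotation_truth: dict
    counts: CountMatrix
    de_truth: pd.DataFrame
    xci_status: pd.Series
    allele_counts: pd.DataFrame
    allele_truth: pd.DataFrame


def simulate_bundle(config: SimulationConfig) -> SimulatedStudy:
    """Run every generator stage under one seed."""
    ann, repeats, ann_truth = simulate_annotation(config)
    xci = simulate_xci_status(ann, config)
    cm, de_truth = simulate_counts(ann, config)
    allele, allele_truth = simulate_allele_counts(ann, xci, config)
    return SimulatedStudy(
        config=config,
        annotation=ann,
        repeats=repeats,
        annotation_truth=ann_truth,
        counts=cm,
        de_truth=de_truth,
        xci_status=xci,
        allele_counts=allele,
        allele_truth=allele_truth,
    )


def write_bundle(study: SimulatedStudy, outdir: str | Path) -> dict[str, Path]:
    """Write every standard-format file the real pipeline consumes."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "annotation": outdir / "annotation.gtf",
        "chrom_lengths": outdir / "chrom_lengths.tsv",
        "repeats": outdir / "repeats.bed",
        "counts": outdir / "counts.tsv",
        "samples": outdir / "samples.tsv",
        "xci_status": outdir / "xci_status.tsv",
        "allele_counts": outdir / "allele_counts.tsv",
        "de_truth": outdir / "truth_degs.tsv",
        "allele_truth": outdir / "truth_allele.tsv",
        "config": outdir / "config.json",
    }
    write_gene_annotation(study.annotation, paths["annotation"], format="gtf")
    pd.Series(study.annotation.chrom_lengths, name="length").rename_axis("chrom").to_csv(
        paths["chrom_lengths"], sep="\t"
    )
    with open(paths["repeats"], "w", encoding="utf-8") as fh:
        for _, r in study.repeats.iterrows():
            fh.write(f"{r['chrom']}\t{r['start']}\t{r['end']}\t{r['repeat_class']}\n")
    write_count_matrix(study.counts, paths["counts"], paths["samples"])
    write_xci_status(study.xci_status, paths["xci_status"])
    write_allele_counts(study.allele_counts, paths["allele_counts"])
    study.de_truth.to_csv(paths["de_truth"], sep="\t")
    study.allele_truth.to_csv(paths["allele_truth"], sep="\t", index=False)
    with open(paths["config"], "w", encoding="utf-8") as fh:
        json.dump(dataclasses.asdict(study.config), fh, indent=2)
    return paths
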
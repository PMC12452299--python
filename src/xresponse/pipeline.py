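"""End-to-end orchestration: per-dataset runs and multi-dataset comparisons.

A run is described by a :class:`RunManifest` naming the input files and the
chosen options; every run serializes its manifest next to its outputs so a
rerun with the same manifest (and seed, where the DE test is involved)
reproduces every output file byte for byte.  All figures-worth of results
are written as tab-separated data files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from xresponse import __version__
from xresponse.annotations_io import (
    read_allele_counts,
    read_count_matrix,
    read_de_table,
    read_gene_annotation,
    read_repeat_annotation,
    read_xci_status,
    write_de_table,
)
from xresponse.allelic import build_ar_table, delta_ar_test, xci_contingency
from xresponse.chrom_response import (
    cdf_comparison_suite,
    chrom_deg_percentages,
    pick_control_chromosome,
    x_vs_autosome_tests,
)
from xresponse.density import (
    cross_dataset_correlation,
    deg_density_tracks,
    deg_position_table,
    density_correlation_suite,
    make_windows,
)
from xresponse.diffexpr import classify_degs, nb_wald_test
from xresponse.overlap import deg_intersections, deg_sets_from_de_tables, shared_degs

__all__ = ["RunManifest", "run_dataset", "run_comparative"]

log = logging.getLogger("xresponse")


@dataclass
class RunManifest:
    """Inputs and options of one dataset run."""

    label: str
    out_dir: str
    de_table: str | None = None
    de_dialect: str = "deseq2_results"
    counts: str | None = None
    sample_meta: str | None = None
    annotation: str | None = None
    annotation_format: str = "gtf"
    chrom_lengths: str | None = None
    repeats: str | None = None
    repeat_format: str = "bed"
    allele_counts: str | None = None
    xci_status: str | None = None
    control_sample: str = "CTRL"
    kd_samples: list[str] = field(default_factory=list)
    x_chrom: str = "chrX"
    control_chrom: str = "auto"
    window: int = 1_000_000
    step: int = 250_000
    min_total: int = 10
    ar_aggregation: str = "weighted_mean"
    seed: int = 0
    stages: list[str] = field(default_factory=lambda: ["chrom_response", "density"])

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["tool_version"] = __version__
        return json.dumps(d, indent=2, sort_keys=True)

    def require(self, attr: str, stage: str) -> str:
        v = getattr(self, attr)
        if not v:
            raise ValueError(f"stage {stage!r} requires manifest input {attr!r}")
        if not Path(v).exists():
            raise FileNotFoundError(f"{stage}: input {attr} = {v} does not exist")
        return v


def _preflight(manifest: RunManifest) -> None:
    needs = {
        "chrom_response": ["annotation"],
        "density": ["annotation", "repeats"],
        "allelic": ["allele_counts", "xci_status"],
    }
    if not (manifest.de_table or manifest.counts):
        raise ValueError("a DE table or a count matrix is required")
    if manifest.counts and not manifest.sample_meta:
        raise ValueError("counts input requires sample_meta")
    for stage in manifest.stages:
        if stage not in needs:
            raise ValueError(f"unknown stage {stage!r}")
        for attr in needs[stage]:
            manifest.require(attr, stage)


def run_dataset(manifest: RunManifest) -> dict[str, Path]:
    """Run the requested stages for one dataset; returns output paths."""
    _preflight(manifest)
    out = Path(manifest.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    if manifest.de_table:
        det = read_de_table(manifest.de_table, dialect=manifest.de_dialect)
        det = classify_degs(det)
    else:
        cm = read_count_matrix(manifest.require("counts", "de"), manifest.require("sample_meta", "de"))
        log.info("%s: DE test on %d genes x %d samples", manifest.label, *cm.counts.shape)
        det = nb_wald_test(cm)
    write_de_table(det, out / "de_table.tsv")
    written["de_table"] = out / "de_table.tsv"

    ann = None
    if manifest.annotation:
        lengths = None
        if manifest.chrom_lengths:
            lengths = (
                pd.read_csv(manifest.chrom_lengths, sep="\t", index_col=0)["length"].to_dict()
            )
        ann = read_gene_annotation(
            manifest.annotation, format=manifest.annotation_format, chrom_lengths=lengths
        )

    if "chrom_response" in manifest.stages:
        summary = chrom_deg_percentages(det, ann)
        summary.table.to_csv(out / "chrom_summary.tsv", sep="\t")
        written["chrom_summary"] = out / "chrom_summary.tsv"
        log.info("%s: %d DE genes not in annotation (excluded)", manifest.label, summary.n_unmapped)
        ztab = x_vs_autosome_tests(summary, x_chrom=manifest.x_chrom)
        ztab.to_csv(out / "z_tests.tsv", sep="\t", index=False)
        written["z_tests"] = out / "z_tests.tsv"
        control = (
            pick_control_chromosome(ann, target=manifest.x_chrom)
            if manifest.control_chrom == "auto"
            else manifest.control_chrom
        )
        ks = cdf_comparison_suite(det, ann, x_chrom=manifest.x_chrom, control_chrom=control)
        ks.to_csv(out / "ks_tests.tsv", sep="\t", index=False)
        written["ks_tests"] = out / "ks_tests.tsv"

    if "density" in manifest.stages:
        repeats = read_repeat_annotation(manifest.repeats, format=manifest.repeat_format)
        corr = density_correlation_suite(
            det, ann, repeats, chrom=manifest.x_chrom, window=manifest.window, step=manifest.step
        )
        corr.to_csv(out / "density_correlations.tsv", sep="\t", index=False)
        written["density_correlations"] = out / "density_correlations.tsv"
        tracks = deg_density_tracks(det, ann, manifest.x_chrom, manifest.window, manifest.step)
        frames = []
        for label, tr in tracks.items():
            f = tr.to_frame()
            f["track"] = label
            frames.append(f)
        pd.concat(frames).to_csv(out / "deg_density_tracks.tsv", sep="\t", index=False)
        written["deg_density_tracks"] = out / "deg_density_tracks.tsv"
        xci = read_xci_status(manifest.xci_status) if manifest.xci_status else None
        pos = deg_position_table(det, ann, chrom=manifest.x_chrom, xci_status=xci)
        pos.to_csv(out / "deg_positions.tsv", sep="\t")
        written["deg_positions"] = out / "deg_positions.tsv"

    if "allelic" in manifest.stages:
        allele = read_allele_counts(manifest.allele_counts)
        xci = read_xci_status(manifest.xci_status)
        art = build_ar_table(
            allele,
            xci,
            control=manifest.control_sample,
            knockdowns=manifest.kd_samples,
            min_total=manifest.min_total,
            aggregation=manifest.ar_aggregation,
        )
        art.to_csv(out / "ar_table.tsv", sep="\t")
        written["ar_table"] = out / "ar_table.tsv"
        cont = xci_contingency(art)
        rows = [
            {"statistic": "odds_ratio", "value": cont.odds_ratio},
            {"statistic": "fisher_p", "value": cont.p},
        ]
        concordant = art[art["ar_class"].isin(["up", "down"])]
        for kd in manifest.kd_samples:
            esc = concordant.loc[concordant["xci_status"] == "escape", f"dAR_{kd}"]
            ina = concordant.loc[concordant["xci_status"] == "inactive", f"dAR_{kd}"]
            if len(esc) >= 3 and len(ina) >= 3:
                t = delta_ar_test(esc, ina)
                rows += [
                    {"statistic": f"shapiro_p_escape_{kd}", "value": t.shapiro_p_escape},
                    {"statistic": f"shapiro_p_inactive_{kd}", "value": t.shapiro_p_inactive},
                    {"statistic": f"mannwhitney_p_{kd}", "value": t.mannwhitney_p},
                ]
        cont.table.to_csv(out / "xci_contingency.tsv", sep="\t")
        pd.DataFrame(rows).to_csv(out / "allelic_tests.tsv", sep="\t", index=False)
        written["xci_contingency"] = out / "xci_contingency.tsv"
        written["allelic_tests"] = out / "allelic_tests.tsv"

    (out / "manifest.json").write_text(manifest.to_json(), encoding="utf-8")
    written["manifest"] = out / "manifest.json"
    return written


def run_comparative(manifests: list[RunManifest], out_dir: str | Path) -> dict[str, Path]:
    """Cross-dataset DEG overlap and X-linked DEG density correlations.

    All datasets must share a window grid (same window/step and X-chromosome
    length); a mismatch raises with a pointer at the offending options.
    """
    if len(manifests) < 2:
        raise ValueError("comparative analysis needs at least two datasets")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    tables = {}
    tracks = {}
    for m in manifests:
        if not m.de_table and (Path(m.out_dir) / "de_table.tsv").exists():
            m = dataclasses.replace(m, de_table=str(Path(m.out_dir) / "de_table.tsv"))
        det = classify_degs(read_de_table(m.require("de_table", "compare"), dialect=m.de_dialect))
        tables[m.label] = det
        ann = read_gene_annotation(
            m.require("annotation", "compare"),
            format=m.annotation_format,
            chrom_lengths=pd.read_csv(m.chrom_lengths, sep="\t", index_col=0)["length"].to_dict()
            if m.chrom_lengths
            else None,
        )
        tracks[m.label] = deg_density_tracks(det, ann, m.x_chrom, m.window, m.step)["deg"]

    collection = deg_sets_from_de_tables(tables)
    for direction in ("up", "down"):
        memb, full = deg_intersections(collection, direction)
        memb.to_csv(out / f"overlap_{direction}.tsv", sep="\t", index=False)
        written[f"overlap_{direction}"] = out / f"overlap_{direction}.tsv"
        (out / f"shared_{direction}.txt").write_text(
            "\n".join(shared_degs(collection, list(collection), direction)) + "\n",
            encoding="utf-8",
        )
        written[f"shared_{direction}"] = out / f"shared_{direction}.txt"

    labels = [m.label for m in manifests]
    rows = []
    for i, la in enumerate(labels):
        for lb in labels[i + 1 :]:
            try:
                res = cross_dataset_correlation(tracks[la], tracks[lb])
            except ValueError as exc:
                raise ValueError(
                    f"{la} vs {lb}: {exc}; re-run both datasets with shared --window/--step"
                ) from exc
            rows.append({"dataset_a": la, "dataset_b": lb, "r": res.r, "p": res.p, "n": res.n})
    pd.DataFrame(rows).to_csv(out / "cross_dataset_correlations.tsv", sep="\t", index=False)
    written["cross_dataset_correlations"] = out / "cross_dataset_correlations.tsv"
    return written
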
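"""Sliding-window density tracks and their correlations.

Densities are computed along a chromosome in windows of 1 Mbp advanced by a
250 kbp step (defaults; four-fold overlapping windows).  A feature is placed
at its midpoint floor((start + end) / 2) in ``count`` mode, or contributes
its overlapped base pairs per window in ``coverage`` mode.  Only full
windows are kept, except that a chromosome shorter than one window yields a
single truncated window.

Correlations between tracks: sample Pearson r with a two-sided t test
(n - 2 df), and the first-order partial correlation controlling for a third
track (typically gene density), r_xy.z = (r_xy - r_xz r_yz) /
sqrt((1 - r_xz^2)(1 - r_yz^2)), t test with n - 3 df.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from xresponse.annotations_io import GenomeAnnotation, normalize_chrom

__all__ = [
    "Windows",
    "DensityTrack",
    "CorrelationResult",
    "midpoint",
    "make_windows",
    "density_track",
    "pearson",
    "partial_correlation",
    "deg_position_table",
    "cross_dataset_correlation",
    "deg_density_tracks",
    "density_correlation_suite",
]

WINDOW = 1_000_000
STEP = 250_000


def midpoint(start: int, end: int) -> int:
    """Feature midpoint, floor((start + end) / 2); requires start < end."""
    if start >= end:
        raise ValueError("start must be < end")
    return (start + end) // 2


@dataclass(frozen=True)
class Windows:
    starts: np.ndarray
    size: int  # actual window span in bp (== chromosome length if truncated)
    step: int
    nominal_size: int

    def __len__(self) -> int:
        return len(self.starts)


def make_windows(chrom_length: int, window: int = WINDOW, step: int = STEP) -> Windows:
    """Sliding full windows over [0, chrom_length).

    Window count is floor((L - window)/step) + 1; a chromosome shorter than
    one window yields the single truncated window [0, L).
    """
    if window <= 0 or step <= 0:
        raise ValueError("window and step must be positive")
    if step > window:
        raise ValueError("step must not exceed window")
    if chrom_length <= 0:
        raise ValueError("chromosome length must be positive")
    if chrom_length < window:
        return Windows(starts=np.array([0]), size=int(chrom_length), step=step, nominal_size=window)
    n = (chrom_length - window) // step + 1
    return Windows(starts=np.arange(n) * step, size=window, step=step, nominal_size=window)


@dataclass
class DensityTrack:
    chrom: str
    windows: Windows
    values: np.ndarray
    mode: str  # count | coverage
    label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != len(self.windows):
            raise ValueError("one value per window required")
        if (self.values < 0).any():
            raise ValueError("densities must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.chrom,
                "window_start": self.windows.starts,
                "window_end": self.windows.starts + self.windows.size,
                "value": self.values,
            }
        )


def density_track(
    features: pd.DataFrame,
    windows: Windows,
    chrom: str,
    mode: str = "count",
    label: str = "",
) -> DensityTrack:
    """Per-window density of features on one chromosome.

    ``count``: number of feature midpoints inside [start, start + size); an
    overlapping grid counts a midpoint in every window containing it.
    ``coverage``: overlapped base pairs divided by the window size.
    """
    chrom = normalize_chrom(chrom)
    feats = features[features["chrom"] == chrom] if "chrom" in features.columns else features
    starts = windows.starts
    if mode == "count":
        mids = np.sort(((feats["start"] + feats["end"]) // 2).to_numpy(dtype=np.int64)) if len(feats) else np.array([], dtype=np.int64)
        values = np.searchsorted(mids, starts + windows.size, side="left") - np.searchsorted(
            mids, starts, side="left"
        )
    elif mode == "coverage":
        fs = feats["start"].to_numpy(dtype=np.int64)
        fe = feats["end"].to_numpy(dtype=np.int64)
        values = np.zeros(len(starts), dtype=float)
        chunk = 64
        for i in range(0, len(starts), chunk):
            ws = starts[i : i + chunk, None]
            ov = np.clip(
                np.minimum(fe[None, :], ws + windows.size) - np.maximum(fs[None, :], ws), 0, None
            )
            values[i : i + chunk] = ov.sum(axis=1) / windows.size
    else:
        raise ValueError(f"unknown density mode {mode!r}")
    return DensityTrack(chrom=chrom, windows=windows, values=np.asarray(values, float), mode=mode, label=label)


@dataclass
class CorrelationResult:
    r: float
    p: float
    n: int
    kind: str = "pearson"
    controlled_for: str | None = None
    label_x: str = ""
    label_y: str = ""


def pearson(x, y, label_x: str = "", label_y: str = "") -> CorrelationResult:
    """Sample Pearson correlation with two-sided t test (n - 2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be equal-length vectors")
    if x.size < 3:
        raise ValueError("need at least 3 paired values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    res = stats.pearsonr(x, y)
    return CorrelationResult(
        r=float(res.statistic), p=float(res.pvalue), n=int(x.size), kind="pearson",
        label_x=label_x, label_y=label_y,
    )


def partial_correlation(x, y, z, label_x: str = "", label_y: str = "", controlled_for: str = "z") -> CorrelationResult:
    """First-order partial correlation of x and y controlling for z.

    r_xy.z = (r_xy - r_xz r_yz) / sqrt((1 - r_xz^2)(1 - r_yz^2)); the p value
    is from t = r sqrt((n-3)/(1-r^2)) with n - 3 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    if not (x.shape == y.shape == z.shape) or x.ndim != 1:
        raise ValueError("inputs must be equal-length vectors")
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 paired values for a partial correlation")
    r_xy = np.corrcoef(x, y)[0, 1]
    r_xz = np.corrcoef(x, z)[0, 1]
    r_yz = np.corrcoef(y, z)[0, 1]
    denom = (1 - r_xz**2) * (1 - r_yz**2)
    if denom <= 0:
        raise ValueError("partial correlation undefined: a control correlation is +-1")
    r = (r_xy - r_xz * r_yz) / np.sqrt(denom)
    r = float(np.clip(r, -1.0, 1.0))
    df = n - 3
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(df / (1 - r**2))
        p = float(2 * stats.t.sf(abs(t), df))
    return CorrelationResult(
        r=r, p=p, n=n, kind="partial", controlled_for=controlled_for,
        label_x=label_x, label_y=label_y,
    )


def deg_position_table(
    det: pd.DataFrame,
    ann: GenomeAnnotation,
    chrom: str = "chrX",
    xci_status: pd.Series | None = None,
    highlight: str = "XIST",
) -> pd.DataFrame:
    """Scatter data for DEGs along one chromosome.

    One row per DEG on ``chrom``: midpoint position, log2 fold change,
    direction (up/down), escape flag when XCI status is supplied, and a
    highlight flag for the XIST/Xist gene itself.
    """
    chrom = normalize_chrom(chrom)
    genes = ann.genes.set_index("gene_id")
    degs = det[det["deg_class"].isin(["up", "down"]) & det.index.isin(genes.index)]
    sub = genes.loc[degs.index]
    degs = degs[(sub["chrom"] == chrom).to_numpy()]
    sub = genes.loc[degs.index]
    out = pd.DataFrame(
        {
            "position": ((sub["start"] + sub["end"]) // 2).to_numpy(),
            "log2fc": degs["log2fc"].to_numpy(),
            "direction": degs["deg_class"].to_numpy(),
        },
        index=degs.index.rename("gene_id"),
    )
    if xci_status is not None:
        out["escape"] = xci_status.reindex(out.index).eq("escape").fillna(False).to_numpy()
    out["highlight"] = out.index.str.upper() == highlight.upper()
    return out.sort_values("position")


def cross_dataset_correlation(track_a: DensityTrack, track_b: DensityTrack) -> CorrelationResult:
    """Pearson correlation of two density tracks on an identical window grid."""
    wa, wb = track_a.windows, track_b.windows
    if (
        track_a.chrom != track_b.chrom
        or wa.size != wb.size
        or wa.step != wb.step
        or len(wa) != len(wb)
        or not np.array_equal(wa.starts, wb.starts)
    ):
        raise ValueError("window grids differ; recompute both tracks on a shared grid")
    return pearson(track_a.values, track_b.values, label_x=track_a.label, label_y=track_b.label)


def deg_density_tracks(
    det: pd.DataFrame,
    ann: GenomeAnnotation,
    chrom: str = "chrX",
    window: int = WINDOW,
    step: int = STEP,
) -> dict[str, DensityTrack]:
    """Count-mode density tracks of all/up/down DEGs on one chromosome."""
    chrom = normalize_chrom(chrom)
    windows = make_windows(ann.chrom_lengths[chrom], window, step)
    genes = ann.genes.set_index("gene_id")
    degs = det[det["deg_class"].isin(["up", "down"]) & det.index.isin(genes.index)]
    feat = genes.loc[degs.index, ["chrom", "start", "end"]].assign(deg_class=degs["deg_class"].to_numpy())
    tracks = {}
    for label, sub in (
        ("deg", feat),
        ("up", feat[feat["deg_class"] == "up"]),
        ("down", feat[feat["deg_class"] == "down"]),
    ):
        tracks[label] = density_track(sub, windows, chrom, mode="count", label=f"{label}_degs")
    return tracks


def density_correlation_suite(
    det: pd.DataFrame,
    ann: GenomeAnnotation,
    repeats: pd.DataFrame,
    chrom: str = "chrX",
    window: int = WINDOW,
    step: int = STEP,
    repeat_mode: str = "count",
    control_gene_density: bool = True,
) -> pd.DataFrame:
    """Correlations of DEG density with gene, SINE and LINE density on one
    chromosome, optionally adding SINE partial correlations controlling for
    gene density, for all/up/down DEG tracks.
    """
    chrom = normalize_chrom(chrom)
    windows = make_windows(ann.chrom_lengths[chrom], window, step)
    gene_track = density_track(
        ann.genes[ann.genes["chrom"] == chrom], windows, chrom, mode="count", label="genes"
    )
    rep_tracks = {
        cls: density_track(
            repeats[(repeats["repeat_class"] == cls)], windows, chrom, mode=repeat_mode, label=cls
        )
        for cls in ("SINE", "LINE")
    }
    deg_tracks = deg_density_tracks(det, ann, chrom, window, step)
    rows = []
    for deg_label, dtr in deg_tracks.items():
        if np.ptp(dtr.values) == 0:
            continue  # no DEGs of this class on the chromosome
        for other_label, otr in (("genes", gene_track), ("SINE", rep_tracks["SINE"]), ("LINE", rep_tracks["LINE"])):
            res = pearson(dtr.values, otr.values, label_x=f"{deg_label}_degs", label_y=other_label)
            rows.append(vars(res))
        if control_gene_density:
            res = partial_correlation(
                dtr.values,
                rep_tracks["SINE"].values,
                gene_track.values,
                label_x=f"{deg_label}_degs",
                label_y="SINE",
                controlled_for="genes",
            )
            rows.append(vars(res))
    rows.append(vars(pearson(rep_tracks["SINE"].values, rep_tracks["LINE"].values, label_x="SINE", label_y="LINE")))
    return pd.DataFrame(rows)
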
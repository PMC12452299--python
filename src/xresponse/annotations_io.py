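"""Readers/writers for external annotation and table formats.

All genomic intervals are stored 0-based half-open internally.  GTF input
(1-based, inclusive) is converted at the I/O boundary and converted back on
write, so a GTF -> internal -> GTF round trip restores the original
coordinates.  Chromosome names are normalized to the "chr"-prefixed dialect
("X" and "chrX" are the same chromosome).  All writers emit tab-separated
UTF-8 with a header line.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ParseError",
    "SchemaError",
    "GenomeAnnotation",
    "CountMatrix",
    "normalize_chrom",
    "read_gene_annotation",
    "write_gene_annotation",
    "read_repeat_annotation",
    "read_de_table",
    "write_de_table",
    "read_count_matrix",
    "write_count_matrix",
    "read_allele_counts",
    "write_allele_counts",
    "read_xci_status",
    "write_xci_status",
]

XCI_STATUSES = ("escape", "inactive", "variable", "unknown")
REPEAT_CLASSES = ("SINE", "LINE", "other")

DE_COLUMNS = ["log2fc", "pvalue", "padj", "mean_expr", "deg_class"]


class ParseError(ValueError):
    """A line of an input file could not be parsed in the named dialect."""


class SchemaError(ValueError):
    """An input table is missing a required column."""


def normalize_chrom(name: str) -> str:
    name = str(name).strip()
    if name.lower().startswith("chr"):
        return "chr" + name[3:]
    return "chr" + name


@dataclass
class GenomeAnnotation:
    """Gene coordinates (0-based half-open) plus chromosome lengths.

    ``genes`` columns: gene_id, chrom, start, end, strand, length.
    ``length`` is the transcribed length used for TPM/FPKM; it defaults to
    end - start, or to the union length of exon records when the source GTF
    carried exons.
    """

    genes: pd.DataFrame
    chrom_lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        g = self.genes
        required = ["gene_id", "chrom", "start", "end", "strand", "length"]
        missing = [c for c in required if c not in g.columns]
        if missing:
            raise SchemaError(f"annotation missing columns: {missing}")
        if g["gene_id"].duplicated().any():
            dups = sorted(g.loc[g["gene_id"].duplicated(), "gene_id"].unique())
            raise ValueError(f"duplicated gene ids: {dups[:10]}")
        if (g["start"] < 0).any() or (g["end"] <= g["start"]).any():
            bad = g.loc[(g["start"] < 0) | (g["end"] <= g["start"]), "gene_id"]
            raise ValueError(f"invalid intervals for genes: {list(bad[:10])}")
        if (g["length"] <= 0).any():
            raise ValueError("gene lengths must be positive")
        if not self.chrom_lengths:
            self.chrom_lengths = (
                g.groupby("chrom", observed=True)["end"].max().astype(int).to_dict()
            )
        for chrom, grp in g.groupby("chrom", observed=True):
            L = self.chrom_lengths.get(chrom)
            if L is not None and int(grp["end"].max()) > L:
                raise ValueError(f"gene extends past the length of {chrom}")
        self.genes = g.reset_index(drop=True)

    @property
    def chromosomes(self) -> list[str]:
        return sorted(self.chrom_lengths)

    def gene_counts(self) -> pd.Series:
        """Number of annotated genes per chromosome."""
        counts = self.genes.groupby("chrom", observed=True).size()
        return counts.reindex(self.chromosomes, fill_value=0)

    def midpoints(self, chrom: str | None = None) -> pd.Series:
        g = self.genes if chrom is None else self.genes[self.genes["chrom"] == chrom]
        mid = (g["start"] + g["end"]) // 2
        return pd.Series(mid.to_numpy(), index=g["gene_id"].to_numpy(), name="midpoint")

    def lengths(self) -> pd.Series:
        return pd.Series(
            self.genes["length"].to_numpy(),
            index=self.genes["gene_id"].to_numpy(),
            name="length",
        )


@dataclass
class CountMatrix:
    """Raw counts (genes x samples) plus per-sample condition metadata."""

    counts: pd.DataFrame
    sample_meta: pd.DataFrame  # index sample, columns condition, replicate

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if "condition" not in self.sample_meta.columns:
            raise SchemaError("sample_meta missing 'condition' column")
        missing = set(self.counts.columns) - set(self.sample_meta.index)
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)}")
        conds = set(self.sample_meta.loc[list(self.counts.columns), "condition"])
        bad = conds - {"control", "deficient"}
        if bad:
            raise ValueError(f"unknown conditions: {sorted(bad)}")

    def samples(self, condition: str) -> list[str]:
        meta = self.sample_meta.loc[list(self.counts.columns)]
        return list(meta.index[meta["condition"] == condition])


# ---------------------------------------------------------------------------
# gene annotations

_GTF_ATTR = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_gtf(path: Path) -> tuple[pd.DataFrame, dict[str, list[tuple[int, int]]]]:
    rows = []
    exons: dict[str, list[tuple[int, int]]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 9:
                raise ParseError(f"{path}:{lineno}: expected 9 GTF fields, got {len(parts)}")
            chrom, _source, feature, start, end, _score, strand, _frame, attrs = parts[:9]
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            attr_map = dict(_GTF_ATTR.findall(attrs))
            gene_id = attr_map.get("gene_id")
            if gene_id is None:
                raise ParseError(f"{path}:{lineno}: missing gene_id attribute")
            # GTF is 1-based inclusive -> 0-based half-open
            start0, end0 = start_i - 1, end_i
            if end0 <= start0:
                raise ParseError(f"{path}:{lineno}: end <= start")
            if feature == "gene":
                rows.append(
                    {
                        "gene_id": gene_id,
                        "chrom": normalize_chrom(chrom),
                        "start": start0,
                        "end": end0,
                        "strand": strand if strand in "+-" else "unknown",
                        "length": attr_map.get("gene_length"),
                    }
                )
            elif feature == "exon":
                exons.setdefault(gene_id, []).append((start0, end0))
    return pd.DataFrame(rows), exons


def _union_length(intervals: list[tuple[int, int]]) -> int:
    total, cur_s, cur_e = 0, None, None
    for s, e in sorted(intervals):
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        total += cur_e - cur_s
    return total


def read_gene_annotation(
    path: str | Path,
    format: str = "gtf",
    chrom_lengths: Mapping[str, int] | None = None,
) -> GenomeAnnotation:
    """Read a gene annotation in GTF or BED dialect.

    GTF ``gene`` records become genes; ``exon`` records, when present,
    define the gene length as the union of exon intervals (otherwise
    end - start, or an explicit ``gene_length`` attribute/column).
    BED is taken as already 0-based half-open, columns
    chrom/start/end/gene_id[/length[/strand]].
    """
    path = Path(path)
    if format == "gtf":
        genes, exons = _parse_gtf(path)
        if genes.empty:
            raise ParseError(f"{path}: no gene records found")
        lengths = []
        for _, row in genes.iterrows():
            if row["length"] is not None:
                lengths.append(int(row["length"]))
            elif row["gene_id"] in exons:
                lengths.append(_union_length(exons[row["gene_id"]]))
            else:
                lengths.append(int(row["end"] - row["start"]))
        genes = genes.assign(length=lengths)
    elif format == "bed":
        rows = []
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                if len(parts) < 4:
                    raise ParseError(f"{path}:{lineno}: BED needs >= 4 columns")
                chrom, start, end, gene_id = parts[:4]
                start_i, end_i = int(start), int(end)
                if end_i <= start_i:
                    raise ParseError(f"{path}:{lineno}: end <= start")
                length = int(parts[4]) if len(parts) > 4 and parts[4] not in (".", "") else end_i - start_i
                strand = parts[5] if len(parts) > 5 and parts[5] in "+-" else "unknown"
                rows.append(
                    {
                        "gene_id": gene_id,
                        "chrom": normalize_chrom(chrom),
                        "start": start_i,
                        "end": end_i,
                        "strand": strand,
                        "length": length,
                    }
                )
        genes = pd.DataFrame(rows)
    else:
        raise ValueError(f"unknown annotation format: {format!r}")
    cl = {normalize_chrom(k): int(v) for k, v in chrom_lengths.items()} if chrom_lengths else {}
    return GenomeAnnotation(genes=genes, chrom_lengths=cl)


def write_gene_annotation(ann: GenomeAnnotation, path: str | Path, format: str = "gtf") -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        if format == "gtf":
            for _, g in ann.genes.iterrows():
                strand = g["strand"] if g["strand"] in "+-" else "."
                attrs = f'gene_id "{g["gene_id"]}"; gene_length "{int(g["length"])}";'
                # internal 0-based half-open -> GTF 1-based inclusive
                fh.write(
                    f"{g['chrom']}\txresponse\tgene\t{g['start'] + 1}\t{g['end']}\t.\t{strand}\t.\t{attrs}\n"
                )
        elif format == "bed":
            for _, g in ann.genes.iterrows():
                strand = g["strand"] if g["strand"] in "+-" else "."
                fh.write(
                    f"{g['chrom']}\t{g['start']}\t{g['end']}\t{g['gene_id']}\t{int(g['length'])}\t{strand}\n"
                )
        else:
            raise ValueError(f"unknown annotation format: {format!r}")


# ---------------------------------------------------------------------------
# repeats


def _repeat_class(field: str) -> str:
    if field.startswith("SINE"):
        return "SINE"
    if field.startswith("LINE"):
        return "LINE"
    return "other"


def read_repeat_annotation(path: str | Path, format: str = "bed") -> pd.DataFrame:
    """Read a repeat track (RepeatMasker ``.out`` or BED with class column).

    Returns a DataFrame with columns chrom, start, end, repeat_class where
    repeat_class is the class-field prefix mapped onto {SINE, LINE, other}.
    """
    path = Path(path)
    rows = []
    if format == "repeatmasker_out":
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                parts = line.split()
                # RepeatMasker .out: 3 header lines (banner + blank); body rows
                # start with the Smith-Waterman score (an integer).
                if not parts or not parts[0].isdigit():
                    continue
                if len(parts) < 11:
                    raise ParseError(f"{path}:{lineno}: truncated RepeatMasker row")
                chrom, begin, end = parts[4], parts[5], parts[6]
                rep_class = parts[10]
                # .out coordinates are 1-based inclusive
                rows.append(
                    {
                        "chrom": normalize_chrom(chrom),
                        "start": int(begin) - 1,
                        "end": int(end),
                        "repeat_class": _repeat_class(rep_class),
                    }
                )
    elif format == "bed":
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                if len(parts) < 4:
                    raise ParseError(f"{path}:{lineno}: repeat BED needs >= 4 columns")
                start_i, end_i = int(parts[1]), int(parts[2])
                if end_i <= start_i:
                    raise ParseError(f"{path}:{lineno}: end <= start")
                rows.append(
                    {
                        "chrom": normalize_chrom(parts[0]),
                        "start": start_i,
                        "end": end_i,
                        "repeat_class": _repeat_class(parts[3]),
                    }
                )
    else:
        raise ValueError(f"unknown repeat format: {format!r}")
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "repeat_class"])
    if not df.empty and (df["start"] < 0).any():
        raise ValueError("negative repeat coordinates")
    return df


# ---------------------------------------------------------------------------
# DE tables

_DESEQ2_ALIASES = {
    "gene": "gene_id",
    "gene_id": "gene_id",
    "log2foldchange": "log2fc",
    "log2fc": "log2fc",
    "pvalue": "pvalue",
    "padj": "padj",
    "basemean": "mean_expr",
    "mean_expr": "mean_expr",
    "deg_class": "deg_class",
}


def read_de_table(path: str | Path, dialect: str = "deseq2_results") -> pd.DataFrame:
    """Read a per-gene differential-expression table.

    ``deseq2_results``: the column dialect produced by count-based DE tools
    (gene id, log2FoldChange, pvalue, padj, optionally baseMean).  ``fpkm_pair``:
    gene id plus WT/KO replicate FPKM columns (wt_fpkm_1, ko_fpkm_1, ...);
    the fold change is the mean over replicate pairs of KO/WT.

    Missing padj (``NA``) is preserved as missing, never coerced to zero.
    Returns a DataFrame indexed by gene_id.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if dialect == "deseq2_results":
        renames = {c: _DESEQ2_ALIASES[c.lower()] for c in df.columns if c.lower() in _DESEQ2_ALIASES}
        df = df.rename(columns=renames)
        required = ["gene_id", "log2fc", "pvalue", "padj"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise SchemaError(f"{path}: DE table missing columns: {missing}")
        if df["gene_id"].duplicated().any():
            dups = sorted(df.loc[df["gene_id"].duplicated(), "gene_id"].unique())
            raise ValueError(f"{path}: duplicated gene ids: {dups[:10]}")
        out = df.set_index("gene_id")
        if "mean_expr" not in out.columns:
            out["mean_expr"] = np.nan
        if "deg_class" not in out.columns:
            out["deg_class"] = "none"
        return out[DE_COLUMNS]
    if dialect == "fpkm_pair":
        if df.columns[0].lower() not in ("gene", "gene_id"):
            raise SchemaError(f"{path}: first column must be the gene id")
        wt_cols = [c for c in df.columns if c.lower().startswith("wt_fpkm")]
        ko_cols = [c for c in df.columns if c.lower().startswith("ko_fpkm")]
        if not wt_cols or len(wt_cols) != len(ko_cols):
            raise SchemaError(f"{path}: need matched wt_fpkm_*/ko_fpkm_* columns")
        df = df.rename(columns={df.columns[0]: "gene_id"}).set_index("gene_id")
        from xresponse.diffexpr import fc_from_fpkm  # local to avoid cycle

        fc = df.apply(lambda r: fc_from_fpkm(r[wt_cols].to_numpy(float), r[ko_cols].to_numpy(float)), axis=1)
        out = pd.DataFrame(index=df.index)
        with np.errstate(divide="ignore"):
            out["log2fc"] = np.log2(fc)
        out["pvalue"] = np.nan
        out["padj"] = np.nan
        out["mean_expr"] = df[wt_cols].mean(axis=1)
        out["deg_class"] = np.where(fc > 1, "up", np.where(fc < 1, "down", "none"))
        out["fold_change"] = fc
        return out
    raise ValueError(f"unknown DE dialect: {dialect!r}")


def write_de_table(det: pd.DataFrame, path: str | Path) -> None:
    """Write a DE table in the deseq2_results dialect."""
    out = det.rename(
        columns={"log2fc": "log2FoldChange", "mean_expr": "baseMean"}
    ).reset_index(names="gene")
    cols = ["gene", "baseMean", "log2FoldChange", "pvalue", "padj"]
    if "deg_class" in out.columns:
        cols.append("deg_class")
    out[cols].to_csv(path, sep="\t", index=False, na_rep="NA")


# ---------------------------------------------------------------------------
# counts


def read_count_matrix(counts_path: str | Path, meta_path: str | Path) -> CountMatrix:
    """Read a genes x samples count TSV plus a sample/condition/replicate TSV."""
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    if counts.index.duplicated().any():
        raise ValueError(f"{counts_path}: duplicated gene ids")
    if not np.issubdtype(counts.to_numpy().dtype, np.number):
        raise ParseError(f"{counts_path}: non-numeric counts")
    meta = pd.read_csv(meta_path, sep="\t", index_col=0)
    return CountMatrix(counts=counts.astype(np.int64), sample_meta=meta)


def write_count_matrix(cm: CountMatrix, counts_path: str | Path, meta_path: str | Path) -> None:
    cm.counts.rename_axis("gene").to_csv(counts_path, sep="\t")
    cm.sample_meta.rename_axis("sample").to_csv(meta_path, sep="\t")


# ---------------------------------------------------------------------------
# allelic counts / XCI status

ALLELE_COLUMNS = ["gene_id", "chrom", "pos", "sample_id", "refCount", "altCount"]


def read_allele_counts(path: str | Path) -> pd.DataFrame:
    """Read per-SNP allelic read counts (gene, chrom, pos, sample, ref, alt)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ALLELE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: allele-count table missing columns: {missing}")
    if (df["refCount"] < 0).any() or (df["altCount"] < 0).any():
        raise ValueError(f"{path}: negative allele counts")
    df["chrom"] = df["chrom"].map(normalize_chrom)
    return df[ALLELE_COLUMNS + [c for c in df.columns if c not in ALLELE_COLUMNS]]


def write_allele_counts(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_xci_status(path: str | Path) -> pd.Series:
    """Read a gene -> XCI status table; unknown labels map to 'unknown'."""
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    gene_col = cols.get("gene") or cols.get("gene_id")
    status_col = cols.get("status") or cols.get("xci_status")
    if gene_col is None or status_col is None:
        raise SchemaError(f"{path}: XCI table needs gene and status columns")
    status = df[status_col].astype(str).str.strip().str.lower()
    bad = ~status.isin(XCI_STATUSES)
    if bad.any():
        warnings.warn(
            f"{path}: {int(bad.sum())} unrecognized XCI labels mapped to 'unknown'",
            stacklevel=2,
        )
        status = status.where(~bad, "unknown")
    out = pd.Series(status.to_numpy(), index=df[gene_col].astype(str).to_numpy(), name="xci_status")
    return out[~out.index.duplicated()]


def write_xci_status(status: pd.Series, path: str | Path) -> None:
    status.rename("status").rename_axis("gene").to_csv(path, sep="\t")
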
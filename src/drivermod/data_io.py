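"""Readers, writers and the aligned multi-omics container.

Input dialects
--------------
* expression — TSV, first column gene symbols, header row of sample IDs,
  log-scale values; ``NA``/empty cells are missing.
* copy-number segments — SEG: ``Sample  Chromosome  Start  End
  [Num_Probes]  Segment_Mean`` with 1-based inclusive coordinates and
  log2 copy ratios.
* gene coordinates — BED4 (0-based half-open); stored 1-based inclusive.
* somatic mutations — MAF-lite TSV with at least ``Hugo_Symbol``,
  ``Tumor_Sample_Barcode``, ``Variant_Classification``.
* group labels — two-column TSV ``sample<TAB>group`` with exactly two
  distinct group names.

Chromosome names are normalized by stripping a leading ``chr`` so BED and
SEG files with different conventions interoperate.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING_TOKENS = {"", "NA", "N/A", "NaN", "nan", "null", "NULL", "."}

SEG_COLUMNS = ["sample", "chrom", "start", "end", "log2"]


class DataError(ValueError):
    """Raised for malformed or inconsistent input files."""


def _normalize_chrom(name: str) -> str:
    name = str(name).strip()
    if name.lower().startswith("chr"):
        name = name[3:]
    return name


# ---------------------------------------------------------------------------
# domain containers


@dataclass(frozen=True)
class GroupLabels:
    """Sample-to-group assignment for a two-group comparison."""

    series: pd.Series  # index: sample ID -> group name

    def __post_init__(self) -> None:
        groups = list(dict.fromkeys(self.series.values))
        if len(groups) != 2:
            raise DataError(f"expected exactly two groups, found {len(groups)}: {groups}")
        counts = self.series.value_counts()
        small = counts[counts < 3]
        if not small.empty:
            raise DataError(f"each group needs >=3 samples; too small: {dict(small)}")
        if self.series.index.duplicated().any():
            dups = self.series.index[self.series.index.duplicated()].tolist()
            raise DataError(f"duplicate sample IDs in labels: {dups[:5]}")

    @property
    def groups(self) -> tuple[str, str]:
        seen = list(dict.fromkeys(self.series.values))
        return (seen[0], seen[1])

    @property
    def samples(self) -> list[str]:
        return list(self.series.index)

    def group_samples(self, group: str) -> list[str]:
        if group not in self.groups:
            raise KeyError(f"unknown group {group!r}; known: {self.groups}")
        return list(self.series.index[self.series == group])

    def restrict(self, samples: Sequence[str]) -> "GroupLabels":
        keep = [s for s in self.series.index if s in set(samples)]
        return GroupLabels(self.series.loc[keep])


@dataclass
class OmicsBundle:
    """Expression, gene-level CNV and mutation matrices aligned on samples.

    All three matrices are genes x samples DataFrames sharing one column
    ordering (the sample intersection, in label-file order).  Gene universes
    may differ between assays.
    """

    expr: pd.DataFrame
    cnv: pd.DataFrame
    mut: pd.DataFrame
    labels: GroupLabels

    def __post_init__(self) -> None:
        samples = self.labels.samples
        for name, mat in (("expr", self.expr), ("cnv", self.cnv), ("mut", self.mut)):
            if list(mat.columns) != samples:
                raise DataError(f"{name} matrix columns do not match the common sample order")
            if mat.index.duplicated().any():
                raise DataError(f"duplicate gene symbols in {name} matrix")
        if not samples:
            raise DataError("empty common sample set")

    @property
    def samples(self) -> list[str]:
        return self.labels.samples

    @property
    def groups(self) -> tuple[str, str]:
        return self.labels.groups

    def group_samples(self, group: str) -> list[str]:
        return self.labels.group_samples(group)

    def restrict_samples(self, samples: Sequence[str]) -> "OmicsBundle":
        samples = [s for s in self.samples if s in set(samples)]
        return OmicsBundle(
            expr=self.expr[samples],
            cnv=self.cnv[samples],
            mut=self.mut[samples],
            labels=self.labels.restrict(samples),
        )

    def drop_samples(self, samples: Iterable[str]) -> "OmicsBundle":
        drop = set(samples)
        return self.restrict_samples([s for s in self.samples if s not in drop])


# ---------------------------------------------------------------------------
# readers


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples expression TSV.

    Duplicate gene rows are collapsed by mean (logged).  Missing tokens
    become NaN; any other non-numeric cell is a hard error naming the line.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except pd.errors.EmptyDataError:
        raise DataError(f"{path}: empty expression file")
    if df.shape[1] < 2:
        raise DataError(f"{path}: need >=2 sample columns, found {df.shape[1]}")
    if pd.Index(df.columns).duplicated().any():
        raise DataError(f"{path}: duplicate sample IDs in header")
    values = df.apply(lambda col: col.map(lambda v: np.nan if (pd.isna(v) or str(v).strip() in MISSING_TOKENS) else v))
    try:
        mat = values.astype(float)
    except ValueError:
        for i, (_, row) in enumerate(values.iterrows(), start=2):
            for col, v in row.items():
                if pd.notna(v):
                    try:
                        float(v)
                    except ValueError:
                        raise DataError(f"{path}:{i}: non-numeric cell {v!r} in column {col!r}")
        raise
    mat.index = mat.index.astype(str)
    if mat.index.duplicated().any():
        n_dup = int(mat.index.duplicated().sum())
        logger.info("%s: collapsing %d duplicate gene rows by mean", path, n_dup)
        mat = mat.groupby(level=0, sort=False).mean()
    if np.isinf(mat.values).any():
        raise DataError(f"{path}: non-finite expression values")
    return mat


def read_segments(path: str | Path) -> pd.DataFrame:
    """Read a SEG file into a (sample, chrom, start, end, log2) table."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError:
        raise DataError(f"{path}: empty SEG file")
    cols = {c.lower(): c for c in df.columns}

    def pick(*names: str) -> str:
        for n in names:
            if n in cols:
                return cols[n]
        raise DataError(f"{path}: missing SEG column (tried {names}); found {list(df.columns)}")

    out = pd.DataFrame(
        {
            "sample": df[pick("sample", "id", "sample_id")].astype(str),
            "chrom": df[pick("chromosome", "chrom", "chr")].map(_normalize_chrom),
            "start": df[pick("start", "loc.start", "start_position")].astype(int),
            "end": df[pick("end", "loc.end", "end_position")].astype(int),
            "log2": df[pick("segment_mean", "seg.mean", "log2")].astype(float),
        }
    )
    if (out["start"] > out["end"]).any():
        bad = out.index[out["start"] > out["end"]][0]
        raise DataError(f"{path}: segment start > end at data row {bad}")
    if not np.isfinite(out["log2"]).all():
        raise DataError(f"{path}: non-finite segment mean")
    # overlap check within (sample, chrom)
    srt = out.sort_values(["sample", "chrom", "start"])
    same = (srt["sample"].values[1:] == srt["sample"].values[:-1]) & (srt["chrom"].values[1:] == srt["chrom"].values[:-1])
    overlap = same & (srt["start"].values[1:] <= srt["end"].values[:-1])
    if overlap.any():
        i = int(np.nonzero(overlap)[0][0])
        raise DataError(
            f"{path}: overlapping segments for sample {srt['sample'].values[i]} on chromosome {srt['chrom'].values[i]}"
        )
    return out.reset_index(drop=True)


def read_gene_coords(path: str | Path) -> pd.DataFrame:
    """Read BED4 gene intervals; returns gene-indexed (chrom, start, end), 1-based inclusive."""
    path = Path(path)
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise DataError(f"{path}:{lineno}: BED4 requires 4 columns, found {len(parts)}")
            chrom, start, end, name = parts[0], parts[1], parts[2], parts[3]
            try:
                start_i, end_i = int(start), int(end)
            except ValueError:
                raise DataError(f"{path}:{lineno}: non-integer BED coordinates")
            if end_i <= start_i:
                raise DataError(f"{path}:{lineno}: empty/inverted BED interval")
            rows.append((name, _normalize_chrom(chrom), start_i + 1, end_i))
    if not rows:
        raise DataError(f"{path}: empty BED file")
    df = pd.DataFrame(rows, columns=["gene", "chrom", "start", "end"]).set_index("gene")
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].tolist()
        raise DataError(f"{path}: duplicate gene symbols: {dups[:5]}")
    return df


def read_mutations(
    path: str | Path,
    samples: Sequence[str] | None = None,
    qualifying_classes: set[str] | None = None,
) -> pd.DataFrame:
    """Read MAF-lite mutation calls into a binary genes x samples matrix.

    A (gene, sample) pair counts once regardless of how many variant rows it
    has.  ``qualifying_classes=None`` keeps every class except ``Silent``.
    ``samples`` fixes the column universe; samples seen in the MAF but not
    listed are kept (columns are the union, listed samples first).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        raise DataError(f"{path}: empty mutation file")
    needed = ["Hugo_Symbol", "Tumor_Sample_Barcode", "Variant_Classification"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing MAF columns {missing}")
    if qualifying_classes is None:
        keep = df["Variant_Classification"].str.lower() != "silent"
    else:
        keep = df["Variant_Classification"].isin(qualifying_classes)
    df = df[keep]
    genes = sorted(df["Hugo_Symbol"].unique())
    col_order = list(samples) if samples is not None else []
    extra = [s for s in sorted(df["Tumor_Sample_Barcode"].unique()) if s not in set(col_order)]
    cols = col_order + extra
    mat = pd.DataFrame(0, index=pd.Index(genes, name="gene"), columns=cols, dtype=np.int8)
    for g, s in zip(df["Hugo_Symbol"], df["Tumor_Sample_Barcode"]):
        mat.at[g, s] = 1
    return mat


def read_labels(path: str | Path) -> GroupLabels:
    """Read the two-column sample/group TSV (optional header)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    except pd.errors.EmptyDataError:
        raise DataError(f"{path}: empty labels file")
    if df.shape[1] != 2:
        raise DataError(f"{path}: labels file must have exactly 2 columns, found {df.shape[1]}")
    first = [str(v).strip().lower() for v in df.iloc[0]]
    if first in (["sample", "group"], ["sample", "label"], ["sample_id", "group"]):
        df = df.iloc[1:]
    series = pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].values, name="group")
    return GroupLabels(series.astype(str))


# ---------------------------------------------------------------------------
# assembly


def assemble_bundle(
    expr: pd.DataFrame,
    seg: pd.DataFrame,
    coords: pd.DataFrame,
    mut: pd.DataFrame,
    labels: GroupLabels,
) -> OmicsBundle:
    """Intersect samples across assays and build the aligned bundle.

    The gene-level CNV matrix is derived from the segments via
    overlap-weighted mapping (:func:`drivermod.gene_selection.map_segments_to_genes`).
    """
    from drivermod.gene_selection import map_segments_to_genes

    seg_samples = set(seg["sample"])
    unknown = seg_samples - set(labels.samples)
    if unknown:
        logger.warning("SEG contains %d samples absent from labels; kept in table, excluded from bundle", len(unknown))
    common = [
        s
        for s in labels.samples
        if s in set(expr.columns) and s in seg_samples and s in set(mut.columns)
    ]
    if not common:
        raise DataError("empty sample intersection across expression, CNV, mutation and labels")
    for name, have in (
        ("expression", set(expr.columns)),
        ("CNV", seg_samples),
        ("mutation", set(mut.columns)),
    ):
        dropped = [s for s in labels.samples if s not in have]
        if dropped:
            logger.info("dropping %d labeled samples missing from %s data", len(dropped), name)
    labels_c = labels.restrict(common)
    counts = labels_c.series.value_counts()
    if len(counts) < 2:
        raise DataError("a group is empty after sample intersection")
    cnv = map_segments_to_genes(seg, coords, common)
    return OmicsBundle(
        expr=expr[common],
        cnv=cnv[common],
        mut=mut[common].astype(np.int8),
        labels=labels_c,
    )


# ---------------------------------------------------------------------------
# writers (round-trip partners of the readers; 6 significant digits)


def write_expression(mat: pd.DataFrame, path: str | Path) -> None:
    mat.to_csv(path, sep="\t", float_format="%.6g", index_label="gene", na_rep="NA")


def write_segments(seg: pd.DataFrame, path: str | Path) -> None:
    out = seg.rename(
        columns={"sample": "Sample", "chrom": "Chromosome", "start": "Start", "end": "End", "log2": "Segment_Mean"}
    )
    out.to_csv(path, sep="\t", float_format="%.6g", index=False)


def write_gene_coords(coords: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        for gene, row in coords.iterrows():
            fh.write(f"{row['chrom']}\t{int(row['start']) - 1}\t{int(row['end'])}\t{gene}\n")


def write_mutations(mut: pd.DataFrame, path: str | Path, variant_class: str = "Missense_Mutation") -> None:
    rows = []
    for gene in mut.index:
        for sample in mut.columns[mut.loc[gene].values > 0]:
            rows.append((gene, sample, variant_class))
    pd.DataFrame(rows, columns=["Hugo_Symbol", "Tumor_Sample_Barcode", "Variant_Classification"]).to_csv(
        path, sep="\t", index=False
    )


def write_labels(labels: GroupLabels, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tgroup\n")
        for sample, group in labels.series.items():
            fh.write(f"{sample}\t{group}\n")


def write_manifest(path: str | Path, manifest: dict) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
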
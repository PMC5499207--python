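"""Readers and writers for the plain-text cohort formats.

All tables are tab-separated. Coordinates follow the conventions used
throughout the package: junction (intron) coordinates are 0-based
half-open, GTF exon records are 1-based inclusive, variant positions are
1-based.
"""

from __future__ import annotations

import re
import warnings

import numpy as np
import pandas as pd

__all__ = [
    "read_counts",
    "write_counts",
    "read_annotation",
    "write_annotation",
    "validate_annotation",
    "read_junction_table",
    "write_junction_table",
    "read_gtf_exons",
    "write_gtf_exons",
    "read_variants",
    "write_variants",
    "variants_to_long",
]

ANNOTATION_COLUMNS = ["batch", "sex", "biopsy_site", "group_id"]


class ValidationError(ValueError):
    """Raised when an input table violates its contract."""


# ---------------------------------------------------------------------------
# gene-level count matrix (genes x samples)
# ---------------------------------------------------------------------------

def write_counts(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")


def read_counts(path) -> pd.DataFrame:
    """Read a genes x samples count matrix.

    Counts must be non-negative integers; a malformed cell raises a
    :class:`ValidationError` naming its row and column.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if raw.index.duplicated().any():
        dup = raw.index[raw.index.duplicated()][0]
        raise ValidationError(f"duplicate gene id {dup!r}")
    if raw.columns.duplicated().any():
        dup = raw.columns[raw.columns.duplicated()][0]
        raise ValidationError(f"duplicate sample id {dup!r}")
    out = {}
    for col in raw.columns:
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = converted.isna() | (converted % 1 != 0) | (converted < 0)
        if bad.any():
            gene = raw.index[bad.to_numpy()][0]
            raise ValidationError(
                f"non-integer count at gene {gene!r}, sample {col!r}: "
                f"{raw.loc[gene, col]!r}"
            )
        out[col] = converted.astype(np.int64)
    counts = pd.DataFrame(out, index=raw.index)
    counts.index.name = "gene_id"
    return counts


# ---------------------------------------------------------------------------
# sample annotation
# ---------------------------------------------------------------------------

def write_annotation(annotation: pd.DataFrame, path) -> None:
    annotation.to_csv(path, sep="\t", index_label="sample_id")


def read_annotation(path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    missing = [c for c in ANNOTATION_COLUMNS if c not in ann.columns]
    if missing:
        raise ValidationError(f"annotation is missing columns: {missing}")
    if ann.index.duplicated().any():
        dup = ann.index[ann.index.duplicated()][0]
        raise ValidationError(f"duplicate sample id {dup!r} in annotation")
    return ann[ANNOTATION_COLUMNS]


def validate_annotation(counts: pd.DataFrame, annotation: pd.DataFrame) -> None:
    """Require exactly one annotation row per count-matrix sample."""
    missing = [s for s in counts.columns if s not in annotation.index]
    if missing:
        raise ValidationError(
            "samples missing from annotation: " + ", ".join(map(str, missing))
        )


# ---------------------------------------------------------------------------
# split-read junction table
# ---------------------------------------------------------------------------

JUNCTION_KEY = ["chrom", "donor", "acceptor", "strand"]


def write_junction_table(junctions: pd.DataFrame, path) -> None:
    junctions.to_csv(path, sep="\t", index=False)


def read_junction_table(path) -> pd.DataFrame:
    tab = pd.read_csv(path, sep="\t")
    missing = [c for c in JUNCTION_KEY if c not in tab.columns]
    if missing:
        raise ValidationError(f"junction table missing columns: {missing}")
    sample_cols = [c for c in tab.columns if c not in JUNCTION_KEY]
    tab[sample_cols] = tab[sample_cols].astype(np.int64)
    return tab


# ---------------------------------------------------------------------------
# minimal exon GTF
# ---------------------------------------------------------------------------

_GTF_ATTR = re.compile(r'(\w+) "([^"]*)"')


def write_gtf_exons(exons: pd.DataFrame, path) -> None:
    """Write exon features; ``exons`` has chrom, start, end (1-based
    inclusive), strand, gene_id and optionally exon_id columns."""
    with open(path, "w") as fh:
        for row in exons.itertuples(index=False):
            exon_id = getattr(row, "exon_id", f"{row.gene_id}.e")
            attrs = f'gene_id "{row.gene_id}"; exon_id "{exon_id}";'
            fh.write(
                f"{row.chrom}\trnadx\texon\t{row.start}\t{row.end}\t.\t"
                f"{row.strand}\t.\t{attrs}\n"
            )


def read_gtf_exons(path) -> pd.DataFrame:
    """Parse exon features from a GTF file (tolerant of odd lines)."""
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                warnings.warn(f"skipping malformed GTF line {lineno}")
                continue
            if parts[2] != "exon":
                continue
            try:
                start, end = int(parts[3]), int(parts[4])
            except ValueError:
                warnings.warn(f"skipping GTF line {lineno}: bad coordinates")
                continue
            attrs = dict(_GTF_ATTR.findall(parts[8]))
            records.append(
                {
                    "chrom": parts[0],
                    "start": start,
                    "end": end,
                    "strand": parts[6],
                    "gene_id": attrs.get("gene_id", ""),
                    "exon_id": attrs.get("exon_id", ""),
                }
            )
    return pd.DataFrame(
        records, columns=["chrom", "start", "end", "strand", "gene_id", "exon_id"]
    )


# ---------------------------------------------------------------------------
# heterozygous-variant allele counts
# ---------------------------------------------------------------------------

VARIANT_KEY = ["chrom", "pos", "ref", "alt", "population_af"]


def write_variants(variants: pd.DataFrame, path) -> None:
    variants.to_csv(path, sep="\t", index=False)


def read_variants(path) -> pd.DataFrame:
    tab = pd.read_csv(path, sep="\t")
    missing = [c for c in VARIANT_KEY if c not in tab.columns]
    if missing:
        raise ValidationError(f"variant table missing columns: {missing}")
    return tab


def variants_to_long(variants: pd.DataFrame) -> pd.DataFrame:
    """Reshape the wide variant table (``<sample>_ref``/``<sample>_alt``
    columns) into one row per (variant, sample)."""
    count_cols = [c for c in variants.columns if c not in VARIANT_KEY]
    samples = sorted({c.rsplit("_", 1)[0] for c in count_cols})
    vid = (
        variants["chrom"].astype(str)
        + ":"
        + variants["pos"].astype(str)
        + ":"
        + variants["ref"].astype(str)
        + ">"
        + variants["alt"].astype(str)
    )
    frames = []
    for s in samples:
        frames.append(
            pd.DataFrame(
                {
                    "variant_id": vid,
                    "sample": s,
                    "population_af": variants["population_af"].to_numpy(),
                    "ref_count": variants[f"{s}_ref"].astype(np.int64).to_numpy(),
                    "alt_count": variants[f"{s}_alt"].astype(np.int64).to_numpy(),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
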
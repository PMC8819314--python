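"""Readers and writers for the plain-text dialects the pipeline consumes.

All formats are tab- or comma-separated text: SEG-like segment tables, MAF-like
mutation tables, expression and count matrices, droplet amplitude CSVs,
clinical tables, gene-length tables, and GMT gene-set files.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .cna import Scale, SegmentProfile
from .intervals import normalize_chrom

SEG_COLUMNS = ["sample", "chrom", "loc.start", "loc.end", "seg.mean"]
MAF_COLUMNS = [
    "Tumor_Sample_Barcode",
    "Hugo_Symbol",
    "Reference_Allele",
    "Tumor_Seq_Allele2",
    "Variant_Classification",
]
DROPLET_COLUMNS = ["well", "assay", "ch1_amplitude", "ch2_amplitude"]
CLINICAL_COLUMNS = ["patient", "time_days", "event", "histology"]


def read_seg(path) -> dict[str, SegmentProfile]:
    """Read a SEG-like TSV into per-sample segment profiles (z scale)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(SEG_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"SEG file missing columns: {sorted(missing)}")
    profiles = {}
    for sample, grp in df.groupby("sample"):
        seg = grp.rename(
            columns={"loc.start": "start", "loc.end": "end", "seg.mean": "value"}
        )[["chrom", "start", "end", "value"]]
        profiles[str(sample)] = SegmentProfile(str(sample), seg, Scale.Z)
    return profiles


def write_seg(profiles: dict[str, SegmentProfile], path) -> None:
    rows = []
    for sample, prof in profiles.items():
        for _, r in prof.segments.iterrows():
            rows.append((sample, r["chrom"], r["start"], r["end"], r["value"]))
    pd.DataFrame(rows, columns=SEG_COLUMNS).to_csv(path, sep="\t", index=False)


def read_maf(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(MAF_COLUMNS[:4]) - set(df.columns)
    if missing:
        raise ValueError(f"mutation file missing columns: {sorted(missing)}")
    return df


def write_maf(mutations: pd.DataFrame, path) -> None:
    mutations.to_csv(path, sep="\t", index=False)


def read_expression(path) -> pd.DataFrame:
    """Expression TSV, first column gene symbol, remaining columns samples."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "gene"
    return df


def write_expression(expr: pd.DataFrame, path) -> None:
    expr.to_csv(path, sep="\t", index_label="gene")


def read_counts(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "gene"
    return df.astype(int)


def read_gene_lengths(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.iloc[:, 0].astype(int)


def read_droplets(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(DROPLET_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"droplet CSV missing columns: {sorted(missing)}")
    return df


def write_droplets(droplets: pd.DataFrame, path) -> None:
    droplets[DROPLET_COLUMNS].to_csv(path, index=False)


def read_clinical(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(CLINICAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"clinical file missing columns: {sorted(missing)}")
    df["event"] = df["event"].astype(bool)
    return df


def write_clinical(clinical: pd.DataFrame, path) -> None:
    clinical.to_csv(path, sep="\t", index=False)


def read_gmt(path) -> dict[str, set[str]]:
    """GMT gene-set file: name <tab> description <tab> member genes..."""
    sets: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        sets[parts[0]] = {g for g in parts[2:] if g}
    return sets


def write_gmt(sets: dict[str, set[str]], path, description: str = "") -> None:
    lines = [
        "\t".join([name, description] + sorted(members)) for name, members in sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_ranked_list(path) -> pd.Series:
    """Ranked-list TSV: gene <tab> score."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.iloc[:, 0].astype(float)


def normalize_seg_chroms(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    df["chrom"] = df["chrom"].map(normalize_chrom)
    return df
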
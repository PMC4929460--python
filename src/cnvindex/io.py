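"""Readers and writers for the plain-text formats shared across the pipeline.

All tabular formats are tab-separated with a header row.  Genomic coordinates
are 0-based half-open (BED convention) throughout; a converter is provided for
1-based closed input.  Gene sets use the GMT dialect (name, description, then
one gene per field).
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

ANNOT_COLUMNS = ["gene_id", "exon_id", "chrom", "start", "end", "burden_count"]
CNV_COLUMNS = ["sample_id", "chrom", "start", "end", "type", "class", "inheritance", "sex"]
SAMPLE_META_COLUMNS = ["sample_id", "region", "period"]
TISSUE_META_COLUMNS = ["tissue_id", "period"]

CNV_TYPES = {"del", "dup"}
CNV_CLASSES = {"pathogenic", "vous", "control"}
CNV_INHERITANCE = {"de_novo", "inherited", "unknown"}
CNV_SEX = {"M", "F", "unknown"}


class FormatError(ValueError):
    """A loadable file violated the declared format contract."""


def _require_columns(df: pd.DataFrame, columns: list[str], path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")


def read_annotation(path) -> pd.DataFrame:
    """Read an exon annotation table (gene/exon intervals plus burden counts)."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "exon_id": str, "chrom": str})
    _require_columns(df, ANNOT_COLUMNS, path)
    if df["exon_id"].duplicated().any():
        dup = df.loc[df["exon_id"].duplicated(), "exon_id"].iloc[0]
        raise FormatError(f"{path}: duplicate exon_id {dup!r}")
    bad = df.index[df["start"] >= df["end"]]
    if len(bad):
        raise FormatError(f"{path}: start >= end at line {bad[0] + 2}")
    return df[ANNOT_COLUMNS + [c for c in df.columns if c not in ANNOT_COLUMNS]]


def write_annotation(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_matrix(path) -> pd.DataFrame:
    """Read an expression/abundance matrix (row IDs in the first column)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.isna().any().any():
        raise FormatError(f"{path}: missing values are not allowed in matrices")
    return df


def write_matrix(df: pd.DataFrame, path, index_label: str = "id") -> None:
    df.to_csv(path, sep="\t", index_label=index_label)


def read_meta(path, columns: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, columns, path)
    return df


def write_meta(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_cnv_table(path) -> pd.DataFrame:
    """Read and validate a CNV call table.

    Errors name the offending line (1-based, counting the header) so a bad
    export can be fixed without guesswork.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "chrom": str})
    _require_columns(df, CNV_COLUMNS, path)
    df = df[CNV_COLUMNS]
    rows = df.itertuples(index=False, name=None)
    for idx, (_sid, _chrom, start, end, typ, cls, inh, sex) in enumerate(rows, start=2):
        if not (int(start) < int(end)):
            raise FormatError(f"{path}: start >= end at line {idx}")
        if typ not in CNV_TYPES:
            raise FormatError(f"{path}: unknown type {typ!r} at line {idx}")
        if cls not in CNV_CLASSES:
            raise FormatError(f"{path}: unknown class {cls!r} at line {idx}")
        if inh not in CNV_INHERITANCE:
            raise FormatError(f"{path}: unknown inheritance {inh!r} at line {idx}")
        if sex not in CNV_SEX:
            raise FormatError(f"{path}: unknown sex {sex!r} at line {idx}")
    return df


def write_cnv_table(df: pd.DataFrame, path) -> None:
    df[CNV_COLUMNS].to_csv(path, sep="\t", index=False)


def one_based_to_bed(start: int, end: int) -> tuple[int, int]:
    """Convert a 1-based closed interval to 0-based half-open coordinates."""
    return start - 1, end


def read_gmt(path) -> dict[str, tuple[str, tuple[str, ...]]]:
    """Read a GMT file into ``{name: (description, genes)}``."""
    out: dict[str, tuple[str, tuple[str, ...]]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise FormatError(f"{path}: GMT line with fewer than 3 fields")
        name, desc, genes = fields[0], fields[1], tuple(g for g in fields[2:] if g)
        if name in out:
            raise FormatError(f"{path}: duplicate set name {name!r}")
        out[name] = (desc, genes)
    return out


def write_gmt(sets: dict[str, tuple[str, tuple[str, ...]]], path) -> None:
    with open(path, "w") as fh:
        for name, (desc, genes) in sets.items():
            fh.write("\t".join([name, desc, *genes]) + "\n")


def write_gene_list(genes, path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in sorted(genes)))


def read_gene_list(path) -> set[str]:
    return {line.strip() for line in Path(path).read_text().splitlines() if line.strip()}


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
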
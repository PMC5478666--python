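"""Tabular input/output.

Interchange formats are plain TSV/CSV with header rows: a probe manifest,
probe-by-sample matrices (first column ``probe_id``), a sample sheet, and a
gene-by-sample expression matrix.  Coordinates are 1-based inclusive
throughout; only the BED export (see :mod:`endomethyl.dmr`) is 0-based
half-open.
"""

from __future__ import annotations

import json
import re
from pathlib import Path
import pandas as pd

from .config import PHASE_PRE, PHASE_REC
from .errors import ValidationError

MANIFEST_COLUMNS = ["probe_id", "chrom", "pos", "genes", "cgi_relation",
                    "snp_flag", "crossreactive_flag"]
SHEET_COLUMNS = ["sample_id", "subject_id", "phase", "age"]

_FLOAT_FMT = "%.6g"


def chrom_sort_key(chrom: str):
    """Natural ordering: chr1 < chr2 < ... < chr22 < chrX < chrY."""
    m = re.match(r"chr(\d+)$", chrom)
    if m:
        return (0, int(m.group(1)), "")
    return (1, 0, chrom)


def sort_manifest(manifest: pd.DataFrame) -> pd.DataFrame:
    key = manifest["chrom"].map(chrom_sort_key)
    order = sorted(range(len(manifest)),
                   key=lambda i: (key.iloc[i], manifest["pos"].iloc[i]))
    return manifest.iloc[order]


def write_manifest(manifest: pd.DataFrame, path) -> None:
    out = manifest.reset_index() if manifest.index.name == "probe_id" else manifest
    out.to_csv(path, sep="\t", index=False)


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "genes": str})
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"manifest {path}: missing columns {sorted(missing)}")
    dup = df["probe_id"].duplicated()
    if dup.any():
        lines = (df.index[dup] + 2).tolist()  # header is line 1
        raise ValidationError(f"manifest {path}: duplicate probe ids at lines {lines}")
    if not pd.api.types.is_integer_dtype(df["pos"]):
        bad = df.index[pd.to_numeric(df["pos"], errors="coerce").isna()] + 2
        raise ValidationError(f"manifest {path}: non-numeric positions at lines {bad.tolist()}")
    df["genes"] = df["genes"].fillna("")
    df = sort_manifest(df).set_index("probe_id")
    return df


def write_matrix(matrix: pd.DataFrame, path, index_label: str = "probe_id") -> None:
    matrix.to_csv(path, sep="\t", index_label=index_label, float_format=_FLOAT_FMT)


def read_matrix(path, sheet: pd.DataFrame | None = None,
                index_label: str = "probe_id") -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValidationError(f"matrix {path}: empty")
    df.index.name = index_label
    if sheet is not None:
        missing = set(sheet["sample_id"]) - set(df.columns)
        if missing:
            raise ValidationError(
                f"matrix {path}: sample columns missing: {sorted(missing)}")
    return df


def write_sample_sheet(sheet: pd.DataFrame, path) -> None:
    sheet[SHEET_COLUMNS].to_csv(path, index=False)


def read_sample_sheet(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"sample_id": str, "subject_id": str})
    missing = set(SHEET_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"sample sheet {path}: missing columns {sorted(missing)}")
    bad = ~df["phase"].isin([PHASE_PRE, PHASE_REC])
    if bad.any():
        raise ValidationError(
            f"sample sheet {path}: unknown phases {sorted(df['phase'][bad].unique())}")
    return df


def parse_gene_tokens(token_string: str) -> list[tuple[str, str]]:
    """Split ``GENE1:Body;GENE2:TSS200`` into (gene, subregion) pairs."""
    if not token_string:
        return []
    pairs = []
    for tok in token_string.split(";"):
        gene, _, region = tok.partition(":")
        if not gene or not region:
            raise ValidationError(f"malformed gene token {tok!r}")
        pairs.append((gene, region))
    return pairs


def write_run_manifest(path, *, params: dict, seed: int, stage_counts: dict) -> None:
    import endomethyl
    payload = {
        "package_version": endomethyl.__version__,
        "seed": seed,
        "parameters": params,
        "stage_counts": stage_counts,
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
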
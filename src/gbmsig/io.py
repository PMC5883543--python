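"""Readers and writers for the plain-text formats used across the pipeline.

Expression matrices are TSV with gene identifiers in the first column and
sample identifiers in the header; clinical tables are per-sample TSV; gene
set collections use the standard GMT layout (name, description, members).
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from gseapy.parser import read_gmt as _gseapy_read_gmt

CLINICAL_COLUMNS = [
    "sample_id",
    "pfs_days",
    "pfs_event",
    "os_days",
    "os_event",
    "age",
    "mgmt_methylated",
    "subtype",
    "batch",
    "adjuvant",
]


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples expression matrix (TSV, gene ids in column 1)."""
    expr = pd.read_csv(path, sep="\t", index_col=0,
                       float_precision="round_trip")
    if expr.empty:
        raise ValueError(f"expression matrix {path} is empty")
    return expr


def write_expression(expr: pd.DataFrame, path: str | Path) -> None:
    # default float repr is shortest-roundtrip, so write -> read is lossless
    expr.to_csv(path, sep="\t", index_label="gene_id")


def read_clinical(path: str | Path) -> pd.DataFrame:
    clin = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = set(CLINICAL_COLUMNS) - set(clin.columns)
    if missing:
        raise ValueError(f"clinical table {path} lacks columns: {sorted(missing)}")
    return clin.set_index("sample_id", drop=False)


def write_clinical(clinical: pd.DataFrame, path: str | Path) -> None:
    clinical.to_csv(path, sep="\t", index=False)


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT gene-set collection into an ordered name -> members mapping."""
    sets = _gseapy_read_gmt(str(path))
    if not sets:
        raise ValueError(f"no gene sets parsed from {path}")
    return {name: list(members) for name, members in sets.items()}


def write_gmt(sets: dict[str, list[str]], path: str | Path,
              descriptions: dict[str, str] | None = None) -> None:
    descriptions = descriptions or {}
    with open(path, "w") as fh:
        for name, members in sets.items():
            desc = descriptions.get(name, "na")
            fh.write("\t".join([name, desc, *members]) + "\n")


def read_gene_list(path: str | Path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_gene_list(genes: list[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g}\n")


def read_json(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def write_json(obj: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
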
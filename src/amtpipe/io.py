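"""Tab-separated I/O for every table the pipeline reads or writes.

All tabular artifacts are plain TSV with a header row.  Multi-valued
protein accessions are serialized as a ``;``-joined string; missing
optional fields are written as empty cells.  Term annotations use the
GMT format (term, description, members...).
"""

from __future__ import annotations

import os
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import InputError

FEATURE_COLUMNS = [
    "run_id",
    "scan",
    "charge",
    "monoiso_mass_da",
    "intensity",
    "peptide_seq",
    "id_score",
    "protein_ids",
]

UMC_COLUMNS = [
    "umc_id",
    "run_id",
    "umc_mass_da",
    "net",
    "umc_intensity",
    "n_ions",
    "peptide_seq",
    "id_score",
    "protein_ids",
]


def join_proteins(value) -> str:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return ""
    if isinstance(value, str):
        return value
    return ";".join(value)


def split_proteins(value):
    if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
        return ()
    return tuple(str(value).split(";"))


def write_tsv(df: pd.DataFrame, path: str, index: bool = False) -> None:
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    out = df.copy()
    if "protein_ids" in out.columns:
        out["protein_ids"] = out["protein_ids"].map(join_proteins)
    out.to_csv(path, sep="\t", index=index, na_rep="")


def read_tsv(path: str, **kwargs) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", **kwargs)
    if "protein_ids" in df.columns:
        df["protein_ids"] = df["protein_ids"].map(split_proteins)
    return df


def write_features(features: pd.DataFrame, path: str) -> None:
    cols = [c for c in FEATURE_COLUMNS if c in features.columns]
    extra = [c for c in features.columns if c not in cols]
    write_tsv(features[cols + extra], path)


def read_features(path: str) -> pd.DataFrame:
    df = read_tsv(path)
    missing = set(FEATURE_COLUMNS[:5]) - set(df.columns)
    if missing:
        raise InputError(f"feature table {path} lacks columns: {sorted(missing)}")
    return df


def write_matrix(matrix: pd.DataFrame, path: str, index_label: str = "feature") -> None:
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    matrix.to_csv(path, sep="\t", index=True, index_label=index_label, na_rep="")


def read_matrix(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_design(design: pd.DataFrame, path: str) -> None:
    write_tsv(design, path)


def read_design(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "run_id" not in df.columns and "sample" not in df.columns:
        raise InputError(f"design table {path} needs a run_id or sample column")
    return df


def read_gmt(path: str) -> dict[str, set[str]]:
    """Read a GMT annotation (term <tab> description <tab> member...)."""
    terms: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            terms[parts[0]] = {m for m in parts[2:] if m}
    return terms


def write_gmt(terms: Mapping[str, set[str]], path: str) -> None:
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    with open(path, "w") as fh:
        for name in sorted(terms):
            members = "\t".join(sorted(terms[name]))
            fh.write(f"{name}\tna\t{members}\n")


def write_id_list(ids, path: str) -> None:
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    with open(path, "w") as fh:
        for i in sorted(ids):
            fh.write(f"{i}\n")


def read_id_list(path: str) -> set[str]:
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}
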
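"""Readers and writers for the pipeline's on-disk formats.

Canonical on-disk format is TSV (UTF-8, '.' decimal separator, missing
values as empty fields); CSV is accepted on read via delimiter sniffing.
Transition reports use Skyline-style column headers; gene sets use the
standard GMT format (set name, description, tab-separated members).
"""

from __future__ import annotations

import warnings
from pathlib import Path

import pandas as pd

__all__ = [
    "read_transition_report",
    "write_transition_report",
    "read_gmt",
    "write_gmt",
    "read_counts_matrix",
    "write_counts_matrix",
    "read_table",
    "write_table",
]

#: Skyline-style report header -> internal column name.
SKYLINE_COLUMNS = {
    "Sample": "sample_id",
    "Protein": "protein_id",
    "Peptide": "peptide_seq",
    "FragmentIon": "fragment_id",
    "IsotopeLabelType": "label",
    "Area": "area",
    "MassErrorPPM": "mass_error_ppm",
    "RetentionTime": "rt_apex",
}
_INTERNAL_TO_SKYLINE = {v: k for k, v in SKYLINE_COLUMNS.items()}


def _sniff_sep(path: Path) -> str:
    header = path.open("r", encoding="utf-8").readline()
    return "\t" if header.count("\t") >= header.count(",") else ","


def read_transition_report(path) -> pd.DataFrame:
    """Read a Skyline-style transition report (TSV or CSV).

    Required columns: Sample, Protein, Peptide, FragmentIon,
    IsotopeLabelType, Area, MassErrorPPM, RetentionTime (internal names are
    also accepted).  Extra columns are ignored; label values are normalized
    case-insensitively to light/heavy.  Raises on a missing column (naming
    it) and on a negative peak area (naming the row).
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path))
    rename = {c: SKYLINE_COLUMNS[c] for c in df.columns if c in SKYLINE_COLUMNS}
    df = df.rename(columns=rename)
    for col in SKYLINE_COLUMNS.values():
        if col not in df.columns:
            raise ValueError(f"missing column: {_INTERNAL_TO_SKYLINE[col]}")
    df = df[list(SKYLINE_COLUMNS.values())]
    df["label"] = df["label"].str.strip().str.lower()
    bad_label = ~df["label"].isin(["light", "heavy"])
    if bad_label.any():
        row = int(bad_label.idxmax()) + 2  # 1-based, after header
        raise ValueError(f"unknown IsotopeLabelType at line {row}")
    negative = df["area"] < 0
    if negative.any():
        row = int(negative.idxmax()) + 2
        raise ValueError(f"negative Area at line {row}")
    return df


def write_transition_report(records: pd.DataFrame, path) -> None:
    """Write transition records with Skyline-style headers (TSV)."""
    out = records.rename(columns=_INTERNAL_TO_SKYLINE)
    out.to_csv(path, sep="\t", index=False)


def read_gmt(path) -> dict[str, list[str]]:
    """Read a GMT gene-set file: name, description, tab-separated members.

    Duplicate members within a set are dropped with a warning; a line with
    no members raises.
    """
    sets: dict[str, list[str]] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3 or not any(f.strip() for f in fields[2:]):
                raise ValueError(f"empty gene set at line {lineno}: {fields[0]!r}")
            name = fields[0]
            members = [f.strip() for f in fields[2:] if f.strip()]
            unique = list(dict.fromkeys(members))
            if len(unique) < len(members):
                warnings.warn(
                    f"gene set {name!r} has duplicate members; deduplicated",
                    stacklevel=2,
                )
            sets[name] = unique
    return sets


def write_gmt(gene_sets: dict[str, list[str]], path, description: str = "na") -> None:
    """Write a gene-set collection in GMT format."""
    with open(path, "w", encoding="utf-8") as fh:
        for name, members in gene_sets.items():
            fh.write("\t".join([name, description, *members]) + "\n")


def read_counts_matrix(path) -> pd.DataFrame:
    """Read a proteins x samples count matrix (first column = protein id)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path), index_col=0)
    df.index.name = "protein_id"
    return df


def write_counts_matrix(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index=True, index_label="protein_id")


def read_table(path) -> pd.DataFrame:
    """Read a generic TSV/CSV table (cohort metadata, abundances, panels)."""
    path = Path(path)
    return pd.read_csv(path, sep=_sniff_sep(path))


def write_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)
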
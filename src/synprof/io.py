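"""Readers and writers for the pipeline's tabular interchange formats.

Everything on disk is plain text: RFC-4180 CSV with a header row for
tables, JSON for reports and the normalizer, TSV + Newick for
dendrograms.  ``load_inputs`` performs schema validation — range checks
on profile scores, code checks on mutations, and referential checks from
the pairs table to the known drugs and lines — and names offenders
precisely.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import CellLinePanel, CompoundLibrary, SynergyMotif

__all__ = [
    "InputValidationError",
    "write_compounds",
    "write_activity",
    "read_activity",
    "write_cell_lines",
    "read_cell_lines",
    "write_pairs",
    "read_pairs",
    "write_profiles",
    "read_profiles",
    "write_motifs",
    "read_motifs",
    "write_json",
    "load_inputs",
]


class InputValidationError(ValueError):
    """An input table failed schema or referential validation."""


def write_compounds(library: CompoundLibrary, path) -> None:
    df = pd.DataFrame(
        library.fingerprints,
        columns=[f"bit_{i}" for i in range(library.n_bits)],
    )
    df.insert(0, "compound_id", library.compound_ids)
    df.to_csv(path, index=False)


def write_activity(records, path) -> None:
    rows = [
        {
            "compound_id": r.compound_id,
            "ic50_um": "" if r.ic50_um is None else f"{r.ic50_um:.6g}",
            "inactive_flag": int(r.inactive_flag),
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=["compound_id", "ic50_um", "inactive_flag"]).to_csv(
        path, index=False
    )


def read_activity(path, target_index: int):
    from .synthetic import ActivityRecord

    df = pd.read_csv(path)
    _require_columns(df, ["compound_id", "ic50_um", "inactive_flag"], path)
    records = []
    for _, row in df.iterrows():
        ic50 = None if pd.isna(row["ic50_um"]) else float(row["ic50_um"])
        records.append(
            ActivityRecord(
                compound_id=str(row["compound_id"]),
                target_index=target_index,
                ic50_um=ic50,
                inactive_flag=bool(int(row["inactive_flag"])),
            )
        )
    return records


def write_cell_lines(panel: CellLinePanel, path) -> None:
    df = pd.DataFrame(
        panel.mutation_codes, columns=[f"gene_{i + 1}" for i in range(panel.n_genes)]
    )
    df.insert(0, "line_id", panel.line_ids)
    df.to_csv(path, index=False)


def read_cell_lines(path) -> CellLinePanel:
    df = pd.read_csv(path)
    _require_columns(df, ["line_id"], path)
    gene_cols = [c for c in df.columns if c != "line_id"]
    codes = df[gene_cols].to_numpy()
    bad = np.argwhere(~np.isin(codes, (0, 1, 2)))
    if len(bad):
        r, c = bad[0]
        raise InputValidationError(
            f"{path}: mutation code {codes[r, c]!r} at line {df['line_id'].iloc[r]!r}, "
            f"column {gene_cols[c]!r} is not in {{0,1,2}}"
        )
    return CellLinePanel(list(df["line_id"].astype(str)), codes.astype(int))


def write_pairs(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_pairs(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ["drug_a", "drug_b", "cell_line", "zip_score"], path)
    same = df["drug_a"] == df["drug_b"]
    if same.any():
        raise InputValidationError(
            f"{path}: row {int(np.flatnonzero(same)[0]) + 2} pairs a drug with itself"
        )
    return df


def write_profiles(profiles: pd.DataFrame, path) -> None:
    profiles.round(6).to_csv(path, float_format="%.6f")


def read_profiles(path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col=0)
    vals = df.to_numpy(dtype=float)
    bad = np.argwhere((vals < 0) | (vals > 1))
    if len(bad):
        r, c = bad[0]
        raise InputValidationError(
            f"{path}: score {vals[r, c]} at row {df.index[r]!r}, column "
            f"{df.columns[c]!r} is outside [0, 1]"
        )
    return df


def write_motifs(motifs: list[SynergyMotif], path) -> None:
    write_json({"motifs": [m.to_dict() for m in motifs]}, path)


def read_motifs(path) -> list[SynergyMotif]:
    with open(path) as fh:
        data = json.load(fh)
    return [SynergyMotif.from_dict(d) for d in data["motifs"]]


def write_json(obj, path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_default) + "\n")


def _require_columns(df: pd.DataFrame, cols, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise InputValidationError(f"{path}: missing required column(s) {missing}")


def load_inputs(
    pairs_path, profiles_path, cell_lines_path
) -> tuple[pd.DataFrame, pd.DataFrame, CellLinePanel]:
    """Read and cross-validate the three tables the analysis needs.

    Raises :class:`InputValidationError` naming the offending file, row
    and column for malformed values, and listing unknown drugs or cell
    lines referenced by the pairs table.
    """
    pairs = read_pairs(pairs_path)
    profiles = read_profiles(profiles_path)
    panel = read_cell_lines(cell_lines_path)
    unknown_drugs = sorted(
        (set(pairs["drug_a"]) | set(pairs["drug_b"])) - set(profiles.index)
    )
    if unknown_drugs:
        raise InputValidationError(
            f"{pairs_path}: unknown drug(s) not present in {profiles_path}: "
            f"{unknown_drugs[:10]}"
        )
    unknown_lines = sorted(set(pairs["cell_line"]) - set(panel.line_ids))
    if unknown_lines:
        raise InputValidationError(
            f"{pairs_path}: unknown cell line(s) not present in {cell_lines_path}: "
            f"{unknown_lines}"
        )
    return pairs, profiles, panel
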
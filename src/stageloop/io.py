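"""Readers and writers for the package's tab-delimited interchange formats.

All on-disk formats are plain TSV with a header row:

- design file: array_id, cy3_stage, cy3_replicate, cy5_stage, cy5_replicate
- spot tables: one file per array with the SPOT_COLUMNS layout
- expression matrix: genes x channels values plus a channel-metadata sidecar
- truth record: per-gene per-stage tau plus scalar effects

A minimal GEO series-matrix adapter is included for loading deposited
two-channel data whose samples are individual channels; it is an optional
convenience and nothing downstream requires it.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

from .design import LoopDesign, design_from_frame, design_to_frame
from .preprocess import ExpressionMatrix


# ---------------------------------------------------------------------------
# design and spot tables
# ---------------------------------------------------------------------------


def write_design(design: LoopDesign, path) -> None:
    design_to_frame(design).to_csv(path, sep="\t", index=False)


def read_design(path) -> LoopDesign:
    return design_from_frame(pd.read_csv(path, sep="\t"))


def write_spot_tables(tables: list[pd.DataFrame], directory) -> list[Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for tab in tables:
        array_id = int(tab["array_id"].iloc[0])
        p = directory / f"array_{array_id:03d}.tsv"
        tab.to_csv(p, sep="\t", index=False)
        paths.append(p)
    return paths


def read_spot_tables(directory) -> list[pd.DataFrame]:
    directory = Path(directory)
    paths = sorted(directory.glob("array_*.tsv"))
    if not paths:
        raise FileNotFoundError(f"no spot tables found under {directory}")
    return [pd.read_csv(p, sep="\t", keep_default_na=False) for p in paths]


def write_truth(truth: dict, path) -> None:
    tab = truth["tau"].copy()
    tab.insert(0, "baseline", truth["baseline"])
    tab.index.name = "gene_id"
    with open(path, "w") as fh:
        fh.write(f"# dye_effect\t{truth['dye_effect']}\n")
        for aid, eff in truth["array_effects"].items():
            fh.write(f"# array_effect\t{aid}\t{eff}\n")
        tab.to_csv(fh, sep="\t")


def read_truth(path) -> dict:
    dye_effect = 0.0
    array_effects = {}
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for i, line in enumerate(lines):
        if not line.startswith("#"):
            body_start = i
            break
        parts = line[1:].strip().split("\t")
        if parts[0] == "dye_effect":
            dye_effect = float(parts[1])
        elif parts[0] == "array_effect":
            array_effects[int(parts[1])] = float(parts[2])
    from io import StringIO

    tab = pd.read_csv(StringIO("".join(lines[body_start:])), sep="\t", index_col=0)
    return {
        "gene_id": tab.index.to_numpy(),
        "baseline": tab["baseline"].to_numpy(),
        "tau": tab.drop(columns="baseline"),
        "dye_effect": dye_effect,
        "array_effects": pd.Series(array_effects),
    }


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------


def write_expression_matrix(matrix: ExpressionMatrix, path) -> None:
    """Values to ``path`` and channel metadata to ``<path>.channels.tsv``."""
    path = Path(path)
    matrix.values.to_csv(path, sep="\t")
    matrix.channel_meta.to_csv(path.with_suffix(path.suffix + ".channels.tsv"), sep="\t")


def read_expression_matrix(path) -> ExpressionMatrix:
    path = Path(path)
    values = pd.read_csv(path, sep="\t", index_col=0)
    meta = pd.read_csv(
        path.with_suffix(path.suffix + ".channels.tsv"), sep="\t", index_col=0
    )
    return ExpressionMatrix(values=values, channel_meta=meta)


def write_annotation(annotation: pd.DataFrame, path) -> None:
    annotation.to_csv(path, sep="\t", index=False)


def read_annotation(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# GEO series-matrix adapter (optional)
# ---------------------------------------------------------------------------


def load_geo_series(path) -> ExpressionMatrix:
    """Parse a GEO series-matrix file whose samples are single channels.

    Channel metadata (stage, dye, array) is read from the
    ``!Sample_characteristics_ch1`` lines, which must contain
    ``stage: <int>``, ``dye: <Cy3|Cy5>`` and ``array: <int>`` entries.
    """
    path = Path(path)
    sample_meta: dict[str, list[str]] = {}
    table_lines: list[str] = []
    in_table = False
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("!series_matrix_table_begin"):
                in_table = True
                continue
            if line.startswith("!series_matrix_table_end"):
                in_table = False
                continue
            if in_table:
                table_lines.append(line)
            elif line.startswith("!Sample_"):
                key, *vals = line.split("\t")
                sample_meta.setdefault(key, []).append(
                    [v.strip('"') for v in vals]
                )
    if not table_lines:
        raise ValueError(f"{path}: no series matrix table found")
    from io import StringIO

    values = pd.read_csv(StringIO("\n".join(table_lines)), sep="\t", index_col=0)
    values.index.name = "gene_id"
    values.columns = [str(c).strip('"') for c in values.columns]

    char_rows = sample_meta.get("!Sample_characteristics_ch1")
    if not char_rows:
        raise ValueError(f"{path}: missing !Sample_characteristics_ch1 metadata")
    n_samples = len(char_rows[0])
    fields: list[dict[str, str]] = [{} for _ in range(n_samples)]
    for row in char_rows:
        for i, cell in enumerate(row):
            if ":" in cell:
                k, v = cell.split(":", 1)
                fields[i][k.strip().lower()] = v.strip()
    meta_rows = []
    for i, f in enumerate(fields):
        try:
            meta_rows.append(
                {
                    "channel_id": values.columns[i],
                    "array_id": int(f["array"]),
                    "dye": f["dye"],
                    "stage": int(f["stage"]),
                    "replicate": int(f.get("replicate", 0)),
                    "pool_id": f.get("pool", f"S{f['stage']}R{f.get('replicate', 0)}"),
                }
            )
        except (KeyError, ValueError) as exc:
            raise ValueError(
                f"{path}: sample {i + 1} has unparseable characteristics "
                f"(need stage/dye/array): {exc}"
            ) from exc
    meta = pd.DataFrame(meta_rows).set_index("channel_id")
    return ExpressionMatrix(values=values, channel_meta=meta)


def write_geo_series(matrix: ExpressionMatrix, path) -> None:
    """Write an ExpressionMatrix in the series-matrix layout load_geo_series
    reads back (round-trips exactly up to float formatting)."""
    meta = matrix.channel_meta
    with open(path, "w") as fh:
        titles = "\t".join(f'"{c}"' for c in matrix.values.columns)
        fh.write(f"!Sample_title\t{titles}\n")
        for key in ("stage", "dye", "array_id", "replicate"):
            label = "array" if key == "array_id" else key
            cells = "\t".join(f'"{label}: {meta.loc[c, key]}"' for c in meta.index)
            fh.write(f"!Sample_characteristics_ch1\t{cells}\n")
        fh.write("!series_matrix_table_begin\n")
        matrix.values.to_csv(fh, sep="\t")
        fh.write("!series_matrix_table_end\n")
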
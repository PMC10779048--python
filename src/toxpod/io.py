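"""Readers and writers for the pipeline's plain-text interchange formats.

All tables are UTF-8 tab-separated with a header row; gene identifiers are
opaque strings.  Gene sets use the GMT dialect (name, free-text description,
then members, one set per line) with an optional direction sidecar TSV
(set, gene, sign ∈ {+1, −1}).  Writers and readers round-trip.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from toxpod.degs import ExpressionMatrix
from toxpod.enrichment import GeneSet, GeneSetCollection

__all__ = [
    "read_expression", "write_expression",
    "read_gene_sets", "write_gene_sets",
    "read_trypan", "write_trypan",
    "read_yaml_config", "write_yaml_config",
]

_DESIGN_COLUMNS = ["condition", "compound", "form", "concentration",
                   "timepoint", "replicate"]


def write_expression(matrix: ExpressionMatrix, matrix_path: str | Path,
                     design_path: str | Path) -> None:
    """Write the log2-ratio matrix (first column gene) and design tables."""
    out = matrix.values.copy()
    out.index.name = "gene"
    out.to_csv(matrix_path, sep="\t")
    design = matrix.design.copy()
    design.index.name = "sample"
    design.to_csv(design_path, sep="\t")


def read_expression(matrix_path: str | Path,
                    design_path: str | Path) -> ExpressionMatrix:
    """Read a matrix + design TSV pair, validating numeric cells."""
    raw = pd.read_csv(matrix_path, sep="\t", index_col=0, dtype=str)
    values = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=float)
    for col in raw.columns:
        parsed = pd.to_numeric(raw[col], errors="coerce")
        bad = parsed.isna() & raw[col].notna()
        if bad.any():
            row = raw.index[bad.argmax()]
            raise ValueError(
                f"non-numeric expression value at gene {row!r}, sample {col!r}"
            )
        if parsed.isna().any():
            row = raw.index[parsed.isna().argmax()]
            raise ValueError(f"missing expression value at gene {row!r}, "
                             f"sample {col!r}")
        values[col] = parsed
    design = pd.read_csv(design_path, sep="\t", index_col=0)
    return ExpressionMatrix(values=values, design=design)


def write_gene_sets(collection: GeneSetCollection, gmt_path: str | Path,
                    directions_path: str | Path | None = None) -> None:
    """Write GMT (+ optional direction sidecar TSV)."""
    with open(gmt_path, "w", encoding="utf-8") as fh:
        for s in collection:
            members = "\t".join(sorted(s.members))
            fh.write(f"{s.name}\tsynthetic gene set\t{members}\n")
    if directions_path is not None:
        rows = [
            {"set": s.name, "gene": g, "sign": sign}
            for s in collection
            for g, sign in sorted(s.directions.items())
        ]
        pd.DataFrame(rows, columns=["set", "gene", "sign"]).to_csv(
            directions_path, sep="\t", index=False
        )


def read_gene_sets(gmt_path: str | Path,
                   directions_path: str | Path | None = None) -> GeneSetCollection:
    """Read a GMT file and optional direction sidecar into a collection."""
    directions: dict[str, dict[str, int]] = {}
    if directions_path is not None:
        side = pd.read_csv(directions_path, sep="\t")
        for row in side.itertuples():
            directions.setdefault(row.set, {})[row.gene] = int(row.sign)
    sets: dict[str, GeneSet] = {}
    with open(gmt_path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"{gmt_path}:{lineno}: GMT line needs name, description "
                    "and >= 1 member"
                )
            name, _desc, *members = parts
            members = [m for m in members if m]
            try:
                sets[name] = GeneSet(
                    name=name, members=frozenset(members),
                    directions=directions.get(name, {}),
                )
            except ValueError as exc:
                raise ValueError(f"{gmt_path}:{lineno}: {exc}") from None
    return GeneSetCollection(sets)


def write_trypan(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_trypan(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"compound", "concentration", "timepoint", "replicate",
                "white_count", "blue_count", "density_viable"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"trypan table missing columns: {sorted(missing)}")
    return df


def write_yaml_config(config: dict, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)


def read_yaml_config(path: str | Path) -> dict:
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"config {path} must be a YAML mapping")
    return data
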
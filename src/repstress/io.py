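"""Readers and writers for the plain-text formats the tool consumes.

Expression matrices are genes × samples TSV (first column = gene identifier)
or GCT 1.2; gene-set collections are GMT; signatures are JSON with a
provenance block; annotation tables are sample-per-row TSV keyed by
``sample_id``.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import pandas as pd

from .enrichment import GeneSet


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a genes × samples expression matrix from TSV or GCT."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline().rstrip("\n")
    if first.startswith("#1.2"):
        df = pd.read_csv(path, sep="\t", skiprows=2, index_col=0)
        df = df.drop(columns=["Description"], errors="ignore")
    else:
        df = pd.read_csv(path, sep="\t", index_col=0)
    return df.astype(float)


def write_expression(expr: pd.DataFrame, path: str | Path) -> None:
    expr.to_csv(path, sep="\t", index_label="gene")


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Read a sample-per-row annotation TSV indexed by ``sample_id``."""
    df = pd.read_csv(path, sep="\t")
    if "sample_id" not in df.columns:
        raise ValueError(f"{path}: annotation table needs a 'sample_id' column")
    return df.set_index("sample_id")


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Read a GMT collection (name, description, members...)."""
    sets: list[GeneSet] = []
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                continue
            name, _desc, *members = fields
            members = [m for m in members if m]
            if members:
                sets.append(GeneSet.from_iterable(name, members))
    return sets


def write_gmt(sets: Sequence[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, "na", *sorted(s.members)]) + "\n")


def read_signature_json(path: str | Path) -> tuple[pd.Series, dict]:
    """Read a signature JSON; returns (weights indexed by gene, provenance)."""
    with open(path) as fh:
        payload = json.load(fh)
    weights = pd.Series(
        {e["symbol"]: float(e["weight"]) for e in payload["genes"]}, name="weight"
    )
    return weights, payload.get("provenance", {})


def write_signature_json(
    weights: pd.Series, provenance: dict, path: str | Path
) -> None:
    payload = {
        "genes": [
            {"symbol": g, "weight": float(w)} for g, w in weights.items()
        ],
        "provenance": provenance,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")
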
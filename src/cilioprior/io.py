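"""Plain-text readers and writers.

All tables are tab-separated with the gene identifier in the first
column; floats are written with a fixed format so a fixed seed reproduces
byte-identical files.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

FLOAT_FORMAT = "%.10g"


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Genes x features TSV with a header row, gene identifiers first."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.to_csv(path, sep="\t", float_format=FLOAT_FORMAT)


def read_table(path: str | Path) -> pd.DataFrame:
    """Plain TSV with a header row (no index column)."""
    return pd.read_csv(path, sep="\t")


def write_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_gene_list(path: str | Path) -> list[str]:
    """One identifier per line; blank lines ignored."""
    lines = Path(path).read_text().splitlines()
    return [ln.strip() for ln in lines if ln.strip()]


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in genes))


def write_json(obj: Mapping, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """GMT gene-set collection: name <tab> description <tab> genes..."""
    collections: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        collections[parts[0]] = [g for g in parts[2:] if g]
    return collections
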
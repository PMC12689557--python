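"""Plain-text readers and writers for the pipeline's tabular formats.

Expression and survival tables are TSV, edge lists and inter-level maps are
two-column TSV, drug targets are (drug, gene) TSV, dose–response and
dilution plates are CSV, and pathway libraries use the GMT dialect
(name, description, tab-separated member ids).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd


def write_expression(expr: pd.DataFrame, path):
    expr.to_csv(path, sep="\t", index_label="gene")


def read_expression(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene")


def write_survival(survival: pd.DataFrame, path):
    survival.to_csv(path, sep="\t", index_label="sample")


def read_survival(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample")


def write_edges(edges, path, header=("source", "target")):
    pd.DataFrame(edges, columns=list(header)).to_csv(path, sep="\t", index=False)


def read_edges(path) -> list:
    df = pd.read_csv(path, sep="\t")
    return [tuple(r) for r in df.itertuples(index=False)]


def write_drug_targets(table: pd.DataFrame, path):
    table.to_csv(path, sep="\t", index=False)


def read_drug_targets(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_dose_response(df: pd.DataFrame, path):
    df.to_csv(path, index=False)


def read_dose_response(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_gmt(library: dict, path, descriptions: dict | None = None):
    lines = []
    for name in sorted(library):
        desc = (descriptions or {}).get(name, "")
        members = "\t".join(sorted(library[name]))
        lines.append(f"{name}\t{desc}\t{members}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_gmt(path) -> dict:
    library = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        library[parts[0]] = set(parts[2:])
    return library
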
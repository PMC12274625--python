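"""Plain-text readers/writers for every pipeline input and output.

All tabular files are TSV; gene sets use the GMT line format
(name <tab> description <tab> member...).  Floats are written with a fixed
repr-stable format so identical runs produce byte-identical files.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .simulate import PairedExpressionSet

__all__ = [
    "write_expression", "read_expression",
    "write_edge_table", "read_edge_table",
    "write_gmt", "read_gmt",
    "write_table", "read_table",
]

_FLOAT_FMT = "%.10g"


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_expression(expr: PairedExpressionSet, values_path, meta_path,
                     feature_meta_path=None) -> None:
    expr.values.to_csv(values_path, sep="\t", float_format=_FLOAT_FMT)
    write_table(expr.sample_meta, meta_path)
    if feature_meta_path is not None:
        write_table(expr.feature_meta, feature_meta_path)


def read_expression(values_path, meta_path,
                    feature_meta_path=None) -> PairedExpressionSet:
    values = pd.read_csv(values_path, sep="\t", index_col=0)
    sample_meta = read_table(meta_path)
    if feature_meta_path is not None:
        feature_meta = read_table(feature_meta_path)
    else:
        # miRNA ids are conventionally prefixed; everything else is a gene
        feature_meta = pd.DataFrame({
            "feature_id": values.index,
            "molecule_type": ["miRNA" if str(f).upper().startswith(("MIR", "HSA-MIR"))
                              else "gene" for f in values.index],
        })
    return PairedExpressionSet(values, feature_meta, sample_meta)


def write_edge_table(df: pd.DataFrame, path) -> None:
    write_table(df, path)


def read_edge_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["confidence"] = pd.to_numeric(df["confidence"], errors="coerce")
    return df


def write_gmt(collection: dict[str, set], path, descriptions: dict | None = None) -> None:
    descriptions = descriptions or {}
    with open(path, "w") as fh:
        for name in sorted(collection):
            desc = descriptions.get(name, "na")
            members = "\t".join(sorted(collection[name]))
            fh.write(f"{name}\t{desc}\t{members}\n")


def read_gmt(path) -> dict[str, set]:
    collection: dict[str, set] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        collection[parts[0]] = set(parts[2:])
    return collection
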
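"""Readers and writers for the pipeline's plain-text formats.

Formats (all uncompressed text):

* expression matrix TSV — first column ``gene``, one column per sample;
* sample sheet CSV — columns ``sample_id``, ``genotype``, ``replicate``;
* DEG table TSV — as produced by :func:`coexcand.deg.call_degs`;
* Ct table CSV — columns ``sample_id``, ``gene_id``, ``ct``;
* pathway gene list — one gene id per line, ``#`` comments allowed.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .deg import ExpressionMatrix
from .simulate import CtTable

__all__ = [
    "read_expression",
    "write_expression",
    "read_deg_table",
    "write_deg_table",
    "read_ct_table",
    "write_ct_table",
    "read_gene_list",
    "write_gene_list",
]


def write_expression(
    matrix: ExpressionMatrix, expression_path: str | Path, samples_path: str | Path
) -> None:
    """Write the FPKM matrix (TSV) and its sample sheet (CSV)."""
    out = matrix.values.rename_axis("gene")
    out.to_csv(expression_path, sep="\t", float_format="%.17g")
    matrix.design.rename_axis("sample_id").to_csv(samples_path)


def read_expression(
    expression_path: str | Path,
    samples_path: str | Path,
    case: str = "high",
    control: str = "low",
) -> ExpressionMatrix:
    """Read an FPKM matrix TSV plus sample sheet CSV."""
    values = pd.read_csv(expression_path, sep="\t", index_col=0)
    values.index = values.index.astype(str)
    design = pd.read_csv(samples_path, index_col=0)
    design.index = design.index.astype(str)
    return ExpressionMatrix(values, design, case=case, control=control)


def write_deg_table(table: pd.DataFrame, path: str | Path) -> None:
    table.rename_axis("gene").to_csv(path, sep="\t", float_format="%.17g")


def read_deg_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", index_col=0)
    table.index = table.index.astype(str)
    for col in table.columns:
        if col.startswith("deg") and col[3:].isdigit():
            table[col] = table[col].astype(bool)
    return table


def write_ct_table(table: CtTable, ct_path: str | Path) -> None:
    """Write Ct rows as CSV (design travels with the expression sample sheet)."""
    table.data.to_csv(ct_path, index=False, float_format="%.17g")


def read_ct_table(
    ct_path: str | Path,
    samples_path: str | Path,
    reference_gene: str,
    case: str = "high",
    control: str = "low",
) -> CtTable:
    data = pd.read_csv(ct_path)
    data["sample_id"] = data["sample_id"].astype(str)
    data["gene_id"] = data["gene_id"].astype(str)
    design = pd.read_csv(samples_path, index_col=0)
    design.index = design.index.astype(str)
    return CtTable(
        data=data,
        design=design,
        reference_gene=reference_gene,
        case=case,
        control=control,
    )


def read_gene_list(path: str | Path) -> list[str]:
    genes = []
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if line and not line.startswith("#"):
            genes.append(line)
    return genes


def write_gene_list(genes, path: str | Path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in sorted(genes)))
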
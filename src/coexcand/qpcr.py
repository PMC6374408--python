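"""Relative qPCR quantification (2^-ddCt) and RNA-seq concordance.

Implements the standard Livak relative-quantification scheme: per-sample
normalization of a target gene's cycle threshold against a reference
gene (dCt = Ct_target - Ct_reference), contrast of genotype means
(ddCt = mean dCt_case - mean dCt_control), and relative quantity
rq = 2^-ddCt, assuming perfect amplification efficiency. Technical
replicates of the same (sample, gene) pair are averaged to a single Ct
before normalization, so significance testing operates on biological
replicates only.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .deg import _pooled_t_pvalues
from .simulate import CtTable

__all__ = [
    "relative_quantity",
    "qpcr_test",
    "concordance",
    "validate_candidates",
]


def _mean_ct(table: CtTable, gene: str) -> pd.Series:
    """One Ct per sample for a gene, averaging technical replicates."""
    rows = table.data[table.data["gene_id"] == gene]
    if rows.empty:
        raise ValueError(f"gene {gene!r} absent from Ct table")
    return rows.groupby("sample_id")["ct"].mean()


def relative_quantity(
    table: CtTable, gene: str
) -> tuple[float, np.ndarray, np.ndarray]:
    """Livak relative quantity of ``gene`` in case versus control.

    Returns ``(rq, delta_ct_case, delta_ct_control)`` where
    ``rq = 2^-(mean dCt_case - mean dCt_control)`` and the dCt arrays hold
    the per-sample reference-normalized values entering the contrast.
    """
    gene_ct = _mean_ct(table, gene)
    try:
        ref_ct = _mean_ct(table, table.reference_gene)
    except ValueError as exc:
        raise ValueError(
            f"reference gene {table.reference_gene!r} missing from Ct table"
        ) from exc
    missing = set(ref_ct.index) - set(gene_ct.index)
    if missing:
        raise ValueError(f"gene {gene!r} not measured in samples {sorted(missing)}")
    delta_ct = gene_ct - ref_ct.loc[gene_ct.index]
    genotype = table.design.loc[delta_ct.index, "genotype"]
    delta_case = delta_ct[genotype == table.case].to_numpy(dtype=float)
    delta_control = delta_ct[genotype == table.control].to_numpy(dtype=float)
    ddct = delta_case.mean() - delta_control.mean()
    return float(2.0 ** (-ddct)), delta_case, delta_control


def qpcr_test(delta_ct_case, delta_ct_control) -> float:
    """Two-sided pooled-variance Student's t-test on dCt values.

    Zero pooled variance returns 1 for equal means and 0 otherwise, the
    same degenerate convention used for the RNA-seq replicate test.
    """
    a = np.asarray(delta_ct_case, dtype=float)
    b = np.asarray(delta_ct_control, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 dCt values per group")
    return float(_pooled_t_pvalues(a[None, :], b[None, :])[0])


def concordance(
    rnaseq_log2fc: dict[str, float], qpcr_rq: dict[str, float]
) -> tuple[int, int, float]:
    """Sign agreement between RNA-seq fold changes and qPCR quantities.

    A gene agrees when ``sign(log2fc) == sign(log2 rq)``; ``rq == 1``
    agrees only with ``log2fc == 0``. Returns
    ``(n_genes, n_agree, fraction)`` over the shared gene set.
    """
    shared = sorted(set(rnaseq_log2fc) & set(qpcr_rq))
    if not shared:
        raise ValueError("no genes shared between RNA-seq and qPCR results")
    n_agree = sum(
        1
        for g in shared
        if np.sign(rnaseq_log2fc[g]) == np.sign(np.log2(qpcr_rq[g]))
    )
    return len(shared), n_agree, n_agree / len(shared)


def validate_candidates(
    table: CtTable, rnaseq_log2fc: dict[str, float], alpha: float = 0.05
) -> pd.DataFrame:
    """Per-gene qPCR validation of RNA-seq fold-change calls.

    For every gene in ``rnaseq_log2fc`` measured in the Ct table, computes
    the relative quantity, the ddCt contrast, the replicate t-test
    p-value, and whether the qPCR direction agrees with the RNA-seq sign.
    """
    measured = set(table.data["gene_id"])
    rows = []
    for gene in sorted(set(rnaseq_log2fc) & measured):
        if gene == table.reference_gene:
            continue
        rq, dcase, dcontrol = relative_quantity(table, gene)
        p = qpcr_test(dcase, dcontrol)
        log2rq = float(np.log2(rq))
        rows.append(
            {
                "gene": gene,
                "rq": rq,
                "delta_delta_ct": -log2rq,
                "p_value": p,
                "significant": p < alpha,
                "rnaseq_log2fc": rnaseq_log2fc[gene],
                "concordant_with_rnaseq": bool(
                    np.sign(rnaseq_log2fc[gene]) == np.sign(log2rq)
                ),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene",
            "rq",
            "delta_delta_ct",
            "p_value",
            "significant",
            "rnaseq_log2fc",
            "concordant_with_rnaseq",
        ],
    )
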
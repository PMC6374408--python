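"""Integration of network rankings with DEG calls into a candidate table.

The three prediction approaches each yield a top-N ranking; a gene
becomes a candidate when it appears in at least one top-N list *and* is
differentially expressed at the base threshold. Filtering happens after
the top-N cut, so the per-approach lists stay comparable across
approaches while only the differential members graduate to candidacy.
Support counts how many approaches nominated each candidate.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .deg import deg_set
from .network import Ranking

__all__ = [
    "integrate_predictions",
    "candidate_summary",
    "export_candidates",
    "read_candidates",
]


def _largest_threshold(row: pd.Series, thresholds: Sequence[int]) -> int:
    passed = [t for t in thresholds if row.get(f"deg{t}", False)]
    return max(passed) if passed else 0


def integrate_predictions(
    rankings: Sequence[Ranking],
    deg_table: pd.DataFrame,
    base_threshold: int = 2,
    up_only: bool = False,
) -> pd.DataFrame:
    """Build the integrated candidate table.

    Parameters
    ----------
    rankings
        Top-N rankings with pairwise-distinct approach labels.
    deg_table
        Output of :func:`coexcand.deg.call_degs`. Ranked genes absent
        from the table are treated as non-differential.
    base_threshold
        log2 fold-change threshold a gene must pass (with p < alpha,
        already folded into the DEG table) to be a candidate.
    up_only
        Restrict candidates to genes up-regulated in the case genotype.

    Returns a DataFrame with one row per candidate: gene, support,
    approaches, log2fc, deg_threshold (largest threshold passed),
    direction, and per-approach rank/statistic columns. Sorted by
    descending support, then ascending best rank, then gene id.
    """
    labels = [r.approach for r in rankings]
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate approach labels: {labels}")
    degs = deg_set(deg_table, base_threshold)
    if up_only:
        degs &= set(deg_table.index[deg_table["log2fc"] > 0])
    thresholds = sorted(
        int(c[3:]) for c in deg_table.columns if c.startswith("deg") and c[3:].isdigit()
    )

    per_gene: dict[str, dict] = {}
    for ranking in rankings:
        for _, entry in ranking.entries.iterrows():
            gene = str(entry["gene"])
            if gene not in degs:
                continue
            rec = per_gene.setdefault(gene, {"approaches": []})
            rec["approaches"].append(ranking.approach)
            rec[f"{ranking.approach}_rank"] = int(entry["rank"])
            rec[f"{ranking.approach}_statistic"] = float(entry["statistic"])

    rows = []
    for gene, rec in per_gene.items():
        deg_row = deg_table.loc[gene]
        rows.append(
            {
                "gene": gene,
                "support": len(rec["approaches"]),
                "approaches": ",".join(rec["approaches"]),
                "log2fc": float(deg_row["log2fc"]),
                "p_value": float(deg_row["p_value"]),
                "deg_threshold": _largest_threshold(deg_row, thresholds),
                "direction": str(deg_row["direction"]),
                "best_rank": min(
                    rec[f"{a}_rank"] for a in rec["approaches"]
                ),
                **{
                    k: v
                    for k, v in rec.items()
                    if k.endswith("_rank") or k.endswith("_statistic")
                },
            }
        )

    columns = [
        "gene",
        "support",
        "approaches",
        "log2fc",
        "p_value",
        "deg_threshold",
        "direction",
        "best_rank",
    ]
    for label in labels:
        columns += [f"{label}_rank", f"{label}_statistic"]
    table = pd.DataFrame(rows, columns=columns)
    if len(table):
        table = table.sort_values(
            ["support", "best_rank", "gene"], ascending=[False, True, True]
        ).reset_index(drop=True)
    return table


def candidate_summary(
    table: pd.DataFrame, rankings: Sequence[Ranking], deg_table: pd.DataFrame,
    base_threshold: int = 2,
) -> dict:
    """Headline counts: candidates per approach, multi-approach support.

    ``deg_in_top_n`` counts, per approach, how many of its top-N genes
    are differential at the base threshold — the per-approach candidate
    yield before integration.
    """
    degs = deg_set(deg_table, base_threshold)
    deg_in_top = {
        r.approach: int(sum(1 for g in r.genes if g in degs)) for r in rankings
    }
    if len(table):
        per_approach = {
            r.approach: int(
                table["approaches"].str.split(",").apply(lambda a: r.approach in a).sum()
            )
            for r in rankings
        }
        n_up = int((table["direction"] == "up").sum())
        support_ge2 = int((table["support"] >= 2).sum())
    else:
        per_approach = {r.approach: 0 for r in rankings}
        n_up = 0
        support_ge2 = 0
    return {
        "n_candidates": int(len(table)),
        "n_up_regulated": n_up,
        "support_ge2": support_ge2,
        "deg_in_top_n": deg_in_top,
        "candidates_per_approach": per_approach,
    }


def export_candidates(
    table: pd.DataFrame,
    tsv_path: str | Path,
    summary: dict | None = None,
    json_path: str | Path | None = None,
) -> None:
    """Write the candidate table as TSV and, optionally, a JSON summary."""
    table.to_csv(tsv_path, sep="\t", index=False)
    if json_path is not None:
        if summary is None:
            raise ValueError("summary required when json_path is given")
        Path(json_path).write_text(
            json.dumps(summary, indent=2, sort_keys=True) + "\n"
        )


def read_candidates(path: str | Path) -> pd.DataFrame:
    """Read back a candidate TSV written by :func:`export_candidates`."""
    table = pd.read_csv(path, sep="\t")
    if len(table):
        table["gene"] = table["gene"].astype(str)
    return table
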
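"""Weighted co-expression network loading and candidate prediction.

The network is a simple undirected graph whose edges carry a positive
log-likelihood score (LLS) quantifying the evidence that two genes share
function. Three guilt-by-association prediction approaches are provided:

guide scoring
    Each non-guide gene is scored by the sum of LLS over its direct edges
    to a set of known pathway (guide) genes; candidates are ranked by
    descending score.
deg-seeded scoring
    The same scorer seeded with differentially expressed pathway genes
    instead of the full guide set.
hub-neighborhood enrichment
    Every sufficiently connected gene (a hub) is tested for enrichment of
    differentially expressed genes among its direct neighbors with a
    one-sided upper-tail hypergeometric test; hubs are ranked by
    ascending p-value.

All rankings are fully deterministic: ties are broken by the statistic,
then (hub only) by larger neighbor overlap, then by lexicographic gene id.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Ranking",
    "read_network",
    "write_network",
    "connected_pathway_subset",
    "guide_predict",
    "hub_overlap_pvalue",
    "hub_predict",
    "top_n",
    "read_ranking",
    "write_ranking",
]

logger = logging.getLogger(__name__)

RANKING_COLUMNS = ("rank", "gene", "statistic")
HUB_COLUMNS = ("rank", "gene", "statistic", "overlap_k", "neighborhood_n", "p_bh")


@dataclass(frozen=True)
class Ranking:
    """An ordered candidate list produced by one prediction approach.

    ``entries`` has columns ``rank`` (1-based, consecutive), ``gene`` and
    ``statistic`` (summed LLS for guide approaches, hypergeometric
    p-value for the hub approach); hub rankings additionally carry
    ``overlap_k``, ``neighborhood_n`` and a Benjamini-Hochberg adjusted
    p-value column ``p_bh`` (informational only, never used for ranking).
    """

    approach: str
    entries: pd.DataFrame

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def genes(self) -> list[str]:
        return list(self.entries["gene"])


def read_network(path: str | Path) -> nx.Graph:
    """Parse a 3-column edge list (geneA, geneB, LLS) into a simple graph.

    Lines starting with ``#`` and blank lines are skipped. Duplicate
    pairs (in either orientation) are collapsed keeping the maximum
    weight, with a warning. Self-loops, malformed lines and non-positive
    weights raise :class:`ValueError` naming the offending line.
    """
    path = Path(path)
    graph = nx.Graph()
    n_lines = 0
    n_duplicates = 0
    with open(path) as handle:
        for lineno, raw in enumerate(handle, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            n_lines += 1
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(
                    f"{path}:{lineno}: expected 3 tab-separated fields, "
                    f"got {len(parts)}"
                )
            a, b, weight_str = (p.strip() for p in parts)
            if a == b:
                raise ValueError(f"{path}:{lineno}: self-loop on gene {a!r}")
            try:
                weight = float(weight_str)
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: non-numeric weight {weight_str!r}"
                ) from exc
            if not weight > 0:
                raise ValueError(f"{path}:{lineno}: non-positive weight {weight}")
            if graph.has_edge(a, b):
                n_duplicates += 1
                graph[a][b]["weight"] = max(graph[a][b]["weight"], weight)
            else:
                graph.add_edge(a, b, weight=weight)
    if n_duplicates:
        logger.warning(
            "%s: %d duplicate edge line(s) collapsed keeping the maximum weight",
            path,
            n_duplicates,
        )
    logger.info(
        "read %s: %d edge lines -> %d nodes, %d edges",
        path,
        n_lines,
        graph.number_of_nodes(),
        graph.number_of_edges(),
    )
    return graph


def write_network(graph: nx.Graph, path: str | Path) -> None:
    """Write the edge list as geneA<TAB>geneB<TAB>LLS, sorted by gene pair.

    Weights are written with 17 significant digits so a read/write round
    trip reproduces them exactly.
    """
    with open(path, "w") as handle:
        handle.write("# geneA\tgeneB\tlls\n")
        for a, b, data in sorted(
            (tuple(sorted((u, v))) + (d,) for u, v, d in graph.edges(data=True))
        ):
            handle.write(f"{a}\t{b}\t{data['weight']:.17g}\n")


def connected_pathway_subset(graph: nx.Graph, pathway_genes: Iterable[str]) -> set[str]:
    """Pathway genes with at least one edge to another pathway gene.

    Pathway genes absent from the network, and those whose edges all lead
    outside the pathway, are excluded. This mirrors restricting a curated
    homolog list to the members that are mutually connected in the
    functional network before using them as guides.
    """
    pathway = set(pathway_genes) & set(graph.nodes)
    return {
        g for g in pathway if any(nb in pathway for nb in graph[g])
    }


def guide_predict(
    graph: nx.Graph,
    guides: Iterable[str],
    exclude_guides: bool = True,
    approach: str = "guide",
) -> Ranking:
    """Rank genes by summed LLS of their direct edges to guide genes.

    Genes with no edge to any guide (score 0) are omitted. Guides
    themselves are excluded from the ranking unless ``exclude_guides`` is
    False. Ordering is by descending score, ties broken by gene id.
    """
    guide_set = set(guides)
    if not guide_set:
        raise ValueError("guide set is empty")
    guides_present = guide_set & set(graph.nodes)
    if not guides_present:
        raise ValueError("no guide gene is present in the network")
    scores: dict[str, float] = {}
    for guide in guides_present:
        for neighbor, data in graph[guide].items():
            if exclude_guides and neighbor in guide_set:
                continue
            scores[neighbor] = scores.get(neighbor, 0.0) + data["weight"]
    ordered = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    entries = pd.DataFrame(
        {
            "rank": np.arange(1, len(ordered) + 1),
            "gene": [g for g, _ in ordered],
            "statistic": [s for _, s in ordered],
        }
    )
    logger.info(
        "%s prediction: %d guides (%d in network) -> %d scored genes",
        approach,
        len(guide_set),
        len(guides_present),
        len(entries),
    )
    return Ranking(approach=approach, entries=entries)


def hub_overlap_pvalue(k: int, universe: int, n_deg: int, degree: int) -> float:
    """Upper-tail hypergeometric p-value P(X >= k).

    Probability that a random size-``degree`` neighborhood drawn from a
    ``universe`` of genes containing ``n_deg`` differentially expressed
    ones overlaps them in at least ``k`` genes.
    """
    return float(stats.hypergeom.sf(k - 1, universe, n_deg, degree))


def hub_predict(
    graph: nx.Graph,
    deg_genes: Iterable[str],
    min_degree: int = 5,
    universe: int | None = None,
) -> Ranking:
    """Rank hub genes by DEG enrichment of their direct neighborhoods.

    Every gene with degree >= ``min_degree`` is a hub. For hub ``h`` with
    degree ``n`` and ``k`` differentially expressed neighbors, the
    statistic is the one-sided upper-tail hypergeometric p-value of ``k``
    given (``universe``, number of DEGs in the network, ``n``). The
    ranking ascends by p-value; ties prefer larger ``k``, then smaller
    gene id. A Benjamini-Hochberg column ``p_bh`` is attached for
    reference but does not affect the order.
    """
    deg_in_net = set(deg_genes) & set(graph.nodes)
    if not deg_in_net:
        raise ValueError("no differentially expressed gene is present in the network")
    n_nodes = graph.number_of_nodes()
    universe_n = n_nodes if universe is None else int(universe)
    degrees = dict(graph.degree())
    max_degree = max(degrees.values()) if degrees else 0
    if universe_n < len(deg_in_net):
        raise ValueError(
            f"universe ({universe_n}) smaller than DEG count ({len(deg_in_net)})"
        )
    if universe_n < max_degree:
        raise ValueError(
            f"universe ({universe_n}) smaller than maximum degree ({max_degree})"
        )
    hubs = [g for g, d in degrees.items() if d >= min_degree]
    overlaps = np.array(
        [sum(1 for nb in graph[h] if nb in deg_in_net) for h in hubs], dtype=int
    )
    ns = np.array([degrees[h] for h in hubs], dtype=int)
    pvals = stats.hypergeom.sf(overlaps - 1, universe_n, len(deg_in_net), ns)
    entries = pd.DataFrame(
        {"gene": hubs, "statistic": pvals, "overlap_k": overlaps, "neighborhood_n": ns}
    )
    entries = entries.sort_values(
        ["statistic", "overlap_k", "gene"], ascending=[True, False, True]
    ).reset_index(drop=True)
    if len(entries):
        entries["p_bh"] = stats.false_discovery_control(
            entries["statistic"].to_numpy(), method="bh"
        )
    else:
        entries["p_bh"] = np.array([], dtype=float)
    entries.insert(0, "rank", np.arange(1, len(entries) + 1))
    logger.info(
        "hub prediction: %d DEGs in network, %d hubs (degree >= %d), universe %d",
        len(deg_in_net),
        len(hubs),
        min_degree,
        universe_n,
    )
    return Ranking(approach="hub", entries=entries)


def top_n(ranking: Ranking, n: int = 20) -> Ranking:
    """First ``n`` entries of a ranking, ranks renumbered from 1."""
    if n < 1:
        raise ValueError("n must be >= 1")
    entries = ranking.entries.head(n).reset_index(drop=True).copy()
    entries["rank"] = np.arange(1, len(entries) + 1)
    return replace(ranking, entries=entries)


def write_ranking(ranking: Ranking, path: str | Path) -> None:
    """Write a ranking as TSV (approach recorded in a header comment)."""
    with open(path, "w") as handle:
        handle.write(f"# approach={ranking.approach}\n")
        ranking.entries.to_csv(handle, sep="\t", index=False)


def read_ranking(path: str | Path) -> Ranking:
    """Read a ranking written by :func:`write_ranking`."""
    with open(path) as handle:
        first = handle.readline().strip()
        if not first.startswith("# approach="):
            raise ValueError(f"{path}: missing '# approach=' header line")
        approach = first.split("=", 1)[1]
        entries = pd.read_csv(handle, sep="\t")
    entries["gene"] = entries["gene"].astype(str)
    return Ranking(approach=approach, entries=entries)
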
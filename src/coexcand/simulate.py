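"""Synthetic planted-module benchmarks for the candidate-gene pipeline.

Generates the three kinds of input the analysis consumes, with known
ground truth so every downstream stage can be scored:

* a sparse weighted co-expression network containing a densely connected
  planted pathway module whose edges carry higher log-likelihood scores
  than the background;
* a matched FPKM matrix for two genotypes ("high" = case, "low" =
  control) with three biological replicates each, log-normal baseline
  expression, Gaussian replicate noise on the log2 scale and planted
  signed log2 effects on a subset of genes that overlaps the module;
* a qPCR Ct table linked to the expression matrix through the standard
  cycle-threshold relation ``Ct = intercept - log2(FPKM) + noise``.

All generators are pure functions of their configuration and seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .deg import ExpressionMatrix

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "generate_network",
    "generate_expression",
    "generate_qpcr",
    "choose_reference_gene",
    "CtTable",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the planted-module benchmark.

    Defaults emulate a two-genotype, three-replicate leaf RNA-seq
    contrast: 2,000 genes of which 200 carry planted absolute log2
    effects between 2 and 6, replicate noise of 0.25 on the log2 scale,
    and a 30-gene pathway module wired far more densely (and with higher
    log-likelihood scores) than the background network.
    """

    n_genes: int = 2000
    n_pathway: int = 30
    n_guides: int = 15
    p_within: float = 0.6
    p_background: float = 0.003
    lls_within_range: tuple[float, float] = (2.0, 4.0)
    lls_background_range: tuple[float, float] = (0.5, 1.5)
    n_replicates: int = 3
    n_deg: int = 200
    deg_log2fc_range: tuple[float, float] = (2.0, 6.0)
    frac_deg_in_pathway: float = 0.1
    base_log2fpkm_mean: float = 5.0
    base_log2fpkm_sd: float = 2.0
    noise_sd: float = 0.25
    hub_min_degree: int = 5
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if not 0 <= self.n_pathway <= self.n_genes:
            raise ValueError("n_pathway must satisfy 0 <= n_pathway <= n_genes")
        if not 0 <= self.n_guides <= self.n_pathway:
            raise ValueError("n_guides must satisfy 0 <= n_guides <= n_pathway")
        for name in ("p_within", "p_background"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for name in ("lls_within_range", "lls_background_range", "deg_log2fc_range"):
            lo, hi = getattr(self, name)
            if not (lo <= hi):
                raise ValueError(f"{name} must have lower <= upper")
            if name != "deg_log2fc_range" and lo <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")
        if not 0 <= self.n_deg <= self.n_genes:
            raise ValueError("n_deg must satisfy 0 <= n_deg <= n_genes")
        if not 0.0 <= self.frac_deg_in_pathway <= 1.0:
            raise ValueError("frac_deg_in_pathway must be in [0, 1]")
        n_in = round(self.frac_deg_in_pathway * self.n_deg)
        if n_in > self.n_pathway:
            raise ValueError(
                "frac_deg_in_pathway places more planted DEGs in the pathway "
                f"({n_in}) than there are pathway genes ({self.n_pathway})"
            )
        if self.n_deg - n_in > self.n_genes - self.n_pathway:
            raise ValueError("n_deg exceeds the number of non-pathway genes available")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.base_log2fpkm_sd < 0:
            raise ValueError("base_log2fpkm_sd must be non-negative")
        if self.hub_min_degree < 1:
            raise ValueError("hub_min_degree must be >= 1")


@dataclass(frozen=True)
class GroundTruth:
    """Planted structure of a simulated benchmark.

    ``deg_genes`` maps each planted differentially expressed gene to its
    true signed log2 effect (positive = up in the case genotype).
    ``hub_genes`` are the planted pathway genes whose realized degree
    reached the hub threshold, recorded when the network is generated so
    hub-recovery checks are well-posed.
    """

    pathway_genes: frozenset[str]
    guide_genes: frozenset[str]
    deg_genes: dict[str, float] = field(default_factory=dict)
    hub_genes: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.guide_genes <= self.pathway_genes:
            raise ValueError("guide_genes must be a subset of pathway_genes")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "pathway_genes": sorted(self.pathway_genes),
            "guide_genes": sorted(self.guide_genes),
            "hub_genes": sorted(self.hub_genes),
            "deg_genes": {g: self.deg_genes[g] for g in sorted(self.deg_genes)},
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            pathway_genes=frozenset(payload["pathway_genes"]),
            guide_genes=frozenset(payload["guide_genes"]),
            deg_genes=dict(payload["deg_genes"]),
            hub_genes=frozenset(payload["hub_genes"]),
        )


@dataclass
class CtTable:
    """qPCR cycle-threshold measurements with the expression design.

    ``data`` has one row per (sample, gene, technical replicate) with
    columns ``sample_id``, ``gene_id``, ``ct``; ``design`` is indexed by
    sample id with ``genotype`` and ``replicate`` columns, as in
    :class:`~coexcand.deg.ExpressionMatrix`.
    """

    data: pd.DataFrame
    design: pd.DataFrame
    reference_gene: str
    case: str = "high"
    control: str = "low"

    def __post_init__(self) -> None:
        required = {"sample_id", "gene_id", "ct"}
        if not required <= set(self.data.columns):
            raise ValueError(f"Ct table needs columns {sorted(required)}")
        samples = set(self.data["sample_id"])
        ref_samples = set(
            self.data.loc[self.data["gene_id"] == self.reference_gene, "sample_id"]
        )
        if samples - ref_samples:
            raise ValueError(
                "reference gene not measured in every sample: "
                f"missing {sorted(samples - ref_samples)}"
            )
        ct = self.data["ct"].to_numpy(dtype=float)
        if not np.isfinite(ct).all() or (ct <= 0).any():
            raise ValueError("Ct values must be finite and positive")


def gene_ids(n: int) -> list[str]:
    """Synthetic zero-padded gene identifiers G000001..G{n}."""
    return [f"G{i:06d}" for i in range(1, n + 1)]


def generate_network(config: SimulationConfig) -> tuple[nx.Graph, GroundTruth]:
    """Draw a planted-module network.

    Every pair of planted pathway genes receives an edge with probability
    ``p_within`` and a weight uniform in ``lls_within_range``; every other
    pair with probability ``p_background`` and weight from
    ``lls_background_range``. All genes appear as nodes (isolated genes
    included). Hub truth records the pathway genes whose realized degree
    reached ``hub_min_degree``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes = np.array(gene_ids(config.n_genes))
    pathway_idx = np.sort(
        rng.choice(config.n_genes, size=config.n_pathway, replace=False)
    )
    guide_idx = np.sort(rng.choice(pathway_idx, size=config.n_guides, replace=False))
    in_pathway = np.zeros(config.n_genes, dtype=bool)
    in_pathway[pathway_idx] = True

    ii, jj = np.triu_indices(config.n_genes, k=1)
    within = in_pathway[ii] & in_pathway[jj]

    graph = nx.Graph()
    graph.add_nodes_from(genes.tolist())
    for mask, prob, (lo, hi) in (
        (within, config.p_within, config.lls_within_range),
        (~within, config.p_background, config.lls_background_range),
    ):
        pi, pj = ii[mask], jj[mask]
        keep = rng.random(pi.size) < prob
        weights = rng.uniform(lo, hi, size=int(keep.sum()))
        graph.add_weighted_edges_from(
            zip(genes[pi[keep]], genes[pj[keep]], map(float, weights))
        )

    hub_genes = frozenset(
        g for g in genes[pathway_idx] if graph.degree(g) >= config.hub_min_degree
    )
    truth = GroundTruth(
        pathway_genes=frozenset(genes[pathway_idx]),
        guide_genes=frozenset(genes[guide_idx]),
        hub_genes=hub_genes,
    )
    return graph, truth


def generate_expression(
    config: SimulationConfig, truth: GroundTruth
) -> tuple[ExpressionMatrix, GroundTruth]:
    """Draw an FPKM matrix with planted differential expression.

    FPKM(gene, sample) = 2^(baseline + effect·[sample is case] + noise)
    with baseline ~ N(base_log2fpkm_mean, base_log2fpkm_sd) per gene and
    noise ~ N(0, noise_sd) per gene and sample. Exactly ``n_deg`` genes
    receive a nonzero effect; ``round(frac_deg_in_pathway * n_deg)`` of
    them are pathway genes (always up-regulated in the case genotype, the
    direction a pathway driving a high-metabolite phenotype implies);
    the remainder are non-pathway genes with random sign.

    Returns the matrix and a new :class:`GroundTruth` with ``deg_genes``
    filled in.
    """
    config.validate()
    genes = gene_ids(config.n_genes)
    gene_set = set(genes)
    if not set(truth.pathway_genes) <= gene_set:
        raise ValueError("ground truth pathway genes are not in the config gene universe")
    rng = np.random.default_rng(config.seed + 1)

    baseline = rng.normal(
        config.base_log2fpkm_mean, config.base_log2fpkm_sd, size=config.n_genes
    )

    n_in = round(config.frac_deg_in_pathway * config.n_deg)
    pathway_sorted = np.array(sorted(truth.pathway_genes))
    non_pathway = np.array([g for g in genes if g not in truth.pathway_genes])
    deg_pathway = rng.choice(pathway_sorted, size=n_in, replace=False)
    deg_background = rng.choice(non_pathway, size=config.n_deg - n_in, replace=False)
    lo, hi = config.deg_log2fc_range
    magnitudes = rng.uniform(lo, hi, size=config.n_deg)
    signs = np.concatenate(
        [np.ones(n_in), rng.choice([-1.0, 1.0], size=config.n_deg - n_in)]
    )
    deg_order = np.concatenate([deg_pathway, deg_background])
    effects = {g: float(s * m) for g, s, m in zip(deg_order, signs, magnitudes)}

    r = config.n_replicates
    samples = [f"high_{k}" for k in range(1, r + 1)] + [
        f"low_{k}" for k in range(1, r + 1)
    ]
    is_case = np.array([1.0] * r + [0.0] * r)
    effect_vec = np.array([effects.get(g, 0.0) for g in genes])
    noise = rng.normal(0.0, config.noise_sd, size=(config.n_genes, 2 * r))
    log2fpkm = baseline[:, None] + effect_vec[:, None] * is_case[None, :] + noise
    values = pd.DataFrame(2.0 ** log2fpkm, index=genes, columns=samples)
    design = pd.DataFrame(
        {
            "genotype": ["high"] * r + ["low"] * r,
            "replicate": list(range(1, r + 1)) * 2,
        },
        index=pd.Index(samples, name="sample_id"),
    )
    matrix = ExpressionMatrix(values, design, case="high", control="low")
    return matrix, dataclasses.replace(truth, deg_genes=effects)


def choose_reference_gene(truth: GroundTruth, expression: ExpressionMatrix) -> str:
    """Pick a housekeeping-style normalization reference for simulated qPCR.

    The most highly expressed gene that is neither planted differential
    nor a pathway member (an actin analog); ties broken by gene id.
    """
    excluded = set(truth.deg_genes) | set(truth.pathway_genes)
    means = expression.values.mean(axis=1)
    candidates = means[~means.index.isin(excluded)]
    if candidates.empty:
        raise ValueError("no non-differential, non-pathway gene available")
    best = candidates.max()
    return str(min(candidates.index[candidates == best]))


def generate_qpcr(
    truth: GroundTruth,
    expression: ExpressionMatrix,
    reference_gene: str,
    ct_intercept: float = 34.0,
    ct_noise_sd: float = 0.2,
    seed: int = 0,
    genes: list[str] | None = None,
) -> CtTable:
    """Simulate a qPCR Ct table consistent with the expression matrix.

    ``Ct(sample, gene) = ct_intercept - log2(FPKM(sample, gene)) + noise``
    with noise ~ N(0, ct_noise_sd). By default the planted differential
    genes plus the reference are assayed; pass ``genes`` to assay a
    specific panel (the reference is always added).
    """
    if reference_gene not in expression.values.index:
        raise ValueError(f"reference gene {reference_gene!r} absent from expression")
    if truth.deg_genes.get(reference_gene):
        raise ValueError(
            f"reference gene {reference_gene!r} is planted as differential"
        )
    if genes is None:
        panel = sorted(set(truth.deg_genes) | {reference_gene})
    else:
        missing = set(genes) - set(expression.values.index)
        if missing:
            raise ValueError(f"genes absent from expression: {sorted(missing)}")
        panel = sorted(set(genes) | {reference_gene})
    rng = np.random.default_rng(seed)
    sub = expression.values.loc[panel]
    ct = (
        ct_intercept
        - np.log2(sub.to_numpy())
        + rng.normal(0.0, ct_noise_sd, size=sub.shape)
    )
    frame = pd.DataFrame(ct, index=panel, columns=sub.columns)
    data = (
        frame.rename_axis("gene_id")
        .reset_index()
        .melt(id_vars="gene_id", var_name="sample_id", value_name="ct")
        .loc[:, ["sample_id", "gene_id", "ct"]]
        .sort_values(["sample_id", "gene_id"])
        .reset_index(drop=True)
    )
    return CtTable(
        data=data,
        design=expression.design.copy(),
        reference_gene=reference_gene,
        case=expression.case,
        control=expression.control,
    )
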
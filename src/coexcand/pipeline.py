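"""End-to-end orchestration: simulate -> deg -> predict -> integrate -> qpcr.

Each stage reads its inputs from, and writes its outputs to, the run's
output directory, so any downstream stage can be re-run from the files on
disk with identical results. A single seed in the configuration drives
every source of randomness; running the same configuration twice produces
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import candidates as cand
from . import deg as degmod
from . import io as cio
from . import network as netmod
from . import qpcr as qpcrmod
from . import simulate as sim

__all__ = ["PipelineConfig", "run_pipeline", "SUMMARY_SCHEMA_VERSION"]

logger = logging.getLogger(__name__)

SUMMARY_SCHEMA_VERSION = 1

FILENAMES = {
    "network": "network.tsv",
    "expression": "expression.tsv",
    "samples": "samples.csv",
    "pathway": "pathway_genes.txt",
    "truth": "truth.json",
    "deg_table": "deg_table.tsv",
    "ranking_guide": "ranking_guide.tsv",
    "ranking_deg_guide": "ranking_deg_guide.tsv",
    "ranking_hub": "ranking_hub.tsv",
    "candidates": "candidates.tsv",
    "candidate_summary": "candidate_summary.json",
    "ct": "qpcr_ct.csv",
    "qpcr_validation": "qpcr_validation.tsv",
    "summary": "summary.json",
}


@dataclass
class PipelineConfig:
    """Configuration for a full pipeline run.

    Either all input paths (network, expression, samples, pathway) exist,
    or a ``simulation`` block is given and the inputs are generated into
    ``out_dir`` first. The Ct table is optional in path mode; in
    simulation mode it is synthesized for the candidate genes.
    """

    out_dir: Path = Path("results")
    seed: int = 0
    simulation: sim.SimulationConfig | None = None
    network_path: Path | None = None
    expression_path: Path | None = None
    samples_path: Path | None = None
    pathway_path: Path | None = None
    ct_path: Path | None = None
    case_genotype: str = "high"
    control_genotype: str = "low"
    alpha: float = 0.05
    fc_thresholds: tuple[int, ...] = (2, 3, 4, 5)
    base_threshold: int = 2
    top_n: int = 20
    min_degree: int = 5
    universe: int | None = None
    up_only: bool = False
    reference_gene: str | None = None
    ct_intercept: float = 34.0
    ct_noise_sd: float = 0.2

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        if self.simulation is None:
            required = {
                "network_path": self.network_path,
                "expression_path": self.expression_path,
                "samples_path": self.samples_path,
                "pathway_path": self.pathway_path,
            }
            missing = [k for k, v in required.items() if v is None]
            if missing:
                raise ValueError(
                    "without a simulation block these input paths are required: "
                    + ", ".join(missing)
                )
        if self.base_threshold not in self.fc_thresholds:
            raise ValueError(
                f"base_threshold {self.base_threshold} not among "
                f"fc_thresholds {self.fc_thresholds}"
            )

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        """Load a flat YAML config; a ``simulation:`` mapping becomes a
        :class:`~coexcand.simulate.SimulationConfig`."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update(overrides)
        if isinstance(raw.get("simulation"), dict):
            sim_block = dict(raw["simulation"])
            for key in (
                "lls_within_range",
                "lls_background_range",
                "deg_log2fc_range",
            ):
                if key in sim_block:
                    sim_block[key] = tuple(sim_block[key])
            raw["simulation"] = sim.SimulationConfig(**sim_block)
        for key in ("out_dir", "network_path", "expression_path", "samples_path",
                    "pathway_path", "ct_path"):
            if raw.get(key) is not None:
                raw[key] = Path(raw[key])
        if "fc_thresholds" in raw:
            raw["fc_thresholds"] = tuple(raw["fc_thresholds"])
        return cls(**raw)

    def path(self, key: str) -> Path:
        return self.out_dir / FILENAMES[key]


def _sim_config(config: PipelineConfig) -> sim.SimulationConfig:
    assert config.simulation is not None
    return dataclasses.replace(config.simulation, seed=config.seed)


def stage_simulate(config: PipelineConfig) -> None:
    """Generate network, expression, sample sheet, pathway list and truth."""
    if config.simulation is None:
        raise ValueError("stage_simulate requires a simulation block")
    config.out_dir.mkdir(parents=True, exist_ok=True)
    sim_cfg = _sim_config(config)
    graph, truth = sim.generate_network(sim_cfg)
    matrix, truth = sim.generate_expression(sim_cfg, truth)
    netmod.write_network(graph, config.path("network"))
    cio.write_expression(matrix, config.path("expression"), config.path("samples"))
    # The known pathway list handed to prediction is the planted guide
    # subset: the remaining planted members are the unknowns the method
    # is supposed to recover. The full module lives in truth.json.
    cio.write_gene_list(truth.guide_genes, config.path("pathway"))
    truth.to_json(config.path("truth"))
    logger.info(
        "simulated %d genes, %d network edges, %d planted DEGs",
        sim_cfg.n_genes,
        graph.number_of_edges(),
        len(truth.deg_genes),
    )


def _input_path(config: PipelineConfig, key: str) -> Path:
    explicit = getattr(config, f"{key}_path", None)
    if config.simulation is None and explicit is not None:
        return Path(explicit)
    return config.path(key)


def _load_expression(config: PipelineConfig) -> degmod.ExpressionMatrix:
    return cio.read_expression(
        _input_path(config, "expression"),
        _input_path(config, "samples"),
        case=config.case_genotype,
        control=config.control_genotype,
    )


def stage_deg(config: PipelineConfig) -> None:
    """Call DEGs from the expression matrix on disk."""
    config.out_dir.mkdir(parents=True, exist_ok=True)
    matrix = _load_expression(config)
    table = degmod.call_degs(
        matrix, alpha=config.alpha, thresholds=config.fc_thresholds
    )
    cio.write_deg_table(table, config.path("deg_table"))
    for t in sorted(config.fc_thresholds):
        n_total, n_up, frac = degmod.direction_summary(table, t)
        logger.info(
            "DEGs at |log2FC| >= %d: %d (%d up, fraction %.3f)", t, n_total, n_up, frac
        )


def stage_predict(config: PipelineConfig) -> None:
    """Run the three prediction approaches and write top-N rankings."""
    graph = netmod.read_network(_input_path(config, "network"))
    pathway = cio.read_gene_list(_input_path(config, "pathway"))
    deg_table = cio.read_deg_table(config.path("deg_table"))
    degs = degmod.deg_set(deg_table, config.base_threshold)

    guides = netmod.connected_pathway_subset(graph, pathway)
    logger.info(
        "pathway genes: %d given, %d connected in the network", len(pathway), len(guides)
    )
    guide_rank = netmod.top_n(
        netmod.guide_predict(graph, guides, approach="guide"), config.top_n
    )

    deg_guides = guides & degs
    logger.info("differential pathway genes used as seeds: %d", len(deg_guides))
    if deg_guides:
        deg_guide_rank = netmod.top_n(
            netmod.guide_predict(graph, deg_guides, approach="deg_guide"),
            config.top_n,
        )
    else:
        deg_guide_rank = netmod.Ranking(
            approach="deg_guide",
            entries=guide_rank.entries.iloc[0:0].copy(),
        )

    degs_in_net = degs & set(graph.nodes)
    if degs_in_net:
        hub_rank = netmod.top_n(
            netmod.hub_predict(
                graph, degs, min_degree=config.min_degree, universe=config.universe
            ),
            config.top_n,
        )
    else:
        hub_rank = netmod.Ranking(
            approach="hub",
            entries=pd.DataFrame(
                columns=["rank", "gene", "statistic", "overlap_k",
                         "neighborhood_n", "p_bh"]
            ),
        )

    netmod.write_ranking(guide_rank, config.path("ranking_guide"))
    netmod.write_ranking(deg_guide_rank, config.path("ranking_deg_guide"))
    netmod.write_ranking(hub_rank, config.path("ranking_hub"))


def stage_integrate(config: PipelineConfig) -> None:
    """Merge the rankings with the DEG table into the candidate table."""
    rankings = [
        netmod.read_ranking(config.path(k))
        for k in ("ranking_guide", "ranking_deg_guide", "ranking_hub")
    ]
    deg_table = cio.read_deg_table(config.path("deg_table"))
    table = cand.integrate_predictions(
        rankings, deg_table, base_threshold=config.base_threshold,
        up_only=config.up_only,
    )
    summary = cand.candidate_summary(
        table, rankings, deg_table, base_threshold=config.base_threshold
    )
    cand.export_candidates(
        table,
        config.path("candidates"),
        summary=summary,
        json_path=config.path("candidate_summary"),
    )
    logger.info(
        "candidates: %d total, %d supported by >= 2 approaches",
        summary["n_candidates"],
        summary["support_ge2"],
    )


def stage_qpcr(config: PipelineConfig) -> None:
    """Validate candidate fold changes with (real or simulated) qPCR."""
    table = cand.read_candidates(config.path("candidates"))
    deg_table = cio.read_deg_table(config.path("deg_table"))
    genes = list(table["gene"]) if len(table) else []

    if config.simulation is not None:
        truth = sim.GroundTruth.from_json(config.path("truth"))
        matrix = _load_expression(config)
        reference = config.reference_gene or sim.choose_reference_gene(truth, matrix)
        if not genes:
            logger.info("no candidates; skipping qPCR simulation")
            cio.write_ct_table(
                sim.generate_qpcr(
                    truth, matrix, reference,
                    ct_intercept=config.ct_intercept,
                    ct_noise_sd=config.ct_noise_sd,
                    seed=config.seed + 2,
                    genes=[reference],
                ),
                config.path("ct"),
            )
            qpcrmod.validate_candidates(
                cio.read_ct_table(
                    config.path("ct"), config.path("samples"), reference,
                    case=config.case_genotype, control=config.control_genotype,
                ),
                {},
                alpha=config.alpha,
            ).to_csv(config.path("qpcr_validation"), sep="\t", index=False)
            return
        ct_table = sim.generate_qpcr(
            truth,
            matrix,
            reference,
            ct_intercept=config.ct_intercept,
            ct_noise_sd=config.ct_noise_sd,
            seed=config.seed + 2,
            genes=genes,
        )
        cio.write_ct_table(ct_table, config.path("ct"))
    else:
        if config.ct_path is None:
            logger.info("no Ct table provided; skipping qPCR validation")
            return
        if config.reference_gene is None:
            raise ValueError("reference_gene is required to read a Ct table")
        reference = config.reference_gene
        ct_table = cio.read_ct_table(
            config.ct_path,
            _input_path(config, "samples"),
            reference,
            case=config.case_genotype,
            control=config.control_genotype,
        )

    log2fc = {g: float(deg_table.loc[g, "log2fc"]) for g in genes if g in deg_table.index}
    validation = qpcrmod.validate_candidates(ct_table, log2fc, alpha=config.alpha)
    validation.to_csv(
        config.path("qpcr_validation"), sep="\t", index=False, float_format="%.17g"
    )
    if len(validation):
        logger.info(
            "qPCR validation: %d genes, %d concordant with RNA-seq",
            len(validation),
            int(validation["concordant_with_rnaseq"].sum()),
        )


def _summarize(config: PipelineConfig) -> dict:
    deg_table = cio.read_deg_table(config.path("deg_table"))
    graph = netmod.read_network(_input_path(config, "network"))
    rankings = {
        k.removeprefix("ranking_"): netmod.read_ranking(config.path(k))
        for k in ("ranking_guide", "ranking_deg_guide", "ranking_hub")
    }
    candidate_summary = json.loads(config.path("candidate_summary").read_text())
    deg_counts = {}
    fraction_up = {}
    for t in sorted(config.fc_thresholds):
        n_total, n_up, frac = degmod.direction_summary(deg_table, t)
        deg_counts[str(t)] = n_total
        fraction_up[str(t)] = frac
    summary = {
        "schema_version": SUMMARY_SCHEMA_VERSION,
        "seed": config.seed,
        "alpha": config.alpha,
        "base_threshold": config.base_threshold,
        "top_n": config.top_n,
        "n_genes": int(len(deg_table)),
        "network": {
            "n_nodes": graph.number_of_nodes(),
            "n_edges": graph.number_of_edges(),
        },
        "deg_counts": deg_counts,
        "fraction_up": fraction_up,
        "ranking_lengths": {k: len(r) for k, r in rankings.items()},
        "candidates": candidate_summary,
    }
    validation_path = config.path("qpcr_validation")
    if validation_path.exists():
        validation = pd.read_csv(validation_path, sep="\t")
        n = int(len(validation))
        n_agree = int(validation["concordant_with_rnaseq"].sum()) if n else 0
        summary["qpcr"] = {
            "n_genes": n,
            "n_concordant": n_agree,
            "concordance": (n_agree / n) if n else None,
        }
    else:
        summary["qpcr"] = None
    return summary


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage in order and write ``summary.json``.

    Returns the summary dictionary. Identical configuration (including
    the seed) yields byte-identical outputs.
    """
    config.out_dir.mkdir(parents=True, exist_ok=True)
    stages = []
    if config.simulation is not None:
        stages.append(("simulate", stage_simulate))
    stages += [
        ("deg", stage_deg),
        ("predict", stage_predict),
        ("integrate", stage_integrate),
        ("qpcr", stage_qpcr),
    ]
    for name, fn in stages:
        try:
            fn(config)
        except Exception:
            logger.error("pipeline stage %r failed", name)
            raise
    summary = _summarize(config)
    config.path("summary").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n"
    )
    return summary
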
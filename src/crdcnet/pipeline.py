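"""End-to-end orchestration: simulate -> preprocess -> DE -> CIN split ->
ceRNA network -> dense modules -> risk model -> evaluation.

One :class:`PipelineConfig` drives every stage; each randomized stage uses
a child stream of the root seed keyed by the stage name, so reruns with
the same seed are byte-identical and stage order cannot perturb streams.
All intermediate artifacts are written as TSV (graphs as GraphML), with a
JSON manifest recording the parameters actually used.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from . import __version__
from .cerna import build_network, identify_cerna_pairs, network_tables
from .cin import cin_score, stepminer_split
from .matrix import ExpressionMatrix
from .modules import (greedy_search, merge_modules, modules_table,
                      permutation_filter, select_top)
from .preprocess import classify_lncrna, differential_expression, log_and_filter
from .simulate import SimulationConfig, _child_rng, simulate_cohort
from .survival import crdc_score, fit_risk_model, km_logrank, roc_auc, training_subset

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Stage parameters for a full run.

    ``simulation=None`` selects real mode, in which ``expression_tsv``,
    ``gene_meta_tsv``, ``interactions_tsv``, ``clinical_tsv`` and
    ``cin_signature_gmt`` must point at existing files.
    """

    simulation: SimulationConfig | None = field(default_factory=SimulationConfig)
    expression_tsv: str | None = None
    gene_meta_tsv: str | None = None
    interactions_tsv: str | None = None
    clinical_tsv: str | None = None
    cin_signature_gmt: str | None = None
    # preprocessing / DE
    missing_frac: float = 0.30
    de_method: str = "mannwhitney"
    lfc_cut: float = 1.0
    fdr_cut: float = 0.01
    restrict_to_degs: bool = True
    # ceRNA identification / network
    cerna_fdr_cut: float = 0.05
    pcc_cut: float = 0.1
    edge_weight_variant: str = "sqrt"
    # module discovery
    d: int = 1
    growth_r: float = 0.1
    lambda_: float = 0.44
    top_fraction: float = 0.10
    n_perm: int = 10_000
    alpha: float = 0.01
    # risk model
    endpoint: str = "DSS"
    seed: int = 0

    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        Path(path).write_text(json.dumps(d, indent=2, default=str) + "\n")


@dataclass
class PipelineResult:
    outdir: Path
    network: nx.Graph
    crdc_genes: list
    risk_table: pd.DataFrame
    evaluation: dict
    manifest: dict


def _load_real_inputs(config: PipelineConfig):
    for name in ("expression_tsv", "gene_meta_tsv", "interactions_tsv",
                 "clinical_tsv", "cin_signature_gmt"):
        path = getattr(config, name)
        if path is None or not Path(path).exists():
            raise FileNotFoundError(f"real mode requires {name}; missing: {path}")
    gene_meta = pd.read_csv(config.gene_meta_tsv, sep="\t", index_col=0)
    sample_meta = None
    tpm = ExpressionMatrix.from_tsv(config.expression_tsv, "TPM", gene_meta, sample_meta)
    interactions = pd.read_csv(config.interactions_tsv, sep="\t")
    clinical = pd.read_csv(config.clinical_tsv, sep="\t", index_col=0)
    from .cin import read_gmt

    signature = next(iter(read_gmt(config.cin_signature_gmt).values()))
    return tpm, interactions, clinical, signature, None


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> PipelineResult:
    """Execute every stage, writing all intermediates under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": config.seed, "stages": {}}

    # ---- stage: input (simulate or load) ------------------------------
    if config.simulation is not None:
        cohort = simulate_cohort(config.simulation, seed=config.seed)
        cohort.write(outdir / "cohort")
        tpm = cohort.expression
        interactions = cohort.interactions
        clinical = cohort.survival
        signature = cohort.truth.cin_like_genes
        truth = cohort.truth
        manifest["stages"]["simulate"] = asdict(config.simulation)
    else:
        tpm, interactions, clinical, signature, truth = _load_real_inputs(config)
        manifest["stages"]["load"] = {"expression": config.expression_tsv}

    sample_meta = tpm.sample_meta
    tumor = list(sample_meta.index[sample_meta["group"] == "tumor"])
    adjacent = list(sample_meta.index[sample_meta["group"] == "adjacent"])

    # ---- stage: preprocess --------------------------------------------
    log2 = log_and_filter(tpm, missing_frac=config.missing_frac)
    rna_class = classify_lncrna(log2.gene_meta)
    mrnas = rna_class.index[rna_class == "mRNA"]
    lncrnas = rna_class.index[rna_class == "lncRNA"]
    manifest["stages"]["preprocess"] = {
        "missing_frac": config.missing_frac,
        "n_genes": int(log2.values.shape[0]),
        "n_mrnas": int(len(mrnas)), "n_lncrnas": int(len(lncrnas)),
    }

    # ---- stage: differential expression -------------------------------
    if config.restrict_to_degs and adjacent:
        de = differential_expression(
            log2, tumor, adjacent,
            lfc_cut=config.lfc_cut, fdr_cut=config.fdr_cut, method=config.de_method,
        )
        de.table.to_csv(outdir / "de_tumor_vs_adjacent.tsv", sep="\t")
        deg = de.significant
        deg_mrnas = [g for g in mrnas if g in set(deg)]
        deg_lncrnas = [g for g in lncrnas if g in set(deg)]
        manifest["stages"]["de"] = {
            "method": config.de_method, "lfc_cut": config.lfc_cut,
            "fdr_cut": config.fdr_cut, "n_deg": int(len(deg)),
            "note": "rank-based two-group test on log2TPM (count-model backends pluggable)",
        }
    else:
        deg_mrnas, deg_lncrnas = list(mrnas), list(lncrnas)
        manifest["stages"]["de"] = {"method": "disabled (full universe)"}

    # ---- stage: CIN score and StepMiner split -------------------------
    cin = cin_score(tpm.subset_samples(tumor), signature)
    split = stepminer_split(cin.scores)
    pd.DataFrame({"score": cin.scores, "label": split.labels}).to_csv(
        outdir / "cin_scores.tsv", sep="\t", index_label="sample")
    high = list(split.labels.index[split.labels == "High"])
    low = list(split.labels.index[split.labels == "Low"])
    manifest["stages"]["cin"] = {
        "threshold": split.threshold, "n_high": len(high), "n_low": len(low),
        "signature_genes_used": len(cin.gene_set_used),
    }

    # ---- stage: ceRNA identification + network ------------------------
    pairs = {}
    for name, samples in (("high", high), ("low", low)):
        pairs[name] = identify_cerna_pairs(
            log2.subset_samples(samples), interactions, deg_mrnas, deg_lncrnas,
            fdr_cut=config.cerna_fdr_cut, pcc_cut=config.pcc_cut,
        )
        pairs[name].to_csv(outdir / f"cerna_pairs_cin_{name}.tsv", sep="\t", index=False)
    network = build_network(
        pairs["high"], pairs["low"], clinical, log2,
        n_high=len(high), n_low=len(low), variant=config.edge_weight_variant,
    )
    nodes_tbl, edges_tbl = network_tables(network)
    nodes_tbl.to_csv(outdir / "network_nodes.tsv", sep="\t")
    edges_tbl.to_csv(outdir / "network_edges.tsv", sep="\t", index=False)
    _write_graphml(network, outdir / "network.graphml")
    manifest["stages"]["network"] = {
        **{k: getattr(network.graph["summary"], k)
           for k in ("n_nodes", "n_edges", "n_gain", "n_loss", "powerlaw_r2")},
        "variant": config.edge_weight_variant,
    }

    # ---- stage: dense modules -----------------------------------------
    modules = greedy_search(network, d=config.d, growth_r=config.growth_r,
                            lambda_=config.lambda_)
    top = select_top(modules, fraction=config.top_fraction)
    surviving = permutation_filter(
        top, log2, training_subset(clinical), background=list(network.nodes),
        n_perm=config.n_perm, alpha=config.alpha,
        rng=_child_rng(config.seed, "permutation"),
    )
    modules_table(modules, kept={m.seed for m in surviving}).to_csv(
        outdir / "modules.tsv", sep="\t")
    if not surviving:
        raise RuntimeError("module_discovery: no module survived the permutation filter")
    crdc = merge_modules(surviving, network)
    pd.Series(crdc.genes, name="gene").to_csv(outdir / "crdc_genes.tsv",
                                              sep="\t", index=False)
    if crdc.subgraph is not None:
        _write_graphml(crdc.subgraph, outdir / "crdc_subnetwork.graphml")
    manifest["stages"]["modules"] = {
        "d": config.d, "growth_r": config.growth_r, "lambda": config.lambda_,
        "top_fraction": config.top_fraction, "n_perm": config.n_perm,
        "alpha": config.alpha, "n_modules": len(modules), "n_top": len(top),
        "n_surviving": len(surviving), "n_crdc_genes": len(crdc.genes),
    }

    # ---- stage: risk model + evaluation -------------------------------
    model = fit_risk_model(log2, crdc.genes, clinical, endpoint=config.endpoint)
    model.table.to_csv(outdir / "risk_model.tsv", sep="\t", index_label="gene")
    scores = crdc_score(log2, model)
    risk_split = stepminer_split(scores.scores.loc[tumor])
    chi2, logrank_p, _curves = km_logrank(risk_split.labels, clinical)
    evaluation = {
        "logrank_chi2": chi2,
        "logrank_p": logrank_p,
        "risk_threshold": risk_split.threshold,
        "n_high": int((risk_split.labels == "High").sum()),
        "n_low": int((risk_split.labels == "Low").sum()),
    }
    if adjacent:
        labels = pd.Series(
            np.where(pd.Index(scores.scores.index).isin(tumor), 1, 0),
            index=scores.scores.index)
        evaluation["tumor_vs_adjacent_auc"] = roc_auc(scores.scores, labels)
    pd.DataFrame({"score": scores.scores}).assign(
        label=risk_split.labels).to_csv(outdir / "crdc_scores.tsv", sep="\t",
                                        index_label="sample")
    manifest["stages"]["risk_model"] = {
        "endpoint": config.endpoint, "n_genes": len(model.genes),
        "dropped": model.dropped,
    }
    manifest["evaluation"] = evaluation
    if truth is not None:
        planted = set(truth.planted_module)
        manifest["ground_truth_recovery"] = {
            "planted_module_genes": sorted(planted),
            "planted_in_crdc": sorted(planted & set(crdc.genes)),
            "module_fully_recovered": planted <= set(crdc.genes),
        }

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    config.to_json(outdir / "pipeline_config.json")
    return PipelineResult(outdir, network, crdc.genes, model.table, evaluation, manifest)


def _write_graphml(graph: nx.Graph, path: Path) -> None:
    g = graph.copy()
    g.graph.pop("summary", None)  # dataclass attrs are not GraphML-serializable
    nx.write_graphml(g, path)
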
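"""Dense-module search on the double-weighted network and the CRDC filters.

The module score is a convex combination of mean edge weight and mean node
weight, score = lambda * sum(E)/n_E + (1 - lambda) * sum(N)/n_N (the edge
term is 0 for a singleton).  Every network node seeds a greedy search:
repeatedly add the best-scoring neighbor within shortest-path distance d
of the module, but only while the score increment exceeds growth_r times
the previous score.  Defaults d = 1, growth_r = 0.1, lambda = 0.44.

Modules then pass three filters: keep the top fraction by score (ceiling,
ties at the cutoff retained); keep modules whose observed multivariate Cox
p on disease-specific survival beats the null distribution of equally
sized random gene sets (random_p < alpha, 10,000 draws by default); merge
the survivors via shared genes into the CRDC subnetwork.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from ._cox import CoxConvergenceError, CoxData
from .matrix import ExpressionMatrix
from .survival import check_survival

logger = logging.getLogger(__name__)


def module_score(graph: nx.Graph, nodes, lambda_: float = 0.44) -> float:
    """lambda * mean induced-edge weight + (1-lambda) * mean node weight."""
    nodes = list(nodes)
    if not nodes:
        raise ValueError("module must contain at least one node")
    if not 0.0 <= lambda_ <= 1.0:
        raise ValueError("lambda_ must lie in [0, 1]")
    sum_n = sum(graph.nodes[v]["weight"] for v in nodes)
    sub = graph.subgraph(nodes)
    n_e = sub.number_of_edges()
    sum_e = sum(d["weight"] for _, _, d in sub.edges(data=True))
    edge_term = sum_e / n_e if n_e else 0.0
    return lambda_ * edge_term + (1.0 - lambda_) * sum_n / len(nodes)


@dataclass
class Module:
    nodes: list  # sorted gene ids
    seed: str
    score: float
    cox_p: float | None = None
    random_p: float | None = None

    @property
    def genes(self) -> list:
        return self.nodes


def _eligible_neighbors(graph: nx.Graph, members: set, d: int) -> set:
    if d == 1:
        out = set()
        for v in members:
            out |= set(graph.adj[v])
        return out - members
    lengths = nx.multi_source_dijkstra_path_length(graph, members, cutoff=d, weight=None)
    return {v for v, dist in lengths.items() if v not in members and dist <= d}


def greedy_search(
    graph: nx.Graph, d: int = 1, growth_r: float = 0.1, lambda_: float = 0.44
) -> list[Module]:
    """Seeded greedy module growth from every node in the network.

    Each step evaluates all eligible neighbors, picks the one giving the
    highest new score (ties broken by lexicographically smallest gene id),
    and accepts it only if new - old > growth_r * old; growth stops at the
    first rejection.  The acceptance rule is applied verbatim even when
    the current score is negative.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("empty network")
    modules = []
    for seed in sorted(graph.nodes):
        members = {seed}
        sum_n = graph.nodes[seed]["weight"]
        sum_e, n_e = 0.0, 0
        score = (1.0 - lambda_) * sum_n
        while True:
            candidates = _eligible_neighbors(graph, members, d)
            if not candidates:
                break
            best, best_score, best_delta = None, -math.inf, None
            for v in sorted(candidates):
                new_e = sum(
                    graph.edges[v, u]["weight"] for u in graph.adj[v] if u in members
                )
                add_ne = sum(1 for u in graph.adj[v] if u in members)
                cand_sum_e, cand_n_e = sum_e + new_e, n_e + add_ne
                edge_term = cand_sum_e / cand_n_e if cand_n_e else 0.0
                cand = (lambda_ * edge_term
                        + (1.0 - lambda_) * (sum_n + graph.nodes[v]["weight"])
                        / (len(members) + 1))
                if cand > best_score:
                    best, best_score = v, cand
                    best_delta = (new_e, add_ne)
            if best is None or not best_score - score > growth_r * score:
                break
            members.add(best)
            sum_n += graph.nodes[best]["weight"]
            sum_e += best_delta[0]
            n_e += best_delta[1]
            score = best_score
        modules.append(Module(sorted(members), seed, score))
    return modules


def select_top(modules: list[Module], fraction: float = 0.10) -> list[Module]:
    """ceil(fraction * count) highest-score modules; cutoff ties retained."""
    if not modules:
        raise ValueError("no modules to select from")
    k = math.ceil(fraction * len(modules))
    scores = sorted((m.score for m in modules), reverse=True)
    cutoff = scores[k - 1]
    return [m for m in modules if m.score >= cutoff]


def permutation_filter(
    modules: list[Module],
    matrix: ExpressionMatrix,
    survival: pd.DataFrame,
    background,
    n_perm: int = 10_000,
    alpha: float = 0.01,
    rng: np.random.Generator | None = None,
    statistic: str = "lr",
) -> list[Module]:
    """Keep modules whose Cox significance beats random gene sets.

    For each module the observed p is a multivariate Cox likelihood-ratio
    p over the module genes' expression; ``random_p`` is the fraction of
    ``n_perm`` equally sized random draws from ``background`` whose p is
    strictly smaller.  Modules with random_p < alpha survive.  Random
    draws whose fit fails are redrawn (count logged).  Annotates cox_p and
    random_p on every input module.
    """
    if matrix.unit != "log2TPM":
        raise ValueError(f"expected log2TPM expression, got {matrix.unit}")
    survival = check_survival(survival)
    rng = np.random.default_rng() if rng is None else rng
    background = [g for g in background if g in matrix.genes]
    common = survival.index.intersection(matrix.samples)
    sub = survival.loc[common]
    data = CoxData(sub["time"], sub["event"])
    expr = matrix.values[common]  # genes x samples

    def fit_p(genes) -> float:
        X = expr.loc[list(genes)].to_numpy(float).T
        if statistic == "lr":
            return data.fit(X).lr_p
        return float(data.fit(X).p.min())

    # cache null p-values per module size: modules of equal size share one null
    null_cache: dict[int, np.ndarray] = {}

    def null_pvalues(k: int) -> np.ndarray:
        if k in null_cache:
            return null_cache[k]
        out = np.empty(n_perm)
        failures = 0
        i = 0
        while i < n_perm:
            genes = rng.choice(background, size=k, replace=False)
            try:
                out[i] = fit_p(genes)
                i += 1
            except (CoxConvergenceError, ValueError, np.linalg.LinAlgError):
                failures += 1
                if failures > 10 * n_perm:
                    raise RuntimeError("random Cox draws keep failing")
        if failures:
            logger.info("permutation_filter: %d failed random draws redrawn (k=%d)",
                        failures, k)
        null_cache[k] = np.sort(out)
        return null_cache[k]

    kept = []
    for mod in modules:
        genes = [g for g in mod.nodes if g in matrix.genes]
        if len(genes) < len(mod.nodes):
            logger.warning("module %s: %d genes lack expression", mod.seed,
                           len(mod.nodes) - len(genes))
        try:
            observed = fit_p(genes)
        except (CoxConvergenceError, ValueError, np.linalg.LinAlgError) as exc:
            logger.warning("module %s: observed Cox fit failed (%s); dropped",
                           mod.seed, exc)
            mod.cox_p, mod.random_p = None, None
            continue
        null = null_pvalues(len(genes))
        mod.cox_p = observed
        mod.random_p = float(np.searchsorted(null, observed, side="left")) / n_perm
        if mod.random_p < alpha:
            kept.append(mod)
    return kept


@dataclass
class CRDCSubnetwork:
    """Union of surviving modules merged via shared genes."""

    genes: list  # sorted union of member-module genes
    members: list = field(default_factory=list)  # surviving Module objects
    components: list = field(default_factory=list)  # list of gene lists
    subgraph: nx.Graph | None = None


def merge_modules(modules: list[Module], network: nx.Graph | None = None) -> CRDCSubnetwork:
    """Merge modules that share at least one gene; union all components.

    Builds the module-overlap graph, takes connected components, unions
    their node sets, and (when the source network is given) attaches the
    induced subgraph.  Idempotent and order-invariant.
    """
    if not modules:
        raise ValueError("no surviving modules to merge")
    overlap = nx.Graph()
    overlap.add_nodes_from(range(len(modules)))
    sets = [set(m.nodes) for m in modules]
    for i in range(len(modules)):
        for j in range(i + 1, len(modules)):
            if sets[i] & sets[j]:
                overlap.add_edge(i, j)
    components = []
    for comp in nx.connected_components(overlap):
        comp_genes = sorted(set().union(*(sets[i] for i in comp)))
        components.append(comp_genes)
    components.sort()
    genes = sorted(set().union(*map(set, components)))
    sub = network.subgraph(genes).copy() if network is not None else None
    return CRDCSubnetwork(genes, list(modules), components, sub)


def modules_table(modules: list[Module], kept: set[str] | None = None) -> pd.DataFrame:
    rows = [
        {
            "seed": m.seed,
            "n_genes": len(m.nodes),
            "genes": ",".join(m.nodes),
            "score": m.score,
            "cox_p": m.cox_p,
            "random_p": m.random_p,
            "kept": (m.seed in kept) if kept is not None else None,
        }
        for m in modules
    ]
    return pd.DataFrame(rows).set_index("seed")
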
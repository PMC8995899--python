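"""CeRNA pair identification and the double-weighted dysregulated network.

Within one CIN stratum, an mRNA–lncRNA pair is a ceRNA pair when (a) the
two genes share significantly more upstream miRNA regulators than chance
(upper-tail hypergeometric test, BH-corrected across all candidate pairs),
and (b) the pair is significantly positively co-expressed (Pearson r
strictly above a cutoff with BH-corrected correlation p below 0.05, the
correlation family being the hypergeometric survivors).

The dysregulated network is the union of pairs qualifying in either
stratum; a stratum where the pair failed identification contributes PCC 0.
Edge weight E compares the stratum correlations through the Fisher z
transform F(r) = atanh(r):

    z = (F(r_high) - F(r_low)) / sqrt(1/(n_high - 3) + 1/(n_low - 3))
    E = Phi^-1(1 - p_two(|z|))

and node weight N = Phi^-1(1 - p) with p the gene's univariate Cox
significance on disease-specific survival of untreated samples.  Inner
probabilities are clamped to [1e-16, 1 - 1e-16] so both weights stay
finite.  An alternative ``variant="printed"`` evaluates the denominator as
1/(n_high+3) + 1/(n_low+3) without the square root for exactness audits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from ._cox import CoxConvergenceError
from .matrix import ExpressionMatrix
from .survival import fit_univariate_cox, training_subset

logger = logging.getLogger(__name__)

P_CLAMP = 1e-16


def _clamp(p):
    return np.clip(p, P_CLAMP, 1.0 - P_CLAMP)


def shared_mirna_test(mirnas_of_mrna, mirnas_of_lncrna, background):
    """Upper-tail hypergeometric test for shared upstream miRNA regulation.

    Returns ``(r, M, K, N_bg, p)`` where r is the shared-regulator count,
    M and K the regulator counts of the mRNA and lncRNA, N_bg the
    background miRNA universe size, and p = P(X >= r) for X hypergeometric
    — i.e. 1 - sum_{i<r} C(K,i) C(N-K, M-i) / C(N, M).
    """
    a, b, bg = set(mirnas_of_mrna), set(mirnas_of_lncrna), set(background)
    if not bg:
        raise ValueError("background miRNA set is empty")
    if not a <= bg or not b <= bg:
        raise ValueError("target miRNA sets must be subsets of the background")
    r, M, K, N = len(a & b), len(a), len(b), len(bg)
    if M > N or K > N:
        raise ValueError("regulator counts exceed background size")
    p = float(stats.hypergeom.sf(r - 1, N, K, M))
    return r, M, K, N, p


def correlation_p(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided t-test p-value for a Pearson correlation with n-2 df."""
    r = np.clip(np.asarray(r, float), -1 + 1e-15, 1 - 1e-15)
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return 2.0 * stats.t.sf(np.abs(t), df=n - 2)


def fisher_z(r) -> np.ndarray:
    """Fisher variance-stabilizing transform F(r) = 0.5 ln((1+r)/(1-r))."""
    r = np.asarray(r, float)
    if np.any(np.abs(r) >= 1):
        raise ValueError("Fisher transform diverges at |r| = 1")
    return np.arctanh(r)


def edge_weight(r_high, r_low, n_high: int, n_low: int, variant: str = "sqrt"):
    """Dysregulation edge weight E from the stratum-correlation difference.

    ``variant="sqrt"`` (default) uses the standard Fisher comparison
    denominator sqrt(1/(n_high-3) + 1/(n_low-3)); ``variant="printed"``
    uses 1/(n_high+3) + 1/(n_low+3) with no square root.  Returns
    ``(E, p_two, z)`` arrays (scalars in, scalars out).
    """
    scalar = np.isscalar(r_high) and np.isscalar(r_low)
    diff = fisher_z(r_high) - fisher_z(r_low)
    if variant == "sqrt":
        if min(n_high, n_low) <= 3:
            raise ValueError("need more than 3 samples per stratum")
        denom = np.sqrt(1.0 / (n_high - 3) + 1.0 / (n_low - 3))
    elif variant == "printed":
        denom = 1.0 / (n_high + 3) + 1.0 / (n_low + 3)
    else:
        raise ValueError(f"unknown edge-weight variant {variant!r}")
    z = np.abs(diff) / denom
    p_two = _clamp(2.0 * stats.norm.sf(z))
    # E = Phi^-1(1 - p_two), evaluated in whichever tail keeps full precision:
    # 1 - p_two = erf(z / sqrt(2)) exactly, avoiding cancellation near z = 0
    comp = _clamp(special.erf(z / np.sqrt(2.0)))
    e = np.where(p_two < 0.5, -stats.norm.ppf(p_two), stats.norm.ppf(comp))
    if scalar:
        return float(e), float(p_two), float(z)
    return e, p_two, z


def node_weight(cox_p) -> float:
    """Node weight N = Phi^-1(1 - p); may be negative for p > 0.5."""
    p = np.asarray(cox_p, float)
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("Cox p-value must lie in (0, 1]")
    out = stats.norm.ppf(1.0 - _clamp(p))
    return float(out) if out.ndim == 0 else out


def classify_dysregulation(r_high: float, r_low: float) -> str:
    """"gain" when correlation strengthens in CIN-High, "loss" when it
    weakens, "undefined" on exact ties (excluded from gain/loss tallies)."""
    if r_high > r_low:
        return "gain"
    if r_high < r_low:
        return "loss"
    return "undefined"


def identify_cerna_pairs(
    matrix: ExpressionMatrix,
    interactions: pd.DataFrame,
    deg_mrnas,
    deg_lncrnas,
    fdr_cut: float = 0.05,
    pcc_cut: float = 0.1,
) -> pd.DataFrame:
    """CeRNA pairs within one stratum's expression matrix.

    ``matrix`` must already be restricted to the stratum's samples
    (log2TPM).  Candidates are all DE-mRNA x DE-lncRNA pairs whose genes
    have at least one known regulator.  Returns the qualifying pairs with
    their shared-regulator counts, hypergeometric statistics and PCCs.
    """
    if matrix.unit != "log2TPM":
        raise ValueError(f"expected log2TPM input, got {matrix.unit}")
    n = matrix.values.shape[1]
    if n < 10:
        raise ValueError(f"stratum has only {n} samples (need >= 10)")
    deg_mrnas = [g for g in deg_mrnas if g in matrix.genes]
    deg_lncrnas = [g for g in deg_lncrnas if g in matrix.genes]
    if not deg_mrnas or not deg_lncrnas:
        raise ValueError("empty DEG universe for mRNAs or lncRNAs")

    background = pd.Index(interactions["mirna"].unique())
    n_bg = len(background)
    mir_pos = {m: i for i, m in enumerate(background)}

    def incidence(genes):
        genes = [g for g in genes if g in targets]
        mat = np.zeros((n_bg, len(genes)), dtype=np.int32)
        for j, g in enumerate(genes):
            rows = [mir_pos[m] for m in targets[g]]
            mat[rows, j] = 1
        return genes, mat

    targets = interactions.groupby("target")["mirna"].agg(list).to_dict()
    mr_genes, A_m = incidence(deg_mrnas)
    ln_genes, A_l = incidence(deg_lncrnas)
    if not mr_genes or not ln_genes:
        raise ValueError("no DEG with known miRNA regulators")

    shared = A_m.T @ A_l                 # (n_mrna, n_lnc) shared counts
    M = A_m.sum(axis=0)[:, None]         # regulators per mRNA
    K = A_l.sum(axis=0)[None, :]         # regulators per lncRNA
    hyper_p = stats.hypergeom.sf(shared - 1, n_bg, K, M)
    hyper_fdr = multipletests(hyper_p.ravel(), method="fdr_bh")[1].reshape(hyper_p.shape)

    mi, li = np.nonzero(hyper_fdr < fdr_cut)
    if mi.size == 0:
        return _empty_pairs()

    # Pearson correlations for the hypergeometric survivors only
    X = matrix.values.loc[[mr_genes[i] for i in mi]].to_numpy(float)
    Y = matrix.values.loc[[ln_genes[j] for j in li]].to_numpy(float)
    Xc = X - X.mean(axis=1, keepdims=True)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    denom = np.sqrt((Xc * Xc).sum(axis=1) * (Yc * Yc).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        pcc = np.where(denom > 0, (Xc * Yc).sum(axis=1) / denom, 0.0)
    pcc_p = correlation_p(pcc, n)
    pcc_fdr = multipletests(pcc_p, method="fdr_bh")[1]

    table = pd.DataFrame(
        {
            "mrna": [mr_genes[i] for i in mi],
            "lncrna": [ln_genes[j] for j in li],
            "shared": shared[mi, li],
            "M": M[mi, 0],
            "K": K[0, li],
            "n_background": n_bg,
            "hyper_p": hyper_p[mi, li],
            "hyper_fdr": hyper_fdr[mi, li],
            "pcc": pcc,
            "pcc_p": pcc_p,
            "pcc_fdr": pcc_fdr,
            "n_samples": n,
        }
    )
    qualified = table[(table["pcc"] > pcc_cut) & (table["pcc_fdr"] < fdr_cut)]
    return qualified.reset_index(drop=True)


def _empty_pairs() -> pd.DataFrame:
    cols = ["mrna", "lncrna", "shared", "M", "K", "n_background", "hyper_p",
            "hyper_fdr", "pcc", "pcc_p", "pcc_fdr", "n_samples"]
    return pd.DataFrame(columns=cols)


@dataclass
class NetworkSummary:
    n_nodes: int
    n_edges: int
    n_mrnas: int
    n_lncrnas: int
    n_gain: int
    n_loss: int
    powerlaw_r2: float


def degree_powerlaw_r2(graph: nx.Graph) -> float:
    """R^2 of the log-log least-squares fit of the degree distribution."""
    degrees = np.array([d for _, d in graph.degree()])
    k, cnt = np.unique(degrees[degrees > 0], return_counts=True)
    if len(k) < 3:
        return float("nan")
    x, y = np.log10(k), np.log10(cnt / cnt.sum())
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = ((y - y.mean()) ** 2).sum()
    return float(1.0 - (resid**2).sum() / ss_tot) if ss_tot > 0 else float("nan")


def build_network(
    pairs_high: pd.DataFrame,
    pairs_low: pd.DataFrame,
    survival: pd.DataFrame,
    matrix: ExpressionMatrix,
    n_high: int | None = None,
    n_low: int | None = None,
    variant: str = "sqrt",
) -> nx.Graph:
    """Assemble the double-weighted dysregulated ceRNA network.

    Edges are the union of pairs qualifying in either stratum, with the
    non-qualifying stratum's PCC set to 0.  Node weights come from
    univariate Cox fits on the untreated DSS subset of ``survival`` using
    ``matrix`` (log2TPM) expression.  Node/edge attributes carry every
    statistic; ``graph.graph["summary"]`` holds counts and the power-law
    fit of the degree distribution.
    """
    if pairs_high.empty and pairs_low.empty:
        raise ValueError("no qualifying ceRNA pairs in either stratum")
    n_high = int(pairs_high["n_samples"].iloc[0]) if n_high is None and not pairs_high.empty else n_high
    n_low = int(pairs_low["n_samples"].iloc[0]) if n_low is None and not pairs_low.empty else n_low
    if n_high is None or n_low is None:
        raise ValueError("stratum sample sizes are required when a stratum has no pairs")

    hi = pairs_high.set_index(["mrna", "lncrna"])
    lo = pairs_low.set_index(["mrna", "lncrna"])
    union = hi.index.union(lo.index)

    train = training_subset(survival)
    graph = nx.Graph()
    node_cache: dict[str, tuple[float, float]] = {}

    def ensure_node(gene: str, biotype: str) -> None:
        if gene in node_cache:
            return
        try:
            fit = fit_univariate_cox(matrix.values.loc[gene, train.index], train)
            p = float(fit.p[0])
        except (CoxConvergenceError, ValueError) as exc:
            logger.warning("node weight: Cox failed for %s (%s); p set to 1", gene, exc)
            p = 1.0
        node_cache[gene] = (node_weight(p), p)
        graph.add_node(gene, weight=node_cache[gene][0], cox_p=p, biotype=biotype)

    for mrna, lnc in union:
        r_hi = float(hi.loc[(mrna, lnc), "pcc"]) if (mrna, lnc) in hi.index else 0.0
        r_lo = float(lo.loc[(mrna, lnc), "pcc"]) if (mrna, lnc) in lo.index else 0.0
        src = hi.loc[(mrna, lnc)] if (mrna, lnc) in hi.index else lo.loc[(mrna, lnc)]
        e, p_two, z = edge_weight(r_hi, r_lo, n_high, n_low, variant=variant)
        ensure_node(mrna, "mRNA")
        ensure_node(lnc, "lncRNA")
        graph.add_edge(
            mrna, lnc,
            weight=e, p_two=p_two, z=z,
            pcc_high=r_hi, pcc_low=r_lo,
            dysreg_type=classify_dysregulation(r_hi, r_lo),
            shared=int(src["shared"]), M=int(src["M"]), K=int(src["K"]),
            hyper_fdr=float(src["hyper_fdr"]),
        )

    types = [d["dysreg_type"] for _, _, d in graph.edges(data=True)]
    biotypes = nx.get_node_attributes(graph, "biotype")
    graph.graph["summary"] = NetworkSummary(
        n_nodes=graph.number_of_nodes(),
        n_edges=graph.number_of_edges(),
        n_mrnas=sum(1 for b in biotypes.values() if b == "mRNA"),
        n_lncrnas=sum(1 for b in biotypes.values() if b == "lncRNA"),
        n_gain=types.count("gain"),
        n_loss=types.count("loss"),
        powerlaw_r2=degree_powerlaw_r2(graph),
    )
    graph.graph["n_high"] = n_high
    graph.graph["n_low"] = n_low
    graph.graph["variant"] = variant
    return graph


def network_tables(graph: nx.Graph) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(node table, edge table) views of the network for TSV export."""
    nodes = pd.DataFrame(
        [
            {"gene": g, "biotype": d["biotype"], "node_weight": d["weight"],
             "cox_p": d["cox_p"], "degree": graph.degree(g)}
            for g, d in graph.nodes(data=True)
        ]
    ).set_index("gene")
    edges = pd.DataFrame(
        [
            {"mrna": u if d2["biotype_u"] == "mRNA" else v,
             "lncrna": v if d2["biotype_u"] == "mRNA" else u,
             **{k: d[k] for k in ("shared", "M", "K", "hyper_fdr", "pcc_high",
                                   "pcc_low", "dysreg_type", "weight")}}
            for u, v, d in graph.edges(data=True)
            for d2 in [{"biotype_u": graph.nodes[u]["biotype"]}]
        ]
    )
    return nodes, edges
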
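"""Synthetic cohorts with planted ground truth for every pipeline stage.

The generator emulates the statistical structure the downstream stages
assume, so each stage has a recoverable answer:

* tumor / adjacent strata, with a CIN-like gene set expressed higher in
  tumors (and higher again in CIN-High tumors, so a CIN-score split can
  recover the strata);
* CIN-High / CIN-Low tumor strata carrying planted gain / loss
  differentially correlated mRNA–lncRNA pairs (Gaussian copula in log2
  space), plus an optional planted *connected* module — an equicorrelated
  block of mRNAs and lncRNAs — for dense-module recovery;
* miRNA–target bipartite tables in which each planted pair shares exactly
  ``shared_mirna_overlap`` common regulators while background genes draw
  regulators independently;
* proportional-hazards survival with planted prognostic genes and
  independent uniform censoring, plus an outcome-independent postoperative
  treatment flag.

Everything is driven by one root seed; each operation uses its own child
stream so outputs are byte-identical across runs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize

from .matrix import TPM_TOTAL, ExpressionMatrix


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class SimulationConfig:
    """Cohort design for the synthetic generator.

    Counts are gene/sample numbers; correlation targets are Pearson
    coefficients in log2 space; ``cin_shift`` and ``planted_de_shift`` are
    log2-expression offsets; ``beta_range`` is the interval planted log
    hazard ratios are drawn from (per standardized log2 expression unit).
    """

    n_genes: int = 1000          # protein-coding genes
    n_lncrnas: int = 120
    n_mirnas: int = 150
    n_tumor: int = 600
    n_adjacent: int = 60
    n_cin_high: int = 300
    n_cin_low: int = 300
    n_planted_gain: int = 25
    n_planted_loss: int = 25
    r_high_gain: float = 0.6
    r_low_gain: float = 0.2
    r_high_loss: float = 0.2
    r_low_loss: float = 0.6
    n_cin_like_genes: int = 70
    cin_shift: float = 1.0       # tumor vs adjacent, log2 units
    cin_shift_within: float = 1.0  # CIN-High vs CIN-Low tumors, log2 units
    n_prognostic: int = 6
    beta_range: tuple[float, float] = (0.7, 0.7)
    censor_rate: float = 0.3
    shared_mirna_overlap: int = 5
    background_mirna_per_gene: float = 3.0
    # planted connected module: an equicorrelated mRNA/lncRNA block whose
    # bipartite pairs all carry the gain (or loss) correlation targets
    n_module_mrnas: int = 3
    n_module_lncrnas: int = 3
    module_type: str = "gain"
    planted_de_shift: float = 2.0  # tumor vs adjacent offset of planted genes
    treatment_rate: float = 0.3
    baseline_median_days: float = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_genes": self.n_genes, "n_lncrnas": self.n_lncrnas,
            "n_mirnas": self.n_mirnas, "n_tumor": self.n_tumor,
            "n_adjacent": self.n_adjacent, "n_cin_high": self.n_cin_high,
            "n_cin_low": self.n_cin_low,
        }
        for name, v in counts.items():
            if v <= 0:
                raise ConfigError(f"{name} must be positive, got {v}")
        if self.n_cin_high + self.n_cin_low != self.n_tumor:
            raise ConfigError("n_cin_high + n_cin_low must equal n_tumor")
        for name in ("r_high_gain", "r_low_gain", "r_high_loss", "r_low_loss"):
            if not abs(getattr(self, name)) < 1:
                raise ConfigError(f"{name} must satisfy |r| < 1")
        if self.r_high_gain <= self.r_low_gain:
            raise ConfigError("gain pairs require r_high_gain > r_low_gain")
        if self.r_high_loss >= self.r_low_loss:
            raise ConfigError("loss pairs require r_high_loss < r_low_loss")
        if not 0.0 <= self.censor_rate < 1.0:
            raise ConfigError("censor_rate must be in [0, 1)")
        if self.shared_mirna_overlap > self.n_mirnas:
            raise ConfigError("shared_mirna_overlap cannot exceed n_mirnas")
        if self.module_type not in ("gain", "loss"):
            raise ConfigError("module_type must be 'gain' or 'loss'")
        n_planted_mrnas = (self.n_planted_gain + self.n_planted_loss
                           + self.n_module_mrnas)
        n_planted_lncs = (self.n_planted_gain + self.n_planted_loss
                          + self.n_module_lncrnas)
        if n_planted_mrnas > self.n_genes or n_planted_lncs > self.n_lncrnas:
            raise ConfigError("more planted genes than genes in the cohort")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationConfig":
        d = json.loads(Path(path).read_text())
        if "beta_range" in d:
            d["beta_range"] = tuple(d["beta_range"])
        return cls(**d)


@dataclass
class GroundTruth:
    """What was planted, keyed by generated gene/sample ids."""

    planted_pairs: list = field(default_factory=list)  # (mrna, lncrna, type)
    planted_module: list = field(default_factory=list)  # gene ids
    planted_prognostic: dict = field(default_factory=dict)  # gene -> beta
    cin_like_genes: list = field(default_factory=list)
    stratum_labels: dict = field(default_factory=dict)  # sample -> label

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        d["planted_pairs"] = [tuple(p) for p in d["planted_pairs"]]
        return cls(**d)


# ---------------------------------------------------------------- ids

def _mrna_ids(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(n)]


def _lncrna_ids(n: int) -> list[str]:
    return [f"LNC{i:04d}" for i in range(n)]


def _mirna_ids(n: int) -> list[str]:
    return [f"miR-{i:04d}" for i in range(n)]


def _child_rng(seed: int, stream: str) -> np.random.Generator:
    """Stable per-stage RNG stream derived from the root seed."""
    name = int.from_bytes(stream.encode(), "little") % (2**32)
    return np.random.default_rng(np.random.SeedSequence((seed, name)))


def plan_truth(config: SimulationConfig, rng: np.random.Generator) -> GroundTruth:
    """Choose planted pair/module/prognostic/CIN-like gene identities."""
    mrnas = _mrna_ids(config.n_genes)
    lncs = _lncrna_ids(config.n_lncrnas)
    truth = GroundTruth()

    next_m, next_l = 0, 0
    for k in range(config.n_planted_gain):
        truth.planted_pairs.append((mrnas[next_m], lncs[next_l], "gain"))
        next_m += 1
        next_l += 1
    for k in range(config.n_planted_loss):
        truth.planted_pairs.append((mrnas[next_m], lncs[next_l], "loss"))
        next_m += 1
        next_l += 1
    mod_m = mrnas[next_m:next_m + config.n_module_mrnas]
    mod_l = lncs[next_l:next_l + config.n_module_lncrnas]
    truth.planted_module = mod_m + mod_l
    next_m += len(mod_m)
    next_l += len(mod_l)

    # CIN-like genes: drawn from coding genes not used for planted pairs
    pool = mrnas[next_m:]
    if config.n_cin_like_genes > len(pool):
        raise ConfigError("not enough free genes for the CIN-like signature")
    truth.cin_like_genes = list(rng.choice(pool, config.n_cin_like_genes, replace=False))

    # prognostic genes: module genes first (so the planted module is the
    # prognostic unit), then random non-planted genes
    betas = rng.uniform(config.beta_range[0], config.beta_range[1],
                        size=config.n_prognostic)
    prognostic = list(truth.planted_module[:config.n_prognostic])
    if len(prognostic) < config.n_prognostic:
        spare = [g for g in pool if g not in set(truth.cin_like_genes)]
        extra = rng.choice(spare, config.n_prognostic - len(prognostic), replace=False)
        prognostic.extend(extra)
    truth.planted_prognostic = {g: float(b) for g, b in zip(prognostic, betas)}

    # sample strata
    tumors = [f"T{i:04d}" for i in range(config.n_tumor)]
    adjacents = [f"A{i:04d}" for i in range(config.n_adjacent)]
    for i, s in enumerate(tumors):
        truth.stratum_labels[s] = "CIN-High" if i < config.n_cin_high else "CIN-Low"
    for s in adjacents:
        truth.stratum_labels[s] = "adjacent"
    return truth


# ---------------------------------------------------------------- interactions

def generate_interactions(
    config: SimulationConfig, truth: GroundTruth, rng: np.random.Generator
) -> pd.DataFrame:
    """Bipartite miRNA -> target table (columns mirna, target, target_kind).

    Planted pairs share *exactly* ``shared_mirna_overlap`` regulators (their
    background regulators are drawn from disjoint remainders of the miRNA
    pool); planted-module genes share one common regulator pool; all other
    genes receive ~Poisson(background_mirna_per_gene) regulators sampled
    independently.
    """
    if config.shared_mirna_overlap > config.n_mirnas:
        raise ConfigError("shared_mirna_overlap cannot exceed n_mirnas")
    mirnas = np.array(_mirna_ids(config.n_mirnas))
    mrnas = _mrna_ids(config.n_genes)
    lncs = _lncrna_ids(config.n_lncrnas)
    kind = {g: "mRNA" for g in mrnas}
    kind.update({g: "lncRNA" for g in lncs})

    regulators: dict[str, set[str]] = {g: set() for g in mrnas + lncs}
    k_over = config.shared_mirna_overlap

    def background(gene: str, forbidden: set[str]) -> set[str]:
        lam = config.background_mirna_per_gene
        n_bg = min(int(rng.poisson(lam)), config.n_mirnas - len(forbidden))
        pool = np.array(sorted(set(mirnas) - forbidden))
        if n_bg <= 0 or pool.size == 0:
            return set()
        return set(rng.choice(pool, size=min(n_bg, pool.size), replace=False))

    planted_genes: set[str] = set()
    for m, l, _type in truth.planted_pairs:
        shared = set(rng.choice(mirnas, size=k_over, replace=False))
        bg_m = background(m, shared)
        bg_l = background(l, shared | bg_m)  # disjoint => overlap stays exact
        regulators[m] = shared | bg_m
        regulators[l] = shared | bg_l
        planted_genes.update((m, l))

    if truth.planted_module:
        shared = set(rng.choice(mirnas, size=k_over, replace=False))
        mod_m = [g for g in truth.planted_module if kind[g] == "mRNA"]
        mod_l = [g for g in truth.planted_module if kind[g] == "lncRNA"]
        used: set[str] = set(shared)
        for g in mod_m + mod_l:
            bg = background(g, used)
            used |= bg  # keep module-pair overlap exactly the shared pool
            regulators[g] = shared | bg
            planted_genes.add(g)

    for g in mrnas + lncs:
        if g not in planted_genes:
            regulators[g] = background(g, set())

    rows = [
        (mir, g, kind[g])
        for g in mrnas + lncs
        for mir in sorted(regulators[g])
    ]
    return pd.DataFrame(rows, columns=["mirna", "target", "target_kind"])


# ---------------------------------------------------------------- expression

def _equicorrelated(rng, n_samples: int, k: int, r: float) -> np.ndarray:
    """k standard-normal variables with pairwise correlation r (one factor)."""
    if not -1.0 / max(k - 1, 1) < r < 1.0:
        raise ConfigError(f"equicorrelation target r={r} infeasible for k={k}")
    if r <= 0:
        cov = np.full((k, k), r) + (1 - r) * np.eye(k)
        chol = np.linalg.cholesky(cov)
        return rng.standard_normal((n_samples, k)) @ chol.T
    common = rng.standard_normal((n_samples, 1))
    noise = rng.standard_normal((n_samples, k))
    return np.sqrt(r) * common + np.sqrt(1 - r) * noise


def generate_expression(
    config: SimulationConfig, truth: GroundTruth, rng: np.random.Generator
) -> ExpressionMatrix:
    """Draw log2-space expression, then emit a TPM matrix.

    Baseline gene means are uniform in log2 [2, 10] with unit noise SD
    (a log-normal TPM skew after exponentiation).  Planted pairs/modules
    are drawn from correlated Gaussians within each CIN stratum; CIN-like
    genes carry the tumor and CIN-High mean offsets; planted ceRNA genes
    carry the tumor DE offset; all other genes are mutually independent.
    The matrix is exponentiated and column-renormalized to TPM.
    """
    for name in ("r_high_gain", "r_low_gain", "r_high_loss", "r_low_loss"):
        if not abs(getattr(config, name)) < 1:
            raise ConfigError(f"{name} must satisfy |r| < 1")
    mrnas = _mrna_ids(config.n_genes)
    lncs = _lncrna_ids(config.n_lncrnas)
    genes = mrnas + lncs
    gidx = {g: i for i, g in enumerate(genes)}
    samples = [s for s in truth.stratum_labels]
    strata = pd.Series({s: truth.stratum_labels[s] for s in samples})
    high = strata.index[strata == "CIN-High"]
    low = strata.index[strata == "CIN-Low"]
    adj = strata.index[strata == "adjacent"]
    sidx = {s: j for j, s in enumerate(samples)}
    cols = {name: np.array([sidx[s] for s in group])
            for name, group in (("high", high), ("low", low), ("adj", adj))}

    n_g, n_s = len(genes), len(samples)
    mu = rng.uniform(2.0, 10.0, size=n_g)
    z = rng.standard_normal((n_g, n_s))

    # planted pairs: overwrite the two genes' z with correlated draws per stratum
    def plant_block(gene_rows: list[int], r_high: float, r_low: float) -> None:
        k = len(gene_rows)
        zh = _equicorrelated(rng, len(cols["high"]), k, r_high)
        zl = _equicorrelated(rng, len(cols["low"]), k, r_low)
        rows = np.array(gene_rows)
        z[np.ix_(rows, cols["high"])] = zh.T
        z[np.ix_(rows, cols["low"])] = zl.T

    for m, l, typ in truth.planted_pairs:
        if typ == "gain":
            plant_block([gidx[m], gidx[l]], config.r_high_gain, config.r_low_gain)
        else:
            plant_block([gidx[m], gidx[l]], config.r_high_loss, config.r_low_loss)
    if truth.planted_module:
        rows = [gidx[g] for g in truth.planted_module]
        if config.module_type == "gain":
            plant_block(rows, config.r_high_gain, config.r_low_gain)
        else:
            plant_block(rows, config.r_high_loss, config.r_low_loss)

    log2 = mu[:, None] + z

    tumor_cols = np.concatenate([cols["high"], cols["low"]])
    cin_rows = np.array([gidx[g] for g in truth.cin_like_genes], dtype=int)
    if cin_rows.size:
        log2[np.ix_(cin_rows, tumor_cols)] += config.cin_shift
        log2[np.ix_(cin_rows, cols["high"])] += config.cin_shift_within

    planted_genes = sorted(
        {g for m, l, _ in truth.planted_pairs for g in (m, l)}
        | set(truth.planted_module)
    )
    if planted_genes:
        pl_rows = np.array([gidx[g] for g in planted_genes])
        log2[np.ix_(pl_rows, tumor_cols)] += config.planted_de_shift

    raw = np.exp2(log2)
    tpm = raw / raw.sum(axis=0, keepdims=True) * TPM_TOTAL

    gene_meta = pd.DataFrame(
        {
            "biotype": ["protein_coding"] * len(mrnas) + ["lincRNA"] * len(lncs),
            "length": np.concatenate(
                [
                    rng.integers(500, 5001, size=len(mrnas)),
                    rng.integers(300, 3001, size=len(lncs)),
                ]
            ),
        },
        index=pd.Index(genes, name="gene"),
    )
    sample_meta = pd.DataFrame(
        {
            "group": np.where(strata == "adjacent", "adjacent", "tumor"),
            "cin_stratum": strata.where(strata != "adjacent", other=pd.NA),
        },
        index=pd.Index(samples, name="sample"),
    )
    values = pd.DataFrame(tpm, index=gene_meta.index, columns=sample_meta.index)
    return ExpressionMatrix(values, "TPM", gene_meta, sample_meta)


# ---------------------------------------------------------------- survival

def generate_survival(
    config: SimulationConfig,
    truth: GroundTruth,
    expression: ExpressionMatrix,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Exponential proportional-hazards event times for tumor samples.

    The linear predictor is sum_g beta_g * standardized log2(TPM+1) of the
    planted prognostic genes; the baseline rate is set so the baseline
    median time equals ``baseline_median_days``.  Censoring times are
    uniform on (0, c) with c calibrated so the expected censored fraction
    equals ``censor_rate``; the treatment flag is an independent Bernoulli.
    """
    if not 0.0 <= config.censor_rate < 1.0:
        raise ConfigError("censor_rate must be in [0, 1)")
    missing = [g for g in truth.planted_prognostic if g not in expression.genes]
    if missing:
        raise ConfigError(f"prognostic gene(s) missing from expression: {missing}")
    tumor = [s for s, lab in truth.stratum_labels.items() if lab != "adjacent"]
    eta = np.zeros(len(tumor))
    for g, beta in truth.planted_prognostic.items():
        x = np.log2(expression.values.loc[g, tumor].to_numpy(float) + 1.0)
        sd = x.std()
        if sd > 0:
            eta += beta * (x - x.mean()) / sd
    lam0 = np.log(2.0) / config.baseline_median_days
    t_event = rng.exponential(1.0, size=len(tumor)) / (lam0 * np.exp(eta))

    if config.censor_rate == 0.0:
        time, event = t_event, np.ones(len(tumor), dtype=bool)
    else:
        # P(C < t) for C ~ U(0,c) is min(t,c)/c; calibrate c so the expected
        # censored fraction over the drawn event times hits censor_rate
        def expected(c: float) -> float:
            return float(np.mean(np.minimum(t_event, c) / c))

        lo, hi = np.min(t_event) * 1e-3, np.max(t_event) * 1e3
        c = optimize.brentq(lambda c: expected(c) - config.censor_rate, lo, hi)
        t_cens = rng.uniform(0.0, c, size=len(tumor))
        event = t_event <= t_cens
        time = np.where(event, t_event, t_cens)

    treatment = rng.random(len(tumor)) < config.treatment_rate
    return pd.DataFrame(
        {
            "time": np.maximum(time, 1e-6),
            "event": event,
            "endpoint": "DSS",
            "treatment": treatment,
            "stratum": [truth.stratum_labels[s] for s in tumor],
        },
        index=pd.Index(tumor, name="sample"),
    )


# ---------------------------------------------------------------- cohort

@dataclass
class SyntheticCohort:
    config: SimulationConfig
    truth: GroundTruth
    expression: ExpressionMatrix  # TPM
    interactions: pd.DataFrame
    survival: pd.DataFrame

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.config.to_json(outdir / "config.json")
        self.truth.to_json(outdir / "ground_truth.json")
        self.expression.to_tsv(outdir / "expression_tpm.tsv")
        self.expression.gene_meta.to_csv(outdir / "gene_meta.tsv", sep="\t")
        self.expression.sample_meta.to_csv(outdir / "sample_meta.tsv", sep="\t")
        self.interactions.to_csv(outdir / "interactions.tsv", sep="\t", index=False)
        self.survival.to_csv(outdir / "clinical.tsv", sep="\t")
        with open(outdir / "cin_like_genes.gmt", "w") as fh:
            fh.write("CIN_LIKE\tsynthetic CIN signature\t"
                     + "\t".join(self.truth.cin_like_genes) + "\n")


def simulate_cohort(config: SimulationConfig, seed: int | None = None) -> SyntheticCohort:
    """Run all three generators from per-stage child streams of one seed."""
    seed = config.seed if seed is None else seed
    truth = plan_truth(config, _child_rng(seed, "plan"))
    interactions = generate_interactions(config, truth, _child_rng(seed, "interactions"))
    expression = generate_expression(config, truth, _child_rng(seed, "expression"))
    survival_tbl = generate_survival(config, truth, expression, _child_rng(seed, "survival"))
    return SyntheticCohort(config, truth, expression, interactions, survival_tbl)
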
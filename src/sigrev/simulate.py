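"""Synthetic data generators for every pipeline input.

Each generator is a pure function of its parameters and seed and returns,
alongside the data, a :class:`SimTruth` recording the planted structure so
downstream recovery can be measured: differentially expressed genes in
two-group designs, signature-reversing/mimicking drugs in a ranked profile
library, signature-positive tumors in cohorts, the hazard ratio in survival
tables, and block memberships in planted-partition graphs.

Noise models: independent Gaussian on the log2 scale for array-like
matrices; negative binomial counts with log-normal gene-wise dispersion for
sequencing-like matrices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .connectivity import RankedProfile
from .diffexp import ExpressionMatrix, GeneSignature
from .exceptions import InvalidConfigError, MissingGeneError

__all__ = [
    "SimConfig",
    "SimTruth",
    "gen_two_group_matrix",
    "gen_count_matrix",
    "gen_drug_library",
    "gen_signature_cohort",
    "gen_survival",
    "gen_planted_graph",
    "graph_to_edge_list",
]


@dataclass
class SimConfig:
    """Parameters of a two-group expression simulation.

    log2_effect is the mean |log2 fold change| planted into DE genes;
    noise_sd the per-gene Gaussian standard deviation on the log2 scale;
    baseline_mean the grand mean log2 intensity.
    """

    n_genes: int = 2000
    n_samples_per_group: int = 3
    de_fraction: float = 0.05
    log2_effect: float = 2.0
    noise_sd: float = 0.5
    baseline_mean: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_samples_per_group < 1:
            raise InvalidConfigError("dimensions must be positive")
        if not 0 <= self.de_fraction <= 1:
            raise InvalidConfigError("de_fraction must lie in [0, 1]")
        if self.log2_effect < 0 or self.noise_sd < 0:
            raise InvalidConfigError("effect size and noise sd must be non-negative")
        if self.de_fraction > 0 and self.de_fraction * self.n_genes < 1:
            raise InvalidConfigError("de_fraction*n_genes must be >= 1 when DE requested")


@dataclass
class SimTruth:
    """Ground truth planted by a generator."""

    de_up: set = field(default_factory=set)
    de_down: set = field(default_factory=set)
    reverser_drugs: set = field(default_factory=set)
    mimic_drugs: set = field(default_factory=set)
    positive_samples: set = field(default_factory=set)
    hazard_ratio: float = 1.0
    communities: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.de_up & self.de_down:
            raise InvalidConfigError("planted up and down genes overlap")
        if self.reverser_drugs & self.mimic_drugs:
            raise InvalidConfigError("a drug cannot both reverse and mimic")


def _gene_ids(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(n)]


# ---------------------------------------------------------------------------
# two-group expression
# ---------------------------------------------------------------------------

def gen_two_group_matrix(cfg: SimConfig) -> tuple[ExpressionMatrix, SimTruth]:
    """Case/control log2 matrix with planted DE genes.

    Planted up genes have a case-minus-control mean difference of exactly
    +log2_effect (down genes -log2_effect); all other genes 0.  Gene
    baselines vary around baseline_mean so the noise filter has something
    to remove at realistic settings.
    """
    rng = np.random.default_rng(cfg.seed)
    genes = _gene_ids(cfg.n_genes)
    n = cfg.n_samples_per_group
    samples = [f"case_{i}" for i in range(n)] + [f"ctrl_{i}" for i in range(n)]
    groups = pd.Series(["case"] * n + ["control"] * n, index=samples)

    n_de = int(round(cfg.de_fraction * cfg.n_genes))
    de_idx = rng.choice(cfg.n_genes, size=n_de, replace=False)
    up_idx, down_idx = de_idx[: n_de // 2 + n_de % 2], de_idx[n_de // 2 + n_de % 2:]

    baseline = cfg.baseline_mean + rng.normal(0.0, 1.0, size=cfg.n_genes)
    effect = np.zeros(cfg.n_genes)
    effect[up_idx] = cfg.log2_effect
    effect[down_idx] = -cfg.log2_effect

    x = np.tile(baseline[:, None], (1, 2 * n)) + rng.normal(
        0.0, cfg.noise_sd, size=(cfg.n_genes, 2 * n))
    x[:, :n] += effect[:, None]

    values = pd.DataFrame(x, index=genes, columns=samples)
    truth = SimTruth(de_up={genes[i] for i in up_idx},
                     de_down={genes[i] for i in down_idx})
    return ExpressionMatrix(values, groups, "log2"), truth


def gen_count_matrix(cfg: SimConfig, mean_count: float = 200.0) -> tuple[ExpressionMatrix, SimTruth]:
    """Negative-binomial count matrix with the same planted DE layout.

    Gene-wise dispersions are drawn from a log-normal (median 0.1), the
    standard overdispersion model for bulk RNA-seq counts.
    """
    rng = np.random.default_rng(cfg.seed)
    genes = _gene_ids(cfg.n_genes)
    n = cfg.n_samples_per_group
    samples = [f"case_{i}" for i in range(n)] + [f"ctrl_{i}" for i in range(n)]
    groups = pd.Series(["case"] * n + ["control"] * n, index=samples)

    n_de = int(round(cfg.de_fraction * cfg.n_genes))
    de_idx = rng.choice(cfg.n_genes, size=n_de, replace=False)
    up_idx, down_idx = de_idx[: n_de // 2 + n_de % 2], de_idx[n_de // 2 + n_de % 2:]

    base_mu = mean_count * 2.0 ** rng.normal(0.0, 1.5, size=cfg.n_genes)
    fold = np.ones(cfg.n_genes)
    fold[up_idx] = 2.0 ** cfg.log2_effect
    fold[down_idx] = 2.0 ** -cfg.log2_effect
    disp = np.exp(rng.normal(np.log(0.1), 0.5, size=cfg.n_genes))

    mu = np.tile(base_mu[:, None], (1, 2 * n))
    mu[:, :n] *= fold[:, None]
    size = 1.0 / disp
    p = size[:, None] / (size[:, None] + mu)
    counts = rng.negative_binomial(size[:, None], p)

    values = pd.DataFrame(counts, index=genes, columns=samples)
    truth = SimTruth(de_up={genes[i] for i in up_idx},
                     de_down={genes[i] for i in down_idx})
    return ExpressionMatrix(values, groups, "count"), truth


# ---------------------------------------------------------------------------
# ranked drug-perturbation library
# ---------------------------------------------------------------------------

def gen_drug_library(n_drugs: int, n_genes: int, signature: GeneSignature,
                     n_reversers: int = 1, n_mimics: int = 0,
                     replicates_per_drug: int = 1, strength: float = 1.0,
                     seed: int = 0,
                     cell_line: str = "HepG2") -> tuple[list[RankedProfile], SimTruth]:
    """Library of ranked profiles with planted reversers and mimics.

    A reverser places each signature down-gene at the top of its ranking
    (and each up-gene at the bottom) independently with probability
    ``strength``; mimics do the opposite; all other drugs rank the universe
    uniformly at random.  Each drug receives ``replicates_per_drug``
    profiles tagged with distinct dose/time metadata.
    """
    if n_reversers + n_mimics > n_drugs:
        raise InvalidConfigError("more planted drugs than drugs")
    if not 0 <= strength <= 1:
        raise InvalidConfigError("strength must lie in [0, 1]")
    universe = _gene_ids(n_genes)
    missing = set(signature.genes) - set(universe)
    if missing:
        raise MissingGeneError(f"signature genes outside universe: {sorted(missing)[:5]}")

    rng = np.random.default_rng(seed)
    drugs = [f"DRUG{i:04d}" for i in range(n_drugs)]
    reversers, mimics = set(drugs[:n_reversers]), set(drugs[n_reversers:n_reversers + n_mimics])
    doses = ["0.1uM", "1uM", "10uM", "30uM"]
    times = ["6h", "24h"]

    profiles = []
    for drug in drugs:
        for r in range(replicates_per_drug):
            if drug in reversers:
                top_pool, bottom_pool = signature.down, signature.up
            elif drug in mimics:
                top_pool, bottom_pool = signature.up, signature.down
            else:
                top_pool, bottom_pool = [], []
            head = [g for g in top_pool if rng.random() < strength]
            tail = [g for g in bottom_pool if rng.random() < strength]
            placed = set(head) | set(tail)
            rest = [g for g in universe if g not in placed]
            rest = [rest[i] for i in rng.permutation(len(rest))]
            ranking = head + rest + tail
            profiles.append(
                RankedProfile(
                    profile_id=f"{drug}_rep{r}",
                    drug_id=drug,
                    cell_line=cell_line,
                    dose=doses[r % len(doses)],
                    time=times[r % len(times)],
                    ranked_genes=ranking,
                )
            )
    return profiles, SimTruth(reverser_drugs=reversers, mimic_drugs=mimics)


# ---------------------------------------------------------------------------
# signature-positive cohorts
# ---------------------------------------------------------------------------

def gen_signature_cohort(n_tumor: int, n_normal: int, signature: GeneSignature,
                         positive_fraction: float = 0.5, noise_sd: float = 0.5,
                         seed: int = 0, log2_effect: float = 1.0,
                         n_genes: int | None = None) -> tuple[ExpressionMatrix, SimTruth]:
    """Tumor/normal cohort in which a fraction of tumors carries the
    signature template.

    Signature-positive tumors shift up-genes by +log2_effect and down-genes
    by -log2_effect; the remaining tumors and all normals carry the inverse
    pattern.  Background genes are pure noise, giving the resampling null
    a realistic universe (default universe size: >= 1000 genes).
    """
    signature.require_nonempty()
    if not 0 <= positive_fraction <= 1:
        raise InvalidConfigError("positive_fraction must lie in [0, 1]")
    if n_tumor < 1:
        raise InvalidConfigError("need at least one tumor sample")
    t = len(signature.genes)
    if n_genes is None:
        n_genes = max(1000, 5 * t)
    if n_genes < t:
        raise InvalidConfigError("n_genes smaller than the signature")

    rng = np.random.default_rng(seed)
    background = [g for g in _gene_ids(n_genes + t) if g not in set(signature.genes)]
    genes = list(signature.genes) + background[: n_genes - t]

    tumors = [f"T{i:04d}" for i in range(n_tumor)]
    normals = [f"N{i:04d}" for i in range(n_normal)]
    samples = tumors + normals
    groups = pd.Series(["tumor"] * n_tumor + ["normal"] * n_normal, index=samples)

    n_pos = int(round(positive_fraction * n_tumor))
    pos = set(np.array(tumors)[rng.choice(n_tumor, size=n_pos, replace=False)])

    w = np.zeros(n_genes)
    w[: len(signature.up)] = log2_effect
    w[len(signature.up): t] = -log2_effect

    x = rng.normal(0.0, noise_sd, size=(n_genes, len(samples)))
    for j, s in enumerate(samples):
        x[:, j] += w if s in pos else -w

    values = pd.DataFrame(x, index=genes, columns=samples)
    return ExpressionMatrix(values, groups, "log2"), SimTruth(positive_samples=pos)


# ---------------------------------------------------------------------------
# survival tables
# ---------------------------------------------------------------------------

def _uniform_censor_bound(rate: float, censor_rate: float) -> float:
    """Upper bound m of U(0, m) censoring giving P(censored) = censor_rate
    for exponential event times with the given rate."""
    def frac_censored(m: float) -> float:
        return (1.0 - np.exp(-rate * m)) / (rate * m) - censor_rate

    lo, hi = 1e-9, 1.0
    while frac_censored(hi) > 0:
        hi *= 2.0
        if hi > 1e12:
            break
    return brentq(frac_censored, lo, hi)


def gen_survival(labels: Mapping[str, str], hazard_ratio: float = 2.0,
                 baseline_rate: float = 0.02, censor_rate: float = 0.0,
                 seed: int = 0) -> tuple[pd.DataFrame, SimTruth]:
    """Exponential survival times with a planted hazard ratio.

    ``labels`` maps sample -> "positive"/"negative"; positives get event
    rate baseline_rate*hazard_ratio, negatives baseline_rate.  Censoring is
    independent uniform, calibrated so the expected censored fraction per
    group equals ``censor_rate``.
    """
    if not labels:
        raise InvalidConfigError("labels must be non-empty")
    if hazard_ratio <= 0 or baseline_rate <= 0:
        raise InvalidConfigError("hazard_ratio and baseline_rate must be positive")
    if not 0 <= censor_rate < 1:
        raise InvalidConfigError("censor_rate must lie in [0, 1)")

    rng = np.random.default_rng(seed)
    rows = []
    bounds = {}
    for sample, lab in labels.items():
        if lab not in ("positive", "negative"):
            raise InvalidConfigError(f"label {lab!r} not in positive/negative")
        rate = baseline_rate * (hazard_ratio if lab == "positive" else 1.0)
        t_event = rng.exponential(1.0 / rate)
        if censor_rate > 0:
            if rate not in bounds:
                bounds[rate] = _uniform_censor_bound(rate, censor_rate)
            t_cens = rng.uniform(0.0, bounds[rate])
        else:
            t_cens = np.inf
        rows.append(
            {
                "sample_id": sample,
                "time": min(t_event, t_cens),
                "event": int(t_event <= t_cens),
                "group": lab,
            }
        )
    return pd.DataFrame(rows), SimTruth(hazard_ratio=hazard_ratio)


# ---------------------------------------------------------------------------
# planted-partition graphs
# ---------------------------------------------------------------------------

def gen_planted_graph(n_nodes: int, n_communities: int, p_in: float = 0.3,
                      p_out: float = 0.01, seed: int = 0) -> tuple[nx.Graph, SimTruth]:
    """Stochastic block model with near-equal block sizes.

    Edges carry a ``combined_score`` attribute drawn uniformly from
    [700, 1000] so the graph round-trips through the confidence-thresholded
    edge-list reader.
    """
    if n_nodes < 1 or n_communities < 1:
        raise InvalidConfigError("need positive node and community counts")
    if p_in <= p_out:
        warnings.warn("p_in <= p_out: planted communities are unrecoverable",
                      stacklevel=2)
    sizes = [n_nodes // n_communities] * n_communities
    for i in range(n_nodes % n_communities):
        sizes[i] += 1
    sizes = [s for s in sizes if s > 0]
    probs = [[p_in if i == j else p_out for j in range(len(sizes))]
             for i in range(len(sizes))]
    g_raw = nx.stochastic_block_model(sizes, probs, seed=seed)
    rng = np.random.default_rng(seed)

    names = [f"N{i:04d}" for i in range(n_nodes)]
    g = nx.Graph()
    g.add_nodes_from(names)
    for u, v in g_raw.edges:
        g.add_edge(names[u], names[v],
                   combined_score=int(rng.integers(700, 1001)))
    communities = {}
    start = 0
    for block, size in enumerate(sizes):
        for i in range(start, start + size):
            communities[names[i]] = block
        start += size
    return g, SimTruth(communities=communities)


def graph_to_edge_list(g: nx.Graph) -> pd.DataFrame:
    """STRING-style edge list (protein1, protein2, combined_score)."""
    rows = [
        {"protein1": u, "protein2": v,
         "combined_score": data.get("combined_score", 999)}
        for u, v, data in g.edges(data=True)
    ]
    return pd.DataFrame(rows, columns=["protein1", "protein2", "combined_score"])
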
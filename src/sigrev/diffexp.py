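"""Differential expression and signature extraction.

Turns a two-group expression matrix (log2 microarray intensities or RNA-seq
counts) into an up/down gene signature via the classical pipeline: low-signal
noise filtering, probe-to-gene collapsing, an empirical-Bayes moderated
t-statistic, significance thresholding (mean-false-positive control or BH
FDR), and fold-change cutoffs.

The moderated t shrinks each gene's pooled sample variance toward a prior
(s0^2, d0) estimated by method of moments from the observed distribution of
log variances, which stabilises inference at small n (here, 3 replicates per
group is typical).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .exceptions import (
    DegenerateInputError,
    InvalidConfigError,
    InvalidSignatureError,
    WrongScaleError,
)

__all__ = [
    "ExpressionMatrix",
    "DEResult",
    "GeneSignature",
    "noise_filter",
    "collapse_probes",
    "moderated_ttest",
    "control_mean_fp",
    "bh_fdr",
    "fold_change_filter",
    "count_filter",
    "tmm_normalize",
    "counts_to_logcpm",
    "build_signature",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Gene x sample expression values with group labels.

    Parameters
    ----------
    values
        DataFrame indexed by gene (or probe) id, one column per sample.
    groups
        Mapping sample id -> group label ("case"/"control" or any two
        levels for DE; more levels are allowed for cohort matrices).
    scale
        "log2" for log2 intensities / log-CPM, "count" for raw counts.
    """

    values: pd.DataFrame
    groups: pd.Series | None = None
    scale: str = "log2"

    def __post_init__(self) -> None:
        if self.values.columns.duplicated().any():
            raise InvalidConfigError("duplicate sample ids")
        if self.scale not in ("log2", "count"):
            raise InvalidConfigError(f"unknown scale {self.scale!r}")
        if isinstance(self.groups, Mapping):
            self.groups = pd.Series(self.groups)
        if self.groups is not None:
            missing = set(self.values.columns) - set(self.groups.index)
            if missing:
                raise InvalidConfigError(f"samples without group label: {sorted(missing)}")
            self.groups = self.groups.reindex(self.values.columns)
        if self.scale == "count":
            v = self.values.to_numpy()
            if (v < 0).any() or not np.allclose(v, np.round(v)):
                raise WrongScaleError("count matrices must hold non-negative integers")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def group_columns(self, level: str) -> list[str]:
        if self.groups is None:
            raise InvalidConfigError("matrix carries no group labels")
        return list(self.groups.index[self.groups == level])


@dataclass
class DEResult:
    """Per-gene differential expression statistics.

    ``table`` columns: log2fc, fold_change, t, p, adj_p, s2 (per-gene pooled
    variance).  ``s2_prior``/``df_prior`` are the empirical-Bayes prior
    variance s0^2 and prior degrees of freedom d0 shared across genes;
    ``df_residual`` is the per-gene residual df d_g.
    """

    table: pd.DataFrame
    s2_prior: float
    df_prior: float
    df_residual: float

    def __post_init__(self) -> None:
        fc = self.table["fold_change"].to_numpy()
        if not np.allclose(fc, np.exp2(self.table["log2fc"].to_numpy())):
            raise InvalidConfigError("fold_change must equal 2**log2fc")


@dataclass
class GeneSignature:
    """Named up/down gene sets, ordered by evidence strength."""

    name: str
    up: list[str]
    down: list[str]
    thresholds: dict = field(default_factory=dict)
    provenance: str = ""

    def __post_init__(self) -> None:
        if set(self.up) & set(self.down):
            raise InvalidSignatureError("up and down gene sets overlap")
        if len(set(self.up)) != len(self.up) or len(set(self.down)) != len(self.down):
            raise InvalidSignatureError("duplicate genes within a signature set")

    @property
    def genes(self) -> list[str]:
        return list(self.up) + list(self.down)

    def require_nonempty(self) -> None:
        if not self.up or not self.down:
            raise InvalidSignatureError(
                f"signature {self.name!r} needs non-empty up and down sets"
            )


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

def noise_filter(m: ExpressionMatrix, cutoff: float = 6.0, fraction: float = 0.85) -> ExpressionMatrix:
    """Drop genes whose log2 signal sits below ``cutoff`` in at least
    ``fraction`` of the arrays.

    The default removes genes below 6 (log2 scale) in >= 85% of samples,
    the conventional low-expression filter for intensity arrays.
    """
    if m.scale != "log2":
        raise WrongScaleError("noise_filter requires a log2-scale matrix")
    below = (m.values < cutoff).mean(axis=1)
    keep = below < fraction
    return ExpressionMatrix(m.values.loc[keep], m.groups, m.scale)


def collapse_probes(m: ExpressionMatrix, probe_to_gene: Mapping[str, str]) -> ExpressionMatrix:
    """Average multiple probes mapping to one gene; drop unmapped probes."""
    if not probe_to_gene:
        raise InvalidConfigError("empty probe-to-gene mapping")
    mapped = m.values.index.intersection(probe_to_gene.keys())
    if mapped.empty:
        raise InvalidConfigError("no probe in the matrix is covered by the mapping")
    sub = m.values.loc[mapped]
    gene_of = pd.Series({p: probe_to_gene[p] for p in mapped})
    collapsed = sub.groupby(gene_of).mean()
    return ExpressionMatrix(collapsed, m.groups, m.scale)


def count_filter(m: ExpressionMatrix, min_count: int = 5, min_below: int = 2) -> ExpressionMatrix:
    """Remove genes with low counts in too many samples of any one group.

    A gene is dropped when, within at least one group, ``min_below`` or more
    samples have a count strictly below ``min_count``.
    """
    if m.scale != "count":
        raise WrongScaleError("count_filter requires a count-scale matrix")
    if m.groups is None:
        raise InvalidConfigError("count_filter needs per-group sample lists")
    drop = np.zeros(len(m.values), dtype=bool)
    for level in m.groups.unique():
        cols = m.group_columns(level)
        n_below = (m.values[cols] < min_count).sum(axis=1)
        drop |= (n_below >= min_below).to_numpy()
    return ExpressionMatrix(m.values.loc[~drop], m.groups, m.scale)


# ---------------------------------------------------------------------------
# TMM normalization (trimmed mean of M-values)
# ---------------------------------------------------------------------------

def _tmm_pair(obs: np.ndarray, ref: np.ndarray, logratio_trim: float = 0.3,
              sum_trim: float = 0.05, a_cutoff: float = -1e10) -> float:
    n_obs, n_ref = obs.sum(), ref.sum()
    pos = (obs > 0) & (ref > 0)
    obs, ref = obs[pos].astype(float), ref[pos].astype(float)
    m = np.log2((obs / n_obs) / (ref / n_ref))
    a = 0.5 * np.log2((obs / n_obs) * (ref / n_ref))
    # delta-method variance of M; precision weighting uses its inverse
    v = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    fin = np.isfinite(m) & np.isfinite(a) & (a > a_cutoff)
    m, a, v = m[fin], a[fin], v[fin]
    if m.size == 0 or np.max(np.abs(m)) < 1e-6:
        return 1.0
    n = m.size
    lo_m = np.floor(n * logratio_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * sum_trim) + 1
    hi_a = n + 1 - lo_a
    rank_m = stats.rankdata(m)
    rank_a = stats.rankdata(a)
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        return 1.0
    f = np.sum(m[keep] / v[keep]) / np.sum(1.0 / v[keep])
    return float(2.0 ** f) if np.isfinite(f) else 1.0


def tmm_normalize(m: ExpressionMatrix) -> pd.Series:
    """Per-sample TMM scale factors (geometric mean 1).

    M-values (log ratios vs a reference sample) are trimmed 30% from each
    tail and A-values 5% from each tail; the factor is the precision-weighted
    mean of the surviving M-values.  The reference is the sample whose upper
    quartile of scaled counts is closest to the mean upper quartile.
    """
    if m.scale != "count":
        raise WrongScaleError("tmm_normalize requires a count-scale matrix")
    counts = m.values.to_numpy(dtype=float)
    if counts.shape[1] < 2:
        raise InvalidConfigError("TMM needs at least two samples")
    lib = counts.sum(axis=0)
    if (lib == 0).any():
        raise DegenerateInputError("sample with all-zero counts")
    uq = np.array([np.quantile(counts[:, j] / lib[j], 0.75) for j in range(counts.shape[1])])
    ref_idx = int(np.argmin(np.abs(uq - uq.mean())))
    factors = np.array([
        _tmm_pair(counts[:, j], counts[:, ref_idx]) for j in range(counts.shape[1])
    ])
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=m.samples, name="tmm_factor")


def counts_to_logcpm(m: ExpressionMatrix, factors: pd.Series | None = None,
                     prior_count: float = 0.5) -> ExpressionMatrix:
    """log2 counts-per-million on TMM-effective library sizes."""
    if m.scale != "count":
        raise WrongScaleError("counts_to_logcpm requires a count-scale matrix")
    if factors is None:
        factors = tmm_normalize(m)
    lib = m.values.sum(axis=0) * factors.reindex(m.samples)
    cpm = (m.values + prior_count) / (lib + 1.0) * 1e6
    return ExpressionMatrix(np.log2(cpm), m.groups, "log2")


# ---------------------------------------------------------------------------
# moderated t-statistic
# ---------------------------------------------------------------------------

def _trigamma_inverse(x: np.ndarray | float) -> np.ndarray | float:
    """Solve trigamma(y) = x by Newton iteration (monotone, convex)."""
    x = np.asarray(x, dtype=float)
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if np.all(np.abs(dif) / y < 1e-8):
            break
    return y


def _fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of the scaled-F prior for gene variances.

    Under the hierarchical model s2_g ~ s0^2 * F(df, d0), the log variances
    have closed-form mean and variance in terms of digamma/trigamma; matching
    the observed moments yields (s0^2, d0).  d0 = inf when the observed
    spread is no wider than the chi-square sampling noise alone.
    """
    s2 = s2[s2 > 0]
    if s2.size < 2:
        raise DegenerateInputError("too few positive variances to fit a prior")
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = e.mean()
    e_var = e.var(ddof=1) - special.polygamma(1, df / 2.0)
    if e_var > 0:
        d0 = 2.0 * float(_trigamma_inverse(e_var))
        s0_sq = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s0_sq = float(np.exp(e_mean))
    return s0_sq, d0


def moderated_ttest(m: ExpressionMatrix, case: str | None = None,
                    control: str | None = None,
                    prior_df: float | None = None) -> DEResult:
    """Empirical-Bayes moderated two-sample t-test, gene-wise.

    log2 fold change is mean(case) - mean(control).  Each gene's pooled
    variance s2_g (d_g = n1+n2-2 df) is shrunk toward the prior:

        s2_tilde = (d0*s0^2 + d_g*s2_g) / (d0 + d_g)

    with (s0^2, d0) fit across genes.  t = log2fc / (s_tilde*sqrt(1/n1+1/n2))
    is referred to a t distribution with d0 + d_g df.  ``prior_df`` overrides
    the estimated d0; 0 recovers the ordinary pooled t exactly.
    """
    if m.scale != "log2":
        raise WrongScaleError("moderated_ttest requires log2-scale data")
    if m.groups is None:
        raise InvalidConfigError("moderated_ttest needs group labels")
    levels = list(pd.unique(m.groups))
    if case is None or control is None:
        if len(levels) != 2:
            raise InvalidConfigError(f"expected exactly 2 groups, got {levels}")
        case, control = levels[0], levels[1]
    x1 = m.values[m.group_columns(case)].to_numpy(dtype=float)
    x2 = m.values[m.group_columns(control)].to_numpy(dtype=float)
    n1, n2 = x1.shape[1], x2.shape[1]
    if n1 < 2 or n2 < 2:
        raise DegenerateInputError("need >=2 samples per group to estimate variance")

    log2fc = x1.mean(axis=1) - x2.mean(axis=1)
    df_res = n1 + n2 - 2
    s2 = ((n1 - 1) * x1.var(axis=1, ddof=1) + (n2 - 1) * x2.var(axis=1, ddof=1)) / df_res

    if prior_df is None:
        s0_sq, d0 = _fit_variance_prior(s2, df_res)
    else:
        if prior_df < 0:
            raise InvalidConfigError("prior_df must be >= 0")
        d0 = float(prior_df)
        s0_sq = float(np.median(s2[s2 > 0])) if d0 > 0 else 0.0

    if np.isinf(d0):
        s2_tilde = np.full_like(s2, s0_sq)
        df_total = np.inf
    else:
        s2_tilde = (d0 * s0_sq + df_res * s2) / (d0 + df_res)
        df_total = d0 + df_res

    se = np.sqrt(s2_tilde * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, log2fc / se, 0.0)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.where(se > 0, p, 1.0)

    table = pd.DataFrame(
        {
            "log2fc": log2fc,
            "fold_change": np.exp2(log2fc),
            "t": t,
            "p": p,
            "adj_p": bh_fdr(pd.Series(p)).to_numpy(),
            "s2": s2,
        },
        index=m.genes,
    )
    return DEResult(table, s2_prior=s0_sq, df_prior=d0, df_residual=float(df_res))


# ---------------------------------------------------------------------------
# multiplicity
# ---------------------------------------------------------------------------

def control_mean_fp(pvals: Sequence[float] | np.ndarray, k: float = 1.0) -> float:
    """p-value cutoff that bounds the expected number of false positives.

    With G tests and cutoff k/G, the expected count of null p-values below
    the cutoff is k.  With G = 10000 and k = 1 this is the familiar 1e-4.
    """
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        raise InvalidConfigError("empty p-value vector")
    if k <= 0:
        raise InvalidConfigError("k must be positive")
    return float(k) / pvals.size


def bh_fdr(pvals: Sequence[float] | pd.Series) -> pd.Series:
    """Benjamini-Hochberg step-up adjusted p-values."""
    arr = np.asarray(pvals, dtype=float)
    if arr.size == 0:
        return pd.Series(dtype=float)
    if (arr < 0).any() or (arr > 1).any() or np.isnan(arr).any():
        raise InvalidConfigError("p-values must lie in [0, 1]")
    adj = multipletests(arr, method="fdr_bh")[1]
    index = pvals.index if isinstance(pvals, pd.Series) else None
    return pd.Series(adj, index=index)


def fold_change_filter(de: DEResult, up_min: float = 3.0, down_max: float = 0.25,
                       genes: Sequence[str] | None = None) -> tuple[list[str], list[str]]:
    """Partition genes by fold change: up if FC > up_min, down if FC < down_max."""
    if up_min <= down_max:
        raise InvalidConfigError("up_min must exceed down_max")
    tab = de.table if genes is None else de.table.loc[list(genes)]
    up = list(tab.index[tab["fold_change"] > up_min])
    down = list(tab.index[tab["fold_change"] < down_max])
    return up, down


# ---------------------------------------------------------------------------
# signature assembly
# ---------------------------------------------------------------------------

def _order_by_evidence(tab: pd.DataFrame, genes: list[str]) -> list[str]:
    # |t| descending; lexicographic gene id breaks exact ties deterministically
    sub = tab.loc[genes]
    order = sorted(genes, key=lambda g: (-abs(sub.at[g, "t"]), g))
    return order


def build_signature(de: DEResult, name: str = "signature", *,
                    p_cutoff: float | None = None, adj_p_cutoff: float | None = None,
                    fc_up: float = 3.0, fc_down: float = 0.25) -> GeneSignature:
    """Assemble an up/down signature from DE results.

    Significance first (raw-p or BH-adjusted cutoff, exactly one required),
    then fold-change cutoffs; each list ordered by |t| descending.
    """
    if (p_cutoff is None) == (adj_p_cutoff is None):
        raise InvalidConfigError("provide exactly one of p_cutoff / adj_p_cutoff")
    col, cut = ("p", p_cutoff) if p_cutoff is not None else ("adj_p", adj_p_cutoff)
    sig_genes = list(de.table.index[de.table[col] < cut])
    up, down = fold_change_filter(de, fc_up, fc_down, genes=sig_genes)
    thresholds = {col + "_cutoff": cut, "fc_up": fc_up, "fc_down": fc_down}
    sig = GeneSignature(
        name=name,
        up=_order_by_evidence(de.table, up),
        down=_order_by_evidence(de.table, down),
        thresholds=thresholds,
        provenance=f"moderated t (d0={de.df_prior:.4g}, s0^2={de.s2_prior:.4g}); "
                   f"{col}<{cut}; FC>{fc_up} or FC<{fc_down}",
    )
    if not sig.up or not sig.down:
        import warnings

        warnings.warn(f"signature {name!r} has an empty up or down list", stacklevel=2)
    return sig
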
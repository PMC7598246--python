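"""Nearest-template prediction (NTP) of signature status in cohorts.

Each sample is compared, by cosine distance on per-gene z-scores, to a
+1/-1 template built from a signature's up/down genes and to the inverse
template.  Significance of the nearest match comes from random templates of
matched size and sign composition; samples with BH-FDR below alpha are
called signature-positive (nearest the template) or signature-negative
(nearest the inverse), otherwise left unclassified.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .diffexp import ExpressionMatrix, GeneSignature, bh_fdr
from .exceptions import DegenerateInputError, InvalidConfigError, MissingGeneError

__all__ = [
    "Template",
    "NTPCall",
    "CohortClassification",
    "build_template",
    "ntp_distance",
    "ntp_significance",
    "classify_cohort",
    "sens_spec",
    "fisher_2x2",
    "mean_across_datasets",
]

POS, NEG, UNCLASSIFIED = "POS", "NEG", "UNCLASSIFIED"


@dataclass
class Template:
    """Ordered gene list with +1 (up) / -1 (down) weights."""

    genes: list[str]
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.genes) != self.weights.size:
            raise InvalidConfigError("genes and weights differ in length")
        if not np.all(np.isin(self.weights, (1.0, -1.0))):
            raise InvalidConfigError("template weights must be +1 or -1")
        if len(set(self.genes)) != len(self.genes):
            raise InvalidConfigError("duplicate genes in template")

    @property
    def n_up(self) -> int:
        return int((self.weights > 0).sum())


@dataclass
class NTPCall:
    sample_id: str
    d_pos: float
    d_neg: float
    p: float
    fdr: float = np.nan
    label: str = UNCLASSIFIED


@dataclass
class CohortClassification:
    calls: list[NTPCall]
    alpha: float
    proportion_positive: float = field(init=False)

    def __post_init__(self) -> None:
        n = len(self.calls)
        self.proportion_positive = (
            sum(c.label == POS for c in self.calls) / n if n else float("nan")
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "sample_id": c.sample_id,
                    "d_pos": c.d_pos,
                    "d_neg": c.d_neg,
                    "p": c.p,
                    "fdr": c.fdr,
                    "label": c.label,
                }
                for c in self.calls
            ]
        )


def build_template(sig: GeneSignature) -> Template:
    """+1/-1 template: up block first, then down block."""
    sig.require_nonempty()
    genes = list(sig.up) + list(sig.down)
    weights = np.concatenate([np.ones(len(sig.up)), -np.ones(len(sig.down))])
    return Template(genes, weights)


def _cosine(x: np.ndarray, w: np.ndarray) -> float:
    nx, nw = np.linalg.norm(x), np.linalg.norm(w)
    if nx == 0:
        raise DegenerateInputError("zero-variance sample vector: cosine undefined")
    return float(np.dot(x, w) / (nx * nw))


def ntp_distance(sample: np.ndarray, tpl: Template) -> tuple[float, float]:
    """Cosine distances of a (z-scored) sample vector to the template and
    its inverse; d_neg = 2 - d_pos by construction."""
    sample = np.asarray(sample, dtype=float)
    if sample.size != len(tpl.genes):
        raise InvalidConfigError("sample vector length must match template")
    if sample.size < 2:
        raise InvalidConfigError("need >=2 template genes")
    c = _cosine(sample, tpl.weights)
    return 1.0 - c, 1.0 + c


def _null_distances(z: np.ndarray, n_up: int, t: int, rng: np.random.Generator,
                    n_resample: int, chunk: int = 250) -> np.ndarray:
    """Nearest cosine distances of every sample to random +/-1 templates.

    z: genes x samples z-score matrix (the universe).  Returns an
    (n_resample, n_samples) array of 1 - |cos|.
    """
    n_genes, n_samples = z.shape
    if n_genes < t:
        raise InvalidConfigError("universe smaller than template")
    w = np.concatenate([np.ones(n_up), -np.ones(t - n_up)])
    out = np.empty((n_resample, n_samples))
    done = 0
    while done < n_resample:
        m = min(chunk, n_resample - done)
        idx = np.empty((m, t), dtype=np.intp)
        for i in range(m):
            idx[i] = rng.choice(n_genes, size=t, replace=False)
        sub = z[idx]                       # (m, t, n_samples)
        num = np.einsum("t,mts->ms", w, sub)
        den = np.sqrt(t) * np.sqrt((sub ** 2).sum(axis=1))
        with np.errstate(invalid="ignore", divide="ignore"):
            cos = np.where(den > 0, num / den, 0.0)
        out[done:done + m] = 1.0 - np.abs(cos)
        done += m
    return out


def ntp_significance(sample: np.ndarray, tpl: Template, universe_z: np.ndarray,
                     n_resample: int = 1000, seed: int | None = None) -> float:
    """Resampling p-value for one sample's nearest-template distance.

    ``sample`` is the z-scored vector over template genes, ``universe_z``
    the z-scored vector over the whole gene universe (used to draw random
    templates of the same size and sign split, without replacement).
    p = (1 + #{null nearest distance <= observed}) / (n_resample + 1).
    """
    d_pos, d_neg = ntp_distance(sample, tpl)
    d_obs = min(d_pos, d_neg)
    rng = np.random.default_rng(seed)
    null = _null_distances(np.asarray(universe_z, dtype=float)[:, None],
                           tpl.n_up, len(tpl.genes), rng, n_resample)[:, 0]
    return float((1 + np.sum(null <= d_obs)) / (n_resample + 1))


def classify_cohort(m: ExpressionMatrix, sig: GeneSignature, alpha: float = 0.05,
                    n_resample: int = 1000, seed: int | None = None) -> CohortClassification:
    """Call every cohort sample POS / NEG / UNCLASSIFIED by NTP.

    Genes are z-scored across the cohort before distances.  Missing
    signature genes are dropped from the template: below 50% coverage a
    warning is raised, below 10% an error.
    """
    if m.values.shape[1] < 2:
        raise InvalidConfigError("cohort needs >=2 samples")
    tpl_full = build_template(sig)
    present = [g for g in tpl_full.genes if g in m.values.index]
    coverage = len(present) / len(tpl_full.genes)
    if coverage < 0.10:
        raise MissingGeneError(
            f"only {coverage:.0%} of signature genes present in the matrix")
    if coverage < 0.50:
        warnings.warn(f"signature coverage is {coverage:.0%}", stacklevel=2)
    keep = {g for g in present}
    mask = [g in keep for g in tpl_full.genes]
    tpl = Template([g for g, k in zip(tpl_full.genes, mask) if k],
                   tpl_full.weights[np.asarray(mask)])

    x = m.values.to_numpy(dtype=float)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (x - mu) / sd, 0.0)
    zdf = pd.DataFrame(z, index=m.values.index, columns=m.values.columns)

    zt = zdf.loc[tpl.genes].to_numpy()     # template genes x samples
    norms = np.linalg.norm(zt, axis=0)
    if (norms == 0).any():
        raise DegenerateInputError("sample with zero variance over template genes")
    cos = (tpl.weights @ zt) / (np.sqrt(len(tpl.genes)) * norms)
    d_pos = 1.0 - cos
    d_neg = 1.0 + cos
    d_obs = np.minimum(d_pos, d_neg)

    rng = np.random.default_rng(seed)
    null = _null_distances(z, tpl.n_up, len(tpl.genes), rng, n_resample)
    p = (1 + (null <= d_obs[None, :]).sum(axis=0)) / (n_resample + 1)
    fdr = bh_fdr(p).to_numpy()

    calls = []
    for i, s in enumerate(m.values.columns):
        label = UNCLASSIFIED
        if fdr[i] < alpha:
            label = POS if d_pos[i] < d_neg[i] else NEG
        calls.append(NTPCall(str(s), float(d_pos[i]), float(d_neg[i]),
                             float(p[i]), float(fdr[i]), label))
    return CohortClassification(calls=calls, alpha=alpha)


def sens_spec(classification: CohortClassification,
              truth: pd.Series | dict) -> dict:
    """Sensitivity/specificity of POS calls against tumor/normal truth.

    sensitivity = P(POS | tumor), specificity = P(not POS | normal), each
    with a 95% Clopper-Pearson interval.
    """
    truth = pd.Series(truth)
    labels = {c.sample_id: c.label for c in classification.calls}
    if not set(labels) <= set(truth.index):
        raise InvalidConfigError("truth labels do not cover all called samples")
    tumors = [s for s in labels if truth[s] == "tumor"]
    normals = [s for s in labels if truth[s] == "normal"]
    if not tumors or not normals:
        raise DegenerateInputError("both tumor and normal classes must be non-empty")
    tp = sum(labels[s] == POS for s in tumors)
    tn = sum(labels[s] != POS for s in normals)
    sens = tp / len(tumors)
    spec = tn / len(normals)
    sens_ci = proportion_confint(tp, len(tumors), alpha=0.05, method="beta")
    spec_ci = proportion_confint(tn, len(normals), alpha=0.05, method="beta")
    return {
        "sensitivity": sens,
        "specificity": spec,
        "sensitivity_ci": tuple(float(v) for v in sens_ci),
        "specificity_ci": tuple(float(v) for v in spec_ci),
        "n_tumor": len(tumors),
        "n_normal": len(normals),
    }


def fisher_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 count table."""
    arr = np.asarray(table)
    if arr.shape != (2, 2):
        raise InvalidConfigError("table must be 2x2")
    if (arr < 0).any() or not np.allclose(arr, np.round(arr)):
        raise InvalidConfigError("counts must be non-negative integers")
    return float(stats.fisher_exact(arr, alternative="two-sided")[1])


def mean_across_datasets(values, decimals: int | None = None) -> float:
    """Arithmetic mean of per-dataset statistics, optionally rounded to the
    precision at which the inputs are reported."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise InvalidConfigError("need at least one value")
    mu = float(arr.mean())
    return round(mu, decimals) if decimals is not None else mu
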
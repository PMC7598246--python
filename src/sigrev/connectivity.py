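"""Rank-based connectivity scoring of drug perturbation profiles.

A drug perturbation is a full ranking of the gene universe, rank 1 = most
up-regulated.  A query signature (up/down gene sets) is scored against a
profile with the weighted Kolmogorov-Smirnov enrichment statistic; the
combined score s = ES_up - ES_down is set to 0 when the two enrichment
scores share a sign, and library-wide per-sign max scaling maps raw scores
into [-1, 1].  Negative scaled scores mark drugs whose transcriptional
effect opposes (reverses) the query signature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

from .diffexp import GeneSignature
from .exceptions import InvalidConfigError, MissingGeneError

__all__ = [
    "RankedProfile",
    "ConnectivityResult",
    "ScoreMatrix",
    "ks_enrichment",
    "connectivity_score",
    "scale_scores",
    "average_replicates",
    "score_library",
    "score_matrix",
    "hcluster",
    "signature_overlap",
]


@dataclass
class RankedProfile:
    """One drug perturbation as a complete ranked gene list.

    ``ranked_genes[0]`` is the most up-regulated gene (rank 1) and the last
    entry the most down-regulated (rank n).
    """

    profile_id: str
    drug_id: str
    cell_line: str
    dose: str
    time: str
    ranked_genes: list[str]

    def __post_init__(self) -> None:
        if len(set(self.ranked_genes)) != len(self.ranked_genes):
            raise InvalidConfigError(f"profile {self.profile_id}: duplicate genes in ranking")
        self._rank_of = {g: i + 1 for i, g in enumerate(self.ranked_genes)}

    @property
    def n_genes(self) -> int:
        return len(self.ranked_genes)

    def ranks_of(self, genes: Iterable[str]) -> np.ndarray:
        """1-based ranks of ``genes``, ascending; missing genes are an error."""
        try:
            ranks = np.array([self._rank_of[g] for g in genes])
        except KeyError as exc:
            raise MissingGeneError(f"gene {exc.args[0]!r} absent from profile universe") from exc
        return np.sort(ranks)


@dataclass
class ConnectivityResult:
    drug_id: str
    es_up: float
    es_down: float
    raw_score: float
    scaled_score: float = np.nan
    n_replicates_averaged: int = 1


@dataclass
class ScoreMatrix:
    """Signatures x drugs matrix of scaled connectivity scores."""

    values: pd.DataFrame
    row_linkage: np.ndarray | None = None
    col_linkage: np.ndarray | None = None


# ---------------------------------------------------------------------------
# the KS enrichment statistic
# ---------------------------------------------------------------------------

def ks_enrichment(tags: Sequence[str], profile: RankedProfile,
                  weight_exponent: int = 0) -> float:
    """Weighted KS enrichment of a tag set in a ranked profile.

    With V(j) the ascending rank of the j-th tag among n genes and t tags:

        a = max_j ( j/t - V(j)/n )
        b = max_j ( V(j)/n - (j-1)/t )
        ES = a if a > b else -b

    Positive ES: tags concentrate at the top (up-regulated end); negative:
    at the bottom; the range is [-1, 1), with -1 attained when every tag
    sits at the very bottom.  Ties (a == b) resolve to -b.  ``weight_exponent=1``
    switches to a running-sum variant where a hit's increment is weighted by
    its distance from the list centre (extreme ranks count more).
    """
    t = len(tags)
    if t < 1:
        raise InvalidConfigError("tag set must be non-empty")
    n = profile.n_genes
    v = profile.ranks_of(tags)  # sorted ascending, 1-based
    if weight_exponent == 0:
        j = np.arange(1, t + 1)
        a = np.max(j / t - v / n)
        b = np.max(v / n - (j - 1) / t)
        return float(a) if a > b else float(-b)
    if weight_exponent == 1:
        return _weighted_running_sum(v, n)
    raise InvalidConfigError("weight_exponent must be 0 or 1")


def _weighted_running_sum(v: np.ndarray, n: int) -> float:
    """GSEA-style running sum with rank-extremity weights.

    Profiles carry no expression statistic, so the weight of a hit at rank r
    is |r - (n+1)/2|: genes at either extreme of the ranking contribute more
    than genes near the middle.  Misses decrement by 1/(n - t).
    """
    t = v.size
    w = np.abs(v - (n + 1) / 2.0)
    if w.sum() == 0:
        w = np.ones_like(w, dtype=float)
    hit = np.zeros(n)
    hit[v - 1] = w / w.sum()
    miss = np.full(n, 1.0 / (n - t)) if n > t else np.zeros(n)
    miss[v - 1] = 0.0
    running = np.cumsum(hit - miss)
    i_max, i_min = np.argmax(running), np.argmin(running)
    return float(running[i_max]) if running[i_max] > -running[i_min] else float(running[i_min])


def connectivity_score(sig: GeneSignature, profile: RankedProfile,
                       weight_exponent: int = 0) -> ConnectivityResult:
    """Combined connectivity of a signature with one profile.

    s = ES_up - ES_down when the two enrichment scores have strictly
    opposite signs, else 0 (the null call: the profile does not coherently
    move the signature in either direction).
    """
    sig.require_nonempty()
    es_up = ks_enrichment(sig.up, profile, weight_exponent)
    es_down = ks_enrichment(sig.down, profile, weight_exponent)
    if es_up * es_down < 0:
        s = es_up - es_down
    else:
        s = 0.0
    return ConnectivityResult(profile.drug_id, es_up, es_down, s)


def scale_scores(raw: Sequence[float]) -> np.ndarray:
    """Map raw scores into [-1, 1] by per-sign maximum over the library."""
    raw = np.asarray(raw, dtype=float)
    if raw.size == 0:
        raise InvalidConfigError("cannot scale an empty score list")
    pos_max = raw[raw > 0].max() if (raw > 0).any() else None
    neg_min = raw[raw < 0].min() if (raw < 0).any() else None
    if pos_max is None and neg_min is None:
        warnings.warn("all connectivity scores are zero (degenerate library)", stacklevel=2)
        return np.zeros_like(raw)
    out = np.zeros_like(raw)
    if pos_max is not None:
        out[raw > 0] = raw[raw > 0] / pos_max
    if neg_min is not None:
        out[raw < 0] = raw[raw < 0] / abs(neg_min)
    return out


def average_replicates(results: Sequence[ConnectivityResult]) -> list[ConnectivityResult]:
    """Average scaled scores across replicate perturbations of each drug.

    Replicates are profiles of the same drug at different doses/time points;
    averaging happens on the scaled scores.  Drug order follows first
    appearance in the input.
    """
    by_drug: dict[str, list[ConnectivityResult]] = {}
    for r in results:
        by_drug.setdefault(r.drug_id, []).append(r)
    out = []
    for drug, reps in by_drug.items():
        out.append(
            ConnectivityResult(
                drug_id=drug,
                es_up=float(np.mean([r.es_up for r in reps])),
                es_down=float(np.mean([r.es_down for r in reps])),
                raw_score=float(np.mean([r.raw_score for r in reps])),
                scaled_score=float(np.mean([r.scaled_score for r in reps])),
                n_replicates_averaged=len(reps),
            )
        )
    return out


def score_library(sig: GeneSignature, library: Sequence[RankedProfile],
                  weight_exponent: int = 0) -> list[ConnectivityResult]:
    """Score one signature against every profile, scale, then average
    replicates per drug."""
    if not library:
        raise InvalidConfigError("empty profile library")
    per_profile = [connectivity_score(sig, p, weight_exponent) for p in library]
    scaled = scale_scores([r.raw_score for r in per_profile])
    for r, c in zip(per_profile, scaled):
        r.scaled_score = float(c)
    return average_replicates(per_profile)


def score_matrix(queries: Sequence[GeneSignature], library: Sequence[RankedProfile],
                 weight_exponent: int = 0) -> ScoreMatrix:
    """Signatures x drugs matrix of per-drug averaged scaled scores."""
    if not library:
        raise InvalidConfigError("empty profile library")
    rows = {}
    for sig in queries:
        per_drug = score_library(sig, library, weight_exponent)
        rows[sig.name] = {r.drug_id: r.scaled_score for r in per_drug}
    values = pd.DataFrame.from_dict(rows, orient="index")
    return ScoreMatrix(values=values)


def hcluster(matrix: ScoreMatrix, axis: str = "rows") -> tuple[np.ndarray, list[str]]:
    """Agglomerative clustering (Euclidean distance, complete linkage).

    Returns the linkage matrix and leaf labels in dendrogram order.  Under
    exact distance ties scipy merges in input order, so label order is
    deterministic for a fixed input.
    """
    if axis not in ("rows", "cols"):
        raise InvalidConfigError("axis must be 'rows' or 'cols'")
    data = matrix.values if axis == "rows" else matrix.values.T
    labels = list(data.index)
    if len(labels) < 2:
        raise InvalidConfigError("need >=2 items to cluster")
    d = pdist(data.to_numpy(), metric="euclidean")
    if np.all(d == 0):
        warnings.warn("all pairwise distances are zero; cluster order is input order",
                      stacklevel=2)
    z = linkage(d, method="complete")
    order = leaves_list(z)
    if axis == "rows":
        matrix.row_linkage = z
    else:
        matrix.col_linkage = z
    return z, [labels[i] for i in order]


def signature_overlap(sigs: Sequence[GeneSignature]) -> pd.DataFrame:
    """Pairwise |up∩up| and |down∩down| counts between signatures."""
    if len(sigs) < 2:
        raise InvalidConfigError("need >=2 signatures")
    rows = []
    for i, a in enumerate(sigs):
        for b in sigs[i + 1:]:
            rows.append(
                {
                    "sig_a": a.name,
                    "sig_b": b.name,
                    "up_overlap": len(set(a.up) & set(b.up)),
                    "down_overlap": len(set(a.down) & set(b.down)),
                }
            )
    return pd.DataFrame(rows)
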
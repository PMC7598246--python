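"""Drug prioritization and treatment-reversal concordance.

The prioritization ledger keeps a drug when (i) its averaged connectivity
score is negative (predicted to reverse the resistance signature), (ii) it
is approved or under clinical investigation, and (iii) "antineoplastic"
appears among its annotated actions; drugs whose targets intersect a
disease-associated gene list are flagged.  The concordance analysis counts
resistance-signature genes whose expression change under drug treatment has
the reversing sign and agrees with an independent drug reference signature.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .connectivity import ConnectivityResult
from .diffexp import DEResult, ExpressionMatrix, GeneSignature, bh_fdr, build_signature, moderated_ttest, noise_filter
from .exceptions import InvalidConfigError

__all__ = [
    "DrugAnnotation",
    "PriorityRecord",
    "ReversalReport",
    "prioritize",
    "reversal_concordance",
    "etiology_signatures",
]

logger = logging.getLogger(__name__)

RETAINED_STATUSES = ("approved", "investigational")
ANTINEOPLASTIC = "antineoplastic"


@dataclass
class DrugAnnotation:
    drug_id: str
    status: str                    # approved | investigational | other
    actions: set = field(default_factory=set)
    targets: set = field(default_factory=set)

    def __post_init__(self) -> None:
        self.status = self.status.strip().lower()
        self.actions = {a.strip().lower() for a in self.actions if a.strip()}
        self.targets = {t.strip() for t in self.targets if t.strip()}


@dataclass
class PriorityRecord:
    drug_id: str
    connectivity_score: float
    status: str
    targets: set
    actions: set
    disease_target_flag: bool

    def __post_init__(self) -> None:
        if self.connectivity_score >= 0:
            raise InvalidConfigError("retained drugs must have a negative score")


@dataclass
class ReversalReport:
    n_up_reversed: int
    n_down_reversed: int
    up_genes: list[str]
    down_genes: list[str]
    alpha: float

    def __post_init__(self) -> None:
        if set(self.up_genes) & set(self.down_genes):
            raise InvalidConfigError("reversed gene lists must be disjoint")
        if (len(self.up_genes), len(self.down_genes)) != (self.n_up_reversed,
                                                          self.n_down_reversed):
            raise InvalidConfigError("counts must match list lengths")


def prioritize(scores: Sequence[ConnectivityResult],
               annotations: Mapping[str, DrugAnnotation] | Iterable[DrugAnnotation],
               disease_genes: Iterable[str]) -> list[PriorityRecord]:
    """Apply the prioritization ledger to per-drug averaged scores.

    Retains drugs with a negative connectivity score, approved or
    investigational status and antineoplastic action; sorts approved before
    investigational, then by score ascending (strongest reversal first).
    """
    if not isinstance(annotations, Mapping):
        annotations = {a.drug_id: a for a in annotations}
    disease_genes = set(disease_genes)
    if not disease_genes:
        warnings.warn("empty disease gene list: all disease flags false", stacklevel=2)

    dropped = [r.drug_id for r in scores if r.drug_id not in annotations]
    if dropped:
        logger.info("dropping %d unannotated drugs", len(dropped))

    records = []
    for r in scores:
        ann = annotations.get(r.drug_id)
        if ann is None or r.scaled_score >= 0:
            continue
        if ann.status not in RETAINED_STATUSES or ANTINEOPLASTIC not in ann.actions:
            continue
        records.append(
            PriorityRecord(
                drug_id=r.drug_id,
                connectivity_score=float(r.scaled_score),
                status=ann.status,
                targets=set(ann.targets),
                actions=set(ann.actions),
                disease_target_flag=bool(ann.targets & disease_genes),
            )
        )
    status_rank = {s: i for i, s in enumerate(RETAINED_STATUSES)}
    records.sort(key=lambda rec: (status_rank[rec.status], rec.connectivity_score,
                                  rec.drug_id))
    return records


def _reference_signs(drug_reference) -> dict[str, int]:
    """Signed reference from a signature (up=+1/down=-1) or fold-change map."""
    if isinstance(drug_reference, GeneSignature):
        signs = {g: 1 for g in drug_reference.up}
        signs.update({g: -1 for g in drug_reference.down})
        return signs
    ref = pd.Series(drug_reference)
    return {g: int(np.sign(v)) for g, v in ref.items() if v != 0}


def reversal_concordance(treated_de: DEResult, drug_reference,
                         resistance_sig: GeneSignature,
                         alpha: float = 0.05) -> ReversalReport:
    """Count resistance-signature genes reversed by treatment.

    Among genes significant in the treated-vs-vehicle comparison
    (adj_p < alpha): a resistance up-gene counts as reversed when its
    treated fold change is negative and the drug reference moves it in the
    same (negative) direction; symmetrically for down-genes.
    """
    ref_signs = _reference_signs(drug_reference)
    tab = treated_de.table
    sig_genes = tab.index[tab["adj_p"] < alpha]
    up_rev, down_rev = [], []
    for g in sig_genes:
        fc_sign = int(np.sign(tab.at[g, "log2fc"]))
        if fc_sign == 0 or ref_signs.get(g, 0) != fc_sign:
            continue
        if g in resistance_sig.up and fc_sign < 0:
            up_rev.append(g)
        elif g in resistance_sig.down and fc_sign > 0:
            down_rev.append(g)
    return ReversalReport(len(up_rev), len(down_rev), up_rev, down_rev, alpha)


def etiology_signatures(cohorts: Mapping[str, ExpressionMatrix], *,
                        adj_p_cutoff: float = 0.0001, fc_up: float = 3.0,
                        fc_down: float = 0.25,
                        noise_cutoff: float | None = None) -> dict[str, GeneSignature]:
    """Run the tumor-vs-normal signature pipeline independently per etiology.

    Each cohort matrix must carry "tumor"/"normal" group labels; results for
    one etiology do not depend on any other cohort.
    """
    out = {}
    for name, m in cohorts.items():
        if m.groups is None or not {"tumor", "normal"} <= set(m.groups.unique()):
            raise InvalidConfigError(f"cohort {name!r} lacks tumor/normal groups")
        if noise_cutoff is not None:
            m = noise_filter(m, cutoff=noise_cutoff)
        de = moderated_ttest(m, case="tumor", control="normal")
        out[name] = build_signature(de, name=name, adj_p_cutoff=adj_p_cutoff,
                                    fc_up=fc_up, fc_down=fc_down)
    return out
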
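"""End-to-end pipeline orchestration.

``run_pipeline`` executes signature extraction -> connectivity scoring ->
drug prioritization, optionally followed by cohort NTP classification,
survival stratification and drug-target network analysis, persisting every
intermediate under the output directory together with a manifest of
versions, parameters and seeds.  Inputs are either simulated (the default)
or read from user-supplied files.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .connectivity import score_library
from .diffexp import build_signature, control_mean_fp, moderated_ttest, noise_filter
from .exceptions import InvalidConfigError
from .io import (
    read_groups_tsv,
    read_matrix_tsv,
    read_profile_library,
    write_matrix_tsv,
    write_profile_library,
    write_signatures_gmt,
    write_tsv,
)
from .network import node_metrics, ppi_enrichment
from .ntp import classify_cohort
from .prioritize import DrugAnnotation, prioritize
from .simulate import (
    SimConfig,
    gen_drug_library,
    gen_planted_graph,
    gen_signature_cohort,
    gen_survival,
    gen_two_group_matrix,
    graph_to_edge_list,
)
from .survival import logrank

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Run parameters; round-trips losslessly through YAML."""

    seed: int = 0
    outdir: str = "sigrev_run"
    simulate: bool = True
    stages: list = field(default_factory=lambda: ["ntp", "survival", "network"])
    # input paths (required when simulate is false)
    expression_tsv: str | None = None
    groups_tsv: str | None = None
    library_ranks: str | None = None
    library_meta: str | None = None
    annotations_tsv: str | None = None
    disease_genes_txt: str | None = None
    # simulation sizes
    n_genes: int = 2000
    n_samples_per_group: int = 3
    de_fraction: float = 0.05
    log2_effect: float = 2.0
    noise_sd: float = 0.5
    n_drugs: int = 100
    n_reversers: int = 3
    n_mimics: int = 3
    replicates_per_drug: int = 2
    strength: float = 0.9
    n_tumor: int = 60
    n_normal: int = 20
    positive_fraction: float = 0.5
    hazard_ratio: float = 2.0
    # analysis thresholds
    noise_cutoff: float = 6.0
    noise_fraction: float = 0.85
    fp_k: float = 1.0
    fc_up: float = 3.0
    fc_down: float = 0.25
    alpha: float = 0.05
    n_resample: int = 1000
    network_threshold: float = 700.0

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise InvalidConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        if not self.simulate:
            required = ["expression_tsv", "groups_tsv", "library_ranks", "library_meta"]
            for name in required:
                value = getattr(self, name)
                if value is None or not Path(value).exists():
                    raise InvalidConfigError(f"input path {name} missing: {value!r}")
        for frac in ("noise_fraction", "alpha", "de_fraction", "positive_fraction"):
            v = getattr(self, frac)
            if not 0 <= v <= 1:
                raise InvalidConfigError(f"{frac}={v} outside [0, 1]")


def _simulated_annotations(drugs, truth, disease_genes, rng) -> dict[str, DrugAnnotation]:
    """Annotation table for a simulated library: planted reversers get the
    approvable antineoplastic profile so the ledger has something to keep."""
    statuses = ["approved", "investigational", "other"]
    anns = {}
    for d in drugs:
        if d in truth.reverser_drugs:
            status = statuses[rng.integers(0, 2)]
            actions = {"antineoplastic", "kinase inhibitor"}
            targets = set(rng.choice(sorted(disease_genes),
                                     size=min(2, len(disease_genes)), replace=False))
        else:
            status = statuses[rng.integers(0, 3)]
            actions = {"antineoplastic"} if rng.random() < 0.3 else {"antihypertensive"}
            targets = set()
        anns[d] = DrugAnnotation(d, status, actions, targets)
    return anns


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the configured stages; returns a run report dict."""
    cfg.validate()
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = np.random.SeedSequence(cfg.seed).spawn(6)
    sub = [int(s.generate_state(1)[0] % (2 ** 31)) for s in seeds]
    report: dict = {"stages": {}}
    tag = f"sigrev {__version__} seed={cfg.seed}"

    # --- stage 1: signature extraction -----------------------------------
    if cfg.simulate:
        simcfg = SimConfig(cfg.n_genes, cfg.n_samples_per_group, cfg.de_fraction,
                           cfg.log2_effect, cfg.noise_sd, seed=sub[0])
        matrix, de_truth = gen_two_group_matrix(simcfg)
    else:
        matrix = read_matrix_tsv(cfg.expression_tsv)
        matrix.groups = read_groups_tsv(cfg.groups_tsv).reindex(matrix.samples)
        de_truth = None
    write_matrix_tsv(matrix, out / "expression.tsv", comment=f"{tag} stage=input")
    filtered = noise_filter(matrix, cfg.noise_cutoff, cfg.noise_fraction)
    de = moderated_ttest(filtered)
    cutoff = control_mean_fp(de.table["p"], cfg.fp_k)
    sig = build_signature(de, name="resistance", p_cutoff=cutoff,
                          fc_up=cfg.fc_up, fc_down=cfg.fc_down)
    write_tsv(de.table.rename_axis("gene"), out / "de.tsv", index=True,
              comment=f"{tag} stage=signature p_cutoff={cutoff:.3g}")
    write_signatures_gmt([sig], out / "signature.gmt")
    report["stages"]["signature"] = {"n_up": len(sig.up), "n_down": len(sig.down),
                                     "p_cutoff": cutoff}

    # --- stage 2: connectivity -------------------------------------------
    if cfg.simulate:
        library, lib_truth = gen_drug_library(
            cfg.n_drugs, cfg.n_genes, sig, cfg.n_reversers, cfg.n_mimics,
            cfg.replicates_per_drug, cfg.strength, seed=sub[1])
        write_profile_library(library, out / "library_ranks.tsv", out / "library_meta.tsv")
    else:
        library = read_profile_library(cfg.library_ranks, cfg.library_meta)
        lib_truth = None
    scores = score_library(sig, library)
    score_df = pd.DataFrame(
        [{"drug_id": r.drug_id, "es_up": r.es_up, "es_down": r.es_down,
          "raw_score": r.raw_score, "scaled_score": r.scaled_score,
          "n_replicates": r.n_replicates_averaged} for r in scores]
    ).sort_values("scaled_score")
    write_tsv(score_df, out / "connectivity.tsv", comment=f"{tag} stage=connect")
    report["stages"]["connectivity"] = {"n_drugs": len(scores)}

    # --- stage 3: prioritization -----------------------------------------
    rng = np.random.default_rng(sub[2])
    if cfg.simulate:
        disease_genes = set(sig.up[:5]) | set(sig.down[:5])
        annotations = _simulated_annotations([r.drug_id for r in scores], lib_truth,
                                             disease_genes, rng)
    else:
        ann_df = pd.read_csv(cfg.annotations_tsv, sep="\t", comment="#")
        annotations = {
            row.drug_id: DrugAnnotation(
                row.drug_id, row.status,
                set(str(row.actions).split(",")), set(str(row.targets).split(",")))
            for row in ann_df.itertuples(index=False)
        }
        disease_genes = set()
        if cfg.disease_genes_txt:
            disease_genes = set(Path(cfg.disease_genes_txt).read_text().split())
    records = prioritize(scores, annotations, disease_genes)
    pri_df = pd.DataFrame(
        [{"drug_id": r.drug_id, "connectivity_score": r.connectivity_score,
          "status": r.status, "targets": ",".join(sorted(r.targets)),
          "actions": ",".join(sorted(r.actions)),
          "disease_target": r.disease_target_flag} for r in records]
    )
    write_tsv(pri_df, out / "priority.tsv", comment=f"{tag} stage=prioritize")
    report["stages"]["prioritize"] = {"n_retained": len(records)}

    # --- optional stages ---------------------------------------------------
    if "ntp" in cfg.stages and cfg.simulate:
        cohort, cohort_truth = gen_signature_cohort(
            cfg.n_tumor, cfg.n_normal, sig, cfg.positive_fraction,
            cfg.noise_sd, seed=sub[3])
        cls = classify_cohort(cohort, sig, cfg.alpha, cfg.n_resample, seed=sub[3])
        write_tsv(cls.to_frame(), out / "ntp_calls.tsv", comment=f"{tag} stage=ntp")
        report["stages"]["ntp"] = {"proportion_positive": cls.proportion_positive}

        if "survival" in cfg.stages:
            labels = {c.sample_id: ("positive" if c.label == "POS" else "negative")
                      for c in cls.calls}
            surv, _ = gen_survival(labels, cfg.hazard_ratio, seed=sub[4])
            res = logrank(surv, groups=("positive", "negative"))
            write_tsv(surv, out / "survival.tsv", comment=f"{tag} stage=survival")
            write_tsv(pd.DataFrame([{"chi2": res.chi2, "p": res.p, "hr": res.hr,
                                     "hr_lo": res.hr_ci[0], "hr_hi": res.hr_ci[1]}]),
                      out / "logrank.tsv", comment=f"{tag} stage=survival")
            report["stages"]["survival"] = {"p": res.p, "hr": res.hr}

    if "network" in cfg.stages and cfg.simulate:
        graph, net_truth = gen_planted_graph(120, 4, seed=sub[5])
        metrics = node_metrics(graph)
        density = 2 * graph.number_of_edges() / max(
            1, graph.number_of_nodes() * (graph.number_of_nodes() - 1))
        write_tsv(metrics, out / "network_metrics.tsv", index=True,
                  comment=f"{tag} stage=network")
        write_tsv(graph_to_edge_list(graph), out / "network_edges.tsv",
                  comment=f"{tag} stage=network")
        report["stages"]["network"] = {
            "n_nodes": graph.number_of_nodes(),
            "n_edges": graph.number_of_edges(),
            "enrichment_p": ppi_enrichment(graph, density),
        }

    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "substreams": sub,
        "config": dataclasses.asdict(cfg),
        "report": report,
    }
    Path(out / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=True))
    return report
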
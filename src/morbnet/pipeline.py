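"""End-to-end orchestration: cohort -> network -> MCL -> characterization.

``run_all`` executes the stages on a directory of registry-style TSV tables
(as written by :mod:`morbnet.simulate` or user-supplied equivalents), writes
every intermediate artifact in its documented format, and records a manifest
(seeds, parameters, row counts per stage) sufficient to reproduce the run.
Stages whose inputs are missing (labs, prescriptions, traits, events) are
skipped with an explicit notice.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io

from .cohort import ExclusionConfig, build_count_matrix, cohort_summary
from .enrichment import (
    lab_scores,
    lab_subcohort,
    little_enrichment_flags,
    oe_ratios,
    polypharmacy_flags,
    polypharmacy_fractions,
    trait_tests,
)
from .mcl import MCLParams, cluster_graph, write_clustering
from .network import EmbeddingConfig, NetworkConfig, build_similarity_graph, fit_embedding, write_abc
from .robustness import PerturbationConfig, robustness_sweep
from .survival import EndpointRules, derive_composite_event, fit_cluster_cox, significance_table

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    input_dir: str = "data"
    output_dir: str = "results/pipeline"
    exclusions: ExclusionConfig = field(default_factory=ExclusionConfig)
    embedding: EmbeddingConfig = field(default_factory=EmbeddingConfig)
    network: NetworkConfig = field(default_factory=NetworkConfig)
    mcl: MCLParams = field(default_factory=MCLParams)
    endpoint_rules: EndpointRules = field(default_factory=EndpointRules)
    min_cluster_size: int = 500
    run_robustness: bool = False
    perturbation: PerturbationConfig = field(default_factory=PerturbationConfig)
    holm_m: int | None = None

    def to_dict(self):
        d = asdict(self)
        return d


def _read(path: Path, name: str) -> pd.DataFrame | None:
    f = path / f"{name}.tsv"
    if not f.exists():
        return None
    return pd.read_csv(f, sep="\t")


def run_all(config: PipelineConfig) -> Path:
    """Run every stage; returns the output directory."""
    cfg = config
    indir = Path(cfg.input_dir)
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"parameters": json.loads(json.dumps(cfg.to_dict(), default=str)),
                      "stages": {}}

    def stage(name, **counts):
        log.info("stage %s: %s", name, counts)
        manifest["stages"][name] = counts

    patients = _read(indir, "patients")
    diagnoses = _read(indir, "diagnoses")
    if patients is None or diagnoses is None:
        raise FileNotFoundError("patients.tsv and diagnoses.tsv are required")
    index_days = patients.set_index("patient_id")["index_day"]
    stage("cohort", n_patients=len(patients), n_diagnosis_records=len(diagnoses))

    m = build_count_matrix(diagnoses, index_days, cfg.exclusions)
    scipy.io.mmwrite(out / "count_matrix.mtx", m.values)
    np.savetxt(out / "count_matrix.rows.txt", m.patient_ids, fmt="%s")
    np.savetxt(out / "count_matrix.cols.txt", m.code_labels, fmt="%s")
    stage("count_matrix", n_patients=m.shape[0], n_codes=m.shape[1],
          nnz=int(m.values.nnz))

    emb, evr = fit_embedding(m, cfg.embedding)
    stage("embedding", n_components=emb.shape[1],
          cumulative_explained_variance=float(evr.sum()))

    graph = build_similarity_graph(emb, cfg.network, nodes=m.patient_ids)
    write_abc(graph, out / "graph.abc")
    stage("network", n_nodes=graph.n_nodes, n_edges=graph.n_edges)

    clustering = cluster_graph(graph, cfg.mcl, min_size=cfg.min_cluster_size)
    write_clustering(clustering, out / "clusters.tsv", out / "clusters.mcl")
    stage("clustering", n_clusters=clustering.n_clusters,
          n_unclustered=clustering.n_unclustered)

    summary = cohort_summary(patients, m, _read(indir, "events"))
    summary.code_carriers.head(50).to_csv(out / "summary_codes.tsv", sep="\t", index=False)
    (out / "summary.json").write_text(json.dumps({
        "n_patients": summary.n_patients,
        "n_males": summary.n_males,
        "n_females": summary.n_females,
        "pct_male": summary.pct_male,
        "mean_age": summary.mean_age,
        "n_with_comorbidity": summary.n_with_comorbidity,
        "pct_with_comorbidity": summary.pct_with_comorbidity,
        "outcome_counts": summary.outcome_counts,
    }, indent=2))

    if cfg.run_robustness:
        sweep = robustness_sweep(graph, clustering, cfg.perturbation, cfg.mcl,
                                 min_size=cfg.min_cluster_size)
        sweep.to_csv(out / "robustness.tsv", sep="\t", index=False)
        stage("robustness", n_rows=len(sweep))

    events = _read(indir, "events")
    cox_all = None
    if events is not None and clustering.n_clusters >= 2:
        records = derive_composite_event(events, index_days, cfg.endpoint_rules)
        records.to_csv(out / "survival_records.tsv", sep="\t")
        cov = patients.set_index("patient_id")[["sex", "age_at_index"]].rename(
            columns={"age_at_index": "age"})
        frames = []
        for outcome in ("new_ischemic", "non_ihd_death", "all_cause"):
            frames.append(fit_cluster_cox(records, clustering, cov, outcome=outcome,
                                          holm_m=cfg.holm_m))
        cox_all = pd.concat(frames, ignore_index=True)
        cox_all.to_csv(out / "cox_results.tsv", sep="\t", index=False)
        significance_table(cox_all.rename(columns={"cluster_label": "cluster_label"})
                           ).to_csv(out / "significance_table.tsv", sep="\t", index=False)
        stage("survival", n_models=len(cox_all))
    else:
        log.info("survival stage skipped: events table missing or <2 clusters")
        stage("survival", skipped=True)

    oe = oe_ratios(m, clustering)
    oe.to_csv(out / "oe_table.tsv", sep="\t", index=False)
    little_enrichment_flags(oe).to_csv(out / "little_enrichment.tsv", sep="\t")
    stage("enrichment", n_rows=len(oe))

    rx = _read(indir, "prescriptions")
    if rx is not None:
        flags = polypharmacy_flags(rx, index_days)
        polypharmacy_fractions(flags, clustering).to_csv(
            out / "polypharmacy.tsv", sep="\t")
        stage("polypharmacy", n_flagged=int(flags.sum()))
    else:
        log.info("polypharmacy stage skipped: prescriptions table missing")
        stage("polypharmacy", skipped=True)

    labs = _read(indir, "labs")
    if labs is not None:
        eligible, selected = lab_subcohort(labs, index_days)
        if len(eligible):
            scores = lab_scores(selected, clustering)
            scores.scores.to_csv(out / "lab_scores.tsv", sep="\t")
            stage("labs", n_eligible=len(eligible))
        else:
            stage("labs", n_eligible=0)
    else:
        log.info("lab stage skipped: labs table missing")
        stage("labs", skipped=True)

    traits = _read(indir, "traits")
    if traits is not None and clustering.n_clusters >= 2:
        tt = trait_tests(traits, clustering)
        tt.to_csv(out / "trait_tests.tsv", sep="\t", index=False)
        stage("traits", n_tests=len(tt))
    else:
        log.info("trait stage skipped: traits table missing or <2 clusters")
        stage("traits", skipped=True)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return out
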
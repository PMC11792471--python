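"""End-to-end orchestration: simulate, QC, map, cluster, summarise.

`run_cohort` wires the whole pipeline together on a synthetic study:
reference generation, operon clustering, per-sample read QC and translated
mapping, profile assembly, and the cohort statistics (phenotype AUC,
diagnosis association, cluster correlations and prevalences).  Given an
output directory it writes every artefact as plain TSV/FASTA/JSON, and the
outputs are byte-identical for identical configurations.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import cohort_stats as cs
from .operon_clustering import (
    ClusterAssignment,
    cluster_genomes,
    pairwise_operon_identity,
    write_cluster_outputs,
)
from .preprocess import QCReport, qc_batch
from .profiler import (
    ReferenceIndex,
    SampleProfile,
    build_sample_profile,
    map_reads,
    write_profiles_tsv,
)
from .reference_db import ReferenceDB
from .synthetic import (
    SimConfig,
    SimulatedCohort,
    generate_fmt_cohort,
    simulate_cohort,
    write_ground_truth_tsv,
    write_metabolome_tsv,
)
from .thresholds import DEFAULT_THRESHOLDS, Thresholds


@dataclass
class CohortResult:
    """Everything computed by :func:`run_cohort`."""

    config: SimConfig
    cohort: SimulatedCohort
    db: ReferenceDB  # cluster-labelled
    assignment: ClusterAssignment
    profiles: list[SampleProfile]
    qc_reports: dict[str, QCReport]
    phenotypes: list[cs.PhenotypeRecord]
    stats: dict = field(default_factory=dict)


def profile_sample(
    sample_id: str,
    batch,
    db: ReferenceDB,
    index: ReferenceIndex,
    t: Thresholds,
    families,
    clusters,
) -> tuple[SampleProfile, QCReport]:
    """QC one sample's reads and profile the survivors."""
    kept, report = qc_batch(batch.qualities, batch.lengths, t)
    passed = batch.truncated(kept).subset(kept >= t.trim_minlen)
    hits = map_reads(passed, db, t, index)
    profile = build_sample_profile(
        sample_id, hits, report.passed_reads, t, families, clusters=clusters
    )
    return profile, report


def cohort_statistics(
    profiles: list[SampleProfile],
    phenotypes: list[cs.PhenotypeRecord],
    assignment: ClusterAssignment,
) -> dict:
    """The statistics layer over profiled samples and phenotype labels."""
    label = {p.sample_id: p.label for p in phenotypes}
    diagnosis = {p.sample_id: p.diagnosis for p in phenotypes}
    high = [p.operon_abundance for p in profiles if label[p.sample_id] == cs.HIGH_SBA]
    low = [p.operon_abundance for p in profiles if label[p.sample_id] == cs.LOW_SBA]
    stats: dict = {"n_samples": len(profiles), "n_clusters": assignment.n_clusters}

    if high and low:
        assoc = cs.mwu_auc(low, high)
        stats["phenotype_auc"] = assoc.auc
        stats["phenotype_mwu_u"] = assoc.statistic
        stats["phenotype_mwu_p"] = assoc.p_value

    table = pd.crosstab(
        pd.Series([diagnosis[p.sample_id] for p in profiles], name="diagnosis"),
        pd.Series([label[p.sample_id] for p in profiles], name="label"),
    )
    if table.shape[0] >= 2 and table.shape[1] >= 2:
        chi2 = cs.chi2_association(table.to_numpy())
        stats["chi2"] = chi2.statistic
        stats["chi2_p"] = chi2.p_value
        stats["chi2_dof"] = chi2.degrees_of_freedom

    clusters = sorted(assignment.cluster_members)
    stats["cluster_prevalence"] = {
        str(cid): cs.prevalence_by_group(profiles, cid, diagnosis) for cid in clusters
    }
    correlations = {}
    for ca_, cb in itertools.combinations(clusters, 2):
        xs = [math.log10(p.cluster_abundances[ca_]) for p in profiles]
        ys = [math.log10(p.cluster_abundances[cb]) for p in profiles]
        try:
            rho, p_value = cs.spearman(xs, ys)
        except ValueError:
            continue
        slope, intercept = cs.theil_sen(xs, ys)
        correlations[f"{ca_}-{cb}"] = {
            "rho": rho, "p": p_value, "slope": slope, "intercept": intercept,
        }
    stats["cluster_correlations"] = correlations
    return stats


def run_cohort(
    config: SimConfig,
    t: Thresholds = DEFAULT_THRESHOLDS,
    outdir: Optional[str | Path] = None,
) -> CohortResult:
    """Run the full pipeline on a simulated case-control cohort."""
    cohort = simulate_cohort(config)
    pairs = pairwise_operon_identity(cohort.db)
    assignment = cluster_genomes(pairs, t, genomes=cohort.db.genomes)
    db = cohort.db.with_clusters(assignment.genome_to_cluster)
    index = ReferenceIndex(db)
    clusters = sorted(assignment.cluster_members)

    profiles = []
    qc_reports = {}
    for sample_id in sorted(cohort.batches):
        profile, report = profile_sample(
            sample_id, cohort.batches[sample_id], db, index, t, config.families, clusters
        )
        profiles.append(profile)
        qc_reports[sample_id] = report

    phenotypes = cs.phenotype_table(cohort.metabolome, t)
    stats = cohort_statistics(profiles, phenotypes, assignment)
    result = CohortResult(
        config=config,
        cohort=cohort,
        db=db,
        assignment=assignment,
        profiles=profiles,
        qc_reports=qc_reports,
        phenotypes=phenotypes,
        stats=stats,
    )
    if outdir is not None:
        write_cohort_outputs(result, pairs, Path(outdir))
    return result


def write_cohort_outputs(result: CohortResult, pairs, outdir: Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.db.to_fasta(outdir / "reference.faa")
    result.db.write_index(outdir / "reference.index.tsv")
    write_cluster_outputs(pairs, result.assignment, outdir / "operon", DEFAULT_THRESHOLDS)
    write_profiles_tsv(result.profiles, outdir / "profiles.tsv")
    write_metabolome_tsv(result.cohort.metabolome, outdir / "metabolome.tsv")
    write_ground_truth_tsv(result.cohort.truth, outdir / "ground_truth.tsv")
    qc = pd.DataFrame(
        [
            {"sample_id": s, "input_reads": r.input_reads, "passed_reads": r.passed_reads,
             "trimmed_bases": r.trimmed_bases, "dropped_short": r.dropped_short}
            for s, r in sorted(result.qc_reports.items())
        ]
    )
    qc.to_csv(outdir / "qc_report.tsv", sep="\t", index=False)
    with open(outdir / "stats.json", "w") as fh:
        json.dump(result.stats, fh, indent=2, sort_keys=True)
        fh.write("\n")


def run_fmt(config: SimConfig, t: Thresholds = DEFAULT_THRESHOLDS):
    """Simulate and analyse an FMT cohort.

    Returns the cohort, the per-subject summary table and the
    response-association result.
    """
    cohort, _truth = generate_fmt_cohort(config)
    summary = cs.fmt_summary(cohort, t)
    assoc = cs.fmt_response_association(
        summary["fold_change"].to_numpy(), summary["response"].astype(bool).to_numpy()
    )
    return cohort, summary, assoc
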
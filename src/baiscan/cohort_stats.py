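"""Cohort-level statistics linking bai abundance to the bile acid phenotype.

The phenotype is the ratio of deoxycholate (DCA, a secondary bile acid) to
cholate (CA, its primary precursor) ion abundances: a sample is
*high-SBA* when DCA:CA exceeds 1 and *low-SBA* (SBA-deficient) otherwise;
an exact tie counts as low-SBA since "high" requires strictly more DCA.

The statistical toolkit mirrors what a practitioner would use on such
data: a chi-square test of phenotype-by-diagnosis contingency tables,
Mann-Whitney U with the AUC summary U/(n1*n2), Spearman rank correlation
between cluster log-abundances, a Theil-Sen robust line (median of pairwise
slopes; intercept the median of y - slope*x), cluster
prevalence/abundance-when-detected summaries, and fold changes of operon
abundance across fecal microbiota transplantation (FMT).

Raw p-values are reported throughout; no multiple-testing correction is
applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .profiler import SampleProfile, operon_abundance
from .thresholds import DEFAULT_THRESHOLDS, Thresholds

HIGH_SBA = "high_SBA"
LOW_SBA = "low_SBA"


@dataclass(frozen=True)
class PhenotypeRecord:
    """Per-sample bile acid measurements and the derived phenotype label."""

    sample_id: str
    dca: float
    ca: float
    diagnosis: str
    label: str

    @property
    def ratio(self) -> float:
        return self.dca / self.ca


@dataclass(frozen=True)
class AssociationResult:
    """Result of a chi-square or Mann-Whitney association test."""

    statistic: float
    p_value: float
    n: int
    degrees_of_freedom: Optional[int] = None
    auc: Optional[float] = None

    def __post_init__(self) -> None:
        if not 0 <= self.p_value <= 1:
            raise ValueError("p_value outside [0, 1]")
        if self.auc is not None and not 0 <= self.auc <= 1:
            raise ValueError("auc outside [0, 1]")


@dataclass
class FMTSeries:
    """One FMT recipient: pre/post (and donor) per-family abundance profiles.

    Profiles are per-family relative-abundance mappings; operon abundances
    are derived with the standard geometric-mean/pseudocount rule.
    """

    subject_id: str
    pre: list[Mapping[str, float]]
    post: list[Mapping[str, float]]
    donor: list[Mapping[str, float]] = field(default_factory=list)
    response: bool = False


def ba_phenotype(dca: float, ca: float, t: Thresholds = DEFAULT_THRESHOLDS) -> str:
    """High/low secondary-bile-acid label from DCA and CA ion abundances."""
    if ca <= 0:
        raise ValueError("CA ion abundance must be positive to form the DCA:CA ratio")
    if dca < 0:
        raise ValueError("DCA ion abundance must be non-negative")
    return HIGH_SBA if dca / ca > t.phenotype_ratio_cutoff else LOW_SBA


def phenotype_table(
    metabolome: pd.DataFrame,
    t: Thresholds = DEFAULT_THRESHOLDS,
) -> list[PhenotypeRecord]:
    """Label every sample of a metabolome table (sample_id, DCA, CA, diagnosis)."""
    records = []
    for row in metabolome.itertuples(index=False):
        records.append(
            PhenotypeRecord(
                sample_id=str(row.sample_id),
                dca=float(row.DCA),
                ca=float(row.CA),
                diagnosis=str(row.diagnosis),
                label=ba_phenotype(float(row.DCA), float(row.CA), t),
            )
        )
    return records


def chi2_association(contingency) -> AssociationResult:
    """Pearson chi-square test on a diagnosis-by-phenotype count table.

    Expected counts come from the row/column margins; dof = (r-1)(c-1).
    Continuity correction is applied only for 2x2 tables (dof == 1).
    """
    table = np.asarray(contingency, dtype=float)
    if table.ndim != 2 or table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    if (table < 0).any():
        raise ValueError("contingency counts must be non-negative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("contingency table has a zero margin")
    res = stats.chi2_contingency(table)
    return AssociationResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n=int(table.sum()),
        degrees_of_freedom=int(res.dof),
    )


def mwu_auc(values_group1: Sequence[float], values_group2: Sequence[float]) -> AssociationResult:
    """Two-sided Mann-Whitney U with the AUC summary.

    ``auc = U / (n1 * n2)`` where U counts pairs in which group 2's value
    exceeds group 1's (ties count one half), i.e. the probability that a
    random group-2 value outranks a random group-1 value.
    """
    g1 = np.asarray(values_group1, dtype=float)
    g2 = np.asarray(values_group2, dtype=float)
    if g1.size == 0 or g2.size == 0:
        raise ValueError("both groups must be non-empty")
    res = stats.mannwhitneyu(g2, g1, alternative="two-sided")
    u = float(res.statistic)
    return AssociationResult(
        statistic=u,
        p_value=float(res.pvalue),
        n=int(g1.size + g2.size),
        auc=u / (g1.size * g2.size),
    )


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation (midranks; p via the t approximation)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("spearman requires two equal-length vectors of length >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("spearman undefined for constant input")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def theil_sen(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Theil-Sen line: median of pairwise slopes, intercept = median(y - slope*x).

    Pairs with equal x are skipped when forming slopes; all-equal x is an
    error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 2:
        raise ValueError("theil_sen requires two equal-length vectors of length >= 2")
    if np.unique(x).size < 2:
        raise ValueError("theil_sen requires at least two distinct x values")
    res = stats.theilslopes(y, x, method="joint")
    return float(res.slope), float(res.intercept)


# ------------------------------------------------- prevalence & abundance

def prevalence_by_group(
    profiles: Sequence[SampleProfile],
    cluster_id: int,
    group_labels: Mapping[str, str],
) -> dict[str, float]:
    """Fraction of samples per group in which the cluster is detected.

    Detection is the >= 4-families-with-reads flag carried by each profile.
    """
    per_group: dict[str, list[bool]] = {}
    for p in profiles:
        group = group_labels[p.sample_id]
        per_group.setdefault(group, []).append(bool(p.cluster_detected.get(cluster_id, False)))
    out = {}
    for group, flags in per_group.items():
        if not flags:
            raise ValueError(f"group {group!r} has no samples")
        out[group] = sum(flags) / len(flags)
    return out


def mean_abundance_when_detected(
    profiles: Sequence[SampleProfile],
    cluster_id: int,
) -> float:
    """Mean log10 cluster abundance over detected samples, reported as 10**mean."""
    logs = [
        math.log10(p.cluster_abundances[cluster_id])
        for p in profiles
        if p.cluster_detected.get(cluster_id, False)
    ]
    if not logs:
        raise ValueError(f"cluster {cluster_id} detected in no sample")
    return float(10 ** (sum(logs) / len(logs)))


# ----------------------------------------------------------------- FMT

def _geometric_mean(values: Sequence[float]) -> float:
    values = list(values)
    if not values:
        raise ValueError("geometric mean of an empty set")
    if any(v <= 0 for v in values):
        raise ValueError("geometric mean requires positive values")
    return float(math.exp(sum(math.log(v) for v in values) / len(values)))


def series_operon_abundances(
    series: FMTSeries,
    t: Thresholds = DEFAULT_THRESHOLDS,
) -> tuple[list[float], list[float], list[float]]:
    """Operon abundances of a subject's pre, post and donor profiles."""
    pre = [operon_abundance(p, t) for p in series.pre]
    post = [operon_abundance(p, t) for p in series.post]
    donor = [operon_abundance(p, t) for p in series.donor]
    return pre, post, donor


def fmt_fold_change(series: FMTSeries, t: Thresholds = DEFAULT_THRESHOLDS) -> float:
    """Post/pre ratio of geometric-mean operon abundance for one recipient.

    Each sample's operon abundance is already pseudocount-floored, so the
    fold change is finite and positive even for recipients with no
    detectable bai genes before transplant.
    """
    if not series.pre or not series.post:
        raise ValueError(f"subject {series.subject_id}: need >= 1 pre and >= 1 post profile")
    pre, post, _ = series_operon_abundances(series, t)
    return _geometric_mean(post) / _geometric_mean(pre)


def fmt_response_association(
    folds: Sequence[float],
    responses: Sequence[bool],
) -> AssociationResult:
    """Mann-Whitney association between fold change and clinical response.

    AUC is the probability that a responder's fold change outranks a
    non-responder's.
    """
    folds = np.asarray(folds, dtype=float)
    responses = np.asarray(responses, dtype=bool)
    if folds.size != responses.size:
        raise ValueError("folds and responses must align")
    resp = folds[responses]
    non = folds[~responses]
    if resp.size == 0 or non.size == 0:
        raise ValueError("both response classes must be present")
    return mwu_auc(non, resp)


def fmt_summary(
    cohort: Iterable[FMTSeries],
    t: Thresholds = DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """Per-subject fold changes and response flags as a tidy table."""
    rows = []
    for series in cohort:
        rows.append(
            {
                "subject_id": series.subject_id,
                "n_pre": len(series.pre),
                "n_post": len(series.post),
                "fold_change": fmt_fold_change(series, t),
                "response": int(series.response),
            }
        )
    return pd.DataFrame(rows)
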
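"""Synthetic data with known ground truth for every pipeline stage.

The generator emulates, at desk scale, the kind of data the pipeline is
built for:

* a reference set of eight-gene bai operons carried by a handful of
  genomes, grouped into clusters at controlled amino-acid divergence
  (genomes of one cluster descend from a shared ancestor; ancestors
  descend from a common root);
* shotgun read sets in which bai-derived reads are in-frame fragments of
  reverse-translated bai genes (random start and strand) hidden in a sea
  of uniform-random background reads;
* a bimodal DCA:CA metabolome coupled to the true bai-operon abundance by
  a threshold rule: samples above the threshold draw log10(DCA:CA) around
  a positive mean, samples below around a negative mean;
* an FMT cohort in which a subset of recipients engraft bai carriers
  (pre-transplant abundance at the pseudocount floor, post high) and
  engraftment is coupled to clinical response.

Reverse translation uses the standard genetic code with uniform,
seeded codon choice; sequencing error is off by default so mapping
thresholds can be probed with explicit substitutions; background reads are
i.i.d. uniform nucleotides, which makes a spurious >= 90%-identity,
>= 25-aa protein hit vanishingly unlikely.  Identical configurations
(including the seed) reproduce byte-identical outputs.
"""

from __future__ import annotations

import logging
import warnings
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .cohort_stats import FMTSeries
from .profiler import operon_abundance
from .reads import ReadBatch
from .reference_db import ReferenceDB, ReferenceSequence
from .thresholds import DEFAULT_FAMILIES, DEFAULT_THRESHOLDS, Thresholds, validate_families
from .translate import CODONS_FOR_AA, encode_nt, revcomp_codes

logger = logging.getLogger(__name__)

AA20 = "ACDEFGHIKLMNPQRSTVWY"
DIAGNOSES = ("CD", "UC", "nonIBD")

# community states: which clusters a sample carries.  "healthy_pair"
# carries clusters 1 and 2 together (their abundances co-vary), "alt"
# carries only the last cluster, "deficient" carries none.
STATE_HEALTHY = "healthy_pair"
STATE_ALT = "alt_cluster"
STATE_DEFICIENT = "deficient"

#: probability of each community state per diagnosis group; the
#: SBA-deficient rates (0.30 CD / 0.16 UC / 0.04 non-IBD) follow the
#: reported frequencies of the deficient state in IBD case-control cohorts.
DEFAULT_STATE_PROBS: dict[str, dict[str, float]] = {
    "CD": {STATE_HEALTHY: 0.30, STATE_ALT: 0.40, STATE_DEFICIENT: 0.30},
    "UC": {STATE_HEALTHY: 0.50, STATE_ALT: 0.34, STATE_DEFICIENT: 0.16},
    "nonIBD": {STATE_HEALTHY: 0.80, STATE_ALT: 0.16, STATE_DEFICIENT: 0.04},
}


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Abundances are read fractions: ``cluster_abundances[c]`` is the
    expected fraction of reads drawn from *each gene family of each
    genome* of cluster ``c``.  ``background_fraction`` defaults to the
    complement of the configured signal.
    """

    seed: int = 0
    # reference set
    n_clusters: int = 3
    genomes_per_cluster: int = 2
    within_cluster_divergence: float = 0.05
    between_cluster_divergence: float = 0.30
    gene_length_aa: int = 300
    families: tuple[str, ...] = DEFAULT_FAMILIES
    # reads
    read_length_nt: int = 150
    n_reads: int = 100_000
    background_fraction: Optional[float] = None
    cluster_abundances: dict[int, float] = field(default_factory=dict)
    qc_fail_fraction: float = 0.0
    # phenotype model
    phenotype_threshold: float = 1e-7
    phenotype_noise_sd: float = 0.0
    phenotype_log_ratio_mean: float = 1.0
    # cohort layout
    n_samples: int = 100
    diagnosis_proportions: dict[str, float] = field(
        default_factory=lambda: {d: 1 / 3 for d in DIAGNOSES}
    )
    state_probabilities: dict[str, dict[str, float]] = field(
        default_factory=lambda: {d: dict(p) for d, p in DEFAULT_STATE_PROBS.items()}
    )
    community_log10_abundance_mean: float = -3.0
    community_log10_abundance_sd: float = 0.3
    # FMT cohort
    n_fmt_subjects: int = 10
    n_fmt_engrafters: int = 5
    fmt_pre_samples: int = 1
    fmt_post_samples: int = 2
    fmt_engraft_abundance: float = 1e-6
    fmt_nonengrafter_abundance: float = 1e-8
    fmt_donor_abundance: float = 1e-5
    fmt_response_coupling: float = 1.0
    fmt_noise_sd: float = 0.0

    def __post_init__(self) -> None:
        self.families = validate_families(self.families)
        for name in ("within_cluster_divergence", "between_cluster_divergence",
                     "qc_fail_fraction", "fmt_response_coupling"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_reads <= 0:
            raise ValueError("n_reads must be positive")
        if self.n_clusters <= 0 or self.genomes_per_cluster <= 0:
            raise ValueError("n_clusters and genomes_per_cluster must be positive")
        if self.read_length_nt > 3 * self.gene_length_aa:
            raise ValueError("reads longer than genes are not supported")
        signal = self.signal_fraction()
        bg = self.background_fraction
        if bg is not None and not 0.0 <= bg <= 1.0:
            raise ValueError("background_fraction must be in [0, 1]")
        if signal + (bg or 0.0) > 1.0 + 1e-9:
            raise ValueError("cluster abundances plus background exceed 1")

    def signal_fraction(self) -> float:
        per_gene = sum(self.cluster_abundances.values())
        return per_gene * self.genomes_per_cluster * len(self.families)

    def rng(self, *salt: int) -> np.random.Generator:
        """Deterministic child generator for one named purpose."""
        return np.random.default_rng([self.seed, *salt])


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    genome_cluster: dict[str, int] = field(default_factory=dict)
    gene_aa: dict[tuple[str, str], str] = field(default_factory=dict)
    gene_nt: dict[tuple[str, str], str] = field(default_factory=dict)
    # per sample
    sample_abundances: dict[str, dict[tuple[str, str], float]] = field(default_factory=dict)
    sample_cluster_abundance: dict[str, dict[int, float]] = field(default_factory=dict)
    sample_operon_abundance: dict[str, float] = field(default_factory=dict)
    sample_state: dict[str, str] = field(default_factory=dict)
    diagnosis: dict[str, str] = field(default_factory=dict)
    phenotype_label: dict[str, str] = field(default_factory=dict)
    read_sources: dict[str, Optional[tuple[str, str]]] = field(default_factory=dict)
    fmt_engrafter: dict[str, bool] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        """Per-sample truth table (state, diagnosis, operon abundance, label)."""
        samples = sorted(self.sample_operon_abundance)
        return pd.DataFrame(
            {
                "sample_id": samples,
                "state": [self.sample_state.get(s, "") for s in samples],
                "diagnosis": [self.diagnosis.get(s, "") for s in samples],
                "true_operon_abundance": [self.sample_operon_abundance[s] for s in samples],
                "phenotype_label": [self.phenotype_label.get(s, "") for s in samples],
            }
        )


def _mutate(residues: str, rate: float, rng: np.random.Generator) -> str:
    """Substitute each position with probability ``rate`` (never to itself)."""
    if rate == 0:
        return residues
    chars = list(residues)
    hits = np.flatnonzero(rng.random(len(chars)) < rate)
    for i in hits:
        alternatives = AA20.replace(chars[i], "")
        chars[i] = alternatives[rng.integers(len(alternatives))]
    return "".join(chars)


def _reverse_translate(residues: str, rng: np.random.Generator) -> str:
    codons = [
        CODONS_FOR_AA[aa][rng.integers(len(CODONS_FOR_AA[aa]))] for aa in residues
    ]
    return "".join(codons)


def generate_reference_operons(config: SimConfig) -> tuple[ReferenceDB, GroundTruth]:
    """Simulate the clustered reference set of eight-gene bai operons.

    Each cluster's genomes share an ancestor mutated from a common root at
    half the between-cluster divergence, so expected pairwise identity is
    about ``1 - 2*within`` inside a cluster and below
    ``1 - between`` across clusters.
    """
    expected_within = 1 - 2 * config.within_cluster_divergence
    if expected_within < DEFAULT_THRESHOLDS.cluster_identity:
        warnings.warn(
            f"within-cluster divergence {config.within_cluster_divergence} puts expected "
            f"pairwise identity ({expected_within:.2f}) below the 90% clustering threshold",
            stacklevel=2,
        )
    rng = config.rng(1)
    truth = GroundTruth()
    entries = []
    roots = {
        fam: "".join(AA20[i] for i in rng.integers(0, 20, config.gene_length_aa))
        for fam in config.families
    }
    for c in range(1, config.n_clusters + 1):
        ancestors = {
            fam: _mutate(root, config.between_cluster_divergence / 2, rng)
            for fam, root in roots.items()
        }
        for g in range(1, config.genomes_per_cluster + 1):
            genome_id = f"C{c:02d}G{g:02d}"
            truth.genome_cluster[genome_id] = c
            for fam in config.families:
                residues = _mutate(ancestors[fam], config.within_cluster_divergence, rng)
                nt = _reverse_translate(residues, rng)
                truth.gene_aa[(genome_id, fam)] = residues
                truth.gene_nt[(genome_id, fam)] = nt
                entries.append(
                    ReferenceSequence(
                        sequence_id=f"{genome_id}_{fam}",
                        genome_id=genome_id,
                        family=fam,
                        residues=residues,
                    )
                )
    return ReferenceDB(entries), truth


def _record_sample_truth(
    truth: GroundTruth,
    sample_id: str,
    abundances: Mapping[tuple[str, str], float],
    config: SimConfig,
    t: Thresholds = DEFAULT_THRESHOLDS,
) -> None:
    truth.sample_abundances[sample_id] = dict(abundances)
    family_totals = {fam: 0.0 for fam in config.families}
    cluster_family: dict[int, dict[str, float]] = {}
    for (genome, fam), a in abundances.items():
        family_totals[fam] += a
        cid = truth.genome_cluster[genome]
        cluster_family.setdefault(cid, {f: 0.0 for f in config.families})[fam] += a
    truth.sample_cluster_abundance[sample_id] = {
        cid: operon_abundance([fams[f] for f in config.families], t)
        for cid, fams in cluster_family.items()
    }
    truth.sample_operon_abundance[sample_id] = operon_abundance(
        [family_totals[f] for f in config.families], t
    )


def generate_community_reads(
    config: SimConfig,
    truth: GroundTruth,
    sample_id: str = "S001",
    abundances: Mapping[tuple[str, str], float] | None = None,
) -> ReadBatch:
    """Simulate one sample's shotgun reads and record its truth.

    ``abundances`` maps (genome_id, family) to a per-gene read fraction;
    when omitted it is expanded from ``config.cluster_abundances`` (every
    genome of a cluster gets the configured per-gene fraction).  Reads are
    in-frame fragments of the reverse-translated genes, on either strand,
    at a uniformly random offset; the remainder of the read budget is
    uniform-random background.  Every read id records its source.
    """
    if not truth.genome_cluster:
        raise ValueError("generate reference operons before community reads")
    if abundances is None:
        abundances = {
            (genome, fam): config.cluster_abundances.get(cid, 0.0)
            for genome, cid in truth.genome_cluster.items()
            for fam in config.families
            if config.cluster_abundances.get(cid, 0.0) > 0
        }
    abundances = {k: v for k, v in abundances.items() if v > 0}
    signal = sum(abundances.values())
    background = (
        config.background_fraction if config.background_fraction is not None else 1.0 - signal
    )
    if signal + background > 1 + 1e-9 or signal > 1 + 1e-9:
        raise ValueError("per-sample read fractions exceed 1")

    sources = sorted(abundances)
    probs = np.array([abundances[s] for s in sources] + [1.0 - signal], dtype=float)
    rng = config.rng(2, zlib.crc32(sample_id.encode()))
    counts = rng.multinomial(config.n_reads, probs / probs.sum())

    low_expected = [
        src for src, n_exp in zip(sources, probs[:-1] * config.n_reads) if n_exp < 1
    ]
    if low_expected:
        logger.warning(
            "sample %s: %d sources have expected read count < 1 and may emit zero reads",
            sample_id, len(low_expected),
        )

    length = config.read_length_nt
    chunks: list[np.ndarray] = []
    origins: list[Optional[tuple[str, str]]] = []
    for src, k in zip(sources, counts[:-1]):
        if k == 0:
            continue
        gene_codes = encode_nt(truth.gene_nt[src])
        starts = rng.integers(0, len(gene_codes) - length + 1, size=k)
        block = np.stack([gene_codes[s : s + length] for s in starts])
        flip = rng.random(k) < 0.5
        block[flip] = revcomp_codes(block[flip])
        chunks.append(block.astype(np.uint8))
        origins.extend([src] * k)
    n_bg = int(counts[-1])
    if n_bg:
        chunks.append(rng.integers(0, 4, size=(n_bg, length), dtype=np.uint8))
        origins.extend([None] * n_bg)

    seq = np.concatenate(chunks) if chunks else np.zeros((0, length), dtype=np.uint8)
    n = seq.shape[0]
    qual = np.full((n, length), 37, dtype=np.uint8)
    if config.qc_fail_fraction > 0:
        fail = rng.random(n) < config.qc_fail_fraction
        qual[fail] = 10  # mean quality below the sliding-window cutoff
    ids = [f"{sample_id}:r{i:07d}" for i in range(n)]
    for read_id, origin in zip(ids, origins):
        truth.read_sources[read_id] = origin
    _record_sample_truth(truth, sample_id, abundances, config)
    return ReadBatch(ids, seq, qual, np.full(n, length, dtype=np.int64))


def generate_metabolome(
    truth: GroundTruth,
    config: SimConfig,
    t: Thresholds = DEFAULT_THRESHOLDS,
    rng: np.random.Generator | None = None,
    noise_sd: float | None = None,
) -> pd.DataFrame:
    """Draw DCA/CA ion abundances coupled to true operon abundance.

    log10(DCA:CA) is normal with mean ``+phenotype_log_ratio_mean`` when
    the sample's true operon abundance exceeds ``phenotype_threshold`` and
    ``-phenotype_log_ratio_mean`` otherwise, with standard deviation
    ``phenotype_noise_sd``.  CA is drawn around 1e6 arbitrary ion-abundance
    units; DCA realises the drawn ratio.  The realised label is stored in
    the ground truth.
    """
    if not truth.sample_operon_abundance:
        raise ValueError("no per-sample truth abundances; generate community reads first")
    if rng is None:
        rng = config.rng(3)
    sd = config.phenotype_noise_sd if noise_sd is None else noise_sd
    rows = []
    for sample_id in sorted(truth.sample_operon_abundance):
        above = truth.sample_operon_abundance[sample_id] > config.phenotype_threshold
        mean = config.phenotype_log_ratio_mean if above else -config.phenotype_log_ratio_mean
        log_ratio = rng.normal(mean, sd)
        ca = 10 ** rng.normal(6.0, 0.3)
        dca = ca * 10**log_ratio
        label = "high_SBA" if dca / ca > t.phenotype_ratio_cutoff else "low_SBA"
        truth.phenotype_label[sample_id] = label
        rows.append(
            {
                "sample_id": sample_id,
                "DCA": dca,
                "CA": ca,
                "diagnosis": truth.diagnosis.get(sample_id, "nonIBD"),
            }
        )
    return pd.DataFrame(rows)


def assign_cohort_states(config: SimConfig, truth: GroundTruth) -> dict[str, dict[tuple[str, str], float]]:
    """Assign diagnosis, community state and per-gene abundances per sample.

    Healthy-pair samples carry clusters 1 and 2 with correlated per-gene
    abundances, alt samples carry only the last cluster, deficient samples
    carry none.  Returns the per-sample abundance maps (the input for read
    generation).
    """
    if config.n_clusters < 2:
        raise ValueError("the cohort model needs at least two reference clusters")
    rng = config.rng(4)
    genomes_by_cluster: dict[int, list[str]] = {}
    for genome, cid in sorted(truth.genome_cluster.items()):
        genomes_by_cluster.setdefault(cid, []).append(genome)
    alt_cluster = max(genomes_by_cluster)
    pair = [c for c in sorted(genomes_by_cluster) if c != alt_cluster][:2]

    diagnoses = sorted(config.diagnosis_proportions)
    diag_p = np.array([config.diagnosis_proportions[d] for d in diagnoses], dtype=float)
    diag_p /= diag_p.sum()

    per_sample: dict[str, dict[tuple[str, str], float]] = {}
    for i in range(config.n_samples):
        sample_id = f"S{i + 1:03d}"
        diagnosis = diagnoses[rng.choice(len(diagnoses), p=diag_p)]
        state_probs = config.state_probabilities[diagnosis]
        states = sorted(state_probs)
        state = states[rng.choice(len(states), p=np.array([state_probs[s] for s in states]) / sum(state_probs.values()))]
        truth.diagnosis[sample_id] = diagnosis
        truth.sample_state[sample_id] = state

        abundances: dict[tuple[str, str], float] = {}
        if state == STATE_HEALTHY:
            base = rng.normal(config.community_log10_abundance_mean, config.community_log10_abundance_sd)
            for offset, cid in zip((0.0, -0.4), pair):
                level = 10 ** (base + offset + rng.normal(0, 0.1))
                for genome in genomes_by_cluster[cid]:
                    for fam in config.families:
                        abundances[(genome, fam)] = level / len(genomes_by_cluster[cid])
        elif state == STATE_ALT:
            level = 10 ** rng.normal(
                config.community_log10_abundance_mean, config.community_log10_abundance_sd
            )
            for genome in genomes_by_cluster[alt_cluster]:
                for fam in config.families:
                    abundances[(genome, fam)] = level / len(genomes_by_cluster[alt_cluster])
        per_sample[sample_id] = abundances
    return per_sample


@dataclass
class SimulatedCohort:
    """A full synthetic study: reference, truth, reads and metabolome."""

    config: SimConfig
    db: ReferenceDB
    truth: GroundTruth
    batches: dict[str, ReadBatch]
    metabolome: pd.DataFrame


def simulate_cohort(config: SimConfig) -> SimulatedCohort:
    """Generate the complete case-control study the pipeline consumes."""
    db, truth = generate_reference_operons(config)
    per_sample = assign_cohort_states(config, truth)
    batches = {
        sample_id: generate_community_reads(config, truth, sample_id, abundances)
        for sample_id, abundances in per_sample.items()
    }
    metabolome = generate_metabolome(truth, config)
    return SimulatedCohort(config, db, truth, batches, metabolome)


def generate_fmt_cohort(config: SimConfig) -> tuple[list[FMTSeries], GroundTruth]:
    """Simulate FMT recipients with engraftment in a subset of responders.

    Engrafters start with no detectable bai genes (all per-family
    abundances zero, i.e. at the pseudocount floor after profiling) and
    end with every family at ``fmt_engraft_abundance``; non-engrafters
    stay flat at ``fmt_nonengrafter_abundance``.  Donor profiles sit above
    the recipients' pre-transplant mean.  Response equals engraftment with
    probability ``fmt_response_coupling`` (flipped otherwise).
    """
    rng = config.rng(5)
    truth = GroundTruth()
    cohort = []
    jitter = (
        (lambda: 10 ** rng.normal(0.0, config.fmt_noise_sd)) if config.fmt_noise_sd > 0 else (lambda: 1.0)
    )
    for i in range(config.n_fmt_subjects):
        subject_id = f"P{i + 1:02d}"
        engrafter = i < config.n_fmt_engrafters
        truth.fmt_engrafter[subject_id] = engrafter
        if engrafter:
            pre = [
                {fam: 0.0 for fam in config.families} for _ in range(config.fmt_pre_samples)
            ]
            post = [
                {fam: config.fmt_engraft_abundance * jitter() for fam in config.families}
                for _ in range(config.fmt_post_samples)
            ]
        else:
            flat = {fam: config.fmt_nonengrafter_abundance for fam in config.families}
            pre = [
                {fam: a * jitter() for fam, a in flat.items()}
                for _ in range(config.fmt_pre_samples)
            ]
            post = [
                {fam: a * jitter() for fam, a in flat.items()}
                for _ in range(config.fmt_post_samples)
            ]
        donor = [{fam: config.fmt_donor_abundance * jitter() for fam in config.families}]
        response = engrafter if rng.random() < config.fmt_response_coupling else not engrafter
        cohort.append(
            FMTSeries(subject_id=subject_id, pre=pre, post=post, donor=donor, response=response)
        )
    return cohort, truth


# ------------------------------------------------------------------- I/O

def write_metabolome_tsv(metabolome: pd.DataFrame, path: str | Path) -> None:
    metabolome.to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_ground_truth_tsv(truth: GroundTruth, path: str | Path) -> None:
    truth.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_fmt_metadata_tsv(cohort: list[FMTSeries], path: str | Path) -> None:
    rows = []
    for series in cohort:
        for role, profiles in (("pre", series.pre), ("post", series.post), ("donor", series.donor)):
            for j, _ in enumerate(profiles):
                rows.append(
                    {
                        "subject_id": series.subject_id,
                        "sample_id": f"{series.subject_id}_{role}{j + 1}",
                        "role": role,
                        "response": int(series.response),
                    }
                )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
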
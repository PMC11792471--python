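"""The synthetic-data generator: determinism, traceability, calibrated counts."""

import logging

import numpy as np
import pytest
from scipy import stats as sps

import baiscan as b
from baiscan.align import align_protein


def test_minimal_reference_has_one_sequence_per_family():
    config = b.SimConfig(seed=2, n_clusters=1, genomes_per_cluster=1, gene_length_aa=60)
    db, truth = b.generate_reference_operons(config)
    assert len(db) == 8
    assert {e.family for e in db} == set(b.DEFAULT_FAMILIES)
    assert all(len(e.residues) == 60 for e in db)


def test_zero_within_divergence_gives_identical_genomes():
    config = b.SimConfig(
        seed=3, n_clusters=2, genomes_per_cluster=3,
        within_cluster_divergence=0.0, gene_length_aa=60,
    )
    db, truth = b.generate_reference_operons(config)
    for fam in b.DEFAULT_FAMILIES:
        for cluster in (1, 2):
            seqs = {
                e.residues for e in db
                if e.family == fam and truth.genome_cluster[e.genome_id] == cluster
            }
            assert len(seqs) == 1


def test_divergence_calibration_within_and_between(three_cluster_reference, three_cluster_config):
    db, truth = three_cluster_reference
    w = three_cluster_config.within_cluster_divergence
    btw = three_cluster_config.between_cluster_divergence
    per_genome = {g: {} for g in db.genomes}
    for e in db:
        per_genome[e.genome_id][e.family] = e.residues
    for fam in b.DEFAULT_FAMILIES[:3]:
        same = align_protein(per_genome["C01G01"][fam], per_genome["C01G02"][fam])
        assert same.identity >= 1 - 2 * w - 0.05
        cross = align_protein(per_genome["C01G01"][fam], per_genome["C02G01"][fam])
        assert cross.identity <= 1 - btw + 0.12


def test_excessive_divergence_warns():
    with pytest.warns(UserWarning, match="clustering threshold"):
        b.generate_reference_operons(
            b.SimConfig(seed=1, within_cluster_divergence=0.10, gene_length_aa=60)
        )


def test_reads_are_deterministic_and_seed_sensitive():
    base = dict(n_clusters=1, genomes_per_cluster=1, gene_length_aa=60,
                n_reads=3000, cluster_abundances={1: 1e-2})
    config = b.SimConfig(seed=9, **base)
    db1, truth1 = b.generate_reference_operons(config)
    batch1 = b.generate_community_reads(config, truth1, "S1")
    db2, truth2 = b.generate_reference_operons(b.SimConfig(seed=9, **base))
    batch2 = b.generate_community_reads(b.SimConfig(seed=9, **base), truth2, "S1")
    assert db1 == db2
    assert batch1.ids == batch2.ids
    assert (batch1.seq_codes == batch2.seq_codes).all()
    other_cfg = b.SimConfig(seed=10, **base)
    db3, truth3 = b.generate_reference_operons(other_cfg)
    batch3 = b.generate_community_reads(other_cfg, truth3, "S1")
    assert (batch3.seq_codes.shape != batch1.seq_codes.shape) or (
        (batch3.seq_codes != batch1.seq_codes).any()
    )


def test_every_read_is_traceable():
    config = b.SimConfig(seed=4, n_clusters=1, genomes_per_cluster=1,
                         gene_length_aa=60, n_reads=500, cluster_abundances={1: 5e-3})
    db, truth = b.generate_reference_operons(config)
    batch = b.generate_community_reads(config, truth, "S1")
    assert len(batch) == 500
    n_signal = 0
    for read_id in batch.ids:
        assert read_id in truth.read_sources
        src = truth.read_sources[read_id]
        if src is not None:
            n_signal += 1
            assert src in truth.gene_nt
    assert n_signal > 0


def test_pure_background_maps_nowhere():
    config = b.SimConfig(seed=6, n_clusters=1, genomes_per_cluster=1,
                         gene_length_aa=100, n_reads=2000, background_fraction=1.0)
    db, truth = b.generate_reference_operons(config)
    batch = b.generate_community_reads(config, truth, "S1")
    assert all(src is None for src in truth.read_sources.values())
    assert b.map_reads(batch, db) == []


def test_signal_counts_fall_in_poisson_interval():
    """Per-family read counts land inside the 99% interval around a*n."""
    config = b.SimConfig(seed=8, n_clusters=1, genomes_per_cluster=1,
                         gene_length_aa=100, n_reads=20000, cluster_abundances={1: 1e-3})
    db, truth = b.generate_reference_operons(config)
    b.generate_community_reads(config, truth, "S1")
    counts = {fam: 0 for fam in b.DEFAULT_FAMILIES}
    for src in truth.read_sources.values():
        if src is not None:
            counts[src[1]] += 1
    mu = 1e-3 * 20000
    lo, hi = sps.poisson.ppf([0.005, 0.995], mu)
    for fam, count in counts.items():
        assert lo <= count <= hi, (fam, count)


def test_overcommitted_abundances_rejected():
    with pytest.raises(ValueError, match="exceed 1"):
        b.SimConfig(seed=1, cluster_abundances={1: 0.2}, background_fraction=0.5,
                    genomes_per_cluster=2)


def test_zero_read_warning_logged(caplog):
    config = b.SimConfig(seed=5, n_clusters=1, genomes_per_cluster=1,
                         gene_length_aa=60, n_reads=100, cluster_abundances={1: 1e-4})
    db, truth = b.generate_reference_operons(config)
    with caplog.at_level(logging.WARNING, logger="baiscan.synthetic"):
        b.generate_community_reads(config, truth, "S1")
    assert any("expected read count < 1" in r.message for r in caplog.records)


def test_qc_fail_fraction_controls_dropped_reads():
    config = b.SimConfig(seed=12, n_clusters=1, genomes_per_cluster=1,
                         gene_length_aa=60, n_reads=4000, qc_fail_fraction=0.25)
    db, truth = b.generate_reference_operons(config)
    batch = b.generate_community_reads(config, truth, "S1")
    _, report = b.qc_batch(batch.qualities, batch.lengths)
    assert report.dropped_short / report.input_reads == pytest.approx(0.25, abs=0.03)


def test_noiseless_metabolome_follows_threshold_rule():
    config = b.SimConfig(seed=13, n_clusters=1, genomes_per_cluster=1,
                         gene_length_aa=60, n_reads=200, phenotype_noise_sd=0.0)
    db, truth = b.generate_reference_operons(config)
    for i, level in enumerate([0.0, 1e-8, 1e-6, 1e-4]):
        abundances = {
            ("C01G01", fam): level for fam in b.DEFAULT_FAMILIES if level > 0
        }
        b.generate_community_reads(config, truth, f"S{i}", abundances)
    table = b.generate_metabolome(truth, config)
    labels = dict(zip(table.sample_id, np.where(table.DCA > table.CA, "high", "low")))
    assert labels == {"S0": "low", "S1": "low", "S2": "high", "S3": "high"}
    assert truth.phenotype_label["S3"] == b.HIGH_SBA
    assert truth.phenotype_label["S0"] == b.LOW_SBA


def test_all_below_threshold_means_all_low():
    config = b.SimConfig(seed=14, n_clusters=1, genomes_per_cluster=1,
                         gene_length_aa=60, n_reads=100, phenotype_noise_sd=0.0)
    db, truth = b.generate_reference_operons(config)
    for i in range(5):
        b.generate_community_reads(config, truth, f"S{i}", {})
    b.generate_metabolome(truth, config)
    assert set(truth.phenotype_label.values()) == {b.LOW_SBA}


def test_fmt_cohort_folds_and_coupling():
    config = b.SimConfig(seed=15, n_fmt_subjects=10, n_fmt_engrafters=5)
    cohort, truth = b.generate_fmt_cohort(config)
    assert len(cohort) == 10
    folds = {s.subject_id: b.fmt_fold_change(s) for s in cohort}
    for series in cohort:
        if truth.fmt_engrafter[series.subject_id]:
            # pre at the 1e-9 floor, post at 1e-6 -> fold 1e3
            assert folds[series.subject_id] == pytest.approx(1e3)
            assert series.response
        else:
            assert folds[series.subject_id] == pytest.approx(1.0)
            assert not series.response
    res = b.fmt_response_association(
        list(folds.values()), [s.response for s in cohort]
    )
    assert res.auc == 1.0


def test_fmt_donors_exceed_pre_transplant_abundance():
    config = b.SimConfig(seed=16)
    cohort, _ = b.generate_fmt_cohort(config)
    from baiscan.cohort_stats import series_operon_abundances

    pre_all, donor_all = [], []
    for series in cohort:
        pre, _, donor = series_operon_abundances(series)
        pre_all.extend(pre)
        donor_all.extend(donor)
    assert np.mean(donor_all) > np.mean(pre_all)
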
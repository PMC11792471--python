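"""Translated-read mapping and abundance arithmetic."""

import numpy as np
import pytest

import baiscan as b
from baiscan.synthetic import _reverse_translate
from baiscan.translate import encode_nt, decode_nt, revcomp_codes

from .test_align import AA20, substitute


@pytest.fixture(scope="module")
def genome_db(single_genome_reference):
    config, db, truth = single_genome_reference
    return config, db, truth, b.ReferenceIndex(db)


def read_from_gene(truth, family, start, length, genome="C01G01", reverse=False):
    nt = truth.gene_nt[(genome, family)]
    fragment = nt[start : start + length]
    if reverse:
        fragment = decode_nt(revcomp_codes(encode_nt(fragment)))
    return fragment


def test_exact_fragment_maps_at_full_identity(genome_db):
    config, db, truth, index = genome_db
    for reverse in (False, True):
        read = read_from_gene(truth, "baiF", start=31, length=150, reverse=reverse)
        hit = b.map_read(read, db, index=index)
        assert hit is not None
        assert hit.family == "baiF"
        assert hit.identity == 1.0
        assert hit.alignment_length >= 49


def test_identity_boundary_three_vs_four_substitutions(genome_db):
    """27/30 matches (0.90) is kept; 26/30 (0.867) falls below the cutoff."""
    config, db, truth, index = genome_db
    peptide = truth.gene_aa[("C01G01", "baiG")][10:40]  # 30 aa
    rng = np.random.default_rng(3)
    for n_sub, expect_hit in ((3, True), (4, False)):
        mutated = substitute(peptide, [8, 14, 20, 26][:n_sub])
        read = _reverse_translate(mutated, rng)
        hit = b.map_read(read, db, index=index)
        if expect_hit:
            assert hit is not None
            assert hit.alignment_length == 30
            assert hit.identity == pytest.approx(27 / 30)
        else:
            assert hit is None


def test_short_alignment_rejected_at_24_aa(genome_db):
    """A 72-nt read translates to 24 aa, below the 25-aa floor."""
    config, db, truth, index = genome_db
    read = read_from_gene(truth, "baiA", start=30, length=72)
    assert b.map_read(read, db, index=index) is None
    read_75 = read_from_gene(truth, "baiA", start=30, length=75)
    hit = b.map_read(read_75, db, index=index)
    assert hit is not None and hit.alignment_length == 25


def test_best_hit_tie_breaks_to_smallest_sequence_id(genome_db):
    config, db, truth, index = genome_db
    # two identical references in different genomes -> equal scores
    entries = list(db.entries)
    clone = b.ReferenceSequence("A0_clone", "ZGEN", "baiA", truth.gene_aa[("C01G01", "baiA")])
    db2 = b.ReferenceDB(entries + [clone])
    read = read_from_gene(truth, "baiA", start=0, length=150)
    hit = b.map_read(read, db2)
    assert hit.sequence_id == "A0_clone"  # lexicographically before C01G01_baiA


def test_gene_relative_abundances():
    counts = {fam: 100 for fam in b.DEFAULT_FAMILIES}
    fracs = b.gene_relative_abundances(counts, 10**5)
    assert all(v == pytest.approx(1e-3) for v in fracs.values())
    fracs = b.gene_relative_abundances({"baiA": 8}, 10**6)
    assert fracs["baiA"] == pytest.approx(8e-6)
    assert sum(v == 0 for v in fracs.values()) == 7
    assert all(v == 0 for v in b.gene_relative_abundances({}, 100).values())
    with pytest.raises(ValueError):
        b.gene_relative_abundances(counts, 0)


def test_operon_abundance_geometric_mean_rules():
    assert b.operon_abundance([1e-6] * 8) == pytest.approx(1e-6)
    assert b.operon_abundance([1e-5] * 4 + [0.0] * 4) == pytest.approx(1e-7)
    assert b.operon_abundance([0.0] * 8) == pytest.approx(1e-9)
    with pytest.raises(ValueError):
        b.operon_abundance([1e-6] * 7)


def test_operon_abundance_monotone_in_added_reads():
    counts = {fam: i for i, fam in enumerate(b.DEFAULT_FAMILIES)}
    denominator = 10**4
    previous = b.operon_abundance(b.gene_relative_abundances(counts, denominator))
    for fam in b.DEFAULT_FAMILIES:
        counts[fam] += 5
        current = b.operon_abundance(b.gene_relative_abundances(counts, denominator))
        assert current >= previous
        previous = current


def test_detection_scale_invariance():
    counts = {fam: c for fam, c in zip(b.DEFAULT_FAMILIES, [3, 0, 1, 7, 2, 0, 5, 1])}
    one = b.gene_relative_abundances(counts, 1000)
    two = b.gene_relative_abundances({f: 2 * c for f, c in counts.items()}, 2000)
    assert one == two


def make_hit(read_id, family, cluster):
    return b.ReadHit(read_id, f"seq_{family}_{cluster}", family, f"G{cluster}",
                     1.0, 30, 150, cluster_id=cluster)


def test_cluster_detection_needs_four_families():
    hits4 = [make_hit(f"r{i}", fam, 1) for i, fam in enumerate(b.DEFAULT_FAMILIES[:4])]
    _, _, detected = b.cluster_profiles(hits4, 1000)
    assert detected[1] is True
    hits3 = [make_hit(f"r{i}", fam, 2) for i, fam in enumerate(b.DEFAULT_FAMILIES[:3])]
    _, _, detected = b.cluster_profiles(hits3, 1000)
    assert detected[2] is False


def test_cluster_counts_conserve_overall_counts():
    hits = [make_hit(f"r{i}", b.DEFAULT_FAMILIES[i % 8], 1 + i % 3) for i in range(50)]
    from baiscan.profiler import count_hits_by_family

    counts, abundances, _ = b.cluster_profiles(hits, 10**4)
    overall = count_hits_by_family(hits)
    for fam in b.DEFAULT_FAMILIES:
        assert sum(counts[c][fam] for c in counts) == overall[fam]
    single = [make_hit(f"s{i}", b.DEFAULT_FAMILIES[i % 8], 1) for i in range(20)]
    counts1, _, _ = b.cluster_profiles(single, 10**4)
    assert counts1[1] == count_hits_by_family(single)


def test_unassigned_cluster_is_an_error():
    hit = b.ReadHit("r1", "s1", "baiA", "G1", 1.0, 30, 150, cluster_id=None)
    with pytest.raises(ValueError, match="cluster"):
        b.cluster_profiles([hit], 1000)


def test_batch_mapping_matches_per_read_mapping(genome_db, rng):
    config, db, truth, index = genome_db
    sequences = [read_from_gene(truth, fam, 12, 150) for fam in b.DEFAULT_FAMILIES[:4]]
    sequences += ["".join("ACGT"[j] for j in rng.integers(0, 4, 150)) for _ in range(30)]
    ids = [f"r{i}" for i in range(len(sequences))]
    batch = b.ReadBatch.from_sequences(ids, sequences)
    batch_hits = {h.read_id: h for h in b.map_reads(batch, db, index=index)}
    for read_id, seq in zip(ids, sequences):
        single = b.map_read(seq, db, index=index)
        if single is None:
            assert read_id not in batch_hits
        else:
            got = batch_hits[read_id]
            assert (got.sequence_id, got.family, got.identity, got.score) == (
                single.sequence_id, single.family, single.identity, single.score
            )
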
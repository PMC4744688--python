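import numpy as np
import pytest

from repeatskim.clustering import RepeatCluster
from repeatskim.preprocess import ReadSet, preprocess_reads
from repeatskim.quantify import (
    HitRecord,
    cross_species_abundance,
    expansion_accounting,
    filter_hits,
    genome_proportion,
    map_reads_to_contigs,
    minimum_baseline_mb,
)
from repeatskim import simulate
from repeatskim.simulate import FamilySpec, SimScenario

from conftest import random_seq


def _hit(read_id="r", contig_id="c", bp=400, cov=1.0, ident=100.0):
    return HitRecord(read_id, contig_id, bp, cov, ident, score=bp)


def test_mapping_perfect_substring(rng):
    contig = random_seq(rng, 1200)
    rs = ReadSet("x", [("r1", contig[300:700])])
    hits = map_reads_to_contigs(rs, [("CL1contig1", contig)])
    assert len(hits) == 1
    h = hits[0]
    assert h.query_coverage == 1.0
    assert h.identity_pct == 100.0
    assert h.matched_query_bp == 400


def test_mapping_tie_goes_to_lexicographically_smaller_contig(rng):
    contig = random_seq(rng, 800)
    rs = ReadSet("x", [("r1", contig[100:500])])
    hits = map_reads_to_contigs(rs, [("CLB", contig), ("CLA", contig)])
    assert hits[0].contig_id == "CLA"


def test_mapping_empty_contig_set(rng):
    assert map_reads_to_contigs(ReadSet("x", [("r", random_seq(rng, 400))]), []) == []


def test_hit_filter_boundaries_are_inclusive():
    hits = [
        _hit("a", bp=220, cov=0.55, ident=91.0),   # exactly at both cuts
        _hit("b", bp=219, cov=219 / 400, ident=95.0),
        _hit("c", bp=360, cov=0.9, ident=89.9),
    ]
    kept = filter_hits(hits)
    assert [h.read_id for h in kept] == ["a"]


def test_genome_proportion_hand_fixture():
    """10 x 400 bp reads, 3 full-length hits to one cluster -> GP 30.00%."""
    cluster = RepeatCluster("CL1", set(), 0.0, contigs=[("CL1contig1", "")])
    hits = [_hit(f"r{i}", "CL1contig1") for i in range(3)]
    table = genome_proportion(hits, [cluster], dataset_bp=4000, genome_size_mb=100.0)
    row = table.iloc[0]
    assert row.gp_pct == pytest.approx(30.0)
    assert row.abundance_mb == pytest.approx(30.0)


def test_abundance_reproduces_reported_scale():
    """GP 21.00% of a 44 940 Mb genome is 9 437 Mb, i.e. 9.44 Gb."""
    cluster = RepeatCluster("CL1", set(), 0.0, contigs=[("CL1contig1", "")])
    hits = [_hit(f"r{i}", "CL1contig1") for i in range(21)]
    table = genome_proportion(hits, [cluster], dataset_bp=40_000, genome_size_mb=44_940.0)
    assert table.iloc[0].gp_pct == pytest.approx(21.0)
    assert round(table.iloc[0].abundance_mb / 1000, 2) == 9.44


def test_no_hits_gives_zero_gp():
    cluster = RepeatCluster("CL1", set(), 0.0, contigs=[("CL1contig1", "")])
    table = genome_proportion([], [cluster], 4000, 100.0)
    assert table.iloc[0].gp_pct == 0.0 and table.iloc[0].abundance_mb == 0.0


def test_gp_scale_invariance_under_read_duplication(rng):
    contig = random_seq(rng, 1200)
    reads = [(f"r{i}", contig[i * 150 : i * 150 + 400]) for i in range(4)]
    reads += [(f"bg{i}", random_seq(rng, 400)) for i in range(4)]
    rs1 = ReadSet("x", reads)
    rs2 = ReadSet("x", reads + [(rid + "_copy", seq) for rid, seq in reads])
    cluster = RepeatCluster("CL1", set(), 0.0, contigs=[("CL1contig1", contig)])
    tables = []
    for rs in (rs1, rs2):
        hits = filter_hits(map_reads_to_contigs(rs, cluster.contigs))
        tables.append(genome_proportion(hits, [cluster], rs.total_bp, 100.0))
    assert tables[0].iloc[0].gp_pct == pytest.approx(tables[1].iloc[0].gp_pct)


def test_identical_species_get_identical_tables(rng):
    contig = random_seq(rng, 1000)
    reads = [("r1", contig[0:400]), ("r2", contig[300:700]), ("r3", random_seq(rng, 400))]
    rs_a = ReadSet("A", reads)
    rs_b = ReadSet("B", reads)
    cluster = RepeatCluster("CL1", set(), 0.0, contigs=[("CL1contig1", contig)])
    table = cross_species_abundance(
        [rs_a, rs_b], cluster.contigs, [cluster], {"A": 100.0, "B": 100.0}
    )
    a = table[table.species_id == "A"].reset_index(drop=True)
    b = table[table.species_id == "B"].reset_index(drop=True)
    assert (a.gp_pct == b.gp_pct).all()
    assert minimum_baseline_mb(table, "A") == pytest.approx(float(b.abundance_mb.sum()))


def test_expansion_accounting_reported_examples():
    first = expansion_accounting(44.94, 35.226, 9.44, 0.20)
    assert first.expansion_gb == 9.71
    assert first.attributable_gb == 9.24
    assert first.pct_of_expansion_attributable == 95

    second = expansion_accounting(45.59, 36.192, 3.95, 0.101)
    assert second.attributable_gb == 3.85
    assert second.pct_of_expansion_attributable == 41
    assert second.pct_of_expansion_from_top == 42

    flat = expansion_accounting(10.0, 5.0, 2.0, 2.0)
    assert flat.attributable_gb == 0.0 and flat.pct_of_expansion_attributable == 0

    shrunk = expansion_accounting(5.0, 6.0, 1.0, 0.1)
    assert not shrunk.expanded and shrunk.pct_of_expansion_attributable is None


def test_gp_estimator_is_nearly_unbiased_over_replicates():
    """Mean GP estimate over 20 re-skims of one genome stays within 10%
    relative of the planted proportion for full-length (4 kb) elements."""
    families = [
        FamilySpec("famA", 4000, 20, divergence=(0.0, 0.01)),
        FamilySpec("famB", 4000, 12, divergence=(0.0, 0.03)),
        FamilySpec("famC", 4000, 8, divergence=(0.0, 0.05)),
    ]
    sc = SimScenario(
        seed=77, genome_length_bp=500_000, families=families, n_reads=1000,
        error_rate=0.005, duplicate_fraction=0.0, organelle_fraction=0.0,
    )
    genome, truth = simulate.simulate_genome(sc)
    # reference contigs: one representative planted copy per family
    contigs, clusters = [], []
    for fam in families:
        s, e = next(
            (iv[2], iv[3]) for iv in truth.copy_intervals if iv[0] == fam.family_id
        )
        cid = f"{fam.family_id}contig1"
        contigs.append((cid, genome[s:e]))
        clusters.append(RepeatCluster(fam.family_id, set(), 0.0, contigs=[(cid, genome[s:e])]))
    est = {f.family_id: [] for f in families}
    for rep in range(20):
        reads = simulate.sample_reads(genome, sc, truth, read_seed=1000 + rep)
        nuclear = preprocess_reads(reads).nuclear
        hits = filter_hits(map_reads_to_contigs(nuclear, contigs))
        table = genome_proportion(hits, clusters, nuclear.total_bp, 100.0)
        for row in table.itertuples():
            est[row.cluster_id].append(row.gp_pct / 100.0)
    rel_bias = [
        abs(np.mean(est[f.family_id]) - truth.family_proportions[f.family_id])
        / truth.family_proportions[f.family_id]
        for f in families
    ]
    assert float(np.mean(rel_bias)) < 0.10
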
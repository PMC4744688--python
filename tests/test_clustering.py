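import networkx as nx
import numpy as np
import pytest

from repeatskim.align import revcomp
from repeatskim.clustering import (
    RepeatCluster,
    annotate_cluster,
    assemble_contigs,
    cluster_graph,
    merge_clusters,
    select_top_families,
    tandem_period,
)
from repeatskim.graph import pairwise_overlaps
from repeatskim.preprocess import ReadSet

from conftest import mutate, random_seq


def test_disconnected_families_become_separate_clusters(rng):
    src1, src2 = random_seq(rng, 600), random_seq(rng, 600)
    reads = []
    for i, src in enumerate((src1, src2)):
        for j in range(4):
            reads.append((f"f{i}_r{j}", src[j * 50 : j * 50 + 400]))
    rs = ReadSet("x", reads)
    g = pairwise_overlaps(rs, method="full")
    clusters = cluster_graph(g, rs)
    non_singleton = [c for c in clusters if c.n_reads > 1]
    assert len(non_singleton) == 2
    got = {frozenset(c.member_read_ids) for c in non_singleton}
    want = {
        frozenset(f"f0_r{j}" for j in range(4)),
        frozenset(f"f1_r{j}" for j in range(4)),
    }
    assert got == want
    assert sum(c.input_read_fraction for c in clusters) == pytest.approx(1.0)


def test_empty_graph_yields_singletons(rng):
    rs = ReadSet("x", [(f"r{i}", random_seq(rng, 400)) for i in range(5)])
    g = nx.Graph()
    g.add_nodes_from(rid for rid, _ in rs.reads)
    clusters = cluster_graph(g, rs)
    assert len(clusters) == 5
    assert all(c.n_reads == 1 for c in clusters)


def test_cluster_graph_matches_brute_force_components(family_readset):
    g = pairwise_overlaps(family_readset, method="full")
    clusters = cluster_graph(g, family_readset)
    want = [set(c) for c in nx.connected_components(g)]
    got = [c.member_read_ids for c in clusters if c.n_reads > 1]
    assert all(c in want for c in got)
    all_ids = set().union(*(c.member_read_ids for c in clusters))
    assert all_ids == {rid for rid, _ in family_readset.reads}


def _fake_clusters(n_a=100, n_b=40, label_a="Gypsy-LTR", label_b="Gypsy-LTR"):
    a = RepeatCluster("CL1", {f"a{i}" for i in range(n_a)}, n_a / 140, annotation=label_a)
    b = RepeatCluster("CL2", {f"b{i}" for i in range(n_b)}, n_b / 140, annotation=label_b)
    reads = ReadSet("x", [(f"a{i}", "A" * 10) for i in range(n_a)] + [(f"b{i}", "A" * 10) for i in range(n_b)])
    return [a, b], reads


def test_merge_requires_five_percent_of_smaller_cluster():
    clusters, reads = _fake_clusters()
    evidence = {("b0", "a0"), ("b1", "a5")}  # 2/40 = 5% of the smaller
    merged = merge_clusters(clusters, reads, evidence_pairs=evidence)
    assert len(merged) == 1 and merged[0].n_reads == 140

    evidence = {("b0", "a0")}  # 2.5%: below threshold
    merged = merge_clusters(clusters, reads, evidence_pairs=evidence)
    assert len(merged) == 2


def test_merge_requires_matching_annotation():
    clusters, reads = _fake_clusters(label_b="Copia-LTR")
    evidence = {(f"b{i}", "a0") for i in range(10)}
    assert len(merge_clusters(clusters, reads, evidence_pairs=evidence)) == 2
    # 'unknown' matches nothing, even against itself
    clusters, reads = _fake_clusters(label_a="unknown", label_b="unknown")
    assert len(merge_clusters(clusters, reads, evidence_pairs=evidence)) == 2


def test_merge_is_transitive_and_preserves_reads():
    a = RepeatCluster("CL1", {f"a{i}" for i in range(50)}, 0.5, annotation="Gypsy-LTR")
    b = RepeatCluster("CL2", {f"b{i}" for i in range(30)}, 0.3, annotation="Gypsy-LTR")
    c = RepeatCluster("CL3", {f"c{i}" for i in range(20)}, 0.2, annotation="Gypsy-LTR")
    reads = ReadSet(
        "x", [(rid, "A" * 10) for cl in (a, b, c) for rid in sorted(cl.member_read_ids)]
    )
    evidence = {(f"b{i}", f"a{i}") for i in range(5)} | {(f"c{i}", f"b{i}") for i in range(5)}
    merged = merge_clusters([a, b, c], reads, evidence_pairs=evidence)
    assert len(merged) == 1
    assert merged[0].n_reads == 100


def test_assembly_reconstructs_tiled_source(rng):
    src = random_seq(rng, 1000)
    windows = [src[s : s + 400] for s in (0, 200, 400, 600)]
    windows[2] = revcomp(windows[2])  # one read on the other strand
    rs = ReadSet("x", [(f"r{i}", w) for i, w in enumerate(windows)])
    cluster = RepeatCluster("CL1", {f"r{i}" for i in range(4)}, 1.0)
    contigs = assemble_contigs(cluster, rs, min_overlap=160)
    assert len(contigs) == 1
    cid, consensus = contigs[0]
    assert cid == "CL1contig1"
    assert consensus in (src, revcomp(src))


def test_assembly_boundary_cases(rng):
    single = RepeatCluster("CL9", {"only"}, 1.0)
    rs = ReadSet("x", [("only", random_seq(rng, 400))])
    assert assemble_contigs(single, rs) == [("CL9contig1", rs.as_dict()["only"])]

    src = random_seq(rng, 650)
    a, b = src[:400], src[250:650]  # 150 bp overlap < 160 threshold
    rs = ReadSet("x", [("a", a), ("b", b)])
    cluster = RepeatCluster("CL2", {"a", "b"}, 1.0)
    contigs = assemble_contigs(cluster, rs, min_overlap=160)
    assert len(contigs) == 2


def test_top_family_threshold_is_inclusive():
    mk = lambda i, frac: RepeatCluster(f"CL{i}", set(), frac)
    clusters = [mk(1, 500 / 1e6), mk(2, 499 / 1e6), mk(3, 0.2)]
    top = select_top_families(clusters, 0.0005)
    assert [c.cluster_id for c in top] == ["CL1", "CL3"]


def test_annotation_by_library_votes(rng):
    element = random_seq(rng, 1500)
    reads = [
        (f"r{i}", mutate(rng, element[i * 100 : i * 100 + 400], 4)) for i in range(8)
    ]
    rs = ReadSet("x", reads)
    cluster = RepeatCluster("CL1", {rid for rid, _ in reads}, 1.0)
    library = [("FRI-1#Gypsy-LTR", element), ("FRI-2#Copia-LTR", random_seq(rng, 1500))]
    assert annotate_cluster(cluster, rs, library) == "Gypsy-LTR"


def test_annotation_tandem_and_unknown(rng):
    monomer = random_seq(rng, 25)
    satellite = (monomer * 40)[:800]
    assert tandem_period(satellite) == 25
    assert tandem_period(random_seq(rng, 800)) is None

    rs = ReadSet("x", [("r0", satellite[:400])])
    cluster = RepeatCluster("CL1", {"r0"}, 1.0, contigs=[("CL1contig1", satellite)])
    assert annotate_cluster(cluster, rs, ref_library=None) == "tandem"

    plain = RepeatCluster(
        "CL2", {"r0"}, 1.0, contigs=[("CL2contig1", random_seq(rng, 800))]
    )
    assert annotate_cluster(plain, rs, ref_library=[]) == "unknown"
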
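import numpy as np
import pytest

from repeatskim.clustering import RepeatCluster
from repeatskim.graph import pairwise_overlaps
from repeatskim.heterogeneity import (
    REGIME_ACCUMULATION,
    REGIME_BURST,
    REGIME_INDETERMINATE,
    HeterogeneityProfile,
    classify_regime,
    profile_cluster,
    regime_summary,
)
from repeatskim.preprocess import ReadSet, preprocess_reads
from repeatskim import simulate
from repeatskim.simulate import FamilySpec, SimScenario

from conftest import random_seq


def test_clique_of_identical_reads_is_pure_high_identity(rng):
    seq = random_seq(rng, 400)
    rs = ReadSet("x", [(f"r{i}", seq) for i in range(10)])
    g = pairwise_overlaps(rs)
    cluster = RepeatCluster("CL1", {rid for rid, _ in rs.reads}, 1.0)
    profile = profile_cluster(g, cluster)
    assert profile.n_edges == 45
    assert profile.high_identity_fraction == 1.0
    assert profile.avg_edge_weight == pytest.approx(400.0)
    assert profile.regime_call == REGIME_BURST


def _profile(frac, edges, members=50):
    return HeterogeneityProfile("CL", members, edges, 0.0, {}, frac, "?")


def test_classification_thresholds():
    assert classify_regime(_profile(0.50, 100)) == REGIME_BURST
    assert classify_regime(_profile(0.02, 1000)) == REGIME_ACCUMULATION
    assert classify_regime(_profile(0.50, 20)) == REGIME_INDETERMINATE
    assert classify_regime(_profile(1.0, 100, members=1)) == REGIME_INDETERMINATE


def test_regime_summary_counts():
    profiles = [_profile(0.5, 100), _profile(0.0, 100), _profile(0.0, 10)]
    for p in profiles:
        p.regime_call = classify_regime(p)
    summary = regime_summary(profiles)
    assert (summary["n_burst"], summary["n_accumulation"], summary["n_indeterminate"]) == (1, 1, 1)
    empty = regime_summary([])
    assert empty["n_burst"] == 0 and empty["avg_edge_weight_histogram"] == {}


def _simulate_families(seed, divergences, copies=60, n_reads=420):
    families = [
        FamilySpec(f"fam{i}", 1000, copies, divergence=d)
        for i, d in enumerate(divergences)
    ]
    sc = SimScenario(
        seed=seed,
        genome_length_bp=len(families) * copies * 1000 + (len(families) * copies + 1) * 400 + 40_000,
        families=families,
        n_reads=n_reads * len(families),
        error_rate=0.005,
        duplicate_fraction=0.0,
        organelle_fraction=0.0,
    )
    genome, truth = simulate.simulate_genome(sc)
    reads = simulate.sample_reads(genome, sc, truth)
    nuclear = preprocess_reads(reads).nuclear
    kept = {rid for rid, _ in nuclear.reads}
    seq_by_id = nuclear.as_dict()
    fam_members = {
        f.family_id: truth.reads_from_family(f.family_id) & kept for f in families
    }
    member_ids = sorted(set().union(*fam_members.values()))
    fam_rs = ReadSet("x", [(rid, seq_by_id[rid]) for rid in member_ids])
    g = pairwise_overlaps(fam_rs, min_overlap=220, min_identity=70.0, seed_k=10)
    return {
        fid: profile_cluster(g, RepeatCluster(fid, members, 0.0))
        for fid, members in fam_members.items()
    }


def test_burst_and_accumulation_families_are_separable():
    profiles = _simulate_families(5, [(0.0, 0.01), (0.02, 0.30)])
    assert profiles["fam0"].regime_call == REGIME_BURST
    assert profiles["fam1"].regime_call == REGIME_ACCUMULATION
    # a recent burst also shows the heavier average edge weight
    assert profiles["fam0"].avg_edge_weight > profiles["fam1"].avg_edge_weight
    # and its identity histogram mass is concentrated at >= 98%
    hist = profiles["fam1"].identity_histogram
    high = sum(v for k, v in hist.items() if k >= 98)
    assert high < 0.10 * sum(hist.values())


def test_high_identity_fraction_decreases_with_divergence():
    """More diverged families never look more burst-like (checked on the
    mean over seeded replicates)."""
    levels = [(0.0, 0.005), (0.0, 0.05), (0.10, 0.30)]
    means = []
    for level in levels:
        vals = [
            _simulate_families(100 + rep, [level], copies=40, n_reads=200)["fam0"].high_identity_fraction
            for rep in range(3)
        ]
        means.append(np.mean(vals))
    assert means[0] >= means[1] >= means[2]
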
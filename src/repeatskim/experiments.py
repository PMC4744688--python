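"""Self-contained recovery experiments on synthetic data.

Each experiment builds a scene with the synthetic-data generator, runs the
relevant pipeline stages and scores the result against the generator's
ground truth.  They are the package's standard validation battery: the test
suite and the reproduction script both call them, so the numbers they
return are always recomputed, never stored.

Scene sizes are chosen to finish on a single CPU in minutes while keeping
every family large enough for its statistics to be stable; see
docs/methods.md for the rationale behind each scenario.
"""

from __future__ import annotations

import numpy as np

from . import clustering, graph, heterogeneity, quantify, simulate
from .ancestral import boxcox, fit_trait_model, inv_boxcox
from .preprocess import preprocess_reads
from .simulate import FamilySpec, SimScenario


def _subseed(seed: int, tag: int) -> int:
    return int(np.random.SeedSequence([seed, tag]).generate_state(1)[0] % (2**31 - 1))


# ---------------------------------------------------------------------------
# Clustering + quantification recovery
# ---------------------------------------------------------------------------

def clustering_scenario(seed: int) -> SimScenario:
    """Ten 2-kb repeat families with a skewed copy-number spectrum in a 1 Mb
    genome, 2500 x 400 bp reads at 0.5% sequencing error.

    Abundant families are more homogeneous (recently amplified), rarer ones
    more diverged, with pairwise internal divergence capped at 20%.
    """
    copy_numbers = [50, 35, 25, 20, 15, 12, 10, 8, 6, 5]
    u_max = [0.005, 0.01, 0.02, 0.03, 0.04, 0.05, 0.06, 0.07, 0.08, 0.03]
    families = [
        FamilySpec(
            family_id=f"fam{i + 1:02d}",
            element_length=2000,
            copy_number=cn,
            regime="burst" if um <= 0.01 else "accumulation",
            divergence=(0.0, um),
        )
        for i, (cn, um) in enumerate(zip(copy_numbers, u_max))
    ]
    return SimScenario(
        seed=seed,
        genome_length_bp=1_000_000,
        families=families,
        n_reads=2500,
        error_rate=0.005,
        duplicate_fraction=0.0,
        organelle_fraction=0.0,
    )


def clustering_quantification_experiment(
    seed: int, n_replicates: int = 20, scenario: SimScenario | None = None
) -> dict:
    """Cluster one skim of the scenario genome and score the partition
    against the planted families (adjusted Rand index over repeat-derived
    reads); then re-skim the same genome ``n_replicates`` times and check
    per-family genome-proportion estimates against the planted proportions
    on the 3-binomial-SE scale."""
    from sklearn.metrics import adjusted_rand_score

    sc = scenario if scenario is not None else clustering_scenario(_subseed(seed, 10))
    genome, truth = simulate.simulate_genome(sc)
    reads = simulate.sample_reads(genome, sc, truth)
    nuclear = preprocess_reads(reads).nuclear
    kept = {rid for rid, _ in nuclear.reads}

    g = graph.pairwise_overlaps(nuclear)
    clusters = clustering.cluster_graph(g, nuclear)

    fam_of = {
        rid: p["origin"]
        for rid, p in truth.read_provenance.items()
        if p["origin"].startswith("fam") and rid in kept
    }
    cluster_of = {
        rid: c.cluster_id for c in clusters for rid in c.member_read_ids
    }
    fam_reads = sorted(fam_of)
    ari = adjusted_rand_score(
        [fam_of[r] for r in fam_reads], [cluster_of[r] for r in fam_reads]
    )

    # map clusters to the family contributing most of their reads
    cluster_family: dict[str, str] = {}
    for c in clusters:
        votes: dict[str, int] = {}
        for rid in c.member_read_ids:
            fam = fam_of.get(rid)
            if fam:
                votes[fam] = votes.get(fam, 0) + 1
        if votes:
            best = max(votes.items(), key=lambda kv: (kv[1], kv[0]))
            if best[1] >= 0.5 * c.n_reads:
                cluster_family[c.cluster_id] = best[0]

    for c in clusters:
        c.contigs = clustering.assemble_contigs(c, nuclear)
    contigs = [ct for c in clusters for ct in c.contigs]
    contig_family = {}
    for c in clusters:
        fam = cluster_family.get(c.cluster_id)
        if fam:
            for cid, _ in c.contigs:
                contig_family[cid] = fam

    n_within = 0
    n_total = 0
    gp_rel_errors = []
    gp_estimates: dict[str, list[float]] = {f: [] for f in truth.family_proportions}
    for rep in range(n_replicates):
        rep_reads = simulate.sample_reads(
            genome, sc, truth, read_seed=_subseed(seed, 100 + rep)
        )
        rep_nuclear = preprocess_reads(rep_reads).nuclear
        hits = quantify.filter_hits(
            quantify.map_reads_to_contigs(rep_nuclear, contigs)
        )
        bp_by_family: dict[str, int] = {}
        for h in hits:
            fam = contig_family.get(h.contig_id)
            if fam:
                bp_by_family[fam] = bp_by_family.get(fam, 0) + h.matched_query_bp
        n_reads_eff = len(rep_nuclear)
        for fam in truth.family_proportions:
            p_true = truth.family_proportions[fam]
            gp_est = bp_by_family.get(fam, 0) / rep_nuclear.total_bp
            se = np.sqrt(p_true * (1 - p_true) / n_reads_eff)
            n_total += 1
            if abs(gp_est - p_true) <= 3 * se:
                n_within += 1
            gp_rel_errors.append(abs(gp_est - p_true) / p_true)
            gp_estimates[fam].append(gp_est)

    rel_bias = [
        abs(float(np.mean(v)) - truth.family_proportions[f]) / truth.family_proportions[f]
        for f, v in gp_estimates.items()
    ]
    return {
        "ari": float(ari),
        "gp_within_3se_fraction": n_within / n_total,
        "gp_mean_rel_error": float(np.mean(gp_rel_errors)),
        "gp_mean_abs_rel_bias": float(np.mean(rel_bias)),
        "n_family_reads": len(fam_reads),
        "n_clusters": len(clusters),
        "n_replicates": n_replicates,
    }


# ---------------------------------------------------------------------------
# Amplification-regime classification
# ---------------------------------------------------------------------------

def regime_scenario(seed: int) -> SimScenario:
    """Two recent-burst and two long-term-accumulation families, sized so
    every family draws at least ~50 reads from an 800-read skim."""
    families = [
        FamilySpec("burst1", 1000, 30, "burst"),
        FamilySpec("burst2", 1000, 30, "burst"),
        FamilySpec("accum1", 1000, 100, "accumulation"),
        FamilySpec("accum2", 1000, 100, "accumulation"),
    ]
    return SimScenario(
        seed=seed,
        genome_length_bp=480_000,
        families=families,
        n_reads=800,
        error_rate=0.005,
        duplicate_fraction=0.0,
        organelle_fraction=0.0,
    )


def regime_experiment(seed: int, n_replicates: int = 20) -> dict:
    """Classify planted families as burst vs accumulation from their
    member-pair similarity profile; returns accuracy over all replicates."""
    n_correct = 0
    n_families = 0
    n_indeterminate = 0
    min_family_reads = None
    for rep in range(n_replicates):
        sc = regime_scenario(_subseed(seed, 200 + rep))
        genome, truth = simulate.simulate_genome(sc)
        reads = simulate.sample_reads(genome, sc, truth)
        nuclear = preprocess_reads(reads).nuclear
        kept = {rid for rid, _ in nuclear.reads}
        fam_members = {
            f.family_id: truth.reads_from_family(f.family_id) & kept
            for f in sc.families
        }
        member_ids = sorted(set().union(*fam_members.values()))
        seq_by_id = nuclear.as_dict()
        fam_readset = simulate.ReadSet(
            nuclear.species_id, [(rid, seq_by_id[rid]) for rid in member_ids]
        )
        hg = graph.pairwise_overlaps(
            fam_readset, min_overlap=220, min_identity=70.0, seed_k=10
        )
        for f in sc.families:
            members = fam_members[f.family_id]
            sz = len(members)
            min_family_reads = sz if min_family_reads is None else min(min_family_reads, sz)
            cluster = clustering.RepeatCluster(f.family_id, members, 0.0)
            profile = heterogeneity.profile_cluster(hg, cluster)
            n_families += 1
            if profile.regime_call == f.regime:
                n_correct += 1
            elif profile.regime_call == heterogeneity.REGIME_INDETERMINATE:
                n_indeterminate += 1
    return {
        "accuracy": n_correct / n_families,
        "n_families": n_families,
        "n_indeterminate": n_indeterminate,
        "min_family_reads": min_family_reads,
    }


# ---------------------------------------------------------------------------
# Ancestral-state parameter recovery
# ---------------------------------------------------------------------------

def root_recovery_experiment(
    seed: int,
    n_replicates: int = 50,
    n_trees: int = 100,
    n_tips: int = 12,
    root_gb: float = 35.0,
    sigma2: float = 1e-9,
    lam: float = -2.0,
) -> dict:
    """Brownian traits are simulated independently on each of ``n_trees``
    random trees per replicate; the per-tree GLS root estimates are averaged
    and the back-transformed t-interval checked for covering the true root.
    Coverage should sit near the nominal 95%."""
    from scipy import stats

    n_covered = 0
    for rep in range(n_replicates):
        rep_seed = _subseed(seed, 300 + rep)
        trees = simulate.random_trees(n_trees, n_tips, rep_seed)
        roots = []
        for ti, tree in enumerate(trees):
            tips, _ = simulate.simulate_traits_on_tree(
                tree, root_gb, sigma2, trend=0.0, lam=lam,
                seed=_subseed(rep_seed, ti),
            )
            yt = {sp: float(boxcox(v, lam)) for sp, v in tips.items()}
            fit = fit_trait_model(tree, yt, "bm")
            roots.append(fit.root_state)
        roots = np.array(roots)
        se = roots.std(ddof=1) / np.sqrt(n_trees)
        tq = stats.t.ppf(0.975, n_trees - 1)
        lo, hi = roots.mean() - tq * se, roots.mean() + tq * se
        lo_gb, hi_gb = sorted((float(inv_boxcox(lo, lam)), float(inv_boxcox(hi, lam))))
        if lo_gb <= root_gb <= hi_gb:
            n_covered += 1
    return {
        "coverage": n_covered / n_replicates,
        "n_replicates": n_replicates,
        "n_trees": n_trees,
        "n_tips": n_tips,
    }


# ---------------------------------------------------------------------------
# Preprocessing truth recovery
# ---------------------------------------------------------------------------

def toy_scenario(seed: int) -> SimScenario:
    """Small mixed scene exercising every preprocessing filter."""
    return SimScenario(
        seed=seed,
        genome_length_bp=200_000,
        families=[
            FamilySpec("famA", 1000, 20, "burst"),
            FamilySpec("famB", 1000, 30, "accumulation"),
        ],
        n_reads=300,
        error_rate=0.005,
        duplicate_fraction=0.08,
        organelle_fraction=0.05,
        short_read_fraction=0.05,
    )


def toy_preprocess_experiment(seed: int) -> dict:
    """Run the preprocessing chain on the toy scene and compare every filter
    count with the generator's truth."""
    sc = toy_scenario(_subseed(seed, 400))
    genome, truth = simulate.simulate_genome(sc)
    db = simulate.make_organelle_db(_subseed(seed, 401))
    reads = simulate.sample_reads(genome, sc, truth, db)
    result = preprocess_reads(reads, db)
    return {
        "duplicate_count_error": result.n_duplicates - truth.n_exact_duplicate_reads,
        "organelle_count_error": result.n_organellar - truth.n_organelle_reads,
        "short_count_error": result.n_short - truth.n_short_reads,
        "n_input": result.n_input,
        "n_nuclear": len(result.nuclear),
    }
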
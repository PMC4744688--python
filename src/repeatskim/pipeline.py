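"""End-to-end orchestration: simulate (optional) -> preprocess -> graph ->
cluster -> quantify -> heterogeneity, with optional ancestral and S/L stages
when trees/traits are supplied.  One config, one seed, one manifest."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from . import (
    ancestral,
    clustering,
    graph,
    heterogeneity,
    preprocess,
    quantify,
    simulate,
    slstats,
)

DEFAULTS = {
    "preprocess": {"target_len": 400, "evalue": 1e-6},
    "graph": {"min_overlap": 220, "min_identity": 90.0, "seed_k": 16},
    "cluster": {
        "assembly_overlap": 160,
        "merge_fraction": 0.05,
        "top_fraction": 0.0005,
    },
    "quantify": {"min_query_cov": 0.55, "min_identity": 90.0},
    "heterogeneity": {
        "high_identity_cut": 98.0,
        "burst_fraction_min": 0.10,
        "profile_min_identity": 70.0,
        "profile_seed_k": 10,
    },
    "ancestral": {"lam": -2.0, "model_selection": "by_loglik"},
}


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _params(config: dict, stage: str) -> dict:
    merged = dict(DEFAULTS.get(stage, {}))
    merged.update(config.get(stage, {}) or {})
    return merged


def run_all(config: dict, outdir: str | Path) -> dict:
    """Run the configured stages; artifacts land under ``outdir`` and the
    returned manifest (also written as manifest.json) records parameters and
    per-stage counts.  Randomness flows entirely from ``config['seed']``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    manifest: dict = {"seed": seed, "stages": {}, "parameters": {}}

    # --- simulate ---------------------------------------------------------
    truth = None
    organelle_db = None
    stage = "simulate"
    try:
        sim_cfg = config.get("simulate")
        if sim_cfg:
            fams = [
                simulate.FamilySpec(
                    family_id=f["family_id"],
                    element_length=int(f["element_length"]),
                    copy_number=int(f["copy_number"]),
                    regime=f.get("regime", "accumulation"),
                    divergence=tuple(f["divergence"]) if f.get("divergence") else None,
                )
                for f in sim_cfg.get("families", [])
            ]
            sc = simulate.SimScenario(
                seed=seed,
                genome_length_bp=int(sim_cfg["genome_length_bp"]),
                families=fams,
                read_length=int(sim_cfg.get("read_length", 400)),
                n_reads=int(sim_cfg.get("n_reads", 1000)),
                error_rate=float(sim_cfg.get("error_rate", 0.005)),
                duplicate_fraction=float(sim_cfg.get("duplicate_fraction", 0.05)),
                organelle_fraction=float(sim_cfg.get("organelle_fraction", 0.02)),
                short_read_fraction=float(sim_cfg.get("short_read_fraction", 0.0)),
            )
            genome, truth = simulate.simulate_genome(sc)
            if sc.organelle_fraction > 0:
                organelle_db = simulate.make_organelle_db(seed)
            species = sim_cfg.get("species_id", "sim")
            reads = simulate.sample_reads(genome, sc, truth, organelle_db, species)
            genome_size_mb = float(
                sim_cfg.get("genome_size_mb", sc.genome_length_bp / 1e6)
            )
            reads.to_fasta(outdir / "reads.fasta")
            manifest["stages"]["simulate"] = {
                "n_reads": len(reads),
                "genome_length_bp": sc.genome_length_bp,
                "n_families": len(fams),
                "true_proportions": truth.family_proportions,
                "n_planted_duplicates": truth.n_planted_duplicates,
                "n_organelle_reads": truth.n_organelle_reads,
                "n_short_reads": truth.n_short_reads,
            }
        else:
            species_cfg = config["reads"]
            reads = preprocess.ReadSet.from_file(
                species_cfg["path"], species_cfg.get("species_id")
            )
            genome_size_mb = float(species_cfg["genome_size_mb"])
            if config.get("organelles"):
                organelle_db = preprocess.OrganelleDB.from_fasta(config["organelles"])
    except KeyError as exc:
        raise StageError(stage, KeyError(f"missing config key {exc}"))
    except Exception as exc:  # noqa: BLE001 - stage-named abort
        raise StageError(stage, exc)

    # --- preprocess -------------------------------------------------------
    stage = "preprocess"
    try:
        p = _params(config, stage)
        result = preprocess.preprocess_reads(
            reads, organelle_db, int(p["target_len"]), float(p["evalue"])
        )
        nuclear = result.nuclear
        preprocess.write_fate_log(result, outdir / "read_fates.tsv")
        nuclear.to_fasta(outdir / "nuclear_reads.fasta")
        manifest["parameters"][stage] = p
        manifest["stages"][stage] = {
            "n_input": result.n_input,
            "n_duplicates": result.n_duplicates,
            "n_organellar": result.n_organellar,
            "n_short": result.n_short,
            "n_nuclear": len(nuclear),
        }
    except Exception as exc:
        raise StageError(stage, exc)

    # --- similarity graph -------------------------------------------------
    stage = "graph"
    try:
        p = _params(config, stage)
        g = graph.pairwise_overlaps(
            nuclear,
            min_overlap=int(p["min_overlap"]),
            min_identity=float(p["min_identity"]),
            seed_k=int(p["seed_k"]),
        )
        graph.write_edge_list(g, outdir / "edges.tsv")
        graph.write_graph_summary(g, outdir / "graph_summary.json")
        manifest["parameters"][stage] = p
        manifest["stages"][stage] = {
            "n_nodes": g.number_of_nodes(),
            "n_edges": g.number_of_edges(),
        }
    except Exception as exc:
        raise StageError(stage, exc)

    # --- clustering -------------------------------------------------------
    stage = "cluster"
    try:
        p = _params(config, stage)
        clusters = clustering.cluster_graph(g, nuclear)
        clusters = clustering.merge_clusters(
            clusters, nuclear, cross_hit_fraction_min=float(p["merge_fraction"])
        )
        top = clustering.select_top_families(clusters, float(p["top_fraction"]))
        for c in clusters:
            c.contigs = clustering.assemble_contigs(
                c, nuclear, min_overlap=int(p["assembly_overlap"])
            )
        with open(outdir / "contigs.fasta", "w") as fh:
            for c in clusters:
                for cid, seq in c.contigs:
                    fh.write(f">{cid}\n{seq}\n")
        with open(outdir / "clusters.tsv", "w") as fh:
            fh.write("cluster_id\tn_reads\tfraction\tannotation\n")
            for c in clusters:
                fh.write(
                    f"{c.cluster_id}\t{c.n_reads}\t{c.input_read_fraction:.6f}\t{c.annotation}\n"
                )
        manifest["parameters"][stage] = p
        manifest["stages"][stage] = {
            "n_clusters": len(clusters),
            "n_non_singleton": sum(1 for c in clusters if c.n_reads > 1),
            "n_top_families": len(top),
        }
    except Exception as exc:
        raise StageError(stage, exc)

    # --- quantify ---------------------------------------------------------
    stage = "quantify"
    try:
        p = _params(config, stage)
        contigs = [ct for c in clusters for ct in c.contigs]
        hits = quantify.filter_hits(
            quantify.map_reads_to_contigs(nuclear, contigs),
            float(p["min_query_cov"]),
            float(p["min_identity"]),
        )
        table = quantify.genome_proportion(
            hits, clusters, nuclear.total_bp, genome_size_mb, nuclear.species_id
        )
        quantify.write_abundance_tsv(table, outdir / "abundance.tsv")
        top_ids = {c.cluster_id for c in top}
        manifest["parameters"][stage] = p
        manifest["stages"][stage] = {
            "n_retained_hits": len(hits),
            "top_gp_pct_total": round(
                float(table[table.cluster_id.isin(top_ids)].gp_pct.sum()), 4
            ),
        }
    except Exception as exc:
        raise StageError(stage, exc)

    # --- heterogeneity ----------------------------------------------------
    stage = "heterogeneity"
    try:
        p = _params(config, stage)
        hg = graph.pairwise_overlaps(
            nuclear,
            min_overlap=int(_params(config, "graph")["min_overlap"]),
            min_identity=float(p["profile_min_identity"]),
            seed_k=int(p["profile_seed_k"]),
        )
        profiles = [
            heterogeneity.profile_cluster(
                hg,
                c,
                high_identity_cut=float(p["high_identity_cut"]),
                burst_fraction_min=float(p["burst_fraction_min"]),
            )
            for c in top
        ]
        heterogeneity.write_profiles_tsv(profiles, outdir / "heterogeneity.tsv")
        manifest["parameters"][stage] = p
        manifest["stages"][stage] = heterogeneity.regime_summary(profiles)
    except Exception as exc:
        raise StageError(stage, exc)

    # --- ancestral (optional) --------------------------------------------
    if config.get("ancestral"):
        stage = "ancestral"
        try:
            p = _params(config, stage)
            trees = ancestral.load_trees(p["trees"])
            traits = ancestral.load_traits_tsv(p["traits"])
            queries = {
                name: set(tips) for name, tips in (p.get("queries") or {}).items()
            }
            estimates = ancestral.reconstruct_over_trees(
                trees,
                traits,
                queries,
                lam=float(p["lam"]),
                model_selection=p["model_selection"],
            )
            ancestral.write_estimates_tsv(estimates, outdir / "ancestral.tsv")
            manifest["parameters"][stage] = {
                k: v for k, v in p.items() if k in ("lam", "model_selection")
            }
            manifest["stages"][stage] = {
                e.node_name: round(e.mean_gb, 3) for e in estimates
            }
        except Exception as exc:
            raise StageError(stage, exc)

    # --- S/L statistics (optional) ---------------------------------------
    if config.get("slstats"):
        stage = "slstats"
        try:
            p = config["slstats"]
            raw = pd.read_csv(p["table"], sep="\t")
            table = slstats.build_sl_table(raw)
            report = slstats.correlation_report(
                table, group_col=p.get("group_col"),
            )
            table.to_csv(outdir / "sl_table.tsv", sep="\t", index=False)
            report.to_csv(outdir / "sl_correlations.tsv", sep="\t", index=False)
            manifest["stages"][stage] = {
                f"{r.sl_col}_vs_{r.size_col}": round(r.tau_b, 3)
                for r in report[report.grouping == "all"].itertuples()
            }
        except Exception as exc:
            raise StageError(stage, exc)

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
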
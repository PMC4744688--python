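"""Per-family genome-proportion / abundance estimation and the cross-species
expansion accounting.

Genome proportion (GP) of a repeat family in a read set is the percentage of
the data-set bases that fall in retained best hits to that family's contigs;
abundance in Mb is GP/100 times the species' genome size in Mb.  Only the
single best-scoring hit per read contributes, and only its top-scoring local
alignment's query bases are counted.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .align import KmerIndex, SeqKmerTable, seeded_best_alignment
from .clustering import RepeatCluster
from .preprocess import ReadSet

DEFAULT_MIN_QUERY_COV = 0.55
DEFAULT_MIN_IDENTITY = 90.0


@dataclass(frozen=True)
class HitRecord:
    read_id: str
    contig_id: str
    matched_query_bp: int
    query_coverage: float
    identity_pct: float
    score: int


def map_reads_to_contigs(
    reads: ReadSet,
    contigs: list[tuple[str, str]],
    seed_k: int = 14,
) -> list[HitRecord]:
    """Best hit per read against the contig database (either strand).

    Score ties go to the longer matched_query_bp, then the lexicographically
    smallest contig id.  Reads without any seeded candidate get no record.
    """
    if not contigs:
        return []
    index = KmerIndex(dict(contigs), k=seed_k)
    contig_tables = {cid: SeqKmerTable(seq, seed_k) for cid, seq in contigs}
    hits: list[HitRecord] = []
    for rid, seq in reads.reads:
        read_table = SeqKmerTable(seq, seed_k)
        best = None  # (-score, -matched_bp, contig_id, aln)
        for cid in index.candidates(seq):
            aln = seeded_best_alignment(read_table, contig_tables[cid])
            if aln is None:
                continue
            key = (-aln.score, -aln.query_span, cid)
            if best is None or key < best[0]:
                best = (key, cid, aln)
        if best is None:
            continue
        _, cid, aln = best
        hits.append(
            HitRecord(
                read_id=rid,
                contig_id=cid,
                matched_query_bp=aln.query_span,
                query_coverage=aln.query_span / len(seq) if seq else 0.0,
                identity_pct=aln.identity_pct,
                score=aln.score,
            )
        )
    return hits


def filter_hits(
    hits: list[HitRecord],
    min_query_cov: float = DEFAULT_MIN_QUERY_COV,
    min_identity: float = DEFAULT_MIN_IDENTITY,
) -> list[HitRecord]:
    """Keep hits covering >= min_query_cov of the read at >= min_identity
    (both inclusive)."""
    return [
        h
        for h in hits
        if h.query_coverage >= min_query_cov and h.identity_pct >= min_identity
    ]


def genome_proportion(
    hits: list[HitRecord],
    clusters: list[RepeatCluster],
    dataset_bp: int,
    genome_size_mb: float,
    species_id: str = "sample",
) -> pd.DataFrame:
    """Per-cluster GP (%) and abundance (Mb) from retained hits.

    Returns a tidy frame (cluster_id, species_id, n_hits, bp, gp_pct,
    abundance_mb) with one row per cluster, in cluster order.
    """
    if dataset_bp <= 0:
        raise ValueError("dataset_bp must be positive")
    if genome_size_mb <= 0:
        raise ValueError("genome_size_mb must be positive")
    contig_to_cluster = {
        cid: c.cluster_id for c in clusters for cid, _ in c.contigs
    }
    bp: dict[str, int] = {c.cluster_id: 0 for c in clusters}
    n_hits: dict[str, int] = {c.cluster_id: 0 for c in clusters}
    for h in hits:
        cl = contig_to_cluster.get(h.contig_id)
        if cl is None:
            continue
        bp[cl] += h.matched_query_bp
        n_hits[cl] += 1
    rows = []
    for c in clusters:
        gp = 100.0 * bp[c.cluster_id] / dataset_bp
        rows.append(
            {
                "cluster_id": c.cluster_id,
                "species_id": species_id,
                "n_hits": n_hits[c.cluster_id],
                "bp": bp[c.cluster_id],
                "gp_pct": gp,
                "abundance_mb": gp / 100.0 * genome_size_mb,
            }
        )
    return pd.DataFrame(rows)


def cross_species_abundance(
    per_species_reads: list[ReadSet],
    contigs: list[tuple[str, str]],
    clusters: list[RepeatCluster],
    per_species_genome_mb: dict[str, float],
    min_query_cov: float = DEFAULT_MIN_QUERY_COV,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    seed_k: int = 14,
) -> pd.DataFrame:
    """GP/abundance table over several species against one contig database."""
    frames = []
    for reads in per_species_reads:
        if reads.species_id not in per_species_genome_mb:
            raise ValueError(f"no genome size for species {reads.species_id}")
        hits = filter_hits(
            map_reads_to_contigs(reads, contigs, seed_k=seed_k),
            min_query_cov,
            min_identity,
        )
        frames.append(
            genome_proportion(
                hits,
                clusters,
                reads.total_bp,
                per_species_genome_mb[reads.species_id],
                species_id=reads.species_id,
            )
        )
    return pd.concat(frames, ignore_index=True)


def minimum_baseline_mb(
    table: pd.DataFrame,
    focal_species: str,
    top_cluster_ids: set[str] | None = None,
) -> float:
    """Minimum over non-focal species of the summed top-family abundance —
    the conservative 'already present in the ancestor' baseline."""
    sub = table[table.species_id != focal_species]
    if top_cluster_ids is not None:
        sub = sub[sub.cluster_id.isin(top_cluster_ids)]
    if sub.empty:
        raise ValueError("no non-focal species in table")
    return float(sub.groupby("species_id").abundance_mb.sum().min())


@dataclass(frozen=True)
class ExpansionAccounting:
    """Attribution of a lineage's genome-size expansion to its top repeat
    families, all values in Gb on the monoploid (1Cx) scale.

    ``expansion_gb``       extant 1Cx minus the reconstructed ancestral 1Cx
    ``attributable_gb``    top-family total minus the cross-species baseline
    ``pct_of_expansion_attributable``  100 * attributable / expansion
    ``pct_of_expansion_from_top``      100 * top_total / expansion
    Percentages are rounded to integers and Gb values to 2 decimals, the
    precision at which they are conventionally reported.
    """

    expansion_gb: float
    attributable_gb: float
    pct_of_expansion_attributable: int | None
    pct_of_expansion_from_top: int | None
    expanded: bool


def expansion_accounting(
    extant_1cx_gb: float,
    mrca_1cx_gb: float,
    top_total_gb: float,
    baseline_gb: float,
) -> ExpansionAccounting:
    if min(extant_1cx_gb, mrca_1cx_gb, top_total_gb, baseline_gb) < 0:
        raise ValueError("all inputs must be non-negative")
    expansion = extant_1cx_gb - mrca_1cx_gb
    attributable = top_total_gb - baseline_gb
    if expansion <= 0:
        return ExpansionAccounting(
            round(expansion, 2), round(attributable, 2), None, None, False
        )
    return ExpansionAccounting(
        expansion_gb=round(expansion, 2),
        attributable_gb=round(attributable, 2),
        pct_of_expansion_attributable=round(100.0 * attributable / expansion),
        pct_of_expansion_from_top=round(100.0 * top_total_gb / expansion),
        expanded=True,
    )


def write_abundance_tsv(table: pd.DataFrame, path) -> None:
    out = table.copy()
    out["gp_pct"] = out.gp_pct.round(2)
    out["abundance_mb"] = out.abundance_mb.round(2)
    out.to_csv(path, sep="\t", index=False)
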
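"""All-vs-all read comparison producing the weighted overlap graph.

Nodes are read ids; an edge joins two reads whose best local alignment
(either strand) spans at least ``min_overlap`` columns at
``min_identity`` percent matches.  The edge weight is
``overlap_bp * identity_pct / 100`` — a score-like quantity bounded by the
read length, so a pair of identical 400 bp reads weighs 400.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx

from .align import (
    SeqKmerTable,
    best_local_alignment,
    candidate_pairs_from_tables,
    seeded_best_alignment,
)
from .preprocess import ReadSet

DEFAULT_MIN_OVERLAP = 220
DEFAULT_MIN_IDENTITY = 90.0
DEFAULT_BAND = 25


def edge_weight(overlap_bp: int, identity_pct: float) -> float:
    return overlap_bp * identity_pct / 100.0


def pairwise_overlaps(
    reads: ReadSet,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    method: str = "seed",
    seed_k: int = 16,
    band: int = DEFAULT_BAND,
) -> nx.Graph:
    """Build the read-overlap similarity graph.

    ``method="seed"`` runs banded DP around the best shared-seed diagonal of
    pairs sharing a canonical k-mer; ``method="full"`` runs exhaustive
    Smith-Waterman on every pair (the oracle mode used in tests).
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    if not 0 < min_identity <= 100:
        raise ValueError("min_identity must be in (0, 100]")
    ids = [rid for rid, _ in reads.reads]
    seqs = [seq for _, seq in reads.reads]
    g = nx.Graph()
    g.add_nodes_from(ids)
    n = len(ids)
    if method == "full":
        pairs = {(i, j) for i in range(n - 1) for j in range(i + 1, n)}
        aligner = lambda i, j: best_local_alignment(seqs[i], seqs[j])
    elif method == "seed":
        tables = [SeqKmerTable(seq, seed_k) for seq in seqs]
        pairs = candidate_pairs_from_tables(tables)
        aligner = lambda i, j: seeded_best_alignment(tables[i], tables[j], band=band)
    else:
        raise ValueError(f"unknown method {method!r}")
    for i, j in sorted(pairs):
        aln = aligner(i, j)
        if aln is not None and aln.overlap_bp >= min_overlap and aln.identity_pct >= min_identity:
            g.add_edge(
                ids[i],
                ids[j],
                overlap_bp=aln.overlap_bp,
                identity_pct=aln.identity_pct,
                weight=edge_weight(aln.overlap_bp, aln.identity_pct),
                strand=aln.strand,
            )
    return g


def average_edge_weight(g: nx.Graph, members: set[str]) -> float:
    """Mean weight over edges with both endpoints in ``members`` (0 if none)."""
    weights = [
        d["weight"]
        for a, b, d in g.edges(members, data=True)
        if a in members and b in members
    ]
    if not weights:
        return 0.0
    return sum(weights) / len(weights)


def pair_identity_histogram(
    g: nx.Graph, members: set[str], bin_width: float = 1.0
) -> dict[float, int]:
    """Member-pair edge counts binned by identity_pct.

    Bins are half-open [lo, lo + bin_width) except the last, which is closed
    at 100 so that perfect-identity pairs land in the top bin.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    hist: dict[float, int] = {}
    top_lo = 100.0 - bin_width
    for a, b, d in g.edges(members, data=True):
        if a not in members or b not in members:
            continue
        ident = d["identity_pct"]
        lo = min((ident // bin_width) * bin_width, top_lo)
        hist[lo] = hist.get(lo, 0) + 1
    return dict(sorted(hist.items()))


def write_edge_list(g: nx.Graph, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("read_a\tread_b\toverlap_bp\tidentity_pct\tweight\n")
        for a, b, d in sorted(g.edges(data=True)):
            fh.write(
                f"{a}\t{b}\t{d['overlap_bp']}\t{d['identity_pct']:.2f}\t{d['weight']:.2f}\n"
            )


def write_graph_summary(g: nx.Graph, path: str | Path) -> None:
    summary = {
        "n_nodes": g.number_of_nodes(),
        "n_edges": g.number_of_edges(),
        "n_isolated": sum(1 for n in g.nodes if g.degree(n) == 0),
    }
    Path(path).write_text(json.dumps(summary, indent=2) + "\n")
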
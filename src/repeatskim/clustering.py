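"""Partition the similarity graph into repeat families, merge over-split
families, assemble per-family consensus contigs and pick the top families.

Clustering itself is connected components of the overlap graph — on small
inputs this is provably identical to brute-force component search, and the
historical concern with graph clustering of repeat reads is over-splitting
(hence the merge step), not over-merging.  Reads without any edge become
singleton clusters so that the clusters always partition the input reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .align import (
    SeqKmerTable,
    best_local_alignment,
    candidate_pairs_from_tables,
    revcomp,
    seeded_best_alignment,
)
from .preprocess import ReadSet

DEFAULT_ASSEMBLY_OVERLAP = 160
DEFAULT_MERGE_FRACTION = 0.05
DEFAULT_TOP_FRACTION = 0.0005
ANNOTATION_UNKNOWN = "unknown"


@dataclass
class RepeatCluster:
    """One repeat family: member reads plus assembled consensus contigs."""

    cluster_id: str
    member_read_ids: set[str]
    input_read_fraction: float
    contigs: list[tuple[str, str]] = field(default_factory=list)
    annotation: str = ANNOTATION_UNKNOWN

    @property
    def n_reads(self) -> int:
        return len(self.member_read_ids)


def cluster_graph(g: nx.Graph, all_reads: ReadSet) -> list[RepeatCluster]:
    """Deterministic partition of the read set into connected components.

    Clusters are ordered by descending member count, ties broken by the
    smallest member read id; ids are CL1, CL2, ...
    """
    n_input = len(all_reads)
    read_ids = {rid for rid, _ in all_reads.reads}
    components = [set(c) for c in nx.connected_components(g)]
    covered = set().union(*components) if components else set()
    for rid in sorted(read_ids - covered):
        components.append({rid})
    components.sort(key=lambda c: (-len(c), min(c)))
    return [
        RepeatCluster(
            cluster_id=f"CL{i}",
            member_read_ids=members,
            input_read_fraction=len(members) / n_input if n_input else 0.0,
        )
        for i, members in enumerate(components, start=1)
    ]


def _cross_evidence_pairs(
    reads: ReadSet,
    min_identity: float,
    min_query_frac: float,
    seed_k: int,
) -> set[tuple[str, str]]:
    """Read pairs linked at the relaxed 'database-hit' thresholds used as
    merge evidence: an alignment covering >= min_query_frac of the shorter
    read at >= min_identity percent identity."""
    ids = [rid for rid, _ in reads.reads]
    seqs = [seq for _, seq in reads.reads]
    tables = [SeqKmerTable(s, seed_k) for s in seqs]
    evidence: set[tuple[str, str]] = set()
    for i, j in candidate_pairs_from_tables(tables):
        aln = seeded_best_alignment(tables[i], tables[j])
        if aln is None:
            continue
        shorter = min(len(seqs[i]), len(seqs[j]))
        if aln.query_span >= min_query_frac * shorter and aln.identity_pct >= min_identity:
            evidence.add((ids[i], ids[j]))
    return evidence


def merge_clusters(
    clusters: list[RepeatCluster],
    reads: ReadSet,
    cross_hit_fraction_min: float = DEFAULT_MERGE_FRACTION,
    evidence_pairs: set[tuple[str, str]] | None = None,
    min_identity: float = 90.0,
    min_query_frac: float = 0.55,
    seed_k: int = 16,
) -> list[RepeatCluster]:
    """Merge clusters that look like fragments of one family.

    Two clusters merge iff (a) at least ``cross_hit_fraction_min`` of the
    smaller cluster's reads have relaxed-threshold alignment evidence to the
    larger cluster, and (b) both carry the same annotation label (the
    'unknown' label matches nothing).  Merging runs to a fixpoint, so it is
    effectively transitive.
    """
    if not 0 < cross_hit_fraction_min <= 1:
        raise ValueError("cross_hit_fraction_min must be in (0, 1]")
    if evidence_pairs is None:
        evidence_pairs = _cross_evidence_pairs(reads, min_identity, min_query_frac, seed_k)
    adjacency: dict[str, set[str]] = {}
    for a, b in evidence_pairs:
        adjacency.setdefault(a, set()).add(b)
        adjacency.setdefault(b, set()).add(a)

    n_input_total = len(reads) if len(reads) else 1
    groups = [
        {"members": set(c.member_read_ids), "annotation": c.annotation}
        for c in clusters
    ]

    def should_merge(ga, gb) -> bool:
        if ANNOTATION_UNKNOWN in (ga["annotation"], gb["annotation"]):
            return False
        if ga["annotation"] != gb["annotation"]:
            return False
        small, large = (ga, gb) if len(ga["members"]) <= len(gb["members"]) else (gb, ga)
        hits = sum(
            1 for rid in small["members"] if adjacency.get(rid, set()) & large["members"]
        )
        return hits >= cross_hit_fraction_min * len(small["members"])

    changed = True
    while changed:
        changed = False
        for i in range(len(groups)):
            if changed:
                break
            for j in range(i + 1, len(groups)):
                if should_merge(groups[i], groups[j]):
                    groups[i]["members"] |= groups[j]["members"]
                    groups.pop(j)
                    changed = True
                    break

    groups.sort(key=lambda grp: (-len(grp["members"]), min(grp["members"])))
    return [
        RepeatCluster(
            cluster_id=f"CL{i}",
            member_read_ids=grp["members"],
            input_read_fraction=len(grp["members"]) / n_input_total,
            annotation=grp["annotation"],
        )
        for i, grp in enumerate(groups, start=1)
    ]


# ---------------------------------------------------------------------------
# Greedy overlap-layout-consensus assembly
# ---------------------------------------------------------------------------

def _compose(flip_a: bool, off_a: int, len_a: int,
             strand_minus: bool, qs: int, ts: int, len_b: int) -> tuple[bool, int]:
    """Placement (flip, offset) of read b implied by an alignment
    a[qs..] ~ b'[ts..], where b' = revcomp(b) when strand_minus and read a
    is already placed at (flip_a, off_a) in the layout frame.

    A placement (flip, off) means: render revcomp(seq) if flip else seq,
    with its first base at coordinate off.
    """
    if not flip_a:
        return strand_minus, off_a + qs - ts
    return (not strand_minus), off_a + len_a - qs + ts - len_b


def assemble_contigs(
    cluster: RepeatCluster,
    reads: ReadSet,
    min_overlap: int = DEFAULT_ASSEMBLY_OVERLAP,
    min_identity: float = 90.0,
    seed_k: int = 16,
) -> list[tuple[str, str]]:
    """Greedy overlap-layout-consensus within one cluster.

    Pairwise overlaps >= min_overlap columns at >= min_identity are joined
    longest-overlap first over a union-find layout (offsets taken from the
    local alignment, so the layout is exact for substitution-only data and
    approximate around indels).  The consensus is the per-column base
    majority, ties broken alphabetically.  Reads that never join anything
    emit themselves as contigs.  Contig ids follow ``CL{n}contig{m}``.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    seq_by_id = reads.as_dict()
    ids = sorted(cluster.member_read_ids)
    seqs = [seq_by_id[rid] for rid in ids]
    n = len(ids)

    tables = [SeqKmerTable(s, seed_k) for s in seqs]
    overlaps = []
    for i, j in sorted(candidate_pairs_from_tables(tables)):
        aln = seeded_best_alignment(tables[i], tables[j])
        if aln is not None and aln.overlap_bp >= min_overlap and aln.identity_pct >= min_identity:
            overlaps.append((aln.overlap_bp, ids[i], ids[j], i, j, aln))
    overlaps.sort(key=lambda t: (-t[0], t[1], t[2]))

    parent = list(range(n))
    placement: list[tuple[bool, int]] = [(False, 0)] * n  # relative to component root
    members: list[list[int]] = [[i] for i in range(n)]

    def root_of(x: int) -> int:
        while parent[x] != x:
            x = parent[x]
        return x

    for _, _, _, i, j, aln in overlaps:
        ra, rb = root_of(i), root_of(j)
        if ra == rb:
            continue
        flip_i, off_i = placement[i]
        new_flip, new_off = _compose(
            flip_i, off_i, len(seqs[i]), aln.strand == "-",
            aln.q_start, aln.t_start, len(seqs[j]),
        )
        old_flip, old_off = placement[j]
        if old_flip == new_flip:
            delta = new_off - old_off
            for x in members[rb]:
                f, o = placement[x]
                placement[x] = (f, o + delta)
        else:
            # mirror rb's whole frame around a pivot chosen so read j lands
            # at new_off: coordinate interval [o, o+L) -> [P-o-L, P-o)
            pivot = new_off + old_off + len(seqs[j])
            for x in members[rb]:
                f, o = placement[x]
                placement[x] = (not f, pivot - o - len(seqs[x]))
        for x in members[rb]:
            parent[x] = ra
        members[ra].extend(members[rb])
        members[rb] = []

    comp_members: dict[int, list[int]] = {}
    for x in range(n):
        comp_members.setdefault(root_of(x), []).append(x)

    contigs: list[tuple[str, str]] = []
    code = {"A": 0, "C": 1, "G": 2, "T": 3}
    bases = np.array(list("ACGT"))
    m = 1
    for root in sorted(comp_members, key=lambda r: (-len(comp_members[r]), ids[r])):
        idxs = comp_members[root]
        if len(idxs) == 1:
            contigs.append((f"{cluster.cluster_id}contig{m}", seqs[idxs[0]]))
            m += 1
            continue
        placed = []
        for x in idxs:
            flip, off = placement[x]
            placed.append((off, revcomp(seqs[x]) if flip else seqs[x]))
        lo = min(off for off, _ in placed)
        hi = max(off + len(s) for off, s in placed)
        counts = np.zeros((hi - lo, 4), dtype=np.int32)
        for off, s in placed:
            for k, base in enumerate(s.upper()):
                c = code.get(base)
                if c is not None:
                    counts[off - lo + k, c] += 1
        covered = counts.sum(axis=1) > 0
        consensus = np.where(covered, bases[np.argmax(counts, axis=1)], "N")
        contigs.append((f"{cluster.cluster_id}contig{m}", "".join(consensus)))
        m += 1
    return contigs


def select_top_families(
    clusters: list[RepeatCluster], min_fraction: float = DEFAULT_TOP_FRACTION
) -> list[RepeatCluster]:
    """Clusters holding at least min_fraction of the input reads (inclusive)."""
    if not 0 < min_fraction < 1:
        raise ValueError("min_fraction must be in (0, 1)")
    return [c for c in clusters if c.input_read_fraction >= min_fraction]


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

def tandem_period(seq: str, max_period: int = 500, min_autocorr: float = 0.75) -> int | None:
    """Smallest lag at which the sequence matches a shifted copy of itself
    well enough to call a tandem array; None if no periodicity is found.

    Uses base-identity autocorrelation: the fraction of positions i with
    seq[i] == seq[i+lag].  Random sequence sits near 0.25.
    """
    s = seq.upper()
    n = len(s)
    arr = np.frombuffer(s.encode("ascii"), dtype=np.uint8)
    for lag in range(2, min(max_period, n // 2) + 1):
        frac = float(np.mean(arr[:-lag] == arr[lag:]))
        if frac >= min_autocorr:
            return lag
    return None


def annotate_cluster(
    cluster: RepeatCluster,
    reads: ReadSet,
    ref_library: list[tuple[str, str]] | None = None,
    min_vote_fraction: float = 0.20,
    min_hit_identity: float = 80.0,
    min_hit_query_frac: float = 0.55,
    tandem_min_autocorr: float = 0.75,
) -> str:
    """Label a cluster from reference-library read votes, else tandem
    periodicity on a contig, else 'unknown'.

    A library label wins if at least ``min_vote_fraction`` of the member
    reads hit that label best.  Labels are taken from the part of a library
    FASTA id after '#' (RepeatMasker-style, e.g. ``FRI-1#Gypsy-LTR``),
    falling back to the whole id.
    """
    seq_by_id = reads.as_dict()
    if ref_library:
        votes: dict[str, int] = {}
        for rid in sorted(cluster.member_read_ids):
            seq = seq_by_id[rid]
            best: tuple[int, str] | None = None
            for name, ref_seq in ref_library:
                aln = best_local_alignment(seq, ref_seq)
                if (
                    aln.query_span >= min_hit_query_frac * len(seq)
                    and aln.identity_pct >= min_hit_identity
                    and (best is None or aln.score > best[0])
                ):
                    label = name.split("#", 1)[1] if "#" in name else name
                    best = (aln.score, label)
            if best is not None:
                votes[best[1]] = votes.get(best[1], 0) + 1
        if votes:
            label, n_votes = max(votes.items(), key=lambda kv: (kv[1], kv[0]))
            if n_votes >= min_vote_fraction * cluster.n_reads:
                return label
    for _, contig_seq in cluster.contigs:
        if tandem_period(contig_seq, min_autocorr=tandem_min_autocorr) is not None:
            return "tandem"
    return ANNOTATION_UNKNOWN
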
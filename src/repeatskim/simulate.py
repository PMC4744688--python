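"""Synthetic genomes, read sets, trees and traits with known ground truth.

The generator emulates the data a low-pass genome skim of a repeat-rich
genome produces: a genome assembled from many repeat families with a skewed
abundance spectrum embedded in single-copy background, fixed-length
single-end reads with substitution sequencing error, a fraction of exact
verbatim duplicate reads (the emulsion-PCR artefact), organelle contaminant
reads, and optionally under-length reads to exercise the length filter.

Two per-family copy-divergence regimes are modelled: a recent amplification
"burst" (copies diverged from the family ancestor at rates U(0, 0.01)
substitutions/site) and long-term "accumulation" without deletion (rates
U(0.02, 0.30)).  Substitutions only by default, so identity arithmetic in
tests is exact; an indel mode exists for robustness checks.

Every emitted read carries exactly one provenance record, and all outputs
are byte-identical under a fixed seed.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
import random

import dendropy
import numpy as np

from .ancestral import boxcox, inv_boxcox
from .preprocess import OrganelleDB, ReadSet

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
REGIME_DIVERGENCE = {"burst": (0.0, 0.01), "accumulation": (0.02, 0.30)}


@dataclass(frozen=True)
class FamilySpec:
    family_id: str
    element_length: int
    copy_number: int
    regime: str = "accumulation"
    divergence: tuple[float, float] | None = None  # overrides the regime default

    @property
    def divergence_range(self) -> tuple[float, float]:
        if self.divergence is not None:
            return self.divergence
        return REGIME_DIVERGENCE[self.regime]


@dataclass
class SimScenario:
    seed: int
    genome_length_bp: int
    families: list[FamilySpec]
    read_length: int = 400
    n_reads: int = 1000
    error_rate: float = 0.005
    duplicate_fraction: float = 0.05
    organelle_fraction: float = 0.02
    short_read_fraction: float = 0.0
    indel_rate: float = 0.0
    background_gc: float = 0.5
    min_copy_gap: int | None = None  # defaults to read_length

    def __post_init__(self) -> None:
        for frac in (
            self.error_rate,
            self.duplicate_fraction,
            self.organelle_fraction,
            self.short_read_fraction,
        ):
            if not 0 <= frac <= 1:
                raise ValueError("fractions must be in [0, 1]")


@dataclass
class SimTruth:
    """Ground truth for one simulated scene."""

    family_proportions: dict[str, float]
    background_proportion: float
    copy_intervals: list[tuple[str, int, int, int, float]]  # family, copy, start, end, rate
    read_provenance: dict[str, dict] = field(default_factory=dict)
    n_planted_duplicates: int = 0
    n_exact_duplicate_reads: int = 0
    n_organelle_reads: int = 0
    n_short_reads: int = 0

    def reads_from_family(self, family_id: str) -> set[str]:
        return {
            rid
            for rid, p in self.read_provenance.items()
            if p["origin"] == family_id
        }


def _random_seq(rng: np.random.Generator, length: int, gc: float = 0.5) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=length, p=p).astype(np.uint8)


def _decode(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def _mutate(rng: np.random.Generator, codes: np.ndarray, rate: float,
            indel_rate: float = 0.0) -> np.ndarray:
    out = codes.copy()
    if rate > 0:
        hit = rng.random(len(out)) < rate
        shift = rng.integers(1, 4, size=int(hit.sum()))
        out[hit] = (out[hit] + shift) % 4
    if indel_rate > 0:
        keep = rng.random(len(out)) >= indel_rate / 2
        out = out[keep]
        n_ins = rng.binomial(len(out), indel_rate / 2)
        if n_ins:
            pos = np.sort(rng.integers(0, len(out) + 1, size=n_ins))
            out = np.insert(out, pos, rng.integers(0, 4, size=n_ins).astype(np.uint8))
    return out


def _revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return (3 - codes)[::-1]


def simulate_genome(sc: SimScenario) -> tuple[str, SimTruth]:
    """Assemble the genome: family copies at random non-overlapping positions
    separated by at least ``min_copy_gap`` of background (default one read
    length, so every read is assignable to a single family)."""
    rng = np.random.default_rng(sc.seed)
    gap0 = sc.min_copy_gap if sc.min_copy_gap is not None else sc.read_length
    copies: list[tuple[str, int, np.ndarray, float]] = []
    for fam in sc.families:
        lo, hi = fam.divergence_range
        ancestor = _random_seq(rng, fam.element_length, sc.background_gc)
        for ci in range(fam.copy_number):
            rate = float(rng.uniform(lo, hi))
            copies.append((fam.family_id, ci, _mutate(rng, ancestor, rate, sc.indel_rate), rate))
    order = rng.permutation(len(copies))
    copies = [copies[i] for i in order]

    total_copy_bp = sum(len(c[2]) for c in copies)
    n_gaps = len(copies) + 1
    fixed = total_copy_bp + n_gaps * gap0
    extra = sc.genome_length_bp - fixed
    if extra < 0:
        raise ValueError(
            f"genome_length_bp too small: need >= {fixed} bp for copies plus gaps"
        )
    gap_extra = rng.multinomial(extra, np.full(n_gaps, 1.0 / n_gaps))

    chunks: list[np.ndarray] = []
    intervals: list[tuple[str, int, int, int, float]] = []
    pos = 0
    for g_extra, (fam_id, ci, seq, rate) in zip(gap_extra[:-1], copies):
        gap_len = gap0 + int(g_extra)
        chunks.append(_random_seq(rng, gap_len, sc.background_gc))
        pos += gap_len
        chunks.append(seq)
        intervals.append((fam_id, ci, pos, pos + len(seq), rate))
        pos += len(seq)
    last_gap = gap0 + int(gap_extra[-1])
    chunks.append(_random_seq(rng, last_gap, sc.background_gc))
    pos += last_gap

    genome = np.concatenate(chunks) if chunks else np.empty(0, dtype=np.uint8)
    fam_bp: dict[str, int] = {f.family_id: 0 for f in sc.families}
    for fam_id, _, start, end, _ in intervals:
        fam_bp[fam_id] += end - start
    glen = len(genome)
    proportions = {f: bp / glen for f, bp in fam_bp.items()} if glen else {}
    truth = SimTruth(
        family_proportions=proportions,
        background_proportion=1.0 - sum(proportions.values()),
        copy_intervals=sorted(intervals, key=lambda t: t[2]),
    )
    return _decode(genome), truth


def true_pairwise_divergences(genome: str, truth: SimTruth, family_id: str) -> np.ndarray:
    """Observed pairwise substitution divergence between the planted copies
    of one family (computed from the genome itself, equal-length copies)."""
    seqs = [
        np.frombuffer(genome[s:e].encode(), dtype=np.uint8)
        for fam, _, s, e, _ in truth.copy_intervals
        if fam == family_id
    ]
    lens = {len(s) for s in seqs}
    if len(lens) != 1:
        raise ValueError("copies differ in length (indel mode); no exact divergence")
    out = []
    for i in range(len(seqs) - 1):
        for j in range(i + 1, len(seqs)):
            out.append(float(np.mean(seqs[i] != seqs[j])))
    return np.array(out)


def sample_reads(
    genome: str,
    sc: SimScenario,
    truth: SimTruth,
    organelle_db: OrganelleDB | None = None,
    species_id: str = "sim",
    read_seed: int | None = None,
) -> ReadSet:
    """Draw reads uniformly from either strand with substitution error, plus
    planted exact duplicates, organelle contaminants and short reads.

    Provenance (family / background / organelle, duplicate-of, short) is
    recorded in ``truth`` for every read, and the realised number of exact
    duplicate reads (planted plus coincidental) is counted for comparison
    with the deduplication stage.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence([sc.seed if read_seed is None else read_seed, 1])
    )
    codes = np.frombuffer(genome.encode("ascii"), dtype=np.uint8)
    lookup = np.full(256, 255, dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        lookup[b] = i
    codes = lookup[codes]
    rl = sc.read_length
    if rl > len(genome):
        raise ValueError("read_length exceeds genome length")

    n = sc.n_reads
    n_org = int(round(n * sc.organelle_fraction)) if organelle_db is not None else 0
    n_dup = int(round(n * sc.duplicate_fraction))
    n_short = int(round(n * sc.short_read_fraction))
    n_normal = n - n_org - n_dup - n_short
    if n_normal < 0:
        raise ValueError("fractions sum beyond 1")

    starts = np.array([iv[2] for iv in truth.copy_intervals])
    ends = np.array([iv[3] for iv in truth.copy_intervals])
    fam_ids = [iv[0] for iv in truth.copy_intervals]

    def origin_of(midpoint: int) -> str:
        if len(starts):
            k = int(np.searchsorted(starts, midpoint, side="right")) - 1
            if k >= 0 and midpoint < ends[k]:
                return fam_ids[k]
        return "background"

    emitted: list[tuple[str, dict]] = []  # (sequence, provenance)

    def genome_read(length: int, short: bool) -> tuple[str, dict]:
        start = int(rng.integers(0, len(codes) - length + 1))
        sub = codes[start : start + length]
        strand = int(rng.integers(0, 2))
        if strand:
            sub = _revcomp_codes(sub)
        sub = _mutate(rng, sub, sc.error_rate)
        return _decode(sub), {
            "origin": origin_of(start + length // 2),
            "duplicate_of": None,
            "short": short,
        }

    for _ in range(n_normal):
        emitted.append(genome_read(rl, short=False))
    for _ in range(n_short):
        length = int(rng.integers(rl // 2, rl))
        emitted.append(genome_read(length, short=True))
    if n_org:
        lengths = np.array([len(s) for _, s in organelle_db.sequences], dtype=float)
        probs = lengths / lengths.sum()
        for _ in range(n_org):
            si = int(rng.choice(len(lengths), p=probs))
            seq = organelle_db.sequences[si][1]
            start = int(rng.integers(0, len(seq) - rl + 1))
            sub = lookup[np.frombuffer(seq[start : start + rl].encode(), dtype=np.uint8)]
            if int(rng.integers(0, 2)):
                sub = _revcomp_codes(sub)
            sub = _mutate(rng, sub, sc.error_rate)
            emitted.append((_decode(sub), {"origin": "organelle", "duplicate_of": None, "short": False}))
    n_sources = len(emitted)
    for _ in range(n_dup):
        src = int(rng.integers(0, n_sources))
        seq, prov = emitted[src]
        emitted.append((seq, {"origin": prov["origin"], "duplicate_of": src, "short": prov["short"]}))

    order = rng.permutation(len(emitted))
    reads: list[tuple[str, str]] = []
    src_id: dict[int, str] = {}
    for out_i, src_i in enumerate(order):
        rid = f"{species_id}_r{out_i:06d}"
        src_id[int(src_i)] = rid
    for out_i, src_i in enumerate(order):
        seq, prov = emitted[int(src_i)]
        rid = src_id[int(src_i)]
        prov = dict(prov)
        if prov["duplicate_of"] is not None:
            prov["duplicate_of"] = src_id[prov["duplicate_of"]]
        truth.read_provenance[rid] = prov
        reads.append((rid, seq))

    truth.n_planted_duplicates += n_dup
    truth.n_organelle_reads += n_org
    truth.n_short_reads += n_short
    counts = Counter(seq for _, seq in reads)
    truth.n_exact_duplicate_reads = sum(c - 1 for c in counts.values())
    return ReadSet(species_id, reads)


def make_organelle_db(
    seed: int, n_seqs: int = 3, length: int = 20000, source_tag: str = "plastid"
) -> OrganelleDB:
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    seqs = [
        (f"{source_tag}_{i + 1}", _decode(_random_seq(rng, length)))
        for i in range(n_seqs)
    ]
    return OrganelleDB(seqs, source_tag)


# ---------------------------------------------------------------------------
# Trees and traits
# ---------------------------------------------------------------------------

def random_trees(
    n_trees: int, n_tips: int, seed: int, birth_rate: float = 1.0
) -> list[dendropy.Tree]:
    """Independent birth-death trees on a shared taxon namespace T1..Tn."""
    from dendropy.simulate import treesim

    taxa = dendropy.TaxonNamespace([f"T{i + 1}" for i in range(n_tips)])
    rng = random.Random(seed)
    trees = []
    for _ in range(n_trees):
        tree = treesim.birth_death_tree(
            birth_rate=birth_rate,
            death_rate=0.0,
            num_extant_tips=n_tips,
            taxon_namespace=taxa,
            rng=rng,
        )
        trees.append(tree)
    return trees


def simulate_traits_on_tree(
    tree: dendropy.Tree,
    root_value_gb: float,
    sigma2: float,
    trend: float = 0.0,
    lam: float = -2.0,
    seed: int = 0,
) -> tuple[dict[str, float], dict]:
    """Brownian evolution (plus optional trend) in Box-Cox space along the
    tree; returns back-transformed tip traits (Gb) and the internal-node
    states (transformed scale) keyed by sorted descendant-tip tuples."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    root_state = float(boxcox(root_value_gb, lam))
    states: dict = {}
    internal: dict = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            states[node] = root_state
        else:
            bl = node.edge.length if node.edge.length is not None else 0.0
            if bl < 0:
                raise ValueError("branch lengths must be non-negative")
            states[node] = states[node.parent_node] + trend * bl + (
                rng.normal(0.0, np.sqrt(sigma2 * bl)) if sigma2 > 0 and bl > 0 else 0.0
            )
    tips: dict[str, float] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            tips[node.taxon.label] = float(inv_boxcox(states[node], lam))
        else:
            labels = tuple(sorted(l.taxon.label for l in node.leaf_iter()))
            internal[labels] = states[node]
    return tips, internal
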
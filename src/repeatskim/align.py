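"""Local-alignment primitives shared by every sequence-comparison stage.

The scoring scheme is the simple nucleotide one used throughout the pipeline:
match +1, mismatch -1, gap -2 (linear).  Ambiguity codes never match anything,
including themselves, so reads containing N/R/Y/... are kept but score as
mismatches.  Significance of database hits uses the Karlin-Altschul form
E = K * m * n * exp(-lambda * S) with K = 0.1 and lambda = 0.7.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

DEFAULT_MATCH = 1
DEFAULT_MISMATCH = -1
DEFAULT_GAP = -2
KA_K = 0.1
KA_LAMBDA = 0.7

_ENC = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _ENC[ord(_b)] = _i
    _ENC[ord(_b.lower())] = _i

_COMP = str.maketrans(
    "ACGTRYSWKMBDHVNacgtryswkmbdhvn",
    "TGCAYRSWMKVHDBNtgcayrswmkvhdbn",
)


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string as int8 codes (A,C,G,T -> 0..3, other -> 4)."""
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@njit(cache=False)
def _sw_kernel(a, b, match, mismatch, gap):  # pragma: no cover - numba
    n = a.shape[0]
    m = b.shape[0]
    ptr = np.zeros((n + 1, m + 1), dtype=np.uint8)
    prev = np.zeros(m + 1, dtype=np.int32)
    cur = np.zeros(m + 1, dtype=np.int32)
    best = 0
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        ai = a[i - 1]
        cur[0] = 0
        for j in range(1, m + 1):
            if ai == b[j - 1] and ai < 4:
                s = match
            else:
                s = mismatch
            h = prev[j - 1] + s
            p = 1
            u = prev[j] + gap
            if u > h:
                h = u
                p = 2
            left = cur[j - 1] + gap
            if left > h:
                h = left
                p = 3
            if h <= 0:
                h = 0
                p = 0
            cur[j] = h
            ptr[i, j] = p
            if h > best:
                best = h
                bi = i
                bj = j
        tmp = prev
        prev = cur
        cur = tmp
    # traceback from the best cell
    i = bi
    j = bj
    cols = 0
    matches = 0
    while i > 0 and j > 0 and ptr[i, j] != 0:
        p = ptr[i, j]
        if p == 1:
            cols += 1
            if a[i - 1] == b[j - 1] and a[i - 1] < 4:
                matches += 1
            i -= 1
            j -= 1
        elif p == 2:
            cols += 1
            i -= 1
        else:
            cols += 1
            j -= 1
    return best, i, bi, j, bj, cols, matches


@njit(cache=False)
def _sw_banded_kernel(a, b, diag, band, match, mismatch, gap):  # pragma: no cover
    """Smith-Waterman restricted to |i - j - diag| <= band.

    Cells outside the band are treated as 0, so the result is exact whenever
    the optimal local alignment stays within the band (always true for
    substitution-only divergence when diag comes from a shared seed).
    """
    n = a.shape[0]
    m = b.shape[0]
    ptr = np.zeros((n + 1, m + 1), dtype=np.uint8)
    prev = np.zeros(m + 1, dtype=np.int32)
    cur = np.zeros(m + 1, dtype=np.int32)
    best = 0
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        jlo = i - diag - band
        if jlo < 1:
            jlo = 1
        jhi = i - diag + band
        if jhi > m:
            jhi = m
        if jlo > m or jhi < 1:
            tmp = prev
            prev = cur
            cur = tmp
            continue
        ai = a[i - 1]
        cur[jlo - 1] = 0  # left neighbour outside the band
        if jhi < m:
            prev[jhi] = 0  # up neighbour outside the previous band
        for j in range(jlo, jhi + 1):
            if ai == b[j - 1] and ai < 4:
                s = match
            else:
                s = mismatch
            h = prev[j - 1] + s
            p = 1
            u = prev[j] + gap
            if u > h:
                h = u
                p = 2
            left = cur[j - 1] + gap
            if left > h:
                h = left
                p = 3
            if h <= 0:
                h = 0
                p = 0
            cur[j] = h
            ptr[i, j] = p
            if h > best:
                best = h
                bi = i
                bj = j
        tmp = prev
        prev = cur
        cur = tmp
    i = bi
    j = bj
    cols = 0
    matches = 0
    while i > 0 and j > 0 and ptr[i, j] != 0:
        p = ptr[i, j]
        if p == 1:
            cols += 1
            if a[i - 1] == b[j - 1] and a[i - 1] < 4:
                matches += 1
            i -= 1
            j -= 1
        elif p == 2:
            cols += 1
            i -= 1
        else:
            cols += 1
            j -= 1
    return best, i, bi, j, bj, cols, matches


@njit(cache=False)
def _extend_kernel(a, b, qp, tp, k, match, mismatch, xdrop):  # pragma: no cover
    """Gapless x-drop extension of an exact k-mer seed a[qp:qp+k] == b[tp:tp+k]."""
    score = k * match
    best = score
    i = qp + k
    j = tp + k
    cur = score
    bqe = i
    bte = j
    while i < a.shape[0] and j < b.shape[0]:
        if a[i] == b[j] and a[i] < 4:
            cur += match
        else:
            cur += mismatch
        i += 1
        j += 1
        if cur > best:
            best = cur
            bqe = i
            bte = j
        if best - cur > xdrop:
            break
    i = qp - 1
    j = tp - 1
    cur = best
    best2 = best
    bqs = qp
    bts = tp
    while i >= 0 and j >= 0:
        if a[i] == b[j] and a[i] < 4:
            cur += match
        else:
            cur += mismatch
        if cur > best2:
            best2 = cur
            bqs = i
            bts = j
        i -= 1
        j -= 1
        if best2 - cur > xdrop:
            break
    return best2, bqs, bqe, bts, bte


@dataclass(frozen=True)
class LocalAlignment:
    """Best local alignment of a query against a target.

    Coordinates are half-open.  For ``strand == '-'`` the target coordinates
    refer to the reverse complement of the target sequence.
    """

    score: int
    q_start: int
    q_end: int
    t_start: int
    t_end: int
    columns: int
    matches: int
    strand: str = "+"

    @property
    def identity_pct(self) -> float:
        if self.columns == 0:
            return 0.0
        return 100.0 * self.matches / self.columns

    @property
    def overlap_bp(self) -> int:
        return self.columns

    @property
    def query_span(self) -> int:
        return self.q_end - self.q_start


def local_align(
    query: str,
    target: str,
    match: int = DEFAULT_MATCH,
    mismatch: int = DEFAULT_MISMATCH,
    gap: int = DEFAULT_GAP,
) -> LocalAlignment:
    """Full Smith-Waterman of query vs target (forward strand only)."""
    if not query or not target:
        return LocalAlignment(0, 0, 0, 0, 0, 0, 0, "+")
    score, qs, qe, ts, te, cols, matches = _sw_kernel(
        encode(query), encode(target), match, mismatch, gap
    )
    return LocalAlignment(int(score), int(qs), int(qe), int(ts), int(te), int(cols), int(matches), "+")


def best_local_alignment(
    query: str,
    target: str,
    match: int = DEFAULT_MATCH,
    mismatch: int = DEFAULT_MISMATCH,
    gap: int = DEFAULT_GAP,
) -> LocalAlignment:
    """Best local alignment over both target strands; '+' wins score ties."""
    fwd = local_align(query, target, match, mismatch, gap)
    rev = local_align(query, revcomp(target), match, mismatch, gap)
    if rev.score > fwd.score:
        return LocalAlignment(
            rev.score, rev.q_start, rev.q_end, rev.t_start, rev.t_end,
            rev.columns, rev.matches, "-",
        )
    return fwd


def evalue(score: float, query_len: int, db_len: int,
           k: float = KA_K, lam: float = KA_LAMBDA) -> float:
    """Karlin-Altschul expectation for a local alignment score."""
    return k * query_len * db_len * float(np.exp(-lam * score))


def banded_local_align(
    query: str,
    target: str,
    diag: int,
    band: int = 25,
    match: int = DEFAULT_MATCH,
    mismatch: int = DEFAULT_MISMATCH,
    gap: int = DEFAULT_GAP,
) -> LocalAlignment:
    """Smith-Waterman restricted to a band around diagonal ``diag``
    (= query_pos - target_pos of a shared seed)."""
    if not query or not target:
        return LocalAlignment(0, 0, 0, 0, 0, 0, 0, "+")
    score, qs, qe, ts, te, cols, matches = _sw_banded_kernel(
        encode(query), encode(target), diag, band, match, mismatch, gap
    )
    return LocalAlignment(int(score), int(qs), int(qe), int(ts), int(te), int(cols), int(matches), "+")


# ---------------------------------------------------------------------------
# k-mer seeding
# ---------------------------------------------------------------------------

def canonical_kmers(seq: str, k: int) -> set[str]:
    """Strand-canonical k-mers of seq (lexicographic min of kmer / revcomp)."""
    out: set[str] = set()
    s = seq.upper()
    for i in range(len(s) - k + 1):
        kmer = s[i : i + k]
        if "N" in kmer:
            continue
        rc = revcomp(kmer)
        out.add(kmer if kmer <= rc else rc)
    return out


def candidate_pairs(seqs: list[str], k: int = 16) -> set[tuple[int, int]]:
    """Index-pairs of sequences sharing at least one canonical k-mer."""
    buckets: dict[str, list[int]] = {}
    for idx, seq in enumerate(seqs):
        for kmer in canonical_kmers(seq, k):
            buckets.setdefault(kmer, []).append(idx)
    pairs: set[tuple[int, int]] = set()
    for members in buckets.values():
        if len(members) < 2:
            continue
        for x in range(len(members) - 1):
            a = members[x]
            for y in range(x + 1, len(members)):
                b = members[y]
                if a < b:
                    pairs.add((a, b))
                elif b < a:
                    pairs.add((b, a))
    return pairs


class KmerIndex:
    """Canonical k-mer -> target-id index for query-vs-database candidate lookup."""

    def __init__(self, targets: dict[str, str], k: int = 14):
        self.k = k
        self.targets = targets
        self._index: dict[str, set[str]] = {}
        for name, seq in targets.items():
            for kmer in canonical_kmers(seq, k):
                self._index.setdefault(kmer, set()).add(name)

    def candidates(self, query: str) -> list[str]:
        hits: set[str] = set()
        for kmer in canonical_kmers(query, self.k):
            found = self._index.get(kmer)
            if found:
                hits |= found
        return sorted(hits)


class SeedExtender:
    """Seeded gapless x-drop extension of a query against a sequence database.

    Used for organelle screening where only a best score (for an E-value) is
    needed, not full alignment statistics.
    """

    def __init__(self, sequences: list[tuple[str, str]], k: int = 12,
                 match: int = DEFAULT_MATCH, mismatch: int = DEFAULT_MISMATCH,
                 xdrop: int = 20):
        self.k = k
        self.match = match
        self.mismatch = mismatch
        self.xdrop = xdrop
        self.total_bp = sum(len(s) for _, s in sequences)
        self._encoded = [encode(s) for _, s in sequences]
        self._index: dict[str, list[tuple[int, int]]] = {}
        for si, (_, seq) in enumerate(sequences):
            s = seq.upper()
            for i in range(len(s) - k + 1):
                kmer = s[i : i + k]
                if "N" in kmer:
                    continue
                self._index.setdefault(kmer, []).append((si, i))

    def best_score(self, query: str, max_seeds: int = 500) -> int:
        best = 0
        for oriented in (query.upper(), revcomp(query.upper())):
            enc_q = encode(oriented)
            seen = 0
            for qp in range(len(oriented) - self.k + 1):
                kmer = oriented[qp : qp + self.k]
                hits = self._index.get(kmer)
                if not hits:
                    continue
                for si, tp in hits:
                    score, *_ = _extend_kernel(
                        enc_q, self._encoded[si], qp, tp, self.k,
                        self.match, self.mismatch, self.xdrop,
                    )
                    if score > best:
                        best = int(score)
                    seen += 1
                    if seen >= max_seeds:
                        break
                if seen >= max_seeds:
                    break
        return best


# ---------------------------------------------------------------------------
# Seeded banded alignment between prepared sequences
# ---------------------------------------------------------------------------

class SeqKmerTable:
    """Per-sequence k-mer table used to vote for an alignment diagonal."""

    __slots__ = ("seq", "k", "entries", "fwd")

    def __init__(self, seq: str, k: int):
        self.seq = seq
        self.k = k
        s = seq.upper()
        self.fwd: dict[str, int] = {}
        self.entries: list[tuple[str, str, int]] = []
        for p in range(len(s) - k + 1):
            kmer = s[p : p + k]
            if "N" in kmer:
                continue
            if kmer not in self.fwd:
                self.fwd[kmer] = p
            self.entries.append((kmer, revcomp(kmer), p))


def seeded_best_alignment(
    qt: SeqKmerTable,
    tt: SeqKmerTable,
    band: int = 25,
    match: int = DEFAULT_MATCH,
    mismatch: int = DEFAULT_MISMATCH,
    gap: int = DEFAULT_GAP,
) -> LocalAlignment | None:
    """Best banded local alignment between two sequences, seeded by shared
    k-mers on either strand; None when the pair shares no seed.

    The most-voted diagonal per orientation is used; for ``strand == '-'``
    target coordinates refer to the reverse complement of the target, as in
    :func:`best_local_alignment`.
    """
    votes_f: dict[int, int] = {}
    votes_r: dict[int, int] = {}
    t_fwd = tt.fwd
    len_t = len(tt.seq)
    k = qt.k
    for kmer, rkmer, p in qt.entries:
        tp = t_fwd.get(kmer)
        if tp is not None:
            d = p - tp
            votes_f[d] = votes_f.get(d, 0) + 1
        tp = t_fwd.get(rkmer)
        if tp is not None:
            d = p - (len_t - k - tp)
            votes_r[d] = votes_r.get(d, 0) + 1
    best: LocalAlignment | None = None
    if votes_f:
        diag = max(votes_f.items(), key=lambda kv: (kv[1], -abs(kv[0])))[0]
        best = banded_local_align(qt.seq, tt.seq, diag, band, match, mismatch, gap)
    if votes_r:
        diag = max(votes_r.items(), key=lambda kv: (kv[1], -abs(kv[0])))[0]
        aln = banded_local_align(qt.seq, revcomp(tt.seq), diag, band, match, mismatch, gap)
        if best is None or aln.score > best.score:
            best = LocalAlignment(
                aln.score, aln.q_start, aln.q_end, aln.t_start, aln.t_end,
                aln.columns, aln.matches, "-",
            )
    return best


def candidate_pairs_from_tables(tables: list[SeqKmerTable]) -> set[tuple[int, int]]:
    """Index-pairs of prepared sequences sharing >= 1 canonical k-mer."""
    buckets: dict[str, list[int]] = {}
    for idx, table in enumerate(tables):
        canon = {min(k, rk) for k, rk, _ in table.entries}
        for kmer in canon:
            buckets.setdefault(kmer, []).append(idx)
    pairs: set[tuple[int, int]] = set()
    for members in buckets.values():
        if len(members) < 2:
            continue
        for x in range(len(members) - 1):
            for y in range(x + 1, len(members)):
                pairs.add((members[x], members[y]))
    return pairs
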
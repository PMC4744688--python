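"""Read ingestion and cleanup: exact-duplicate removal, organelle screening
and fixed-length standardisation.

The output of the full chain (dedup -> organelle screen -> length
standardisation) is the set of unique nuclear reads that every downstream
stage consumes.  Duplicate detection deliberately does *not* collapse
reverse complements: emulsion-PCR artefacts are same-strand copies, so the
criterion is identical length plus identical sequence (case-insensitive).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO

from .align import SeedExtender, evalue

DEFAULT_EVALUE = 1e-6
DEFAULT_TARGET_LEN = 400


@dataclass
class ReadSet:
    """Species-tagged nucleotide reads with unique ids."""

    species_id: str
    reads: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [rid for rid, _ in self.reads]
        if len(ids) != len(set(ids)):
            raise ValueError(f"duplicate read ids in ReadSet for {self.species_id}")

    @property
    def total_bp(self) -> int:
        return sum(len(seq) for _, seq in self.reads)

    def __len__(self) -> int:
        return len(self.reads)

    def as_dict(self) -> dict[str, str]:
        return dict(self.reads)

    @classmethod
    def from_file(cls, path: str | Path, species_id: str | None = None) -> "ReadSet":
        """Load reads from FASTA or FASTQ (qualities ignored)."""
        path = Path(path)
        fmt = "fastq" if path.suffix.lower() in {".fastq", ".fq"} else "fasta"
        reads = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), fmt)]
        return cls(species_id or path.stem, reads)

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for rid, seq in self.reads:
                fh.write(f">{rid}\n{seq}\n")


@dataclass
class OrganelleDB:
    """Reference organelle (plastid / mitochondrial) sequences used to screen
    out contaminating reads."""

    sequences: list[tuple[str, str]]
    source_tag: str = "plastid"

    def __post_init__(self) -> None:
        if not self.sequences:
            raise ValueError("organelle database is empty")
        for name, seq in self.sequences:
            if len(seq) < 50:
                raise ValueError(f"organelle sequence {name} is < 50 bp")

    @property
    def total_bp(self) -> int:
        return sum(len(s) for _, s in self.sequences)

    @classmethod
    def from_fasta(cls, path: str | Path, source_tag: str = "plastid") -> "OrganelleDB":
        seqs = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
        return cls(seqs, source_tag)


def remove_exact_duplicates(reads: ReadSet) -> tuple[ReadSet, int]:
    """Retain the first read of every (length, sequence) group, input order
    preserved; returns the deduplicated set and the number removed."""
    seen: set[str] = set()
    kept: list[tuple[str, str]] = []
    removed = 0
    for rid, seq in reads.reads:
        key = seq.upper()
        if key in seen:
            removed += 1
        else:
            seen.add(key)
            kept.append((rid, seq))
    return ReadSet(reads.species_id, kept), removed


def standardize_length(reads: ReadSet, target_len: int = DEFAULT_TARGET_LEN) -> ReadSet:
    """Truncate longer reads at the 3' end to target_len; drop shorter reads."""
    if target_len <= 0:
        raise ValueError("target_len must be positive")
    kept = [
        (rid, seq[:target_len])
        for rid, seq in reads.reads
        if len(seq) >= target_len
    ]
    return ReadSet(reads.species_id, kept)


def screen_organelle(
    reads: ReadSet,
    db: OrganelleDB,
    evalue_max: float = DEFAULT_EVALUE,
    seed_k: int = 12,
) -> tuple[ReadSet, ReadSet]:
    """Split reads into (nuclear, organellar).

    A read is organellar iff its best seeded gapless local alignment against
    the database reaches E <= evalue_max under the Karlin-Altschul model with
    m = read length and n = total database length.
    """
    if evalue_max <= 0:
        raise ValueError("evalue_max must be positive")
    extender = SeedExtender(db.sequences, k=seed_k)
    nuclear: list[tuple[str, str]] = []
    organellar: list[tuple[str, str]] = []
    for rid, seq in reads.reads:
        score = extender.best_score(seq)
        if score > 0 and evalue(score, len(seq), db.total_bp) <= evalue_max:
            organellar.append((rid, seq))
        else:
            nuclear.append((rid, seq))
    return (
        ReadSet(reads.species_id, nuclear),
        ReadSet(reads.species_id, organellar),
    )


@dataclass
class PreprocessResult:
    nuclear: ReadSet
    n_input: int
    n_duplicates: int
    n_organellar: int
    n_short: int
    fates: dict[str, str]


def preprocess_reads(
    reads: ReadSet,
    organelle_db: OrganelleDB | None = None,
    target_len: int = DEFAULT_TARGET_LEN,
    evalue_max: float = DEFAULT_EVALUE,
) -> PreprocessResult:
    """Full preprocessing chain: dedup -> organelle screen -> standardise.

    Fates recorded per read id: kept | duplicate | organellar | short.
    """
    fates: dict[str, str] = {}
    unique, _ = remove_exact_duplicates(reads)
    unique_ids = {rid for rid, _ in unique.reads}
    for rid, _ in reads.reads:
        if rid not in unique_ids:
            fates[rid] = "duplicate"
    if organelle_db is not None:
        nuclear, organellar = screen_organelle(unique, organelle_db, evalue_max)
        for rid, _ in organellar.reads:
            fates[rid] = "organellar"
    else:
        nuclear, organellar = unique, ReadSet(reads.species_id, [])
    final = standardize_length(nuclear, target_len)
    final_ids = {rid for rid, _ in final.reads}
    for rid, _ in nuclear.reads:
        fates[rid] = "kept" if rid in final_ids else "short"
    return PreprocessResult(
        nuclear=final,
        n_input=len(reads),
        n_duplicates=len(reads) - len(unique),
        n_organellar=len(organellar),
        n_short=len(nuclear) - len(final),
        fates=fates,
    )


def write_fate_log(result: PreprocessResult, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["read_id", "fate"])
        for rid, fate in result.fates.items():
            writer.writerow([rid, fate])
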
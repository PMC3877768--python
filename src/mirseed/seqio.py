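"""Sequence I/O and read preprocessing.

Reads arrive as 4-line FASTQ records; references as FASTA.  All sequences are
normalized to the DNA alphabet {A,C,G,T,N} (RNA references are printed with U,
sequencers emit T), 3' sequencing adapters are clipped off, and identical
inserts are collapsed into (sequence, occurrence) pairs so the matcher only
sees distinct sequences.
"""

from __future__ import annotations

import gzip
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator

from Bio import SeqIO

from .errors import FastqParseError, InvalidAlphabetError, ReferenceError_

#: Illumina TruSeq small-RNA 3' adapter. The library kit is known but the
#: adapter string itself is configuration, not a claim about any given run.
DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"

#: Shortest insert worth keeping: the matcher anchors on 16-nt seeds, so
#: anything shorter can never match.
DEFAULT_MIN_INSERT_LENGTH = 16

_VALID = set("ACGTN")
_REFERENCE_ROLES = ("mature", "star", "antagomir", "pri_hairpin")


@dataclass(frozen=True)
class Read:
    """One sequencing read: identifier, bases, optional per-base qualities."""

    read_id: str
    sequence: str
    quality: str | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"read {self.read_id!r}: empty sequence")
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise ValueError(
                f"read {self.read_id!r}: quality length {len(self.quality)} != "
                f"sequence length {len(self.sequence)}"
            )


@dataclass(frozen=True)
class ReferenceSmallRNA:
    """A named reference small RNA with a biological role tag.

    Roles: ``mature`` (annotated mature miRNA), ``star`` (the strand processed
    from the opposite hairpin arm), ``antagomir`` (synthetic inhibitor) or
    ``pri_hairpin`` (primary transcript hairpin).
    """

    ref_id: str
    sequence: str
    role: str = "mature"

    def __post_init__(self) -> None:
        if self.role not in _REFERENCE_ROLES:
            raise ValueError(f"unknown reference role {self.role!r}")
        object.__setattr__(self, "sequence", normalize_alphabet(self.sequence))
        if "N" in self.sequence:
            raise ReferenceError_(
                f"reference {self.ref_id!r} contains N after normalization"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class TrimResult:
    """Outcome of 3'-adapter removal for one read."""

    read: Read
    adapter_found: bool
    trimmed_length: int
    kept: bool


def normalize_alphabet(seq: str) -> str:
    """Uppercase *seq* and convert RNA U to DNA T.

    Characters outside {A,C,G,T,U,N} raise :class:`InvalidAlphabetError`
    naming the first offending (1-based) position.
    """
    if not seq:
        raise ValueError("empty sequence")
    out = seq.upper().replace("U", "T")
    for i, ch in enumerate(out):
        if ch not in _VALID:
            raise InvalidAlphabetError(
                f"invalid character {ch!r} at position {i + 1}"
            )
    return out


def _open_text(path: str | Path) -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fastq(path: str | Path) -> Iterator[Read]:
    """Stream :class:`Read` objects from a 4-line FASTQ file (optionally gzipped).

    Sequences are alphabet-normalized; record order is preserved.  A file
    ending mid-record raises :class:`FastqParseError` with the 0-based index
    of the offending record.
    """
    with _open_text(path) as fh:
        record_index = 0
        while True:
            lines = [fh.readline() for _ in range(4)]
            lines = [ln.rstrip("\n") for ln in lines]
            if not lines[0]:
                return
            if not all(lines[1:]):
                raise FastqParseError(
                    f"{path}: truncated FASTQ record at record {record_index}"
                )
            header, seq, plus, qual = lines
            if not header.startswith("@") or not plus.startswith("+"):
                raise FastqParseError(
                    f"{path}: malformed FASTQ record at record {record_index}"
                )
            yield Read(header[1:].split()[0], normalize_alphabet(seq), qual)
            record_index += 1


def write_fastq(reads: Iterable[Read], path: str | Path) -> None:
    with open(path, "wt") as fh:
        for r in reads:
            qual = r.quality if r.quality is not None else "I" * len(r.sequence)
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{qual}\n")


def read_reference_fasta(
    path: str | Path, role: str = "mature", roles: dict[str, str] | None = None
) -> list[ReferenceSmallRNA]:
    """Load references from FASTA.

    A per-record role can be given in the FASTA description as ``role=<tag>``
    or through the *roles* mapping; otherwise *role* applies to every record.
    """
    refs = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ReferenceError_(f"duplicate reference id {rec.id!r} in {path}")
        seen.add(rec.id)
        rec_role = role
        if roles and rec.id in roles:
            rec_role = roles[rec.id]
        else:
            for tok in rec.description.split():
                if tok.startswith("role="):
                    rec_role = tok[5:]
        refs.append(ReferenceSmallRNA(rec.id, str(rec.seq), rec_role))
    return refs


def write_reference_fasta(refs: Iterable[ReferenceSmallRNA], path: str | Path) -> None:
    with open(path, "wt") as fh:
        for ref in refs:
            fh.write(f">{ref.ref_id} role={ref.role}\n{ref.sequence}\n")


def trim_adapter_3p(
    read: Read,
    adapter: str = DEFAULT_ADAPTER,
    min_overlap: int = 6,
    max_mismatch_rate: float = 0.1,
    min_insert_length: int = DEFAULT_MIN_INSERT_LENGTH,
) -> TrimResult:
    """Clip the 3' adapter off *read* at the leftmost acceptable alignment.

    A cut point ``p`` is acceptable when the adapter prefix of length
    ``l = min(len(adapter), len(read) - p)`` (``l >= min_overlap``) aligns at
    ``p`` with at most ``floor(l * max_mismatch_rate)`` mismatches.  ``N``
    never matches an adapter base.  Degenerate reads are never an error: they
    simply come back with ``kept=False``.
    """
    adapter = normalize_alphabet(adapter)
    if not 1 <= min_overlap <= len(adapter):
        raise ValueError("require adapter length >= min_overlap >= 1")
    if not 0 <= max_mismatch_rate < 0.5:
        raise ValueError("require 0 <= max_mismatch_rate < 0.5")

    seq = read.sequence
    n = len(seq)
    for p in range(0, n - min_overlap + 1):
        ell = min(len(adapter), n - p)
        allowed = int(ell * max_mismatch_rate)
        mism = 0
        for i in range(ell):
            if seq[p + i] != adapter[i] or seq[p + i] == "N":
                mism += 1
                if mism > allowed:
                    break
        else:
            insert = seq[:p]
            kept = len(insert) >= min_insert_length
            trimmed = Read(
                read.read_id,
                insert if insert else "N",  # placeholder; never kept
                read.quality[:p] if (read.quality and insert) else None,
            )
            if not insert:
                kept = False
            return TrimResult(trimmed, True, n - p, kept)
    return TrimResult(read, False, 0, len(seq) >= min_insert_length)


def collapse_reads(reads: Iterable[Read | str]) -> list[tuple[str, int]]:
    """Collapse identical sequences into (sequence, occurrences) pairs.

    Output is ordered by descending occurrence count, ties broken
    lexicographically by sequence; occurrence counts sum to the number of
    input reads.
    """
    tally: Counter[str] = Counter(
        r.sequence if isinstance(r, Read) else r for r in reads
    )
    return sorted(tally.items(), key=lambda kv: (-kv[1], kv[0]))


def write_collapsed_tsv(
    collapsed: Iterable[tuple[str, int]], path: str | Path, header: str | None = None
) -> None:
    with open(path, "wt") as fh:
        if header:
            fh.write(header)
        fh.write("sequence\tcount\n")
        for seq, count in collapsed:
            fh.write(f"{seq}\t{count}\n")


def read_collapsed_tsv(path: str | Path) -> list[tuple[str, int]]:
    out = []
    with _open_text(path) as fh:
        for line in fh:
            if line.startswith("#") or line.startswith("sequence\t"):
                continue
            seq, count = line.rstrip("\n").split("\t")
            out.append((normalize_alphabet(seq), int(count)))
    return out
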
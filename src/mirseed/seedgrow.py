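"""Seed-and-grow exact matching of small-RNA reads to reference sequences.

Every 16-mer of every reference is indexed.  A read sharing any indexed
16-mer is anchored there and the perfect match is grown one base at a time
toward the 5' end and then toward the 3' end, stopping at the first mismatch
or when either sequence is exhausted.  Read bases left outside the grown
region are reported as 5'/3' non-matching flanks, so isomiR end heterogeneity
and untemplated tails remain visible instead of being discarded.  The
alignment is strictly ungapped and mismatch-free inside the matched span.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .errors import IntegrityError, ReferenceError_
from .seqio import ReferenceSmallRNA

DEFAULT_SEED_LENGTH = 16

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MatchRecord:
    """One maximal ungapped perfect match of a read against a reference.

    Coordinates are 1-based inclusive on the reference.  The read always
    decomposes as ``flank5 + reference[ref_start..ref_end] + flank3``.
    """

    sequence: str
    ref_id: str
    ref_start: int
    ref_end: int
    flank5: str
    flank3: str
    occurrences: int = 1

    @property
    def matched_length(self) -> int:
        return self.ref_end - self.ref_start + 1

    def validate(self, ref: ReferenceSmallRNA) -> None:
        span = ref.sequence[self.ref_start - 1 : self.ref_end]
        if self.sequence != self.flank5 + span + self.flank3:
            raise IntegrityError(
                f"match on {self.ref_id} does not decompose: "
                f"{self.sequence!r} != {self.flank5!r}+{span!r}+{self.flank3!r}"
            )


class SeedIndex:
    """Exact k-mer index over a set of references.

    Maps every k-mer to the list of ``(ref_id, 0-based offset)`` pairs at
    which it occurs; a reference of length L contributes exactly L - k + 1
    entries.
    """

    def __init__(self, k: int = DEFAULT_SEED_LENGTH):
        if k < 1:
            raise ValueError("seed length k must be >= 1")
        self.k = k
        self.entries: dict[str, list[tuple[str, int]]] = defaultdict(list)
        self.references: dict[str, ReferenceSmallRNA] = {}

    def add(self, ref: ReferenceSmallRNA) -> None:
        if ref.ref_id in self.references:
            raise ReferenceError_(f"duplicate reference id {ref.ref_id!r}")
        self.references[ref.ref_id] = ref
        for offset, kmer in enumerate_seeds(ref, self.k):
            self.entries[kmer].append((ref.ref_id, offset))

    def lookup(self, kmer: str) -> list[tuple[str, int]]:
        return self.entries.get(kmer, [])


def enumerate_seeds(ref: ReferenceSmallRNA, k: int = DEFAULT_SEED_LENGTH) -> list[tuple[int, str]]:
    """All k-mers of *ref* as (0-based offset, k-mer), ascending offset.

    A reference of length L yields exactly L - k + 1 seeds; e.g. a 23-nt
    reference has eight 16-nt seeds (bases 1-16, 2-17, ..., 8-23).
    """
    seq = ref.sequence
    if len(seq) < k:
        raise ReferenceError_(
            f"reference {ref.ref_id!r} is shorter ({len(seq)} nt) than the "
            f"seed length {k}"
        )
    return [(i, seq[i : i + k]) for i in range(len(seq) - k + 1)]


def build_index(
    refs: Sequence[ReferenceSmallRNA],
    k: int = DEFAULT_SEED_LENGTH,
    add_reverse_complements: bool = False,
) -> SeedIndex:
    """Index *refs*; optionally also each reverse complement as ``<id>|rc``.

    Indexing both strands mirrors matching reads against sense and anti-sense
    reference sequences; the matcher itself stays strand-agnostic.
    """
    index = SeedIndex(k)
    for ref in refs:
        index.add(ref)
    if add_reverse_complements:
        for ref in list(refs):
            index.add(
                ReferenceSmallRNA(
                    ref.ref_id + "|rc", reverse_complement(ref.sequence), ref.role
                )
            )
    return index


def _grow(read: str, ref: str, read_anchor: int, ref_anchor: int, k: int) -> tuple[int, int]:
    """Extend the anchored k-mer match maximally in both directions.

    Returns (read_start, ref_start) of the maximal perfect run, both 0-based;
    the run length is recovered by growing forward from the anchor end.
    """
    i, j = read_anchor, ref_anchor
    while i > 0 and j > 0 and read[i - 1] == ref[j - 1] and read[i - 1] != "N":
        i -= 1
        j -= 1
    return i, j


def match_read(
    sequence: str,
    index: SeedIndex,
    refs: Mapping[str, ReferenceSmallRNA] | None = None,
) -> list[MatchRecord]:
    """All maximal seed-and-grow matches of one read sequence.

    For every (read k-mer, indexed reference k-mer) anchor pair the match is
    grown base-by-base 5'-ward and 3'-ward while the bases agree; distinct
    anchors inside the same maximal run collapse to one record.  Records are
    sorted by (descending matched length, ref_id, ref_start).  A read sharing
    no k-mer with any reference yields an empty list, not an error.
    """
    if refs is None:
        refs = index.references
    k = index.k
    seen: set[tuple[str, int, int, int]] = set()
    records: list[MatchRecord] = []
    for read_off in range(len(sequence) - k + 1):
        kmer = sequence[read_off : read_off + k]
        if "N" in kmer:
            continue
        for ref_id, ref_off in index.lookup(kmer):
            ref_seq = refs[ref_id].sequence
            rs, js = _grow(sequence, ref_seq, read_off, ref_off, k)
            # grow 3'-ward from the anchor's right edge
            i, j = read_off + k, ref_off + k
            while (
                i < len(sequence)
                and j < len(ref_seq)
                and sequence[i] == ref_seq[j]
                and sequence[i] != "N"
            ):
                i += 1
                j += 1
            key = (ref_id, js, j, rs)
            if key in seen:
                continue
            seen.add(key)
            records.append(
                MatchRecord(
                    sequence=sequence,
                    ref_id=ref_id,
                    ref_start=js + 1,
                    ref_end=j,
                    flank5=sequence[:rs],
                    flank3=sequence[i:],
                    occurrences=1,
                )
            )
    records.sort(key=lambda r: (-r.matched_length, r.ref_id, r.ref_start))
    return records


def match_library(
    collapsed: Iterable[tuple[str, int]],
    index: SeedIndex,
    refs: Mapping[str, ReferenceSmallRNA] | None = None,
    mode: str = "best",
) -> list[MatchRecord]:
    """Match a collapsed read library.

    ``mode="best"`` keeps only the top-sorted record per distinct sequence so
    each read is counted once; ``mode="all"`` keeps every match.  Each record
    carries its sequence's occurrence count.
    """
    if mode not in ("all", "best"):
        raise ValueError(f"mode must be 'all' or 'best', got {mode!r}")
    out: list[MatchRecord] = []
    for sequence, occurrences in collapsed:
        if len(sequence) < index.k:
            continue
        hits = match_read(sequence, index, refs)
        if not hits:
            continue
        if mode == "best":
            hits = hits[:1]
        for h in hits:
            out.append(
                MatchRecord(
                    h.sequence, h.ref_id, h.ref_start, h.ref_end,
                    h.flank5, h.flank3, occurrences,
                )
            )
    return out


def export_stack(records: Sequence[MatchRecord], ref: ReferenceSmallRNA) -> str:
    """Render matches to one reference as a padded, gapless stacked alignment.

    The first row is the reference, padded with '.' by the widest overhanging
    flanks; each record is one row with its matched bases in uppercase under
    reference positions ref_start..ref_end and its flanks in lowercase.  All
    rows have equal length.  Output is padded FASTA text.
    """
    for rec in records:
        if rec.ref_id != ref.ref_id:
            raise ValueError(f"record for {rec.ref_id!r} in stack for {ref.ref_id!r}")
        rec.validate(ref)
    L = len(ref.sequence)
    pad5 = max((len(r.flank5) - (r.ref_start - 1) for r in records), default=0)
    pad5 = max(pad5, 0)
    pad3 = max((len(r.flank3) - (L - r.ref_end) for r in records), default=0)
    pad3 = max(pad3, 0)
    width = pad5 + L + pad3
    lines = [f">{ref.ref_id}", "." * pad5 + ref.sequence + "." * pad3]
    for n, rec in enumerate(records):
        left = pad5 + (rec.ref_start - 1) - len(rec.flank5)
        body = (
            rec.flank5.lower()
            + ref.sequence[rec.ref_start - 1 : rec.ref_end]
            + rec.flank3.lower()
        )
        row = "." * left + body
        row += "." * (width - len(row))
        lines.append(f">{ref.ref_id}|read{n}|occ={rec.occurrences}")
        lines.append(row)
    return "\n".join(lines) + "\n"


def write_matches_tsv(
    records: Iterable[MatchRecord], path: str | Path, header: str | None = None
) -> None:
    with open(path, "wt") as fh:
        if header:
            fh.write(header)
        fh.write("sequence\tref_id\tref_start\tref_end\tflank5\tflank3\toccurrences\n")
        for r in records:
            fh.write(
                f"{r.sequence}\t{r.ref_id}\t{r.ref_start}\t{r.ref_end}\t"
                f"{r.flank5}\t{r.flank3}\t{r.occurrences}\n"
            )


def read_matches_tsv(path: str | Path) -> list[MatchRecord]:
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or line.startswith("sequence\t"):
                continue
            seq, ref_id, rs, re_, f5, f3, occ = (line.rstrip("\n") + "\t").split("\t")[:7]
            out.append(MatchRecord(seq, ref_id, int(rs), int(re_), f5, f3, int(occ)))
    return out
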
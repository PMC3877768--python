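"""Ungapped antagomir-vs-pri-miRNA complementarity scanning.

An antagomir can silence an unrelated miRNA if it base-pairs with that
miRNA's primary transcript.  This module slides the full-length query across
a longer target and scores each window either for Watson-Crick
complementarity between query and target (``complement`` mode — the two
strands forming a duplex, query antiparallel to the target) or for plain
sequence identity (``identity`` mode).  G:U wobble pairs can be credited at a
fractional weight in complement mode.  The top-ranked window is the
candidate hybrid region.  No gaps, no thermodynamics: match counting only.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from .errors import SpanError
from .seqio import ReferenceSmallRNA
from .seedgrow import reverse_complement

#: The anti-miR21 antagomir (RNA as printed; normalized to DNA internally).
ANTI_MIR21 = "ACGGCAACACCAGUCGAUGGGCUGU"

_WC = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass(frozen=True)
class HybridHit:
    """One scored window of the query on the target (1-based inclusive span)."""

    query_id: str
    target_id: str
    target_start: int
    target_end: int
    mode: str
    matched_bases: int
    wobble_bases: int
    score: float
    window_length: int


def complementarity_scan(
    query: ReferenceSmallRNA,
    target: ReferenceSmallRNA,
    mode: str = "complement",
    allow_wobble: bool = True,
    wobble_weight: float = 0.5,
) -> list[HybridHit]:
    """Score every placement of the full-length query window on the target.

    complement mode: position i of the window pairs target base
    ``target[offset+i]`` with query base ``query[L-1-i]`` (antiparallel
    duplex); a Watson-Crick pair scores 1 and a G:U (here G:T) wobble scores
    *wobble_weight* when *allow_wobble*.  identity mode: positions score 1
    when target and query bases are equal (parallel reading).  Hits are
    ranked by descending score, ties by ascending target_start.
    """
    if mode not in ("complement", "identity"):
        raise ValueError(f"mode must be 'complement' or 'identity', got {mode!r}")
    q = query.sequence
    t = target.sequence
    L = len(q)
    if L > len(t):
        raise SpanError(
            f"query {query.ref_id!r} ({L} nt) longer than target "
            f"{target.ref_id!r} ({len(t)} nt)"
        )
    hits: list[HybridHit] = []
    for offset in range(len(t) - L + 1):
        matched = 0
        wobble = 0
        for i in range(L):
            tb = t[offset + i]
            if mode == "identity":
                if tb == q[i] and tb != "N":
                    matched += 1
                continue
            qb = q[L - 1 - i]
            if qb == "N" or tb == "N":
                continue
            if _WC[qb] == tb:
                matched += 1
            elif allow_wobble and {qb, tb} == {"G", "T"}:
                wobble += 1
        score = matched + (wobble_weight * wobble if mode == "complement" else 0.0)
        hits.append(
            HybridHit(
                query.ref_id, target.ref_id, offset + 1, offset + L,
                mode, matched, wobble if mode == "complement" else 0, score, L,
            )
        )
    hits.sort(key=lambda h: (-h.score, h.target_start))
    return hits


def best_hybrid(
    query: ReferenceSmallRNA,
    targets: Iterable[ReferenceSmallRNA],
    mode: str = "complement",
    allow_wobble: bool = True,
    wobble_weight: float = 0.5,
) -> list[HybridHit]:
    """Top hit per target, ranked across targets by descending score."""
    tops = [
        complementarity_scan(query, t, mode, allow_wobble, wobble_weight)[0]
        for t in targets
    ]
    tops.sort(key=lambda h: (-h.score, h.target_id, h.target_start))
    return tops


def write_hits_tsv(hits: Iterable[HybridHit], path: str | Path, header: str | None = None) -> None:
    with open(path, "wt") as fh:
        if header:
            fh.write(header)
        fh.write(
            "query_id\ttarget_id\ttarget_start\ttarget_end\tmode\t"
            "matched_bases\twobble_bases\tscore\twindow_length\n"
        )
        for h in hits:
            fh.write(
                f"{h.query_id}\t{h.target_id}\t{h.target_start}\t{h.target_end}\t"
                f"{h.mode}\t{h.matched_bases}\t{h.wobble_bases}\t{h.score:.6g}\t"
                f"{h.window_length}\n"
            )
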
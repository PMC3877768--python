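"""End-to-end orchestration: simulate/load -> trim -> match -> count -> compare.

Every tabular output carries a provenance header (tool version, config hash,
seed) as '#'-prefixed comment lines so a result file can always be traced to
the configuration that produced it.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from . import __version__
from .errors import ConfigurationError
from .quantify import (
    CountTable,
    compare_all,
    count_matches,
    write_comparison_tsv,
    write_count_table,
)
from .seedgrow import build_index, match_library, write_matches_tsv
from .seqio import (
    DEFAULT_ADAPTER,
    DEFAULT_MIN_INSERT_LENGTH,
    Read,
    collapse_reads,
    read_fastq,
    read_reference_fasta,
    trim_adapter_3p,
    write_fastq,
)


@dataclass
class PipelineConfig:
    """Configuration for one full pipeline run."""

    references_fasta: str
    libraries: Mapping[str, str]  # sample_id -> FASTQ path
    sample_conditions: Mapping[str, str]  # sample_id -> condition label
    output_dir: str
    control: str
    treated: str
    adapter: str = DEFAULT_ADAPTER
    min_overlap: int = 6
    max_mismatch_rate: float = 0.1
    min_insert_length: int = DEFAULT_MIN_INSERT_LENGTH
    k: int = 16
    match_mode: str = "best"
    add_reverse_complements: bool = False
    use_cpm: bool = False
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 8:
            raise ConfigurationError(f"seed length k={self.k} below minimum 8")
        if set(self.libraries) != set(self.sample_conditions):
            raise ConfigurationError("libraries and sample_conditions disagree on samples")
        if not Path(self.references_fasta).exists():
            raise ConfigurationError(f"reference FASTA not found: {self.references_fasta}")
        for sample, path in self.libraries.items():
            if not Path(path).exists():
                raise ConfigurationError(f"library FASTQ for {sample!r} not found: {path}")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def provenance_header(self) -> str:
        return (
            f"# mirseed {__version__}\n"
            f"# config_hash={self.config_hash()} seed={self.rng_seed}\n"
        )


def trim_library(
    reads,
    adapter: str = DEFAULT_ADAPTER,
    min_overlap: int = 6,
    max_mismatch_rate: float = 0.1,
    min_insert_length: int = DEFAULT_MIN_INSERT_LENGTH,
) -> list[Read]:
    """Adapter-trim a read stream, keeping only inserts long enough to match.

    Trim decisions depend only on the base text, so they are cached per
    distinct sequence; small-RNA libraries are highly redundant.
    """
    kept = []
    cache: dict[str, object] = {}
    for read in reads:
        res = cache.get(read.sequence)
        if res is None:
            res = trim_adapter_3p(
                Read("_", read.sequence),
                adapter, min_overlap, max_mismatch_rate, min_insert_length,
            )
            cache[read.sequence] = res
        if res.kept:
            n = len(res.read.sequence)
            kept.append(
                Read(read.read_id, res.read.sequence,
                     read.quality[:n] if read.quality else None)
            )
    return kept


def run_pipeline(config: PipelineConfig) -> dict:
    """Run trim -> match -> quantify -> compare over all configured libraries.

    Writes per-sample trimmed FASTQ and match TSVs, the count table and the
    comparison report under ``output_dir``; returns the in-memory results.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    header = config.provenance_header()

    refs = read_reference_fasta(config.references_fasta)
    index = build_index(refs, config.k, config.add_reverse_complements)

    table = CountTable(sample_conditions=dict(config.sample_conditions))
    matches_by_sample = {}
    for sample_id in sorted(config.libraries):
        reads = read_fastq(config.libraries[sample_id])
        trimmed = trim_library(
            reads, config.adapter, config.min_overlap,
            config.max_mismatch_rate, config.min_insert_length,
        )
        write_fastq(trimmed, outdir / f"{sample_id}.trimmed.fastq")
        collapsed = collapse_reads(trimmed)
        records = match_library(collapsed, index, mode=config.match_mode)
        write_matches_tsv(records, outdir / f"{sample_id}.matches.tsv", header)
        matches_by_sample[sample_id] = records
        table = count_matches(records, sample_id, table)

    write_count_table(table, outdir / "counts.tsv", header)
    results = compare_all(table, config.control, config.treated, config.use_cpm)
    write_comparison_tsv(results, outdir / "comparison.tsv", header)
    return {
        "count_table": table,
        "comparisons": {r.ref_id: r for r in results},
        "matches": matches_by_sample,
    }
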
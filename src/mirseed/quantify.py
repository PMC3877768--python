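"""Per-reference read counting and between-condition comparison.

Matched reads from each library are totalled into a reference x sample count
table; conditions are compared by fold change of mean counts (optionally
counts-per-million) with a two-tailed unpaired Student's t-test when both
conditions are replicated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    ConfigurationError,
    DegenerateLibraryError,
    InsufficientReplicatesError,
    UndefinedFoldChangeError,
)
from .seedgrow import MatchRecord


@dataclass
class CountTable:
    """Reference x sample matrix of matched-read counts with condition labels."""

    counts: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(dtype=float)
    )
    sample_conditions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        for sample in self.counts.columns:
            if sample not in self.sample_conditions:
                raise ConfigurationError(f"sample {sample!r} has no condition label")

    def get(self, ref_id: str, sample_id: str) -> float:
        """Count for (ref, sample); absent keys read as 0."""
        try:
            return float(self.counts.at[ref_id, sample_id])
        except KeyError:
            return 0.0

    def samples_in(self, condition: str) -> list[str]:
        return [s for s in self.counts.columns if self.sample_conditions[s] == condition]


def count_matches(
    records: Iterable[MatchRecord], sample_id: str, table: CountTable
) -> CountTable:
    """Add one sample's per-reference occurrence totals to *table*.

    Records are expected from best-mode matching so every collapsed sequence
    contributes to exactly one reference.
    """
    if sample_id not in table.sample_conditions:
        raise ConfigurationError(f"sample {sample_id!r} has no condition label")
    totals: dict[str, int] = {}
    for rec in records:
        totals[rec.ref_id] = totals.get(rec.ref_id, 0) + rec.occurrences
    col = pd.Series(totals, dtype=float)
    new_index = table.counts.index.union(col.index)
    counts = table.counts.reindex(new_index).fillna(0.0)
    counts[sample_id] = col.reindex(new_index).fillna(0.0)
    return CountTable(counts, dict(table.sample_conditions))


def cpm_normalize(table: CountTable) -> CountTable:
    """Counts-per-million: each sample scaled so its column sums to 1e6."""
    totals = table.counts.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise DegenerateLibraryError(
            f"zero matched reads in sample(s): {', '.join(zero.index)}"
        )
    return CountTable(table.counts * 1e6 / totals, dict(table.sample_conditions))


def students_t_test(
    group_a: Sequence[float], group_b: Sequence[float], welch: bool = False
) -> tuple[float, float]:
    """Two-tailed unpaired t-test; equal-variance (Student) by default.

    Zero pooled variance is handled explicitly: equal means give (0, 1);
    unequal means are a degenerate separation reported as p = 0.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise InsufficientReplicatesError("each group needs >= 2 values")
    if welch:
        t, p = stats.ttest_ind(a, b, equal_var=False)
        return float(t), float(p)
    na, nb = len(a), len(b)
    pooled = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if pooled == 0.0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return math.copysign(math.inf, a.mean() - b.mean()), 0.0
    t = (a.mean() - b.mean()) / math.sqrt(pooled * (1 / na + 1 / nb))
    p = 2.0 * stats.t.sf(abs(t), na + nb - 2)
    return float(t), float(p)


@dataclass(frozen=True)
class ComparisonResult:
    """Fold change and test outcome for one reference between two conditions."""

    ref_id: str
    mean_control: float
    mean_treated: float
    fold_change: float
    percent_change: float
    p_value: float | None
    degenerate: bool = False


def compare_conditions(
    table: CountTable,
    ref_id: str,
    control: str,
    treated: str,
    use_cpm: bool = False,
) -> ComparisonResult:
    """Compare mean counts of *ref_id* between two conditions.

    ``fold_change = mean(treated) / mean(control)``;
    ``percent_change = (fold_change - 1) * 100``.  The p-value comes from a
    two-tailed unpaired equal-variance Student's t-test and is absent when
    either condition has fewer than two samples.
    """
    if use_cpm:
        table = cpm_normalize(table)
    ctrl_samples = table.samples_in(control)
    trt_samples = table.samples_in(treated)
    if not ctrl_samples or not trt_samples:
        raise ConfigurationError(
            f"need >= 1 sample per condition ({control!r}: {len(ctrl_samples)}, "
            f"{treated!r}: {len(trt_samples)})"
        )
    ctrl = [table.get(ref_id, s) for s in ctrl_samples]
    trt = [table.get(ref_id, s) for s in trt_samples]
    mean_c = float(np.mean(ctrl))
    mean_t = float(np.mean(trt))
    if mean_c == 0:
        raise UndefinedFoldChangeError(
            f"control mean for {ref_id!r} is zero; fold change undefined"
        )
    fold = mean_t / mean_c
    p: float | None = None
    degenerate = False
    if len(ctrl) >= 2 and len(trt) >= 2:
        _, p = students_t_test(ctrl, trt)
        degenerate = p == 0.0 and mean_c != mean_t
    return ComparisonResult(ref_id, mean_c, mean_t, fold, (fold - 1.0) * 100.0, p, degenerate)


def compare_all(
    table: CountTable, control: str, treated: str, use_cpm: bool = False
) -> list[ComparisonResult]:
    """compare_conditions for every reference with a nonzero control mean."""
    out = []
    for ref_id in table.counts.index:
        try:
            out.append(compare_conditions(table, ref_id, control, treated, use_cpm))
        except UndefinedFoldChangeError:
            continue
    return out


def write_count_table(table: CountTable, path: str | Path, header: str | None = None) -> None:
    with open(path, "wt") as fh:
        if header:
            fh.write(header)
        cond_row = "\t".join(
            ["#condition"] + [table.sample_conditions[s] for s in table.counts.columns]
        )
        fh.write(cond_row + "\n")
        table.counts.to_csv(fh, sep="\t", index_label="ref_id")


def read_count_table(path: str | Path) -> CountTable:
    conditions: dict[str, str] = {}
    rows: list[str] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#condition"):
                cond_line = line.rstrip("\n").split("\t")[1:]
            elif line.startswith("#"):
                continue
            else:
                rows.append(line)
    from io import StringIO

    df = pd.read_csv(StringIO("".join(rows)), sep="\t", index_col="ref_id")
    conditions = dict(zip(df.columns, cond_line))
    return CountTable(df.astype(float), conditions)


def write_comparison_tsv(
    results: Iterable[ComparisonResult], path: str | Path, header: str | None = None
) -> None:
    with open(path, "wt") as fh:
        if header:
            fh.write(header)
        fh.write(
            "ref_id\tmean_control\tmean_treated\tfold_change\tpercent_change\tp_value\n"
        )
        for r in results:
            p = "" if r.p_value is None else f"{r.p_value:.6g}"
            fh.write(
                f"{r.ref_id}\t{r.mean_control:.6g}\t{r.mean_treated:.6g}\t"
                f"{r.fold_change:.6g}\t{r.percent_change:.6g}\t{p}\n"
            )
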
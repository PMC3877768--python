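"""Livak 2^-ddCt relative quantification of qPCR threshold cycles.

Each condition's target-gene Ct is normalized against a reference gene
(here typically 18s rRNA) to give dCt = mean(Ct_target) - mean(Ct_reference);
ddCt = dCt_treated - dCt_control; the relative quantity is RQ = 2^-ddCt,
so one extra cycle of delay corresponds to a twofold reduction.  Replicates
are averaged at the Ct level within each condition.  No amplification-
efficiency correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import NormalizationError

MAX_CYCLES = 40  # qPCR run length; a Ct at or beyond this is no detection


@dataclass(frozen=True)
class CtMeasurement:
    """One well: sample, condition, gene, reference-gene flag, threshold cycle."""

    sample_id: str
    condition: str
    gene: str
    is_reference_gene: bool
    ct: float

    def __post_init__(self) -> None:
        if not 0 < self.ct < MAX_CYCLES:
            raise ValueError(
                f"Ct {self.ct} outside (0, {MAX_CYCLES}) for {self.gene}/{self.sample_id}"
            )


@dataclass(frozen=True)
class RQResult:
    """ddCt outcome for one gene: RQ = 2^-ddCt and its percent change."""

    gene: str
    delta_ct_treated: float
    delta_ct_control: float
    delta_delta_ct: float
    rq: float
    percent_change: float


def delta_ct(measurements: Iterable[CtMeasurement], gene: str) -> float:
    """mean(target Ct) - mean(reference-gene Ct) over one condition's wells."""
    ms = list(measurements)
    target = [m.ct for m in ms if m.gene == gene and not m.is_reference_gene]
    reference = [m.ct for m in ms if m.is_reference_gene]
    if not target:
        raise NormalizationError(f"no target measurements for gene {gene!r}")
    if not reference:
        raise NormalizationError("no reference-gene measurements (e.g. 18s) present")
    return float(np.mean(target) - np.mean(reference))


def relative_quantity(delta_ct_treated: float, delta_ct_control: float, gene: str = "") -> RQResult:
    """RQ = 2^-(dCt_treated - dCt_control) with percent change (RQ - 1) x 100."""
    ddct = delta_ct_treated - delta_ct_control
    rq = 2.0 ** (-ddct)
    return RQResult(gene, delta_ct_treated, delta_ct_control, ddct, rq, (rq - 1.0) * 100.0)


def rq_from_measurements(
    measurements: Sequence[CtMeasurement], control: str, treated: str
) -> list[RQResult]:
    """One RQResult per target gene measured in both conditions."""
    ms = list(measurements)
    ctrl = [m for m in ms if m.condition == control]
    trt = [m for m in ms if m.condition == treated]
    genes = sorted(
        {m.gene for m in ms if not m.is_reference_gene}
    )
    out = []
    for gene in genes:
        if not any(m.gene == gene for m in ctrl) or not any(m.gene == gene for m in trt):
            continue
        out.append(
            relative_quantity(delta_ct(trt, gene), delta_ct(ctrl, gene), gene)
        )
    return out


def read_ct_tsv(path: str | Path) -> list[CtMeasurement]:
    """Load Ct wells from TSV: sample_id, condition, gene, is_reference_gene, ct."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"sample_id", "condition", "gene", "is_reference_gene", "ct"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    truthy = {"1", "true", "yes", "y", "t"}
    return [
        CtMeasurement(
            str(r.sample_id),
            str(r.condition),
            str(r.gene),
            str(r.is_reference_gene).strip().lower() in truthy,
            float(r.ct),
        )
        for r in df.itertuples()
    ]


def write_rq_tsv(results: Iterable[RQResult], path: str | Path, header: str | None = None) -> None:
    with open(path, "wt") as fh:
        if header:
            fh.write(header)
        fh.write("gene\tdelta_ct_treated\tdelta_ct_control\tdelta_delta_ct\trq\tpercent_change\n")
        for r in results:
            fh.write(
                f"{r.gene}\t{r.delta_ct_treated:.6g}\t{r.delta_ct_control:.6g}\t"
                f"{r.delta_delta_ct:.6g}\t{r.rq:.6g}\t{r.percent_change:.6g}\n"
            )
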
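"""Synthetic two-condition small-RNA-seq libraries with known ground truth.

Each read is a miRNA-derived insert followed by the 3' sequencing adapter.
Inserts are drawn per library from condition-specific true abundance
fractions over a reference panel; isomiR end heterogeneity is emulated by
independent 5'/3' end shifts (negative = templated trimming of the mature
sequence, positive = templated extension into fixed flanking context), and
uniform per-base substitution errors are applied to the insert.  True
generated counts are recorded before any error, so pipeline estimates can be
checked against exact ground truth.  Generation is a pure function of
(seed, condition, replicate index).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .seqio import DEFAULT_ADAPTER, Read, ReferenceSmallRNA

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class SimReference:
    """A reference panel entry: sequence plus optional templated flanks.

    ``flank5``/``flank3`` are the genomic context used for positive
    (extension) end shifts; a shift beyond the available context is clamped.
    """

    ref: ReferenceSmallRNA
    flank5: str = ""
    flank3: str = ""

    @property
    def ref_id(self) -> str:
        return self.ref.ref_id


@dataclass
class SimulationConfig:
    """Everything that defines a simulated experiment.

    ``abundances`` maps condition -> {ref_id -> fraction}; fractions per
    condition must sum to 1.  ``end_shift_probabilities`` is a distribution
    over shifts in bases applied independently at each end: negative trims,
    positive extends into flanking context.
    """

    references: Sequence[SimReference]
    abundances: Mapping[str, Mapping[str, float]]
    reads_per_library: int = 50_000
    replicates_per_condition: int = 3
    end_shift_probabilities: Mapping[int, float] = field(
        default_factory=lambda: {-2: 0.02, -1: 0.08, 0: 0.80, 1: 0.08, 2: 0.02}
    )
    substitution_error_rate: float = 0.001
    adapter: str = DEFAULT_ADAPTER
    rng_seed: int = 0

    def __post_init__(self) -> None:
        ids = [r.ref_id for r in self.references]
        if len(set(ids)) != len(ids):
            raise ConfigurationError("duplicate reference ids in simulation config")
        for cond, fracs in self.abundances.items():
            total = sum(fracs.values())
            if abs(total - 1.0) > 1e-9:
                raise ConfigurationError(
                    f"abundance fractions for condition {cond!r} sum to {total}, not 1"
                )
            unknown = set(fracs) - set(ids)
            if unknown:
                raise ConfigurationError(f"unknown references in abundances: {unknown}")
        shifts = self.end_shift_probabilities
        if abs(sum(shifts.values()) - 1.0) > 1e-9:
            raise ConfigurationError("end shift probabilities must sum to 1")
        if any(not 0 <= p <= 1 for p in shifts.values()):
            raise ConfigurationError("end shift probabilities must lie in [0, 1]")
        if not 0 <= self.substitution_error_rate <= 1:
            raise ConfigurationError("substitution error rate must lie in [0, 1]")
        max_trim = -min(shifts, default=0)
        for r in self.references:
            if 2 * max_trim >= len(r.ref.sequence):
                raise ConfigurationError(
                    f"end shifts of {max_trim} would exhaust reference {r.ref_id!r}"
                )

    @property
    def conditions(self) -> list[str]:
        return sorted(self.abundances)


def _library_rng(config: SimulationConfig, condition: str, replicate_index: int) -> np.random.Generator:
    cond_idx = config.conditions.index(condition)
    return np.random.default_rng([config.rng_seed, cond_idx, replicate_index])


def _shifted_insert(sim_ref: SimReference, shift5: int, shift3: int) -> str:
    """Apply end shifts: negative trims the mature end, positive extends into context."""
    seq = sim_ref.ref.sequence
    if shift5 < 0:
        seq = seq[-shift5:]
    elif shift5 > 0:
        take = min(shift5, len(sim_ref.flank5))
        seq = (sim_ref.flank5[-take:] if take else "") + seq
    if shift3 < 0:
        seq = seq[:shift3]
    elif shift3 > 0:
        seq = seq + sim_ref.flank3[:shift3]
    return seq


def _mutate(seq: str, rng: np.random.Generator, rate: float) -> str:
    if rate <= 0:
        return seq
    n_err = rng.binomial(len(seq), rate)
    if n_err == 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    for i in rng.choice(len(arr), size=n_err, replace=False):
        choices = _BASES[_BASES != arr[i]]
        arr[i] = choices[rng.integers(len(choices))]
    return arr.tobytes().decode()


def simulate_library(
    config: SimulationConfig, condition: str, replicate_index: int
) -> tuple[list[Read], dict[str, int]]:
    """One replicate library: reads plus the true per-reference counts.

    Truth counts are the multinomial draws before end shifts or errors, and
    sum exactly to ``reads_per_library``.
    """
    if condition not in config.abundances:
        raise ConfigurationError(f"unknown condition {condition!r}")
    rng = _library_rng(config, condition, replicate_index)
    refs = {r.ref_id: r for r in config.references}
    ref_ids = [r.ref_id for r in config.references]
    fracs = np.array([config.abundances[condition].get(rid, 0.0) for rid in ref_ids])
    truth_counts = rng.multinomial(config.reads_per_library, fracs)
    truth = dict(zip(ref_ids, (int(c) for c in truth_counts)))

    shift_values = np.array(sorted(config.end_shift_probabilities))
    shift_probs = np.array(
        [config.end_shift_probabilities[s] for s in shift_values]
    )

    sample_id = f"{condition}_{replicate_index}"
    reads: list[Read] = []
    serial = 0
    for rid, n in zip(ref_ids, truth_counts):
        sim_ref = refs[rid]
        if n == 0:
            continue
        s5 = rng.choice(shift_values, size=n, p=shift_probs)
        s3 = rng.choice(shift_values, size=n, p=shift_probs)
        for a, b in zip(s5, s3):
            insert = _shifted_insert(sim_ref, int(a), int(b))
            insert = _mutate(insert, rng, config.substitution_error_rate)
            seq = insert + config.adapter
            reads.append(Read(f"{sample_id}:{serial:06d}", seq, "I" * len(seq)))
            serial += 1
    return reads, truth


def simulate_experiment(
    config: SimulationConfig,
) -> tuple[dict[str, list[Read]], pd.DataFrame]:
    """All conditions x replicates.

    Returns ``(libraries, truth)`` where libraries maps sample_id
    (``{condition}_{replicate}``) to its reads and truth is a reference x
    sample DataFrame of true generated counts.
    """
    libraries: dict[str, list[Read]] = {}
    truth_cols: dict[str, dict[str, int]] = {}
    for condition in config.conditions:
        for rep in range(config.replicates_per_condition):
            sample_id = f"{condition}_{rep}"
            reads, truth = simulate_library(config, condition, rep)
            libraries[sample_id] = reads
            truth_cols[sample_id] = truth
    truth_df = pd.DataFrame(truth_cols).fillna(0).astype(int)
    return libraries, truth_df


def scaled_fractions(
    base: Mapping[str, float], factors: Mapping[str, float]
) -> dict[str, float]:
    """Scale chosen references' fractions by exact factors, renormalizing the rest.

    References named in *factors* get exactly ``base[r] * factors[r]``; the
    remaining probability mass is shared among the untouched references in
    proportion to their base fractions, so the configured fold changes of the
    scaled references hold exactly at equal library depth.
    """
    scaled = {r: base[r] * f for r, f in factors.items()}
    if any(v < 0 for v in scaled.values()):
        raise ConfigurationError("scaled fractions must be non-negative")
    rest = {r: v for r, v in base.items() if r not in factors}
    remaining = 1.0 - sum(scaled.values())
    if remaining < 0 or (not rest and abs(remaining) > 1e-12):
        raise ConfigurationError("scaled fractions exceed 1")
    rest_total = sum(rest.values())
    out = dict(scaled)
    for r, v in rest.items():
        out[r] = remaining * v / rest_total
    return out


# ---------------------------------------------------------------------------
# Default reference panel: miRBase-style mature sequences for the miRNAs the
# assay panel follows, with short fixed flanking context for templated
# extensions.  Condition names follow the transfection arms: "mock" and
# "antimir21".

DEFAULT_PANEL: list[SimReference] = [
    SimReference(ReferenceSmallRNA("miR21", "UAGCUUAUCAGACUGAUGUUGA", "mature"), "GTTCG", "CTGAC"),
    SimReference(ReferenceSmallRNA("miR21*", "CAACACCAGUCGAUGGGCUGU", "star"), "GACAA", "TTGAA"),
    SimReference(ReferenceSmallRNA("miR30", "UGUAAACAUCCUCGACUGGAAG", "mature"), "CGACT", "CTTTC"),
    SimReference(ReferenceSmallRNA("miR20", "UAAAGUGCUUAUAGUGCAGGUAG", "mature"), "TGTCA", "TTTGG"),
    SimReference(ReferenceSmallRNA("miR28", "AAGGAGCUCACAGUCUAUUGAG", "mature"), "GGTCC", "TTACC"),
]

#: Control-arm abundance fractions for the default panel.
DEFAULT_CONTROL_FRACTIONS = {
    "miR21": 0.35,
    "miR21*": 0.05,
    "miR30": 0.25,
    "miR20": 0.20,
    "miR28": 0.15,
}

#: Treated-arm fold factors emulating the reported effect directions:
#: miR21 reduced to 0.87x, miR30 strongly reduced, the antagomir-borne
#: star-strand sequence sharply increased.
DEFAULT_TREATED_FACTORS = {"miR21": 0.87, "miR30": 0.20, "miR21*": 6.0}


def default_config(
    rng_seed: int = 0,
    reads_per_library: int = 50_000,
    replicates_per_condition: int = 3,
    substitution_error_rate: float = 0.001,
    end_shift_probabilities: Mapping[int, float] | None = None,
) -> SimulationConfig:
    """The default mock vs anti-miR21 experiment over the default panel."""
    control = dict(DEFAULT_CONTROL_FRACTIONS)
    treated = scaled_fractions(control, DEFAULT_TREATED_FACTORS)
    return SimulationConfig(
        references=DEFAULT_PANEL,
        abundances={"mock": control, "antimir21": treated},
        reads_per_library=reads_per_library,
        replicates_per_condition=replicates_per_condition,
        end_shift_probabilities=dict(
            end_shift_probabilities
            or {-2: 0.02, -1: 0.08, 0: 0.80, 1: 0.08, 2: 0.02}
        ),
        substitution_error_rate=substitution_error_rate,
        rng_seed=rng_seed,
    )


def write_truth_tsv(truth: pd.DataFrame, path: str | Path, header: str | None = None) -> None:
    with open(path, "wt") as fh:
        if header:
            fh.write(header)
        truth.to_csv(fh, sep="\t", index_label="ref_id")
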
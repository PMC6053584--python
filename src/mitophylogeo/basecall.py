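"""Microarray base calling from four-channel hybridization intensities.

Each position is interrogated on both strands by four probes (A, C, G, T).
The presumptive call is the highest-intensity channel; confidence is the
differential signal-to-noise ratio dS/N = (highest - second highest) / sum.
Calls agreeing on both strands with dS/N >= 0.13 are "strong"; calls with
0.10 <= dS/N < 0.13 are accepted only when they match the reference base
("weak_ref"); strand disagreement or dS/N < 0.10 yields "ambiguous", and
such positions are excluded from downstream analyses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .alignment import SequenceAlignment

logger = logging.getLogger(__name__)

CHANNELS = ("A", "C", "G", "T")
STRONG_DSN = 0.13
WEAK_DSN = 0.10


@dataclass
class IntensityQuartet:
    """Four-channel intensities for one position on one strand."""

    position: int  # 1-based
    strand: str  # "forward" | "reverse"
    intensities: tuple[float, float, float, float]  # A, C, G, T
    reference_base: str

    def __post_init__(self) -> None:
        if any(x < 0 for x in self.intensities):
            raise ValueError("negative intensity")
        if self.strand not in ("forward", "reverse"):
            raise ValueError(f"bad strand {self.strand!r}")


def ds_n(quartet: IntensityQuartet) -> float:
    """Differential signal-to-noise: (max - second max) / sum; 0 if all zero."""
    vals = sorted(quartet.intensities, reverse=True)
    total = sum(vals)
    if total == 0:
        return 0.0
    return (vals[0] - vals[1]) / total


def _strand_call(q: IntensityQuartet) -> str | None:
    vals = q.intensities
    top = max(vals)
    if top == 0 or list(vals).count(top) > 1:
        return None  # all-zero or tied top channel: no call
    return CHANNELS[vals.index(top)]


@dataclass
class BaseCall:
    base: str  # called base or 'N'
    status: str  # "strong" | "weak_ref" | "ambiguous"
    dsn_forward: float
    dsn_reverse: float


def call_base(forward: IntensityQuartet, reverse: IntensityQuartet) -> BaseCall:
    """Call one position from both strands using the dS/N decision rules."""
    if forward.position != reverse.position:
        raise ValueError("strand quartets are for different positions")
    dsn_f, dsn_r = ds_n(forward), ds_n(reverse)
    call_f, call_r = _strand_call(forward), _strand_call(reverse)
    if call_f is None or call_r is None:
        logger.info("position %d: uncallable intensities", forward.position)
        return BaseCall("N", "ambiguous", dsn_f, dsn_r)
    if call_f != call_r:
        return BaseCall("N", "ambiguous", dsn_f, dsn_r)
    lo = min(dsn_f, dsn_r)
    if lo >= STRONG_DSN:
        return BaseCall(call_f, "strong", dsn_f, dsn_r)
    if lo >= WEAK_DSN and call_f == forward.reference_base:
        return BaseCall(call_f, "weak_ref", dsn_f, dsn_r)
    return BaseCall("N", "ambiguous", dsn_f, dsn_r)


def call_sequence(table: pd.DataFrame) -> tuple[str, frozenset[int]]:
    """Call every position of an intensity table (both strands required).

    Returns the called sequence ('N' at ambiguous positions) and the set of
    1-based ambiguous positions (candidates for exclusion).
    """
    seq: list[str] = []
    ambiguous: set[int] = set()
    for pos, grp in table.groupby("position", sort=True):
        quartets = {
            row.strand: IntensityQuartet(
                int(pos),
                row.strand,
                (row.I_A, row.I_C, row.I_G, row.I_T),
                row.ref,
            )
            for row in grp.itertuples()
        }
        if set(quartets) != {"forward", "reverse"}:
            raise ValueError(f"position {pos}: need both strands")
        result = call_base(quartets["forward"], quartets["reverse"])
        seq.append(result.base)
        if result.status == "ambiguous":
            ambiguous.add(int(pos))
    return "".join(seq), frozenset(ambiguous)


def read_intensity_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"position", "strand", "I_A", "I_C", "I_G", "I_T", "ref"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"intensity table missing columns: {sorted(missing)}")
    return df


def write_intensity_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def call_alignment_sample(
    aln: SequenceAlignment, table: pd.DataFrame, sample_id: str
) -> SequenceAlignment:
    """Replace one sample's sequence by microarray calls, excluding ambiguities."""
    seq, ambiguous = call_sequence(table)
    idx = aln.sample_ids.index(sample_id)
    seqs = list(aln.sequences)
    full = list(seqs[idx])
    for row_pos, base in zip(sorted(table["position"].unique()), seq):
        full[row_pos - 1] = base
    seqs[idx] = "".join(full)
    return SequenceAlignment(
        list(aln.sample_ids), seqs, aln.excluded_positions | ambiguous
    )
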
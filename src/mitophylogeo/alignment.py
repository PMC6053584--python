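"""Aligned mitogenome handling.

FASTA I/O, variable-site classification, haplotype collapsing, and
tandem-repeat reduction for near-identical whole-mitogenome alignments.
All coordinates are 1-based inclusive, matching the convention used for
mitogenome annotations (e.g. a control-region repeat at 15,696-15,735).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

BASES = frozenset("ACGT")
GAP = "-"
#: IUPAC ambiguity codes (everything that is neither a plain base nor a gap).
AMBIGUITY = frozenset("RYSWKMBDHVN")
#: Purines / pyrimidines -- a substitution within one set is a transition.
_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")


class AlignmentError(ValueError):
    """Raised for ragged, duplicate-id, or otherwise malformed alignments."""


@dataclass
class SequenceAlignment:
    """An aligned set of equal-length sequences over {A,C,G,T,-,IUPAC}.

    ``excluded_positions`` holds 1-based columns that were flagged as
    unresolvable (e.g. ambiguous microarray calls) and are skipped by site
    classification and haplotype identity.
    """

    sample_ids: list[str]
    sequences: list[str]
    excluded_positions: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if len(self.sample_ids) != len(self.sequences):
            raise AlignmentError("one id per sequence required")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise AlignmentError("duplicate sample ids")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise AlignmentError(f"ragged alignment: lengths {sorted(lengths)}")
        self.sequences = [s.upper().replace("U", "T") for s in self.sequences]
        if any(p < 1 or p > self.length for p in self.excluded_positions):
            raise AlignmentError("excluded positions outside [1, length]")

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    @property
    def length(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    def to_array(self) -> np.ndarray:
        """Return the alignment as an (n, length) array of single characters."""
        return np.frombuffer(
            "".join(self.sequences).encode(), dtype="S1"
        ).reshape(self.n, self.length)

    def kept_columns(self) -> np.ndarray:
        """0-based indices of columns not in ``excluded_positions``."""
        mask = np.ones(self.length, dtype=bool)
        for p in self.excluded_positions:
            mask[p - 1] = False
        return np.flatnonzero(mask)

    def subset(self, sample_ids: list[str]) -> "SequenceAlignment":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in index]
        if missing:
            raise AlignmentError(f"unknown sample ids: {missing}")
        return SequenceAlignment(
            list(sample_ids),
            [self.sequences[index[s]] for s in sample_ids],
            self.excluded_positions,
        )


def read_alignment(path) -> SequenceAlignment:
    """Read a FASTA alignment; uppercases and maps U->T."""
    ids, seqs = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        seqs.append(str(rec.seq))
    if not ids:
        raise AlignmentError(f"no FASTA records in {path}")
    return SequenceAlignment(ids, seqs)


def write_alignment(aln: SequenceAlignment, path) -> None:
    records = [
        SeqRecord(Seq(s), id=i, description="")
        for i, s in zip(aln.sample_ids, aln.sequences)
    ]
    SeqIO.write(records, str(path), "fasta")


@dataclass
class SiteClassification:
    """Per-alignment tallies of substitution and indel variation.

    Substitution accounting ignores gap characters: a column counts as
    variable when it shows >= 2 distinct bases among unambiguous calls, and
    is parsimony-informative when >= 2 of those bases each occur in >= 2
    sequences (otherwise it is a singleton site).  Columns opposing a gap to
    one or more bases are tallied separately as indel sites.  Columns
    containing any ambiguity character, and excluded positions, are skipped.
    """

    n_variable: int = 0
    n_parsimony_informative: int = 0
    n_singleton: int = 0
    n_transitions: int = 0
    n_transversions: int = 0
    n_indel_sites: int = 0
    n_multiallelic: int = 0

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def _is_transition(a: str, b: str) -> bool:
    pair = {a, b}
    return pair <= _PURINES or pair <= _PYRIMIDINES


def classify_sites(aln: SequenceAlignment) -> SiteClassification:
    if aln.n == 0:
        raise AlignmentError("empty alignment")
    arr = aln.to_array()
    out = SiteClassification()
    ambig_bytes = {c.encode() for c in AMBIGUITY}
    for col_idx in aln.kept_columns():
        col = arr[:, col_idx]
        chars = [c.decode() for c in col]
        if any(c in AMBIGUITY for c in chars):
            continue
        bases = [c for c in chars if c in BASES]
        has_gap = len(bases) < len(chars)
        uniq, counts = np.unique(bases, return_counts=True) if bases else ([], [])
        if has_gap and len(uniq) >= 1:
            out.n_indel_sites += 1
        if len(uniq) >= 2:
            out.n_variable += 1
            if np.count_nonzero(np.asarray(counts) >= 2) >= 2:
                out.n_parsimony_informative += 1
            else:
                out.n_singleton += 1
            if len(uniq) >= 3:
                out.n_multiallelic += 1
            for a, b in itertools.combinations(uniq, 2):
                if _is_transition(a, b):
                    out.n_transitions += 1
                else:
                    out.n_transversions += 1
    return out


@dataclass
class HaplotypeTable:
    """Distinct sequences, the sample->haplotype map, and per-population counts.

    Two samples share a haplotype iff their sequences are identical over all
    non-excluded positions.
    """

    haplotype_seq: dict[str, str]
    sample_to_haplotype: dict[str, str]
    counts: pd.DataFrame  # haplotype x population counts
    excluded_positions: frozenset[int] = field(default_factory=frozenset)

    @property
    def n_haplotypes(self) -> int:
        return len(self.haplotype_seq)

    @property
    def n_samples(self) -> int:
        return len(self.sample_to_haplotype)

    def haplotypes_per_population(self) -> pd.Series:
        return (self.counts > 0).sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"sample_id": s, "haplotype_id": h}
            for s, h in self.sample_to_haplotype.items()
        ]
        return pd.DataFrame(rows)


def collapse_haplotypes(
    aln: SequenceAlignment, population_map: dict[str, str] | None = None
) -> HaplotypeTable:
    """Group samples with identical sequences (over non-excluded positions)."""
    kept = aln.kept_columns()
    keys: dict[str, str] = {}
    hap_of: dict[str, str] = {}
    hap_seq: dict[str, str] = {}
    for sid, seq in zip(aln.sample_ids, aln.sequences):
        key = "".join(seq[i] for i in kept)
        if key not in keys:
            keys[key] = f"H{len(keys) + 1:03d}"
            hap_seq[keys[key]] = seq
        hap_of[sid] = keys[key]
    if population_map is None:
        population_map = {s: "all" for s in aln.sample_ids}
    df = pd.DataFrame(
        {
            "haplotype": [hap_of[s] for s in aln.sample_ids],
            "population": [population_map[s] for s in aln.sample_ids],
        }
    )
    counts = pd.crosstab(df["haplotype"], df["population"])
    return HaplotypeTable(hap_seq, hap_of, counts, aln.excluded_positions)


def collapse_tandem_repeats(
    aln: SequenceAlignment, repeat_regions: list[tuple[int, int]]
) -> tuple[SequenceAlignment, dict[int, int | None]]:
    """Reduce each tandem-repeat region to a single repeat unit.

    ``repeat_regions`` gives the 1-based inclusive span of ONE unit; any
    immediately following duplicate copies of that unit (identical to the
    first unit, or all-gap, in every sequence) are removed.  Returns the
    reduced alignment and an old->new 1-based coordinate map (``None`` for
    dropped columns).
    """
    arr = aln.to_array()
    length = aln.length
    drop = np.zeros(length, dtype=bool)
    for start, end in repeat_regions:
        if not (1 <= start <= end <= length):
            raise AlignmentError(f"repeat region {start}-{end} outside alignment")
        unit = arr[:, start - 1 : end]
        u = end - start + 1
        nxt = end  # 0-based start of candidate copy
        while nxt + u <= length:
            block = arr[:, nxt : nxt + u]
            dup = np.all(
                np.all(block == unit, axis=1) | np.all(block == b"-", axis=1)
            )
            if not dup:
                break
            drop[nxt : nxt + u] = True
            nxt += u
    keep = ~drop
    new_pos = np.cumsum(keep)
    coord_map: dict[int, int | None] = {
        old + 1: (int(new_pos[old]) if keep[old] else None) for old in range(length)
    }
    new_excluded = frozenset(
        coord_map[p] for p in aln.excluded_positions if coord_map[p] is not None
    )
    new_seqs = ["".join(np.char.decode(arr[i, keep])) for i in range(aln.n)]
    if drop.any():
        dropped = int(drop.sum())
        warnings.warn(f"collapsed {dropped} repeat columns", stacklevel=2)
    return (
        SequenceAlignment(list(aln.sample_ids), new_seqs, new_excluded),
        coord_map,
    )
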
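"""Position frequency matrices from labelled homolog alignments and the
thermophilic-minus-mesophilic frequency difference (∆PFM).

The evolutionary signal used for stability triage: homologs of the
engineering target are split into thermophilic and non-thermophilic classes,
a per-class position frequency matrix (PFM) is built on the columns of the
shared alignment mapped to the query's residue numbering, and

    ∆PFM(p, a) = f_thermo(p, a) − f_nonthermo(p, a)

so that a positive value means residue ``a`` at query position ``p`` is
enriched among thermophilic homologs. (The sign convention is fixed so that
the selection rule "keep substitutions with ∆PFM > 0" always means
thermophilic-preferred.) Gapped symbols are excluded from frequency
denominators; the per-column gap load is reported separately.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import GAP, Alignment
from .mutations import AMINO_ACIDS, MutationSpec

log = logging.getLogger(__name__)

THERMOPHILIC = "thermophilic"
NON_THERMOPHILIC = "non_thermophilic"

_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}


class UnmappedPositionError(KeyError):
    """A query position has no alignment column (query gapped there)."""


@dataclass
class LabeledFamily:
    """A homolog alignment with per-sequence thermostability labels.

    Sequences without a label are excluded from PFM construction with a
    logged warning; the query must be present in the alignment.
    """

    alignment: Alignment
    labels: dict[str, str]
    query_id: str

    def __post_init__(self) -> None:
        if self.query_id not in self.alignment.ids:
            raise ValueError(f"query id {self.query_id!r} not in alignment")
        unlabeled = [
            i for i in self.alignment.ids
            if i != self.query_id and i not in self.labels
        ]
        if unlabeled:
            log.warning(
                "%d sequences have no thermostability label and are excluded: %s",
                len(unlabeled), unlabeled[:5],
            )

    def class_ids(self, class_label: str) -> list[str]:
        return [
            i for i in self.alignment.ids
            if self.labels.get(i) == class_label
        ]


def map_columns_to_query(alignment: Alignment, query_id: str) -> dict[int, int]:
    """Map 1-based alignment columns to 1-based query residue positions.

    Columns where the query carries a gap are unmapped (absent from the
    result); mapped positions run strictly increasing 1..L_query.
    """
    query = alignment.get(query_id)
    if all(c == GAP for c in query):
        raise ValueError(f"query {query_id!r} is entirely gapped")
    mapping: dict[int, int] = {}
    pos = 0
    for col, c in enumerate(query, start=1):
        if c != GAP:
            pos += 1
            mapping[col] = pos
    return mapping


@dataclass
class PositionFrequencyMatrix:
    """Per-query-position amino-acid frequencies for one sequence class.

    ``frequencies`` is an (L, 20) array over :data:`AMINO_ACIDS`, rows
    normalised over non-gap symbols (an all-gap column yields a zero row);
    ``gap_fraction`` holds the per-position fraction of gapped class members.
    """

    class_label: str
    positions: np.ndarray            # 1-based query positions, shape (L,)
    frequencies: np.ndarray          # shape (L, 20)
    gap_fraction: np.ndarray         # shape (L,)
    n_sequences: int
    _pos_index: dict[int, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._pos_index = {int(p): i for i, p in enumerate(self.positions)}

    def freq(self, position: int, residue: str) -> float:
        try:
            row = self._pos_index[position]
        except KeyError:
            raise UnmappedPositionError(
                f"query position {position} is not covered by the PFM"
            ) from None
        return float(self.frequencies[row, _AA_INDEX[residue]])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.frequencies, columns=list(AMINO_ACIDS))
        df.insert(0, "position", self.positions)
        df["gap_fraction"] = self.gap_fraction
        return df


def build_pfm(
    family: LabeledFamily,
    class_label: str,
    unknown_symbol: str = "skip",
) -> PositionFrequencyMatrix:
    """Count residue frequencies per query-mapped column for one class.

    ``unknown_symbol`` governs non-canonical symbols (X, B, ...): ``"skip"``
    drops them from the denominator with a warning, ``"raise"`` errors.
    """
    ids = family.class_ids(class_label)
    if not ids:
        raise ValueError(f"no sequences labelled {class_label!r}")
    mapping = map_columns_to_query(family.alignment, family.query_id)
    cols = sorted(mapping)
    positions = np.array([mapping[c] for c in cols], dtype=int)
    counts = np.zeros((len(cols), len(AMINO_ACIDS)), dtype=float)
    gaps = np.zeros(len(cols), dtype=float)
    seqs = [family.alignment.get(i) for i in ids]
    unknown_seen = 0
    for row, col in enumerate(cols):
        for s in seqs:
            c = s[col - 1]
            if c == GAP:
                gaps[row] += 1
            elif c in _AA_INDEX:
                counts[row, _AA_INDEX[c]] += 1
            elif unknown_symbol == "raise":
                raise ValueError(f"unknown symbol {c!r} in column {col}")
            else:
                unknown_seen += 1
    if unknown_seen:
        log.warning("skipped %d non-canonical symbols", unknown_seen)
    totals = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        freqs = np.where(totals > 0, counts / totals, 0.0)
    return PositionFrequencyMatrix(
        class_label=class_label,
        positions=positions,
        frequencies=freqs,
        gap_fraction=gaps / len(ids),
        n_sequences=len(ids),
    )


@dataclass
class DeltaPFM:
    """Thermophilic-minus-non-thermophilic frequency difference per
    (position, residue); every entry lies in [−1, 1]."""

    positions: np.ndarray
    values: np.ndarray               # shape (L, 20)
    n_thermo: int
    n_nonthermo: int
    _pos_index: dict[int, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._pos_index = {int(p): i for i, p in enumerate(self.positions)}

    def value(self, position: int, residue: str) -> float:
        try:
            row = self._pos_index[position]
        except KeyError:
            raise UnmappedPositionError(
                f"query position {position} has no ∆PFM entry "
                "(column gapped in the query)"
            ) from None
        return float(self.values[row, _AA_INDEX[residue]])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(AMINO_ACIDS))
        df.insert(0, "position", self.positions)
        return df


def delta_pfm(
    pfm_thermo: PositionFrequencyMatrix,
    pfm_nonthermo: PositionFrequencyMatrix,
) -> DeltaPFM:
    """∆PFM = PFM(thermophilic) − PFM(non-thermophilic), positionwise."""
    if not np.array_equal(pfm_thermo.positions, pfm_nonthermo.positions):
        raise ValueError("PFMs cover different query position sets")
    return DeltaPFM(
        positions=pfm_thermo.positions.copy(),
        values=pfm_thermo.frequencies - pfm_nonthermo.frequencies,
        n_thermo=pfm_thermo.n_sequences,
        n_nonthermo=pfm_nonthermo.n_sequences,
    )


def mutation_dpfm(
    dpfm: DeltaPFM, m: MutationSpec, with_wt: bool = False
) -> float | tuple[float, float]:
    """∆PFM of the substituting residue at the mutation's position.

    Raises :class:`UnmappedPositionError` for query-gapped positions — an
    unmapped position is distinct from a ∆PFM value of 0.
    """
    v = dpfm.value(m.position, m.mut_residue)
    if with_wt:
        return v, dpfm.value(m.position, m.wt_residue)
    return v


def family_dpfm(family: LabeledFamily) -> DeltaPFM:
    """Convenience: both class PFMs and their difference in one call."""
    return delta_pfm(
        build_pfm(family, THERMOPHILIC),
        build_pfm(family, NON_THERMOPHILIC),
    )


# ---------------------------------------------------------------------------
# Homolog pipeline filters (greedy stand-ins for cd-hit / blastp windowing)

def pairwise_identity(a: str, b: str) -> float:
    """Fraction of matching residues over columns where neither side is
    gapped, normalised by the shorter ungapped length."""
    matches = 0
    len_a = sum(1 for c in a if c != GAP)
    len_b = sum(1 for c in b if c != GAP)
    denom = min(len_a, len_b)
    if denom == 0:
        return 0.0
    for ca, cb in zip(a, b):
        if ca != GAP and cb != GAP and ca == cb:
            matches += 1
    return matches / denom


def greedy_redundancy_filter(
    ids: list[str], sequences: list[str], identity_threshold: float = 0.90
) -> list[str]:
    """Greedy longest-first redundancy removal.

    Sequences are visited in order of decreasing ungapped length (ties by
    id); one is discarded if its identity to any already-retained sequence
    reaches the threshold. Deterministic for a given input.
    """
    if not sequences:
        raise ValueError("empty sequence set")
    if not 0 < identity_threshold < 1:
        raise ValueError("identity_threshold must lie in (0, 1)")
    order = sorted(
        range(len(sequences)),
        key=lambda i: (-sum(1 for c in sequences[i] if c != GAP), ids[i]),
    )
    retained: list[int] = []
    for i in order:
        if all(
            pairwise_identity(sequences[i], sequences[j]) < identity_threshold
            for j in retained
        ):
            retained.append(i)
    keep = {ids[i] for i in retained}
    return [i for i in ids if i in keep]


def similarity_window_filter(
    ids: list[str],
    sequences: list[str],
    query: str,
    lo: float = 0.40,
    hi: float = 1.00,
) -> list[str]:
    """Keep sequences whose identity to the query falls in [lo, hi]."""
    if lo > hi:
        raise ValueError(f"lo ({lo}) exceeds hi ({hi})")
    return [
        i for i, s in zip(ids, sequences)
        if lo <= pairwise_identity(s, query) <= hi
    ]
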
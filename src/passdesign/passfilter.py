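"""PASS (Position Analysis and Source Search) triage of candidate
stabilizing mutations.

Candidates arriving from folding-free-energy (∆∆G) screening are filtered
two ways and the union is kept:

* Way 1 — position: keep candidates falling inside flexible regions, i.e.
  maximal runs of residues whose RMSF exceeds a cutoff (0.2 nm by default).
  Rigidifying flexible sites is a classical stabilization route.
* Way 2 — evolutionary source: keep candidates with ∆∆G < 0 (predicted
  stabilizing) and ∆PFM > 0 (substitution enriched among thermophilic
  homologs). Both inequalities are strict.

Predictions are scored against experimental outcomes with the study's own
convention: the "true-positive rate" is the fraction of selected mutants
confirmed improved (conventionally a precision / positive predictive value),
and the "true-negative rate" the fraction of predicted-destabilizing mutants
confirmed decreased.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .msa import DeltaPFM, mutation_dpfm
from .mutations import MutationSpec

log = logging.getLogger(__name__)

IMPROVED = "improved"
DECREASED = "decreased"


class MissingScoreError(KeyError):
    """A candidate mutation lacks a required ∆∆G or ∆PFM entry."""


@dataclass
class FlexibilityProfile:
    """Per-residue RMSF (nm) on contiguous 1-based positions."""

    positions: np.ndarray
    rmsf_nm: np.ndarray
    source: str = ""

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=int)
        self.rmsf_nm = np.asarray(self.rmsf_nm, dtype=float)
        if np.any(self.rmsf_nm < 0):
            raise ValueError("RMSF values must be non-negative")
        if len(self.positions) == 0:
            raise ValueError("empty flexibility profile")
        expected = np.arange(self.positions[0], self.positions[0] + len(self.positions))
        if not np.array_equal(self.positions, expected):
            raise ValueError("flexibility profile has holes in position coverage")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, source: str = "") -> "FlexibilityProfile":
        return cls(
            positions=df["position"].to_numpy(),
            rmsf_nm=df["rmsf_nm"].to_numpy(),
            source=source,
        )


def flexible_regions(
    profile: FlexibilityProfile,
    cutoff: float = 0.2,
    min_run: int = 3,
) -> list[tuple[int, int]]:
    """Maximal runs of consecutive positions with RMSF strictly above
    *cutoff*, discarding runs shorter than *min_run* residues.

    Returns closed intervals ``(first, last)``, sorted and disjoint.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    above = profile.rmsf_nm > cutoff
    regions: list[tuple[int, int]] = []
    start = None
    for pos, flag in zip(profile.positions, above):
        if flag and start is None:
            start = int(pos)
        elif not flag and start is not None:
            if pos - start >= min_run:
                regions.append((start, int(pos) - 1))
            start = None
    if start is not None:
        last = int(profile.positions[-1])
        if last - start + 1 >= min_run:
            regions.append((start, last))
    return regions


def way1_filter(
    candidates: Sequence[MutationSpec],
    regions: Sequence[tuple[int, int]],
) -> list[MutationSpec]:
    """Keep candidates whose position lies inside any flexible region."""
    return [
        m for m in candidates
        if any(lo <= m.position <= hi for lo, hi in regions)
    ]


def way2_filter(
    candidates: Sequence[MutationSpec],
    ddg: Mapping[MutationSpec, float],
    dpfm: DeltaPFM,
    negative_control: bool = False,
) -> list[MutationSpec]:
    """Keep candidates with ∆∆G < 0 and ∆PFM > 0 (both strict).

    With ``negative_control=True`` the ∆PFM condition flips to < 0,
    reproducing the destabilizing-control selection.
    """
    missing = [m for m in candidates if m not in ddg]
    if missing:
        raise MissingScoreError(
            f"no ∆∆G entry for {[str(m) for m in missing[:5]]}"
        )
    kept = []
    for m in candidates:
        v = mutation_dpfm(dpfm, m)
        dpfm_ok = v < 0 if negative_control else v > 0
        if ddg[m] < 0 and dpfm_ok:
            kept.append(m)
    return kept


def pass_select(
    candidates: Sequence[MutationSpec],
    profile: FlexibilityProfile,
    ddg: Mapping[MutationSpec, float],
    dpfm: DeltaPFM,
    cutoff: float = 0.2,
    min_run: int = 3,
) -> pd.DataFrame:
    """Apply both PASS ways and report the union.

    Returns a report with one row per candidate: its scores, per-way flags,
    the final ``selected`` flag (way1 OR way2) and a rationale string.
    """
    regions = flexible_regions(profile, cutoff=cutoff, min_run=min_run)
    w1 = set(way1_filter(candidates, regions))
    w2 = set(way2_filter(candidates, ddg, dpfm))
    rows = []
    for m in candidates:
        reasons = []
        if m in w1:
            reasons.append(
                "Way 1: inside flexible region "
                + next(f"{lo}-{hi}" for lo, hi in regions if lo <= m.position <= hi)
            )
        if m in w2:
            reasons.append("Way 2: ddg < 0 and dpfm > 0")
        rows.append({
            "mutation": str(m),
            "position": m.position,
            "ddg": ddg.get(m, np.nan),
            "dpfm": mutation_dpfm(dpfm, m),
            "in_flexible_region": m in w1,
            "way1_selected": m in w1,
            "way2_selected": m in w2,
            "selected": m in w1 or m in w2,
            "rationale": "; ".join(reasons),
        })
    columns = [
        "mutation", "position", "ddg", "dpfm", "in_flexible_region",
        "way1_selected", "way2_selected", "selected", "rationale",
    ]
    report = pd.DataFrame(rows, columns=columns)
    log.info(
        "PASS: %d candidates -> %d Way 1, %d Way 2, %d selected (union)",
        len(candidates), len(w1), len(w2), int(report["selected"].sum()),
    )
    return report


@dataclass
class ValidationResult:
    """Confusion counts and the study-convention rates, in percent."""

    n_predicted_stabilizing: int
    n_confirmed: int
    n_predicted_destabilizing: int
    n_confirmed_destabilizing: int

    @property
    def tp_rate(self) -> float:
        """Percent of predicted-stabilizing mutants confirmed improved
        (a precision-like quantity under the study's naming)."""
        return 100.0 * self.n_confirmed / self.n_predicted_stabilizing

    @property
    def tn_rate(self) -> float:
        """Percent of predicted-destabilizing mutants confirmed decreased."""
        return 100.0 * self.n_confirmed_destabilizing / self.n_predicted_destabilizing


def evaluate_predictions(
    predicted_stabilizing: Iterable[MutationSpec],
    predicted_destabilizing: Iterable[MutationSpec],
    outcomes: Mapping[MutationSpec, str],
) -> ValidationResult:
    """Score predictions against experimental outcome labels.

    Every evaluated mutation needs an outcome of ``"improved"`` or
    ``"decreased"``; a missing outcome is an error, never an implicit miss.
    """
    stab = list(predicted_stabilizing)
    destab = list(predicted_destabilizing)
    missing = [m for m in (*stab, *destab) if m not in outcomes]
    if missing:
        raise KeyError(
            f"no experimental outcome for {[str(m) for m in missing[:5]]}"
        )
    return ValidationResult(
        n_predicted_stabilizing=len(stab),
        n_confirmed=sum(outcomes[m] == IMPROVED for m in stab),
        n_predicted_destabilizing=len(destab),
        n_confirmed_destabilizing=sum(outcomes[m] == DECREASED for m in destab),
    )
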
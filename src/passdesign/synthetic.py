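"""Seeded generators emulating every upstream data source the pipeline
consumes: labelled homolog families with planted thermophilic residue
preferences, RMSF profiles with planted flexible windows, ∆∆G tables with
planted stabilizing sets, additive/epistatic two-substrate fitness
landscapes, and jittered reactive-geometry coordinate frames.

All generators are pure functions of an explicit design + seed (no hidden
global state); landscape observation noise is frozen per genotype so
oracles are deterministic, as the ISM engine requires.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .assays import ActivityPair
from .io import GAP, Alignment, Frame, build_frame
from .ism import FitnessOracle
from .msa import NON_THERMOPHILIC, THERMOPHILIC, LabeledFamily
from .mutations import AMINO_ACIDS, MutationSpec, VariantGenotype
from .passfilter import FlexibilityProfile

QUERY_ID = "QUERY"


# ---------------------------------------------------------------------------
# Labelled homolog families

@dataclass
class FamilyDesign:
    """A homolog family with planted thermophilic/mesophilic residue
    contrasts at chosen positions.

    ``planted`` maps a 1-based query position to a (thermo-preferred,
    meso-preferred) residue pair realised with probability ``p`` in the
    corresponding class (background residues otherwise). ``gap_rate``
    applies to homolog columns only; the query is kept ungapped so every
    query position is mappable.
    """

    length: int = 120
    n_thermo: int = 50
    n_meso: int = 50
    planted: dict[int, tuple[str, str]] = field(default_factory=dict)
    p: float = 0.8
    gap_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.5 < self.p <= 1:
            raise ValueError("preference probability p must lie in (0.5, 1]")
        if not 0 <= self.gap_rate < 0.5:
            raise ValueError("gap_rate must lie in [0, 0.5)")
        bad = [q for q in self.planted if not 1 <= q <= self.length]
        if bad:
            raise ValueError(f"planted positions outside 1..length: {bad}")


def gen_family(design: FamilyDesign) -> LabeledFamily:
    """Generate an aligned, labelled family realising the planted contrasts."""
    rng = np.random.default_rng(design.seed)
    aas = np.array(list(AMINO_ACIDS))
    query = aas[rng.integers(0, 20, size=design.length)]
    ids = [QUERY_ID]
    seqs = ["".join(query)]
    labels: dict[str, str] = {}

    def draw(cls: str, idx: int) -> str:
        chars = []
        for pos0 in range(design.length):
            if design.gap_rate and rng.random() < design.gap_rate:
                chars.append(GAP)
                continue
            pos = pos0 + 1
            if pos in design.planted:
                thermo_res, meso_res = design.planted[pos]
                pref = thermo_res if cls == THERMOPHILIC else meso_res
                if rng.random() < design.p:
                    chars.append(pref)
                    continue
            chars.append(str(aas[rng.integers(0, 20)]))
        return "".join(chars)

    for cls, n, tag in (
        (THERMOPHILIC, design.n_thermo, "T"),
        (NON_THERMOPHILIC, design.n_meso, "M"),
    ):
        for i in range(n):
            sid = f"{tag}{i:04d}"
            ids.append(sid)
            seqs.append(draw(cls, i))
            labels[sid] = cls
    return LabeledFamily(
        alignment=Alignment(ids=ids, sequences=seqs),
        labels=labels,
        query_id=QUERY_ID,
    )


# ---------------------------------------------------------------------------
# Flexibility profiles

def gen_rmsf(
    length: int,
    windows: Sequence[tuple[int, int]],
    high: float = 0.25,
    low: float = 0.10,
    noise: float = 0.0,
    seed: int = 0,
) -> FlexibilityProfile:
    """RMSF profile ≈ *high* inside the planted windows, ≈ *low* outside.

    Overlapping or adjacent windows are merged with a warning; values are
    clipped at zero after Gaussian noise.
    """
    import logging

    for lo, hi in windows:
        if not (1 <= lo <= hi <= length):
            raise ValueError(f"window ({lo},{hi}) outside 1..{length}")
    merged: list[list[int]] = []
    for lo, hi in sorted(windows):
        if merged and lo <= merged[-1][1] + 1:
            logging.getLogger(__name__).warning(
                "merging overlapping windows %s and (%d,%d)", merged[-1], lo, hi
            )
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])
    rng = np.random.default_rng(seed)
    values = np.full(length, low, dtype=float)
    for lo, hi in merged:
        values[lo - 1:hi] = high
    if noise:
        values = values + rng.normal(0, noise, size=length)
    return FlexibilityProfile(
        positions=np.arange(1, length + 1),
        rmsf_nm=np.clip(values, 0.0, None),
        source=f"synthetic(seed={seed})",
    )


# ---------------------------------------------------------------------------
# ∆∆G tables with planted stabilizing sets

def gen_ddg(
    candidates: Sequence[MutationSpec],
    planted_stabilizing: Sequence[MutationSpec],
    effect: float = 2.0,
    noise: float = 0.0,
    seed: int = 0,
) -> tuple[dict[MutationSpec, float], dict[MutationSpec, bool]]:
    """∆∆G table: planted mutations centered at −effect, the rest at
    +effect; returns (table, truth labels)."""
    planted = set(planted_stabilizing)
    stray = planted - set(candidates)
    if stray:
        raise ValueError(f"planted mutations not among candidates: {sorted(map(str, stray))}")
    rng = np.random.default_rng(seed)
    table: dict[MutationSpec, float] = {}
    truth: dict[MutationSpec, bool] = {}
    for m in candidates:
        center = -effect if m in planted else effect
        table[m] = center + (rng.normal(0, noise) if noise else 0.0)
        truth[m] = m in planted
    return table, truth


# ---------------------------------------------------------------------------
# Two-substrate fitness landscapes

@dataclass
class LandscapeDesign:
    """An additive-plus-epistatic two-substrate landscape on log-activity
    scale.

    ``effects`` maps (position, residue) → (log-effect on cis, log-effect on
    trans); the wild-type residue at each site has implicit effect 0.
    ``epistasis`` adds pairwise terms keyed by a frozenset of two
    (position, residue) entries. Observation noise of width ``noise_sd``
    (log scale) is frozen per genotype from the seed.
    """

    sites: dict[int, str]                       # position -> wild-type residue
    effects: dict[tuple[int, str], tuple[float, float]]
    epistasis: dict[frozenset, tuple[float, float]] = field(default_factory=dict)
    base_cis: float = 1.0
    base_trans: float = 1.0
    noise_sd: float = 0.0
    seed: int = 0

    @classmethod
    def random(
        cls,
        sites: dict[int, str],
        effect_sd: float = 0.5,
        substrate_correlation: float = 0.0,
        n_epistatic_pairs: int = 0,
        epistasis_sd: float = 1.0,
        noise_sd: float = 0.0,
        seed: int = 0,
    ) -> "LandscapeDesign":
        """Draw per-(site, residue) effects from a bivariate normal with the
        given cis/trans correlation; optionally plant random pairwise
        epistasis terms."""
        rng = np.random.default_rng(seed)
        cov = effect_sd ** 2 * np.array(
            [[1.0, substrate_correlation], [substrate_correlation, 1.0]]
        )
        effects = {}
        for pos, wt in sorted(sites.items()):
            for aa in AMINO_ACIDS:
                if aa == wt:
                    continue
                e = rng.multivariate_normal([0.0, 0.0], cov)
                effects[(pos, aa)] = (float(e[0]), float(e[1]))
        epistasis: dict[frozenset, tuple[float, float]] = {}
        positions = sorted(sites)
        for _ in range(n_epistatic_pairs):
            p1, p2 = rng.choice(positions, size=2, replace=False)
            a1 = AMINO_ACIDS[rng.integers(0, 20)]
            a2 = AMINO_ACIDS[rng.integers(0, 20)]
            if a1 == sites[int(p1)] or a2 == sites[int(p2)]:
                continue
            key = frozenset({(int(p1), a1), (int(p2), a2)})
            e = rng.normal(0, epistasis_sd, size=2)
            epistasis[key] = (float(e[0]), float(e[1]))
        return cls(
            sites=dict(sites), effects=effects, epistasis=epistasis,
            noise_sd=noise_sd, seed=seed,
        )


class LandscapeOracle(FitnessOracle):
    """Synthetic oracle: log SA = log base + Σ site effects (+ pair terms)
    + frozen per-genotype noise; total on every genotype over its sites."""

    def __init__(self, design: LandscapeDesign):
        self.design = design

    def _noise(self, key: str) -> tuple[float, float]:
        if not self.design.noise_sd:
            return 0.0, 0.0
        sub = zlib.crc32(key.encode()) ^ (self.design.seed & 0x7FFFFFFF)
        rng = np.random.default_rng(sub)
        n = rng.normal(0, self.design.noise_sd, size=2)
        return float(n[0]), float(n[1])

    def evaluate(self, genotype: VariantGenotype) -> ActivityPair:
        d = self.design
        log_cis = np.log(d.base_cis)
        log_trans = np.log(d.base_trans)
        state = {
            pos: genotype.residue_at(pos, wt) for pos, wt in d.sites.items()
        }
        for pos, res in state.items():
            if res != d.sites[pos]:
                e = d.effects.get((pos, res), (0.0, 0.0))
                log_cis += e[0]
                log_trans += e[1]
        for key, (ec, et) in d.epistasis.items():
            if all(state.get(pos) == res for pos, res in key):
                log_cis += ec
                log_trans += et
        nc, nt = self._noise(str(genotype))
        return ActivityPair(
            sa_cis=float(np.exp(log_cis + nc)),
            sa_trans=float(np.exp(log_trans + nt)),
        )

    def additive_optimum(self, metric: str = "activity_cis") -> VariantGenotype:
        """Closed-form argmax for the purely additive case: per site, the
        residue with the largest effect on the chosen metric (wild type if
        all effects are negative)."""
        if self.design.epistasis:
            raise ValueError("closed form only valid without epistasis")
        idx = {"activity_cis": 0, "activity_trans": 1}[metric]
        muts = []
        for pos, wt in self.design.sites.items():
            best_aa, best_e = wt, 0.0
            for aa in AMINO_ACIDS:
                if aa == wt:
                    continue
                e = self.design.effects.get((pos, aa), (0.0, 0.0))[idx]
                if e > best_e or (e == best_e and best_aa != wt and aa < best_aa):
                    best_aa, best_e = aa, e
            if best_aa != wt:
                muts.append(MutationSpec(position=pos, wt_residue=wt, mut_residue=best_aa))
        return VariantGenotype(mutations=frozenset(muts))


def gen_landscape(design: LandscapeDesign) -> LandscapeOracle:
    return LandscapeOracle(design)


# ---------------------------------------------------------------------------
# Reactive-geometry coordinate frames

#: Default role selectors matching the frames built by :func:`gen_frames`.
DEFAULT_ROLES = {
    "h_o": ("S", 401, "HO2"),
    "o_ser": ("A", 39, "OG"),
    "c_d": ("S", 401, "C1"),
    "c_a": ("N", 402, "C4N"),
    "ring": [
        ("N", 402, nm) for nm in ("N1N", "C2N", "C3N", "C4N", "C5N", "C6N")
    ],
}


def default_role_map():
    """An :class:`~passdesign.geometry.AtomRoleMap` for generated frames."""
    from .geometry import AtomRoleMap, AtomSelector

    return AtomRoleMap(
        h_o=AtomSelector(*DEFAULT_ROLES["h_o"]),
        o_ser=AtomSelector(*DEFAULT_ROLES["o_ser"]),
        c_d=AtomSelector(*DEFAULT_ROLES["c_d"]),
        c_a=AtomSelector(*DEFAULT_ROLES["c_a"]),
        ring=[AtomSelector(*r) for r in DEFAULT_ROLES["ring"]],
    )


def _build_frame(dist1: float, dist2: float, angle: float) -> Frame:
    """One frame realising the target indicators exactly (distances nm,
    angle degrees; coordinates in Å)."""
    if dist1 <= 0 or dist2 <= 0:
        raise ValueError("target distances must be positive")
    if not 0 <= angle <= 90:
        raise ValueError("target elevation angle must lie in [0, 90]")
    ring_radius = 1.39  # Å, aromatic C–C
    theta = np.radians(angle)
    ring_names = [r[2] for r in DEFAULT_ROLES["ring"]]
    atoms = []
    ring_coords = []
    for i, nm in enumerate(ring_names):
        phi = 2 * np.pi * i / 6
        coord = np.array([ring_radius * np.cos(phi), ring_radius * np.sin(phi), 0.0])
        ring_coords.append(coord)
        atoms.append(("N", 402, "NAD", nm, coord))
    c_a = ring_coords[3]  # C4N
    d2 = dist2 * 10.0
    in_plane = c_a / np.linalg.norm(c_a)
    c_d = c_a - d2 * (np.cos(theta) * in_plane + np.sin(theta) * np.array([0, 0, 1.0]))
    atoms.append(("S", 401, "CHD", "C1", c_d))
    h_o = c_d + np.array([0.0, 1.0, 0.0])
    atoms.append(("S", 401, "CHD", "HO2", h_o))
    o_ser = h_o + dist1 * 10.0 * np.array([0.0, np.sqrt(0.5), np.sqrt(0.5)])
    atoms.append(("A", 39, "SER", "OG", o_ser))
    return build_frame(atoms)


def gen_frames(
    n: int,
    target_geometry: tuple[float, float, float] = (0.25, 0.27, 60.0),
    jitter: float = 0.0,
    modes: Sequence[tuple[float, float, float]] | None = None,
    mode_weights: Sequence[float] | None = None,
    seed: int = 0,
) -> list[Frame]:
    """Generate *n* frames around one or more target geometries.

    ``target_geometry`` is (dist1 nm, dist2 nm, angle deg); ``modes``
    overrides it with several targets (e.g. a 180°-flipped conformation)
    drawn with ``mode_weights``. ``jitter`` is the per-coordinate Gaussian
    SD in Å applied to every atom.
    """
    rng = np.random.default_rng(seed)
    geometries = list(modes) if modes is not None else [tuple(target_geometry)]
    if mode_weights is None:
        weights = np.full(len(geometries), 1 / len(geometries))
    else:
        weights = np.asarray(mode_weights, dtype=float)
        weights = weights / weights.sum()
    frames = []
    for _ in range(n):
        g = geometries[int(rng.choice(len(geometries), p=weights))]
        frame = _build_frame(*g)
        if jitter:
            frame = frame.copy()
            frame.coord = frame.coord + rng.normal(0, jitter, size=frame.coord.shape)
        frames.append(frame)
    return frames
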
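"""Reactive-conformation geometry of the hydride-transfer step.

For an NAD⁺-dependent dehydrogenase, a frame is catalytically poised when
three indicators are favourable:

* ``dist1`` — distance from the hydroxyl hydrogen at the R-configured
  stereocenter to the catalytic serine side-chain oxygen (proton relay);
* ``dist2`` — distance from the hydride-donating substrate carbon (C_D) to
  the accepting nicotinamide C4 (C_A);
* ``angle`` — the hydride attack angle toward the nicotinamide ring,
  measured by default as the elevation of the C_D→C_A vector above the
  least-squares plane of the six ring atoms (well-defined without an
  explicit hydride position); the C_D–H_D–C_A convention is selectable.

Coordinates are read in Å (PDB convention); distances are reported in nm
and angles in degrees.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .io import Frame

ANGSTROM_PER_NM = 10.0

Convention = Literal["ring_elevation", "donor_hydride_acceptor"]


class SelectorError(ValueError):
    """An atom-role selector resolved to zero or multiple atoms."""


@dataclass(frozen=True)
class AtomSelector:
    """Selects one atom by chain, residue number and atom name."""

    chain: str
    res_id: int
    atom_name: str

    def resolve(self, frame: Frame) -> np.ndarray:
        mask = (
            (frame.chain_id == self.chain)
            & (frame.res_id == self.res_id)
            & (frame.atom_name == self.atom_name)
        )
        n = int(mask.sum())
        if n != 1:
            raise SelectorError(
                f"selector {self} matched {n} atoms (need exactly 1)"
            )
        return frame.coord[mask][0].astype(float)


@dataclass
class AtomRoleMap:
    """Role → selector map for the indicator computation.

    ``h_o`` hydroxyl hydrogen at the R stereocenter, ``o_ser`` catalytic
    serine Oγ, ``c_d`` hydride-donating carbon, ``c_a`` accepting carbon
    (nicotinamide C4), ``ring`` the six nicotinamide ring atoms; ``h_d``
    (donated hydride) only for the alternate angle convention.
    """

    h_o: AtomSelector
    o_ser: AtomSelector
    c_d: AtomSelector
    c_a: AtomSelector
    ring: list[AtomSelector]
    h_d: AtomSelector | None = None

    def __post_init__(self) -> None:
        if len(self.ring) != 6:
            raise ValueError("RING must contain exactly 6 atom selectors")


@dataclass(frozen=True)
class GeometryIndicators:
    dist1: float   # nm
    dist2: float   # nm
    angle: float   # degrees


def ring_plane_normal(ring_coords: np.ndarray) -> np.ndarray:
    """Unit normal of the least-squares plane through the ring atoms.

    The normal is the principal axis of smallest variance of the centered
    coordinates; a degenerate (collinear) ring is rejected. Sign is fixed
    by the axis ordering of SVD, but the elevation angle is sign-free.
    """
    centered = ring_coords - ring_coords.mean(axis=0)
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[1] < 1e-9 * max(s[0], 1e-30):
        raise ValueError("degenerate (collinear) ring atoms")
    return vt[2]


def compute_indicators(
    frame: Frame,
    roles: AtomRoleMap,
    convention: Convention = "ring_elevation",
) -> GeometryIndicators:
    """Compute (dist1, dist2, angle) for one coordinate frame.

    ``ring_elevation`` (default): angle = elevation of the C_D→C_A vector
    above the least-squares nicotinamide plane, in [0°, 90°]; equals 90°
    minus the angle between that vector and the ring normal.
    ``donor_hydride_acceptor``: the C_D–H_D–C_A angle (requires ``h_d``).
    """
    h_o = roles.h_o.resolve(frame)
    o_ser = roles.o_ser.resolve(frame)
    c_d = roles.c_d.resolve(frame)
    c_a = roles.c_a.resolve(frame)
    dist1 = float(np.linalg.norm(h_o - o_ser)) / ANGSTROM_PER_NM
    dist2 = float(np.linalg.norm(c_d - c_a)) / ANGSTROM_PER_NM
    if convention == "ring_elevation":
        ring = np.array([sel.resolve(frame) for sel in roles.ring])
        normal = ring_plane_normal(ring)
        v = c_a - c_d
        nv = np.linalg.norm(v)
        if nv == 0:
            raise ValueError("C_D and C_A coincide")
        sin_elev = abs(float(np.dot(v / nv, normal)))
        angle = float(np.degrees(np.arcsin(np.clip(sin_elev, 0.0, 1.0))))
    elif convention == "donor_hydride_acceptor":
        if roles.h_d is None:
            raise ValueError("h_d selector required for this convention")
        h_d = roles.h_d.resolve(frame)
        u = c_d - h_d
        w = c_a - h_d
        cosang = np.dot(u, w) / (np.linalg.norm(u) * np.linalg.norm(w))
        angle = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
    else:
        raise ValueError(f"unknown convention {convention!r}")
    return GeometryIndicators(dist1=dist1, dist2=dist2, angle=angle)


def population_stats(
    frames: Sequence[Frame],
    roles: AtomRoleMap,
    convention: Convention = "ring_elevation",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-frame indicator table plus mean/SD summary over the ensemble."""
    if not frames:
        raise ValueError("need at least one frame")
    rows = []
    for i, frame in enumerate(frames):
        ind = compute_indicators(frame, roles, convention)
        rows.append({
            "frame": i,
            "dist1_nm": ind.dist1,
            "dist2_nm": ind.dist2,
            "angle_deg": ind.angle,
        })
    series = pd.DataFrame(rows)
    summary = (
        series[["dist1_nm", "dist2_nm", "angle_deg"]]
        .agg(["mean", "std"])
        .T.reset_index(names="indicator")
    )
    return series, summary


def classify_conformations(
    series: pd.DataFrame, k: int = 2, seed: int = 0
) -> tuple[np.ndarray, pd.DataFrame, bool]:
    """k-means over standardized (dist1, dist2, angle) with deterministic
    farthest-point initialization.

    Returns (labels, per-class indicator means, well_separated flag); the
    flag is False when between-class separation is under twice the mean
    within-class spread, signalling a forced split of unimodal data.
    """
    from sklearn.cluster import KMeans

    X = series[["dist1_nm", "dist2_nm", "angle_deg"]].to_numpy(dtype=float)
    if len(X) < k:
        raise ValueError("fewer frames than requested classes")
    if len(np.unique(X, axis=0)) < k:
        raise ValueError("fewer distinct frames than requested classes")
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    # farthest-point init: start at the point farthest from the centroid,
    # then greedily add the point farthest from all chosen centers
    centers = [Z[int(np.argmax(np.linalg.norm(Z - Z.mean(axis=0), axis=1)))]]
    while len(centers) < k:
        d = np.min(
            [np.linalg.norm(Z - c, axis=1) for c in centers], axis=0
        )
        centers.append(Z[int(np.argmax(d))])
    km = KMeans(n_clusters=k, init=np.array(centers), n_init=1, random_state=seed)
    labels = km.fit_predict(Z)
    means = (
        series.assign(conformation=labels)
        .groupby("conformation")[["dist1_nm", "dist2_nm", "angle_deg"]]
        .mean()
        .reset_index()
    )
    if k == 1:
        return labels, means, True
    within = float(np.mean([
        np.linalg.norm(Z[labels == c] - km.cluster_centers_[c], axis=1).mean()
        for c in range(k) if np.any(labels == c)
    ]))
    between = float(np.min(
        [np.linalg.norm(a - b) for i, a in enumerate(km.cluster_centers_)
         for b in km.cluster_centers_[i + 1:]]
    )) if k > 1 else np.inf
    well_separated = between > 2 * within
    if not well_separated:
        import logging
        logging.getLogger(__name__).warning(
            "low between-class separation: data may be unimodal"
        )
    return labels, means, well_separated
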
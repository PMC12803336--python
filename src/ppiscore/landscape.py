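"""Spherical-coordinate DockQ landscape and its inertia anisotropy.

For a decoy ensemble of one target, every model is superposed on the native
receptor (C-alpha Kabsch fit), the receptor C-alpha center of mass is moved
to the origin, and the ligand C-alpha center of mass of each model is
recorded as a direction (theta, phi) at the common radius R — the native
receptor-ligand COM separation.  The shape of the high-DockQ region is then
summarized by the DockQ^3-weighted moment-of-inertia tensor

    I_ab = (1/Nm) sum_i DockQ_i^3 (r_i^2 delta_ab - r_ai r_bi)

whose sorted eigenvalues l1 <= l2 <= l3 give the relative anisotropy

    kappa^2 = 1 - 3 (l1 l2 + l2 l3 + l1 l3) / (l1 + l2 + l3)^2,

0 for an isotropic shell and 1 for a collinear distribution.  Landscapes of
easy-to-score targets tend to be isotropic (small kappa^2).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .dockq_metric import dockq, kabsch_superpose
from .structio import DimerStructure, StructureError

__all__ = [
    "LandscapePoint",
    "InertiaSummary",
    "landscape_points",
    "dockq_weighted_inertia",
    "relative_anisotropy",
    "landscape_summary",
]


@dataclass(frozen=True)
class LandscapePoint:
    """One model's ligand-COM direction at the common radius R."""

    radius: float
    theta: float
    phi: float
    dockq: float

    def cartesian(self) -> np.ndarray:
        st = np.sin(self.theta)
        return self.radius * np.array(
            [st * np.cos(self.phi), st * np.sin(self.phi), np.cos(self.theta)]
        )


@dataclass(frozen=True)
class InertiaSummary:
    tensor: np.ndarray
    eigenvalues: np.ndarray  # ascending, nonnegative
    kappa2: float


def _chain_calpha(structure, chain: str) -> tuple[np.ndarray, np.ndarray]:
    sub = structure.extract_chain(chain)
    mask = sub.atom_names == "CA"
    return sub.atom_keys()[mask], sub.coords[mask]


def landscape_points(
    models: Sequence[DimerStructure],
    native: DimerStructure,
    dockq_values: Sequence[float] | None = None,
) -> list[LandscapePoint]:
    """Project each model onto the (theta, phi) sphere of radius R.

    Theta is measured from +z and phi from +x in the native receptor frame.
    DockQ weights are computed on the fly unless supplied.
    """
    rk, rec_ca = _chain_calpha(native, native.receptor_chain)
    _, lig_ca = _chain_calpha(native, native.ligand_chain)
    if len(rec_ca) < 3:
        raise StructureError("native receptor has fewer than 3 C-alpha atoms")
    rec_com = rec_ca.mean(axis=0)
    R = float(np.linalg.norm(lig_ca.mean(axis=0) - rec_com))
    key_index = {k: i for i, k in enumerate(rk)}
    points = []
    for m, model in enumerate(models):
        mk, m_rec_ca = _chain_calpha(model, model.receptor_chain)
        shared = [k for k in mk if k in key_index]
        if len(shared) < 3:
            raise StructureError("model shares fewer than 3 receptor C-alphas")
        midx = {k: i for i, k in enumerate(mk)}
        mob = m_rec_ca[[midx[k] for k in shared]]
        ref = rec_ca[[key_index[k] for k in shared]]
        transform, _ = kabsch_superpose(mob, ref)
        _, m_lig_ca = _chain_calpha(model, model.ligand_chain)
        v = transform.apply(m_lig_ca).mean(axis=0) - rec_com
        norm = np.linalg.norm(v)
        if norm == 0:
            raise StructureError("ligand COM coincides with receptor COM")
        u = v / norm
        theta = float(np.arccos(np.clip(u[2], -1.0, 1.0)))
        phi = float(np.arctan2(u[1], u[0])) % (2.0 * np.pi)
        q = (
            dockq_values[m]
            if dockq_values is not None
            else dockq(model, native).dockq
        )
        points.append(LandscapePoint(radius=R, theta=theta, phi=phi, dockq=float(q)))
    return points


def dockq_weighted_inertia(points: Sequence[LandscapePoint]) -> InertiaSummary:
    """DockQ^3-weighted inertia tensor of the landscape point cloud."""
    if len(points) == 0:
        raise ValueError("at least one landscape point is required")
    tensor = np.zeros((3, 3))
    for p in points:
        r = p.cartesian()
        w = p.dockq**3
        tensor += w * (np.dot(r, r) * np.eye(3) - np.outer(r, r))
    tensor /= len(points)
    eig = np.linalg.eigvalsh(tensor)
    eig = np.clip(eig, 0.0, None)
    total = eig.sum()
    kappa2 = _kappa2(eig) if total > 0 else float("nan")
    return InertiaSummary(tensor=tensor, eigenvalues=eig, kappa2=kappa2)


def _kappa2(eig: np.ndarray) -> float:
    l1, l2, l3 = eig
    s = l1 + l2 + l3
    return float(1.0 - 3.0 * (l1 * l2 + l2 * l3 + l1 * l3) / s**2)


def relative_anisotropy(summary: InertiaSummary | np.ndarray) -> float:
    """kappa^2 from an inertia summary or a triple of eigenvalues."""
    eig = (
        np.sort(np.asarray(summary, dtype=float))
        if not isinstance(summary, InertiaSummary)
        else summary.eigenvalues
    )
    if np.any(eig < 0):
        raise ValueError("eigenvalues must be nonnegative")
    if eig.sum() == 0:
        raise ValueError("kappa^2 undefined for an all-zero spectrum")
    return _kappa2(eig)


def landscape_summary(
    models: Sequence[DimerStructure],
    native: DimerStructure,
    dockq_values: Sequence[float] | None = None,
) -> tuple[list[LandscapePoint], InertiaSummary]:
    points = landscape_points(models, native, dockq_values)
    return points, dockq_weighted_inertia(points)
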
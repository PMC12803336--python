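"""DockQ model-quality metric and interface RMSDs.

DockQ compares a docked model of a two-chain complex with its reference
(native) structure and averages three terms in [0, 1]:

    DockQ = ( Fnat + 1/(1+(LRMSD/d1)^2) + 1/(1+(iRMSD/d2)^2) ) / 3

with scale factors d1 = 8.5 A and d2 = 1.5 A.  Fnat is the fraction of the
native cross-chain heavy-atom contacts (< 5 A) reproduced by the model;
LRMSD is the ligand backbone RMSD after superposing on the receptor
backbone; iRMSD is the backbone RMSD over the native interface residues
(any heavy atom < 10 A from the partner chain) after superposing on those
same atoms.  DockQ = 1 iff the model is identical to the native interface.

Also provided: an alternative interface RMSD defined through delta-rSASA
interface residues, where each monomer's interface C-alpha set is aligned
to its bound counterpart and the residual displacements of both monomers
are pooled:  iRMSD = sqrt((d_B1 + d_B2) / (N1 + N2)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .interface_features import InterfaceSet, interface_residues
from .structio import DimerStructure, Structure, StructureError

__all__ = [
    "DockQResult",
    "RigidTransform",
    "D1_LRMSD_SCALE",
    "D2_IRMSD_SCALE",
    "BACKBONE_ATOMS",
    "kabsch_superpose",
    "native_contacts",
    "fnat",
    "lrmsd",
    "irmsd_dockq",
    "dockq",
    "dockq_from_terms",
    "irmsd_rsasa",
]

D1_LRMSD_SCALE = 8.5
D2_IRMSD_SCALE = 1.5
NATIVE_CONTACT_CUTOFF = 5.0
INTERFACE_CUTOFF = 10.0
BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O"})


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid-body transform x -> R @ x + t."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation)
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8) or np.linalg.det(R) < 0:
            raise ValueError("rotation must be orthonormal with det +1")

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points) @ np.asarray(self.rotation).T + self.translation


@dataclass(frozen=True)
class DockQResult:
    fnat: float
    lrmsd: float
    irmsd: float
    dockq: float
    d1: float = D1_LRMSD_SCALE
    d2: float = D2_IRMSD_SCALE


def kabsch_superpose(
    mobile: np.ndarray, reference: np.ndarray
) -> tuple[RigidTransform, float]:
    """Least-squares rigid superposition of paired point sets.

    Returns the proper rigid transform minimizing the RMSD of
    ``transform(mobile)`` to ``reference``, and that minimal RMSD.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("point sets must be matching (n, 3) arrays")
    n = len(mobile)
    if n < 3:
        raise ValueError("at least 3 paired points required")
    mc, rc = mobile.mean(axis=0), reference.mean(axis=0)
    mob_c, ref_c = mobile - mc, reference - rc
    # collinear sets leave the rotation underdetermined
    if np.linalg.matrix_rank(mob_c, tol=1e-8) < 2:
        raise ValueError("degenerate (collinear) point set")
    rot, rssd = Rotation.align_vectors(ref_c, mob_c)
    R = rot.as_matrix()
    transform = RigidTransform(rotation=R, translation=rc - R @ mc)
    return transform, float(rssd / np.sqrt(n))


def _cross_chain_pairs(dimer: DimerStructure, cutoff: float) -> set[tuple[str, str]]:
    rec, lig = dimer.receptor, dimer.ligand
    rk, lk = rec.atom_keys(), lig.atom_keys()
    tree = cKDTree(rec.coords)
    pairs: set[tuple[str, str]] = set()
    for j, nbrs in enumerate(cKDTree(lig.coords).query_ball_tree(tree, cutoff)):
        for i in nbrs:
            if np.linalg.norm(rec.coords[i] - lig.coords[j]) < cutoff:
                pairs.add((rk[i], lk[j]))
    return pairs


def native_contacts(
    native: DimerStructure, cutoff: float = NATIVE_CONTACT_CUTOFF
) -> set[tuple[str, str]]:
    """Cross-chain heavy-atom pairs strictly closer than *cutoff* (5 A).

    Pairs are identified by (receptor atom key, ligand atom key) so they can
    be looked up in any model sharing the native's atom identities.
    """
    return _cross_chain_pairs(native, cutoff)


def fnat(
    model: DimerStructure,
    native: DimerStructure,
    cutoff: float = NATIVE_CONTACT_CUTOFF,
    native_contact_set: set | None = None,
) -> float:
    """Fraction of native cross-chain contacts present in the model."""
    ref = native_contacts(native, cutoff) if native_contact_set is None else native_contact_set
    if not ref:
        raise StructureError("native structure has no cross-chain contacts")
    mod = _cross_chain_pairs(model, cutoff)
    return len(ref & mod) / len(ref)


def _paired_coords(
    model: Structure, native: Structure, keys: list[str] | np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Coordinates of the given atom keys in both structures, in key order."""
    mk = {k: i for i, k in enumerate(model.atom_keys())}
    nk = {k: i for i, k in enumerate(native.atom_keys())}
    mi, ni = [], []
    for k in keys:
        if k in mk and k in nk:
            mi.append(mk[k])
            ni.append(nk[k])
    return model.coords[mi], native.coords[ni]


def _backbone_keys(structure: Structure, chain: str) -> list[str]:
    sub = structure.extract_chain(chain)
    mask = np.isin(sub.atom_names, list(BACKBONE_ATOMS))
    return list(sub.atom_keys()[mask])


def lrmsd(model: DimerStructure, native: DimerStructure) -> float:
    """Ligand backbone RMSD after superposing on the receptor backbone."""
    rec_keys = _backbone_keys(native, native.receptor_chain)
    lig_keys = _backbone_keys(native, native.ligand_chain)
    mob_rec, ref_rec = _paired_coords(model, native, rec_keys)
    if len(mob_rec) < 3:
        raise StructureError("too few shared receptor backbone atoms")
    transform, _ = kabsch_superpose(mob_rec, ref_rec)
    mob_lig, ref_lig = _paired_coords(model, native, lig_keys)
    if len(mob_lig) == 0:
        raise StructureError("no shared ligand backbone atoms")
    moved = transform.apply(mob_lig)
    return float(np.sqrt(((moved - ref_lig) ** 2).sum(axis=1).mean()))


def _native_interface_residues(
    native: DimerStructure, cutoff: float = INTERFACE_CUTOFF
) -> set[str]:
    """Residues with any heavy atom strictly within *cutoff* of the partner."""
    rec, lig = native.receptor, native.ligand
    rres, lres = rec.residue_keys(), lig.residue_keys()
    tree = cKDTree(rec.coords)
    out: set[str] = set()
    for j, nbrs in enumerate(cKDTree(lig.coords).query_ball_tree(tree, cutoff)):
        for i in nbrs:
            if np.linalg.norm(rec.coords[i] - lig.coords[j]) < cutoff:
                out.add(rres[i])
                out.add(lres[j])
    return out


def irmsd_dockq(
    model: DimerStructure,
    native: DimerStructure,
    interface: set[str] | None = None,
) -> float:
    """Backbone RMSD over native interface residues after self-superposition.

    The interface (residues with any heavy atom < 10 A across chains) is
    determined on the native only and applied to both structures.
    """
    if interface is None:
        interface = _native_interface_residues(native)
    if not interface:
        raise StructureError("native structure has an empty interface")
    res_keys = native.residue_keys()
    mask = np.isin(res_keys, list(interface)) & np.isin(
        native.atom_names, list(BACKBONE_ATOMS)
    )
    keys = list(native.atom_keys()[mask])
    mob, ref = _paired_coords(model, native, keys)
    if len(mob) < 3:
        raise StructureError("too few shared interface backbone atoms")
    _, rmsd = kabsch_superpose(mob, ref)
    return rmsd


def dockq_from_terms(
    fnat_value: float,
    lrmsd_value: float,
    irmsd_value: float,
    d1: float = D1_LRMSD_SCALE,
    d2: float = D2_IRMSD_SCALE,
) -> float:
    """Average of Fnat and the two scaled-RMSD terms, each in [0, 1]."""
    return (
        fnat_value
        + 1.0 / (1.0 + (lrmsd_value / d1) ** 2)
        + 1.0 / (1.0 + (irmsd_value / d2) ** 2)
    ) / 3.0


def dockq(
    model: DimerStructure,
    native: DimerStructure,
    d1: float = D1_LRMSD_SCALE,
    d2: float = D2_IRMSD_SCALE,
    native_contact_set: set | None = None,
    native_interface: set[str] | None = None,
) -> DockQResult:
    """Composite DockQ of *model* against *native*.

    Precomputed native contact/interface sets may be passed when scoring
    many models against one target.
    """
    f = fnat(model, native, native_contact_set=native_contact_set)
    lr = lrmsd(model, native)
    ir = irmsd_dockq(model, native, interface=native_interface)
    score = dockq_from_terms(f, lr, ir, d1, d2)
    return DockQResult(fnat=f, lrmsd=lr, irmsd=ir, dockq=float(score), d1=d1, d2=d2)


def _interface_calpha(
    structure: Structure, residues: set[str]
) -> list[str]:
    mask = np.isin(structure.residue_keys(), list(residues)) & (
        structure.atom_names == "CA"
    )
    return list(structure.atom_keys()[mask])


def irmsd_rsasa(
    monomers: tuple[Structure, Structure],
    bound_reference: DimerStructure,
    interface: InterfaceSet | None = None,
) -> float:
    """Pooled interface C-alpha RMSD of two monomer conformations.

    Interface residues are defined on the bound reference by delta-rSASA.
    Each monomer conformation is aligned to its bound counterpart — on its
    interface C-alpha set when that set has >= 3 atoms, otherwise on all of
    its C-alpha atoms — and the squared residual displacements of interface
    C-alphas are pooled over both monomers:
    iRMSD = sqrt((d_B1 + d_B2) / (N1 + N2)).
    """
    if interface is None:
        interface = interface_residues(bound_reference)
    chain_sets = {
        bound_reference.receptor_chain: set(interface.receptor_residues),
        bound_reference.ligand_chain: set(interface.ligand_residues),
    }
    total_sq = 0.0
    total_n = 0
    for mono in monomers:
        chain = mono.chains[0]
        if chain not in chain_sets:
            raise StructureError(f"monomer chain {chain!r} not in bound reference")
        bound_mono = bound_reference.extract_chain(chain)
        iface_keys = _interface_calpha(bound_mono, chain_sets[chain])
        if not iface_keys:
            continue
        mob_if, ref_if = _paired_coords(mono, bound_mono, iface_keys)
        if len(mob_if) != len(iface_keys):
            raise StructureError("monomer conformation is missing interface atoms")
        if len(mob_if) >= 3:
            transform, _ = kabsch_superpose(mob_if, ref_if)
        else:
            ca_keys = list(
                bound_mono.atom_keys()[bound_mono.atom_names == "CA"]
            )
            mob_all, ref_all = _paired_coords(mono, bound_mono, ca_keys)
            if len(mob_all) < 3:
                raise StructureError("too few C-alpha atoms for alignment")
            transform, _ = kabsch_superpose(mob_all, ref_all)
        moved = transform.apply(mob_if)
        total_sq += float(((moved - ref_if) ** 2).sum())
        total_n += len(mob_if)
    if total_n == 0:
        raise StructureError("no interface residues with C-alpha atoms")
    return float(np.sqrt(total_sq / total_n))
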
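"""Physical features of protein-protein interfaces.

Implements per-residue solvent accessible surface area (Shrake-Rupley),
relative SASA against extended Gly-X-Gly reference areas, the
delta-rSASA interface-residue definition (a residue is interfacial iff its
relative accessibility drops when the partner chain is present), the
cross-chain heavy-atom contact count Nc at a distance cutoff dc (default
4.5 A, strict '<'), and the interface separability S: the training accuracy
of a degree-3 polynomial-kernel maximum-margin classifier predicting chain
membership from atom coordinates.  S = 1 means a cubic surface perfectly
separates the chains (a flat, non-intertwined interface); S near 0.5 means
the chains are highly intertwined.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .structio import DimerStructure, Structure, StructureError

__all__ = [
    "InterfaceSet",
    "FeatureVector",
    "VDW_RADII",
    "GXG_REFERENCE_AREAS",
    "shrake_rupley",
    "residue_sasa",
    "relative_sasa",
    "interface_residues",
    "count_interface_contacts",
    "contact_count_scan",
    "interface_separability",
    "point_separability",
]

# Van der Waals radii (A), Bondi-style values used by common SASA codes.
VDW_RADII: dict[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "SE": 1.90,
    "F": 1.47,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
}
DEFAULT_RADIUS = 1.70

# Theoretical maximum accessible areas (A^2) of residue X in an extended
# Gly-X-Gly tripeptide (Tien et al., 2013), used as rSASA denominators.
GXG_REFERENCE_AREAS: dict[str, float] = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}


@dataclass(frozen=True)
class InterfaceSet:
    """Residue keys (``chain:resnum:icode``) buried upon complex formation."""

    receptor_residues: frozenset
    ligand_residues: frozenset

    def __len__(self) -> int:
        return len(self.receptor_residues) + len(self.ligand_residues)

    @property
    def all_residues(self) -> frozenset:
        return self.receptor_residues | self.ligand_residues


@dataclass(frozen=True)
class FeatureVector:
    """The two interface features used by the combined scoring function."""

    n_contacts: int
    separability: float
    contact_cutoff: float = 4.5

    def __post_init__(self):
        if self.n_contacts < 0:
            raise ValueError("n_contacts must be nonnegative")
        if not 0.0 <= self.separability <= 1.0:
            raise ValueError("separability must lie in [0, 1]")
        if self.contact_cutoff <= 0:
            raise ValueError("contact_cutoff must be positive")

    def as_array(self) -> np.ndarray:
        return np.array([float(self.n_contacts), self.separability])


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic golden-spiral points on the unit sphere."""
    i = np.arange(n) + 0.5
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def shrake_rupley(
    coords: np.ndarray,
    radii: np.ndarray,
    probe_radius: float = 1.4,
    n_points: int = 960,
) -> np.ndarray:
    """Per-atom SASA (A^2) by test points on inflated atomic spheres.

    A point on atom i's sphere of radius ``r_i + probe`` counts as exposed
    if it lies outside every neighbor's inflated sphere; the atom's area is
    4*pi*(r_i+probe)^2 times its exposed fraction.
    """
    if probe_radius <= 0:
        raise ValueError("probe_radius must be positive")
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    n = len(coords)
    pts = _sphere_points(n_points)
    inflated = radii + probe_radius
    tree = cKDTree(coords)
    max_reach = 2.0 * inflated.max()
    areas = np.empty(n)
    for i in range(n):
        nbrs = [j for j in tree.query_ball_point(coords[i], inflated[i] + max_reach)
                if j != i]
        test = coords[i] + inflated[i] * pts
        if nbrs:
            nb_coords = coords[nbrs]
            nb_rad = inflated[nbrs]
            d2 = ((test[:, None, :] - nb_coords[None, :, :]) ** 2).sum(axis=2)
            buried = (d2 < (nb_rad**2)[None, :]).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        areas[i] = 4.0 * np.pi * inflated[i] ** 2 * frac
    return areas


def _atom_radii(structure: Structure) -> np.ndarray:
    return np.array([VDW_RADII.get(e, DEFAULT_RADIUS) for e in structure.elements])


def residue_sasa(
    structure: Structure, probe_radius: float = 1.4, n_points: int = 960
) -> dict[str, float]:
    """Solvent accessible surface area per residue (A^2)."""
    if structure.n_atoms == 0:
        raise StructureError("cannot compute SASA of an empty structure")
    atom_areas = shrake_rupley(
        structure.coords, _atom_radii(structure), probe_radius, n_points
    )
    out: dict[str, float] = {}
    for key, area in zip(structure.residue_keys(), atom_areas):
        out[key] = out.get(key, 0.0) + float(area)
    return out


def relative_sasa(
    structure: Structure,
    probe_radius: float = 1.4,
    reference_areas: dict[str, float] | None = None,
    n_points: int = 960,
) -> dict[str, float]:
    """Per-residue SASA divided by its extended-tripeptide reference area."""
    refs = GXG_REFERENCE_AREAS if reference_areas is None else reference_areas
    res_name_by_key: dict[str, str] = {}
    for key, name in zip(structure.residue_keys(), structure.res_names):
        res_name_by_key.setdefault(key, name)
    sasa = residue_sasa(structure, probe_radius, n_points)
    out = {}
    for key, area in sasa.items():
        name = res_name_by_key[key]
        if name not in refs:
            raise KeyError(f"no reference area for residue {name!r} ({key})")
        out[key] = area / refs[name]
    return out


def interface_residues(
    dimer: DimerStructure,
    probe_radius: float = 1.4,
    reference_areas: dict[str, float] | None = None,
    n_points: int = 960,
) -> InterfaceSet:
    """Residues whose relative accessibility drops in the complex.

    A residue belongs to the interface iff
    rSASA(complex) - rSASA(isolated monomer, same conformation) < 0.
    """
    bound = relative_sasa(dimer, probe_radius, reference_areas, n_points)
    flagged: dict[str, set] = {dimer.receptor_chain: set(), dimer.ligand_chain: set()}
    for chain in (dimer.receptor_chain, dimer.ligand_chain):
        mono = relative_sasa(
            dimer.extract_chain(chain), probe_radius, reference_areas, n_points
        )
        for key, free_value in mono.items():
            if bound[key] - free_value < 0.0:
                flagged[chain].add(key)
    return InterfaceSet(
        receptor_residues=frozenset(flagged[dimer.receptor_chain]),
        ligand_residues=frozenset(flagged[dimer.ligand_chain]),
    )


def count_interface_contacts(dimer: DimerStructure, cutoff: float = 4.5) -> int:
    """Number of cross-chain heavy-atom pairs strictly closer than *cutoff*."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    rec = dimer.receptor.coords
    lig = dimer.ligand.coords
    tree = cKDTree(rec)
    count = 0
    for j, nbrs in enumerate(cKDTree(lig).query_ball_tree(tree, cutoff)):
        if nbrs:
            d = np.linalg.norm(rec[nbrs] - lig[j], axis=1)
            count += int((d < cutoff).sum())
    return count


def contact_count_scan(
    dimer: DimerStructure, cutoffs: np.ndarray | None = None
) -> dict[float, int]:
    """Nc over a range of cutoffs (utility for cutoff selection)."""
    if cutoffs is None:
        cutoffs = np.arange(1.0, 30.0 + 1e-9, 0.1)
    return {float(c): count_interface_contacts(dimer, float(c)) for c in cutoffs}


def point_separability(
    points_a: np.ndarray,
    points_b: np.ndarray,
    regularization: float = 1.0,
    seed: int = 0,
) -> float:
    """Training accuracy of a cubic-kernel SVM separating two point clouds.

    Coordinates are standardized before fitting; classes are weighted
    inversely to their sizes.  The fit is deterministic for fixed inputs;
    *seed* is accepted for interface uniformity.
    """
    points_a = np.asarray(points_a, dtype=float)
    points_b = np.asarray(points_b, dtype=float)
    if len(points_a) == 0 or len(points_b) == 0:
        raise ValueError("both point sets must be nonempty")
    X = np.vstack([points_a, points_b])
    y = np.concatenate([np.zeros(len(points_a)), np.ones(len(points_b))])
    Xs = StandardScaler().fit_transform(X)
    clf = SVC(
        kernel="poly",
        degree=3,
        coef0=1.0,
        gamma="scale",
        C=regularization,
        class_weight="balanced",
        random_state=int(seed),
    )
    clf.fit(Xs, y)
    return float((clf.predict(Xs) == y).mean())


def interface_separability(
    dimer: DimerStructure,
    regularization: float = 1.0,
    seed: int = 0,
    use_interface: bool = True,
    min_atoms_per_chain: int = 10,
) -> float:
    """Separability S of a dimer's interface.

    The point sets are the heavy atoms of the delta-rSASA interface residues
    of each chain; when the interface is empty or a chain contributes fewer
    than *min_atoms_per_chain* atoms (e.g. far-apart decoys), the whole
    chains are used instead so that S is always defined.
    """
    rec = dimer.receptor
    lig = dimer.ligand
    if rec.n_atoms == 0 or lig.n_atoms == 0:
        raise StructureError("both chains must contain atoms")
    pts_r, pts_l = rec.coords, lig.coords
    if use_interface:
        iface = interface_residues(dimer)
        if len(iface) > 0:
            rk = rec.residue_keys()
            lk = lig.residue_keys()
            mask_r = np.isin(rk, list(iface.receptor_residues))
            mask_l = np.isin(lk, list(iface.ligand_residues))
            if mask_r.sum() >= min_atoms_per_chain and mask_l.sum() >= min_atoms_per_chain:
                pts_r, pts_l = rec.coords[mask_r], lig.coords[mask_l]
    return point_separability(pts_r, pts_l, regularization=regularization, seed=seed)
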
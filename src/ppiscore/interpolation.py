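"""Linear bound-unbound conformational interpolation of monomers.

The unbound conformer is matched to the bound one by global sequence
alignment: unaligned terminal residues are trimmed, substituted residues
are dropped, and residues whose heavy-atom name sets differ between the two
conformers are dropped, leaving Nh paired heavy atoms.  After (optionally)
Kabsch-superposing the unbound conformer onto the bound one — so the
displacement captures internal deformation rather than global pose — the
per-atom displacement matrix D (rows r_U,i - r_B,i) defines a linear path

    I_n = bound + (n / N_I) * D,        n = 0 .. N_I,

whose endpoints reproduce the bound and unbound conformations exactly.
N_I defaults to 6; in automatic mode it is raised until the RMS per-image
spacing |D|/N_I is at most 1 A.  The interface RMSD (delta-rSASA
definition) is tracked along the path, normalized by its unbound-endpoint
value to give iRMSD* in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import Align

from .dockq_metric import irmsd_rsasa, kabsch_superpose
from .interface_features import InterfaceSet, interface_residues
from .structio import DimerStructure, Structure, StructureError

__all__ = [
    "MatchedConformerPair",
    "InterpolationSet",
    "match_conformations",
    "displacement_matrix",
    "interpolate_images",
    "irmsd_progression",
]

DEFAULT_N_IMAGES = 6
MAX_IMAGE_SPACING = 1.0  # A, used when n_images is chosen automatically
MIN_IDENTITY = 0.30

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


@dataclass
class MatchedConformerPair:
    """Atomwise-paired bound and unbound conformations of one monomer."""

    bound_coords: np.ndarray  # (Nh, 3)
    unbound_coords: np.ndarray  # (Nh, 3)
    template: Structure  # bound-structure subset carrying atom identities

    @property
    def n_atoms(self) -> int:
        return len(self.bound_coords)


@dataclass
class InterpolationSet:
    displacement: np.ndarray  # (Nh, 3)
    n_images: int
    images: list[np.ndarray]  # coordinates for n = 0 .. n_images
    pair: MatchedConformerPair

    @property
    def spacing(self) -> float:
        """RMS per-atom displacement between consecutive images (A)."""
        return _rms_norm(self.displacement) / self.n_images

    def image_structure(self, n: int) -> Structure:
        return self.pair.template.with_coords(self.images[n])


def _rms_norm(displacement: np.ndarray) -> float:
    return float(np.sqrt((displacement**2).sum(axis=1).mean()))


def _residue_table(structure: Structure):
    """Ordered residue keys with residue name and atom indices."""
    keys = structure.residue_keys()
    order: dict[str, list[int]] = {}
    names: dict[str, str] = {}
    for i, (k, rn) in enumerate(zip(keys, structure.res_names)):
        order.setdefault(k, []).append(i)
        names.setdefault(k, rn)
    return list(order), names, order


def _sequence(res_keys, names) -> str:
    return "".join(_THREE_TO_ONE.get(names[k], "X") for k in res_keys)


def match_conformations(
    bound: Structure, unbound: Structure, superpose: bool = True
) -> MatchedConformerPair:
    """Pair the heavy atoms of two conformers of the same monomer.

    Residues aligned to gaps (terminal overhangs and insertions),
    substituted residues, and residues whose heavy-atom name sets differ
    are excluded.  Raises if sequence identity over aligned columns falls
    below 30%.  When *superpose* is set (default), the unbound coordinates
    are rigidly superposed onto the bound ones over the matched atoms.
    """
    for s, label in ((bound, "bound"), (unbound, "unbound")):
        if len(s.chains) != 1:
            raise StructureError(f"{label} conformer must be a single chain")
    b_keys, b_names, b_atoms = _residue_table(bound)
    u_keys, u_names, u_atoms = _residue_table(unbound)
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -5.0
    aligner.extend_gap_score = -0.5
    aln = aligner.align(_sequence(b_keys, b_names), _sequence(u_keys, u_names))[0]
    pairs: list[tuple[str, str]] = []
    n_aligned = n_match = 0
    for (b0, b1), (u0, u1) in zip(*aln.aligned):
        for off in range(b1 - b0):
            bk, uk = b_keys[b0 + off], u_keys[u0 + off]
            n_aligned += 1
            if b_names[bk] == u_names[uk]:
                n_match += 1
                pairs.append((bk, uk))
    if n_aligned == 0 or n_match / n_aligned < MIN_IDENTITY:
        raise StructureError(
            "conformers do not appear to be the same protein "
            f"(identity {0 if n_aligned == 0 else n_match / n_aligned:.0%})"
        )
    b_idx: list[int] = []
    u_idx: list[int] = []
    for bk, uk in pairs:
        b_by_name = {bound.atom_names[i]: i for i in b_atoms[bk]}
        u_by_name = {unbound.atom_names[i]: i for i in u_atoms[uk]}
        if set(b_by_name) != set(u_by_name):
            continue  # unequal heavy-atom sets: drop the residue
        for name in sorted(b_by_name):
            b_idx.append(b_by_name[name])
            u_idx.append(u_by_name[name])
    if not b_idx:
        raise StructureError("no atoms could be paired between conformers")
    bound_coords = bound.coords[b_idx]
    unbound_coords = unbound.coords[u_idx]
    if superpose and len(b_idx) >= 3:
        transform, _ = kabsch_superpose(unbound_coords, bound_coords)
        unbound_coords = transform.apply(unbound_coords)
    template = bound.subset(np.asarray(b_idx))
    return MatchedConformerPair(
        bound_coords=bound_coords,
        unbound_coords=unbound_coords,
        template=template,
    )


def displacement_matrix(pair: MatchedConformerPair) -> np.ndarray:
    """Row i = r_unbound,i - r_bound,i over the matched atoms."""
    return pair.unbound_coords - pair.bound_coords


def interpolate_images(
    pair: MatchedConformerPair, n_images: int | None = DEFAULT_N_IMAGES
) -> InterpolationSet:
    """Linear path of conformations from bound (n=0) to unbound (n=N_I).

    With ``n_images=None`` the image count starts at the default and is
    raised until consecutive images are at most 1 A RMS apart.
    """
    disp = displacement_matrix(pair)
    if n_images is None:
        n_images = DEFAULT_N_IMAGES
        while _rms_norm(disp) / n_images > MAX_IMAGE_SPACING:
            n_images += 1
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    images = [pair.bound_coords + (n / n_images) * disp for n in range(n_images + 1)]
    images[-1] = pair.unbound_coords.copy()  # exact endpoint, no rounding
    return InterpolationSet(
        displacement=disp, n_images=n_images, images=images, pair=pair
    )


def irmsd_progression(
    images_a: InterpolationSet,
    images_b: InterpolationSet,
    bound_dimer: DimerStructure,
    interface: InterfaceSet | None = None,
) -> list[tuple[int, float, float]]:
    """(n, iRMSD, iRMSD*) along a pair of monomer interpolation paths.

    iRMSD uses the delta-rSASA interface of the bound dimer; iRMSD* is
    normalized by the unbound endpoint so iRMSD*(N_I) = 1.
    """
    if images_a.n_images != images_b.n_images:
        raise ValueError("both monomers must use the same number of images")
    if interface is None:
        interface = interface_residues(bound_dimer)
    values = []
    for n in range(images_a.n_images + 1):
        conf = (images_a.image_structure(n), images_b.image_structure(n))
        values.append(irmsd_rsasa(conf, bound_dimer, interface=interface))
    end = values[-1]
    return [
        (n, v, v / end if end > 0 else (0.0 if v == 0 else float("nan")))
        for n, v in enumerate(values)
    ]
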
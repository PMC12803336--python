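"""Reading, writing, and normalizing two-chain protein structures.

Structures are held as flat numpy arrays of heavy-atom records.  PDB text is
parsed and emitted through :mod:`biotite`; on read we keep a single conformer
(altloc '' or 'A' equivalent), drop all HETATM records (waters, ions, small
molecules) and all hydrogen/deuterium atoms, and require exactly two protein
chains.  The larger chain (by residue count) is designated the receptor, with
ties broken by lexicographic chain id; the same designation is inherited by
every docked model of a target.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import biotite.structure as bts
from biotite.structure.io.pdb import PDBFile

__all__ = [
    "Structure",
    "DimerStructure",
    "StructureError",
    "read_structure",
    "write_structure",
    "assign_receptor_ligand",
]

_HYDROGENS = frozenset({"H", "D"})


class StructureError(ValueError):
    """Raised for malformed or out-of-contract structure input."""


@dataclass
class Structure:
    """Heavy-atom coordinate table for one or more protein chains.

    All per-atom fields are parallel arrays of length ``n_atoms``.
    Coordinates are in Angstrom.
    """

    chain_ids: np.ndarray
    res_numbers: np.ndarray
    icodes: np.ndarray
    res_names: np.ndarray
    atom_names: np.ndarray
    elements: np.ndarray
    coords: np.ndarray

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    @property
    def chains(self) -> list[str]:
        """Distinct chain ids in order of first appearance."""
        _, idx = np.unique(self.chain_ids, return_index=True)
        return [self.chain_ids[i] for i in sorted(idx)]

    def chain_mask(self, chain_id: str) -> np.ndarray:
        return self.chain_ids == chain_id

    def subset(self, mask: np.ndarray) -> "Structure":
        return Structure(
            chain_ids=self.chain_ids[mask],
            res_numbers=self.res_numbers[mask],
            icodes=self.icodes[mask],
            res_names=self.res_names[mask],
            atom_names=self.atom_names[mask],
            elements=self.elements[mask],
            coords=self.coords[mask],
        )

    def extract_chain(self, chain_id: str) -> "Structure":
        mask = self.chain_mask(chain_id)
        if not mask.any():
            raise StructureError(f"chain {chain_id!r} not present")
        return self.subset(mask)

    def with_coords(self, coords: np.ndarray) -> "Structure":
        coords = np.asarray(coords, dtype=float)
        if coords.shape != self.coords.shape:
            raise StructureError("replacement coordinates have wrong shape")
        return replace(self, coords=coords)

    def residue_keys(self) -> np.ndarray:
        """Per-atom residue identifiers ``chain:resnum:icode``."""
        return np.array(
            [
                f"{c}:{n}:{i}"
                for c, n, i in zip(self.chain_ids, self.res_numbers, self.icodes)
            ]
        )

    def atom_keys(self) -> np.ndarray:
        """Per-atom identifiers ``chain:resnum:icode:atom_name``."""
        return np.array(
            [
                f"{c}:{n}:{i}:{a}"
                for c, n, i, a in zip(
                    self.chain_ids, self.res_numbers, self.icodes, self.atom_names
                )
            ]
        )

    def unique_residues(self, chain_id: str | None = None) -> list[str]:
        """Residue keys in order of first appearance, optionally per chain."""
        keys = self.residue_keys()
        if chain_id is not None:
            keys = keys[self.chain_mask(chain_id)]
        seen: dict[str, None] = {}
        for k in keys:
            seen.setdefault(k, None)
        return list(seen)

    def residue_count(self, chain_id: str | None = None) -> int:
        return len(self.unique_residues(chain_id))

    def validate(self) -> None:
        if self.n_atoms == 0:
            raise StructureError("structure has no atoms")
        if not np.all(np.isfinite(self.coords)):
            raise StructureError("non-finite coordinates")
        if any(e in _HYDROGENS for e in self.elements):
            raise StructureError("hydrogen atoms present after heavy-atom filter")


@dataclass
class DimerStructure(Structure):
    """A two-chain heavy-atom complex with receptor/ligand designation."""

    receptor_chain: str = ""
    ligand_chain: str = ""

    def validate(self) -> None:
        super().validate()
        chains = self.chains
        if len(chains) != 2:
            raise StructureError(
                f"expected exactly two chains, found {len(chains)}: {chains}"
            )
        if self.receptor_chain == self.ligand_chain:
            raise StructureError("receptor and ligand chains must differ")
        for c in (self.receptor_chain, self.ligand_chain):
            if c not in chains:
                raise StructureError(f"designated chain {c!r} not in structure")

    @property
    def receptor(self) -> Structure:
        return self.extract_chain(self.receptor_chain)

    @property
    def ligand(self) -> Structure:
        return self.extract_chain(self.ligand_chain)

    def copy(self) -> "DimerStructure":
        return DimerStructure(
            chain_ids=self.chain_ids.copy(),
            res_numbers=self.res_numbers.copy(),
            icodes=self.icodes.copy(),
            res_names=self.res_names.copy(),
            atom_names=self.atom_names.copy(),
            elements=self.elements.copy(),
            coords=self.coords.copy(),
            receptor_chain=self.receptor_chain,
            ligand_chain=self.ligand_chain,
        )


def _guess_element(atom_name: str) -> str:
    stripped = "".join(c for c in atom_name if c.isalpha())
    if not stripped:
        return ""
    if stripped[:2].upper() in ("SE", "CL", "BR"):
        return stripped[:2].upper()
    return stripped[0].upper()


def _from_atom_array(arr: bts.AtomArray) -> Structure:
    elements = np.array(
        [
            e.upper() if e else _guess_element(a)
            for e, a in zip(arr.element, arr.atom_name)
        ]
    )
    return Structure(
        chain_ids=arr.chain_id.astype(str),
        res_numbers=arr.res_id.astype(int),
        icodes=arr.ins_code.astype(str),
        res_names=arr.res_name.astype(str),
        atom_names=arr.atom_name.astype(str),
        elements=elements,
        coords=arr.coord.astype(float),
    )


def read_structure(pdb_text: str) -> DimerStructure:
    """Parse PDB text into a normalized two-chain heavy-atom dimer.

    HETATM records (waters, ions, ligands), hydrogens, and alternate
    conformers beyond the first are discarded.  Raises
    :class:`StructureError` unless exactly two chains with at least one
    residue each remain.
    """
    try:
        pdb = PDBFile.read(io.StringIO(pdb_text))
        arr = pdb.get_structure(model=1, altloc="first", extra_fields=[])
    except Exception as exc:  # biotite raises several types on bad input
        raise StructureError(f"could not parse PDB text: {exc}") from exc
    if arr.array_length() == 0:
        raise StructureError("no ATOM records found")
    arr = arr[~arr.hetero]
    if arr.array_length() == 0:
        raise StructureError("no protein ATOM records found (HETATM only)")
    struct = _from_atom_array(arr)
    heavy = np.array([e not in _HYDROGENS for e in struct.elements])
    struct = struct.subset(heavy)
    if struct.n_atoms == 0:
        raise StructureError("no heavy atoms after hydrogen filtering")
    chains = struct.chains
    if len(chains) != 2:
        raise StructureError(
            f"expected exactly two protein chains, found {len(chains)}: {chains}"
        )
    dimer = DimerStructure(
        chain_ids=struct.chain_ids,
        res_numbers=struct.res_numbers,
        icodes=struct.icodes,
        res_names=struct.res_names,
        atom_names=struct.atom_names,
        elements=struct.elements,
        coords=struct.coords,
        receptor_chain=chains[0],
        ligand_chain=chains[1],
    )
    dimer = assign_receptor_ligand(dimer)
    dimer.validate()
    return dimer


def assign_receptor_ligand(structure: DimerStructure) -> DimerStructure:
    """Designate the chain with more residues as the receptor.

    Ties are broken by lexicographic chain-id order, so the assignment is a
    pure function of the structure and stable across re-reads.
    """
    chains = structure.chains
    if len(chains) != 2:
        raise StructureError("receptor/ligand assignment requires two chains")
    a, b = sorted(chains)
    na, nb = structure.residue_count(a), structure.residue_count(b)
    receptor, ligand = (a, b) if na >= nb else (b, a)
    out = DimerStructure(
        chain_ids=structure.chain_ids,
        res_numbers=structure.res_numbers,
        icodes=structure.icodes,
        res_names=structure.res_names,
        atom_names=structure.atom_names,
        elements=structure.elements,
        coords=structure.coords,
        receptor_chain=receptor,
        ligand_chain=ligand,
    )
    return out


def _to_atom_array(structure: Structure) -> bts.AtomArray:
    n = structure.n_atoms
    arr = bts.AtomArray(n)
    arr.chain_id = structure.chain_ids.astype("U4")
    arr.res_id = structure.res_numbers.astype(int)
    arr.ins_code = structure.icodes.astype("U1")
    arr.res_name = structure.res_names.astype("U5")
    arr.atom_name = structure.atom_names.astype("U6")
    arr.element = structure.elements.astype("U2")
    arr.hetero = np.zeros(n, dtype=bool)
    arr.coord = structure.coords.astype(np.float32)
    return arr


def write_structure(structure: Structure, path=None) -> str:
    """Render a structure as PDB ATOM records; optionally write to *path*.

    Round-tripping through :func:`read_structure` preserves chains, residue
    identities, atom names, and coordinates to PDB format precision (1e-3 A).
    """
    if structure.n_atoms == 0:
        raise StructureError("cannot write an empty structure")
    structure.validate()
    pdb = PDBFile()
    pdb.set_structure(_to_atom_array(structure))
    buf = io.StringIO()
    pdb.write(buf)
    text = buf.getvalue()
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text
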
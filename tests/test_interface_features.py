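import numpy as np
import pytest

from ppiscore.interface_features import (
    count_interface_contacts,
    interface_residues,
    interface_separability,
    point_separability,
    relative_sasa,
    residue_sasa,
    shrake_rupley,
    _sphere_points,
)
from ppiscore.structio import DimerStructure


def make_micro_dimer(chain_a_coords, chain_b_coords, res_per_atom=True):
    """One-atom-per-residue dimer from explicit coordinate lists."""
    a = np.asarray(chain_a_coords, dtype=float)
    b = np.asarray(chain_b_coords, dtype=float)
    n = len(a) + len(b)
    return DimerStructure(
        chain_ids=np.array(["A"] * len(a) + ["B"] * len(b)),
        res_numbers=np.concatenate(
            [np.arange(1, len(a) + 1), np.arange(1, len(b) + 1)]
        ),
        icodes=np.array([""] * n),
        res_names=np.array(["ALA"] * n),
        atom_names=np.array(["CA"] * n),
        elements=np.array(["C"] * n),
        coords=np.vstack([a, b]),
        receptor_chain="A",
        ligand_chain="B",
    )


class TestShrakeRupley:
    def test_isolated_atom_is_full_inflated_sphere(self):
        area = shrake_rupley(np.zeros((1, 3)), np.array([1.7]))
        assert area[0] == pytest.approx(4 * np.pi * (1.7 + 1.4) ** 2, rel=1e-9)

    def test_fully_enclosed_atom_has_zero_area(self):
        shell = 3.0 * _sphere_points(120)
        coords = np.vstack([np.zeros(3), shell])
        radii = np.full(len(coords), 1.7)
        assert shrake_rupley(coords, radii)[0] == 0.0

    def test_two_atom_pair_matches_analytic_cap_area(self):
        # accessible area of two overlapping inflated spheres in closed form
        r1, r2, d = 1.7 + 1.4, 1.52 + 1.4, 2.4
        coords = np.array([[0.0, 0.0, 0.0], [d, 0.0, 0.0]])
        areas = shrake_rupley(coords, np.array([1.7, 1.52]))
        h1 = r1 - (d**2 + r1**2 - r2**2) / (2 * d)
        h2 = r2 - (d**2 + r2**2 - r1**2) / (2 * d)
        exact = np.array(
            [4 * np.pi * r1**2 - 2 * np.pi * r1 * h1,
             4 * np.pi * r2**2 - 2 * np.pi * r2 * h2]
        )
        assert np.abs(areas / exact - 1).max() < 0.02

    def test_against_independent_sasa_implementation(self, mixed_dimer):
        biotite_struct = pytest.importorskip("biotite.structure")
        from ppiscore.structio import _to_atom_array
        from ppiscore.interface_features import _atom_radii

        radii = _atom_radii(mixed_dimer)
        ours = shrake_rupley(mixed_dimer.coords, radii, n_points=960)
        theirs = biotite_struct.sasa(
            _to_atom_array(mixed_dimer), vdw_radii=radii, point_number=960
        )
        # per-atom deviation reflects differing sphere-point placements
        assert np.abs(ours - theirs).max() < 2.0  # A^2
        assert ours.sum() == pytest.approx(theirs.sum(), rel=0.01)


class TestResidueSasa:
    def test_residue_totals_partition_molecular_area(self, mixed_dimer):
        from ppiscore.interface_features import _atom_radii

        per_res = residue_sasa(mixed_dimer)
        total = shrake_rupley(mixed_dimer.coords, _atom_radii(mixed_dimer)).sum()
        assert sum(per_res.values()) == pytest.approx(total, rel=1e-9)

    def test_relative_sasa_of_isolated_residue_against_own_reference(self):
        d = make_micro_dimer([[0, 0, 0]], [[50, 0, 0]])
        iso_area = 4 * np.pi * (1.7 + 1.4) ** 2
        rs = relative_sasa(d, reference_areas={"ALA": iso_area})
        assert rs["A:1:"] == pytest.approx(1.0, rel=1e-9)

    def test_relative_sasa_consistent_with_reference_table(self, planar_dimer):
        from ppiscore.interface_features import GXG_REFERENCE_AREAS

        sasa = residue_sasa(planar_dimer)
        rsasa = relative_sasa(planar_dimer)
        for key in sasa:
            assert rsasa[key] == pytest.approx(
                sasa[key] / GXG_REFERENCE_AREAS["ALA"], rel=1e-12
            )
            assert rsasa[key] >= 0

    def test_unknown_residue_type_error_names_residue(self):
        d = make_micro_dimer([[0, 0, 0]], [[50, 0, 0]])
        d.res_names[:] = "XXX"
        with pytest.raises(KeyError, match="XXX"):
            relative_sasa(d)


class TestInterfaceResidues:
    def test_far_apart_chains_have_empty_interface(self):
        d = make_micro_dimer([[0, 0, 0], [3.8, 0, 0]], [[50, 0, 0], [53.8, 0, 0]])
        iface = interface_residues(d)
        assert len(iface) == 0

    def test_contacting_residues_are_both_flagged(self):
        d = make_micro_dimer([[0, 0, 0]], [[4.0, 0, 0]])
        iface = interface_residues(d)
        assert iface.receptor_residues == frozenset({"A:1:"})
        assert iface.ligand_residues == frozenset({"B:1:"})

    def test_buried_core_residue_far_from_interface_not_flagged(self):
        # chain A: central atom enclosed by a shell of its own chain
        shell = 3.0 * _sphere_points(120)
        chain_a = np.vstack([np.zeros(3), shell])
        d = make_micro_dimer(chain_a, [[7.0, 0.0, 0.0]])
        iface = interface_residues(d)
        assert "A:1:" not in iface.receptor_residues

    def test_empty_interface_iff_no_contacts_when_separated(self, mixed_dimer):
        shifted = mixed_dimer.copy()
        mask = shifted.chain_mask(shifted.ligand_chain)
        shifted.coords[mask] += np.array([0.0, 0.0, 200.0])
        assert count_interface_contacts(shifted, cutoff=5.0) == 0
        assert len(interface_residues(shifted)) == 0


class TestContacts:
    @pytest.mark.parametrize("distance,expected", [(4.4, 1), (4.6, 0)])
    def test_strict_cutoff_boundary(self, distance, expected):
        d = make_micro_dimer([[0, 0, 0]], [[distance, 0, 0]])
        assert count_interface_contacts(d, cutoff=4.5) == expected

    def test_brute_force_equivalence_random_configuration(self, rng):
        a = rng.uniform(0, 25, size=(100, 3))
        b = rng.uniform(0, 25, size=(100, 3))
        d = make_micro_dimer(a, b)
        brute = sum(
            1 for p in a for q in b if np.linalg.norm(p - q) < 4.5
        )
        assert count_interface_contacts(d, cutoff=4.5) == brute

    def test_rigid_transform_invariance_and_cutoff_monotonicity(self, mixed_dimer, rng):
        from scipy.spatial.transform import Rotation

        base = count_interface_contacts(mixed_dimer, 4.5)
        moved = mixed_dimer.copy()
        moved.coords = moved.coords @ Rotation.random(random_state=3).as_matrix().T + [
            10.0, -4.0, 7.0,
        ]
        assert count_interface_contacts(moved, 4.5) == base
        counts = [count_interface_contacts(mixed_dimer, c) for c in (2.0, 4.5, 6.0, 9.0)]
        assert counts == sorted(counts)


class TestSeparability:
    def test_plane_separated_chains_give_unity(self, planar_dimer):
        assert interface_separability(planar_dimer) == 1.0

    def test_interdigitated_chains_defeat_cubic_surface(self, interdigitated_dimer):
        assert interface_separability(interdigitated_dimer) <= 0.75

    def test_identically_distributed_clouds_near_chance(self, rng):
        pts_a = rng.normal(scale=10.0, size=(1500, 3))
        pts_b = rng.normal(scale=10.0, size=(1500, 3))
        s = point_separability(pts_a, pts_b)
        assert s == pytest.approx(0.5, abs=0.05)

    def test_determinism_under_fixed_seed(self, mixed_dimer):
        s1 = interface_separability(mixed_dimer, seed=4)
        s2 = interface_separability(mixed_dimer, seed=4)
        assert s1 == s2

    def test_rigid_transform_invariance(self, mixed_dimer):
        from scipy.spatial.transform import Rotation

        base = interface_separability(mixed_dimer)
        moved = mixed_dimer.copy()
        moved.coords = moved.coords @ Rotation.random(random_state=9).as_matrix().T + [
            3.0, 3.0, -8.0,
        ]
        assert interface_separability(moved) == pytest.approx(base, abs=0.02)
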
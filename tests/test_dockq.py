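import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from ppiscore.dockq_metric import (
    dockq,
    dockq_from_terms,
    fnat,
    irmsd_dockq,
    irmsd_rsasa,
    kabsch_superpose,
    lrmsd,
    native_contacts,
)
from ppiscore.interface_features import interface_residues
from ppiscore.structio import StructureError

from test_interface_features import make_micro_dimer


def random_rigid(rng):
    R = Rotation.random(random_state=rng.integers(2**31)).as_matrix()
    t = rng.uniform(-20, 20, 3)
    return R, t


class TestKabsch:
    def test_identical_sets_give_zero_rmsd_identity_rotation(self, rng):
        pts = rng.normal(size=(8, 3))
        transform, rmsd = kabsch_superpose(pts, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-7)
        assert np.allclose(transform.rotation, np.eye(3), atol=1e-8)

    def test_rigid_copy_recovered_exactly(self, rng):
        pts = rng.normal(size=(10, 3)) * 5
        R, t = random_rigid(rng)
        moved = pts @ R.T + t
        transform, rmsd = kabsch_superpose(moved, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-8)
        assert np.allclose(transform.apply(moved), pts, atol=1e-7)

    def test_against_numerical_optimization_oracle(self, rng):
        # independent route: minimize RMSD over rotation vectors directly
        a = rng.normal(size=(10, 3)) * 4
        b = rng.normal(size=(10, 3)) * 4
        _, rmsd = kabsch_superpose(a, b)

        ac, bc = a - a.mean(0), b - b.mean(0)

        def objective(rv):
            return np.sqrt(
                ((ac @ Rotation.from_rotvec(rv).as_matrix().T - bc) ** 2)
                .sum(axis=1)
                .mean()
            )

        best = min(
            minimize(objective, x0, method="Nelder-Mead").fun
            for x0 in rng.uniform(-np.pi, np.pi, size=(12, 3))
        )
        assert rmsd == pytest.approx(best, abs=1e-3)

    def test_degenerate_inputs_rejected(self, rng):
        with pytest.raises(ValueError):
            kabsch_superpose(rng.normal(size=(2, 3)), rng.normal(size=(2, 3)))
        line = np.outer(np.arange(5.0), [1.0, 0.0, 0.0])
        with pytest.raises(ValueError):
            kabsch_superpose(line, line)


class TestNativeContacts:
    @pytest.mark.parametrize("distance,expected", [(4.9, 1), (5.1, 0)])
    def test_strict_five_angstrom_boundary(self, distance, expected):
        d = make_micro_dimer([[0, 0, 0]], [[distance, 0, 0]])
        assert len(native_contacts(d)) == expected

    def test_far_apart_chains_empty(self):
        d = make_micro_dimer([[0, 0, 0]], [[50, 0, 0]])
        assert native_contacts(d) == set()

    def test_brute_force_set_equivalence(self, rng):
        a = rng.uniform(0, 20, size=(60, 3))
        b = rng.uniform(0, 20, size=(60, 3))
        d = make_micro_dimer(a, b)
        rec, lig = d.receptor, d.ligand
        rk, lk = rec.atom_keys(), lig.atom_keys()
        brute = {
            (rk[i], lk[j])
            for i in range(len(a))
            for j in range(len(b))
            if np.linalg.norm(a[i] - b[j]) < 5.0
        }
        assert native_contacts(d) == brute


class TestFnat:
    def test_self_model_is_one(self, mixed_dimer):
        assert fnat(mixed_dimer, mixed_dimer) == 1.0

    def test_displaced_ligand_is_zero(self, mixed_dimer):
        far = mixed_dimer.copy()
        far.coords[far.chain_mask(far.ligand_chain)] += [100.0, 0, 0]
        assert fnat(far, mixed_dimer) == 0.0

    def test_half_of_contacts_preserved_by_construction(self):
        # four well-separated native contact pairs at 4 A; model breaks two
        a = [[0, 0, 0], [20, 0, 0], [40, 0, 0], [60, 0, 0]]
        b = [[0, 4, 0], [20, 4, 0], [40, 4, 0], [60, 4, 0]]
        native = make_micro_dimer(a, b)
        model = make_micro_dimer(
            a, [[0, 4, 0], [20, 4, 0], [40, 12, 0], [60, 12, 0]]
        )
        assert fnat(model, native) == 0.5

    def test_contactless_native_rejected(self):
        native = make_micro_dimer([[0, 0, 0]], [[50, 0, 0]])
        with pytest.raises(StructureError):
            fnat(native, native)


def _test_kabsch_reference(mobile, reference):
    """Independent SVD-based superposition used only as a test oracle."""
    mc, rc = mobile.mean(0), reference.mean(0)
    H = (mobile - mc).T @ (reference - rc)
    U, _, Vt = np.linalg.svd(H)
    D = np.diag([1.0, 1.0, np.sign(np.linalg.det(Vt.T @ U.T))])
    R = Vt.T @ D @ U.T
    return R, rc - R @ mc


class TestLrmsd:
    def test_self_model_is_zero(self, mixed_dimer):
        assert lrmsd(mixed_dimer, mixed_dimer) == pytest.approx(0.0, abs=1e-9)

    def test_pure_ligand_translation_equals_shift(self, mixed_dimer):
        shifted = mixed_dimer.copy()
        shifted.coords[shifted.chain_mask(shifted.ligand_chain)] += [3.0, 0, 0]
        assert lrmsd(shifted, mixed_dimer) == pytest.approx(3.0, abs=1e-9)

    def test_random_decoy_matches_independent_two_step_oracle(self, mixed_dimer, rng):
        decoy = mixed_dimer.copy()
        R, t = random_rigid(rng)
        decoy.coords = decoy.coords @ R.T + t
        lig_mask = decoy.chain_mask(decoy.ligand_chain)
        decoy.coords[lig_mask] += rng.normal(scale=2.0, size=(lig_mask.sum(), 3))
        value = lrmsd(decoy, mixed_dimer)

        rec_mask = mixed_dimer.chain_mask(mixed_dimer.receptor_chain) & (
            mixed_dimer.atom_names == "CA"
        )
        bb_lig = lig_mask & (mixed_dimer.atom_names == "CA")
        R2, t2 = _test_kabsch_reference(
            decoy.coords[rec_mask], mixed_dimer.coords[rec_mask]
        )
        moved = decoy.coords[bb_lig] @ R2.T + t2
        oracle = np.sqrt(((moved - mixed_dimer.coords[bb_lig]) ** 2).sum(1).mean())
        assert value == pytest.approx(oracle, abs=1e-6)


class TestIrmsdDockq:
    def test_self_model_is_zero(self, mixed_dimer):
        assert irmsd_dockq(mixed_dimer, mixed_dimer) == pytest.approx(0.0, abs=1e-9)

    def test_small_rigid_ligand_shift_bounded_by_shift(self, mixed_dimer):
        shifted = mixed_dimer.copy()
        shifted.coords[shifted.chain_mask(shifted.ligand_chain)] += [0, 0, 1.0]
        value = irmsd_dockq(shifted, mixed_dimer)
        assert 0.0 < value <= 1.0 + 1e-9

    def test_matches_brute_force_oracle(self, mixed_dimer, rng):
        decoy = mixed_dimer.copy()
        lig_mask = decoy.chain_mask(decoy.ligand_chain)
        decoy.coords[lig_mask] += rng.normal(scale=1.0, size=(lig_mask.sum(), 3))
        value = irmsd_dockq(decoy, mixed_dimer)

        # oracle: interface residues by explicit double loop, then SVD fit
        rec = mixed_dimer.receptor
        lig = mixed_dimer.ligand
        iface = set()
        for i in range(rec.n_atoms):
            for j in range(lig.n_atoms):
                if np.linalg.norm(rec.coords[i] - lig.coords[j]) < 10.0:
                    iface.add(rec.residue_keys()[i])
                    iface.add(lig.residue_keys()[j])
        mask = np.isin(mixed_dimer.residue_keys(), list(iface)) & (
            mixed_dimer.atom_names == "CA"
        )
        R2, t2 = _test_kabsch_reference(
            decoy.coords[mask], mixed_dimer.coords[mask]
        )
        moved = decoy.coords[mask] @ R2.T + t2
        oracle = np.sqrt(((moved - mixed_dimer.coords[mask]) ** 2).sum(1).mean())
        assert value == pytest.approx(oracle, abs=1e-6)


class TestCompositeDockq:
    def test_self_model_scores_exactly_one(self, mixed_dimer):
        assert dockq(mixed_dimer, mixed_dimer).dockq == pytest.approx(1.0, abs=1e-12)

    def test_analytic_halfway_case(self):
        assert dockq_from_terms(0.5, 8.5, 1.5) == pytest.approx(0.5, rel=1e-12)

    def test_limit_of_bad_model_tends_to_zero(self):
        assert dockq_from_terms(0.0, 1e9, 1e9) == pytest.approx(0.0, abs=1e-12)

    def test_invariant_under_common_rigid_transform(self, mixed_dimer, decoy_ensemble, rng):
        models, _ = decoy_ensemble
        decoy = models[len(models) // 2]
        base = dockq(decoy, mixed_dimer)
        R, t = random_rigid(rng)
        moved = decoy.copy()
        moved.coords = moved.coords @ R.T + t
        moved_native = mixed_dimer.copy()
        R2, t2 = random_rigid(rng)
        moved_native.coords = moved_native.coords @ R2.T + t2
        res = dockq(moved, moved_native)
        assert res.dockq == pytest.approx(base.dockq, abs=1e-6)

    def test_median_dockq_nonincreasing_with_perturbation(self, mixed_dimer, rng):
        from ppiscore.synthetic import _perturb_ligand

        medians = []
        for magnitude in (0.2, 2.0, 8.0, 30.0):
            qs = [
                dockq(_perturb_ligand(mixed_dimer, magnitude, rng), mixed_dimer).dockq
                for _ in range(6)
            ]
            medians.append(np.median(qs))
        assert medians == sorted(medians, reverse=True)


class TestIrmsdRsasa:
    def test_bound_against_itself_is_zero(self, mixed_dimer):
        confs = (mixed_dimer.receptor, mixed_dimer.ligand)
        assert irmsd_rsasa(confs, mixed_dimer) == pytest.approx(0.0, abs=1e-9)

    def test_matches_direct_formula_evaluation(self, mixed_dimer, rng):
        iface = interface_residues(mixed_dimer)
        chain_sets = {
            mixed_dimer.receptor_chain: iface.receptor_residues,
            mixed_dimer.ligand_chain: iface.ligand_residues,
        }
        confs = []
        for chain in (mixed_dimer.receptor_chain, mixed_dimer.ligand_chain):
            mono = mixed_dimer.extract_chain(chain)
            confs.append(
                mono.with_coords(
                    mono.coords + rng.normal(scale=0.7, size=mono.coords.shape)
                )
            )
        value = irmsd_rsasa(tuple(confs), mixed_dimer, interface=iface)

        total_sq, total_n = 0.0, 0
        for conf, chain in zip(confs, (mixed_dimer.receptor_chain, mixed_dimer.ligand_chain)):
            bound = mixed_dimer.extract_chain(chain)
            mask = np.isin(bound.residue_keys(), list(chain_sets[chain])) & (
                bound.atom_names == "CA"
            )
            R2, t2 = _test_kabsch_reference(conf.coords[mask], bound.coords[mask])
            moved = conf.coords[mask] @ R2.T + t2
            total_sq += ((moved - bound.coords[mask]) ** 2).sum()
            total_n += mask.sum()
        assert value == pytest.approx(np.sqrt(total_sq / total_n), abs=1e-6)
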
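"""Synthetic structures, decoy ensembles, and scored-model tables.

Three generators, all bit-reproducible under a fixed seed:

``make_toy_dimer``
    A two-chain heavy-atom toy complex built from interlocking "combs" of
    residue fingers (C-alpha plus one pseudo-side-chain atom per residue,
    ~3.8 A virtual bonds along fingers).  At ``intertwine = 0`` the chains
    pack against opposite sides of a flat interface; at ``intertwine = 1``
    the fingers of the two chains fully interdigitate on offset lattice
    columns, which no cubic surface can separate.  The lattice guarantees
    self-avoidance and cross-chain contacts at every intertwining level.

``make_decoy_set``
    Rigid rotations/translations of the ligand with magnitudes scheduled
    over a logarithmic range plus adaptive refills, so the ensemble spans
    DockQ bins from 0 to 1.  DockQ is always computed by the metric module,
    never synthesized, so decoys exercise the metric end to end.

``make_score_dockq_dataset``
    Per-model (DockQ, score) tables with Spearman correlation calibrated by
    bisection on the noise amplitude, optional 1:1 class balance at DockQ
    0.23, and an exactly enforced negative-dominance fraction mu (the
    requested count of negatives is re-ranked to strictly outrank every
    positive; the slight resulting shift in rho is re-measured and
    reported).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dockq_metric import _native_interface_residues, dockq, native_contacts
from .evaluation import spearman_rho
from .sampling import POSITIVE_CUTOFF, ScoredModelSet
from .structio import DimerStructure, StructureError

__all__ = [
    "SyntheticSpec",
    "make_toy_dimer",
    "make_decoy_set",
    "make_score_dockq_dataset",
]

BOND_LENGTH = 3.8  # A, virtual C-alpha bond along a finger
FINGER_RESIDUES = 6
ARC_SPACING = 3.9  # A, spacing between adjacent (opposite-chain) columns
CONTACT_GAP = 1.5  # A, vertical gap between chains at intertwine = 0
CB_OFFSET = 1.53  # A, pseudo-side-chain bond length
JITTER_SIGMA = 0.15  # A
MIN_SEPARATION = 2.4  # A, self-avoidance floor


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for the synthetic generators."""

    seed: int = 0
    n_residues_per_chain: int = 60
    intertwine: float = 0.0
    n_models: int = 500
    rho_target: float = -0.5
    mu_target: float = 0.0

    def __post_init__(self):
        if self.n_residues_per_chain < 50:
            raise ValueError("chains must have at least 50 residues")
        if not 0.0 <= self.intertwine <= 1.0:
            raise ValueError("intertwine must lie in [0, 1]")
        if not -1.0 <= self.rho_target <= 1.0:
            raise ValueError("rho_target must lie in [-1, 1]")
        if not 0.0 <= self.mu_target <= 1.0:
            raise ValueError("mu_target must lie in [0, 1]")


def _ring_calpha(n_res: int, n_fingers: int, parity: int, z_base: float) -> np.ndarray:
    """Serpentine path over vertical fingers placed on a ring.

    The two chains occupy alternating angular columns (parity 0/1) of a
    common ring, so the interdigitated state has no single-chain boundary
    region that a low-degree surface could exploit.
    """
    radius = 2 * n_fingers * ARC_SPACING / (2.0 * np.pi)
    coords = []
    for finger in range(n_fingers):
        angle = (2 * finger + parity) * np.pi / n_fingers
        x, y = radius * np.cos(angle), radius * np.sin(angle)
        levels = range(FINGER_RESIDUES)
        if finger % 2 == 1:  # descend so consecutive fingers connect nearby
            levels = reversed(levels)
        for level in levels:
            coords.append([x, y, z_base + level * BOND_LENGTH])
    return np.array(coords[:n_res])


def make_toy_dimer(spec: SyntheticSpec, max_retries: int = 5) -> DimerStructure:
    """Two-chain toy complex with controllable interface intertwining."""
    n = spec.n_residues_per_chain
    n_fingers = math.ceil(n / FINGER_RESIDUES)
    finger_height = (FINGER_RESIDUES - 1) * BOND_LENGTH
    # chain A fingers span [-finger_height, 0]; chain B rises from z_b,
    # ending half a bond offset from A's levels at full interdigitation
    z_b = CONTACT_GAP - spec.intertwine * (
        finger_height + CONTACT_GAP - BOND_LENGTH / 2.0
    )
    ca_a = _ring_calpha(n, n_fingers, 0, -finger_height)
    ca_b = _ring_calpha(n, n_fingers, 1, z_b)
    for attempt in range(max_retries):
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, attempt]))
        coords = []
        for ca in (ca_a, ca_b):
            jittered = ca + rng.normal(scale=JITTER_SIGMA, size=ca.shape)
            radial = jittered.copy()
            radial[:, 2] = 0.0
            radial /= np.linalg.norm(radial, axis=1, keepdims=True)
            cb = jittered + CB_OFFSET * radial  # side chains point outward
            cb += rng.normal(scale=JITTER_SIGMA, size=cb.shape)
            chain = np.empty((2 * len(ca), 3))
            chain[0::2] = jittered
            chain[1::2] = cb
            coords.append(chain)
        all_coords = np.vstack(coords)
        from scipy.spatial import cKDTree

        tree = cKDTree(all_coords)
        close = tree.query_pairs(MIN_SEPARATION)
        # consecutive CA-CB of the same residue are bonded, allow them
        bonded = {(i, i + 1) for i in range(0, len(all_coords), 2)}
        if not (close - bonded):
            break
    else:
        raise StructureError("could not place a self-avoiding toy dimer")
    n_atoms = 4 * n
    chain_ids = np.array(["A"] * (2 * n) + ["B"] * (2 * n))
    res_numbers = np.repeat(np.arange(1, n + 1), 2)
    res_numbers = np.concatenate([res_numbers, res_numbers])
    dimer = DimerStructure(
        chain_ids=chain_ids,
        res_numbers=res_numbers,
        icodes=np.array([""] * n_atoms),
        res_names=np.array(["ALA"] * n_atoms),
        atom_names=np.array(["CA", "CB"] * (2 * n)),
        elements=np.array(["C"] * n_atoms),
        coords=all_coords,
        receptor_chain="A",
        ligand_chain="B",
    )
    dimer.validate()
    return dimer


def _random_rotation(rng: np.random.Generator, angle: float) -> np.ndarray:
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    from scipy.spatial.transform import Rotation

    return Rotation.from_rotvec(angle * axis).as_matrix()


def _perturb_ligand(
    native: DimerStructure, magnitude: float, rng: np.random.Generator
) -> DimerStructure:
    model = native.copy()
    mask = model.chain_mask(model.ligand_chain)
    lig = model.coords[mask]
    center = lig.mean(axis=0)
    angle = min(np.pi, 0.03 * np.pi * magnitude)
    R = _random_rotation(rng, angle)
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    model.coords[mask] = (lig - center) @ R.T + center + magnitude * direction
    return model


def make_decoy_set(
    native: DimerStructure, n_models: int = 500, seed: int = 0
) -> tuple[list[DimerStructure], ScoredModelSet]:
    """Rigid-body decoy ensemble spanning the DockQ range.

    Magnitudes of the ligand perturbation are first scheduled over a
    logarithmic range; the remaining budget adaptively targets empty
    0.05-wide DockQ bins by interpolating perturbation magnitudes between
    the nearest bracketing decoys.  The zero-perturbation decoy (DockQ = 1)
    is always included.
    """
    if n_models < 2:
        raise ValueError("n_models must be >= 2")
    rng = np.random.default_rng(seed)
    contacts = native_contacts(native)
    interface = _native_interface_residues(native)
    models: list[DimerStructure] = [native.copy()]
    magnitudes: list[float] = [0.0]
    qualities: list[float] = [
        dockq(models[0], native, native_contact_set=contacts,
              native_interface=interface).dockq
    ]
    n_scheduled = max(2, int(0.8 * (n_models - 1)))
    for s in np.geomspace(0.05, 60.0, n_scheduled):
        model = _perturb_ligand(native, float(s), rng)
        q = dockq(
            model, native, native_contact_set=contacts, native_interface=interface
        ).dockq
        models.append(model)
        magnitudes.append(float(s))
        qualities.append(q)
    n_bins = 20
    while len(models) < n_models:
        qs = np.asarray(qualities)
        ss = np.asarray(magnitudes)
        counts = np.bincount(
            np.minimum((qs * n_bins).astype(int), n_bins - 1), minlength=n_bins
        )
        target_bin = int(np.argmin(counts))
        lo, hi = target_bin / n_bins, (target_bin + 1) / n_bins
        above = ss[qs >= hi]
        below = ss[(qs < lo) & (ss > 0)]
        s_small = above.max() if len(above) else 0.02
        s_large = below.min() if len(below) else 80.0
        s_small, s_large = min(s_small, s_large), max(s_small, s_large)
        s = float(
            np.exp(rng.uniform(np.log(max(s_small, 1e-3)), np.log(max(s_large, 1e-2))))
        )
        model = _perturb_ligand(native, s, rng)
        q = dockq(
            model, native, native_contact_set=contacts, native_interface=interface
        ).dockq
        models.append(model)
        magnitudes.append(s)
        qualities.append(q)
    df = pd.DataFrame(
        {
            "model_id": [f"decoy_{i:04d}" for i in range(len(models))],
            "dockq": qualities,
        }
    )
    return models, ScoredModelSet(df)


def _calibrate_noise(
    dockq_vals: np.ndarray, base: np.ndarray, noise: np.ndarray, rho_target: float
) -> np.ndarray:
    """Bisect the noise amplitude so Spearman rho matches the target."""
    target = abs(rho_target)
    lo, hi = 1e-4, 1e4
    for _ in range(60):
        mid = math.sqrt(lo * hi)
        measured = abs(spearman_rho(dockq_vals, base + mid * noise))
        if measured > target:
            lo = mid
        else:
            hi = mid
    return base + math.sqrt(lo * hi) * noise


def make_score_dockq_dataset(
    n: int,
    rho_target: float,
    mu_target: float | None = None,
    balanced: bool = True,
    seed: int = 0,
    cutoff: float = POSITIVE_CUTOFF,
) -> tuple[ScoredModelSet, dict]:
    """Scored-model table with controlled Spearman rho and exact mu.

    With ``mu_target=None`` the negative-dominance fraction is left as the
    noise produces it; any numeric value (including 0) is enforced exactly.
    Returns the table and an info dict with the re-measured correlation
    (``achieved_rho``), the score orientation (``lower_is_better``, true
    for energy-like negative targets), and the resulting ``mu``.
    """
    if not -1.0 < rho_target < 1.0:
        raise ValueError("|rho_target| must be < 1")
    rng = np.random.default_rng(seed)
    if balanced:
        n_pos = n // 2
        q = np.concatenate(
            [
                rng.uniform(cutoff, 1.0, size=n_pos),
                rng.uniform(0.0, cutoff, size=n - n_pos),
            ]
        )
        rng.shuffle(q)
    else:
        q = rng.uniform(0.0, 1.0, size=n)
    noise = rng.standard_normal(n)
    if rho_target == 0.0:
        score = noise.copy()
        lower_is_better = False
    else:
        sign = 1.0 if rho_target > 0 else -1.0
        score = _calibrate_noise(q, sign * q, noise, rho_target)
        lower_is_better = rho_target < 0
    labels = q >= cutoff
    if labels.sum() == 0:
        raise ValueError("dataset has no positive models")
    if mu_target is not None:
        k = math.ceil(mu_target * n)
        if k > (~labels).sum():
            raise ValueError("mu_target infeasible: not enough negative models")
        score = _enforce_mu(score, labels, k, lower_is_better)
        mu = k / n
    else:
        better = -score if lower_is_better else score
        best_pos = better[labels].max()
        mu = float(((~labels) & (better > best_pos)).mean())
    df = pd.DataFrame(
        {"model_id": [f"m{i:06d}" for i in range(n)], "dockq": q, "score": score}
    )
    info = {
        "achieved_rho": spearman_rho(q, score),
        "lower_is_better": lower_is_better,
        "mu": mu,
    }
    return ScoredModelSet(df, positive_cutoff=cutoff), info


def _enforce_mu(
    score: np.ndarray, labels: np.ndarray, k: int, lower_is_better: bool
) -> np.ndarray:
    """Permute score values so exactly k negatives outrank every positive."""
    better = -score if lower_is_better else score
    order = np.argsort(-better, kind="stable")  # best first
    sorted_vals = better[order]
    neg_in_order = order[~labels[order]]
    pos_in_order = order[labels[order]]
    head = list(neg_in_order[:k]) + [pos_in_order[0]]
    head_set = set(head)
    rest = [i for i in order if i not in head_set]
    new_order = np.array(head + rest)
    better_new = np.empty_like(better)
    better_new[new_order] = sorted_vals
    return -better_new if lower_is_better else better_new
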
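# Methods

This note records the models and procedures implemented in `ppiscore`,
the parameter choices that matter, and what the synthetic fixtures do and
do not establish about real protein data.

## Structures and normalization

Structures are heavy-atom tables parsed from PDB text (via biotite).
HETATM records (waters, ions, small molecules), hydrogens/deuteriums, and
alternate conformers beyond the first are removed on read, giving a
deterministic single-conformer model. Residue identity is
(chain, residue number, insertion code); coordinates are in Å throughout.
Exactly two chains are required; the chain with more residues is
designated the receptor (ties broken by lexicographic chain id). The rule
is applied to the target and inherited by its models, so the designation
is stable across re-reads. The original curators' receptor/ligand labels
are not machine-recoverable from coordinates alone, which is why a
deterministic size-then-id rule is used instead.

## Solvent accessibility and interface residues

Per-atom SASA uses the Shrake–Rupley construction with 960 deterministic
golden-spiral test points per atom and a 1.4 Å probe; van der Waals radii
are Bondi-style constants embedded in the module (C 1.70, N 1.55, O 1.52,
S 1.80, …, default 1.70 Å). Relative SASA divides each residue's area by
the theoretical maximum of that residue type in an extended Gly-X-Gly
tripeptide (Tien et al. 2013 values, embedded as constants).

A residue is an interface residue iff its relative accessibility is
strictly lower in the complex than in the isolated chain held in the same
conformation (ΔrSASA < 0). Because the same test-point set is used for
both evaluations, the complex can only remove accessible points, so the
comparison is exact rather than tolerance-based.

## Interface features

- **Nc** counts cross-chain heavy-atom pairs with separation strictly
  below the cutoff d_c (default 4.5 Å). Comparisons are strict `<` at
  every cutoff in the package. A scan utility reports Nc over
  d_c = 1–30 Å; the benchmark that selected 4.5 Å on real targets is out
  of scope.
- **S** is the *training* accuracy of an SVC with a degree-3 polynomial
  kernel (coef0 = 1, gamma = "scale", C = 1.0, class-balanced weights)
  predicting chain membership from atom coordinates, standardized before
  fitting. Training accuracy (not cross-validation) is used so that a
  perfectly separating cubic surface gives exactly S = 1. The point sets
  are the heavy atoms of the ΔrSASA interface residues; when the
  interface is empty or a chain contributes fewer than 10 atoms (e.g.
  far-apart decoys), whole chains are used so S is always defined. The
  choice of interface atoms over all atoms is switchable
  (`use_interface=False`). S is reported on the closed interval [0, 1];
  values may drift slightly below 0.5 for pathological inputs since
  accuracy is not floored.

## DockQ

DockQ(model, native) = (Fnat + 1/(1+(LRMSD/d₁)²) + 1/(1+(iRMSD/d₂)²))/3
with d₁ = 8.5 Å, d₂ = 1.5 Å.

- Native contacts are cross-chain heavy-atom pairs < 5 Å, identified by
  (chain, residue, atom name) so they can be looked up in any model with
  shared atom identities; Fnat is the preserved fraction. Contacts are at
  heavy-atom pair level; a residue-level variant can be obtained by
  aggregating keys but is not the default.
- LRMSD superposes the model's receptor backbone (N, CA, C, O; OXT
  excluded) on the native's, then takes the RMSD of ligand backbone atoms
  without further fitting.
- iRMSD takes the native's interface residues (any heavy atom < 10 Å
  across chains, computed on the native only), superposes the model on
  the native over those residues' backbone atoms, and reports that fit
  RMSD.
- Superpositions use the Kabsch least-squares rigid fit; fewer than three
  paired points or collinear sets raise errors.

An alternative interface RMSD pools the ΔrSASA interface C-α residuals of
the two monomers, iRMSD = √((d_B,1 + d_B,2)/(N₁ + N₂)), after aligning
each monomer's interface C-α set to its bound counterpart. When a monomer
has fewer than three interface C-α atoms, alignment falls back to all of
its C-α atoms so the displacement of a single interface residue is still
meaningful.

## DockQ landscape and κ²

Each decoy is superposed on the native receptor's C-α atoms, the receptor
C-α COM is placed at the origin, and the ligand C-α COM direction is
recorded as (θ, φ) — θ from +z, φ from +x — at the common radius R, the
native receptor–ligand C-α COM separation (projected-R convention: points
are placed *at* R regardless of the decoy's actual COM distance). COMs
are unweighted means over C-α atoms; ligand orientation is ignored. The
inertia tensor I_αβ = (1/N_m) Σᵢ DockQᵢ³ (rᵢ²δ_αβ − r_αi r_βi) is
diagonalized; eigenvalues are sorted ascending (κ² is symmetric in them,
so the ordering convention is immaterial) and clipped at zero against
roundoff. κ² is 0 for an isotropic shell, 0.25 for a single off-origin
cluster, 1 for a collinear distribution.

## Sampling and balancing

DockQ bin k covers [k/20, (k+1)/20), with the last bin right-closed so
DockQ = 1 is binned. Uniform subsampling keeps at most 50 models per bin,
drawn without replacement. Balancing adds up to 1000 extra negatives
(DockQ < 0.23) not already selected, then randomly trims the majority
class to an exact 1:1 ratio. Positives are DockQ ≥ 0.23 (inclusive).
Trimming the majority class at random was chosen over deterministic rules
because only the balanced outcome, not the mechanism, is specified by the
protocol; the energy-minimization step that real pipelines run between
subsampling and balancing is a no-op hook here.

## Evaluation statistics

- Spearman ρ is the Pearson correlation of average ranks (ties get
  average ranks); constant inputs raise errors. ρ is reported signed:
  energy-like scores (lower = better) correlate negatively with DockQ and
  are never auto-flipped — every evaluation routine takes an explicit
  `lower_is_better` flag.
- ROC AUC is the probability a random positive outranks a random
  negative, ties counting ½; the AUC curve spans cutoffs 0.2–0.8 in steps
  of 0.1.
- h(R) is the fraction of targets with at least one positive in the top R
  by score; h_k(R) is the fraction of N_s random size-N_m draws (without
  replacement) with at least one positive in the top R. Both implement
  the "fraction with at least one positive" semantics directly; within
  rankings, ties keep stable input order.
- μ is the fraction of all models that are negative and strictly outrank
  every positive.

## Two-feature SVR score

An RBF-kernel support vector regression predicts DockQ from standardized
(Nc, S). Defaults: C = 1.0, ε = 0.1, gamma = "scale" (the
1/(n_features·variance) width heuristic); all exposed. Features are
standardized on training data only, which also makes predictions
invariant under affine rescaling of the raw features. Because the score
predicts DockQ, higher is better. Generalization is measured
leave-one-target-out: fit on all other targets, Spearman ρ on the held-out
target, averaged to ⟨ρ⟩_t.

## Bound↔unbound interpolation

Conformers are matched by global sequence alignment (match 2, mismatch
−1, gap open −5, extend −0.5); unaligned terminal residues are trimmed,
substituted residues dropped, and residues with unequal heavy-atom name
sets dropped. Below 30% identity over aligned columns the pair is
rejected as different proteins. Missing-residue reconstruction is
replaced by residue dropping — a deliberate simplification; real
pipelines rebuild residues with an external fixer.

The unbound conformer is Kabsch-superposed onto the bound one *before*
the displacement matrix D̄ is formed, so D̄ captures internal deformation
rather than global pose; without this the interpolation images would
mostly translate. The superposition is optional (`superpose=False`) for
callers who want raw displacements. Images are I_n = bound + (n/N_I)·D̄
for n = 0…N_I inclusive; both endpoints are reproduced exactly (the last
image is assigned, not recomputed, to avoid rounding). N_I defaults to 6;
automatic mode raises N_I until |D̄|/N_I ≤ 1 Å, where |D̄| is the RMS of
per-atom displacement norms (the matrix norm is a package choice; only
the spacing criterion depends on it). iRMSD* divides each image's
ΔrSASA-interface iRMSD by the unbound endpoint's value, so
iRMSD*(N_I) = 1 by construction.

## Synthetic fixtures

**Toy dimers.** Each chain is a serpentine of vertical 6-residue fingers
(C-α plus one pseudo-C-β per residue, 3.8 Å bonds along fingers) placed
on alternating angular columns of a common ring (arc spacing 3.9 Å
between opposite-chain columns). The ring removes boundary columns that a
low-degree surface could otherwise exploit in the interdigitated state.
At `intertwine = 0` chain B sits 1.5 Å above chain A's finger tips — a
flat, plane-separable interface; at `intertwine = 1` the fingers fully
interleave, offset by half a bond along z, so nearest cross-chain
distances (≈ 4.3 Å) give contacts without clashes. Gaussian jitter
(σ = 0.15 Å) avoids exact degeneracies; a KD-tree check enforces
self-avoidance (≥ 2.4 Å between non-bonded atoms) with a bounded number
of re-jitter retries. One pseudo-side-chain atom per residue is
sufficient for contacts, SASA, separability, and DockQ mechanics at desk
scale; these toys have no real secondary structure, packing, or
energetics, so tests passing on them demonstrate the *mechanics* of the
metrics, not scoring performance on real proteins.

**Decoy ensembles.** Ligand perturbations combine a rotation about the
ligand COM (angle 0.03π per Å of magnitude, capped at π) and a
translation along a random direction. Magnitudes follow a logarithmic
schedule over 0.05–60 Å for 80% of the budget; the remainder adaptively
targets the emptiest 0.05-wide DockQ bin by interpolating magnitudes
between the nearest bracketing decoys. The zero-perturbation decoy
(DockQ = 1) is always included, and every DockQ value is computed by the
metric module.

**Score tables.** DockQ values are uniform on [0, 1] (or uniform within
each class for balanced sets, half positive at the 0.23 cutoff). Scores
are a monotone base (±DockQ, matching the requested correlation sign)
plus Gaussian noise whose amplitude is bisected (60 iterations on a fixed
noise vector) until the measured Spearman ρ matches the target; a target
of 0 yields pure noise, independent of DockQ. A requested
negative-dominance fraction μ is then enforced *exactly* by permuting the
score values: the naturally best k = ⌈μn⌉ negatives receive the k best
values, the best positive the next, and the rest keep their relative
order. The permutation preserves the score distribution but shifts ρ —
negligibly for small μ, substantially for μ ≳ 0.1 — so the re-measured ρ
is reported with the dataset rather than re-calibrated.

## Problem sizes and numerical choices

Default test and acceptance runs use 60-residue chains (240 heavy atoms),
decoy ensembles of 80–500 models, and score tables of 2,000–20,000
models, sizes chosen so the full pipeline — SASA, SVM fits, DockQ over
ensembles — completes in seconds while leaving all statistics
well-resolved. Distance comparisons are strict `<` everywhere; Kabsch
fits reject < 3 points and collinear sets; inertia eigenvalues are
clipped at 0; κ² of an all-zero spectrum, AUC of single-class data,
Spearman of constant data, and Fnat of a contact-free native all raise
errors rather than returning conventional values.

## Known limitations

- Toy structures carry only C-α/pseudo-C-β atoms, so backbone-dependent
  quantities (LRMSD, iRMSD) reduce to their C-α restrictions on them;
  full-backbone inputs use all of N, CA, C, O.
- S depends mildly on SVM hyperparameters; the declared fixed convention
  (degree 3, coef0 1, C 1.0, standardized coordinates) makes values
  reproducible but not comparable to differently configured fits.
- The landscape ignores ligand orientation; two decoys with the same COM
  direction but different orientations are indistinguishable there.
- Benchmark campaigns on real PDB targets (hundreds of thousands of
  docking-engine decoys, external scoring programs) are out of scope;
  nothing here estimates those reported per-target correlations.
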
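# Methods

## Problem setting

An "active-site capping" element is a contiguous chain segment that is
α-helical in part of a protein's conformational ensemble, disordered
(unmodeled) in another part, and sometimes present in an alternative, rigidly
displaced placement. `capscan` detects such segments across an ensemble of
coordinate models of one protein, quantifies the occupancy of the three
states, and measures the geometric consequences for the catalytic site. The
package's synthetic generator plants this exact signature with known ground
truth, so every quantitative claim in the test suite is a recovery of a
planted value or an analytic closed form.

## Reference mapping

Members of an ensemble rarely share residue numbering or modeled extent.
Each chain is mapped onto a user-supplied reference sequence by global
Needleman–Wunsch alignment (Biopython `PairwiseAligner`; match +1,
mismatch 0, gap open −5, gap extend −0.5). The scores only need to produce
the unique identity alignment for near-identical sequences — they are not
tuned for remote homology, and a mapping with fewer than 30% identical
aligned pairs is rejected as the wrong protein (`min_identity`, exposed).
Reference positions without a modeled residue are UNMAPPED and propagate as
`D` (disordered) through the whole pipeline. Residues keep their author
numbering so results can be cross-referenced with the literature (e.g.
"Lys 391"); modified residues (MSE, SEP, …) map to their parent amino acid;
alternate locations resolve to the highest-occupancy conformer (ties broken
by altloc letter).

## Cα-only secondary structure

Deposited substate models and synthetic backbones may lack side chains and
amide hydrogens, so hydrogen-bond-based assignment (DSSP-style) is not
uniformly applicable. Assignment therefore uses P-SEA-style Cα geometry:

- helix pattern at residue *i*: d(i,i+2) ∈ [5.1, 6.4] Å and
  d(i,i+3) ∈ [4.2, 5.5] Å, or Cα-dihedral α(i) ∈ [30°, 80°] with
  Cα-angle τ(i) ∈ [85°, 100°];
- strand pattern: d(i,i+2) ∈ [6.7, 7.1] Å and d(i,i+3) ∈ [9.9, 10.7] Å.

A 5-residue window whose internal distances all satisfy the pattern (or
whose center satisfies the angular pattern) nucleates a helix; nuclei are
then extended outward while the per-residue distance pattern persists, which
is what lets an ideal helix be assigned H over ≥ 90% of its length including
termini. Minimum run lengths (H ≥ 5, E ≥ 3) demote isolated hits to coil.
Consecutive Cα further apart than 4.5 Å are treated as a chain break and
split windows; missing positions are `D` and never influence neighbors
except by breaking windows. 3₁₀ and π helices are not distinguished from α.
All thresholds live in `SSParams`.

On the package's own generators the assigner is calibrated as: ideal helices
(n ≥ 8) ≥ 90% H; self-avoiding random coils (bond 3.8 Å, minimum
non-adjacent separation 3.0 Å) < 10% H on average; a fully extended chain
0% H. These are properties of the geometric thresholds, not fitted values.

## Folding-event calling

For each reference position the screen computes f_H (fraction of members
assigning H) and f_D (fraction disordered). A position is event-positive
when f_H ≥ θ_H · s_max and f_D ≥ θ_D, where s_max is the best per-position
member support (1 − min f_D); the support normalization keeps θ_H meaningful
when every member is partially modeled. Defaults θ_H = θ_D = 0.15 with
minimum event length 5 and a merge gap of 2 were chosen so that a capping
segment present in ~30% of members and absent in ~70% is detected with wide
margin while single-position noise is not; all are config-exposed, and no
numeric criterion for an "event" exists in the literature that this could be
matched against. Detection requires ≥ 4 members by default (overridable with
a warning): with fewer structures, occupancy fractions are not meaningful.

## Three-state assignment

Per event, a member is **unfolded** when its segment helicity (#H / #non-D
within the segment) is undefined or < 0.3. Remaining members are **folded**
when the segment's mean Cα displacement from the reference placement is
< 4 Å, otherwise **alternative**. Displacement is measured after Kabsch
superposition on the shared core — all mutually modeled positions outside
the event segment ± 5 residues — so that global pose differences cancel.
The reference placement is the *modal* one: segment centroids of all helical
members are expressed in a common frame and single-link clustered at the
displacement threshold; the largest cluster defines "in place". This makes
the assignment symmetric in member order and robust to the file order of
the ensemble. A user can pin `reference_member` explicitly (e.g. a deposited
ground-state model).

## pLDDT dip test

The dip statistic is Δ = mean pLDDT(segment) − mean pLDDT(flanks), with two
flanks of 15 residues truncated at chain ends. A flank baseline (rather than
the whole-chain mean) is robust to domain-level pLDDT gradients. The null
distribution slides a segment of the same length to uniformly random
positions that do not overlap the true segment, recomputing the same
statistic with its own flanks; the one-sided p-value for a decrease carries
the add-one correction p = (1 + #{Δ_null ≤ Δ_obs}) / (n_perm + 1), so p ∈
(0, 1] and the test is exact-level under exchangeability. With n_perm = 999
the measured type-I error at α = 0.05 over 500 independent null profiles
(Gaussian noise, σ = 2) is ~0.05, and power for a 10-unit dip on a
16-residue segment is ~1.0 (both recomputed by `scripts/acceptance.py`).
Positions near chain ends enter the null with truncated flanks, which makes
the test mildly conservative for interior segments.

## Geometry

- **Superposition** — least-squares rigid fit via SVD (scipy
  `Rotation.align_vectors`), reflection-corrected to det(R) = +1. Inputs with
  < 3 points or collinear geometry raise a degeneracy error rather than
  returning an arbitrary rotation.
- **Pocket volume** — a uniform grid (default 0.5 Å) marks points whose
  clearance from every van-der-Waals surface exceeds the small probe
  (default 1.4 Å) as cavity candidates. Bulk solvent is removed by a
  large-probe (default 3.4 Å) flood fill: grid points a 3.4 Å sphere can
  occupy are labeled by 26-connectivity, components touching the bounding
  box are bulk, and every candidate within 3.4 Å of bulk is discarded. One
  connected component is reported — the one containing (or nearest) the seed
  point, or the largest when no seed is given; the recommended seed for an
  enzymatic site is the centroid of the catalytic atom set. On a hollow
  spherical shell of inner radius R the estimate is within 1% of the closed
  form (4/3)π(R − r_probe)³ at 0.5 Å spacing and converges under grid
  refinement (< 3% change when halving the spacing). The min/max-probe
  semantics mirror common pocket tools, but no bit-compatibility with any
  particular surface implementation is claimed — reported volumes are
  meaningful primarily as *relative* changes between states.
- **SASA / BSA** — Shrake–Rupley quadrature (960 sphere points by default,
  delegated to biotite) with an element radius table
  (C 1.7, N 1.55, O 1.52, S 1.8, P 1.8 Å, common ions; overridable). Buried
  surface area is SASA(A) + SASA(B) − SASA(A∪B). float32 quadrature makes
  BSA of non-interacting chains zero only to ~10⁻⁴ Å². Waters are excluded
  from SASA/BSA and pocket grids by default because deposited models differ
  arbitrarily in water content.

## Synthetic data: what it emulates and what it does not

`make_ensemble` plants a shared self-avoiding coil scaffold, replaces the
event segment with an ideal α-helix (radius 2.3 Å, rise 1.5 Å/residue,
twist 100°/residue) centered on the scaffold segment for folded members,
deletes the segment's residues for unfolded members, and rigidly translates
the helix (default 8 Å, directed away from the scaffold body) for
alternative members. Defaults are the study conditions: 100 members of a
552-residue chain, segment 385–400, fractions 0.23/0.69/0.08 (largest-
remainder rounding to counts), 39 missing N-terminal residues, noise-free.
The unfolded state is realized as *missing residues* because that is how an
unfolded domain manifests in experimental density; a coil-coordinates
variant can be composed from `make_coil` if needed. Optional isotropic
Gaussian jitter models coordinate uncertainty.

Deliberately not emulated: side chains, partial helix occupancy
(intermediate cluster morphologies), physically realistic unfolding
pathways, correlated (domain-level) motions, and crystallographic artifacts.
Passing the planted-truth tests therefore demonstrates that the estimators
are unbiased and exact under the stated three-state model — not that real
ensembles are noiseless; on deposited data the thresholds (θ_H, θ_D,
helicity floor, displacement threshold) are the knobs a user should
sensitivity-check.

`make_site_fixture` places pseudo-atoms C1/C6 at 3.4 Å, an ion with water
oxygens at 2.4/2.8/3.2 Å, and a sealed spherical shell cavity, so distance
and volume code paths are verified against planted values and closed forms.

## Numerical and design notes

- All randomness flows through `numpy.random.default_rng(seed)`; identical
  config + seed reproduces report bytes exactly (tested).
- Largest-remainder rounding converts state fractions to member counts, so
  23/69/8 members result from 0.23/0.69/0.08 at n = 100 exactly.
- Problem sizes in the test suite and acceptance script (100-member
  ensembles, 500 calibration replicates, 0.5 Å grids) were chosen as the
  smallest sizes at which the quantities of interest are stable to well
  inside their stated tolerances.
- Event statistics define a member as "helical" at an event when ≥ 50% of
  its modeled event positions are H, and "disordered" when > 50% of event
  positions are missing; these summaries are descriptive and do not feed
  back into detection.
- Known limitations: no β-sheet pairing/topology; no sequence-based
  secondary-structure prediction; pocket volumes depend on the surface
  definition (see above); the event caller's merge rule can, in pathological
  mosaics, split one region into two calls when θ_D is raised — on planted
  single-event data event counts are monotone non-increasing in θ_D
  (tested).
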
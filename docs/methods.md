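# Methods

This note documents the models behind `rodbend`: what the synthetic
generators emulate, how each analysis is defined, the tunable parameters
with their defaults and units, and the numerical and design choices made
where the problem left them open. All lengths are nm, all angles degrees,
energies are in units of kT, and residue indices are 1-based everywhere
(file-format conversion happens only in `rodbend.io`).

## The synthetic rod and its bending ensemble

The receptor dimer is idealised as a rigid rod of one backbone particle
per residue. `RodSpec` builds `n_chains` (default 2) parallel chains along
+z with `rise_per_residue` (default 0.15 nm, the per-residue rise of an
α-helical coiled coil) and a 1.0 nm lateral chain offset, then adds
isotropic Gaussian noise (`noise_sd`, default 0.05 nm). The noise stands
in for helical wobble and coarse-grained jitter: every analysis in scope
depends only on axis geometry and pairwise distances, so finer structure
is deliberately not modelled. Defaults are a 500-residue chain with the
hinge at residue 268 — the HAMP/coiled-coil junction in Tsr numbering —
so the worked examples read in the system's native coordinates; for other
chain lengths the default hinge scales proportionally. The default domain
partition (ligand-binding 1–220, HAMP 221–hinge, coiled-coil hinge+1–end)
is carried as per-particle labels for domain-local analyses.

`bend_at_hinge` rotates all residues above the hinge rigidly about an
axis perpendicular to the rod axis through the hinge-residue centroid.
`sample_bending_ensemble` draws one bending angle per frame from a
`BendingDistribution`, picks a fresh random in-plane axis per frame
(bending has no preferred direction), and adds fresh positional noise;
the ground-truth angles are returned for recovery experiments.

The bending law is a gamma distribution parameterised by its mode
(default 30°) and scale (`spread_deg`, default 5°), truncated at
`max_deg` (default 60°) by rejection; a wrapped-normal family is
available, and `spread_deg = 0` degenerates to a point mass (used for
fixed-angle ensembles). The gamma family was chosen because it is
strictly non-negative, unimodal and right-skewed, which is what bending
of a stiff rod produces. The scale was calibrated once so that the
documented modal behaviour is a stable property of samples: with scale
5° the two histogram bins flanking 30° exceed every other 5° bin by
several sampling standard deviations at a few thousand frames, while ~4%
of the untruncated mass lies above 60°, so the cap is genuinely
exercised. Note that because the mode lies exactly on a bin edge, the
bins [25°,30°) and [30°,35°) are intrinsically near-equiprobable: the
"modal bin" of a sampled ensemble is whichever of the two wins, and its
midpoint is 27.5° or 32.5°. Checks therefore ask that the modal bin
*touch* 30°.

## Hinge localisation by bisection line fitting

For each candidate split residue *i* (keeping at least `min_segment`
residues per side, default 10 — end fits are otherwise unstable), two
total-least-squares lines are fitted: one to backbone positions with
resid ≤ *i*, one to resid > *i*. The TLS line is the principal axis of
the centred point cloud; its residual is the mean squared perpendicular
distance, computed as (trace − largest eigenvalue) of the 3×3 scatter
matrix. MSD(*i*) is the count-weighted mean of the two residuals, and the
profile minimum is the hinge. Prefix sums of first and second moments
make the whole profile O(N); a brute-force per-split refit serves as the
test oracle.

Two choices matter here:

* **Chain pooling.** A homodimer bends as one body, so the default fit
  collapses each residue to its cross-chain centroid first. Fitting the
  raw union of two laterally offset chains instead leaves a constant
  floor of inter-chain variance (0.25 nm² at a 1.0 nm offset) in every
  residual, and near a kink a slightly tilted axis can absorb part of
  that floor — which systematically displaces the argmin a few residues
  from the true hinge and makes a straight dimer score a non-zero,
  split-dependent profile. The centroid trace is free of the artefact
  (straight dimer → MSD ≈ 0 at every split). Per-chain fitting with
  count-weighted averaging of the chains' profiles is available via
  `per_chain=True` and is likewise unbiased.
* **Tie-break.** An exact kink fits perfectly when split either at the
  pivot residue or one below it, because the pivot lies on both arms.
  Ties (within 1e-12 nm²) resolve to the highest residue: under the
  "lower segment is resid ≤ i" convention the pivot belongs to the lower
  segment. With noise the recovered hinge is within ±1 residue at
  0.05 nm noise and degrades monotonically with noise.

Profiles whose full range is below 1e-6 nm² are flagged flat ("no
hinge") rather than reporting a spurious argmin.

The bending angle is the unsigned angle between the two segment axes
(each oriented from low to high residue), so 0° is straight and the value
lies in [0°, 180°]; no bending direction is defined. Histograms use
fixed-origin bins [0, w), default width 5°; the modal angle is the
midpoint of the highest-count bin, ties resolving to the lower bin with a
flag.

## Elastic network models

All particles within a cutoff are joined by springs of equal, unit
strength; eigenvalues are reported in arbitrary units and only ratios and
shapes are interpreted. The GNM builds the N×N Kirchhoff/Laplacian matrix
(off-diagonal −1 for connected pairs, degree on the diagonal; cutoff
0.7 nm). The ANM builds the 3N×3N Hessian from the standard
super-elements −(r_ij r_ijᵀ)/d_ij² (cutoff 1.3 nm). Zero modes are
|λ| < 1e-8·λ_max; a connected GNM has one, a 3-D non-degenerate ANM six
per component. Decomposition is a full symmetric eigendecomposition, or
shift-invert Lanczos for the k lowest modes on large systems (the full
decomposition is the test oracle). A relative gap < 1e-6 between the
dominant (lowest nonzero) mode and the next raises a degeneracy warning
and both modes are surfaced.

Slow-mode hinge detection takes the dominant GNM mode and selects
residues whose |component| falls below a quantile (default 0.1) of the
within-component magnitudes, merged into contiguous per-chain runs, each
annotated with its minimum-|component| residue and the mode's sign
crossings. At the default cutoff the two chains of the idealised dimer
are separate graph components (chain offset 1.0 nm > 0.7 nm), so the
analysis runs per connected component with that component's slowest
internal mode; runs from the chains are merged by residue index. On bent
dimer rods the slow-mode hinge run overlaps the bisection hinge.

One geometric caveat is worth stating. The ANM of a perfectly straight
line, or of the two-chain planar ladder, is degenerate (transverse
displacements cost nothing at first order, or the two bending
polarisations are split by construction: in-plane bending stretches the
"rails" differentially and is far stiffer than out-of-plane). A
Gaussian-noise rod is 3-D non-degenerate — it shows exactly six zero
modes — but its transverse stiffness is entirely noise-generated, so the
two bending polarisations split by O(1) in a single noise realisation.
The physically meaningful statement "a straight rod's two lowest modes
are degenerate transverse bending modes" requires a cylindrically
symmetric cross-section, which is what a real coiled-coil has. The
package therefore provides `helical_rod` — a straight rod whose backbone
traces a helix (default radius 0.3 nm, rise 0.15 nm) — for which the ANM
transverse pair is degenerate to a few parts per thousand; that is the
structure used to verify the rod-physics invariant.

## Conformer metrics

Superposition uses the SVD (Kabsch) construction with reflection
correction; inputs need ≥ 3 points and a centred scatter of rank ≥ 2.
RMSD series superpose each frame on a reference using only the selected
particles, so domain-local series are blind to rigid motion about a
distant hinge. Modal RMSDs are midpoints of fixed-origin histogram bins
(default width 0.02 nm, matching the 2-decimal precision such values are
reported at). GROMOS clustering computes all pairwise post-fit RMSDs,
repeatedly takes the frame with most neighbours within the cutoff as a
centroid (ties → lowest frame id), assigns the neighbourhood as a
cluster, removes it, and recounts; sizes are non-increasing by
construction. The "middle structure" of a cluster is interpreted as its
RMSD medoid (the member minimising the summed RMSD to the others), the
GROMACS convention. Time-window clustering (e.g. the last stretch of a
trajectory) restricts to frames inside the window. Reported modal RMSDs
of real receptor domains (~0.4–0.65 nm) are used only to set realistic
noise regimes for the synthetic ensembles, not as recovery targets — they
derive from microsecond MD that is not reproducible at the desk.

## Interaction fingerprints

A fingerprint D[i, t] is the minimum distance from any particle of query
residue *i* to any particle of the partner selection at frame *t*
(kd-tree per frame). Contact sets binarise at a threshold (default
0.8 nm at one particle per residue — the colour scale such fingerprints
are plotted with is not standardised, so the threshold is explicit and
configurable); window-based sets require contact in ≥ 50% of frames.
Interface similarity is the per-frame Jaccard index between a query
frame's contact set and the reference fingerprint's time-averaged contact
set; frames where both sets are empty are flagged undefined (NaN), never
scored 1. Vesicle systems are non-periodic spheres, so no minimum-image
convention is applied anywhere.

## Vesicle construction

`VesicleSpec` defaults: 35,000 lipids at fractions 0.70/0.20/0.10
DPPE/DPPG/CL by count (the as-built composition; cardiolipin is one
record per molecule regardless of its two phosphates, since all analyses
count molecules), area per lipid 0.78 nm², bilayer thickness 4.0 nm,
minimum headgroup separation 0.45 nm. Species counts use largest-remainder
apportionment (exact totals); leaflet splits are proportional to leaflet
sphere areas. The outer radius solves 4π(R² + (R−t)²) = n·APL in closed
form; with the defaults, 2R = 69.8 nm ≈ 70 nm. The area per lipid is the
closing free parameter of that relation (lipid count, thickness and
target diameter being fixed); 0.78 nm² is the documented one-time
calibration and is in the physical range for PE-rich headgroup-sphere
areas. Headgroups are placed on each leaflet sphere by a seeded randomly
rotated Fibonacci lattice with 0.03 nm tangential jitter (small enough
that the minimum-separation constraint survives; violating points revert
to their lattice positions), species assigned by seeded permutation.
Leaflet identity is assigned at construction, never inferred from
distance.

Protein anchors are placed at near-equal-area sites: a Fibonacci lattice
polished by a short deterministic tangential-repulsion relaxation
(two sites relax to antipodes; 30 sites keep ≥ 0.8 of the equal-area
separation). Each anchor carries a footprint (default radius 0.6 nm, the
transmembrane cross-section of a four-helix receptor dimer); lipids
inside a footprint are evicted and re-placed uniformly at random outside
all footprints, preserving species and leaflet counts.

## Lipid lateral dynamics

Lateral diffusion is a sequential Metropolis Monte Carlo per leaflet
sphere (compiled with numba; cell-list hard core; exactly reproducible
under its seed). Per sweep, each lipid proposes a Gaussian tangent-plane
displacement (`step_length`, default 0.3 nm — small against the 1 nm
interaction range, large enough to decorrelate shell occupancy in tens of
sweeps) re-projected to its sphere. Moves into a protein footprint or
within the hard-core separation of another headgroup are rejected; the
energy is a square well, −ε_species when within `interaction_range`
(default 1.0 nm, 3-D distance to the nearest anchor) and 0 otherwise,
accepted with min(1, e^(−ΔE)). Default well depths are ε_CL = ln 2,
ε_DPPG = ln 1.5, ε_DPPE = 0: in the dilute limit the equilibrium shell
concentration of a species is exactly e^ε times bulk, so the defaults
encode a doubling of cardiolipin and a 1.5× enrichment of DPPG at the
protein, with the zwitterionic DPPE neutral. Temperature enters only
through ε being expressed in kT. Frames are recorded every
`record_stride` sweeps (default 100) and the returned ensemble's "times"
count sweeps.

## Shell enrichment and mixing

A lipid is in-shell when its headgroup lies within `shell` (default
1.0 nm) 3-D Euclidean distance of any protein anchor — the distance is to
the protein, not along the membrane, and with a 4 nm bilayer only the
anchor leaflet can populate a 1 nm shell. Three conventions are reported
side by side because they answer different questions and the field's
usage is ambiguous:

* `vs_bulk` — shell composition over global composition,
  (c_s/Σc)/(n_s/Σn). Null value 1; insensitive to total shell packing.
* `vs_dppe` — the same normalised to DPPE; identically 1 for DPPE.
  Algebraically equal to vs_bulk(s)/vs_bulk(DPPE).
* `concentration` — per-area number density in the shell over the bulk,
  using the exact spherical annulus and cap areas. This is the quantity
  that converges to the Boltzmann factor e^ε in the dilute limit and the
  natural reading of "doubles in concentration".

With the default well depths the steady-state fraction-based vs_bulk for
CL converges to e^(ε_CL)/⟨e^ε⟩ ≈ 1.7 rather than 2 (other species are
enriched too), while the concentration ratio converges to ≈ 2; both are
emitted so neither reading is guessed. Steady-state summaries pool counts
over the last 50% of frames (pooled counts, not means of per-frame
ratios, so sparse-shell frames do not dominate); frames with an empty
shell are flagged undefined.

A known bias of the concentration convention at these geometries: the
shell annulus (footprint edge to 1 nm) is barely wider than one hard-core
diameter, so it coincides with the hard-disk wall-contact layer at the
footprint boundary, whose equilibrium density is enhanced by roughly
1/(1−η) (~10–15% at the default packing fraction ≈ 0.2). The enhancement
is species-independent — it cancels exactly in `vs_bulk` and `vs_dppe`
and appears as a common factor in `concentration` (the flat-energy null
sits near 1.13 for every species). Enrichment *ratios between species*
are unaffected.

The mixing statistic guards against spontaneous phase separation: for
each lipid, the fraction of its k nearest same-leaflet neighbours
(default k = 6, the 2-D coordination number) sharing its species,
averaged per species and compared with the well-mixed expectation
(n_s−1)/(n_leaflet−1). The demixing index (observed − expected) stays
within ±0.02 of zero for well-mixed vesicles of ≥ 10⁴ lipids and exceeds
0.4 for a two-patch demixed sphere; with all well depths zero the
generator provably cannot demix (the flat-energy chain is uniform on the
constraint set), which the tests confirm.

## What the generators do and do not emulate

The synthetic ensembles reproduce the *statistical* structure the
analyses consume: a single hinge with a configurable angle law, isotropic
positional noise, species-labelled lipids with tunable protein affinity
and hard-core packing on leaflet spheres. They do not contain forcefield
energetics, helical secondary structure (beyond `helical_rod`'s
geometry), membrane curvature elasticity, solvent, or self-assembly
dynamics. Passing recovery tests therefore demonstrates that the
analysis pipeline measures what it claims to measure at realistic noise
levels — not that any particular molecular system behaves this way.
Conversely, the construction-level numbers (lipid counts, composition,
vesicle diameter) are exact properties of the builder.

## Problem sizes used in validation

The validation suite and the acceptance script were sized for a
single-CPU desk run: 5,000-frame ensembles for bending statistics,
50-frame ensembles for hinge recovery, a 2,000-lipid vesicle with 4
protein sites and 10⁵ Monte-Carlo sweeps for enrichment recovery, and
150–500-residue rods for the network models. These sizes keep every
statistical tolerance several sampling standard deviations wide, as
detailed above.

## Known limitations

* The bisection method assumes exactly one hinge; multi-hinge
  segmentation is out of scope, and a straight rod is reported as
  hinge-free rather than segmented.
* GNM slow-mode hinge detection on a quasi-one-dimensional rod is driven
  largely by connectivity, so its node gravitates toward the chain
  middle; it corroborates a central hinge (as here, residue 268 of 500)
  but could not localise a strongly off-centre hinge by itself.
* The Monte-Carlo lipid model has no lipid–lipid interactions beyond the
  hard core, so it cannot produce cooperative phase behaviour — by
  design, since its role is a controllable enrichment ground truth.
* Fingerprint binarisation follows the minimum-distance definition only;
  alternative contact definitions (heavy-atom counts, buried surface)
  are not implemented at the one-particle-per-residue resolution.
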
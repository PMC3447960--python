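# rodbend

Analysis toolkit for coarse-grained simulations of rod-shaped membrane
receptors — bacterial chemoreceptors such as the *E. coli* serine receptor
Tsr being the motivating system — together with the synthetic generators
needed to exercise every analysis against known ground truth.

A chemoreceptor homodimer is a ~20 nm rod (ligand-binding domain, HAMP
linker, cytoplasmic coiled-coil) that bends sharply about a single hinge
near the HAMP/coiled-coil junction. `rodbend` implements the analysis layer
such a study needs, at one backbone particle per residue:

- **Hinge localisation by bisection line fitting** — for every candidate
  split residue *i*, fit total-least-squares axes to the backbone above and
  below the split and record the count-weighted mean squared deviation
  MSD(*i*); the profile minimum locates the hinge.
- **Bending-angle statistics** — per-frame angle θ = arccos(d̂₁·d̂₂)
  between the two segment axes, histogrammed in fixed 5° bins with modal
  and maximum summaries.
- **Elastic network models** — Gaussian (Kirchhoff Γ, cutoff 0.7 nm) and
  anisotropic (Hessian H, cutoff 1.3 nm) networks with unit springs;
  slow-mode analysis identifies hinges as runs of residues where the
  dominant eigenvector |v₁| is small.
- **Conformer metrics** — Kabsch superposition RMSD, per-domain RMSD series
  with modal summaries, GROMOS neighbour-counting clustering, and
  RMSD-medoid ("middle structure") representatives.
- **Interaction fingerprints** — per-residue minimum distance to a partner
  protein copy over time, contact sets, and Jaccard similarity tracking
  convergence of a forming interface toward a reference binding surface.
- **Vesicle construction and lipid analysis** — geometric assembly of a
  two-leaflet spherical vesicle (default: 35,000 lipids at 7:2:1
  DPPE:DPPG:CL, closing to a ~70 nm outer diameter), evenly placed protein
  anchors, square-well Metropolis Monte Carlo of lipid lateral diffusion,
  and shell-enrichment / lateral-mixing statistics (e.g. cardiolipin
  doubling its concentration within 1 nm of a protein when its well depth
  is ln 2 kT).

Because no trajectories are deposited for such studies, the package ships
first-class synthetic generators: a rod/bending-ensemble generator with a
configurable hinge and truncated-gamma bending law (mode 30°, cap 60°), and
the vesicle builder above. Every analysis is validated by parameter
recovery against these generators and by independent brute-force oracles.

## Worked example

```python
import rodbend as rb
from rodbend.vesicle import VesicleSpec, allocate_counts, solve_radius

# a 500-frame synthetic dimer ensemble at the documented defaults
ens, truth = rb.sample_bending_ensemble(
    rb.RodSpec(noise_sd=0.05, seed=1), rb.BendingDistribution(),
    n_frames=500, seed=1)

profile = rb.ensemble_hinge_profile(ens, min_segment=10)
series = rb.bending_series(ens, profile.hinge, bin_width=5.0)
print(f"hinge residue      : {profile.hinge}")
print(f"modal bending angle: {series.modal_deg:.1f} deg (bin {series.modal_bin})")
print(f"max bending angle  : {series.max_deg:.1f} deg")

spec = VesicleSpec()
r_out, r_in = solve_radius(spec)
print(f"vesicle: counts={allocate_counts(spec)}, outer diameter={2*r_out:.1f} nm")
```

prints

```
hinge residue      : 267
modal bending angle: 27.5 deg (bin (25.0, 30.0))
max bending angle  : 59.1 deg
vesicle: counts={'DPPE': 24500, 'DPPG': 7000, 'CL': 3500}, outer diameter=69.8 nm
```

The generator kinked the rod at residue 268 with a 30°-mode, 60°-capped
bending law; the bisection profile recovers the hinge to within one
residue, the modal histogram bin touches 30°, and the maximum angle sits
just under the cap. The default vesicle specification reproduces the
24,500/7,000/3,500 DPPE/DPPG/CL split and a ~70 nm outer diameter.

The same pipelines are available from the shell:

```sh
rodbend generate ensemble --config rod.cfg --seed 1 --out ens.pdb
rodbend hinge --in ens.pdb --out hinge_out/
rodbend enm --in rod.pdb --model gnm --out enm_out/
rodbend vesicle build --seed 1 --n-sites 4 --out ves.gro
rodbend vesicle dynamics --in ves.gro --n-sweeps 20000 --out frames/
rodbend lipids enrich --frames frames/ --sites ves.gro.vesicle.json --out enrich/
```

Structures are exchanged as PDB/GRO, trajectories as multi-model PDB; all
internal coordinates are nm and residue indices are 1-based.

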
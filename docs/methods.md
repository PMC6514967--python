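# Methods

## The protocol

`metabind` implements a binding-mode determination protocol built from four
stages: (i) funnel-restrained well-tempered metadynamics along a binding
CV, run first as a short pathway-sampling segment and then as a
multiple-walker production run; (ii) free-energy reconstruction from the
deposited hills and location of the global minimum; (iii) extraction of all
frames within a CV window of the minimum, backbone superposition, and
average-linkage clustering on the unfitted ligand-heavy-atom RMSD with
population ranking; (iv) unbiased refinement of each cluster representative
with a four-way convergence classification.  The protocol's success
criterion is that the top-populated cluster refines to the reference
binding mode.

The binding CV is s = z(ligand anchor) − z(receptor anchor), positive
toward the solvent.  Restraints: harmonic CV walls with
κ = 1500 kJ·mol⁻¹·nm⁻², and the sigmoidal funnel
R(z) = d/(1+exp(m(z−w))) + r1,
V = h(1 − 1/(1+exp(λ(r−R(z))))), wide (d+r1) around the receptor and
narrowing to a tube of radius r1 in the solvent.  λ is treated as nm⁻¹ so
the exponent is dimensionless.  The funnel axis is the laboratory z axis
through the receptor anchor atom; tilted funnels are not supported.  No
funnel-volume correction is applied to the reconstructed free energy; the
profile is used only to locate its minimum, not to report absolute binding
free energies.

Well-tempered deposition: W = W₀·exp(−V(s,t)/(kB·ΔT)), ΔT = (γ−1)T.
Defaults follow the published GPCR settings: γ=50, W₀=7 kJ/mol for the
initial pathway run; γ=20, W₀=5 kJ/mol for the 32-walker production run;
σ = 0.1 nm in both (the bare "0.1" is read as nm, consistent with the other
lengths).  The deposition stride is not stated in the source protocol; the
default here is 500 integration steps.  Multiple walkers share one
in-process hill list: each deposit is scaled by the bias of *all* walkers
and is felt by all walkers from the next force evaluation — the behavioural
contract of file-synchronized walkers, without the file mechanics.  Bias
evaluation is direct vectorized summation over the hill list.

Free-energy reconstruction uses the standard well-tempered rescaling
F(s) = −(γ/(γ−1))·V(s) on a uniform grid (default step 0.01 nm, range
[min hill − 3σ, max hill + 3σ]), shifted so the global minimum is zero.
The minimum is refined by a parabolic fit through the minimum grid point
and its two neighbours; no smoothing is applied before minimum location.
Ties within 1e-9 resolve toward the smaller CV.

Extraction uses a closed interval |s − s_min| ≤ ΔCV with ΔCV = 0.3 nm
(3 Å), read inclusively; a 1e-12 nm epsilon keeps exact-boundary frames in
despite double-precision representation error.  Superposition is a Kabsch
least-squares fit on the backbone atoms (via scipy's rotation alignment);
collinear backbones are rejected.  The clustering distance is the
*unfitted* RMSD of the ligand heavy atoms — no second fit — which equals
the Euclidean distance of flattened ligand coordinates divided by √n_atoms,
so the distance matrix is one `pdist` call.  The linkage criterion is not
stated in the source protocol; average linkage (the default of the
trajectory-analysis tool it cites) is used, with scipy's deterministic
merge ordering.  The cluster count target is 5.  The representative is the
member with minimal intra-cluster RMSD sum.  Pocket RMSD uses backbone
atoms within 5 Å of the reference ligand, selected once from the reference
frame.

Refinement classification, over the final half of the run:
`converged_to_reference` if mean ligand RMSD ≤ 2 Å (the scale of a stably
bound pose); else `dissociated` if the CV exceeds the funnel-mouth CV more
than half the time; else `flexible` if the RMSD standard deviation exceeds
1.5 Å; else `alternative_stable`.  The source protocol describes these
outcomes narratively; the thresholds here make them reproducible and are
configuration keys.

## Toy systems

The published validation of this protocol used three all-atom GPCR/membrane
systems at ~1.5 μs of cumulative metadynamics each, far beyond desk scale.
The package therefore validates the machinery on synthetic systems whose
correct answers are known by construction:

**Double well.**  One mobile particle; U(z) = barrier·((z/a)²−1)² + tilt·z
plus a weak transverse harmonic.  The tilt is solved at build time (Brent's
method on the trapezoid-rule Boltzmann integral) so that the basin
free-energy difference equals the requested ΔF exactly (quadrature error
< 0.01 kJ/mol).  Since the CV is the particle's z, the analytic free-energy
profile *is* the 1D potential.

**Binding system.**  A frozen 14-bead scaffold (anchor bead at the
origin, an 8-bead pocket ring, a 4-bead floor ring closing the receptor
interior, a base bead) and a rigid 4-bead asymmetric ligand.  Each planted
pose contributes an anisotropic Gaussian well in 12-dimensional pose space,
E = −depth·exp(−Σᵢ[(dxᵢ²+dyᵢ²)/(2n·σ_xy²) + dzᵢ²/(2n·σ_z²)]), whose
minimum is exactly the pose.  The bound pose (ligand anchor at
CV = 0.46 nm, echoing the 4.6 Å histamine reference) is the sum of a broad
capture well (24 kJ/mol, σ = 0.22 nm isotropic) and a narrow core
(16 kJ/mol, σ_xy = 0.18 / σ_z = 0.09 nm); a reversed-orientation decoy
sits at CV = 1.2 nm with a 12 kJ/mol well.  Stiff bead–bead springs
(8000 kJ·mol⁻¹·nm⁻²) keep the ligand effectively rigid; short-range
Gaussian repulsion from the scaffold (30 kJ/mol, σ = 0.1 nm) closes the
pocket walls.  The shape was chosen against two failure modes of a single
isotropic well: a Gaussian well in 12 dimensions is strongly entropically
destabilized at 310 K, so the broad component supplies thermal retention
(the potential depth must sit well above the target free-energy depth of
~25 kJ/mol), while the narrow z-core sharpens the curvature of F(s) at the
minimum so that the hill-broadened minimum can be located to better than
0.05 nm.  The analytic CV profile is computed at build time by trapezoid
Boltzmann integration of the rigid-ligand field over the transverse plane
for the two planted orientations; intermediate orientations are neglected,
which is adequate for locating the minimum and quantifying the
bound/solvent contrast.  The decoy sits 7 hill-widths above the bound
pose: closer placements visibly bias the broadened minimum location.

**Planted ensembles.**  For validating clustering in isolation, frames are
drawn mode-by-mode from a single multinomial draw of per-mode counts, with
per-atom Gaussian noise and optional global rigid motion (which backbone
superposition must undo).  The default validation ensemble uses five modes
at 70/20/5/4/1% — one dominant mode, mid-size secondary modes and
sub-percent tails, the population pattern the protocol produces on real
receptors.

What the toys do *not* emulate: conformational flexibility of receptor and
ligand, explicit solvent and membrane, rugged energy landscapes, and
force-field error.  Passing tests therefore demonstrate that the
*protocol machinery* — bias bookkeeping, free-energy reconstruction,
extraction, clustering, classification — is correct, not that the physics
of any particular receptor is reproduced.

## Dynamics

BAOAB-discretized Langevin dynamics samples the canonical ensemble; the
source protocol used a Berendsen thermostat with pressure coupling on
membrane systems, but the protocol's logic only requires canonical
sampling, so the simpler vacuum constant-volume integrator is a documented
deviation.  Scaffold atoms are frozen (the clustering fit is on the
backbone, so a rigid backbone is the minimal faithful analogue).  Defaults:
friction 1 ps⁻¹, 310 K.  The time step defaults to 2 fs in `RunSpec`
(matching the all-atom setting) but the smooth toy potentials are stable
far beyond that; the pipeline uses 5 fs and the double-well validation
10 fs, each more than 25 steps per fastest oscillation period.  All
randomness derives from one master seed via `numpy` seed sequences, with
per-walker spawned streams, so every run is bitwise reproducible.

## Problem sizes

Desk-scale defaults, chosen to give converged validation results on the toy
landscapes: initial pathway run 100k steps; production 32 walkers × 40k
steps (hills every 500 steps → 2560 shared hills); refinement 40k steps per
cluster.  The double-well free-energy validation uses 4 walkers × 200k
steps at dt = 10 fs, which recovers a constructed ΔF = 10 kJ/mol within
1 kJ/mol; the residual fluctuation of the estimate (~±0.5 kJ/mol) is the
intrinsic ripple of well-tempered hill deposition at W₀ = 5 kJ/mol, which
decays only slowly with run length.

## Numerical notes and limitations

* Sigmoids are evaluated with `scipy.special.expit`; the funnel gradient on
  the axis (r = 0) is defined as zero — the prefactor vanishes to machine
  precision there.
* Wall and funnel gradients are analytic (the integrator needs forces);
  both are validated against central differences.
* Non-finite forces raise an integration error with the step index; the
  check is a single scalar-sum test per step.
* The funnel radius saturates at double precision more than ~1.8 nm from
  its inflection point; monotonicity is strict only where the sigmoid is
  numerically resolvable.
* `reconstruct_fes` of an empty hill list returns a flat profile with a
  warning flag rather than raising; locating a minimum on a flat profile
  raises.
* Trajectories are written as extended multi-frame XYZ (with CV, time and
  walker id in the comment lines); of the two interchange formats
  supported by the analysis stages, XYZ was chosen over multi-model PDB
  because the pseudo-atom beads carry no chemical identity.
* One-dimensional CV only; adaptive-width Gaussians, transition-tempered
  variants, 2D profiles, reweighting and block-error convergence analysis
  are out of scope.
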
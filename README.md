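# metabind

Determining *where and how* a small ligand binds inside a receptor is hard
when the bound structure is unknown: plain molecular dynamics rarely samples
a binding event, and docking often fails when the receptor conformation is
off. `metabind` implements, end to end and at desk scale, a
metadynamics-based protocol for predicting ligand binding modes:

1. **Funnel-restrained well-tempered metadynamics** along a binding
   collective variable (CV) — the z component of the distance between a
   receptor anchor atom and the ligand's amine nitrogen — drives the ligand
   in and out of the pocket while a funnel-shaped restraint suppresses
   irrelevant solvent sampling.
2. **Multiple walkers** share one history-dependent bias: every deposited
   Gaussian hill is felt by all replicas, and the free-energy profile is
   reconstructed from the merged hill list as F(s) = −(γ/(γ−1))·V(s).
3. **Frames within ΔCV ≤ 3 Å of the free-energy minimum** are extracted,
   superposed on the receptor backbone, and clustered by hierarchical
   agglomerative (average-linkage) clustering on the *unfitted* RMSD of the
   ligand heavy atoms; clusters are ranked by population.
4. **Unbiased MD refinement** of each cluster representative checks whether
   the pose stays put; the protocol succeeds when the top-populated cluster
   converges to the reference binding mode.

The well-tempered bias deposits Gaussians of width σ and height
W = W₀·exp(−V(s,t)/(kB·ΔT)) with ΔT = (γ−1)·T.  The funnel restraint is

    R(z) = d / (1 + exp(m·(z−w))) + r1
    V_funnel(x,y,z) = h · (1 − 1 / (1 + exp(λ·(r(x,y) − R(z)))))

with harmonic walls κ(z−z_low)² / κ(z−z_up)² confining the CV itself.

Because the published application of this protocol runs on μs-scale
all-atom GPCR/membrane systems, this package ships **synthetic toy systems
with analytically known answers** instead: a 1D double well whose basin
free-energy difference is calibrated exactly, and a 3D "pocket + channel"
receptor–ligand system with a planted bound pose, a reversed-orientation
decoy, and planted cluster populations.  Every stage of the protocol is
validated against those known answers.

## Worked example

```python
from metabind.pipeline import PipelineConfig, run_pipeline

cfg = PipelineConfig(seed=7, outdir="run7", system={"kind": "binding", "seed": 7})
manifest = run_pipeline(cfg)
print(manifest["stages"]["report"])
```

This runs the full protocol on the toy binding system (32 walkers, γ=20,
W₀=5 kJ/mol, σ=0.1 nm) and prints a summary like

```
reference_cv              0.46      # CV of the planted bound pose (nm)
fes_minimum_cv            0.4672    # located free-energy minimum (nm)
extracted_fraction_pct    27.5      # frames within 3 Å of the minimum
cluster_populations_pct   [98.2, 1.0, 0.4, 0.4, 0.1]
top_cluster_ligand_rmsd_A 0.58      # unfitted ligand RMSD to the reference
success                   True      # top cluster refined to the reference
```

The located minimum falls within 0.05 nm of the planted bound-pose CV, one
cluster dominates the population ranking, its representative sits about
half an ångström from the planted pose, and its unbiased refinement stays
bound — the same qualitative signature the protocol shows on real
receptors.  (Numbers vary
slightly with the seed; the run writes HILLS/COLVAR files, the free-energy
profile, cluster assignments and refinement time series into `run7/`.)

The same flow is available from the shell:

```bash
metabind pipeline --seed 7 --out run7
metabind fes --hills run7/multiwalker_hills.dat --gamma 20 --out fes.dat
```

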
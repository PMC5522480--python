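# helixsans

Quantitative analysis pipeline for polypeptides whose secondary structure
is switched by the hydrogen-bonding pattern of their side-chains.

Cationic polypeptides bearing side-chain 1,2,3-triazoles are random coils
at neutral pH: the triazole both donates (C5-H) and accepts (N3) hydrogen
bonds — a *binary* H-bonding (BHB) pattern that competes with the
backbone's own i → i+4 amide ladder. Protonation at N3 (pKa ≈ 4.1 on the
polymer) turns the ring into a triazolium, a donor-only (*unitary*, UHB)
group, and the chain folds into an α-helix. `helixsans` implements the
analyses that quantify this transition, driven end-to-end by a
synthetic-data generator that emulates the statistical structure of MD
trajectories and reduced SANS measurements:

* **peptide_model** — residue/atom topology with per-site protonation,
  formal charges (+1 per terminal trimethylammonium, +1 per triazolium,
  zwitterionic termini) and donor/acceptor tables;
* **synthetic_data** — ideal helices, self-avoiding random coils,
  perturbed and folding trajectories, geometric solvation with planted
  depletion zones, noisy multi-contrast SANS curves, titration tables;
  multi-model PDB and 3-column ASCII I/O;
* **helix_geometry** — axis/radius/twist/rise fitting of Cα traces and
  RMSD to an ideal helix (r = 0.23 nm, γ = 100°, rise 0.15 nm) after
  optimal superposition;
* **hbond_analysis** — geometric H-bond detection (d ≤ 0.35 nm,
  ∠H-D-A ≤ 30°) partitioned into backbone–backbone, backbone–water and
  backbone–side-chain bonds, with chain-end (dangling group) accounting;
* **hydration_analysis** — g(r) between the backbone centre of mass and
  water oxygens (0.04 nm bins, five-block standard errors) and the water
  depletion radius;
* **sans_model / sans_fit** — orientationally averaged cylinder form
  factor, analytic Percus–Yevick and numerically solved Hayter–Penfold
  (rescaled-MSA) structure factors, additive low-q power law; simultaneous
  multi-contrast fitting, and the contrast-variation estimator in which
  the slope of particle SLD against solvent SLD is the water volume
  fraction φ_w inside the particle:

      I(q) = scale · φ · P_cyl(q) · S_HP(q) + A·q⁻ⁿ + B
      SLD_particle = φ_w · SLD_solvent + (1 − φ_w) · SLD_dry

* **pipeline / cli** — orchestration, flat key-value configs, JSON
  reports, Henderson–Hasselbalch pKa fitting, and a `helixsans` command
  with `simulate`, `analyze-traj`, `fit-sans` and `fit-pka` subcommands.

## Worked example

```python
import numpy as np
from helixsans import (
    PipelineConfig, run_conformation_pipeline, run_sans_pipeline,
    fit_pka, simulate_titration,
)

# helical-state trajectory: 20 solvated frames of the protonated 10-mer
cfg = PipelineConfig.conformation(kind="stable_helix", n_frames=20,
                                  n_waters=2000, seed=7)
rep = run_conformation_pipeline(cfg)
helix = rep.stages["helix"]
hb = rep.stages["hbonds"]
print(f"fitted radius   : {helix['final_fit']['radius_nm']:.3f} nm")
print(f"fitted twist    : {helix['final_fit']['twist_deg']:.1f} deg")
print(f"RMSD_helix      : {helix['rmsd_mean_nm']:.3f} "
      f"+/- {helix['rmsd_std_nm']:.3f} nm")
print(f"B-B per residue : {hb['per_residue_mean']['BB']:.2f}")
print(f"dangling N-H/C=O: {hb['dangling_nh']} / {hb['dangling_co']}")
print(f"depletion radius: {rep.stages['hydration']['depletion_radius_nm']:.2f} nm")

# acidic-condition SANS: three contrasts (100/75/50 % D2O), joint fit
srep = run_sans_pipeline(PipelineConfig.sans(preset="pH2", seed=7, n_starts=3))
jf = srep.stages["joint_fit"]["params"]
wf = srep.stages["water_fraction"]
print(f"power-law n     : {srep.stages['powerlaw'][0]['exponent']:.2f}")
print(f"cylinder R, L   : {jf['radius_a']:.1f} A, {jf['length_a']:.1f} A")
print(f"water fraction  : {wf['phi_water']:.3f}  (r^2 = {wf['r_squared']:.5f})")

t = simulate_titration(4.1, np.linspace(2, 9, 40), noise_sd=0.02, seed=7)
print(f"fitted pKa      : {fit_pka(t).pka:.2f}")
```

prints

```
fitted radius   : 0.231 nm
fitted twist    : 101.3 deg
RMSD_helix      : 0.036 +/- 0.007 nm
B-B per residue : 0.42
dangling N-H/C=O: 4 / 4
depletion radius: 0.44 nm
power-law n     : 3.59
cylinder R, L   : 13.0 A, 75.0 A
water fraction  : 0.507  (r^2 = 0.99995)
fitted pKa      : 4.09
```

Reading: the perturbed helical ensemble fits a helix of radius 0.231 nm
and twist ≈ 100° (ideal: 0.23 nm, 100°) with Cα RMSD 0.036 nm from the
ideal reference; only ~0.4 backbone–backbone H-bonds per residue survive
because four N-H and four C=O groups dangle at the chain ends; a ~0.4 nm
water-free zone surrounds the backbone centre of mass. The three-contrast
SANS fit recovers the planted cylinder (R = 13 Å, L = 75 Å), the
surface-scattering decay exponent ≈ 3.6, and — from the slope of particle
SLD against solvent SLD — a 51 % water volume fraction inside the
cylinder. The basic-condition preset (`preset="pH8"`) yields a shorter
cylinder (~62 Å) holding more water (~59 %), the signature of the coil
state. The titration fit returns the planted pKa of 4.1.

The same pipelines run from the shell:

```sh
helixsans simulate --kind stable_helix --n-frames 20 --out traj.pdb
helixsans analyze-traj --trajectory traj.pdb --out report.json
helixsans fit-sans --out sans_report.json
helixsans fit-pka --curve titration.dat
```

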
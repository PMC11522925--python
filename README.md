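# entryscope

Trajectory analysis for polyester-degrading serine hydrolases (PET
hydrolases such as LCC and PES-H1 variants): how the enzyme adsorbs onto
the polymer surface and how a polymer chain enters the binding cleft into a
catalytically competent pose.

The package is aimed at molecular-simulation practitioners who have
enzyme–polymer trajectories (or want validated synthetic test cases) and
need the standard post-processing chain behind interfacial-biocatalysis
studies:

- **Contacts** — residue–polymer contact maps at a 3 Å heavy-atom cutoff,
  persistence filtering (≥ 75 % of weighted simulation time), and
  proximal/distal classification of binding sites at 12 Å from the
  catalytic serine Oγ.
- **Energetics** — pairwise nonbonded interaction energies
  E = Σ k·qᵢqⱼ/r + 4ε[(σ/r)¹² − (σ/r)⁶] per residue and per
  physicochemical class (apolar/polar/charged/aromatic, scaled by the
  number of contacting residues), intramolecular polymer unit–unit
  energies, binding-onset detection at −10 kcal·mol⁻¹, and per-site
  parent-vs-variant comparisons.
- **Entry** — the SER–C reaction coordinate (serine Oγ to the nearest
  ester carbonyl carbon), productive-pose detection (SER–C and both
  oxyanion-hole distances ≤ 4 Å), *si*/*re* face labelling of the serine's
  approach to the planar ester, and segmentation into
  outside (> 6 Å) → entry → inside (< 4 Å) phases.
- **FES** — weighted 2D free-energy surfaces
  ΔG = −k_B T ln(P/P_max) in kJ/mol with replica pooling, feature
  extraction (productive/nonproductive minima, minimax barrier), and
  parent-vs-variant classification at a 1 k_BT threshold.
- **Pathways** — PCA of ester-C→Cα distances (10 Å feature radius) during
  entry, per-residue PC contributions, and k-means assignment of entries
  to the three preferred entry routes in the PC1/PC2 plane.
- **Kinetics** — conventional (vary substrate load, g/L) and inverse
  (vary enzyme, μM) Michaelis–Menten fits v = V_max·x/(K_m + x), and the
  secondary parameters k_cat, molar K_m, and molar catalytic efficiency
  η = k_cat / molar K_m.

Synthetic generators (`entryscope.synthcase`) produce all of the above
with planted ground truth: contact patterns with exact persistence
fractions, entry trajectories along three spatial corridors with known
phase boundaries, Metropolis samples of analytic 2D potentials, and noisy
kinetic datasets.

## Worked example

```python
from entryscope import synthcase as sc, entry as en, kinetics as kin
from entryscope.model_io import AnalysisConfig

cfg = AnalysisConfig()                      # 3/12/4/6/10 Å, 303 K defaults
spec = sc.FixtureSpec(seed=1, n_residues=40, n_polymer_units=5,
                      n_frames=120, noise=0.3)
system, ref = sc.make_toy_system(spec)
traj, truth, corridor = sc.simulate_entry(system, ref, spec, corridor=2, seed=11)

series = en.entry_series(traj, system, cfg)
events = en.segment_entries(series, cfg)
ev = events[0]
print(ev.outside, ev.entry, ev.inside, ev.face, ev.productive)
# (0, 96) (96, 100) (100, 120) si True

sec = kin.secondary_params(None, None, None, k_cat=0.047, molar_K_m=0.357)
print(kin.round_report(sec.molar_eta))
# 0.132
```

The first line says the polymer stayed outside the cleft (SER–C > 6 Å)
for frames 0–95, crossed the boundary zone in frames 96–99, and sat
inside (< 4 Å) from frame 100 on, reaching a productive *si*-face pose.
The second computes the molar catalytic efficiency
η = 0.047 / 0.357 μM⁻¹ min⁻¹ μM⁻¹ for a leaf-branch-compost cutinase
variant from its turnover number and molar attack-site K_m.

The same stages run end-to-end from a single config:

```bash
entryscope run --config config.yaml --out-dir results/
entryscope synth --seed 3 --out-dir fixture/     # topology + trajectory + truth
```

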
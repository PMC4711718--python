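# lungphantom

Synthesis of labeled anthropomorphic pulmonary CT phantoms: artery, vein,
and airway trees grown sequentially under coupled oxygen-demand maps,
rasterized with partial-volume realism, post-processed into CT-like volumes,
and shipped with a voxel-wise artery/vein/airway reference standard.

## Why

Validating pulmonary image-processing methods — vessel segmentation,
artery–vein separation, airway analysis — requires reference standards that
are prohibitively expensive to produce by manual annotation. A synthetic CT
in which every voxel's identity is known by construction sidesteps the
problem, provided the simulated lungs are statistically close to real ones.
`lungphantom` generates such phantoms in two modes:

* **segment mode** — an idealized bronchopulmonary segment on a cubic grid,
  from a configuration alone;
* **anthropomorphic mode** — phantoms adapted to a labeled chest CT case
  (lung mask + artery/vein/airway segmentations), matching its geometry,
  tree complexity, and intensity statistics, and embedded back into the
  host CT. Because real labeled cohorts are access-controlled, a
  self-validating synthetic case generator (`make_fixture_case`) stands in
  for them in tests and demos.

## The model

Trees are grown by iterative, demand-driven constrained constructive
optimization. An *oxygenation map* O(x) ∈ [0, 1] acts as the sampling
density for new terminal sites; a candidate is admissible if it keeps a
minimum distance D_T from the existing tree surface and a 26-connected
path of positive demand to the tree exists. Each accepted terminal is
attached at the bifurcation point (searched along the k = 5 nearest
segments) that minimizes the material cost Σ l^μ r^λ.

Hemodynamics follow Poiseuille flow: a segment of length l and radius r has
resistance 8ηl/(πr⁴); terminal flows are Q/N_f each; sibling radius ratios
β obey the bifurcation law β_l^γ + β_r^γ = 1 (γ = 2.55) together with equal
sibling pressure drops, solved bottom-up with the reduced-resistance scheme
so every terminal sits exactly at P_fin (P_ini = 25 mmHg, P_fin = 10 mmHg,
η = 36 mPa·s, Q = 138.83 cc/min).

The three flow systems are coupled through their demand maps: arteries grow
centrally (chessboard-distance gradient from a central core), airways grow
in a shell around the realized arterial tree ("close and parallel", with a
null zone on occupied voxels plus a security margin), veins grow in the
periphery, far from both. Airways receive N_f/FA terminals (FA ∈ {1,2,3}),
mimicking the earlier CT invisibility of small bronchi.

Realism post-processing: airway hollowing from per-generation wall
thickness ratios WT/D; a linear HU mapping of vessels and airway walls into
the 35–45 HU non-contrast window (segment mode) or per-case Normal(μ, σ)
compartment draws (anthropomorphic mode); a diffeomorphic cubic-B-spline
bending anchored so tree nodes stay fixed while segment midpoints move by
up to d_max voxels; parenchyma textured as Normal(−800, 150) HU, a Gaussian
reconstruction kernel (σ = 1.5 mm), additive Gaussian noise (σ = 20 HU) and
low-density salt-and-pepper noise.

Validation statistics mirror the phantom realism question: histograms of
in-lung HU, parenchyma-to-structure distances (dispersion), and
artery-to-airway distances (arterial–bronchial relationship) are compared
between case populations and phantoms with the histogram match distance
(L1 between CDFs, the 1-D earth mover's distance) and the
Kolmogorov–Smirnov distance, summarized by Wilcoxon rank-sum p, Cohen's d,
and AUC.

## Worked example

```python
from lungphantom import PhantomConfig, generate_segment_phantom

cfg = PhantomConfig(shape=(101, 101, 101), n_terminals=50, fa=3, master_seed=1)
phantom = generate_segment_phantom(cfg)
for name, tree in phantom.trees.items():
    root_seg = tree.children[tree.root_id][0]
    print(name, tree.n_terminals, round(tree.radius[root_seg], 2))
```

prints

```
artery 50 2.29
airway 17 2.05
vein 50 2.48
```

— 50 arterial and venous terminals as configured, 17 airway terminals
(⌈50/3⌉ from FA = 3), and root radii of ~2–2.5 mm produced by the
hemodynamic solve. `phantom.final` is the finished CT volume (HU window
spans −1000 to 100 in this run) and `phantom.labels` the reference standard
with codes 0 = background, 1 = artery, 2 = vein, 3 = airway.

The same pipeline is scriptable from the shell:

```bash
lungphantom segment-phantom --nf 50 --fa 3 --seed 1 --out out/seg01
lungphantom fixture --seed 0 --out out/case0
lungphantom anthro-phantom out/case0 --seed 7 --out out/anthro07
lungphantom batch --mode segment --plan-only --out out/batch   # 96-row manifest
```

The full study protocol — N_f ∈ {30,…,100}, FA ∈ {1,2,3}, four repetitions
(96 phantoms), and four phantoms per labeled lung — is in
`lungphantom.run_segment_batch` / `run_anthro_batch`.

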
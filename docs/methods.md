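# Methods

This note records the scientific and numerical choices behind
`lungphantom`, in the spirit of a model-description appendix: what is
simulated, which parameters matter, what the synthetic case generator does
and does not emulate, and where the design was genuinely open.

## Growth model

Tubular trees are binary trees of straight cylindrical segments grown by
demand-driven constrained constructive optimization.

**Sampling.** Terminal candidates are voxel centers drawn with probability
proportional to the oxygenation map. A candidate is rejected unless (i) its
demand is positive, (ii) its distance to the existing tree *surface* is at
least D_T = 1 mm, and (iii) a 26-connected path of strictly positive demand
connects it to the tree. Measuring admissibility from the tube surface
rather than the segment axis keeps new terminals from being swallowed
inside existing vessels, which matters once proximal radii exceed D_T.
After each accepted terminal, demand within 2·D_T of it is halved — a
cheap demand-satisfaction rule that spreads terminals without changing the
support of the map (the connectivity structure of the positive set is
computed once per growth).

**Attachment.** Among the k = 5 segments nearest the candidate, the
bifurcation point is searched *on* the target segment: a 19-point coarse
scan of the interior (t ∈ [0.05, 0.95]) followed by golden-section
refinement of the bracketing interval, minimizing the global material cost
Σ l^μ r^λ (μ = λ = 2) after a full hemodynamic re-solve. Ties break toward
the lowest segment id. Restricting the junction to the segment (rather
than jointly optimizing an off-segment junction position) keeps the search
space one-dimensional and matches how the optimum is independently checked
(exhaustive scan along the segment); the cost difference against a free
junction is small at the tree sizes used here.

**Hemodynamics.** Poiseuille resistance 8ηl/(πr⁴); equal terminal flows
Q/N_f; bifurcation law β_l^γ + β_r^γ = 1 with γ = 2.55; sibling pressure
drops equalized. The bottom-up reduced resistance

    R*_i = 8 η l_i / π + ( β_l⁴/R*_l + β_r⁴/R*_r )⁻¹,
    (β_l/β_r)⁴ = (Q_l R*_l)/(Q_r R*_r),

followed by r_root = (Q_root R*_root / ΔP)^{1/4} and top-down scaling
r_child = β r_parent makes every root-to-terminal pressure drop exactly
P_ini − P_fin in exact arithmetic; numerically the terminal pressures agree
to better than 10⁻⁶ relative. Units: pressures in mmHg, viscosity in
mPa·s, flow in cc/min (the physiological per-gram normalization of the
flow constant is treated as an opaque total scale), radii reported in mm
after SI conversion. With the default parameters a 50-terminal tree on a
101 mm segment develops a root radius near 2.3 mm and sub-voxel
(≈0.5–0.8 mm) terminal radii — thin peripheral vessels are therefore
represented mostly by partial-volume voxels, as in real CT.

## Oxygenation maps

Values are clipped to [0, 1] and normalized to a maximum of exactly 1; all
voxels occupied by previously generated structures, dilated by a security
margin (2 iterations of the 6-connected structuring element by default),
carry exactly zero demand.

*Segment mode.* The arterial map is 1 on a central core box spanning 1/3 of
each dimension and decays linearly with chessboard distance to 0 at the
volume faces (a continuous ramp; the number of gradient levels equals the
maximal chessboard distance). The venous map is its complement (peaks at
the periphery). The airway map is an artery-proximity band: full demand for
surface distance up to 2·r_max (r_max = 3 mm), linear decay to zero over a
further r_max_decay (default r_max), multiplied by the central-core prior.
The published description of this band is internally inconsistent (maximal
demand "at 2·r_max" yet decaying "until r_max"); the plateau-then-decay
reading preserves the close-and-parallel anatomy and is the one
implemented.

*Anthropomorphic mode.* The arterial map is the closed form
max(0, 1 − d_E/d_max) of the Euclidean distance to the real arterial
centerline (d_max = 10 mm), zero outside the lung. The airway map reuses
the segment-mode proximity construction around the *synthetic* arteries but
is zeroed outside the convex hull of the real bronchial segmentation —
no airway growth where no bronchus was observed; if the security margin
would annihilate the whole hull-constrained region (possible for small
hulls), the margin is relaxed stepwise toward zero before giving up. The
venous map places value 1 on the skeleton of the ridge of the
distance-from-structures field (voxels reaching ≥ 90% of a local maximum
filter over a ~5 mm window), decaying to a floor of ox_min = 0.001 at
d_max; the floor keeps all of the lung reachable. Convex hulls are
evaluated on voxel centers.

## Rasterization and overlap resolution

A segment is a capsule (cylinder plus hemispherical caps); a voxel's gray
value is the fraction of a supersampling lattice (3³ by default, 5³ in
oracle tests) inside the union of capsules, so gray ∈ [0, 1] encodes
partial volume exactly and the total gray of an isolated capsule matches
πr²l + 4/3 πr³ to a few percent at voxel-resolved radii. Contested voxels
go to the structure with the largest gray; exact ties fall to the fixed
priority artery > airway > vein. Each structure is then pruned to the
single 26-connected component containing the voxel nearest its perfusion
point, with removed fragments cleared from both mask and gray. Labels are
0/1/2/3 for background/artery/vein/airway; the airway label marks the full
(pre-hollowing) tube, while the airway gray channel carries the hollowed
walls.

## CT realism

**Hollowing.** Per segment of generation g (bifurcations counted from the
root), the lumen capsule of radius r − WT with WT = 2r·(WT/D)(g) is removed
by subtracting its supersampled occupancy, preserving fractional walls on
both boundaries. The default table uses WT/D = 0.20 for all generations
(equivalent to a luminal-diameter-to-wall ratio of 3); per-generation
tables are configuration.

**Intensities.** Segment mode maps positive gray affinely so the minimum
positive value lands at 35 HU and the maximum at 45 HU (degenerate
single-valued input maps to 45). Anthropomorphic mode draws each structure
voxel from its compartment's Normal(μ, σ); partial voxels are attenuated at
composition through the occupancy weights. Airway-wall statistics default
to 40 ± 3 HU (mid-window) rather than being measured from the case, since
thin walls cannot be sampled reliably.

**Deformation.** One cubic B-spline displacement field (control spacing
10 mm) is fit by ridge-regularized weighted least squares to scattered
anchors: zero displacement at every node of all three trees (weight 10)
and a random displacement (uniform direction, magnitude uniform in
[0, d_max·voxel]) at every segment midpoint (weight 1). Control-point
displacements are capped at 0.4 × control spacing — a sufficient condition
for diffeomorphism of cubic B-spline fields — and the whole field is
rescaled if any node anchor would move 0.4 voxel or more. Images are pulled
back through x ↦ x + u(x) (trilinear for gray, nearest for labels); tree
polylines move through the inverse map, computed by the fixed-point
iteration p ← p₀ − u(p). d_max = 0 short-circuits to a bitwise identity.

**Parenchyma and noise.** Background voxels (in-lung, zero occupancy) draw
i.i.d. Normal(−800, 150) HU — the printed magnitude 800 is implemented
with a negative sign, since aerated parenchyma is ≈ −800 HU. The composite
is the occupancy-weighted blend of structure HU over background, blurred
with a Gaussian reconstruction kernel (σ = 1.5 mm, converted to voxels per
axis); additive white noise (σ = 20 HU) and salt-and-pepper replacement
(density 0.001; pepper −1000, salt +100 HU) finish the image. The blur is
applied to the full composite: a reconstruction kernel acts globally, not
only on parenchyma. Outside the lung, anthropomorphic composites use the
host's body intensity estimated on a band 3–7 voxels beyond the lung (far
enough to escape the host's own kernel bleed), so the juxta-pleural shell
matches the case after embedding.

## Case adaptation

Features extracted from a labeled case: per-compartment intensity mean/SD,
terminal counts (skeleton voxels with exactly one 26-neighbor, on a 3D
thinning of each mask), root locations (the skeleton endpoint with the
largest maximal-inscribed-sphere radius, i.e. the Euclidean distance
transform maximized over the endpoint's 5-voxel skeleton neighborhood;
ties break lexicographically), the arterial centerline, and the bronchial
convex hull. Parenchymal statistics are computed on the lung interior
only — voxels within 3 mm of the pleura or of any structure are excluded —
because partial volume and the reconstruction kernel bleed structure and
chest-wall intensities into that guard zone and would otherwise bias the
parenchyma mean by tens of HU on small lungs; every phantom would inherit
the bias through its adapted intensity model.

Adaptation copies grid geometry, sets per-structure terminal counts from
the skeletons (an FA override caps airways at ⌈N_f(artery)/FA⌉), fills the
intensity model from the measured statistics (airway defaults kept), and
places each perfusion point at the demand argmax within a 10 mm ball of
the extracted root (falling back to the root when the ball holds no
demand). Airway and vein maps depend on previously grown structures, so
their perfusion points are resolved in pipeline order.

## The synthetic case generator

`make_fixture_case` fabricates the labeled "real case" bundles used in
tests: an ellipsoidal lung; an arterial tree built by recursive bisection
of well-separated leaf targets in the central core; a bronchial tree that
accompanies a proximal subset of the arterial targets at an ≈8.5 mm offset
(airways become CT-invisible before vessels, so the visible bronchial tree
reaches only 45–90% of the arterial extent); a venous tree in the
peripheral shell; and a CT assembled with the same composition model used
for phantoms. Seeded between-case jitter — compartment-mean shifts
(σ = 4 HU vessels, 30 HU parenchyma), lung size (±9%), terminal counts
(±2), root positions, bronchial offset and reach — is the generator's
model of inter-patient variability. The generator verifies its own ground
truth (one connected component per structure mask; skeleton endpoints equal
to the designed leaf count plus the root end, less at most one merged tip)
and deterministically redraws the geometry from (seed, attempt) until the
checks pass, so downstream consumers can rely on the designed terminal
counts to ±1.

What the fixtures do *not* emulate: real airway lumens and walls (fixture
airways are voxelized opaque), hilar anatomy and lobar subdivision, disease
phenotypes, scanner-specific noise spectra, and anisotropic clinical voxel
grids (tests use 1 mm isotropic 64³–96³ lattices). Tests passing on
fixtures therefore demonstrate the pipeline's internal consistency and
statistical calibration at reduced scale, not clinical realism on real
cohorts.

## Validation statistics

Histogram PDFs use 64 uniform bins — [−1024, 100] HU for intensities,
[0, 30] mm for distances — with out-of-range samples clipped into the edge
bins; no smoothing. The match distance is Σ|CDF_p − CDF_q|·Δ (the 1-D
earth mover's distance); the Kolmogorov–Smirnov distance is
max|CDF_p − CDF_q|. Population comparison reports the two-sided rank-sum
p-value (full enumeration over rank subsets when both samples have n ≤ 8,
midranks for ties; tie-corrected normal approximation otherwise), Cohen's
d oriented intra-minus-inter with pooled SD, and AUC = U/(n₁n₂) with ties
counted half. The self-consistency check compares four synthetic cases
(6 intra pairs) against three phantoms generated from the first case
(12 inter pairs) on 64³ grids and requires AUC ∈ [0.3, 0.7] for all three
measures under both metrics; at these sample sizes AUC is quantized in
steps of 1/72, which bounds how sharp the criterion can be.

## Problem sizes and determinism

Default test and demonstration sizes: 51³ growth grids, 64³–96³
anthropomorphic cases, one 101³ segment phantom for the noise-calibration
and reference measurements; these sizes make the full suite and the
reference script complete in minutes while keeping every voxel-level
contract exercised. A master seed derives independent per-stage seeds
through `numpy` seed sequences keyed by (master, stage), so any stage can
be reproduced in isolation and identical configurations yield bitwise
identical volumes.

## Known limitations

Terminal radii below half the voxel size rasterize to sparse
partial-volume trails whose skeletons can merge nearby tips, so
terminal-count round trips are only reliable when the designed terminal
spacing is resolved (the recovery test uses 96³ for this reason). The
attachment search is local (k nearest segments) and can miss globally
cheaper attachments in dense trees. Arterio-venous networks are open
(no capillary closure), branching is strictly binary, and supernumerary
vessels are out of scope.
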
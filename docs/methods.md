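# Methods

## Shape model

The resting discocyte is an axisymmetric solid of revolution with
Evans–Fung-style quartic half-thickness profile

    h(x) = ½ √(1 − x²) (C₀ + C₂ x² + C₄ x⁴),   x = r / R₀ ∈ [0, 1],

so the full thickness at radius r is 2 h(r/R₀) and the rim closes exactly
at r = R₀. Defaults (all config-overridable): C₀ = 0.81 μm,
C₂ = 7.83 μm, C₄ = −4.39 μm, R₀ = 3.91 μm. These reproduce the canonical
human RBC: diameter 7.82 μm, center thickness 0.81 μm, maximal thickness
2.566 μm at x ≈ 0.70, volume 94.09 fL, surface area 134.09 μm²,
sphericity 0.746. Volume and area are computed by adaptive quadrature of
the profile (trig substitution r = R sin θ regularizes the rim, where the
√(1−x²) factor has a vertical tangent); spheres use closed forms.

**Sphering morph.** A sphering index s ∈ [0, 1] blends the normalized
biconcave profile (weight 1−s) with the equal-volume-sphere profile
(weight s) on an interpolated support radius, followed by an isotropic
rescale so volume is conserved (rescale is exact; the volume-drift
tolerance along the morph is < 0.1%). s = 0 is the identity; s = 1 is the
equal-volume sphere. Along s, surface area decreases and sphericity
increases strictly — the blend is a phenomenological bridge between the
two observed endpoint shapes, not a membrane-mechanics model (no spectrin
elasticity, bending energy, or echinocyte spiculation).

## Synthetic tomograms

`rasterize_cell` samples a (rotated) shape onto a voxel grid with
supersampled partial-volume averaging: the voxel value is
medium_RI + (cell_RI − medium_RI) × (occupied subvoxel fraction),
supersample 3³ points per voxel by default. Voxel-sum volume of a 3 μm
sphere at 0.1 μm voxels agrees with the closed form to < 0.1%.

`simulate_field` emulates a dish of ~200×-diluted blood: cells settle
near one focal plane, nearly flat (tilt ~ |N(0, 5°)| about a random
in-plane axis, uniform spin), with i.i.d. per-cell draws of volume
(normal, clipped to [25, 195] fL), sphering index (normal, clipped to
[0, 1]) and cytoplasmic RI (normal). Non-overlap is enforced by rejection
sampling of lateral positions with bounding-sphere clearance 0.8 μm and a
hard cap of 10⁴ attempts per cell (failure raises, suggesting a larger
field). The field is sized automatically from the cell count with ~30%
lateral slack. Additive i.i.d. Gaussian RI noise completes the volume.
All randomness flows from one `numpy` Generator, so a (preset, seed) pair
is bit-reproducible.

Default imaging magnitudes, chosen as typical holotomography values:
medium RI 1.337, cell RI mean 1.40 (SD 0.005), noise SD 0.004 RI units,
voxel 0.1 μm isotropic. The instrument's true voxel spacing is sample
metadata and is therefore a *required* field when reading tomograms; only
the simulator defaults it.

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: the optical transfer function (missing
cone, anisotropic z-resolution, diffraction ringing), intracellular RI
texture, membrane flicker, echinocytes, touching or overlapping cells,
and time-dependent shape change after solution exposure (observations in
the emulated protocol happen within ~30 min; presets are time-static).

## Solution chemistry and shape response

`ideal_osmolarity` sums (g/L ÷ molar mass) × dissociation count × 1000
(NaCl ν = 2, M = 58.44; glucose ν = 1, M = 180.16; mannitol ν = 1,
M = 182.17), giving mOsm/L. Osmotic coefficients are deliberately ignored
(NaCl's is ≈ 0.93), so the ideal value runs slightly above osmometer
readings; presets accept measured-osmolality overrides. Cell volume
responds by the Boyle–van 't Hoff relation
V = V_iso (R_w · iso/osm + 1 − R_w) with osmotically active water
fraction R_w = 0.57 (Ponder's classic value) and isotonic anchor
294 mOsm/kg (the emulated subjects' mean serum osmolality; their mean
cell volume, 89.5 fL, anchors V_iso for solution-derived presets).

Shape response is an explicit empirical lookup, because the emulated
experiments report regions, not mechanism: plasma and AS → biconcave
(s ~ N(0.05, 0.03)); PBS and NaCl alone at any concentration → spherical
(s ~ N(0.97, 0.02)); NaCl 0.3–0.45% with glucose 2.63–3.92 g/dL →
biconcave; NaCl + mannitol inside a wider window → biconcave, with the
0.45–0.75% NaCl band flagged "hyper-flat" (s ~ N(0.02, 0.015), below the
plasma draw, since those cells are flatter than in plasma). All window
boundaries are inclusive and exposed in `BICONCAVE_REGIONS`. The mannitol
window's sugar bounds at high NaCl are not pinned by the emulated data;
2.5–3.5% was chosen to contain the reported biconcave observations and is
config-overridable. Whether PBS sphering is osmotic or membrane-chemical
is left open: the generator treats s and volume as independent knobs.

Named-medium presets carry the measured group volume distributions
(plasma 88.06 ± 8.43 fL, PBS 81.77 ± 8.51 fL, AS 89.27 ± 9.48 fL). No
numeric sphericity was reported for the plasma group, so the plasma
preset targets the canonical biconcave shape rather than a printed value.

## Segmentation

Foreground is `values ≥ threshold`. The default threshold is the midpoint
medium_RI + ½(cell_RI − medium_RI): under partial-volume imaging the
midpoint level makes voxel-counted volume unbiased. When the expected
cell RI is unknown, a two-class variance-maximizing (Otsu) threshold is
the fallback; the threshold in force is always logged. Connected
components (26-connectivity default, 6 available) are labeled in scan
order of their first voxel, filtered by a volume gate of [30, 180] fL
(brackets physiological RBC volumes; rejects noise specks and doublets)
and by border exclusion (on by default — a clipped cell has no valid
area). No watershed splitting: fields are sparse by design, and touching
cells fall to the volume gate.

## Morphometry

- **Volume**: voxel count × voxel volume. Mesh-enclosed volume
  (divergence theorem on the isosurface mesh) is available separately for
  sensitivity checks.
- **Surface area**: triangle-area sum of a marching-cubes isosurface of
  the cell's RI patch at the segmentation threshold, with subvoxel
  interpolation. Voxel-face counting is not offered: it overestimates a
  sphere's area by ~50% and cannot meet a 2% contract. The patch is
  padded with medium so surfaces close; super-threshold voxels that are
  not part of the cell (stray noise, neighbours) are clamped to medium
  before meshing. Cells under 8 voxels are rejected. Sphere benchmark at
  0.1 μm voxels: area within 0.6% of 4πr².
- **Sphericity**: Ψ = π^(1/3)(6V)^(2/3)/A. Values > 1 are impossible for
  true shapes (isoperimetric inequality) but can arise from mesh bias;
  they are returned unclipped with a warning.
- **Axes**: the cell mask is projected along the optical axis (cells lie
  flat in the dish, so the projection is the en-face outline); axis
  diameters are 4√λ for the eigenvalues λ of the projection's second
  central moment matrix (the ellipse with identical normalized second
  moments; for a filled disk of radius r this returns exactly 2r). The
  pixel self-covariance term (voxel²/12) is added before the eigenvalue
  step. 3D principal-axis lengths are available as auxiliaries.
- **Aspect ratio** is short/long, so it lies in (0, 1] as the reporting
  convention requires; the inverse wording ("long to short") conflicts
  with that range and was resolved in favour of the range.

## Statistics

Group reporting is mean ± sample SD (n−1). One-way ANOVA is computed from
between/within sums of squares; the post-hoc procedure is
Bonferroni-adjusted pairwise *pooled* (Student's) t-tests with
m = C(k, 2) comparisons (all pairs; Welch's test is available behind a
flag). Tail probabilities for t and F come from the regularized
incomplete beta function rather than lookup tables and are cross-checked
against scipy's independent implementations in the test suite. The
pooled-vs-per-pair variance choice for the post-hoc tests was open;
pooled per pair was chosen and is logged. Star annotation uses strict
inequalities: `*` p < 0.05, `**` p < 0.01, `***` p < 0.001.

## Pipeline determinism

`run_experiment` derives per-condition, per-stage seeds as
CRC32(root_seed:condition:stage) masked to 31 bits, so conditions are
independent streams: adding or removing a condition never changes
another's output. Every parameter, seed, threshold and output-file
checksum lands in `run_manifest.json`. A stage failure aborts only its
condition; the others proceed and the failure is recorded.

## Problem sizes and numerical tolerances

Quadratures target 1e-9 relative error. Default test/demo problem sizes —
fields of 5–40 cells at 0.1–0.12 μm voxels, supersample 2–3 — were chosen
so the full validation suite exercises every estimator end-to-end on a
workstation in about two minutes; estimator accuracy at these settings
(volume within 2%, area within 2% on the sphere benchmark) is what the
tests assert, and finer grids only improve it. The type-I-error
calibration of the t-test uses 10,000 simulated null replicates at
n = 40 per group.

## Known limitations

- No optical forward model: segmentation operates on ideal partial-volume
  tomograms; real reconstructions have anisotropic resolution and
  artifacts that will degrade area estimates first.
- The shape-response table interpolates nothing between regimes: a
  solution is biconcave, spherical, or hyper-flat; intermediate sphering
  appears only through the within-regime spread of s.
- The en-face axis fit assumes settled cells; strongly tilted discs would
  foreshorten the projection (tilt is capped at small angles in the
  generator for this reason).
- Mesh-based area carries a small positive bias (~0.5% on a 0.1 μm-voxel
  sphere) that does not vanish with refinement at fixed supersampling;
  it is well inside the 2% estimator contract.
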
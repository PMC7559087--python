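# Methods

`ocdvc` implements subvolume digital volume correlation (DVC) for in situ
micro-CT mechanics of osteochondral tissue–biomaterial systems: a reference
scan and one or more loaded scans are correlated on a grid of cubic
subvolumes, the displacement field is rigid-body corrected and
differentiated to a strain field, measurement error is quantified on a
repeat (zero-strain) scan pair, and implant micromotion is summarised per
system component. Because no suitable scan pair is openly available at this
scale, the package ships a synthetic phantom generator with exact analytic
ground truth; every claim the test suite makes is a claim about recovery of
that ground truth.

## Correlation model

Each measurement point is a cubic subvolume (edge `N` voxels) of the
reference volume. Its displacement is the offset that maximises the
zero-normalised cross-correlation (ZNCC) with the deformed volume:

    ZNCC(u) = Σ (f − f̄)(g_u − ḡ_u) / (‖f − f̄‖ ‖g_u − ḡ_u‖)

with `f` the reference subvolume and `g_u` the deformed content at trial
offset `u`. Three schemes are provided:

- **DC** — exhaustive integer ZNCC search in a radius around a predictor
  (default 4 voxels), then per-axis 3-point subpixel refinement. When the
  integer peak lands on the border of the search window the search is
  re-centred there and repeated (up to 8 times): a median-smoothed predictor
  can be biased by neighbours across a displacement discontinuity, and
  walking to the peak is both cheaper and more robust than enlarging the
  radius everywhere.
- **FFT** — cyclic cross-correlation of zero-mean windows via the frequency
  domain; the integer peak is wrap-limited to half the window and the
  reported correlation is rescaled to the true (non-cyclic) ZNCC of the best
  offset. Cyclic correlation is exact for feature-rich texture and small
  shifts, but for smooth texture the wrapped window edges can displace the
  peak — the reason the combined scheme below is the workhorse.
- **FFT+DC** — `n_passes` (default 3) multi-pass scheme: the first passes run
  FFT correlation on windows enlarged by a pre-shift margin (default
  12 voxels per side, giving the coarse passes extra capture range), each
  result is median-filtered (3³, component-wise) and used as the integer
  predictor of the next pass; the final pass is DC at the target subvolume
  size with a small residual radius (default 2 voxels — after the pre-shift
  the integer residual is at most a voxel or so).

Subpixel refinement fits, per axis, a Gaussian through the log of the
3-point correlation profile, `δ = (ln c₋ − ln c₊)/(2 ln c₋ − 4 ln c₀ +
2 ln c₊)`; non-positive profile values fall back to the parabola vertex
`δ = (c₋ − c₊)/(2(c₋ − 2c₀ + c₊))` and are flagged. Both estimators share
the convention that the offset moves toward the larger neighbour. A profile
plateau returns the boundary value ±0.5, flagged. When the integer peak
correlation is within 1e−7 of 1 the match is exact and refinement is
skipped — the 3-point fit is undefined there and would otherwise convert
perfect integer matches into spurious subvoxel offsets.

Degenerate inputs degrade gracefully: subvolumes whose intensity standard
deviation is below 1e−6 of the volume's dynamic range (true voids) are
flagged invalid rather than raising, and the correlation coefficient of each
point lets downstream consumers mask unreliable regions (the reporting
default masks below 0.8).

Units: grids and search offsets live in voxels (storage order z, y, x);
every reported displacement is physical micrometres with component order
(x, y, z), and grid-point positions are voxel centres, `(index + 0.5) ×
voxel size`. Only isotropic voxels are supported.

## Rigid-body correction and strain

Scan-to-scan rigid movement is fitted by orthogonal Procrustes (Kabsch) over
valid points and subtracted at the reference positions, so pure rigid fields
cancel to numerical precision. In the zero-strain study the correction is
always applied, as in the experimental workflow. In the loaded study it is
**off by default**: the synthetic rig has no mounting drift, and subtracting
a fitted rigid transform from a genuinely compressed field removes part of
the physical translation — strains are unaffected (rigid fields carry no
strain) but displacement magnitudes, and with them the norm-based
micromotion normalisation, are not.

Strain is the infinitesimal tensor ε = (H + Hᵀ)/2, with the displacement
gradient H estimated per grid point by a linear least-squares fit over a
window³ neighbourhood (default 3³ = 27 points, valid points only; points
whose neighbourhood design matrix has rank < 4 are flagged). The estimate is
exact for affine fields regardless of window size. At the applied strains
(≈2.5%) the difference from Green–Lagrange strain is second order. Shear
components use the tensor convention (ε_xy), not engineering shear (γ).

Where a component mask is available, strain windows are restricted to grid
points of the same component (centre-voxel label). This is the single-volume
analogue of correlating separately extracted component stacks: a mixed
window charges the displacement noise of a texture-poor void — or the
genuine displacement discontinuity at the implant–void interface — to the
neighbouring tissue's strain. For the per-component summaries the windows
are further restricted to subvolumes at least 90% inside the component
(when at least 8 such points exist), since straddling subvolumes measure a
mixture of both sides' motion.

## Zero-strain error analysis

Two consecutive scans of the unloaded specimen differ only by noise; any
strain measured between them is error. Per component:

- **MAER** (accuracy) — mean over points of the mean absolute value of the
  six strain components;
- **SDER** (precision) — population standard deviation of the per-point mean
  absolute strain about MAER (the definition is implemented with the square
  root, as its name requires);
- displacement precision — per-component standard deviation of the
  displacement vector components.

The study sweeps subvolume sizes (default 16–80 voxels in increments of 16)
for a chosen method, fits `error = a · size^b` by least squares in log
space (R² also in log space, where the model is linear), and selects the
smallest size whose MAER **and** SDER fall below the acceptable error — 10%
of the nominal applied strain, i.e. 0.25% strain (2500 µε) at the 2.5%
nominal of this system. Error units are reported simultaneously as strain
fraction, percent and microstrain.

## Micromotion reporting

Sampling mirrors collecting a few well-correlated subvolumes per component
on a handful of transverse slices: 5 evenly spaced grid levels, 3
seeded-random points per component per level, correlation ≥ 0.8, preferring
subvolumes ≥90% inside the component (the reproducible analogue of manual
within-component selection). Per component the report gives mean ± SD of
total displacement and of minimum principal strain (smallest eigenvalue of
the strain tensor). Relative micromotion is the per-slice absolute
difference of mean total displacement between implant and bone, averaged
over slices where both are sampled — normalising against bone by
subtraction, so any global rigid translation cancels; division by the
near-zero bone motion would be ill-posed.

## Synthetic phantom

The generator builds a 1.9 × 1.6 × 1.6 mm (192 × 160 × 160 voxels at 10 µm)
specimen: a subchondral bone region with trabecular-like two-phase texture
(thresholded band-pass noise, 90 µm grain), an articular cartilage band
(top 35% of the height) with low-amplitude 60 µm speckle, a cylindrical
defect (radius 0.25 × width — a 5 mm punch in a ~10 mm sample) containing a
0/90° log-pile implant lattice (200 µm struts at 200 µm spacing, with 10 µm
in-strut material speckle), a new-tissue cap, and a poorly textured void
under and around the implant. The whole volume is blurred with a 10 µm
(1 voxel) Gaussian emulating the scanner point spread — real
reconstructions never have single-voxel interfaces, and unblurred binary
texture causes integer peak-locking that no real system exhibits in this
form. Repeat scans add independent Gaussian noise with SD 1% of the dynamic
range.

Deformations are analytic, applied by pull-back resampling
(`out(x) = ref(x − u(x))`, cubic spline), so the ground-truth displacement
and strain are exact at every voxel: translations, small rigid rotations,
uniaxial platen compression (fixed bottom face, Poisson ratio 0.3), and the
micromotion scenario — far-field compression with the implant + new-tissue
cap frozen as a rigid body at its centroid's far-field motion plus a 40 µm
offset, blended over a 15 µm Gaussian band across the surrounding void.
Freezing the implant reproduces the mechanically meaningful case: an
implant riding over an underlying void moves largely rigidly and carries
little internal strain.

The default study: load1 = 1% nominal compression; load2 = 2.5% nominal
compression + 40 µm implant micromotion. All randomness derives from one
seed via `numpy.random.SeedSequence`.

What the phantom does **not** emulate: ring, beam-hardening or
phase-contrast artefacts; anatomical trabecular architecture; staining
gradients in cartilage; scanner drift. Passing tests therefore demonstrate
correctness of the measurement chain on realistic texture and noise, not
performance on every pathology of real scans.

## Numerical and design choices

- The DC inner loop is an authored ZNCC search (sliding-window BLAS
  numerator, box-sum variances); `skimage.feature.match_template` computes
  the same quantity and serves as the independent oracle in the tests, but
  is several times slower at these window sizes.
- Peak ties are broken by smallest Euclidean offset, then lexicographically.
- The loaded analysis uses an interior volume of interest (grid inset:
  8 voxels below the moving platen, 4 voxels laterally). Material adjacent
  to the platen leaves the imaged domain under load, and subvolumes at any
  face have one-sided search ranges; both corrupt near-face measurements.
- Problem sizes were chosen for a desk-scale study: 192 × 160² phantom
  voxels, sweep sizes 16–80, loaded analysis at a 32-voxel subvolume. At
  10 µm voxels the voxel-unit sweep matches the experimental protocol's
  range while physical sizes are roughly 2× the original's (4.5 µm voxels);
  the µm conversions in all outputs follow the voxel size strictly.
- Components that cannot support a strain neighbourhood at a given
  subvolume size (e.g. the thin new-tissue cap at 64–80 voxel subvolumes)
  are omitted from that sweep entry with a warning rather than padded.

## Known limitations

- Cyclic FFT correlation (standalone) mislocates integer peaks by a voxel
  or two on smooth, coarse-grained texture when the shift is a noticeable
  fraction of the window; the FFT+DC scheme is immune because the final DC
  pass re-searches with full normalisation. This mirrors the empirical
  superiority of the combined scheme on real data.
- The 3-point subpixel estimators carry interpolation bias (largest near
  half-voxel offsets, sharp texture); expect ~0.01–0.05 voxel systematic
  error there.
- Strain in strongly periodic structures (the printed lattice) is degraded
  by residual peak-locking even after PSF blur.
- Grid points whose subvolume straddles a genuine displacement
  discontinuity (implant/void) measure a weighted mixture of both sides;
  they are excluded from component summaries by the 90%-inside rule but do
  appear in the raw field.
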
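# Methods

## Imaging model and index conventions

Volumes are indexed `(x, y, z)` with `z` the optical axis; voxel `(i, j, k)`
sits at physical position `(i·sx, j·sy, k·sz)` μm.  The default voxel size,
`(0.358, 0.358, 0.5)` μm, corresponds to a 1024-px confocal frame covering a
366.6 μm field of view recorded in 0.5 μm axial steps; TIFF metadata
overrides it when present.  Intensities are kept in their stored dtype on
disk and promoted to float64 for all computation.

## Partial volume correlation

**Stage 1 — lateral.**  Slices at equal heights are compared on a grid of
`window` = 32×32 px sub-windows stepped by `step_xy` = 16 px (half-window
overlap; finer stepping buys nothing once the field is smoothed at the
sub-volume scale).  The correlation at integer lag `(dx, dy)` is the
Pearson coefficient of the two windows restricted to their overlap.  This
normalization makes the surface exactly 1 at the true lag for a rigid
integer shift of identical content, is invariant to affine intensity
changes of either window, and — unlike full-window normalization with
zero padding — carries no triangular envelope, so the sub-pixel estimate
is unbiased at large lags.  Lags are bounded by `search_xy` = ±8 px:
cell-induced matrix displacements are ≲ 2 μm (≈ 6 px laterally), and an
open-ended search only adds opportunities for spurious peaks.  Sub-pixel
refinement is a per-axis 3-point Gaussian (log-parabola) interpolation,
falling back to a plain parabola when a neighbor sample is non-positive;
peaks on the search border are flagged invalid.

Two validation passes follow standard PIV practice: windows whose
intensity standard deviation is below 1% of the slice-wide value (empty
pores) are rejected, and the normalized median test (residual against the
median of the 8 grid neighbors, normalized by the neighbors' median
residual plus a 0.1 px noise floor, threshold 2) removes vectors that
locked onto a spurious peak.

**Stage 2 — axial.**  Each lattice node owns a sub-volume V₁ of
32×32×`subvolume_depth` (20) px.  Its lateral displacement is estimated
from the *ensemble average* of the stage-1 correlation surfaces over the
sub-volume's slice range — the correlation-plane counterpart of averaging
the 2D vector field over V₁.  When a large axial displacement
decorrelates individual slice pairs, single-slice vectors become noisy
and occasionally wrong, while the ensemble surface accumulates the true
peak coherently; averaging the surfaces rather than the vectors is the
standard remedy for low signal-to-noise interrogation in μPIV and costs
nothing here because the surfaces exist anyway.  V₂ is then extracted at
the laterally offset position (rounded to whole pixels; the sub-voxel
remainder only rescales the correlation by ≈ 1−ρ″·0.5² and does not move
the axial peak) and scanned over Δz ∈ [−12, 12] px, chosen to bracket the
largest axial displacements seen in practice (6 μm).  The normalized
volume correlation C(Δz) is evaluated per offset; out-of-bounds offsets
are masked.  D_z is the centre of a Gaussian fitted by nonlinear least
squares to the 5 samples around the peak (fitting the raw C values
tolerates near-zero samples; log-space would not), with a 3-point
parabola as fallback and ties in the integer argmax broken toward the
smaller |Δz| — a small-deformation prior.  The axial lattice step
defaults to 10 px, half the sub-volume depth (its Nyquist spacing).

**Field validation.**  The assembled lattice passes the same normalized
median test in 3D (26 neighbors).  Flagged nodes keep their values but
are masked; all accuracy statistics and downstream mechanics use valid
nodes only.

**Smoothing.**  `smooth_field` implements penalized least squares on the
lattice diagonalized by the DCT-II (discrete spline smoothing), with the
parameter chosen by generalized cross-validation on a log-spaced grid
(10⁻⁹…10⁹, ties toward the smallest value so noise-free fields pass
through unchanged).  Invalid nodes enter with zero weight and are imputed;
the robust mode re-weights residuals with a bisquare function three
times so isolated spikes are replaced by the local trend.  Smoothing is
*off* by default for simulator validation (the benchmarks grade the raw
algorithm) and recommended *on* for experimental stacks.

**DVC baseline.**  `dvc_field` searches all integer 3D lags within
(±8, ±8, ±12) via FFT-accelerated normalized correlation
(`skimage.feature.match_template`, verified in the tests against direct
evaluation of the correlation definition), with per-axis 3-point
refinement.  It is the slow, single-stage oracle used for
cross-validation; PVC and DVC agree to < 0.5 px RMS per component on
speckle pairs with |u| ≤ 4 px.

## Virtual specimens

The generator emulates the statistics a correlation algorithm actually
sees in confocal reflection images of collagen: a Poisson cloud of point
scatterers (default density 100,000 per 256³ px ≈ 0.006 px⁻³) rendered as
isotropic 3D Gaussians ("width" read as σ = 2 px; an FWHM reading would
halve the speckle size) with unit amplitudes, summed into the volume with
support truncated at 4σ.  Deformations move the scatterer centres and the
volume is re-rendered, so the pair is exactly consistent with the
prescribed field.  The standard benchmark field is a uniform
z-compression plus x-shear, both linear in z about the mid-plane with a
4 px peak — inside the ±12 px scan range and below the large-strain
failure regime.  Matrix remodeling is emulated by overwriting 110 random
8³ px cubes (≈ 4–5% of the volume) with the upper-2% (densified) or
lower-2% (degraded) intensity quantile, in the *translated* stack only,
mimicking turnover between the two imaging time points.  Rigid-shift
fixtures use integer translation with zero fill and no wrap-around
(wrap-around would fabricate correlated content at the boundary);
statistics are taken on interior nodes.

What the simulator does **not** reproduce: fiber-shaped (elongated,
oriented) structures, the polarization-dependent loss of vertical fibers
in reflection confocal, the axially elongated reflection PSF, detector
noise and bleaching.  Passing the synthetic benchmarks therefore
demonstrates the correctness and precision of the estimation chain on
speckle with known truth, not the full error budget of a microscope.
Notably, the real instrument's elongated axial PSF *helps* the lateral
stage (slices decorrelate more slowly with axial motion), so the
isotropic-PSF benchmark is conservative in that respect.

## Known accuracy limits of the two-stage design

Because stage 1 compares slices *at the same height*, an axial
displacement u_z decorrelates the pair by ρ ≈ exp(−u_z²/4σ²): at
u_z = 3.4 px and σ = 2 px only ≈ half the speckle is common, and with
~40 scatterers per window the lateral estimate carries 0.1–0.25 px RMS
noise with a tail to ≈ 0.8 px.  Mean absolute errors on the full-scale
benchmark are ≈ 0.09 px laterally and ≈ 0.03 px axially (2.3% / 0.7% of
the 4 px peak), but the *maximum* per-node deviation is governed by that
tail and lands near 15–25% of the peak, concentrated where |u_z| is
large.  The same data contain the information — the DVC baseline reaches
≈ 0.05 px everywhere — so this is a structural property of the two-stage
split, not of the implementation; recovering it within PVC would require
feeding the axial estimate back into the lateral stage (an iterative
variant deliberately out of scope).  Large strains (≳ 15%) and 3D
rotations are likewise outside the method's validity; `cauchy_stress`
warns when strain magnitudes exceed 5%.

## Surfaces, distances and mechanics

The cell mask comes from thresholding the fluorescence channel (Otsu by
default; the largest connected component is kept and holes filled).  The
surface is a marching-cubes triangulation at level 0.5 of the mask after
a σ = 0.8 voxel Gaussian anti-aliasing step — on a digital sphere of
radius 10 voxels this brings the mesh area from +8.5% (staircase) to
within ≈ 1.6% of the analytic value; structures too thin to survive the
smoothing fall back to the binary surface.  Faces are oriented outward
(positive signed volume).  Membrane distances use an exact Euclidean
distance transform of the mask's boundary voxels with anisotropic
physical sampling; the returned nearest point is a boundary voxel centre,
so directions derived from it wobble by up to half a voxel — negligible
for 10 μm distance bins, visible in the tangential residual of perfectly
radial test fields.

Strain uses central differences (second-order one-sided at lattice
boundaries) on displacement components converted to μm, with physical
lattice spacing in the denominators; nodes whose stencil touches an
invalid node are themselves invalid.  The constitutive step is linear
isotropic elasticity, σ = 2Gε + λ tr(ε) I with λ = 2Gν/(1−2ν)
(G = 50 Pa, ν = 0.2 by default — typical for 2 mg/mL collagen), applied
only as a small-strain approximation and always flagged as such in the
outputs.  Tensors are interpolated trilinearly to face centres;
per-face traction is T = σ·n with normal part T_n = T·n (pulling < 0).
Contractility sums A·(T·R̂_cm) over faces with R̂_cm pointing from the
face centre toward the mesh's volume centroid, so a uniformly inward
(pulling) traction on a sphere gives C = p·4πr² > 0 — the discrete sum
matches this closed form to < 2% at radius ≥ 10 voxels.  Units:
1 Pa·μm² = 10⁻¹² N, so contractility in nN is the Pa·μm² sum × 10⁻³.

The normal/tangential decomposition reports the signed normal component
(positive toward the cell) alongside |D| and |D_t|; distance profiles
export both the signed mean of Dn and the mean of |Dn| per 10 μm bin,
since either convention appears in practice.

## Problem sizes and determinism

The full-scale benchmark (two rendered 256³ stacks, 15×15×24 lattice)
runs in ~1–2 minutes on one CPU; the unit suite uses 96×96×48 volumes at
the same scatterer density, which preserves the speckle statistics while
keeping each pipeline run under a second.  All stochastic fixtures
(scatterer positions, remodeling cube placement) derive from explicit
`numpy.random.default_rng` seeds, and identical seeds give bit-identical
stacks, lattices and masks end to end.
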
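# Methods

This note documents the models, estimators and numerical choices behind
the toolkit, and what the synthetic benchmarks do and do not establish
about real data.

## Elastic model

The substrate is treated as a linearly elastic, isotropic half-space
with Young's modulus E (default 9000 Pa) and Poisson ratio ν (default
0.5, incompressible silicone). The in-plane surface displacement
response to in-plane surface traction is the Boussinesq solution, which
in Fourier space is the per-mode 2×2 kernel G(k) implemented in
`tfm.traction.boussinesq_kernel`. The substrate thickness (default
70 μm) is carried in the configuration for provenance but no
finite-thickness correction is applied: the half-space kernel is
accurate when the analysed cell is small compared to the substrate
thickness, which holds for single cells on gels this thick. Analysing
cell colonies comparable in size to the gel thickness with this kernel
would overestimate compliance.

**Forward model.** `forward_displacement` zero-pads the traction grid to
at least twice its linear size (`pad_factor=2`), multiplies by G(k) per
mode and inverse-transforms. Padding suppresses the interaction of
periodic images that the FFT otherwise implies; the k = 0 mode is set to
zero, so displacements are reported relative to their spatial mean.

**Inversion (FTTC).** `fttc_invert` applies
f(k) = [GᵀG + λ²I]⁻¹ Gᵀ u(k) per mode with the same padding. The
Tikhonov parameter λ carries the units of G (m/Pa) and defaults to 0
(direct inverse); noisy experimental fields benefit from a small
positive value, exposed on the CLI as `--lambda`. The k = 0 mode is
zeroed and the cropped output field is re-centered so the reported
tractions carry zero net force — the physical force-free condition for
a cell in mechanical equilibrium; zeroing the padded grid's mean alone
would leave the balancing residual in the discarded pad region. Modes
at the Nyquist frequency are evaluated at the signed frequency of the
transform ordering (`fftfreq`). On periodic band-limited inputs the
forward/inverse pair is exact to machine precision with `pad_factor=1`;
on compact fields the contracting-disk round trip at 2 μm spacing shows
~0.02% RMS error inside the disk.

## Displacement estimation

**Drift.** Stage drift between the relaxed and stressed frames is
estimated by full-frame mean-subtracted FFT cross-correlation with the
same three-point subpixel fit used by the PIV, and removed by Fourier
phase-ramp resampling. The search is limited to ±64 px.

**PIV.** The relaxed (post-removal) frame is the reference, so the
displacement field describes the stressed state's deformation and
aligns with the traction that caused it. Window and overlap are stated
physically (defaults 20 μm / 18 μm) and rounded to integer pixels
(43 px windows, 4 px ≈ 1.84 μm grid step at 0.46 μm/px). Each
reference window is matched against the deformed frame by
zero-normalized cross-correlation (ZNCC): the correlation numerator is
computed by batched FFTs, the per-lag local means and variances with
integral images. The per-lag normalization matters — normalizing by a
single global variance leaves the triangular overlap envelope in the
map, which drags the fitted peak toward zero lag by roughly
σ_peak²/(W−|lag|) pixels (≈10% amplitude underestimation at the
sub-pixel displacements typical here). The lag search spans ±¼ window;
windows whose search region would cross the frame border are dropped
rather than padded.

**Subpixel peak.** Three-point Gaussian (log-parabola) fit per axis,
falling back to a plain parabola when a sample is non-positive. After
the initial fit, each axis triplet is re-taken through the refined apex
by quadratic interpolation over the 3×3 neighborhood; sampling the
transverse triplet at the integer column otherwise leaks up to ~0.1 px
of cross-axis error for non-separable peaks. On constructed rigid
shifts the estimator is accurate to <0.04 px; peaks on the map border
return the integer lag with a flag.

**Validation.** Vectors are rejected when the peak-to-second-peak ratio
falls below 1.3 or when they fail a normalized local-median test
(deviation from the neighborhood median vector exceeding three times
the neighborhood's median residual plus a 0.1 px floor; the floor keeps
noise-free uniform fields untouched). Rejected vectors are replaced by
the median of valid 8-neighbors, iterating until the grid is complete —
FTTC needs a full grid — but they keep `valid=False` so consumers can
audit the filling.

**Window-response compensation.** Windowed correlation reports
(approximately) the top-hat average of the true displacement over the
window, attenuating spatial frequency k by W(k) = sinc(k_x w/2)
sinc(k_y w/2). The attenuation was verified against the empirically
measured response on single-mode synthetic scenes before adoption.
Because strain energy is quadratic in the field, the uncompensated
chain underestimates it by 10–40% on cell-sized features at the 20 μm
window. `compensate_window_response` applies the Wiener-style gain
H = W/(W² + α) on the padded FFT: resolvable frequencies are restored
by ≈1/W while frequencies beyond the window cutoff, which carry only
estimator noise, are rolled off. The default α = 0.05 caps the gain at
~2.2; α = 0 disables the step. The pipeline applies it between
validation and inversion.

## Per-cell metrics

Masks live at image resolution: `cell_boundary` (the drawn cell
outline) and `traction_area` (the region whose tractions are attributed
to the cell). When only a labeled cell raster is available,
`CellMask.from_labels` derives the traction area by dilating the cell
footprint by a Euclidean-distance margin (default 15 μm) so stresses
smeared outward by the finite PIV window are still credited to the
cell. Masks are rasterized onto the analysis grid by node-center
membership. All internal computation is SI; the reporting layer
converts to μm², pJ, nN, J/m² and N/m².

- **Strain energy** U = ½ Σ (u·t_x + v·t_y) ΔA over the traction area.
  Restricting to the mask keeps background PIV noise from inflating U.
- **Force epicenter**: the point minimizing the sum of squared
  single-node torques Σ[(x_i−x_c) f_{y,i} − (y_i−y_c) f_{x,i}]²,
  solved from the 2×2 normal equations. When the normal matrix is
  rank-deficient (all forces parallel — e.g. an ideal force dipole) the
  smaller eigenvalue vanishes relative to the larger; the |f|-weighted
  centroid is returned with a degeneracy flag. The eigenvalue-ratio
  test (1e−9) is used rather than the determinant, which is scale-free
  only in the well-conditioned case.
- **Contractility** C = Σ f⃗_i·ê_i with ê_i the unit vector from node i
  toward the epicenter; nodes at the epicenter contribute zero. C is
  bounded by Σ|f⃗_i| with equality only for perfectly convergent
  fields, and vanishes for purely circulating fields.

## Substrate characterization (AFM)

Approach force curves are fit with the Hertz–Sneddon spherical-indenter
law. Convention: the `position` series increases as the probe
approaches and indents, so indentation is δ = position − contact_point;
for raw piezo-height curves the cantilever deflection (force/spring
constant) is subtracted from δ, while curves already expressed against
tip–sample separation skip the correction — the reader distinguishes
the two dialects via header metadata. Contact is initialized at the
first crossing of baseline mean + 3 SD sustained for three samples
(baseline statistics from the first 64 samples), then E, the contact
point and a constant force baseline are jointly refined by bounded
nonlinear least squares over the whole curve; pre-contact points
constrain the baseline, post-contact points (at least 8 required) the
power law. E is initialized from the closed-form estimate at the
deepest point. Defaults: probe radius 10 μm, ν = 0.5, 5 nN setpoint.
Noiseless simulated curves recover E to <0.1%; with 1%-of-setpoint
Gaussian noise the median error over 200 replicates stays below 2%.

## Synthetic scenes

The generator emulates single-cell experiments at the imaging scale of
the pipeline defaults: 512×512 px at 0.46 μm/px (≈235 μm field), bead
diameters Normal(1.11, 0.05) μm drawn as Gaussian spots (σ = d/2.355
combined in quadrature with a 0.3 μm PSF), 16-bit-like intensities with
Gaussian read noise, and subpixel stage drift. Bead density defaults to
6 per 100 μm² (~24 per PIV window), following the standard PIV seeding
guideline of well over ten particles per interrogation window. Bead
count is Poisson in the density; positions are i.i.d. uniform; the
whole module is deterministic given the seed.

Traction templates (contracting disk, annulus, force dipole, inward
multipole) are force-balanced by construction and have closed-form
contractility. Disk and annulus edges are rasterized area-weighted (4×4
supersampling per cell) so the discretized integrals match the closed
forms to ≪1%. Ground-truth displacements come from the forward model on
the same grid; bead motion interpolates that grid bilinearly. The
reference ensemble (`reference_scene_set`) spans contractilities of
~70–1070 nN with footprints of ~1500–4000 μm², the envelope reported
for breast epithelial lines on ~9 kPa substrates; peak stresses fall in
the hundreds of Pa, consistent with that literature.

**What the benchmarks show — and don't.** End-to-end recovery within
15% (typically 5–12%) on these scenes validates the estimator chain:
drift correction, PIV response, the elastic inversion and the metric
definitions, under realistic bead statistics, shot-to-shot seeding
variability and camera noise. The scenes do not model photobleaching,
out-of-plane motion, bead aggregation, refractive-index artifacts,
non-elastic substrate behavior, or segmentation error in hand-drawn
masks — on real data those terms add systematic uncertainty that no
synthetic benchmark here bounds.

## Problem sizes and runtime

Default scenes are 512×512 px (≈13k PIV windows, ~8 s per scene on one
CPU); the ten-scene recovery study runs in ~2 minutes. Forward/inverse
FTTC grids are 117×117 at 2 μm spacing, seconds to evaluate. Hertz
curves use 1024 samples. These sizes were chosen so the full validation
cycle runs comfortably on a laptop while keeping every estimate in the
asymptotic regime of its estimator.

## Known limitations

- Single-pass PIV only: strong displacement gradients within one window
  (features much smaller than 20 μm) remain under-resolved even with
  window compensation; multi-pass window deformation is out of scope.
- The Wiener α is a fixed default, not noise-adaptive; extremely noisy
  fields may prefer a larger α or λ > 0 in the inversion.
- The epicenter/contractility pair assumes an essentially convergent
  force pattern; for multipolar patterns with no dominant center the
  contractility underreports coordinated force generation.
- Tractions outside the drawn traction area are discarded, so a
  too-tight mask biases contractility and energy low.
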
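# Methods

## The model

A resolution voxel of a turbid sample contains N sub-resolution
scatterers with amplitudes a_n and round-trip axial phases
φ_n = 2·k·z_n (k the centre wavenumber, z the optical depth). The
single-frame pixel value is the coherent magnitude

R_m = | Σ_n a_n · exp(i(φ_n + θ_{n,m})) |,

and the displayed value after M acquisitions is the linear-scale average
I = (1/M) Σ_m R_m — magnitudes, not intensities, are averaged, and images
are only converted to dB for display. In conventional acquisition the
local phases θ are frozen, so every frame carries the same speckle. In
speckle-modulated acquisition a ground-glass diffuser in a conjugate image
plane contributes

θ(x, y) = g · k · Δn · d(x_d + x, y_d + y) ⊛ PSF_4f,

where d is the surface height map, Δn ≈ 0.5 the glass/air index contrast,
(x_d, y_d) the (moving) diffuser offset, PSF_4f the Gaussian smoothing PSF
of the 4f relay that images the diffuser onto the sample, and g = 2 by
default because the beam traverses the glass on the way in and out
(`round_trip=False` exposes the single-pass convention). For phases
spread far beyond 2π with spatial decorrelation inside one voxel, each
frame is an independent fully developed speckle realisation: the
single-frame amplitude is Rayleigh (contrast √(4/π − 1) ≈ 0.5227) and
compounding M frames reduces the speckle contrast by exactly 1/√M.

Two front-ends produce images from the same physics:

1. the **direct phasor model** (`smoct.forward`), in which each pixel is
   the Gaussian-PSF-weighted coherent sum over scatterers (lateral FWHM =
   the main objective's resolution; axial FWHM = the coherence gate), and
2. the **spectral-domain chain** (`smoct.recon`): per A-scan,
   S(k) = source(k)·|E_r + Σ a_n exp(i(2kz_n + β(k−k₀)²))|² on a uniform
   2048-sample k grid, reconstructed by background subtraction, a
   2048-point Hann window, multiplication by exp(−i·β̂(k−k₀)²) and a DFT.
   Because the simulated k axis is uniform, the "phase matrix" is an exact
   DFT; spectrometer λ→k resampling is out of scope.

A consistency test asserts that both front-ends produce the same fully
developed speckle contrast (within 5% at the densities used).

## Statistics

**Normalized s.d.** C = population (1/n) s.d. / mean of linear-scale
magnitudes over a homogeneous region (population convention so closed-form
toy cases are exact). C mixes speckle with genuine sample variability, so
the **normalized speckle** isolates the decaying part by a variance
decomposition:

s(M) = √(max(C(M)² − C_base², 0)) / √(C(1)² − C_base²),

where C_base is the intrinsic (speckle-free) component. In simulations
with constant per-voxel N and equal amplitudes, C_base = 0 exactly and is
passed as such; on data the default estimate is C at the largest available
M. The decay exponent is fitted by least squares on log s vs log M and
should be −0.5 for independent frames. The **independence horizon** is
the largest M such that |s(M′)·√M′ − 1| ≤ 5% for all M′ ≤ M.

In the fully averaged limit a voxel converges to a·√(Nπ)/2 (the Rayleigh
mean), so with N ~ Poisson(λ) the pixel distribution approaches a mapped
Poisson law. `distribution_analysis` fits either the Rayleigh model
(ML scale, KS distance) or this limit law, with (λ, a) moment-matched from
the sample mean and CV; the crossover of the two goodness-of-fit distances
as M grows is the statistical signature that averaging has removed speckle
and exposed the scatterer statistics. Histogram-narrowing is reported as
IQR vs M. All distribution statistics are computed on linear-scale values.

## Synthetic phantoms

- **Homogeneous field**: per-voxel counts ~ Poisson(mean); positions
  uniform within each voxel (half-open cells, 0-based, z into the sample).
  Defaults mirror the nanoparticle phantom densities of 12 (spheres) and
  33.6 (rods) per voxel; the per-voxel means are taken as given rather
  than re-derived from a voxel volume. An optional lognormal amplitude
  model (unit mean, configurable CV) represents particle-size variability;
  the default is constant amplitude.
- **Wedge gap**: two filled blocks separated along y by a scatterer-free
  gap whose full width grows linearly from zero, w(x) = x·tan(angle);
  the per-column ground-truth width is recorded.
- **Beads**: each 3 µm bead is one dominant point scatterer (amplitude =
  ratio × mean background amplitude) because the bead diameter is at or
  below the simulated PSF; centres are ground truth.

What the generators do **not** emulate: material optics (absorption
spectra, index mixing), multiple scattering, polarisation, sample motion,
aggregation. Passing tests therefore demonstrate the speckle/compounding
physics and the analysis chain, not instrument- or tissue-specific effects.

## Diffuser model and the independence study

Surfaces are stationary Gaussian random fields with Gaussian
autocorrelation R(δ) = rms²·exp(−δ²/ℓ²) (spectral synthesis: filter white
noise with a Gaussian kernel of s.d. ℓ/2, periodic boundaries, rescale to
the requested RMS). Presets follow the qualitative grit ordering
(1500-grit roughest, 3 µm-lapped finest); the "effective" preset is sized
so the total thickness span exceeds λ/Δn = 1.8 µm at 900 nm, the condition
for a full 2π single-pass phase span. The smoothed phase is sampled at a
scatterer's exact lateral position by bilinear interpolation: nearest-cell
lookup would pin nearby scatterers to identical phases, freezing their
pairwise interference across frames and injecting a spurious variance
floor into the 1/√M law that a continuous surface does not have. Power
loss by deflection is representable as a scalar per-preset transmission
(default 1); angular scattering itself is not modelled — the model is a
scalar phase mask plus 4f relay, not a wave-optics propagation.

The frame-independence study uses 2×10⁴ voxels (8 µm square, one
resolution element each) of 50 equal-amplitude scatterers, a surface with
rms 2.0 µm and correlation length 1.2 µm on a 0.5 µm grid, a 0.8 µm FWHM
relay PSF, and offsets advanced by 3 correlation lengths per frame. These
conditions put the smoothed phase (s.d. ≈ 12 rad, decorrelating over
~1.4 µm) well inside the voxel, the regime speckle modulation requires;
they compensate for the scalar model's lack of the angular-deflection
decorrelation a physical ground glass also provides. Because the relay PSF
must stay below the main PSF, the acquired voxel is deliberately larger
than the diffuser's phase grain — the resolution cost that buys speckle
removal. Motion schedules convert the translation (0.3 mm/s between
B-scans) and rotation (~9 mm/s rim speed vs ~20 kHz A-scan rate →
0.45 µm per A-scan) geometries into offset sequences; moving faster than
one phase change per integration time attenuates the fringe amplitude by
the mean resultant length of K+1 uniform phasors (`washout_factor`,
evaluated by a fixed-seed Monte Carlo; → √(π/4)/√(K+1) for large K).

## Reconstruction choices

- Dispersion estimation minimises Σ| |R_low| − |R_high| | over β, where
  R_low/R_high are magnitude reconstructions from Hann-windowed lower and
  upper halves of the 2048 samples; pixels below 5% of the sub-band
  maximum are ignored and the lowest four depth bins are excluded from the
  signal-presence check (residual DC). Minimisation is bounded scalar
  search with tolerance 10⁻³ of the bracket width. Meaningful quadratic
  coefficients at this k scale are tens of rad·(rad/µm)⁻² (tens of radians
  at the band edge, i.e. many-pixel blur); the defaults and studies use
  that range.
- Frame exclusion computes the Pearson correlation of each linear-magnitude
  frame to the all-frame mean and drops frames below a user threshold
  (manual in practice; explicit parameter here). Excluding every frame is
  an error advising a lower threshold.
- The dB display is 20·log₁₀(mean + ε) with ε = 10⁻¹² of the image
  maximum, making display output deterministic and finite.
- Shot noise is additive complex circular Gaussian on the pre-magnitude
  field per frame (s.d. = `additive_floor` per quadrature), giving Rician
  single-frame statistics for a bright reflector.

## Resolution and attenuation metrics

**Minimum detectable gap.** Effective resolution is the narrowest gap a
segmentation procedure reliably finds: per column, threshold at
α×(column median) (α = 0.5), clean the below-threshold mask by a
morphological opening with a 1-pixel-radius disk, and take the longest
dark run overlapping the expected gap locus. Two guards are our
construction (the underlying procedure is not uniquely defined anywhere):
the run must be the *dominant* dark feature of its column (strictly longer
than any non-overlapping run — a gap indistinguishable from a dark speckle
grain is not a detection), and the measured width must agree with the
ground truth within max(2 px, 50%). A column is detectable when it
succeeds in ≥80% of replicate seeds; the minimum detectable gap is the
smallest width in the contiguous detectable range extending to the widest
gap. In simulation, modalities share ground-truth coordinates by
construction, so no registration step exists. The en face gap study uses
a 400×120 µm field at 2 µm pixels, 12 scatterers per voxel, a 4.3° wedge
(gap 0→30 µm), M = 100 modulated frames vs a conventional image (with
noise disabled, averaging identical conventional frames is a no-op, so a
single frame is formed); five phantom seeds per comparison.

**Attenuation fits.** Depth profiles (laterally averaged linear
magnitudes) are fitted to A·exp(−2µz)·[1 + ((z−z_f)/z_R)²]^(−1/2) by
nonlinear least squares; the 95% CI of µ comes from the fit covariance.
The simulation study uses µ = 0.002 µm⁻¹ over 300 µm, 50 lateral columns,
30 dB additive SNR, with the confocal geometry (z_f = 150 µm,
z_R = 100 µm) pinned to its known values — compared between the
single-frame (speckled) and M = 100 modulated profiles. The multiple-
scattering term sometimes added to such fits is omitted (the simulator is
single-scattering); an optional roll-off term is likewise out of scope for
the synthetic spectrometer.

**Line pairs.** Visual scoring of bar targets is replaced by an automated
criterion: the smallest line-pair spacing whose steady-state Michelson
contrast after PSF blur exceeds 0.1.

## Determinism and problem sizes

Every stochastic operation takes an explicit seed; pipeline recipes derive
per-operation seeds from the master seed by SHA-256 of a stable operation
tag, so outputs are byte-identical across reruns and adding recipes never
shifts existing seeds. Study sizes (10⁴–2×10⁴ voxels, 100 frames,
10⁵ pixels for distribution tests, 5 seeds for the gap comparison) were
chosen so that Monte-Carlo error sits comfortably below each assertion
tolerance while a full run of the suite stays in the minutes range.

## Known limitations

- Scalar phase-screen diffuser: no angular deflection, no wave-optics
  propagation between diffuser and sample, no vectorial fields.
- Single scattering only; no polarisation, Doppler/angiography interplay,
  or sample motion (frames are co-registered by construction).
- The spectral simulator uses a uniform k axis and no spectrometer
  roll-off; the confocal factor enters only the attenuation fit, not image
  formation.
- The paper-style per-voxel densities are taken as given; the absolute
  voxel volume is not modelled.
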
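# Methods

## Measurement model

An acquisition scheme is an ordered list of excitation lines, each with 1–4
contiguous detector emission bands; flattening the (excitation, band) pairs
gives the measurement axis of length M.  The bundled default scheme has 11
excitation lines (one per fluorophore plus a dedicated autofluorescence
line) and 26 detectors spanning emissions from ~415 to 810 nm, with 25 nm
bands starting 10 nm red of each line.

Each pixel's measured M-vector is modeled as a non-negative linear
superposition of reference spectra:

    b = R x + noise,   x ≥ 0

R is M×C with one column per fluorophore plus ≥1 autofluorescence (AF)
column.  Columns are normalized to unit maximum, so unmixed coefficients
stay on the raw image's intensity scale.  Whether to normalize per spectrum
or per detector row was an open choice; per-spectrum maximum was chosen for
that reason (coefficients are then directly comparable to raw counts).

## Reference spectra

A reference spectrum is extracted from a 1-plex (or unlabeled AF) stack as
the mean spectrum of the brightest pixels — by default the top 0.1% ranked
by intensity summed over the measurement axis, an anatomy-free,
reproducible proxy for "region of maximum expression"; an explicit mask
overrides it.  Extraction is invariant to positive rescaling of the input.

The AF channel is placed from an excitation–emission matrix (EEM) scan: the
chosen excitation maximizes total emission summed red of the line plus a
10 nm guard offset (ties to the shortest wavelength, for determinism), and
the four AF detector bands are an equal-width contiguous partition of the
remaining red-shifted emission range.  The guard offset and the equal-width
banding rule are package conventions; nothing in the physics forces either,
and both are parameters.  Note that for emitters whose emission rises close
to the excitation line, the guarded row-sum argmax can sit slightly blue of
the excitation-profile peak — the contract is the argmax, not the peak.

A conditioning report (condition number, pairwise column cosine
similarities, minimum pairwise angle, warning below a 5° default threshold)
guards against near-parallel reference columns before unmixing; it warns
and never mutates.  The bundled 11-column fixture matrix has condition
number ≈6 and minimum pairwise angle ≈38°.

## Unmixing

Per pixel, `min ‖Rx − b‖₂ s.t. x ≥ 0` is solved with an active-set NNLS
solver (exact at these sizes: C ≤ ~12, M ≤ ~26; exactness was preferred
over speed).  The per-pixel Euclidean residual norm is stored alongside a
relative residual (residual/‖b‖, defined 0 at b = 0) for QC.  Negative raw
intensities (detector offset artifacts) are clamped to zero with a warning
before solving.  No Poisson-variance weighting and no background
pre-subtraction are applied — the plain Euclidean objective is the
documented contract.  Chunked evaluation only batches pixels; it is
bit-identical to a per-pixel loop.  Samples whose tissues differ in
intrinsic fluorescence can carry extra AF columns (one reference spectrum
per AF channel, auto-named AF2, AF3, …).

## Simulator

Fluorophores are parametric stand-ins with Gaussian excitation and emission
profiles.  Real dye spectra are asymmetric; Gaussians were chosen for
analytic band integrals and controllable overlap.  The response entry for
line e and band [a, b] is

    brightness × exp(−(e−ex_peak)²/2σ_ex²) × ∫_a^b N(em_peak, σ_em)

The ten default fluorophores have excitation peaks at 405–775 nm and
emission peaks at 430–800 nm with σ of ~18–30 nm, giving the heavy spectral
overlap that makes the unmixing problem non-trivial.  AF is a broad-band
emitter (σ ≈ 80 nm) with a smooth low-frequency spatial field (a few random
cosine modes spanning 0.3–1× the AF amplitude).

Scenes compose per-channel abundance fields from geometric domains (boxes,
ellipsoids, stripes), explicit arrays, and Gaussian point sources (the PSF
is applied analytically to point sources only; domain fields are piecewise
smooth already).  Noise: expected intensities are scaled by a photon
budget, Poisson sampled, rescaled, and Gaussian read noise is added, with a
floor at zero; disabling noise reproduces the linear model exactly.  All
randomness flows from one scene seed with per-stage sub-streams.

Scene factories mirror the validation experiments: `make_multiplex_scene`
(ten overlapping blob expression fields over AF),
`make_redundant_detection_scene` (two channels sharing one abundance field
scaled by per-channel gains — the simulator analog of detecting one target
with two probe sets/amplifiers), and `make_single_molecule_scene`
(uniformly sampled dot positions with a minimum-separation constraint,
written identically into both channels of a redundant pair).

Default problem sizes used in tests and in `scripts/acceptance.py`
(64×64×3 multiplex frames, 88×88×2 voxel-statistics frames, 64×64×8
single-molecule stacks, 25 dots, 3 replicates) keep full runs in the
seconds-to-minutes range on one CPU while leaving hundreds of voxels or
dots per statistic.

What the simulator does **not** emulate: asymmetric/tabulated dye spectra,
optical sectioning and defocus, bleaching, chromatic aberration, detector
crosstalk beyond band integration, or spatially structured (non-smooth)
autofluorescence.  Passing tests therefore demonstrate the correctness of
the computational pipeline under the stated forward model, not performance
on any particular real sample type.

## Quantitation

**Signal-to-background** = (mean over a high-expression mask − mean over a
low-expression mask)/(low mean).  Measuring "background" where expression
is merely low over-counts background, so the estimate is a lower bound on
true S/B; the acceptance checks verify both monotonicity in amplification
gain and this lower-bound property.  A zero background mean is an error
(the caller should include a read-noise floor).  Mean (not median) pixel
statistics are used and documented.

**Voxel binning**: pixels per voxel per axis = round(voxel/pixel), min 1 —
e.g. 2.0 µm voxels over 0.18 µm pixels → 11 pixels, the ratio not being
exactly integer.  Aggregation is the **sum** of raw unmixed intensities
(a voxel's amplified signal models molecule count; summing preserves
linearity in content); trailing partial blocks are dropped.

**Normalization** divides a channel's voxel values by its 99.9th-percentile
value — robust to single hot voxels, scale-invariant, no clipping.

**Scatter statistics** report the product-moment Pearson r, the
through-origin slope Σab/Σa², and a free-intercept OLS fit so "zero
intercept" accuracy is itself checkable.

**Display scaling** maps [0, clip] linearly to 8 bits, with the clip level
the (1 − saturation_fraction) quantile pooled across replicates (default
0.1% saturated; fraction 0 clips at the pooled maximum so nothing
saturates, the single-molecule convention).  The 255 bin is reserved for
clipped pixels, so the saturated-pixel count is exactly the count at or
above the clip level rather than an artifact of 8-bit rounding.

## Dot detection and colocalization

Detection is scale-normalized Laplacian-of-Gaussian over an explicit list
of physical scales (µm): per scale, response = σ²·(−LoG) with per-axis
sigma in pixels σ/pixel_size(axis) — anisotropy enters through the pixel
sizes; sigmas under one pixel are clamped with a warning.  Dots are local
maxima over space+scale above a threshold; maxima closer than a minimum
separation are resolved by keeping the stronger response.  Everything is
deterministic.  LoG was chosen over DoG/wavelet variants as the standard,
parameter-light detector; scales and thresholds are configuration (defaults
calibrated on the bundled synthetic fixture: scales 0.35/0.5/0.7 µm,
threshold 0.03 per unit dot amplitude 10).

Colocalization matches two dot lists one-to-one greedily by ascending
distance within a radius (ties by channel-A then channel-B index; default
radius 2× the mean detection scale).  Greedy equals the optimal assignment
whenever inter-dot spacing exceeds twice the radius — i.e. at
single-molecule densities — and is deterministic.  Replicate summaries
report mean ± s.e.m. (sample SD/√n; n = 1 yields 0 with a warning).

## Workflow, I/O, determinism

Stacks are OME-TIFF (axes ZCYX, physical sizes in µm in the metadata,
channel names as OME channel annotations); reference spectra, voxel tables
and dot lists are CSV in physical µm with the origin at the corner of pixel
(0,0,0).  The YAML run config is validated strictly (unknown keys are
errors).  The workflow executes reference extraction → matrix build +
conditioning report → unmixing → optional S/B, voxel-statistics and dot
stages, and writes a JSON run report (versions, seed, parameters,
warnings).  All randomness flows from the config's master seed; rerunning
an identical config reproduces every CSV byte-for-byte and every array
exactly.

## Known limitations

- Coefficients are floating point; integer-TIFF export is not a first-class
  path.
- The dot detector does no sub-pixel (Gaussian-fit) refinement; positions
  are pixel centers, accurate to ~half a pixel.
- One global AF field per scene; spatially abrupt AF transitions are only
  representable through extra AF channels, not within one field.
- S/B depends on the caller's masks; the automatic quantile-based masks in
  the workflow are a convenience, not a substitute for anatomical masks.
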
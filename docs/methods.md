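# Methods

This note documents the physical model, the synthetic-data design, the
numerical choices, and the known limitations of `eatomo`. Nothing here
states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Physical model

**Electrostatics.** The electrode pair is treated quasi-statically: the
potential obeys the continuity equation ∇·(σ∇φ) = 0 on a uniform 2-D
grid with Dirichlet values on the rasterised electrode footprints and
φ = 0 on the outer boundary (a grounded bath). The grounded boundary
also provides the return path for the two-positive-electrode (2p)
wiring, whose circuit closure is otherwise undefined in a bounded
domain. Domains should be at least ~10× the electrode gap so the
boundary perturbs the near-electrode field at only the percent level;
the solver does not enforce this.

**Deposition and initial pressure.** Per pulse, H = σ|E|²·τ_eff with
τ_eff the integral of the normalised squared drive waveform — for a
trapezoidal pulse of FWHM w and linear edges of duration r, τ_eff =
w − r/3 (≈95 ns for the default 100 ns / 15 ns pulse). The conversion to
pressure uses the Grüneisen-like factor β/(κρC_v). A single heat
capacity per medium is used everywhere; at the level of this model the
distinction between C_v and C_p (≲1% for water-like media) is far below
other uncertainties, and any electrical-absorption efficiency factor is
folded into the same coefficient. Conductivity is static: the gradual
conductivity rise during electroporation pulse trains saturates at high
pulse counts, so a constant σ is the operating regime modelled here.

**Acoustic forward model.** Source maps are thin 2-D slices observed by
an in-plane ring, so propagation uses the 3-D free-space Green's
function (spherical spreading, 1/d) restricted to the plane. Source
pixels are binned into detector time samples by arrival time with
linear two-sample splitting; `oversample=k` bins at k× the output rate
and decimates with a zero-phase FIR filter, which flattens the binning
kernel's in-band roll-off (the single-rate triangular kernel loses ~7%
at 6 MHz of a 40 MHz record). The physically emitted pulse is the time
derivative of the printed retarded-potential integral; both forms are
available, with `derivative` the default. The derivative is taken with
a central-difference stencil at the output rate and is therefore
band-shaped by sin(ωΔt)/(ωΔt); comparisons against closed-form
references must apply the same stencil.

**Directivity.** Detectors are ideal points by default. An optional
`element_width` models the finite element aperture as a Gaussian beam
profile with the half-power width of a flat piston at 5 MHz. The
Gaussian (soft-apodized) profile is used instead of the piston's sinc
because the sinc's sign-flipping sidelobes are an artefact of the
ideal-piston idealisation and produce non-physical ripple in
aperture-sweep experiments. Directivity is what creates the ring
array's centre-gain behaviour — an off-centre source falls outside the
acceptance cone of most elements, so its reconstructed intensity drops;
with ideal point detectors the full-ring back-projection is essentially
position-independent and no such trend exists. The centre-gain
experiment therefore runs with `element_width=1.5e-3` (comparable to
the ~2.5 mm pitch of 128 elements on a 50 mm ring).

**Noise.** Thermal noise is additive white Gaussian, scaled to a target
peak-signal-over-noise-std SNR (20·log₁₀ convention throughout) and
seeded for bit reproducibility. In the voltage-ramp video the noise
floor is fixed in absolute terms relative to a reference-voltage
acquisition, so low-voltage frames genuinely disappear into it.

## Signal processing

The trace chain follows the standard radiofrequency-ultrasound recipe:
zero-phase Butterworth filters (order 8 low-pass; order 5 band-pass
2–6 MHz for the 5 MHz transducer response, ≥40 dB an octave out of
band), Hilbert-envelope detection, and discrete-wavelet denoising with
coif-3, per-level MAD noise estimates and the universal threshold
σ̂√(2 ln N).

Two choices deserve justification:

* **Hard thresholding with cycle spinning** (8 circular shifts) is the
  default shrinkage. Soft thresholding biases every retained coefficient
  by the threshold, which costs ~4–5 dB of output SNR on sparse
  pulse-like signals; hard thresholding plus translation averaging
  removes the pseudo-Gibbs artefacts of a decimated transform and is the
  classic remedy. Soft mode remains available via
  `DenoiseSpec(mode="soft")`.
* **Arrival picking.** The envelope of a bipolar N-wave is *bimodal* —
  it peaks at the compression and rarefaction edges, ±a/v_s around the
  geometric arrival — so an envelope-argmax picker flips between the
  two lobes and corrupts distance sweeps. The distance-sweep driver
  uses the leading-edge half-maximum crossing instead: its offset is
  constant across distances and lands entirely in the regression
  intercept, leaving the slope (the sound speed) unbiased. Both pickers
  are exposed in `estimate_tof`.

Frame averaging is non-overlapping (3000 raw frames at 1 ms → 300
frames at 10 ms); a non-divisible trailing remainder is truncated with
a warning. Averaged frames mix their whole block, so per-frame metadata
(drive voltage, programmed source position) is reported as the block
mean.

## Reconstruction

UBP filters each trace into b(t) = 2p(t) − 2t·dp/dt (central
differences, one-sided at the ends, absolute time including the
acquisition offset t₀) and back-projects over circular shells with
uniform per-element weights; linear interpolation samples b at each
pixel's flight time. An envelope option back-projects the Hilbert
envelope of b for non-negative display images. DAS simply delays and
sums (envelope-detected) traces — it shares no filtering with UBP and
serves as the independent cross-check.

Because the ring-in-plane geometry feeds a 3-D back-projection formula
with 2-D data, the raw UBP image of a smooth source carries a
half-order filter mismatch plus amplified out-of-band binning noise
from the discrete forward model; applying the chain's own 6 MHz
low-pass to the traces before reconstruction removes the latter. The
reconstruction is quantitative up to a global scale only; normalisation
(`max1`) is explicit and recorded in the image provenance.

## Synthetic data: what it emulates, what it does not

The generators produce: anti-aliased disc and Gaussian sources,
electrode-pair deposition patterns from the actual field solver
(1p1g and 2p wiring), ideal and smooth N-shaped reference waveforms
with 2–6 MHz content, seeded white noise at configurable SNR, and frame
sequences with linearly ramping amplitude or a moving compact source
(the 3-s, 1-kHz, 100→1000 V ramp of the imaging experiments). The
moving-source video translates a tip-sized 0.25 mm spot at the
electrode-pair's peak deposition amplitude; grid snapping keeps the
programmed trajectory exact.

Not emulated: heterogeneous sound speed and acoustic attenuation
(reconstruction deliberately uses the same uniform v_s as the forward
model), elevational (out-of-plane) spreading, transducer impulse-response
ringing beyond the band-pass magnitude, electrode ring-down artefacts,
muscle-fibre conductivity anisotropy, and dynamic conductivity during a
pulse train. Passing tests therefore demonstrate correctness of the
algorithms under the stated model, not performance on bench data; the
instrument-dependent figures (absolute SNR, sensitivity floor, maximum
depth, resolution) are covered qualitatively only.

## Numerical choices

* **Field solver:** 5-point finite differences, harmonic-mean face
  conductivities, Jacobi-preconditioned conjugate gradients, relative
  residual 1e-8 (non-convergence raises with the attained residual).
  Point-like electrodes occupy a single lattice node whose effective
  electrostatic radius is h·e^(−γ)/(2√2) ≈ 0.19853 h, from the constant
  term of the 2-D lattice Green's function — this is what makes a
  sub-1% comparison against the two-line-charge closed form possible at
  ordinary grid resolutions. Rasterised discs only a few pixels across
  have an effective radius well below their nominal one; resolve a disc
  with ≥10 pixels across before interpreting absolute amplitudes.
* **Grids:** 0-based indexing, pixel centres at (i+0.5)·Δx, origin at
  the ring/domain centre. Even-sized grids have no on-axis pixel; tests
  that need an exact centre use odd sizes.
* **Desk-scale defaults:** 64 elements, 500 raw video frames, 120–200
  pixel grids at 0.25 mm, chosen so each experiment completes in seconds
  while keeping ≥4 samples per acoustic wavelength at band edge; the
  `profile="full"` flag restores 128 elements and 3000 frames.
* **Oracles:** the closed-form uniform-disc (chord-arc) waveform has
  integrable inverse-square-root singularities in its derivative; it is
  not square-integrable raw, so comparisons are made inside the 6 MHz
  detection band with the reference built at 16× oversampling and FIR
  decimation.
* **Ties and degenerate inputs:** image peak location is the first
  argmax in row-major order; all-zero images are exempt from `max1`
  normalisation; zero traces yield a "no arrival" (None) pick; an
  all-zero clean record rejects finite-SNR noise addition as undefined.

## Containers

Channel data and frame stacks are HDF5 (`/traces` or `/frames` float32,
`/geometry` group, acquisition attributes); images are 32-bit float
TIFF with a JSON sidecar for pixel size and provenance; tables are CSV;
configurations are YAML. Every CLI run writes a manifest (command,
config snapshot, seed, version, timestamps) sufficient to reproduce its
outputs. An import hook for externally deposited waveform archives is
an explicit `NotImplementedError` stub: their internal layout is not
standardised, and guessing it would corrupt silently.

## Known limitations

* The forward model's 2-D/3-D hybrid geometry makes absolute pressure
  amplitudes at the detector approximate; all downstream claims are
  about ratios, positions, and shapes.
* UBP with uniform aperture weights is not an exact inverse for this
  geometry; round-trip fidelity is quantified (normalised
  cross-correlation), not assumed.
* The Gaussian directivity model matches a piston's main lobe only; it
  underestimates far-sidelobe leakage.
* The CG solver is single-level; very large grids (≫500²) would benefit
  from a multigrid preconditioner.
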
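# Methods

`osteoflow` implements, on fully synthetic channel data, a pipeline for
measuring the direction and velocity of blood flow inside tibial cortical
bone with ultrafast plane-wave ultrasound, alongside a conventional-Doppler
branch that emulates the simultaneous femoral-artery reference recording.
This note describes the models, the estimators, the numerical choices, and
what the synthetic experiments do and do not demonstrate.

## Coordinate and sign conventions

`x` is the long-bone axis in mm, positive toward the heart (proximal); `z`
is depth, 0 at the probe face, increasing toward the marrow. Axial velocity
(flow in central, Haversian-type canals) is positive toward the heart;
radial velocity (flow in perforating, Volkmann-type canals) is positive
toward the marrow, so centrifugal flow (endosteum to periosteum) is
negative. Times are microseconds, frequencies MHz, speeds accepted in m/s.

## Layered-medium acoustics

The scanned region is a stack of three horizontal layers: cutaneous tissue
(default 1570 m/s), cortical bone, and marrow (1480 m/s). The compressional
speed in the cortex is more than twice the soft-tissue speed, so refraction
at the periosteal and endosteal interfaces dominates image formation.
Cortical anisotropy uses a three-parameter even, pi-periodic model

    c(gamma) = c0 (1 + a2 cos 2*gamma + a4 cos 4*gamma),

with `gamma` the propagation angle from the bone axis and defaults
c0 = 3300 m/s, a2 = 0.06, a4 = 0.01. These are design defaults, kept
configurable; the group/phase velocity distinction is ignored (weak
anisotropy), and segment speeds are evaluated at the straight-segment
direction.

Receive delays are Fermat-minimal travel times over the interface crossing
points (golden-section refinement after a coarse scan; marrow pixels use
warm-started coordinate descent over the two crossings). Because the layer
stack is laterally invariant, one travel-time-vs-offset profile per depth
row suffices; tables for any element/pixel combination are cubic
interpolations of those profiles (verified against the scalar solver to
1e-14 s). Transmit delays follow the refracted plane wavefront via
horizontal-slowness conservation, referenced to the trailing edge of the
aperture so all table entries are non-negative. Steering angles beyond the
critical angle mark pixels invalid instead of aborting.

## Synthetic data generator

The generator is first-class, tested code. It emulates the statistical
structure the analysis relies on, not a calibrated tissue model:

* **Static speckle** -- Poisson-count, uniformly placed point scatterers
  with Gaussian reflectivities in tissue (1.2 /mm^2), cortex (2.0 /mm^2)
  and marrow (0.8 /mm^2); single scattering (Born), no shear conversion.
* **Probe drift** -- a rigid raised-cosine ramp displacing every scatterer,
  default 0.4 mm over the 4 s recording (peak velocity 0.157 mm/s),
  non-pulsatile by construction.
* **Cortical blood** -- scatterers (3 /mm^2 in canal regions, reflectivity
  0.25 of the bone matrix) moving along two orthogonal canal networks with
  a raised-cosine pulsatile waveform (default 60 bpm, systolic fraction
  0.3): bone-axis movers with peak -10 mm/s (baseline -0.5) and
  transcortical movers with peak -2 mm/s (baseline -0.1). Movers wrap
  periodically inside their canal region, keeping counts stationary for the
  clutter filter.
* **Canal geometry** -- real canals are far below the ~1.5 mm resolution
  cell; a validation phantom must nevertheless make the two motion
  populations identifiable, or no estimator could be scored against the
  generator's truth. The default phantom therefore concentrates the radial
  network in one 6 mm transcortical band (axial movers fill the rest;
  axial:radial count ratio 0.7, consistent with central canals
  outnumbering perforating ones). Passing tests demonstrate recovery of
  two resolvable populations, *not* sub-resolution canal separation.
* **Artery scene** -- a soft-tissue tube with Poiseuille flow along x:
  scatterers drawn uniformly over the 3D cross-section (so the mean speed
  is half the centerline speed), centerline waveform peaking at 500 mm/s.

RF traces are sums of Gaussian-windowed sinusoids (fractional bandwidth
0.6) at the forward-model round-trip times, plus white noise at a default
30 dB below the frame RMS. The forward travel times use a 4x finer offset
search than the beamformer's tables and all wave speeds perturbed by +0.5%
(inverse-crime mitigation: simulation and reconstruction never share exact
numerics). Scatterers are frozen within a compound frame for the bone
protocol; the artery ensembles move per transmit, since intra-ensemble
motion is the Doppler signal there.

## Beamforming and transverse oscillations

Delay-and-sum on the analytic (Hilbert-transformed) traces with linear
sub-sample interpolation; Hanning receive apodization over a +-30 deg
acceptance cone; coherent compounding of the 15 steered transmits per
frame. The measured -6 dB lateral PSF width of the default configuration
is 1.47 mm. The default grid is 0.5 mm laterally and 0.125 mm in depth:
the finer z-pitch resolves the axial analytic carrier so it can be
spectrally filtered.

The transverse-oscillation (TO) pair is built after beamforming by
multiplying the lateral spatial spectrum with conjugate Gaussian passbands
at +-1/lambda_0x (lambda_0x = 3.5 mm, sigma_f = 1/(4 lambda_0x)). Two
refinements proved necessary:

1. **Axial narrowbanding.** The broadband beamformed pulse has a spatially
   varying axial phase slope; phases aggregated across pixels then
   underestimate depth motion by 2x or more. An axial Gaussian passband
   (sigma 0.25 /mm) centred on the cortex carrier *measured from the delay
   tables* (the apodization-weighted z-gradient of the round-trip delay
   times f0; about 1.54 cycles/mm, i.e. lambda_z = 1.30 mm in bone)
   enforces one clean carrier. The same gradient map supplies the
   per-layer lambda_z used to convert phase to velocity -- using the
   tissue speed inside the cortex would bias radial velocities by ~2x.
2. **A second, wider conjugate pair for the radial route.** The nominal
   passband smears laterally over ~2 mm (sigma_x = 1/(2 pi sigma_f)),
   which buries the weak transcortical signal under the dominant axial-canal
   signal. The radial ROI series therefore uses mirror bands at
   0.35 +- 0.2 /mm (sigma_x ~ 0.8 mm); the conjugate symmetry that cancels
   lateral phase in the half-sum is preserved.

## Clutter filtering

The Casorati matrix (pixels x frames) of each filtered sequence is
decomposed by SVD; the `k` strongest components are the clutter. The
synthetic scene's clutter (static speckle plus smooth drift) has rank 3-5,
measured on a blood-free phantom -- far below in vivo recordings, whose
hand-held and physiological motion supports thresholds an order of
magnitude larger at the same frame count. Defaults are chosen relative to
the measured rank: k = 12 for the power-Doppler/axial routes and k = 18
for the radial route, whose slow flow needs the residual clutter pushed
further down. Thresholds are configuration inputs, never chosen
automatically (an energy-elbow utility exists for exploration only).
Removing components beyond the clutter rank necessarily removes the
slowest blood components too; this distorts the recovered waveform upward
(high-pass overshoot) when k is too large and dilutes it toward zero when
k is too small, the classic operating-point trade-off of eigen-based
clutter filters.

## Velocity estimation and ROI reduction

Per pixel, lag-1 temporal autocorrelations R+ and R- of the TO pair are
averaged over a 6-frame sliding window. The half-difference of their
phases responds only to lateral motion (one-way TO carrier), the half-sum
only to depth motion (two-way axial carrier); signs map to the anatomical
convention above. Aliasing is flagged at |phi| within 5% of pi, not
corrected.

Reducing the fields to one series per component is where a plain cortex
average fails: pixels carrying the other component's flow (or none) dilute
the mean toward zero. The pipeline instead aggregates coherently -- the
autocorrelations are summed over selected pixels *before* taking the phase
(an energy-weighted circular mean, unbiased for common motion) -- with
component-specific selections:

* **Axial**: pixels whose lateral-motion energy, the time-sum of
  |R+ - R-| (zero for static or depth-only motion), exceeds half its ROI
  mean. The phase-to-velocity factor uses the *measured* lateral spectral
  centroid of the filtered blood signal rather than 1/lambda_0x: the
  band-limited image spectrum pulls the effective carrier down by ~8%.
* **Radial**: the canal region is *detected*, not cherry-picked: the
  signed coherent depth-motion statistic (time-sum of Im(R+ + R-), one
  sign for unidirectional depth flow, random sign for axial crosstalk) is
  thresholded at the mean of its majority-sign pixels, cleaned by a 3x9
  morphological opening, and dilated back so the whole detected band is
  aggregated. Estimating only over above-threshold pixels inflates the
  peak by ~30% (selection on the measured statistic); aggregation over the
  full detected region removes that bias.

Probe drift is tracked by subpixel phase correlation of each frame's
envelope against the first frame, on the flow-free rows flanking the
cortex (overlying tissue and marrow move rigidly with the bone in this
model; intracortical blood would drag a cortex-only window by up to a
quarter of the drift). Velocity is the time derivative after a 0.25 s
moving average, since the raw displacement staircase is dominated by the
tracker's quantization.

## Hemodynamic metrics

The ROI power-Doppler series (mean |blood|^2, 9-frame moving average)
provides the cardiac segmentation: local maxima with >= 0.5 s separation
and prominence >= 25% of the dynamic range; heart rate =
60 (n_peaks - 1)/(t_last - t_first). Velocity series are cleaned by a
Fourier-series selection filter (DC plus the 5 largest-magnitude bins in
0.3-10 Hz, conjugate mirrors included); per-cycle peak positive/negative
and the recording time-average are taken on the filtered series (the raw
series is kept alongside). The artery branch beamforms each 30-transmit
ensemble, filters it per ensemble (k = 3) and applies the conventional
lag-1 autocorrelation estimator; because transmit is steered 20 deg while
receive is broadside, the Doppler phase lives on the tx/rx bisector with a
cos(separation/2) gain before the vessel-axis projection.

## Measured behaviour at the default conditions

All numbers below are computed by the test suite and
`scripts/acceptance.py`, not assumed. Across five independent recordings
the seed-averaged peak estimates recover the truth within 10% (axial) and
15% (radial), with per-recording spreads of +-25% that mirror the large
per-subject SDs such measurements show in practice; heart rate is within
1.5 bpm in every recording and agrees with the artery branch within 1 bpm.
Drift displacement is tracked within ~5% and its velocity carries ~1% of
its energy in the cardiac band.

One documented limitation: comparing drift-on against drift-free
recordings at the fixed SVD thresholds changes the seed-averaged peaks by
more than 10% (about 15% axial, 30-45% radial). The drift-free scene's
clutter rank is ~3 versus ~5 with drift, so the same threshold removes two
additional blood components there: the comparison measures the filter's
sensitivity to clutter rank, not a drift artifact. An adaptive threshold
would close the gap but is deliberately excluded from the validated
pipeline.

## Problem sizes

Default experiments use a 64-element, 2.5 MHz array sampled at 10 MHz, a
41 x 121 pixel grid, 400 frames, and phantoms of roughly 750 scatterers;
the artery branch uses a 48-element 5 MHz array and 400 ensembles of 30
transmits. These sizes keep a full recording (simulation plus analysis)
under a minute on one CPU while leaving every pipeline stage's behaviour
measurable.
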
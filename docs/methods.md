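# Methods

This note documents the models behind `vagusmap`, the parameters that
matter, the numerical choices, and what the synthetic studies do and do not
establish. Units: SI meters/volts internally; tables and thresholds use the
conventional µm / µV / degrees. Angles are degrees counterclockwise from
3 o'clock; the cuff opening defines 90° (12 o'clock, ventral); clock hour
*h* maps to (90 − 30·h) mod 360.

## Forward model

The cross-sectional conduction problem is solved with a P1 finite-element
discretization of the complete electrode model (CEM): finite electrode
arcs (14, default covering half the inter-electrode pitch), per-electrode
contact impedance (default 1 kΩ lumped, entered as Ω·m²), and a Dirichlet
ground node at the cuff opening. The mesh is a structured triangulation of
concentric rings whose per-ring node counts are multiples of 14, so it is
*exactly* invariant under rotation by one electrode pitch: protocol
rotation-equivariance holds to solver precision (~1e-10) rather than
re-meshing tolerance, and reciprocity tests can be asserted at 1e-10.

The model is two-dimensional. At cuff level the insulating cuff separates
the nerve from the saline bath, which contacts the nerve only at the
cylinder ends; a 2D slab (thickness = electrode width, 3 mm) therefore
contains the nerve disk only by default. An `include_exterior` mode meshes
the near-insulating cuff annulus and the saline annulus out to the 8 mm
outer diameter and verifies that saline sensitivity is negligible. A 3D
extruded mode is deliberately not provided: every downstream stage
(reconstruction, localization, co-registration) is cross-sectional, and the
third dimension would add longitudinal current spreading only — which is
instead captured by a single dilution factor in the traffic model (below).

Nerve conductivity is 0.3 S/m, saline 1.4 S/m. The skip-4 protocol cycles
the injection pair (200 µA) through all 14 positions; all 14 electrode
voltages are recorded per injection against the quasi-tripolar reference.
The physical reference (shunted rings flanking the measurement ring) has no
geometric analog in a single-ring cross-section; it is modeled as the mean
potential of the 14 cuff electrodes. Measurement ordering is pair-major,
electrode-minor: 196 values per frame.

Sensitivities use the adjoint method: J[(k,e), m] = −σ_m t A_m ∇u_k·∇w_e
volts per unit *fractional* conductivity change, with u_k the injection
field and w_e the unit-current adjoint field of the measurement pattern.
The element Jacobian is converted to a square-voxel grid (150 µm, ~340
voxels over the 3 mm disk) by summing element columns into the voxel
containing each centroid — total sensitivity is conserved exactly; voxels
with no element are kept as flagged zero columns.

A consequence of the mean-electrode reference and the disk's mirror
symmetry is that ~2 measurement channels per injection pair have an almost
exactly zero baseline transfer voltage. Envelope demodulation on such
channels returns noise with an undefined sign, so the evoked pipeline
excludes channels whose measured carrier amplitude is below 300 µV
("low_carrier"); the spontaneous (magnitude) pipeline keeps them, since a
dV-RMS measurement needs no carrier sign.

## Synthetic phantom

`make_phantom` realizes organ-labeled fascicle disks: laryngeal at 0°
(3 o'clock, ~15 fascicles), pulmonary at 210° (8 o'clock, ~18), cardiac at
90° (12 o'clock, 1–2 smaller fascicles), centers at ~0.6 of the nerve
radius with Gaussian angular/radial scatter, placed without overlap by
rejection sampling (an impossible packing raises a placement error naming
the colliding groups). Per-animal variation adds a random cuff orientation
(±60°), per-group angle jitter (SD 10°) and Poisson-jittered fascicle
counts — the cuff orientation is exactly the nuisance the clusterization
stage must undo. Note the idealized 3-vs-8 o'clock layout puts the
pulmonary–laryngeal separation at ~150–160°, at the upper edge of the
separations measured in vivo, where CoM scatter pulls the means lower.

Physiology is generated with exact ground truth: blood-pressure beats
(asymmetric systolic bumps peaked exactly at the stored beat times), a
plateau-shaped capnogram whose half-level crossings bracket the stored
breath midpoints, an ECG R-wave preceding each BP peak, and EMG noise.
The channels are clean monitoring signals (no additive noise) so trigger
detection is exact to one sample; real auxiliary channels are noisier, and
trigger jitter would smear coherent averages — a limitation, not a claim.

Neural traffic is a fractional conductivity decrease of the active group's
fascicles, default −1 % at full depth:

- *evoked*: a Gaussian impulse (σ = 1 ms) at conduction latency
  travel_distance / velocity = 0.4 m / 40 m/s = 10 ms after each 20 Hz
  stimulus;
- *gated*: a burst envelope (cardiac: σ = 30 ms at BP-peak + 150 ms;
  pulmonary: σ = 0.5 s at the breath midpoint) multiplying unit-RMS
  300–1500 Hz activity, with cycle-to-cycle amplitude variability
  (CV 0.3). The high-frequency carrier is what survives the 250 Hz
  high-pass of the dV-RMS chain; a smooth slow bump would not.

Because the 2D model concentrates all current in the imaging plane, a
full-depth −1 % change would produce boundary-voltage modulations far above
the microvolt regime the recording chain (0.2 µV amplitude criterion, 1 µV /
10 nV noise-correction amplitudes) is designed for. A per-mode dilution
factor (evoked 5e-3, cardiac-gated 5e-3, pulmonary-gated 5e-4) models the
longitudinal spreading and partial synchronous recruitment of the real
cylindrical geometry, placing evoked dV at ~1–3 µV and spontaneous dV-RMS
below 0.2 µV. These are order-of-magnitude generator choices, fixed once;
all localization claims are relative, not absolute.

Raw recordings are (V0 + J·δσ(t))·sin(2π·6 kHz·t) + white noise, per
injection pair, synthesized lazily (deterministically per pair) so the
196 × 50 kS/s ensemble never resides in memory at once. White-noise RMS
defaults: 15 µV evoked (post-averaging best-trace SNR ≈ 3–5, matching the
in vivo operating point), 0.1 µV spontaneous. Artifact channels
("bad contacts", default 5 % of traces) carry broadband noise (evoked) or
fluctuating/ramping/drifting burst components (spontaneous) constructed to
violate the corresponding exclusion criteria.

## Signal processing

Zero-phase (forward–backward) 5th-order Butterworth filters everywhere, so
no group delay biases peak latency. Band-pass ±1 kHz (evoked) or ±2 kHz
(spontaneous) around 6 kHz; Hilbert-transform envelope; for spontaneous
branches a 250 Hz high-pass and moving-window RMS (cardiac 0.1 s, pulmonary
2 s) at the original 20 µs step.

One numerical point deserves emphasis: the analytic-signal transform of a
finite record leaks the strong carrier line through the band edges of the
filter's *edge transients*, leaving an envelope ripple of order 1e-6 of the
carrier amplitude — up to ~0.3 µV on strong channels, i.e. larger than
nanovolt-scale dV-RMS signals. The chain therefore trims 0.5 s from each
record end between filtering and demodulation (the trimmed length keeps an
integer number of carrier cycles), which reduces the interior ripple to
sub-picovolt level. Trigger guards exclude epochs near the record edges.

On the window assignment for the RMS conversion: with heart periods of
0.5–0.75 s, a 2 s moving window spans several cardiac cycles and averages
away any heartbeat-locked modulation, while 0.1 s over-resolves a ~5 s
breath; the defaults therefore pair 0.1 s with the cardiac branch and 2 s
with the pulmonary branch. Both windows are configurable per run.

Quality control:

- *evoked* (applied to averaged traces): pre-stimulus noise SD > 1 µV,
  mean |amplitude| > 2 µV, max |amplitude| > 4 µV (the strict ends of the
  1–4 / 2–6 / 4–8 µV working ranges; configurable), plus the low-carrier
  rule above. With the structurally null channels and the default 5 % bad
  contacts, ~80 % of the 196 traces are retained.
- *spontaneous* (applied to the **continuous, pre-averaging** dV-RMS
  traces — stationary artifacts are averaged flat and would otherwise
  pass): amplitude deviation > 0.2 µV; derivative > 50 µV/s (first
  differences over the step); pointwise deviation > 3 ensemble SDs; the
  same test on the residual after reconstructing each trace from only the
  first principal component of the 196-trace ensemble (the PC1
  reconstruction itself can be tested instead via a switch); and a manual
  override list. Criteria are evaluated against the full ensemble and the
  flags unioned, not applied sequentially. Because a pointwise 3-SD rule on
  finite ensembles flags isolated samples by chance, criteria 3–4 require
  the threshold to be exceeded in > 5 % of time points. Ensemble criteria
  are re-evaluated on any subset and are therefore not guaranteed
  idempotent; the amplitude/derivative criteria are.

SNR is |peak mean − baseline mean| / baseline SD on the averaged trace
(the baseline SD is the standard estimator of "average noise"); the branch
SNR reported is the best kept trace's. The default baseline window is 10 %
of the epoch centered on the minimum of the ensemble-mean trace (a time of
low traffic). Synthetic spontaneous SNRs come out far higher than in vivo
values because the phantom's baseline variability is idealized; evoked SNR
is calibrated to the in vivo operating point (~3–5) through the noise
default.

## Reconstruction and localization

The linear model dv = J x is inverted as
x = (JᵀJ + λ²I)⁻¹ Jᵀ dv with λ = `lambda_scale` · ε · s₁/s̄ (ε the fixed
noise amplitude: 1 µV evoked, 10 nV spontaneous; s₁, s̄ the largest and
mean singular values of the kept-row Jacobian). The noise-based voxel
correction divides each voxel by its noise-propagation scale ε‖M_v‖ (M the
regularized inverse), so under measurement noise of RMS ε every voxel has
unit variance — that is the only reading under which the fixed 1 µV / 10 nV
amplitudes parameterize the correction. Zero-sensitivity voxels are set to
0 and flagged.

Two interpretive choices matter and are isolated behind options:

- **λ regime.** At `lambda_scale = 1` the top singular modes are fit, but
  the signal's Z-contrast against noise is poor: the noise normalization
  equalizes noise across voxels while the compact signal lives in the top
  modes, and at the channel noise of a coherently averaged recording the
  peak-frame Z barely exceeds noise frames. The pipeline default
  (`lambda_scale = 2e4`) puts λ above s₁, making the image noise-normalized
  sensitivity backprojection — a matched-filter-like statistic whose
  signal-to-noise contrast is the per-voxel detection SNR. For top-16-voxel
  CoM localization (the purpose here) this is the robust regime; it is not
  a quantitative conductivity image. The base rule and closed-form solution
  remain available (`lambda_scale = 1`, or ε → 0 for the unregularized
  oracle).
- **Sign and magnitude.** The Hilbert envelope measures |V0 + δV|, so
  baseline-subtracted evoked δV carries sign(V0), which the pipeline
  restores from the forward model before inversion. Spontaneous dV-RMS
  values are magnitudes, |J·p|-like per row; they are inverted with the
  element-wise |J| (`rectified_inversion`, default on), which maps a
  compact nonnegative source linearly where the signed J does not. For a
  single-voxel source |J p| = |J_col| p exactly.

Peak time is the argmax over time of the maximum-voxel |Z| (earliest wins a
tie), searched within a physiologic window: 7–16 ms post-stimulus for the
evoked branch (10 ms conduction latency ± dispersion), around the gated
phase for spontaneous branches. Evoked traces are smoothed over 0.6 ms
before inversion (the compound response is ~1 ms wide; instantaneous
samples carry the full post-averaging noise). The CoM is the
intensity-weighted mean of the 16 highest-|Z| voxel centers (~5 % of the
grid); ties at rank 16 prefer voxels nearer the image centroid.

## Selective stimulation

Responses follow a von-Mises-shaped angular kernel with half-width at half
maximum of spread/2 (default spread 26°, the focused-stimulation
characterization at 2/3 of the radius), normalized so the best-aligned pair
shows the organ's peak effect: HR −10.1 %, breathing −38.6 %, EMG RMS ×12
by default, plus seeded measurement noise. Metrics: HR from BP beat
intervals, breathing rate from EtCO2 cycle intervals (apnea → −100 %), EMG
RMS ratio after 5–2000 Hz band-pass with a 1 s window (window-boundary
smearing is excluded by contracting each analysis window by half the RMS
window). Significance per pair is |response| > 3× the baseline fluctuation
SD; spatial selectivity requires < 7 of 14 significant pairs. The selection
takes the maximal-|response| pair plus all pairs at ≥ 50 % of it; the CoM
is their unweighted circular mean angle (a response-weighted variant is
available) at a fixed radius of 2/3 R (angular steering has no depth
resolution). An antipodal two-pair selection has no defined circular mean
and raises an error.

## Co-registration and statistics

MicroCT tables are mapped to the circular frame by centering on the
outline ellipse, rotating its axes onto X/Y, scaling each axis to the nerve
radius (no shear), and rotating the cuff-opening landmark to 90°; the
transform is exactly invertible and preserves angular order. The outline
is either carried by the table or fit by least squares; the cuff opening is
a physical landmark supplied as data, not inferred. Organ CoMs are
unweighted means of fascicle centers. Errors between techniques are the
Cartesian distance plus |Δr| and the wrapped |Δθ| ∈ [0°, 180°] — the
radial/angular split is a decomposition for interpretation, not a
Pythagorean identity.

Clusterization searches per-animal rigid rotations on an exhaustive 1°
grid by coordinate descent (cycling animals until no improvement,
deterministic, identity-initialized), minimizing the sum over organs of the
mean member-to-centroid distance; each animal's internal geometry is
preserved by construction, and the objective is invariant to a common
global rotation, which is fixed afterwards by re-anchoring the laryngeal
centroid at 90°. Dispersion is the mean member-to-centroid distance (an
RMS variant is available). Discrimination of angular separations uses
one-sample t-tests against zero mean with exact small-sample df and no
multiple-testing correction.

## Study conditions and scale

The default synthetic study is 4 animals × 3 organs × 3 techniques with
desk-scale recording durations — evoked 8 s per frame (vs 60 s in vivo),
cardiac-gated 12 s, pulmonary-gated 24 s (vs 480 s) at the full 50 kS/s —
chosen so the complete study runs in ~5 minutes on one CPU; coherent
averaging then spans ~130 stimuli, ~18 heartbeats and ~4 breaths per
frame. Default rates: HR 120 bpm, 13 breaths/min (porcine anesthesia
range). The mesh is ~5000 elements (vs millions in a 3D production solve);
the finite-difference and reciprocity oracles bound its fidelity.

What passing tests show: the chain is self-consistent (closed-loop CoM
recovery within 25 % of nerve diameter at all angles, in fact within a few
voxels), the statistics behave as designed (√N averaging, unit-variance
noise correction, criterion-complete exclusion), and the co-registration
algebra is exactly invertible. What they do not show: performance under
real electrode drift, stimulation artifacts, trigger jitter, anisotropic
and dispersive tissue, or model mismatch between the reconstruction
Jacobian and the true geometry — the synthetic recordings are generated by
the same forward model used to invert them, except for noise, artifacts
and the fascicle-to-voxel discretization.
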
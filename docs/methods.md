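# Methods

## The measurement principle

During a focal sweep every scene point passes through best focus exactly
once. An event camera converts the resulting intensity transient into a
stream of signed threshold crossings: while the blur shrinks the pixel's
intensity moves monotonically toward its sharp value (a run of one
polarity), and once focus has passed it moves back (the opposite
polarity). The time of focus t_f is therefore marked by a *polarity
inversion*, estimated as the average timing of the consecutive ON and OFF
events that straddle it. Depth follows by evaluating the sweep's focus
trajectory at t_f: z = d(t_f). The blur-circle inversion
z = ∓d·c/(s·(d−f) ∓ c), c = f²/N, is implemented and tested as the exact
algebraic inverse of the blur model, but on the focus mark itself the
residual blur is zero by construction, so the direct readout is used.

## Optics

- Blur diameter s = c·|z−d| / ((d−f)·z). The textbook form holds for a
  moving object and fixed focus; during a sweep the roles invert (z fixed,
  d(t) swept). The formula is symmetric in usage.
- PSF: isotropic Gaussian, σ = α·s. Default α = 0.25 matches the second
  moment of an ideal uniform blur disc of diameter s (a pillbox of radius
  s/2 has per-axis RMS s/4). Wave optics, aberrations and lens distortion
  are out of scope.
- Equivalent focal length: the three-element stack (liquid lens 50–120 mm,
  offset lens −150 mm, objective 35 mm f/2) is summarised by a single
  f_eq. Because the inter-lens spacings are not modelled, a
  thin-lenses-in-contact helper (1/f_eq = Σ 1/f_i) provides an explicitly
  approximate default; f_eq = 28.5 mm, its value at mid-range liquid-lens
  power, is the configuration default. The operating depth range of the
  physical three-lens instrument therefore cannot be certified from these
  parameters alone.
- Sweep: linear in optical power (dioptres) over the window, matching the
  roughly linear current-to-power response of a liquid lens; a
  linear-in-distance profile is available. Default window 5 ms from
  0.18 m to 3.0 m, the far end just short of the desk-scale hyperfocal.
- Hyperfocal H = c/coc + f with coc defaulting to one pixel pitch; depths
  beyond H are never reported valid.

## Event model

Per pixel a log-intensity reference is kept. When |log I − ref| reaches
the contrast threshold n, ⌊|Δ|/n⌋ events are emitted, each stepping the
reference by ±n (step-by-n rather than reset-to-current, so multi-event
bursts are well defined), with polarity sign(dI/dt) and crossing times
interpolated linearly inside the render step. Public streams quantise to
1 µs; the low-level engine keeps float times, which is what the
convergence test against the closed-form event-time formula uses. The
threshold defaults to n = 0.15, a conventional contrast-detector
operating point — the instrument's own value is tuned per scene and is
not published. No refractory period, shot noise, background activity or
pixel mismatch is modelled.

Two consequences of this noise-free, net-intensity model matter for
interpreting results:

- A pixel emits one polarity at a time (the sign of its net dI/dt).
  "Superimposed" opposite-polarity streams from two nearby edges appear
  as interleaved runs in one pixel's train and as mixed polarities across
  the overlap region at one instant — not as simultaneous ON and OFF at
  one pixel.
- Deblurring a random texture is a backwards heat flow: per-pixel
  intensity is not monotone in σ, which creates polarity inversions
  unrelated to focus. The fixtures therefore use uniform-reflectance
  objects, whose depth cues live at contours, as they do for the silicon
  retina itself.

## The five-neuron circuit

Neurons are LIF with exact exponential decay between fixed steps
(dt = 50 µs, delta-current synapses). Wiring per pixel: ON/OFF relays →
OUT (excitatory, sub-threshold alone, delay 2 steps); relays → matching
blocker (delay 1); blocker → OUT (delay 1); OUT → OUT self-excitation;
shared Sync → OUT strong inhibition plus state reset. A blocker first
fires on the second same-polarity spike and, because its reset potential
sits close to threshold, re-fires on every subsequent run spike.

The blocker→OUT synapse is *shunting*: it clamps OUT's membrane to rest
immediately before the step's inputs integrate. A subtractive IPSP paired
with each EPSP would cancel the newest excitation and leave OUT holding a
stale residual from the start of the run; the shunt instead guarantees
OUT always carries exactly the last same-polarity spike's decaying EPSP.
An opposite-polarity event then fires OUT iff it arrives within the
coincidence window τ_out·ln(w/(θ−w)) ≈ 0.81 ms (τ_out = 2 ms, w = 0.6,
θ = 1) of the last lead event — the membrane leak is the circuit's
implementation of "smallest interval between opposite polarities", and
the reference (non-spiking) detector applies the same gate. Blockers
integrate over a slower membrane (τ = 6 ms) so that any spike pair able
to leave a near-threshold residue in OUT is guaranteed to have fired (and
shunted through) its blocker first; the constraint validator checks this
coverage along with the other behavioural constraints, each by name.
Input relays carry a one-step refractory, collapsing same-polarity bursts
inside one simulation step to a single spike.

Readout: the first OUT spike marks the trailing event of the inversion
(two synaptic steps late); the last relay spike of the opposite polarity
marks the leading event. The focus time is the midpoint of the two marks,
i.e. the average-timing estimator computed from the circuit's own spike
record. Using the raw OUT onset alone would bias depth late by half the
straddle gap, which near the hyperfocal is a material depth error. OUT's
self-excitation sustains a contiguous spike train until the lens-driven
Sync spike (modelled as an external source at each sweep end) inhibits and
resets the circuit; each sweep window is simulated with fresh state.

## Synthetic scenes

The generator renders depth-labelled reflectance maps through the
time-varying Gaussian PSF (per-depth-layer convolution via
`scipy.ndimage.gaussian_filter`, far-to-near compositing by blurred layer
masks, no inter-layer blur bleeding) at a 25 µs render step. Fixture
optics use a 64×64 region with 3×3-binned 15 µm pixels (45 µm pitch) so
blur kernels stay resolvable on the small array; the full-sensor default
remains 640×480 at 15 µm. Fixtures: a uniform disc ("sphere"), a bar, a
textured plane, a multi-object scene (three discs and one square, uniform
reflectance, depths 0.3/0.6/0.9/1.2 m), and the two-edges pair. The
two-edges fixtures place a dark bar (0.1) at 0.3 m and a bright bar (0.9)
at 0.6 m on mid-grey: opposite contrasts make the overlapping blurred
edges push the gap pixels in opposite directions simultaneously, which is
what produces interleaved polarity runs (flagged ambiguous) in the near
configuration; the far configuration separates the inner edges by 24 px
and stays clean. Background pixels carry no ground-truth depth and a
uniform reflectance, so they emit no events of their own; error metrics
score only pixels where both an estimate and a truth exist.

What passing on these fixtures does *not* show: robustness to sensor
noise, textured surfaces, occlusion boundaries between overlapping
objects at the same image location, real liquid-lens hysteresis, or the
full-resolution sensor; the desk-scale numbers characterise the method
under ideal conditions.

## Numerical choices and degenerate inputs

- Intensities ≤ 0 are floor-clamped (1e-6) before logs, with a warning.
- PSF σ above 64 px is clamped with a warning (kernel-size cap).
- Oracle tie-break: among equal smallest gaps the earliest pair wins;
  ambiguity counts every adjacent opposite-polarity pair, gated or not.
- Depth inversion raises a singular-configuration error when the
  denominator vanishes (blur at the aperture-limited bound).
- Focus times outside the sweep window, and depths beyond the hyperfocal,
  invalidate the pixel and are counted on the depth map.
- Determinism: fixtures are seeded; the simulator and circuit are
  deterministic given the stream.

## Known limitations

- The event-reference step-by-n scheme makes the straddle asymmetric (the
  trailing event sits a full threshold below the last leading event's
  level), so even the midpoint estimator carries a small late bias that
  grows toward the hyperfocal, where the depth-per-microsecond rate is
  largest.
- Valid pixels concentrate in contour bands; uniform interiors are
  unmeasurable by construction, as for any temporal-contrast sensor.
- The circuit weights and time constants are behaviourally, not
  physiologically, chosen; the constraint validator defines the admissible
  family, not a unique parameter set.
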
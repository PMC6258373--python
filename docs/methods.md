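# Model and methods

`v1l4sim` implements a point-neuron circuit model of layer 4 (L4) of mouse
primary visual cortex: the thalamorecipient layer, driven by a bank of
linear–nonlinear–Poisson (LNP) filters standing in for the LGN, embedded in
a background of traveling-wave input standing in for the rest of the brain.
This note records the model's assumptions, the parameters that matter, the
numerical choices, and the design decisions taken where the construction was
genuinely open.

## Network composition and geometry

45,000 neurons of seven types are placed in a cylindrical slab 100 µm high:
five "core" types (Scnn1a, Rorb, Nr5a1 excitatory: 3700/3300/1500; PV1, PV2
inhibitory: 800/700) fill the inner 400 µm-radius cylinder at
200,000 mm⁻³, and two generic LIF types (29,750 excitatory, 5,250
inhibitory) fill the annulus out to 845 µm to absorb boundary artefacts.
All neurons here are leaky integrate-and-fire points; the "core" flag marks
the population whose neighbourhoods are unaffected by the outer boundary and
over which structural summaries are reported.

Every neuron carries an *assigned* preferred direction, tiled linearly over
[0°, 360°) within each type in cell-id order. The assigned value seeds the
functional wiring rules; the preference actually expressed in simulation
emerges from the circuit and need not coincide with it.

## Recurrent connectivity and the four rule variants

Connection probability is a product of a linear distance term (peak at zero
separation, zero at 300 µm for excitatory sources and 160 µm for inhibitory
sources; peaks 0.34/0.26 for E→E/E→I under like-to-like probability, 0.255
for both under random probability, 1.0 for inhibitory sources) and, for E→E
pairs under "L" probability rules, a linear orientation term falling from 1
at Δori = 0° to 0.5 at 90°. Each ordered pair is an independent Bernoulli
draw; established connections carry 3–7 synapses (uniform integer).
Like-to-like *weights* multiply the class base weight by
F_w = exp(−Δθ²/σ_θ²), σ_θ = 50°. The two-letter rule tag picks the
probability rule (first letter) and the weight rule (second letter):
LL, LR, RL, RR.

Design choices where the construction was open:

- distance is planar (x–y); the 100 µm slab is thin relative to every
  lateral scale,
- no self-connections; at most one edge per ordered pair,
- a fixed 1 ms conduction delay on recurrent edges (a nonzero delay is
  required for causal event ordering on the integration grid),
- Δori folds direction differences into orientation space
  (min(d mod 180, 180 − d mod 180)).

The interior (core) populations reproduce the expected partner statistics —
mean in/out partners ≈ 490/480 for excitatory and ≈ 490/530 for inhibitory
cells — while cells near the outer rim necessarily have truncated
neighbourhoods; structural summaries therefore report both all-cell and
core-only statistics, and headline numbers use the core.

## LGN front end

9,000 filters (3,000 each transient ON, OFF, ON/OFF) tile a 130° × 90°
field. Each subfield is a centre–surround difference of Gaussians
(A_S = A_C/6, σ_S = 2σ_C) with the biphasic temporal kernel
k·t·e^(−kt)·(1 − k²t²/6), whose integral is exactly zero, so static scenes
produce no linear drive. The ON pathway sees the movie S, the OFF pathway
255 − S; per subfield the rate is max(R₀ + L, 0); ON/OFF units sum their two
subfield rates and subtract the mean baseline. The first 500 ms of every
response is overwritten with R₀ (every stimulus opens with a 500 ms gray
prefix that analysis discards).

Numerical choices: spatial kernels are truncated at 3σ_S (<0.2% mass);
the sampled temporal kernel is truncated at 10⁻⁶ of its peak envelope and
its residual discretisation sum is redistributed proportionally to |w| so
the zero-integral property is exact on the grid; the pre-movie history is
taken to continue the first frame, which makes the gray-screen response
exactly R₀ at all times. Spikes are per-millisecond Bernoulli samples with
p = R·dt (thinning-equivalent at these rates).

Kernel parameter ranges are produced by `calibrate_filter_params`: the
temporal constant k is root-solved so the kernel's peak temporal frequency
is 4 Hz and σ_C so the peak spatial frequency is 0.05 cpd (the closed forms
are f_TF ≈ 97.1·k Hz and f_SF ≈ 0.129/σ_C cpd); sampling ranges are ±13.5%
around the roots, which keeps every filter's grid argmax on target. The
amplitude A_C is set by secant iteration so the strongest grating F0 in a
probe bank is 11.5 Hz (per-filter ±10% jitter); the frozen defaults are
k ∈ (0.0357, 0.0468) ms⁻¹, σ_C ∈ (2.19, 2.88)°, A_C = 2.63·10⁻⁴.
The baseline range R₀ ∈ [1, 5] Hz is a package default chosen to span
typical LGN spontaneous rates; it is exposed as configuration. ON/OFF
subfields are displaced by 2σ_C in a random direction — overlapping but
resolvable, and the displacement axis gives the unit its orientation-biased
F1.

Retinotopy maps cortical position to visual space at 120°/mm (azimuth) and
50°/mm (elevation), centre to centre. Feedforward selection uses per-cell
"lasso" capture regions: three concentric circles of diameter U[15°, 20°]
for inhibitory targets; for excitatory targets, ON and OFF ellipses (minor
radius U[3°, 4°], aspect U[2.8, 3.0], centres separated by U[10°, 11°]
along the assigned preferred direction, minor axis along that line) plus a
circular ON/OFF lasso of the minor radius. A filter is a candidate if any
of its subfield centres falls in the matching lasso; ON/OFF candidates must
additionally have their subfield axis within ±15° of the target's assigned
orientation. Up to 8 (excitatory) or 15 (inhibitory) filters per type are
kept, each contributing 30 synapses. This yields ≈600 LGN synapses per
excitatory core cell, ≈100 cortical targets per filter, and ≈3,000 total
synapses per core cell together with the recurrent budget.

## Background traveling waves

3,000 Poisson generators tile the model footprint (plus a 150 µm margin so
edge cells keep full candidate pools). Waves alternate with silent gaps:
duration U[200, 1200] ms, gap U[250, 1750] ms, amplitude U[5, 15] Hz,
direction uniform; the band is 2,000 µm wide, rectangular, unbounded
perpendicular to its motion, and traverses the footprint within its duration
(speed = (diameter + width)/duration). A generator is therefore ON for
width/(diameter + width) ≈ 0.50 of each wave's duration, giving a long-run
mean rate of ≈2.1 Hz. Each cell listens to 18–24 generators within 150 µm;
all of a cell's background edges share one synapse multiplier m ∈ {1..16}
drawn from a truncated geometric distribution (p = 0.5), the long tail that
skews the spontaneous-rate distribution across cells.

## Point-neuron dynamics

Threshold-normalised LIF: threshold 1, reset 0, absolute refractory 3 ms;
membrane time constants 15 ms (excitatory) and 10 ms (inhibitory) — package
defaults standing in for per-type averages of detailed counterpart models.
Two synapse models:

- **instantaneous**: each arriving event dumps weight × n_syn on the
  membrane;
- **kinetic**: excitatory events drive a single-exponential current
  (τ_E = 1 ms on excitatory, 7 ms on inhibitory targets), inhibitory events
  a peak-normalised difference of exponentials (rise/decay 4/17 ms on
  excitatory, 1/8 ms on inhibitory targets); the membrane integrates both
  leakily. The per-step update is the exact matrix exponential of the
  linear cascade, so subthreshold trajectories match the closed form to
  machine precision.

Fixed step dt = 0.1 ms resolves the 1 ms delay and 3 ms refractory period
exactly; external (LGN, background, optogenetic) spikes are binned at 1 ms,
their native resolution. Inputs arriving during the refractory period are
discarded, not queued — but the per-cell input *accumulators* (summed
arriving weight, kept separately for LGN and for all excitatory and
inhibitory sources) count every arrival, since they measure delivered
synaptic input, not its postsynaptic effect.

In-silico optogenetics: LGN silencing deletes all LGN spikes from a chosen
onset; population silencing attaches one inhibitory synapse per selected
cell driven by an independent 100 Hz Poisson train, with weight
proportional to the labelled current amplitude (the −100 pA label maps to
the reference weight 0.3).

## Weight calibration

Only per-class scalar weights are calibrated; the per-edge F_w structure
and the topology are never touched, so calibration cannot convert an "R"
variant into an "L" variant, and all four variants run the identical
protocol. Three stages:

1. **LGN weights** (per target type): purely feedforward regime, scaled to
   per-class rate targets by geometric bracketing/bisection — the
   rate-versus-weight curve of a threshold neuron is nearly a step, so
   damped multiplicative updates overshoot, while bisection in log space is
   reliable.
2. **Background weights**: background-only regime, same bracketing, aiming
   slightly below (0.85×) the spontaneous targets.
3. **Recurrent class weights** (E→E, E→I, I→E, I→I): full network. The
   four log-weights are solved against four log-rate observables — the
   spontaneous rate and the training-grating response of each class — by a
   damped quasi-Newton iteration (finite-difference Jacobian, Broyden
   rank-1 updates, steps halved when the synchrony guard trips). The
   observables are strongly cross-coupled and bounded by a sharp synchrony
   cliff, which defeats any fixed pairing of knob to observable; the small
   Newton solve is the minimal reliable automation of what was originally
   a manual search.

Training data are single *fixed* trials — one grating (1,000 ms scored) and
one gray screen (2,000 ms scored) — reused across iterations so the fixed
point is deterministic. The gray window is longer than the grating window
because the wave background has ~1 s structure: a 500 ms window often
contains no wave at all and the spontaneous-rate observable becomes
uninformative. For the same reason the training background trials are
*duty-matched*: the schedule seed is advanced until the generators' ON
fraction over the scored window is within 10% of its long-run expectation.

Rate targets (package defaults; the quantities are physiological but not
fixed by published data): spontaneous 0.75 Hz (E) and 1.75 Hz (I) —
mid-band of the 0.5–1.0 and 1.5–2.0 Hz ranges; training-grating population
rates 3.5 Hz (E) and 10 Hz (I) (fast-spiking populations respond at
~10–20 Hz; the per-cell Rmax over all directions comes out above the
population mean at one grating); feedforward-only 5.5 Hz (E) and 12 Hz (I).
Convergence requires the spontaneous rate within 0.5 Hz and the grating
response within 1 Hz of target per class. The synchrony guard rejects any
iterate in which more than 10% of all neurons fire within a single 5 ms bin
— the epileptic-like signature; a median-relative rate criterion would
misfire because the traveling waves legitimately modulate the population
rate severalfold.

A feasibility sweep over (LGN weight, recurrent excitation, inhibition)
informed the default targets and the Newton starting point: the calibrated
operating point of the reduced instantaneous-synapse network is
*suppressive* (full-network grating responses sit below the feedforward-only
rates), because at this granularity each synaptic event is large and the
network sits close to the synchrony boundary; recurrent amplification above
unity is epileptic there. This is a property of the reduction, not of the
full-size model it approximates.

## Matched-density reduction

`scale = s` shrinks cell counts by s, radii by √s, and the LGN field by √s
with filter count tracking its area, preserving areal cell density, filter
density per deg², and every local wiring rule; lasso geometry and
connectivity cutoffs stay absolute. Dynamical measurements (the LGN input
fraction, rule-variant comparisons, silencing, spectra) default to s = 0.1
(4,500 cells), the size at which the full calibration-plus-battery pipeline
runs in about two minutes; structural measurements always run at full size.
Reduced-scale interiors reproduce the full-scale wiring statistics, but the
slab-wide in-degree is lower (kernels truncate at the smaller rim), which
is one reason reduced-scale dynamical quantities carry wider error than
structural ones.

## What the simulations do and do not emulate

The stimulus generator reproduces the standard battery — square-wave
drifting gratings on the 8 × 6 × 5 direction/SF/TF grids with the g1–g240
naming, full-field flashes with fixed timings, moving bars, gray screen —
at 1 ms and 1.25°/pixel with a 500 ms gray prefix. Natural movies and
images are accepted as user-supplied arrays in the same layout but are not
bundled. The LGN bank contains only the three transient types: sustained
responses, direction-selective units and eye-specific pathways are absent,
so flash responses are faster and direction selectivity weaker than in
vivo. Passing tests show that the construction rules and analysis chain
reproduce the model's own published statistics, not that the reduced LIF
network reproduces cortex: dendritic processing, conductance synapses,
plasticity and the full diversity of interneurons are all outside the
model class.

## Known limitations

- The reduced instantaneous-synapse network is bistable near its operating
  point: a ~15% increase of recurrent excitatory weight tips it into
  network-wide volleys. The synchrony guard steers the calibration away,
  but quantities sensitive to the recurrent/feedforward balance (the LGN
  input fraction above all) inherit several points of run-to-run spread.
- Calibration targets are inputs, not measurements; changing them moves the
  operating point and everything downstream.
- The CV of inter-spike intervals is reported as the squared SD/mean ratio
  (the convention used throughout the variability summaries here);
  `squared=False` gives the conventional ratio.
- Both F1 conventions (|b| and 2|b| for a fitted a + b·sin ωt) are in
  circulation; `f0_f1` exposes them explicitly and defaults to |b|.
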
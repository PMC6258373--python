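# v1l4sim

A point-neuron circuit model of layer 4 (L4) of mouse primary visual
cortex — the thalamorecipient layer — for in-silico visual physiology.
The package is for computational neuroscientists who want to build the
45,000-neuron L4 circuit from its published construction rules, drive it
with arbitrary grayscale movies through an LGN filter bank, perturb it
(LGN or population silencing), and analyse the spiking output with the
standard single-unit and population metrics.

## The model in brief

**Circuit.** Seven cell types in a 100 µm slab: five types in a 400 µm
"core" cylinder (Scnn1a/Rorb/Nr5a1 excitatory, PV1/PV2 inhibitory) and two
generic LIF types in the surrounding annulus (845 µm outer radius), at
200,000 mm⁻³. Recurrent connection probability is
p = p_dist(d) · p_ori(Δori): linear in intersomatic distance (zero beyond
300 µm for excitatory, 160 µm for inhibitory sources) and, for E→E pairs
under like-to-like rules, linear in the difference of assigned preferred
orientations (1 at 0°, 0.5 at 90°). Like-to-like weights multiply the class
base weight by F_w = exp(−Δθ²/σ_θ²), σ_θ = 50°. The four rule variants
LL/LR/RL/RR toggle the probability (first letter) and weight (second
letter) rules between like-to-like (L) and random (R).

**LGN front end.** 9,000 linear–nonlinear–Poisson filters (transient ON,
OFF and two-subfield ON/OFF) with centre–surround difference-of-Gaussians
spatial kernels (A_S = A_C/6, σ_S = 2σ_C) and the biphasic temporal kernel
D_t(t) = k·t·e^(−kt)·(1 − k²t²/6); rates R(t) = max(R₀ + L(t), 0) are
sampled as Poisson trains. Filters are wired to cortex retinotopically
(120°/mm × 50°/mm) through per-cell elliptical "lasso" capture regions
aligned with each cell's assigned orientation; each selected filter
contributes 30 synapses (≈600 LGN synapses per excitatory core cell).

**Background.** 3,000 Poisson generators driven by rectangular traveling
waves (duration 200–1,200 ms, gaps 250–1,750 ms, amplitude 5–15 Hz, width
2 mm) stand in for the rest of the brain; a long-tailed per-cell synapse
multiplier skews the spontaneous-rate distribution.

**Dynamics.** Threshold-normalised leaky integrate-and-fire neurons
(3 ms refractory period) with either instantaneous ("charge-dump") or
kinetic synapses (single-exponential excitation, difference-of-exponentials
inhibition). Per-class synaptic weight scales are calibrated in three
stages against spontaneous and grating-response rate targets; see
`docs/methods.md` for the full account.

**Analysis.** Spontaneous rate, tuning curves and Rmax, OSI
(|Σf·e^{2iθ}/Σf|), DSI, F0/F1, lifetime sparsity, CV of ISIs, Fano factor,
signal/noise correlations, optogenetic modulation index, rate skewness,
inverse-distance-weighted multi-unit spectra, per-cell LGN input fractions,
thalamocortical convergence of connected pairs, and flash PSTHs.

## Worked example

Build a matched-density 10% instance, calibrate it, and measure its
physiology (about three minutes on one CPU):

```python
import numpy as np
from v1l4sim import analysis, protocols
from v1l4sim.stimuli import GRATING_DIRECTIONS

model = protocols.calibrated_network("LL", scale=0.1, seed=1)
spont, _ = protocols.spont_protocol(model, n_trials=10, seed=42)
rates, fracs, _ = protocols.grating_battery(model, tf_hz=2.0, seed=7)
osi = analysis.osi(np.asarray(GRATING_DIRECTIONS), rates.T)
frac = protocols.preferred_orientation_lgn_fraction(rates, fracs)

exc = model.is_exc()
print(f"spontaneous rate: E {spont[exc].mean():.2f} Hz, "
      f"I {spont[~exc].mean():.2f} Hz")
print(f"mean excitatory OSI: {np.nanmean(osi[exc]):.2f}")
print(f"LGN share of excitatory input: {np.nanmean(frac[exc]):.2f}")
```

```
spontaneous rate: E 0.94 Hz, I 2.57 Hz
mean excitatory OSI: 0.41
LGN share of excitatory input: 0.45
```

The spontaneous rates sit in the physiological bands the calibration
targets (≈0.5–1 Hz excitatory, ≈1.5–2.5 Hz inhibitory); the OSI reflects
like-to-like wiring (it collapses to ≈0 under the LR/RR variants); and the
LGN fraction says that at the preferred orientation roughly half of the
excitatory synaptic input to excitatory cells arrives from the thalamus,
the rest from recurrent cortical and background sources.

A thin CLI wraps the same library:

```
v1l4sim build --rule LL --scale 0.1 --seed 0 --out net.h5
v1l4sim simulate --net net.h5 --stim g8 --trials 10 --synapse kinetic --seed 7 --out run.h5
v1l4sim analyze --spikes run.h5 --metrics rates,cv,fano,sparsity --out report.csv
```

(`g8` is grating direction 0°, 0.05 cpd, 4 Hz under the g1–g240 naming.)

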
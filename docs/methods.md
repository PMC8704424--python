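# Methods

`stimlimit` quantifies how much a subretinal microelectrode can safely
stimulate, in three coupled steps: the electrochemical charge budget of the
electrode, the electric field that budget can establish in tissue, and the
spiking response of retinal ganglion cells (RGCs) within that budget. This
note records the models, the parameter choices that matter, and the known
limitations.

## Electrochemical limits

**Charge storage capacity (CSC).** From a slow cyclic voltammogram
(triangular sweep, 200 mV/s, −0.6 to +0.8 V vs. Ag/AgCl), the anodic CSC is
the time integral of the positive current over samples whose potential lies
inside the water window, divided by geometric disk area (π d²/4); the
cathodic CSC uses the negative current. Integration is trapezoidal. When a
scan holds two or more complete cycles, the first (conditioning) cycle is
discarded and the rest averaged — standard voltammetric practice; a partial
cycle is integrated as-is with a warning.

**Charge injection capacity (CIC).** A biphasic anodic-first current pulse
polarizes the electrode; the measured potential is decomposed into the
ohmic access voltage `V_a` (the near-instantaneous step at each current
edge) and the residual polarization `E_ma`/`E_mc` = ΔV − V_a, read 10 μs
after the end of the anodic/cathodic phase. Design choices the source data
do not pin down, resolved here:

* `V_a` is the potential step across the single sample interval containing
  a current edge. Each edge's step is rescaled by |I_phase/ΔI| before
  averaging: the anodic→cathodic edge of a gap-free pulse carries a 2I
  step, and without the rescaling `V_a` would depend on the interphase gap.
* Polarizations are referenced to the pre-pulse baseline (mean over 1 ms
  before onset), which removes any DC offset and makes electrodes
  comparable. Whether the underlying measurements are referenced to
  open-circuit potential or baseline is not stated anywhere we could
  check; the choice only shifts both limits equally.
* The CIC is the per-phase charge of the largest pulse in an increasing
  family whose polarizations stay inside the water window, refined by
  linear interpolation in charge toward the first failing pulse — the same
  interpolation convention the response analysis uses for thresholds. For
  a purely capacitive electrode this interpolation is exact.

Sampling must resolve the 10 μs read-out delay: `measure_polarization`
rejects records coarser than the delay, and the transient generator
defaults to 500 kHz accordingly.

Units are SI internally; mC/cm² and nC appear only at reporting
boundaries. The per-electrode charge limits at 3.3 mC/cm² compute to
2.59 / 10.37 / 23.33 nC for 10 / 20 / 30 μm disks; the conventional
rounded values 2.5 / 10 / 25 nC are not mutually consistent with any
single density (they imply 3.18–3.54 mC/cm²), so the package reports
exact arithmetic and offers 2-significant-figure rounding only as a
presentation option.

## Volume-conductor field model

The potential in a homogeneous ohmic medium obeys ∇·(σ∇V) = 0 with
E = −∇V; σ defaults to 0.2 S/m. Two solution routes:

**Closed form.** For a disk carrying uniform current density in full
space, on axis: V(z) = (I/2πσa²)(√(z²+a²) − z) and
E_z = (I/2πσa²)(1 − z/√(z²+a²)); off-axis values come from
elliptic-integral quadrature of the surface-source integral. The
equipotential-disk variant (primary current distribution) is the
oblate-spheroidal solution, on axis V(z) = (I/4πσa)·arctan(a/z) in full
space. Half-space (insulating substrate plane) doubles both. Uniform
current density is the default boundary condition, matching a
current-source drive of a high-capacitance film; the equipotential variant
is provided for sensitivity analysis.

**Finite volume.** An axisymmetric finite-volume discretization on a
graded tensor grid (uniform cells across two electrode radii — 16 per
radius by default — then 8% geometric coarsening to the far boundary at
9 mm, the radius of the 18 mm conductive-sphere geometry). Neumann flux
J = I/πa² through the disk, zero flux on the substrate plane and the
axis, V = 0 on the far boundary standing in for the distant return
electrode. The plane is a symmetry plane of the full-space problem, so
one solver serves both geometries (half the current for full space).
Direct sparse solve; the residual is checked against 1e-8 relative. On
axis the solver agrees with the closed form to better than 1% for
z ∈ [2, 50] μm and with the point monopole to ~1% out to ~15 radii, where
the grounded far boundary begins to bias the potential (≈ z/R_domain).

**Activation depth.** The depth is the largest on-axis height where
|E| ≥ 1000 V/m — a commonly used minimum field for retinal stimulation —
found by bisection (closed form, 0.01 μm tolerance) or interpolation
(grid). The inverse, `required_current`, follows from linearity:
I_req = E_thr/|E|(z; I=1). At the CIC-limited 1 ms currents the depths at
σ = 0.2 S/m are ≈32 / 64 / 95 μm for 10 / 20 / 30 μm disks (31 / 62 / 99
at the rounded 2.5/10/25 μA currents), strictly increasing with diameter.
Note that published depths of ∼20/35/55 μm for these conditions are not
reproducible from σ = 0.2 S/m under either boundary condition or
geometry; they are approximately consistent with σ ≈ 0.5 S/m. The
package exposes σ as a config knob and makes no guess about which value
produced the printed figures; the diameter ordering and the closed-form
oracle agreement are the verifiable claims.

"Depth" is measured on axis from the electrode plane. An iso-surface
reading (the radius of the 1000 V/m contour) would differ off-axis; the
on-axis scalar is what a single per-diameter number can support.

## Evoked-response statistics

Per-trial spike times are referenced to stimulus onset, with a ≥2 s
pre-stimulus baseline. Definitions:

* **Evoked count** (per trial): spikes in the 0–500 ms window minus
  baseline rate × window duration. Suppression below baseline stays
  negative. The 500 ms window follows the span over which evoked activity
  is analyzed; it is configurable.
* **Response probability** (per level): fraction of trials with ≥1 spike
  in the window. A boolean cannot be rate-corrected, so this is
  deliberately *not* spontaneous-corrected; counts and booleans are kept
  as distinct metrics throughout.
* **Charge threshold**: the charge at which response probability first
  crosses 0.5, by lowest-crossing linear interpolation between tested
  levels. A curve already at ≥0.5 at its lowest level is flagged
  left-censored; one that never reaches 0.5 within the CIC limit yields
  no threshold and the cell counts as non-responsive. Lowest-crossing is
  deterministic and conservative for non-monotone empirical curves.
* **Half-max**: same interpolation on the mean-count curve at 50% of its
  within-CIC maximum.
* **Dynamic range**: DR = 10·log₁₀(max within-CIC mean count / count at
  threshold), with the threshold count linearly interpolated at the
  threshold charge (nearest-level mode available). The 10·log₁₀
  (power-style) convention is a documented choice — spike counts are
  magnitude-like; multiply by 2 for the 20·log₁₀ convention.
* **PSTH**: trial-averaged rate on uniform bins (−50 to +500 ms, 10 ms
  default), satisfying Σ rate·Δt = mean post-stimulus count exactly.
* Latency summaries split at 100 ms (short vs. long); an optional 5–10 ms
  cut is available descriptively, with no claim about direct vs.
  network-mediated origin.

Population summaries report mean, median, 25–75% quartiles and 9–91%
whiskers of thresholds and dynamic ranges over cells with a threshold,
the responsive fraction over all tested cells, and charge-density
thresholds (threshold / geometric area).

## Synthetic data generator

The generator exists so every stage is testable end to end without
instrument data. It emulates structure, not biophysics.

**Electrode circuit.** Access resistance in series with a specific
polarization capacitance c_s (per geometric area) reproduces pulse
transients exactly (V = IR + Q/c_sA); slow CV uses a separate
pseudocapacitance profile per sweep direction (baseline + Gaussian redox
peaks), so anodic and cathodic CSC can differ as they do for oxide films.
The shipped `fig2_electrode` preset is designed for 12 / 17 mC/cm²
anodic/cathodic CSC and c_s = 4.125 mF/cm², giving a CIC of
0.8 V × 4.125 mF/cm² = 3.3 mC/cm² with the anodic limit binding.

**Cell population.** Per cell, drawn independently (log-normal across
cells unless noted): a responsiveness Bernoulli (p_resp), a logistic
per-trial spiking probability with midpoint Q₀ (the cell's threshold) and
scale 0.1·Q₀, a mean evoked count ramping linearly from a designed count
at threshold (median 2.0) to a maximum at the CIC limit, gamma-distributed
spontaneous rates (mean 0.15 Hz, shape 2), and a latency mixture (60%
gamma short component, mean 10 ms, shape 2; 40% uniform 100–400 ms).
Pulse trains scale the midpoint by a per-diameter factor < 1 and the
maximum count by a gain ≥ 1; the logistic scale tracks the scaled
midpoint. On a responding trial the evoked count is
1 + Poisson(max(m−1, 0)), so the probability of ≥1 evoked spike equals
the logistic exactly and probability-based thresholds are unbiased up to
spontaneous contamination. Distances to the electrode are drawn uniform
0–25 μm but do not modulate responses in this version; coupling them to
the field model is an extension hook.

The count ramp is anchored at the threshold (not at zero) because the
dynamic-range calibration needs a controlled count *at* threshold; with
the anchor, the designed analyzer-scale DR is 10·log₁₀(m_max/(0.5·m₀)).

**Spontaneous rate choice.** 0.15 Hz mean keeps the boolean response
probability usable (≈7% contamination of the 0.5 s window). Degenerated
retina can show far higher, oscillatory spontaneous activity; that regime
would swamp a boolean threshold and is deliberately not emulated — the
generator reproduces the conditions under which 50% thresholds are
measurable at all.

**Calibration presets.** `fig7_population` carries the single-pulse
threshold medians 0.83 / 1.8 / 3.6 nC for 10 / 20 / 30 μm, train medians
0.46 / 1.6 / 2.4 nC (as midpoint factors), and responsive fractions
0.47 / 1.0 / 1.0. `fig8_population` is the same population with
p_resp = 1 and count parameters calibrated so the *analyzer's* mean
dynamic range lands on 5.0 / 6.5 / 8.0 dB (single; the 30 μm value 1.6×
the 10 μm value) and 6.5 / 7.5 / 8.45 dB (trains; 1.3×). The absolute dB
levels are free parameters chosen once in the few-dB range typical of
such recordings; only the ratios are calibration targets. Calibration was
performed by fixed-point iteration on a dedicated calibration seed at
n = 800 cells/diameter, separate from any seed used in tests.

**Estimator biases, measured and accepted.** With 5 repeats × 8
geometrically spaced levels (CIC/12 to CIC), the lowest-crossing
threshold estimator carries a systematic −5 to −8% bias (early noise
crossings with 0.2-quantized probabilities, plus the spontaneous
contamination shift); population medians at n = 60 therefore recover
generative medians to within ~15%, sampling noise included. About 7% of
truly non-responsive cells acquire a spurious threshold from spontaneous
spikes alone, inflating the recovered responsive fraction by ~4
percentage points at p_resp = 0.47. Both effects are properties of the
estimator definitions, not implementation artifacts; tests budget for
them and real recordings share them.

**Determinism.** Every stochastic routine takes an explicit seed; cells
and trials use spawned substreams so each is reproducible from
(parameters, seed, index). The pipeline derives per-stage seeds from one
top-level seed via named substreams.

## What the synthetic tests do and do not show

Passing tests demonstrate that the analysis recovers the generative
structure it assumes: linear-circuit electrochemistry, logistic
recruitment with saturating counts, Poisson spontaneous activity. They do
not validate the models against real tissue — no electrode Faradaic
kinetics, no biophysical spike generation, no distance- or
field-dependent recruitment, no oscillatory spontaneous activity, no
cell-type structure. The field model is quasi-static and homogeneous; no
time dependence, no retinal layering, no multi-electrode interaction.

## Problem sizes

Default study sizes: 60 cells/diameter for threshold and dynamic-range
recovery (240 for the dynamic-range ratio check, where the mean-of-ratios
noise at 60 would dominate the 10% check margin), 400 cells for the
responsive-fraction estimate in the acceptance report, 8 charge levels ×
5 repeats per cell, a 132×132-node field grid. These sizes put sampling
noise comfortably below the tolerances they are tested against.
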
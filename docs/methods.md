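# Methods

This note documents the physical model, the calibration constants, the
synthetic-data generator, the numerical choices and the known limitations of
the package. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Physical model and assumptions

A blood pool on a non-porous surface is treated as a gravity-flattened
pancake: its lateral extent (centimetres) is far above the capillary length
√(γ/ρg) ≈ 2.4 mm, so the height h is taken uniform, V = m/ρ and h = V/A.
Blood behaves as a colloidal suspension that gels shortly after deposition;
after gelation, water evaporates at the surface at a rate set by vapour
transport, while the drying front — the edge between wet red and dried dark
blood — recedes from the rim toward the centre. Evaporation leaves a dry
biological deposit of fraction 0.23 of the initial mass.

Edge geometry is captured by the shape factor L\* = A/(hP). The areal
evaporation rate is modelled as

J\* = D · M · P_w(T) / (L_k · R · T · √L\*),

with L_k = kT/(πd²P_a) the Knudsen layer thickness. The inverse weighting
J\*·R·T·L_k·√L\*/(M·P_w) maps measured wet-area rates of pools of different
sizes and shapes onto a common diffusion-coefficient plateau; the calibrated
plateau level for drying whole blood at ~23 °C / 20 % RH is
D_blood = 1×10⁻⁹ m² s⁻¹. The apparent contact angle of a flattened puddle
follows from the edge force balance 1 − cos θ = ρgh²/(2γ) with h = m/(ρA),
i.e. θ = arccos(1 − g·m²/(2γρA²)); the argument is range-checked and an
out-of-range pool (too heaped for the pancake limit) raises an explicit
error rather than being clamped. A superficially similar form with the
opposite sign of the mass term has circulated; it is undefined for any
positive mass, which is why the derivation above is used.

The wet area and the remaining mass are linked by the empirical normalised
relation m/mᵢ = 1 − α[1 − A/Aᵢ]^β with α = 0.78, β = 0.16. Composing the
stages (height prior → mᵢ = hAᵢρ → L\* → J\* → m_x from A_x →
δt = (mᵢ − m_x)/(J\*Aᵢ)) yields the closed-form age

t_x = α·R·k_B·T²·√Aᵢ·√h·ρ·[1 − A_x/Aᵢ]^β / (M·d²·π·√P·D_blood·P_w·P_a),

and the package proves the two routes numerically identical (relative error
below 1e-10 over random parameter sweeps in the test suite).

## Parameters, units, defaults

All internal quantities are strict SI; g, mm², °C and % are converted at the
I/O boundary.

| parameter | default | unit | note |
|---|---|---|---|
| ρ (whole blood) | 1060 | kg m⁻³ | literature value; configurable |
| γ (blood/air) | 0.058 | N m⁻¹ | literature value; configurable |
| M (water) | 0.018015 | kg mol⁻¹ | |
| d (water molecule) | 2.75×10⁻¹⁰ | m | kinetic diameter |
| residual mass fraction | 0.23 | – | dry deposit after complete drying |
| D_blood | 1×10⁻⁹ | m² s⁻¹ | plateau at ~23 °C / 20 % RH, non-porous |
| α, β (mass–area) | 0.78, 0.16 | – | normalised-curve fit constants |
| tile height prior | 1.44 ± 0.19 | mm | repeat measurements on tile |
| plateau window | [0.35, 0.85] | water fraction | see below |
| MC draws / coverage | 2000 / 0.90 | – | median point estimate |

P_w(T) uses the Buck correlation (error ≪ 0.1 % over 0–100 °C, far below
every other term); it is a swappable callable for users who prefer another
correlation. Humidity does not enter J\* explicitly — the calibrated
D_blood absorbs the ambient RH of the calibration conditions. An optional
`use_humidity_deficit` flag multiplies P_w by (1 − RH) as a documented
extension, off by default; it is an uncalibrated research mode.

Because D_blood is condition-specific, the estimator refuses to run outside
22–24 °C or 15–25 % RH unless `force=True`, in which case the report carries
explicit warnings.

## Estimator design choices

- **Flux-bearing area.** The age formula uses the total area Aᵢ in
  δt = δm/(J\*Aᵢ), even though the rate plateau is established on the
  wet-area basis. This is the calibrated estimator and the default. A
  wet-area-basis variant, which integrates dt = dm/(J\*·A_wet(m)) along the
  mass–area relation (with the substitution w = u^β so the integrand is
  smooth at the fully-wet end), is available behind `flux_basis="wet"` for
  research into this internal tension; the two bases are not interchangeable
  and only the total basis matches the calibration.
- **Uncertainty.** Monte Carlo over a positively-truncated normal height
  prior and multiplicative Gaussian measurement noise (default 2 % relative
  sd on areas and perimeter). Point estimate: median of draws — the mean is
  biased under the √h nonlinearity and the clipping at the fully-wet end;
  the median is invariant under the monotone map from noise to age.
  Interval: central 90 % of draws.
- **Multiple snapshots.** Each snapshot i gives a formation-time draw
  (capture time minus age); per draw the median across snapshots aligns them
  to a common formation time, so repeated photographs as the pool dries
  average the error down.
- **Guards.** A_x = Aᵢ (no front yet) and A_x = 0 (fully dried) raise
  distinct advisory errors: the method needs a visible front.

## Drying-curve analysis choices

- **Differencing.** Evaporation rates use centred finite differences on the
  raw, possibly irregular time grid, divided by the basis area interpolated
  at the evaluation time; no resampling, so no resampling artefacts.
  Optional Savitzky–Golay smoothing (order 2) of the mass channel is off by
  default.
- **Plateau estimation.** Median and median absolute deviation over the
  water-fraction window [0.35, 0.85]. The early excursion (pre-coagulation
  dynamics) and the late tail (wet-area measurements become unreliable, and
  the rate falls as evaporation moves inside the porous deposit) are
  asymmetric, which is why a robust location estimate is used and the window
  excludes both ends.
- **Mass–area fit.** Bounded nonlinear least squares (α ∈ (0,1), β ∈ (0,2],
  start (0.8, 0.2)). The model is anchored at (1, 1) by construction. Note
  that dm/dA diverges as A/Aᵢ → 1, so β is poorly constrained by noisy
  points near the fully-wet end; fits over several pools, or over noiseless
  simulated curves, recover the constants sharply, while a single noisy
  record constrains α well and β only loosely. Normalised ratios are
  accepted up to 5 % beyond [0, 1] (measurement noise) and clipped.
- **Shape-linear fit.** Ordinary least squares of J\*/L\* on θ, with the
  per-pool J\* averaged after 50 % of the initial mass has evaporated so the
  slow final stage does not bias the mean.

## Image pipeline

Segmentation classifies blood pixels by red dominance (R − max(G, B)), which
captures both the saturated wet red and the dark dried red-brown while
rejecting a neutral background and the neutral reference bar; speckle is
removed by opening, gaps closed, interior holes (cracks photograph
near-black) filled, and the largest connected component kept. The wet/dry
split inside the pool is an Otsu threshold on the value channel with two
absolute-reference guards so a fully-wet or fully-dry pool is not split
arbitrarily. Perimeter uses the multi-directional Crofton estimator —
boundary-pixel counting overestimates raster perimeters by up to ~27 %.
Areas are pixel counts times the squared scale; the scale is entered
manually (reference length in pixels), automatic ruler detection is out of
scope. Frames whose wet fraction falls below 10 % are flagged
`tail-unreliable`: near the end the contrast degrades and wet-area estimates
should not be trusted.

The pipeline is validated only against the synthetic renderer (below); real
photographs bring lighting gradients, specular highlights and substrate
texture that the renderer does not model, so the shipped thresholds are a
starting point, not a guarantee.

## Synthetic data generator

The simulator emulates the calibration experiments: pools of 0.1–50 g
(presets span 0.30–31.37 g; the shape-study preset draws twenty masses
within 5.24 ± 0.47 g) on tile at 23 °C / 20 % RH, sampled every 120 s to
match two-minute time-lapse photography. Boundaries are circles perturbed
by low-order Fourier modes (k = 2–6, amplitude ∝ irregularity), rescaled to
the exact pancake area m/(ρh); polygon area and perimeter are exact
(shoelace / segment sums, 720 vertices, so a zero-irregularity circle meets
P = 2√(πA) to < 0.1 %). Mass falls linearly at J\*Aᵢ to the residual
plateau (total-area flux basis, matching the estimator so the noiseless
round trip is exact); the wet area follows the inverted mass–area relation.
The residual fraction (0.23) and the fit limit (1 − α = 0.22) differ by
0.01; the simulator stops at the residual fraction, where the inverted fit
still leaves a positive wet area (~7.7 % of Aᵢ), honouring both constants.
A wet-area-basis mode integrates dm/dt = −J\*A_wet(m) with fine-step RK4;
in that mode the wet-basis rate series is constant at J\* by construction,
which makes the weighted-rate collapse onto D_blood a testable property
(`SimulationResult.true_rate_series` exposes the exact flux channel as the
oracle for the finite-difference estimator).

Observation noise: 2 % relative sd on areas (repeat photographic
measurement), 1×10⁻⁵ kg on mass (0.01 g balance precision), all from a
seeded generator; the seed fully determines every output, shapes and noise
drawn from independent child streams.

The renderer draws the pool silhouette, a dried annulus and a wet core
obtained by thresholding the Euclidean distance transform of the pool mask —
a uniform inward offset of the boundary, matching a front that recedes
toward the centre — with the threshold chosen so the core pixel count equals
the simulated wet area to within one pixel. Ground-truth masks are emitted
with every frame. The renderer does **not** model the true front physics
(non-uniform recession, serum separation), illumination gradients or crack
mechanics beyond a decorative texture; passing image tests therefore
demonstrate the segmentation logic, not field robustness.

The simulator omits the brief pre-coagulation rate dip seen in early drying;
plateau-window tests on simulated data exercise the window logic through
the late tail only.

## Problem sizes used in tests and the acceptance script

Simulated records run at their natural cadence (120 s; 600 s for the
50-pool cohort, whose estimates need only one snapshot each); rendered-image
tests use 20 frames at 256×256 px across five shapes; Monte-Carlo estimates
use 500–20000 draws depending on how tight the assertion is. The whole
suite and the acceptance script each run in well under a minute on one CPU.

## Known limitations

- Calibrated for non-porous surfaces and ~23 °C / 20 % RH only; no
  temperature/humidity reference table exists yet, and porous or absorbent
  substrates, pooled-with-body scenarios and anticoagulated blood are out of
  scope.
- The height prior ships only for tile; other surfaces need user priors.
- The exact ρ and γ of the calibration experiments are unknown; defaults
  are literature values and configurable.
- The tension between the wet-area-basis rate plateau and the total-area
  age formula is inherited from the calibration, not resolved here; both
  modes are implemented and documented.
- Coagulation chemistry, thermal transients and crack-pattern morphology
  are not modelled.
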
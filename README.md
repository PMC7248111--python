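# bloodpool

Forensic dating of drying human blood pools from photographs of the
advancing drying front.

## The problem

When a blood pool is found at a crime scene without a body, none of the
usual time-of-event methods (body temperature, rigor mortis, entomology)
apply, yet the time at which the pool was formed can be decisive for the
timeline. A drying pool offers its own clock: desiccation starts at the
triple line and a visible front — the transition between red (wet) and
dark (dried) blood — recedes toward the centre at a rate set by simple
evaporation physics. This package turns calibrated plan-view photographs of
that front into an estimate of the time since deposition, with uncertainty,
for pools on non-porous surfaces (tile and similar) in indoor conditions
near 23 °C and 20 % relative humidity.

It is written for bloodstain-pattern analysts and researchers in biofluid
drying: the field tool needs nothing but photographs and a reference length,
and every stage of the pipeline (segmentation → geometry → evaporation model
→ age) is also exposed as a library and validated end-to-end against a
forward simulator.

## The model

A blood pool is intermediate between a sessile drop and an open stretch of
liquid: gravity flattens it into a pancake of nearly uniform height
*h* ≈ 1.44 mm on tile, but the drying front makes edge geometry matter.
The pipeline composes:

1. **Shape factor** — L\* = A / (hP), with A the plan area and P the
   perimeter: compact pools (large L\*) evaporate more slowly per unit area
   than thin, stretched ones.
2. **Evaporation rate** — from an effective vapour diffusion coefficient
   D_blood = 1×10⁻⁹ m² s⁻¹ (the plateau value onto which measured wet-area
   rates collapse once weighted by R·T·L_k·√L\*/(M·P_w)):

   J\* = D_blood · M · P_w / (L_k · R · T · √L\*)   [kg m⁻² s⁻¹]

   where L_k = kT/(πd²P_a) is the Knudsen layer thickness, M the molar mass
   of water and P_w(T) the saturation vapour pressure (Buck correlation).
3. **Mass–area relation** — the empirical collapse of normalised drying
   curves, m/mᵢ = 1 − α[1 − A/Aᵢ]^β with α = 0.78, β = 0.16, converts the
   measured wet area A_x into the remaining mass m_x.
4. **Age** — with mᵢ = hAᵢρ, the elapsed time is δt = (mᵢ − m_x)/(J\*·Aᵢ),
   or equivalently in closed form

   t_x = α·R·k_B·T²·√Aᵢ·√h·ρ·[1 − A_x/Aᵢ]^β / (M·d²·π·√P·D_blood·P_w·P_a).

Uncertainty is propagated by seeded Monte Carlo over the surface height
prior (tile: 1.44 ± 0.19 mm) and area/perimeter measurement noise; the
package refuses to report outside the calibration conditions (22–24 °C,
15–25 % RH) unless forced. See `docs/methods.md` for assumptions,
parameters and limitations.

## Worked example

A pool on tile at 22.5 °C, measured from a photograph (or entered directly):
total area 3000 mm², wet area 2000 mm², perimeter 210 mm.

```bash
bloodpool --seed 1 estimate-age --ai-mm2 3000 --ax-mm2 2000 --p-mm 210 \
          --temp-c 22.5 --rh 0.20
```

prints (abridged):

```json
{
  "age_s": 26691.85,
  "age_hms": "7:24:52",
  "interval_s": [23442.60, 29642.50],
  "interval_hms": ["6:30:43", "8:14:02"],
  "coverage": 0.9,
  "method": "closed_form",
  ...
}
```

The pool was formed an estimated 7 h 25 min before the photograph, with a
90 % interval of roughly 6 h 31 min – 8 h 14 min; the interval width is
dominated by the ±0.19 mm height prior (age scales as √h). The full report
echoes every constant, parameter and flag used — a forensic estimate must be
auditable.

Other entry points: `bloodpool simulate` (forward-simulate drying records
and rendered photo sequences), `bloodpool segment` (masks and calibrated
measurements from one image), `bloodpool analyze` (rate series and plateau
from a CSV record), `bloodpool fit` (mass–area fit across records).

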
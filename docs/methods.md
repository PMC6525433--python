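# Methods

## Model

The package simulates energy-taxis-driven aerotaxis in a 1-D capillary
[0, S]. Two advecting populations (right-movers R, left-movers L, constant
speed v) exchange through direction reversals whose frequency is a
piecewise-constant function of the local oxygen concentration C, expressed in
percent of air oxygen. Four thresholds order as Ĉ_min < C_min < C_max <
Ĉ_max: right-movers reverse at the high frequency for Ĉ_min < C < C_max,
left-movers for C_min < C < Ĉ_max, and both otherwise at F_min. The overlap
(C_min, C_max) traps cells (both directions reverse rapidly) and is where the
band forms; below Ĉ_min or above Ĉ_max both populations run and disperse.
Within the currently detected band the high frequency is the separately
measured in-band value F_max,band; the low-frequency branch is never
overridden. Threshold comparisons are strict: C exactly equal to a switch
value takes the low branch. This is a measure-zero choice in the continuum
but makes discrete tie-breaking deterministic.

Oxygen obeys ∂C/∂t = D ∂²C/∂x² − K θ(C) B with B = R + L, Dirichlet C_o at
the meniscus face x = 0, zero flux at the sealed end, and C(x,0) = 0
(the assay equilibrates the capillary under nitrogen before air is applied).
The gate θ stops consumption in depleted cells. Swimmer boundary conditions
reflect each population into the other (R(0) = L(0), R(S) = L(S) in flux
form), so the total number of bacteria is exactly conserved. Cell growth is
neglected: band formation (minutes) is much faster than division.

Switch thresholds live in percent units throughout; the oxygen state is
stored in μM and converted with the Henry's-law factor (1300 μM per unit
fraction of air oxygen, i.e. 13 μM per 1%; the literature-comparison
parameter set uses 1200). Keeping the conversion out of the switching logic
lets the comparison runs swap the factor without touching the model core.

## Parameters

Defaults are the experimentally determined wild-type values:

| symbol | meaning | default | units |
|---|---|---|---|
| B_o | total cell density | 7×10⁸ | cells/ml |
| C_o | oxygen at meniscus | 21 | % air oxygen |
| D | oxygen diffusivity | 2000 | μm²/s |
| K | per-cell consumption | 4×10⁻⁹ | μM·ml/(s·cell) |
| v | swimming speed | 20 | μm/s |
| F_max,band / F_max / F_min | reversal frequencies | 0.96 / 0.65 / 0.35 | 1/s |
| Ĉ_max / C_max / C_min / Ĉ_min | C-switches | 10 / 2 / 0.3 / 0.01 | % |
| S | capillary length | 5000 | μm |

The in-band/outside distinction in F_max reflects single-cell tracking, which
finds markedly higher reversal rates inside the band. Hydrodynamic mixing by
swimmers is negligible next to molecular oxygen diffusion, so D is fixed.

## Numerics

First-order conservative upwind finite volumes for advection, explicit
central finite volumes for diffusion, forward-Euler in time, integrated
dimensionally. The default mesh is 128 control volumes per mm (640 cells;
dx = 7.8125 μm). The step is safety × min(dx/v, dx²/(2D)) with safety = 0.9;
for the defaults diffusion binds (dt ≈ 0.0137 s, ~21 800 steps per 300 s,
about 3 s of wall time). Steps are additionally clipped to land exactly on
requested output times, and halved-and-retried if a step would produce
negative values (never triggered under the default bound). Consumption is
clamped per cell to the oxygen actually available, min(K·B·dt, C), which
preserves non-negativity exactly; at the default step the clamp and a
consume-then-truncate variant give identical results to the digits reported.
The meniscus Dirichlet value acts on the boundary face (half-cell gradient);
against the closed-form erfc invasion profile at 50 s the oxygen solver is
accurate to 0.07% locally.

Each step proceeds: detect band from the current B profile → transport update
using that band for the frequency override → oxygen update → advance time.
A cell is "in the band" when its center lies within [xL, xR]; sub-cell
weighting would be spurious at first order. Before any band qualifies the
outside-band F_max applies everywhere. Total bacterial mass is conserved to
~10⁻¹⁵ relative over 600 s (tolerance asserted: 10⁻⁹), and 0 ≤ C ≤ C_o holds
at every step.

Band detection intersects the density profile with the horizontal line at
half its maximum (absolute, not background-subtracted; a subtracted variant
is available but off by default) and takes the outermost crossings bracketing
the global maximum, each located by linear interpolation between cell
centers. A band qualifies only when the peak exceeds 1.5× the background
(median density outside the FWHM support); otherwise the near-uniform early
profile would put the half-max line under the whole domain. The base-case
readouts are insensitive to this ratio anywhere in [1.2, 2]. The 50/50
initial split of R and L is reaction-neutral; any split with R + L = B_o
relaxes within a few reversal times.

## Experiment drivers

* **Base case**: wild-type defaults to 600 s. Produces a band that forms
  within ~10 s, stabilises within two minutes, and sits at 414.1 μm with
  width 135.4 μm and peak 2.9×B_o at 300 s, drifting 0.02 μm between 300 s
  and 600 s. Oxygen across the band spans 0.07–3.18% (≈1–41 μM).
* **Comparison parameters**: the earlier literature parameter set (lower
  density and consumption, faster swimming, narrower favourable window,
  Henry factor 1200). The band keeps moving: 1528 μm at 300 s, 1781 μm at
  600 s. A run is labelled "moving" when the 300→600 s drift exceeds 50 μm —
  two orders of magnitude above the base case's drift and far below the
  comparison run's, so the verdict is insensitive to the threshold.
* **Sensitivity sweep**: one parameter at a time, all others at base, each
  row a fresh 300 s run; percent changes are taken against the computed base
  row. Rows also report a smoothness diagnostic: the count of band-side
  movements exceeding one cell width between consecutive steps after the
  120 s formation transient (the qualitative "wavy vs smooth" judgement made
  quantitative). Failed rows are reported as failed, never dropped.
* **Switch identification**: exhaustive search over an ordered candidate grid
  for the four C-switches, scoring each candidate's 300 s band by the
  Euclidean residual of (location, width) against the target. The response
  surface is piecewise-constant in the switches, so gradient methods are
  inappropriate; the driver reports whether the best candidate is unique
  within a residual tolerance (identification from location and width alone
  is otherwise ill-posed).

## Known limitations

* First order in space and time by design; the band profile carries both
  physical smearing (telegraph-process diffusivity v²/2f ≈ 300 μm²/s) and
  numerical smearing (≈ v·dx/2 = 78 μm²/s at the default mesh). Band width
  at 300 s decreases from 135.4 to 125.4 μm when the mesh is doubled to
  256 cells/mm, while location moves 414.1 → 408.1 μm (−1.4%); reported
  geometry is therefore mesh-sensitive at the few-percent level.
* Oxygen readouts at the band sides sit on a steep gradient (~0.03%/μm), so
  small positional differences translate into visible concentration
  differences; they should be read as band-relative physiology (right side
  near Ĉ_min, middle inside the favourable window, left side just above
  C_max), not as absolute values beyond a few hundredths of a percent.
* The band-feedback loop has mild hysteresis: a −50% perturbation of Ĉ_min
  (0.01 → 0.005%) leaves a persistent one-cell (−1% location, −6% width)
  shift imprinted during formation, although the corresponding +50%
  perturbation changes nothing. The depletion front's quadratic touch-down
  separates these tiny-concentration contours by only ~8 μm.
* Strictly 1-D: no capillary cross-section effects, no cell growth or death,
  no hydrodynamic coupling, and a piecewise-constant (not sigmoidal)
  frequency response.
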
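# Methods

## Model structure and assumptions

`aedespop` simulates a closed *Aedes albopictus* population (no immigration
or emigration) on a homogeneous surface of at least 4 ha — the square whose
side exceeds twice the ~100 m active flight range, so that neglecting
dispersal is defensible. Only adult females are tracked after emergence; the
sex-ratio σ removes males at emergence. The ten compartments and their
couplings are listed in the README; three structural assumptions matter
most:

* **Hard diapause switch.** Egg hatching is off between `t_end` and
  `t_start` (day-of-year dates, defaults 30 September and 10 March). Field
  populations enter dormancy gradually over weeks; the model collapses this
  into a date. All other stages keep developing and dying through winter,
  which empties them within weeks of `t_end` because aquatic mortality
  `exp(−T/2) + μ_X` is large in cold water and egg maturation stops below
  `T_Ag` = 10 °C (which also shuts down oviposition, so the winter egg pool
  decays at exactly μ_E — a property the tests exploit).
* **Density dependence** acts twice: larval mortality is multiplied by
  `1 + L/k_L`, and emergence success is `exp(−μ_em (1 + P/k_P))`. Both
  capacities are per-hectare constants κ_X scaled by the simulated area and
  inflated up to two-fold by the normalised two-week rain sum.
* **Air temperature stands in for water temperature**, justified by the
  small urban containers the species breeds in.

## Parameters

Defaults (changeable via YAML config with the same names): β₁ = 95 and β₂ =
75 eggs per oviposition (nulliparous/parous); κ_L = κ_P = 250,000 ha⁻¹
(reconstructed as 10 individuals cm⁻² × 50 cm² per breeding site × 20 sites
per household × 25 households ha⁻¹); σ = 0.5; mortalities (day⁻¹) μ_E =
0.05, μ_L = 0.08, μ_P = 0.03, μ_em = 0.1, μ_A = 0.02, plus μ_r = 0.08 added
to the host- and oviposition-site-seeking stages; degree-day pairs T_E =
10.4 °C / TDD_E = 110 °C·day (egg development) and T_Ag = 10 °C / TDD_Ag =
77 °C·day (egg maturation in engorged females); gonotrophic transition rates
γ_Aem = 0.4, γ_Ah = 0.2, γ_Ao = 0.2 day⁻¹; season bounds t_start = 10 March,
t_end = 30 September. σ = 0 is accepted as a degenerate diagnostic case (no
females, hence no oviposition ever).

## Rainfall machinery

`P_norm(t)` is the trailing 14-day rainfall sum (days t−13…t), min–max
rescaled over the whole supplied series to [0, 1]; the first 13 days take
the first full-window value, and a constant-rainfall series degenerates to
all zeros. Whole-series scaling was chosen because simulations run on full
multi-year records; a trailing window preserves causality.

Egg hatching is gated by water availability in two modes. In the default
mode, hatching during spring (season start to `spring_end`, default 30 June)
requires a rainfall event (P > 0 mm); for the rest of the favourable season
the gate is dropped on the assumption that garden watering keeps urban
containers flooded through the dry Mediterranean summer. The exact calendar
end of the rain-gated regime is nowhere pinned down by data; 30 June sits
between the wet spring and the dry high summer and is exposed as
configuration. The alternative `rain_threshold` mode gates hatching on
P strictly above a threshold (0, 2, 4 mm …) all season long — the
counterfactual used to probe the artificial-flooding assumption; under it,
dry summers collapse the population by several orders of magnitude.

## Numerics

The system is discretised with the explicit Euler method. The default step
is 0.1 day: the stiffest rate in the system is larval mortality at 0 °C
(≈ 1.08 day⁻¹), which makes a full-day step marginally stable, while 0.1 day
keeps all per-step rate×dt products ≤ ~0.11. Forcing is evaluated once per
calendar day and held constant over the ten sub-steps; the daily trajectory
records the state at the end of each day. Any component driven below zero by
an Euler undershoot is clamped to zero. On leap years, 29 February reuses
28 February forcing for the spin-up climatology, and season dates live on a
365-day calendar (29 February folds onto day 59).

Convergence is first order, verified by Richardson comparison (the dt = 0.05
error is about half the dt = 0.1 error). On an exponentially growing
trajectory the accumulated bias between dt = 0.1 and dt = 0.05 is about
∫λ²/2 dt × Δdt ≈ 1% per simulated year of the annual adult peak — small for
within-year phenology, visible when comparing absolute abundances across
several compounding years. The integrator is vectorised across parameter
sets, so a single run and the 2,186-scenario design share one code path; a
unit test pins the two to 13 significant digits.

## Synthetic weather

The generator emulates the coastal Mediterranean climate the model was built
for: daily mean temperature is a sinusoid with its minimum (~0 °C) in
mid-January and maximum (~34 °C) in mid-July plus AR(1) noise (sd 1 °C,
autocorrelation 0.6), clipped to [−5, 40] °C; rainfall is an independent
Bernoulli wet-day indicator with monthly probabilities (dry summers, wet
autumns) times Gamma amounts, with the monthly structure solved analytically
so the expected annual total is 750 mm. The spin-up "average year" is the
day-of-year climatology of the supplied record.

What it does **not** reproduce: rain-spell persistence (wet days are
independent), the diurnal temperature cycle, and — importantly — the
distinction between extreme and mean temperatures. Anchoring the *daily
mean* cycle at 0 and 34 °C yields Septembers near 25 °C, several degrees
warmer than a real coastal autumn. Two visible consequences, both computed
by the tests and the acceptance script rather than asserted from outside:

* The population **declines across years** (roughly an order of magnitude
  per year): winter egg survival is exp(−μ_E × ~165 d) ≈ 3 × 10⁻⁴, and the
  realised seasonal amplification under this climate (~10²) does not
  compensate. The population therefore never saturates its carrying
  capacities, and density-dependent parameters (κ_L, κ_P, μ_em's
  density term) have correspondingly small influence.
* The **adult peak sits at the very end of the favourable season**
  (1–3 October): at 25 °C September growth is strongly positive, so the
  adult stock keeps rising until hatching stops at `t_end` and the aquatic
  pipeline empties over the following two or three days. Under a record
  with cool Septembers, or in a capacity-saturated population, the peak
  detaches from the season end and moves into late August.

Passing tests on this generator therefore demonstrate the mechanics of the
model — rate functions, diapause bookkeeping, density-dependence signs,
integrator accuracy, output definitions — not that any particular real
population is stable or peaks on a particular date.

## Aggregated outputs and validation

The adult peak is the maximum of the seven-compartment adult total within a
calendar year, earliest date on ties. The attack rate averages A_h over the
21 days centred on the peak, truncated (not padded) at year bounds. The
parity rate is the favourable-season total of parous females over the total
of all females; emerging adults A_em count in the denominator ("total
females" read literally — they are females, merely unclassified). The
spin-up year is excluded from all outputs.

Validation samples the oviposition flux E_l at the ovitrap collection dates
(traps are emptied at each visit, so the instantaneous daily flux is the
default match); an accumulate-between-visits mode exists because traps do
integrate egg laying between collections, but it is off by default. Both
series are divided by their maxima before the Pearson correlation, making
the comparison scale-free.

## Sensitivity analysis

All 20 parameters vary over three levels — nominal and ±10%, with the two
calendar dates shifted by ±10% of their day-of-year, rounded to whole days —
in a regular 3^(20−13) fractional factorial. The 13 generator vectors over
GF(3)⁷ were found by randomised search subject to every four columns of the
7×20 alias matrix being linearly independent, i.e. the fraction has
resolution V; the coded model matrix (intercept, 20 linear main effects, 190
pairwise products) is exactly orthogonal and full rank on the 2,186
scenarios (the all-nominal run is removed from the design and simulated
separately as the reference). Variance contributions are sequential sums of
squares obtained from a QR decomposition — on an orthogonal design these are
order-invariant, and they sum to the regression r² by construction. Terms
above 1% of output variance are retained. Scenario simulations that produce
non-finite outputs are flagged, never silently dropped; the decomposition
refuses to run if more than 5% fail.

Because the default synthetic climate keeps the population far below its
carrying capacities, the retained set is dominated by parameters of the
multiplicative seasonal loop (t_end, σ, μ_E, β₁, γ_Ah, …) rather than the
density-dependent ones (κ_P); the expected-influence check for the
density-linked parameters is accordingly a warning, not a failure.

## Known limitations

Deterministic dynamics (no demographic noise); no dispersal or spatial
heterogeneity; hard on/off diapause; constant year-round egg mortality
(winter survivorship is likely underestimated); wet-day independence in the
weather generator; no pathogen transmission layer. The printed step dt and
the daily forcing resolution bound the temporal fidelity to ~1 day.
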
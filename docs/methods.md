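# Methods

This note records the model, its assumptions, the defaults and why they
were chosen, and what the synthetic inputs do and do not emulate.

## Scope and design stance

`chemrisk` is a desk-scale re-engineering of the class of multimedia
accident-consequence models that couple an atmospheric dispersion core to
a surface-soil compartment and a population dose module. It is **not** a
port of any operational system: the dispersion core, deposition scheme
and re-volatilization hook were designed from standard building blocks
(Gaussian puffs, Pasquill–Gifford sigmas, constant deposition velocity,
first-order losses) so that every term is inspectable and the whole chain
is testable against closed-form oracles. Exact reproduction of any
particular operational model's concentration fields is a non-goal; the
qualitative structure (downwind plume, soil build-up and slow dissipation,
a finite exposure window, the cross-age-group risk algebra) is the point.

## Air transport

* One puff is emitted per integration sub-step during the release
  (release mass apportioned uniformly over the release duration).
* Advection: each sub-step the puff centre moves `u · Δt` toward
  `wind_from + 180°`. Stability class and wind are piecewise-constant
  over each meteorological hour.
* Spread: σ_y from the Briggs open-country interpolation of the
  Pasquill–Gifford curves, driven by the puff's cumulative travel
  distance under the *current* stability class (a standard desk-scale
  simplification; a virtual-distance scheme would track class history).
* Vertical treatment: uniform mixing through the surface layer height
  *H* (default 10 m). σ_z is computed and carried but unused; with a
  10 m assessment layer a reflection stack adds nothing testable.
* σ_y floor of `dx/2` (50 m at the default grid): below that the
  cell-centre discretisation of the kernel can place more than one
  cell-integral of mass into a single cell, which would let a deposition
  debit exceed the puff's content.
* Losses: first-order decay in air (default 0.0144 h⁻¹ ≈ 2-day
  half-life, the OH-reaction scale for benzyl chloride); export when the
  centre passes a 5 km buffer beyond the domain (bounded memory,
  negligible return flow at the default winds).

### Sub-stepping and segment integration

The surface-loss rate `v_d/H` is 1.8 h⁻¹ at the defaults, so an explicit
one-hour deposition step would remove more mass than a parcel holds.
Hours are therefore integrated in 6 sub-steps of 600 s (explicit Euler,
per-sub-step removal ≤ 30 %). Independently, a puff at 2.5 m/s travels
1.5 km per sub-step — many cells — so evaluating its kernel only at the
end point would deposit in punctate spots along the track. Each
sub-step's kernel is instead averaged over midpoint samples spaced at
most `dx/2` apart along the advection segment, with σ_y growing along
it: the line-segment ("slug") treatment of a moving source. The
single-position evaluation remains available as the elementary
`step_hour` operation.

## Soil compartment

* Receptor: a surface layer with bulk density 1,300 kg/m³ and mixing
  depth 1 cm — conventional screening values for surficial contamination
  relevant to incidental ingestion; both configurable.
* Deposition: flux `v_d · C` with constant `v_d` = 0.005 m/s. Deposited
  mass is debited puff-by-puff from the airborne pool, which is what
  closes the ledger identity
  `released = airborne + exported + decayed_air + (deposited − revolatilized)`
  to floating-point accuracy (the simulation tracks the worst hourly
  closure error; the suite requires < 1 %, observed ~1e−16).
* Decay: one first-order multiplication per simulated day.
* Re-volatilization (off by default): a first-order fraction of each
  cell's soil burden returns each hour to the local air column, where a
  per-cell ventilation box (`C = E / (u · Δt · dx · H)`, wind floored at
  0.5 m/s) converts it to a concentration before the mass is vented
  (booked as exported). The returned air does not advect between cells;
  this is deliberately the simplest mechanism that yields the observed
  phenomenology of a slowly decaying, soil-driven air signal after the
  primary plume is gone — which is what makes the last-exceedance
  endpoint rule non-trivial.

## Endpoint rule

The exposure window ends on the **last** day on which any cell's
daily-average air concentration strictly exceeds the atmospheric
background; equality counts as extinct. A first-crossing rule would
terminate at a transient dip and truncate the dose of everything that
rebounds afterwards — the re-volatilization pathway produces exactly such
dips. If the final simulated day still exceeds background the package
raises a horizon-too-short error rather than silently truncating the
window. The ppb→mg/m³ conversion uses a molar volume of 24.45 L/mol
(25 °C, 1 atm), configurable.

## Dose and risk

`LADD = IR · ΣC_soil / (BW · LT)` over days 1..endpoint, `ECR = LADD ·
CSF`. The typeset form of such dose equations is often ambiguous about
the denominator; division by the *product* BW·LT is the only reading
with correct mg/kg/d units and is the standard LADD convention. Packaged
exposure factors: intakes 80/80/40/40 mg/d, body weights
13.3/53.6/63.3/60.7 kg, shared lifetime 30,186 d; CSF 0.17 (mg/kg·d)⁻¹
for oral benzyl chloride. Zone thresholds 10⁻⁶ (red) and 10⁻⁷ (orange);
a tie at exactly 10⁻⁶ is classed red (the safety-conservative reading of
"at or above the acceptable-risk limit"). Summaries (max, mean, zone
percentages) are taken over **all** grid cells including zero cells;
green is computed as `100 − (red + orange)` so the three percentages
partition 100 exactly, and percentages are rounded half-up to two
decimals only at report time.

## Synthetic meteorology

The generator draws, per hour: direction from a wrapped normal around a
prevailing "from" direction; speed from a zero-truncated normal;
stability class from a fixed categorical distribution over A–F. Defaults
(315° ± 35°, 2.5 ± 1.2 m/s, weights 5/10/15/40/15/15 %) describe a
moderately windy mid-latitude winter regime with a north-westerly
prevailing flow, so plumes trend south-east. It is deliberately simple:
no diurnal cycle, no autocorrelation between consecutive hours, no
speed–stability coupling, no precipitation or humidity. Passing tests
therefore demonstrate the method's behaviour under a controlled,
statistically stationary wind climate — not fidelity to any real
meteorological archive, which the CSV reader exists to supply.

## The packaged full-scale example

`examples/ulsan_benzyl_chloride.yaml`: 40 t over 1 h at midnight,
160 × 120 cells of 100 m, 100-day horizon, generator seed 2017. The
example enables re-volatilization, and its two persistence constants
(soil decay 0.015 d⁻¹, re-volatilization 2.5×10⁻⁵ d⁻¹) are **scenario
calibrations, not chemical property estimates**: they are set, by a
deliberately documented derivation, so the deterministic example
exhibits the intended demonstration structure — an extinction endpoint
inside the horizon (day 85) *and* a non-empty red zone for every age
group. Those two requirements bound the total soil-loss rate from both
sides (the adult red zone needs the cumulative soil exposure at the
maximum cell to reach ~2.8×10⁵ mg/kg·d given the ~6.8×10³ mg/kg day-1
peak; the endpoint must still be crossed before the horizon), leaving a
narrow feasible band that the packaged values sit inside with ~15–20 %
margin on each side. Hydrolysis half-lives measured for benzyl chloride
in wet media are far shorter; a literal parameterisation would end the
scenario in days and demonstrate nothing about long-window assessment.

## Numerical and interface choices

* Grid indexing: cell (0,0) at the south-west; fields are `(ny, nx)`
  arrays with row 0 the southern row; concentrations at cell centres.
  ASCII-grid writers emit the north row first per the format.
* Daily air fields are the mean of 24 hourly fields; soil is recorded at
  end of day after its daily decay.
* Everything is linear in release mass (superposition), which the suite
  checks exactly and which makes the cross-group calibration in
  `scripts/acceptance.py` a one-scalar operation.
* Determinism: a single integer seeds the generator; identical config +
  seed reproduce byte-identical summaries.
* Problem sizes: the test suite runs the miniature 20 × 15 / 10-day
  scenario for physics and pipeline checks (sub-second) and the full
  160 × 120 / 100-day example once per session (~1 s of simulation;
  puffs persist only hours, after which each hour is one vectorised
  per-cell update).

## Known limitations

* No terrain, no wet deposition, no puff splitting, no nested fine grid;
  a single uniform grid.
* No water compartment and no non-cancer (hazard-quotient) endpoint;
  soil-ingestion is the only chronic pathway, with dermal and inhalation
  excluded by construction.
* Re-volatilized air does not advect; near-field secondary
  concentrations are box-model estimates, adequate for endpoint timing,
  not for exposure via inhalation (which is out of scope anyway).
* The stability class applied to a puff is the current hour's, not the
  history-weighted one.
* Whole-domain averaging for the mean ECR is a design choice; restricting
  to on-plume cells would raise means substantially.
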
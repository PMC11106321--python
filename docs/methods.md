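# Methods

This note records the models, conventions, parameter choices and known
limitations behind `peatflux`, in the order the pipeline runs.

## Chamber flux computation

A closed chamber of system volume *V* (m³) sealed on a collar of area *A*
(m²) accumulates gas at a rate proportional to the surface flux. The mole
fraction is modeled as linear in time over the analysis window; nonlinear
(exponential) chamber fits are deliberately out of scope — the linear fit on
a short window is the chosen estimator throughout.

* **Dead band and stop time.** Samples with 10 s < *t* ≤ 120 s enter the
  fit (defaults; both configurable). The dead band discards placement and
  mixing artifacts. At the default 1-Hz cadence this is 110 points; fewer
  than 3 in-window points is a fit failure (run excluded, logged).
* **R² convention.** For a zero-variance (constant) response, R² is defined
  as 0, so flat series deterministically fail QC. Textbook R² is undefined
  there; the pipeline needs a deterministic verdict.
* **Gas-law conversion.** flux = slope · P·V/(R·T·A) with P in Pa and
  R = 8.314462618 J mol⁻¹ K⁻¹. Chamber geometry and pressure are run
  metadata, not constants (defaults: V = 0.0058 m³, A = 0.0318 m² — an
  8-inch-collar smart-chamber configuration; P = 101.325 kPa when
  unmeasured). No water-vapor dilution correction is applied; whether
  instrument software applies one is instrument-specific, so fluxes here are
  defined on the measured (wet) mole fraction.
* **QC thresholds.** R² strictly greater than 0.9 (CO₂) and 0.7 (CH₄).
  Strict inequality makes the boundary case deterministic.
* **Outlier screen.** Within each site × gas × calendar-month group of
  QC-passing records, values outside median ± 3·IQR are flagged and excluded
  downstream (retained in outputs with a flag). Groups with fewer than 4
  records or zero IQR flag nothing; k is configurable and k = ∞ disables the
  screen. This replaces a manual/graphical screening step with a
  reproducible rule.
* **Aggregation.** Replicates → plot-day mean (passing, non-flagged only) →
  annual site mean ± sd/√n over plot-day values. A complete campaign gives
  n = 360 per site (10 plots × 12 months × 3 days). The SE treats plot-day
  values as exchangeable; plot/month random effects would make it an
  underestimate if they were large (see the generator defaults below).
* **Units.** µmol m⁻² s⁻¹ × M × 31,536,000 s × 10⁻⁸ → Mg gas ha⁻¹ yr⁻¹,
  with M = 44.01 (CO₂) and 16.04 (CH₄) g mol⁻¹ and a 365-day year.
  CH₄ → CO₂e uses GWP₁₀₀ = 27 exactly.
* **Landscape SE.** The default combination of site SEs is the quadrature
  *sum* √(se₁² + se₂²) — this is the convention consistent with the bundled
  campaign's reported landscape uncertainty (0.41 and 0.27 combine to 0.49).
  The conventional SE of a mean of independent site means (quadrature/n) is
  available via `se_rule="mean"`.

## FAO-56 Penman–Monteith and the water balance

Standard FAO-56 daily chain: Δ from the mean of the daily temperature
extremes; γ from barometric pressure at station elevation; es as the mean of
saturation vapor pressures at tmax and tmin (not es(tmean) — the station
logs 15-min temperature, so extremes are available); ea = RH_mean/100 · es;
extraterrestrial radiation Ra from latitude and day of year; clear-sky
Rso = (0.75 + 2·10⁻⁵·z)·Ra; net shortwave with albedo 0.23 (reference
grass — consistent with taking k_C = 1); net longwave from the
Stefan–Boltzmann formula with the cloudiness ratio Rs/Rso clipped at 1
(logged); soil heat flux G = 0 at daily steps; ET₀ floored at 0.

Wind is height-adjusted to 2 m by the log-profile factor
4.87/ln(67.8·z − 5.42). Days with more than 25% of 15-min intervals missing
are flagged; missing daily ET₀ is imputed by month-of-year mean up to 10%
missing days, beyond which the annual sum fails loudly.

ET_a = k_C·ET₀ with k_C = 1.0 by default: in a swamp inundated most of the
year, soil moisture never limits evaporation. Annual runoff closes the
balance, R_E = P − ET_a, assuming no change in catchment storage (no
discharge rating is attempted). Negative runoff is allowed but flagged as a
deficit, and propagates as zero fluvial export.

## Fluvial export

POM (mg L⁻¹) = (filter dry mass − combusted mass)·1000/volume filtered;
POC = 0.50 · POM. Negative mass differences are weighing noise: clamped to 0
and flagged, not an error. mg L⁻¹ is identified with g m⁻³ exactly (fresh
water). J = C_W·R_E with C_W the unweighted mean of monthly TOC values and
the month SE taken across months; runoff is treated as fixed in the export
SE (the concentration term dominates). C→CO₂ uses 44/12 exactly, matching
how budget tables are conventionally reported. Note that the bundled
campaign's reported annual mean TOC (54.20) differs by 0.1 mg L⁻¹ from the
sum of its reported annual DOC and POC means (37.10 + 17.20) — a rounding
artifact of month-level pairing; the pipeline always computes TOC from
samples and carries full precision.

## Carbon budgets

All budget arithmetic is linear, so SEs combine in quadrature
(√Σ(scale·se)²). The heterotrophic ratio (0.54 pristine / 0.81 logged,
from regional syntheses) scales the flux SE only by default; including a
ratio SE via the product rule is a switch. Carbon inputs (litterfall
6.7 ± 0.6 / 6.9 ± 0.6, root mortality 2.0 ± 1.5 / 1.2 ± 1.0 MgC ha⁻¹ yr⁻¹)
are literature values shipped in the parameter file and overridable. The
fluvial term is shared between sites (one river outlet drains both).
Sign convention: negative budget = net removal; adding a positive loss term
always makes a budget less negative.

Quadrature gives smaller onsite-budget SEs than the bundled campaign file's
source reports (e.g. ±5.9 vs a reported ±7.5 MgCO₂e for the pristine site);
the reported values cannot be reconstructed from the printed component SEs
under any standard propagation, so the package reports the quadrature
values. Means agree to print precision. Report tables round to one decimal
for MgC rows and two decimals for landscape totals; internal math is full
precision.

## Synthetic campaign generator

What it emulates: the campaign design (2 sites × 10 plots × 12 months ×
3 consecutive days × 3 replicates of 120-s runs at 1 Hz; a 365-day met year
at 15-min cadence; 12 monthly triplicate DOC/POC samplings; daily
groundwater levels as an uncoupled covariate).

* **Flux model.** Per gas: site-fixed mean + Gaussian plot effect + Gaussian
  month effect + Gaussian run residual, on the annual mass-flux scale. CH₄
  is truncated at zero. Defaults: CO₂ true fluxes 12.61/9.43 MgCO₂ ha⁻¹ yr⁻¹
  with components (plot, month, residual) = (0.3, 0.3, 13.4), chosen so the
  plot-day sd (≈7.8) matches the bundled campaign's implied dispersion
  (SE ≈ 0.41 at n = 360) while keeping plot-day values near-exchangeable —
  chamber campaigns are dominated by replicate-level scatter, and a
  residual-dominated decomposition also keeps the sd/√n standard error
  approximately honest. CH₄ true fluxes 0.0259/0.0170 MgCH₄ with components
  (0.0003, 0.0003, 0.008): *deliberately milder* than the campaign's implied
  CH₄ dispersion, because a zero-truncated Gaussian at that dispersion would
  bias the realized mean upward by ~25% of the true flux. Real CH₄ flux
  variability is right-skewed, which a Gaussian-on-the-flux-scale model
  cannot represent; generated CH₄ uncertainties are therefore smaller than
  field ones, and passing recovery tests demonstrates estimator correctness,
  not field-level CH₄ precision.
* **Series model.** baseline (420 ppm CO₂ / 2.0 ppm CH₄) + slope·t +
  Gaussian noise (0.05 ppm CO₂, 0.001 ppm CH₄ — analyzer-like precision).
  The slope is the latent flux pushed back through the gas-law relation for
  the configured geometry; each run records its latent truth.
* **QC failures.** A configured fraction of runs receives a saturating
  response, dC/dt decaying with τ = 8 s (flux shut-off / chamber-feedback
  shape), so the post-dead-band record is essentially flat and the linear
  R² collapses for both gases. A run is counted as rejected when every gas
  record fails QC; with the default noise levels clean runs essentially
  never co-fail both gases, so the realized rejected fraction is binomial
  in the configured fraction.
* **Met year.** Two-season sinusoidal wet-day probability and rain-amount
  modulation with gamma daily amounts, rescaled exactly to the configured
  annual depth (default 2130 mm) and spread over random 0.5–3 h windows;
  sinusoidal diurnal/seasonal temperature; RH anti-phased with the diurnal
  cycle, clipped to [0, 100]; daylight half-sine solar damped on wet days;
  folded-normal wind. The generated year yields annual ET₀ ≈ 1250 mm at the
  default equatorial geography — realistic for the emulated region, though
  the generator makes no attempt at weather autocorrelation beyond the
  seasonal cycle.
* **Water samples.** Between-month and within-month Gaussian components
  around DOC 37.10 and POC 17.20 mg L⁻¹; POC realized through the
  gravimetric pair (tare + POM mass, volume 0.5 L, OC fraction 0.50) so the
  pipeline must invert the laboratory arithmetic.
* **What passing tests do not show.** The generator is Gaussian,
  uncorrelated across days, has no flux–groundwater coupling (none is
  modeled downstream either), and allows negative CO₂ run fluxes at the
  default dispersion (a dark-chamber artifact class the QC and outlier
  screens must tolerate). Recovery on this generator validates the
  estimator chain, not the field representativeness of any particular
  dataset.

## Numerical and interface choices

* Reproducibility: every generator draws from streams spawned from a single
  integer seed; identical config + seed gives byte-identical CSVs and
  report JSON.
* Instrument cadence within the 2-min window is configurable
  (default 1 s); it is not a measured property of the emulated design.
* Seconds per year = 31,536,000 (365-day year).
* CSVs are UTF-8 with a header row, ISO-8601 dates, empty fields for
  missing values. Configuration is flat TOML.
* The `summary` pipeline mode injects site-level annual values directly
  into the budget chain (bypassing raw fitting) from a parameter file;
  the bundled file carries the Muara Siran campaign summaries and is
  clearly separated from the raw-data path.
* Problem sizes in the test-suite and acceptance script are desk-scale:
  recovery uses the full 2-site campaign design (2160 runs) or a reduced
  2 × 5 × 6 × 2 × 3 design for repeated-seed coverage; these sizes give
  standard errors small enough for 3-SE recovery checks to be meaningful.

## Known limitations

* ET_a for an arbitrary station can only be validated against the FAO-56
  component oracle, not against an independent annual measurement.
* The outlier screen is a rule-based stand-in for manual screening; counts
  removed will not match any particular manual workflow.
* No tree-mediated CH₄, no river degassing, no in-transit DOC oxidation:
  the fluvial and CH₄ terms are lower bounds in the same sense as the
  measurements they process.
* Mixed-effects inference across sites/months is out of scope; the package
  reports design-based means and SEs only.
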
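# Methods

## Scientific problem

Soil respiration (Rs, the CO2 efflux from the soil surface, in
µmol CO2 m⁻² s⁻¹) is the sum of root/rhizosphere (autotrophic, Rroot) and
microbial (heterotrophic, Rh) components. Continuous chamber records from
forest sites show that summer nighttime Rs frequently *exceeds* daytime Rs,
even though soil is often warmer during the day — the opposite of what a
single temperature-response curve predicts. Two mechanisms can produce this:

1. **Photosynthate-supply lag.** Carbon fixed by the canopy takes hours to
   reach roots and rhizosphere microbes. A daytime GPP peak plus a 6–12 h
   transport lag places the substrate peak after dark, elevating nighttime
   Rroot (and, through rhizosphere priming, Rh).
2. **Day/night-asymmetric temperature response.** The basal rate Rs0 and/or
   the sensitivity Q10 differ between day and night, e.g. through daytime
   xylem export of root-respired CO2.

The practical consequence: estimating nighttime Rs by extrapolating a
daytime-only Rs–Ts relationship systematically underestimates nighttime
effluxes, which matters both for manual-chamber field campaigns (daytime
measurements only) and for land-surface models whose root phenology
suppresses nighttime root growth.

## Analysis chain

For each site-season the pipeline, exposed as
`DielSiteModel(series, meta).fit()`:

1. **Solar partition.** Sunrise/sunset per day from the NOAA solar-position
   equations (zenith 90.833°, i.e. standard refraction + solar radius). An
   hourly bin `[h, h+1)` is daytime iff its midpoint lies in
   `[sunrise, sunset)`. A "night of date d" spans sunset(d)→sunrise(d+1)
   (sunset-anchored), making (day of d, following night) the paired diel
   unit. The pairing convention is not dictated by the underlying field
   protocol; it is declared here and recorded in the run manifest.
2. **Season selection** on the diel date: summer = JJA north of the
   equator, DJF south; other seasons shift analogously.
3. **QC cascade**, in fixed order with per-rule accounting:
   treatment rows out → non-positive Rs out → Tukey-fence outliers
   (`[Q1 − 1.5·IQR, Q3 + 1.5·IQR]`, type-7 linear-interpolation quantiles,
   fences computed on the analysed site-season subset) out → days with
   < 3 valid hours in either period out → months with < 10 surviving days
   out. The Tukey stage refits its fences if re-run, so the cascade is
   near- but not strictly idempotent; all other stages are no-ops on their
   own output.
4. **Diel statistics.** Daily day/night means of Rs, Ts, SWC; paired
   two-sided Student's t on the daily (night − day) differences (α = 0.05;
   Welch unpaired available by option). Percent difference is
   100·mean(night−day)/mean(day), computed per site and then averaged
   across sites.
5. **Temperature response.** Rs = Rs0·e^(β·Ts) fitted per period on hourly
   data. Default estimator: OLS on ln Rs (closed form, matches
   multiplicative flux noise); optional nonlinear least squares on the
   original scale, initialised from the log fit. Q10 = e^(10β) exactly.
   Fits require ≥ 30 hours and non-degenerate Ts; t-tests require ≥ 5
   paired days (stability floors, recorded in the manifest).
6. **Temperature adjustment.** Rs_adj = Rs·Q10^((T̄s − Ts)/10) with the
   period-matched Q10 and T̄s the mean of all analysed soil temperatures of
   the site-season. At Ts = T̄s the flux is unchanged.
7. **Extrapolation bias.** Apply the daytime fit to nighttime Ts;
   bias% = 100·(mean pred − mean obs)/mean obs (negative =
   underestimation), paired t on hourly (pred − obs). With an Rh partition
   (trenching-style), Rroot = Rs − Rh (negative hours dropped and counted;
   a site with > 20% negative hours is excluded), per-component biases are
   computed the same way and the root share is the ratio of bias fluxes.
8. **Scaling.** A per-forest-class flux gap (obs − pred) scales to carbon
   as gap × area × night_seconds × 12·10⁻⁶ g µmol⁻¹ × 10⁻¹⁵ Pg g⁻¹, with
   night_seconds = 92 summer days × the class's mean astronomical night
   length. Areas are configuration constants (m²); none are downloaded.
9. **Cross-site association.** Standardized major axis (model II)
   regression — slope = sign(r)·sd(y)/sd(x), 95% CI
   slope·(√(B+1) ± √B), B = F₀.₉₅(1, n−2)·(1−r²)/(n−2) — for night-vs-day
   flux comparisons and Rs–GPP relationships, and a Pearson lag profile
   r(l) = corr(Rs(t), GPP(t−l)) for l = 0…45 days (≥ 10 pairs per lag,
   earliest lag wins ties).
10. **Model evaluation** (`esm`): hourly land-model tables are split
    day/night by the model's own GPP (night iff GPP ≤ 10⁻⁶ µmol m⁻² s⁻¹,
    a numerical-zero tolerance), summarised as multi-year day/night means
    and the percent night shortfall per component, and compared across
    sites with the same SMA utilities. Nutrient-competition variants enter
    only as labels on input tables.

## Synthetic generator

`generate_site(GeneratorConfig)` produces an hourly site-summer with known
ground truth; it is the data source for every test. On a solar-local hourly
grid (drivers evaluated at hour midpoints):

* `Ts(t) = mean_Ts + A_syn(d) + Ts_amplitude·sin(2π(t_sol − 6 − Ts_phase_lag)/24)`
  with `A_syn` a stationary day-scale AR(1) weather anomaly
  (sd 2 °C, ρ = 0.8) shared by all hours of a calendar day;
* `GPP(t) = gpp_max · scale_d · max(0, sin(solar elevation))`, `scale_d` a
  stationary lognormal AR(1) day-to-day productivity factor
  (ρ = 0.7, log-sd 0.3, mean 1);
* substrate `S(t) = Σ_τ k(τ)·GPP(t−τ)` with a gamma kernel (mean
  `lag_mean`, shape `lag_shape`) integrated over hour bins centred on
  integer lags and normalised to unit mass on 0–48 h — a flexible unimodal
  positive kernel standing in for phloem transport, for which no standard
  functional form exists;
* `Rroot = base_root·f(t)·S·e^(β_root·Ts)`,
  `Rh = base_het·f(t)·(1 + priming_coef·S)·e^(β_het·Ts)`,
  `Rs = (Rroot + Rh)·ε`, with `f(t)` the optional night basal factor
  (astronomical night) and ε lognormal, mean 1, CV = `noise_cv`
  (multiplicative, as chamber fluxes are positive and heteroscedastic).
  With `noise_cv = 0`, `Rs = Rroot + Rh` holds bit-exactly.

Defaults describe a mid-latitude (45° N) temperate-forest summer
(June–August, 92 days): mean 5-cm Ts 18 °C; diel amplitude 1.5 °C peaking
4 h after solar noon (the diel wave at 5 cm under canopy is strongly damped
and delayed); midday uptake 20 µmol m⁻² s⁻¹; transport lag 8 h (shape 6,
within the 6–12 h range reported for forests); β_root = β_het = ln 2/10
(Q10 = 2); basal rates chosen so roots carry roughly half the flux; noise
CV 10%. Under these conditions the lag mechanism produces a night excess of
~0.6–0.8 µmol m⁻² s⁻¹ (≈ 15–20%) and a daytime-fit night bias of ≈ −30%:
a deliberately mechanism-dominant regime so that sign structure, not noise,
drives the tests. Three lead-in days are simulated and discarded so the
substrate convolution starts in steady state.

`GeneratorConfig.null()` is the no-mechanism reference: equatorial site,
no substrate coupling, equal β, no synoptic anomaly, and the Ts harmonic
peaking at sunset, so the hour-midpoint day and night Ts samples are
identical sets and any diel Rs difference is pure noise.

What the generator does *not* emulate: weather-driven GPP–temperature
covariance, rain pulses and SWC limitation of fluxes, chamber artefacts
(pressure pumping, low-turbulence nighttime overestimation), multi-chamber
spatial heterogeneity, and the xylem CO2-export mechanism (no accepted
equations to implement). Passing tests therefore demonstrate correctness of
the analysis chain and recoverability of known mechanisms — not that real
chamber data are free of the confounds above.

## Numerical choices and degenerate inputs

* Sunrise/sunset: NOAA equations; polar day/night raises an explicit error
  naming the date. The independent test oracle scans solar elevation on a
  15-second grid for the zenith crossing (agreement required within 2 min).
* Quantiles: NumPy `linear` (type 7); fences move with the estimator, so
  the choice is pinned and tested against a brute-force implementation.
* Zero-variance t-test inputs: an exact shift reports p → 0, identity
  reports p = 1 (machine-limited paired t is otherwise undefined).
* Zero Ts variance → fit error ("temperature range too small"); all-equal
  Rs → IQR 0, fences collapse to the value, nothing removed.
* Multiple chambers: port-level hourly means, then equal port weights
  (declared choice; the field protocol is silent).
* Depth selection: column nearest 5 cm, ties to the shallower depth.
* Hour bins left-closed; timestamps are site standard time (no DST).
* Determinism: one `numpy` Generator seeded from `GeneratorConfig.seed`;
  identical configs are bit-identical, and the pipeline manifest hashes
  every threshold so a rerun reproduces tables byte-for-byte.

## Problem sizes

Tests and the acceptance script use 92-day single-summer sites (≈ 2,200
hourly records each), 20–30-site batches for cross-site statistics, and
100–200 seed replicates for Monte-Carlo rates; these sizes give stable
rates and parameter-recovery statistics for the properties tested.

## Known limitations

* The per-site percent diel difference averages per-site percentages; a
  pooled-flux definition would weight sites differently.
* SMA confidence intervals use the standard F-based construction, which
  assumes bivariate normality; for small n (< 5 sites) they are indicative
  only.
* Under the default 200-day white-noise null, the maximum of the 46-lag
  Pearson profile exceeds 0.2 in ≈ 15% of realisations; the lag profile is
  an identification tool, not a significance test, and no multiplicity
  correction is applied.
* The Pg C scaling propagates no uncertainty beyond the flux-gap SEM; it
  is a magnitude estimate, not an inventory.
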
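# Methods

This note records the models, parameter choices, numerical conventions and
known limitations behind `elasmoiso`. It is the package's own account of its
science; every number quoted here is computed by the test suite or the
example scripts, not asserted from memory.

## The proxy system

Oxygen-isotope ratios of biominerals record the temperature and isotopic
composition of the water they formed in. The package implements two linear
paleothermometers:

* aragonite (bivalve shell carbonate, δ18Oc on the VPDB scale):
  `T(°C) = 20.6 − 4.34·(δ18Oc − δ18Ow)`
* biogenic apatite phosphate (shark tooth enameloid, δ18Op on VSMOW):
  `T(°C) = 117.4 − 4.50·(δ18Op − δ18Ow)`

with δ18Ow the ambient-seawater value on VSMOW. Both are exact closed forms
together with their algebraic inverses (the "starred" forward predictions
δ18Oc*, δ18Op* used throughout). Two transfer functions connect the
substrates: the affine VPDB→VSMOW scale map
`δ18Oc[VSMOW] = 30.92 + 1.03092·δ18Oc[VPDB]` and the empirical
carbonate→phosphate regression `δ18Op = (δ18Oc[VSMOW] − 8.67)/1.02`. A
linear Southern Ocean mixing relation `δ18Ow = 0.24·S − 8.45` (S in PSU)
converts salinity anomalies to δ18Ow shifts. Coefficient standard errors
(±9.5 and ±0.43 on the phosphate equation, ±1.24 and ±0.06 on the
transfer) are stored on the coefficient objects but are *not* propagated in
the deterministic layer — that layer stays exact and testable, and
uncertainty enters only in the Bayesian inversion when
`propagate_coeff_uncertainty=True`.

Raw mass-spectrometer values are calibrated to VSMOW with a two-point line
through the silver-phosphate reference materials USGS 80 (13.1‰) and
USGS 81 (35.4‰); applying the fitted map to the reference measurements
returns the accepted values exactly. An optional drift correction (off by
default) removes a linear trend of reference residuals against analysis
order before the two-point fit; the published protocols name drift and
linearity corrections without giving formulas, so this minimal linear form
is the package's own choice.

## Climate fields, envelopes and isoscapes

Gridded monthly seawater temperature and δ18Ow climatologies (two CO2
cases, "3x" and "6x" pre-industrial) are carried as xarray datasets on
(month, lat, lon), depth-averaged over the upper 25 m water column
(thickness-weighted, partial bottom layer clipped) and averaged over the
trailing 100 simulated years when multi-year fields are supplied. Site
series are cosine-latitude area-weighted means over ocean cells in a
lat/lon box; land is NaN and never imputed. The derived 12-month
δ18Oc*/δ18Op* series and their min–max define the *seasonal envelope* — the
band a non-migrating resident should record.

Isoscape summaries (mean ± 2σ of cell-wise δ18Op*) use the sample-SD
convention with a reliability correction for area weights; this is
configurable (`sd_ddof=0` for population SD) because the convention behind
published ±2σ values is not stated. Area weighting by cos(latitude) is
likewise an assumption, switchable to unweighted. The exact extraction
boxes for "Seymour Island" and "southern Chile" live in archived
supplementary material not shipped here; the `SiteSpec` defaults are
editable placeholders and should be set from that source when working with
real model output.

## CO2-case validation against serial bivalves

Serial δ18Oc profiles along bivalve growth axes (umbo→edge) carry the true
seasonal cycle. A profile point is "inside" a case's envelope when
`min − tol ≤ x ≤ max + tol` with `tol = 0` by default (whether the original
visual comparison used any tolerance is unknowable from the text; zero is
the strict choice). Fractions are pooled over all points across specimens —
the comparison is between a point cloud and a band, not between shells —
with a per-specimen alternative available. The case with the highest
inside-fraction wins; ties prefer the smaller maximum exceedance, then the
lexicographically first label. No phase alignment between shell distance
and calendar month is attempted: ranges are compared, not phases.

## Bayesian temperature inversion

The model for one taxon's measurements y_1..y_n:

* latent preferred temperature `T*` (flat prior on the environmental-prior
  temperature range, extended by ±3σ_T) and spread `σ_T` (half-normal,
  scale 2.5 °C);
* per-tooth formation conditions `(T_i, w_i)` drawn from the environmental
  prior π(T, w) tilted by `N(T_i; T*, σ_T)` — the environmental prior is an
  ensemble of paired (temperature, δ18Ow) draws from climate fields
  (area-weighted, jointly sampled so their correlation survives) or a
  uniform rectangle fallback spanning T ∈ [−0.43, 35.58] °C and
  δ18Ow ∈ [−2.85, 0.00]‰;
* likelihood `y_i ~ Normal(predict_d18Op(T_i, w_i), noise_sd)` with
  `noise_sd = 0.3‰` by default, the cross-run analytical uncertainty of the
  reference materials.

The per-tooth latents are marginalized over the prior ensemble
(Rao-Blackwellization: the likelihood of y_i given (T*, σ_T) is the
tilt-weighted mixture over ensemble draws). The posterior over (T*, σ_T) —
plus the two phosphate-equation coefficients as `Normal(117.4, 9.5)` and
`Normal(4.50, 0.43)` parameters when propagation is on — is explored with a
Goodman–Weare stretch-move ensemble sampler written in numpy for bit-stable
seeding (16 walkers, 3000 steps, 1000 warm-up by default; all randomness
flows from one integer seed). Convergence is judged by split-R-hat < 1.01
over four pooled walker groups and a crude autocorrelation ESS > 400;
failure flags the result rather than hiding it. Results are the posterior
mean and central 95% interval of T*.

The σ_T prior scale of 2.5 °C encodes that a taxon's within-unit preference
spread is of the order of the seasonal temperature amplitude it tracks (a
few °C), not of the full regional range; a much more diffuse scale lets σ_T
escape to values where the tilt goes flat and the preference becomes
unidentifiable.

`collapse=True` drops the hierarchy to a single shared (T, w) parcel. This
collapsed posterior has a deterministic oracle
(`posterior_grid_oracle`): dense-grid integration (≥500 points per free
dimension) with the prior entering as a density — analytic uniform for the
rectangle prior, Gaussian KDE of the draws otherwise. Sampler-vs-oracle
agreement within 0.1 °C on fixed cases, simulation-based calibration
(uniformity of the true value's rank among posterior draws), and
coverage/bias of the 95% intervals under the generative model are all
enforced in the test suite; the parameter-recovery check runs 100
replicates at each of four true preferences (8, 12, 16, 20 °C) with 15
teeth and 0.3‰ noise, using a 1200-draw prior ensemble and a shortened
sampler (12 walkers, 500 steps) sized to keep the whole suite fast.

Posterior interval widths with coefficient-uncertainty propagation off are
narrower than the published-style ±6–8 °C intervals, which include
calibration uncertainty; switching propagation on widens them accordingly.
Reproducing specific published posterior values is not attempted: it
requires the archived measurement data and climate-model output.

## Habitat-use statistics

Kruskal–Wallis (mid-rank ties, tie-corrected H, chi-square reference with
k−1 df; delegated to scipy) and a hand-implemented Dunn post hoc test
(pooled-rank z with tie correction, two-sided normal p; none/Bonferroni/
Holm adjustment, default none to mirror how such pairwise tables are
usually printed) compare δ18Op distributions across stratigraphic units
and between pelagic and benthic guilds. Both tests also offer
`method="exact"`: full enumeration of the permutation distribution of the
statistic, feasible for pooled n ≲ 10 and validated in the tests against an
independently coded brute-force oracle. The conventional reading — small p
means the groups differ — is used throughout (the source prose is
internally inconsistent on this; its tables' asterisk convention matches
the conventional reading).

Low outliers are flagged by z < −2 within whatever comparison pool the
caller chooses (bulk, per-unit or per-taxon; the pool is deliberately not
fixed). The habitat classifier reads a taxon×unit distribution against the
local seasonal δ18Op* envelope and the co-occurring-bivalve
phosphate-equivalent median: fewer than 4 values → `insufficient_n`; ≥2 KDE
modes separated by >1.0‰ (minor modes below 25% of the peak density are
ignored) → `bimodal_mixed`; median below the envelope minimum by >0.5‰ or
below the bivalve median by >1.0‰ → `warm_or_brackish_shifted` (lower
δ18Op means warmer and/or fresher water), symmetrically on the high side →
`cold_or_deep_shifted`; otherwise `local`. The numeric thresholds are this
package's definitions — the published framework gives the logic, not
numbers — and are configurable. "Local" is deliberately the residual label:
the framework treats agreement with local conditions as the null reading,
so borderline shifts classify conservatively. Widening the envelope can
only move labels toward `local` (tested property).

## Synthetic data

The generator produces inputs with the statistical structure the analysis
assumes, not a climate-model emulation. Monthly temperature is a sinusoid
with extrema in March and September–October (the austral cycle at the study
site), a linear meridional gradient (0.4 °C/deg, warmer northward) anchored
at 64.25°S, and cell noise (0.15 °C); δ18Ow couples linearly to the
noise-free temperature (−0.1063 ‰/°C, fresher when warmer, as for a
meltwater/precipitation-fed coastal sea) around a case mean, plus 0.05‰
noise. Case defaults (site mean/amplitude/δ18Ow: 13.5 °C/3.5 °C/−1.94‰ for
"3x"; 16.0 °C/3.35 °C/−2.43‰ for "6x") are solved so the site box yields
T ≈ 10–17 °C and seasonal δ18Op* envelopes near 20.0–22.3‰ and 19.0–21.2‰
respectively — the documented study conditions. A land strip north of 52°S
exercises the missing-data path.

Tooth scenarios sample a truncated normal centered mid-envelope (SD =
envelope width/5) for `local`, shift the center by ∓1.5‰ (default) for
`warm_shifted`/`cold_shifted`, mix in a uniform 17–19‰ low tail for
`brackish_outliers` (the tail's distribution is a choice matching the
spirit of observed low outliers, not a mechanism claim), and mix two
centers at ±max(shift, 1)‰ for `bimodal`; per-tooth noise is Normal(0,
0.3‰). The default assemblage mixes these modes across units at sample
sizes echoing the real collection, giving per-unit spreads inside the
observed 0.6–1.8‰ band. Bivalve profiles sample the seasonal δ18Oc* cycle
at monthly resolution over one or more years, optionally restricted to a
growth window (winter-only windows produce the cold-biased shells seen in
some taxa).

What the generator does *not* emulate — and hence what green tests do not
demonstrate about real data: spatial structure beyond a first-order
gradient, interannual variability in the monthly climatology, growth-rate
variation and ontogenetic trends within shells, diagenetic alteration, and
any taxon's true preference distribution. Passing tests show the pipeline's
statistics recover *designed* structure at realistic noise, no more.

## Numerical conventions

* ‰ values are plain decimals; no ratio-scale arithmetic anywhere.
* Round-trip identities hold to 1e-9; calibration reproduces reference
  values to 1e-9 in floating point.
* Grids are normalized to ascending latitude and longitudes in [−180, 180).
* Weighted SDs use normalized weights with the (1 − Σw²) reliability
  correction when `sd_ddof=1`.
* Log-likelihoods use log-sum-exp; posterior intervals are percentile-based.
* Degenerate inputs fail loudly: empty groups, zero-SD z-score pools,
  coincident calibration references, empty regions and missing envelopes
  raise instead of returning NaN silently.

## Known limitations

* The hierarchical inversion's structure (tilted-ensemble prior, σ_T
  half-normal) is this package's definition of a loosely specified
  published approach; alternative hierarchies would give different σ_T
  posteriors, though T* is robust in simulation.
* The KDE mode counter is a heuristic; mixtures separated by less than
  about twice the KDE bandwidth read as unimodal.
* Moderate habitat shifts (≲1‰) relative to a seasonally biased bivalve
  baseline classify conservatively as `local`.
* No regridding or interpolation between grid resolutions; inputs must
  share a grid.
* Exact rank tests enumerate permutations and are exponential in pooled n;
  they are intended for n ≤ ~10.
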
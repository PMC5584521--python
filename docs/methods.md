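# Methods

## Stoichiometric accounting

For a saturated acyclic alkane CₙH₂ₙ₊₂, complete oxidation balances to

* methanogenic: CₙH₂ₙ₊₂ + (n−1)/2 H₂O → (3n+1)/4 CH₄ + (n−1)/4 CO₂
* sulfidogenic: CₙH₂ₙ₊₂ + (3n+1)/4 SO₄²⁻ + (3n+1)/2 H⁺ →
  (3n+1)/4 H₂S + n CO₂ + (n+1) H₂O

Cell growth is deliberately ignored — the balances describe complete
mineralization, which is the standard assumption for long-incubation
carbon recovery. Each CH₄ formed or SO₄²⁻ reduced carries 8 electron
equivalents, so both routes transfer 6n+2 e⁻ per mole of alkane and the
coefficient Y = (3n+1)/4 (12.25 for hexadecane) is a pathway-independent
currency: *net methane produced + net sulfate reduced* per mole of alkane
consumed equals Y at 100 % recovery. Coefficients are stored as exact
rationals (`fractions.Fraction`; they are quarters for every n) so
element-balance checks close to exactly zero; floats appear only at
export. Only saturated acyclic alkanes are accepted — general
hydrocarbons are rejected rather than silently computed, because the
closed forms above are specific to H = 2n+2.

The culture liquid volume is not part of the chemistry but is needed to
convert between mM and mmol. The working default is **0.2 l**, chosen so
that the standard 0.34 mmol hexadecane dose (100 µl at 0.773 g/ml,
molar mass 226.4 g/mol) demands ≈21 mM sulfate for complete sulfidogenic
oxidation — consistent with how such cultures are usually dosed in 600 ml
vials. It is a configuration parameter everywhere it enters.

## Mass balance and partition statistics

Endpoint net values are background-corrected against a substrate-free
control: M = detected CH₄ − 0.66 mmol, S = (initial − detected sulfate)
− 0.096 mmol by default; both constants are configurable. Negative nets
are returned as-is with a `DataQualityWarning` (visible QC beats silent
clipping); `clip_negative` opts into clipping.

Two partition conventions are computed side by side and labelled
distinctly, because they answer different questions and differ
numerically whenever recovery ≠ 100 %:

* the electron-flow split 100·M/(M+S), 100·S/(M+S) — shares of the
  *recovered* electron flow, summing to 100;
* substrate-normalized contributions E_M = 100·M/(Y·hex),
  E_S = 100·S/(Y·hex) — shares of the *consumed substrate*, summing to
  the carbon recovery.

All ratio statistics are computed **per replicate first**, then averaged
(SE = sd/√n). The order matters: the mean of per-replicate ratios is not
the ratio of treatment means, and published treatment tables for this
kind of experiment are only reproducible replicate-first. A consequence,
demonstrated in the tests, is that treatment-mean S/M cannot be
recombined exactly from treatment-mean M and S — reconstructions from
printed means can drift by a few percent relative to per-replicate
averages.

## Logistic kinetics

Cumulative methane is fitted with y(t) = a/(1 + e^(−k(t−t_c))) by
least squares (`scipy.optimize.least_squares`, ftol = xtol = gtol =
1e-12, ≤10⁴ evaluations, positivity bounds on a and k). μ_max is defined
as the fitted k: the per-capita rate (1/y)dy/dt = k(1 − y/a) has
supremum k in the y→0 limit, which is the natural "maximum specific
rate" of a logistic and is verified numerically in the tests. Days are
converted to months with 30.4375 d/month (Julian year / 12,
configurable), so k is reported in month⁻¹.

The starting point is deterministic — a₀ = 1.05·max(y), t_c from the
half-maximum crossing, k₀ from a logit-linear regression — giving
reproducible fits with no random restarts; `restarts > 0` adds seeded
jittered starts and keeps the best RSS. Degenerate inputs (flat series,
optimizer failure) come back as `converged=False` with a diagnostic
message rather than an exception. The control background is *not*
subtracted before fitting by default (production curves are fitted as
measured); pipelines that need the pure logistic shape can enable
`subtract_background_before_fit`.

## Isotopes

α_app = (δ¹³CO₂ + 1000)/(δ¹³CH₄ + 1000), with headspace CO₂ (not DIC)
deltas assumed. Classification thresholds default to the literature
values 1.025 (aceticlastic below) and 1.065 (hydrogenotrophic above) and
are configurable; the labels say "dominated" because α_app is a coarse
index, not an apportionment. The plateau summary is simply the mean ± SE
of the last `window` (default 3) sampled points plus a trend flag from
the OLS slope over that window — there is no standard fitted-asymptote
procedure for these trajectories, and the windowed mean is transparent.
Per treatment × day, α_app is averaged replicate-first, consistent with
the mass balance.

## Sulfate response

S/M is regressed on initial sulfate (mM) by OLS (statsmodels) with an
estimated intercept — nothing forces the line through the origin, and
leaving the intercept free makes deviations visible. R² is the squared
Pearson correlation; the slope p-value is the two-sided t-test with n−2
df. The default uses per-replicate points; a means mode uses treatment
means. Days where any culture has M ≤ 0 (pre-lag) are skipped with a log
message instead of producing infinite ratios. Slope stability across
days is summarized by the slope range and flagged unstable when the
max/min slope ratio exceeds 1.5 (or the sign changes).

## Synthetic experiment generator

The generator produces the data structure the analysis assumes, with
every generating parameter known, so parameter recovery can be measured
exactly. Defaults describe the study conditions the package targets:
six treatments (0.5, 2, 4, 10, 15, 25 mM sulfate), 3 replicates, 15
sampling days over 0–421 d, 0.34 mmol hexadecane in 0.2 l, ~120 d lag,
ultimate degradation extent 0.9, recovery target 95 %, partition slope
β = 0.1 (S/M per mM), per-treatment logistic rates 0.41–0.20 month⁻¹,
background offsets 0.66 mmol CH₄ and 0.096 mmol sulfate, and Gaussian
measurement noise at realistic magnitudes (0.05 mmol on amounts, 0.5 ‰
on deltas, 0.01 mmol on residual alkane).

Mechanics, per treatment:

* alkane consumption is a lagged logistic (midpoint = lag + 110 d);
* the recovered fraction r of the stoichiometric equivalents is split so
  S/M = β·C₀, i.e. f_M = r/(1+βC₀), f_S = r − f_M of the yield Y; the
  unrecovered fraction is implicitly biomass/intermediates and carries
  no isotope fractionation;
* **sulfate capping:** when Y·f_S·hex_ultimate would exceed the sulfate
  actually supplied (minus the background draw), f_S is capped at the
  supply and the deficit rerouted to methane, preserving the recovery
  target. Under the default dosing this happens at 0.5–4 mM — low-sulfate
  cultures are genuinely sulfate-limited, as real ones are — so the
  imposed S/M = β·C₀ law is only observable uncapped in a sulfate-replete
  configuration. Exact-slope property tests therefore run a 1 l-volume
  variant in which no treatment caps; the study-condition default keeps
  the cap and demonstrates recovery preservation instead;
* observed methane/sulfate are the net trajectories plus constant
  background offsets;
* δ¹³C comes from a two-endmember scheme: aceticlastic methane enters at
  the substrate δ (−30 ‰), hydrogenotrophic methane at δ(CO₂ pool) −
  ε_h (45 ‰), and the CO₂ pool — seeded with 0.3 mmol at substrate δ,
  fed by gross oxidation CO₂ — enriches by Rayleigh-type mass balance as
  hydrogenotrophic consumption proceeds. The hydrogenotrophic fraction
  f_h ramps from 0.3 to 0.8 (below 5 mM sulfate) or 0.5 (above) between
  lag end and day 330, which makes α_app rise toward a plateau that is
  lower at high sulfate. Delta bookkeeping is delta-linear, which makes
  the closed-system isotope balance exact by construction (the
  carbon-weighted mean δ over all pools stays at the substrate value);
  the difference from exact ratio-space Rayleigh algebra is far below
  measurement noise at these fractionations. The scheme is generator
  fiction — the simplest construction with the right qualitative
  behaviour — not a mechanistic model;
* the deterministic surface is integrated on a fixed 1 d internal grid
  and sampled at the requested days, so refining the sampling grid
  changes nothing at shared days; halving the internal step moves deltas
  by < 0.1 ‰ (first-order integration). One caveat observed in testing:
  because the observed deltas are cumulative-pool mixtures, α_app at
  high sulfate can dip by ~1e-5 before the f_h ramp engages; strict
  monotonicity holds once the ramp is underway;
* noise is applied last from substreams seeded by (seed, treatment,
  replicate); seeded runs are bit-reproducible and zero noise gives the
  exact surface.

What passing tests on synthetic data do **not** show: real cultures have
replicate-level biological variation (not just measurement noise),
partition laws that need not be linear or time-constant, non-logistic
kinetics, and isotope systematics with temperature- and species-dependent
enrichment factors. The generator validates the *pipeline*, not the
biology.

## Monte-Carlo problem sizes

The acceptance-level recovery checks use 100 seeded synthetic
experiments (6 treatments × 3 replicates × 15 days each, with a logistic
fit per replicate), 100 seeded noisy curves for the kinetics bias check
and 200 seeded regressions for the slope bias check — sizes at which the
Monte-Carlo standard errors are a few tenths of a percent of the
generating values, tight enough to expose systematic bias while keeping
the whole suite under a minute on one CPU.

## Pipeline and report

`run_report` writes `balance.tsv`, `kinetics.tsv`, `alpha.tsv`,
`sm_regression.tsv` and `run.log` into a fresh `run_NNNN` directory;
identical input + configuration gives byte-identical outputs (the log
carries a configuration hash, no timestamps). Full precision is kept
internally; rounding (recovery/contributions 1 dp, ratios 2 dp, rates
3 dp) happens only at serialization.

## Known limitations

* The balance needs an endpoint residual-alkane measurement; without it
  the recovery denominator is undefined and the pipeline refuses to
  guess.
* Background correction assumes the control offset is constant; a
  time-resolved control could be substituted via the configurable
  constants but no time-dependent correction is implemented.
* The plateau summary is a windowed mean, not an asymptote fit; on a
  still-rising trajectory it reports the trend flag rather than
  extrapolating.
* Only saturated acyclic alkanes are in scope; no thermodynamics (ΔG),
  no VFA or sulfide accounting, no mechanistic competition kinetics.
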
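# Methods

This note documents the models, parameters, numerical choices and known
limitations of the `ojip` package: an analysis chain for fast (OJIP)
chlorophyll-a fluorescence transients of dark-adapted leaves under graded
root-cutting stress, from raw induction curves to the JIP-test parameter
system, per-group energy pipeline models, and the many-to-one statistics
that locate the root-cutting-ratio (RCR) threshold at which photosynthesis
changes.

## Transients and cardinal points

A transient is a same-length pair of series: strictly increasing sample
times (seconds, log-dense from ≤ 20 µs to ≥ 0.3 s, at least 40 points) and
non-negative fluorescence counts. The cardinal steps are

| mark | time    | meaning |
|------|---------|---------|
| O    | 20 µs   | F0 — all PSII reaction centers open |
| —    | 300 µs  | F300µs, feeds the initial slope M0 |
| J    | 2 ms    | FJ |
| I    | 30 ms   | FI |
| P    | maximum | Fm — all centers closed |

Values at fixed marks are interpolated **linearly in log10(time)** between
bracketing samples (exact when a grid point coincides). OJIP curves are
conventionally displayed, and are near-piecewise-linear, on a log time
axis, so log-linear interpolation has far lower bias than linear-time
interpolation on a geometric grid. Fm is the global maximum of the sampled
curve (with t_Fm the first time it is attained) rather than a plateau fit;
on noisy data this estimator carries a small positive extreme-value bias
(≈ σ√(2 ln n) in log counts), which slightly *raises* measured Fv/Fm.

A curve is flagged **flat** when Fv = Fm − F0 < ε_flat · F0 with
ε_flat = 0.05 (configurable). Flat curves keep F0/Fm/Fv but all
ratio-type parameters are flagged missing. With the default 3 % per-point
noise, the max-based Fm places genuinely horizontal curves near the 0.05
boundary, so flat detection on single noisy curves is deliberately
conservative: borderline curves pass through with extreme (near-zero)
yield values rather than being silently dropped.

Duplicate measurements of a leaf are averaged **pointwise on the raw
curves** (grids must agree to 1 ppm; no silent resampling) before any
parameter is computed — measurements are averaged, not parameters.

## The JIP parameter system

With VJ = (FJ − F0)/(Fm − F0) and M0 = 4(F300µs − F0)/(Fm − F0):

* specific fluxes per reaction center: TR0/RC = M0/VJ,
  ET0/RC = (M0/VJ)(1 − VJ), ABS/RC = (M0/VJ)/(1 − F0/Fm),
  DI0/RC = ABS/RC − TR0/RC;
* quantum yields: φP0 = TR0/ABS = 1 − F0/Fm (= Fv/Fm), ψ0 = ET0/TR0 =
  1 − VJ, φE0 = ET0/ABS = φP0·ψ0;
* performance index (absorption basis):
  PI_abs = (RC/ABS) · φP0/(1 − φP0) · ψ0/(1 − ψ0), with RC/ABS =
  1/(ABS/RC). The absorption-based PI is used throughout; the total
  (PI_total) variant needs I-step yields that are outside this package's
  scope;
* phenomenological fluxes per excited cross-section, anchored on the
  O-step approximation ABS/CS0 = F0: TR0/CS0 = φP0·F0, ET0/CS0 = φE0·F0,
  DI0/CS0 = F0 − TR0/CS0; RC densities RC/CS0 = F0/(ABS/RC) and
  RC/CSm = Fm/(ABS/RC);
* Sm = ∫ (Fm − F(t)) dt / (Fm − F0), trapezoidal in linear time from the
  20 µs mark to t_Fm (units: seconds). The lower limit is the O-step mark,
  not the first sample, so Sm is grid-origin independent. On the default
  70-point geometric grid the trapezoidal error against an analytic
  single-exponential rise is ≈ 0.4 %.

Degenerate inputs propagate as flagged NaN, never infinities: at VJ = 0
the per-RC fluxes diverge and are flagged; at VJ = 1, ET0/RC = 0 is kept
as a well-defined limit; PI_abs is undefined at ψ0 ∈ {0, 1}. Group
statistics exclude flagged values explicitly and report the exclusions.

## Energy pipeline models

Per group, the pipeline model is the arithmetic mean of the per-CS0 fluxes
over non-flagged leaf records (pooling replicates, days and clock times
unless pre-filtered) plus an active-RC fraction, RC/CS0(group) /
RC/CS0(control) clipped to [0, 1]. The fraction drives the open/filled
circle display (default 12 circles, rounded half away from zero — a
display granularity only). Aggregation averages *parameters*, never
cardinal points: the JIP map is nonlinear, so the parameters of mean
cardinal points differ (tested by counterexample). Rendering is
deterministic (fixed SVG hash salt, no embedded dates); arrow widths are
proportional to fluxes normalized by the control's ABS/CS0.

## Group statistics

The observation unit is the leaf-level (duplicate-averaged) measurement;
replicate plants, days and clock times are treated as independent
observations within their stratum (a mixed-model treatment of the repeated
measures is a known limitation, see below). Per parameter: one-way ANOVA
across all groups, then two-sided Dunnett many-to-one comparisons against
the control using the multivariate-t distribution (scipy), with a fixed
internal substream for the integration so results are reproducible and
order-independent. Adjusted p values map onto four tiers:
\* < 0.05, ** < 0.005, *** < 0.0005, **** < 0.0001. Comparisons are
two-sided because stress moves parameters in both directions (Fm down, M0
and DI0/CS0 up). Classical equal-variance Dunnett is the default; a
warning is emitted when the ratio of Levene-type group dispersions (mean
absolute deviation from the median) exceeds 4.

**Threshold rule.** The detected threshold is the smallest RCR level at
which *every* parameter of the core set (default Fm, Fv/Fm, PI_abs) is
significant at that level *and at all larger levels* (persistence). Levels
not testable for a parameter (fewer than 2 usable observations after
flagged-missing exclusion — e.g. an all-flat group) are skipped rather
than counted as evidence against persistence; a non-monotone significance
pattern (as produced by late-day self-recovery) triggers a warning.
`threshold_from_jip` applies the rule within the **midday (13:00)
stratum** by default: stress expression on the transient is maximal at
midday, and within one clock time the group dispersions are comparable.
Pooling all clock times (`clock_time=None`) is supported but mixes
flat-midday and recovered-evening curves of the severe groups, inflating
the pooled Dunnett variance and its power at the onset level — the
dispersion warning flags exactly this situation.

## The synthetic experiment

The generator emulates the design — 7 RCR groups {0, 10, 20, 30, 50, 75,
100 %} × 3 replicate plants × 5 clock times {9, 11, 13, 15, 17 h} × 2 days
× 2 measurements per leaf = 420 transients — with a closed-form phase
model: three logistic rises in log10 time (OJ, JI, IP) at τ = 0.4, 8 and
80 ms, widths 0.28/0.25/0.22 decades, weights 0.5/0.3/0.2, on a 70-point
geometric grid over [20 µs, 1 s]. The overall amplitude is solved on the
grid so unstressed, unmodulated curves hit Fv/Fm = 0.82 exactly — the
conventional healthy dark-adapted value just above the 0.8 guideline.
F0_base = 500 counts gives realistic instrument-scale intensities.

Stress phenomenology (defaults):

* amplitude depression d(r) = 0 for r ≤ 30 %, then 0.25 / 0.45 / 0.75 at
  50 / 75 / 100 % — onset at 50 % RCR, inside the 30–50 % band the
  threshold detector should recover;
* near-total amplitude collapse (×0.01 → flat curves) for 75/100 % at
  midday (13:00, 15:00);
* partial self-recovery at 17:00 for 50/75 % (depression ×0.4) but not
  100 %;
* J-phase weight inflation (+0.15, taken from the IP phase) at 100 %,
  raising VJ and lowering ψ0;
* deterministic diurnal amplitude modulation with a midday minimum
  (1.0/0.97/0.93/0.96/0.99 at 9–17 h), applied to all groups alike, with
  9:00 as the unmodulated reference — so the Fv/Fm target is exact at 9:00
  and the whole-day control mean sits at ≈ 0.82.

Noise: per-point multiplicative lognormal (σ = 0.03), a lognormal
per-plant amplitude effect (σ = 0.02) and a per-day intercept (σ = 0.01).
Randomness uses one root seed with per-curve substreams keyed by the
design labels, so any design subset reproduces the identical curves.
The ground-truth table holds the noise-free cardinal points and JIP
parameters per leaf condition plus the applied effect sizes (all zero in
the null generator, which keeps labels and noise but removes every
effect).

What the generator does **not** emulate: mechanistic QA/QB redox kinetics
(the logistic phases are phenomenological), detector nonlinearity,
autocorrelated instrument drift, leaf-position/light-exposure confounders,
and day × treatment interactions. Because amplitude depression scales the
whole variable rise, ground-truth VJ and M0 are stress-invariant except at
100 % RCR — real stressed leaves often show J-step and slope changes at
milder stress. F0 is nearly, not exactly, stress-stable (the 20 µs
logistic tail is ≈ 0.5 % of the rise), moving ≤ 2 % across the gradient
while Fm collapses by > 60 %. Passing tests therefore demonstrate that the
chain recovers effects of this shape and size under i.i.d. lognormal
noise, not performance on field data.

## Numerical and design choices

* Time is absolute seconds from flash onset; series are positional and
  0-based internally, never exposed in formats.
* CSV/TSV dialects: long-format transient CSV (one row per sample) and
  leaf-level JIP TSV with "NA" for flagged-missing; full `%.12g` / `%.10g`
  precision for lossless round-trips.
* Dunnett p values: multivariate-t integration seeded with a fixed
  internal constant; repeated calls and row permutations agree to the
  integration tolerance (~1e-4), tiers exactly.
* Strict config parsing: unknown keys are errors naming the key.
* The Monte-Carlo calibration and threshold-recovery checks use 1000 null
  tables and 200 simulated experiments respectively — sizes at which the
  binomial error on the measured rates (≈ ±0.7 % and ±3 %) is well inside
  the asserted bands.

## Known limitations

* No mixed-effects or repeated-measures modeling; pooling across days and
  clock times treats correlated observations as independent.
* No multiple-testing correction *across* parameters (Dunnett controls
  the family across groups within one parameter only).
* I-step-based parameters (VI, ψRE0, PI_total), L/K-band connectivity
  analyses and quenching protocols are out of scope.
* Flat-curve detection on noisy single curves is conservative (see above);
  the ε_flat threshold is configurable where stricter behaviour is needed.
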
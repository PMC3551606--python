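# Methods

This note records the models implemented in `foldshift`, their assumptions,
the defaults that matter, and the places where a design choice was genuinely
open. It is written for someone deciding whether the numbers the package
produces mean what they hope.

## Two-state thermal unfolding (`cd_thermo`)

The CD melt model assumes a two-state equilibrium N ⇌ D with linear
temperature baselines for each state:

    y(T) = [(Yn + Mn·T) + (Yd + Md·T)·K(T)] / (1 + K(T))
    K(T) = exp(−ΔG(T)/(R·T)),   ΔG(T) = ΔH·(1 − T/Tm)

with T in Kelvin throughout and R = 1.987204×10⁻³ kcal·mol⁻¹·K⁻¹. The
van't Hoff free energy uses ΔCp = 0: ΔH is treated as
temperature-independent. This is the standard approximation for short melts
of small proteins; its main consequence is that ΔG_u extrapolated far from
Tm (e.g. to 4 °C) is increasingly approximate, and the real stability curve
(which ΔCp bends downward at low temperature) is not captured. The fit is
parameterised by (ΔH, Tm) rather than (ΔH, ΔS) because Tm is directly
identified by the data midpoint, which decorrelates the two nonlinear
parameters; ΔS = ΔH/Tm is derived afterwards.

Fitting is nonlinear least squares (Levenberg–Marquardt via lmfit) with:

* Tm initialised at the temperature of maximum |dY/dT| (central
  differences), clipped 1 K inside the scan range;
* baselines initialised by OLS on the first and last 15% of points;
* three restarts with ΔH₀ ∈ {15, 30, 60} kcal/mol, keeping the lowest-RMSE
  solution. ΔH is bounded to [10⁻³, 500] kcal/mol and Tm to [150, 500] K to
  keep the optimizer out of non-physical territory;
* the exponent −ΔG/(RT) clipped to ±500 so extreme trial parameters cannot
  overflow.

`converged` requires both optimizer success and a fitted Tm inside the
scanned temperature range — a midpoint outside the scan is an extrapolation,
not a measurement. A melt must span at least 30 °C; shorter scans cannot
constrain two baselines and a transition simultaneously.

**Cooperativity label.** Experimental papers describe curves qualitatively
("progressive and non-cooperative") without a statistic. The package
reproduces that call with a deterministic rule: a fit is labelled
`non-cooperative` when it did not converge, when ΔH < 5 kcal/mol, or when
the transition amplitude (baseline separation at Tm) is below 3× the
residual RMSE or numerically zero. These thresholds are engineering guards,
not fitted quantities; they matter only for the label, never for the
thermodynamics.

Derived quantities: ΔG_u(T) = ΔH(1 − T/Tm); fraction unfolded
K/(1+K); ΔΔG_u(mutant) = ΔG_u(mut) − ΔG_u(ref) at a common reference
temperature, negative meaning destabilising. The default reference is
293.15 K (20 °C), where the biology of interest (population of the
denatured state under assay conditions) is evaluated; 277 K is equally
valid and exposed everywhere as a parameter.

Mean residue ellipticity conversion:
[θ] = signal_mdeg / (10 · path_cm · conc_M · n_residues), deg·cm²·dmol⁻¹.

**Accuracy.** On the default 47-point grid with noise at 3% of the
transition amplitude, the median |Tm error| is below 0.5 °C and the median
relative ΔH error below 10% (ΔH is always the softer parameter; treat
single-curve ΔG_u values as ±10% at best). A brute-force grid search over
(ΔH, Tm) with baselines solved linearly at each node reaches the same
residual RMSE within 5%, which checks that the optimizer finds the global
basin.

## Double-mutant cycles (`mutant_cycles`)

Coupling energy in the Horovitz–Fersht convention:

    ΔΔG_int = ΔG_wt − ΔG_m1 − ΔG_m2 + ΔG_dm

computed from the four constructs' ΔG_u at a shared reference temperature.
The sign convention makes a stabilising interaction (e.g. an intact salt
bridge lost twice over in the single mutants but only once in the double)
positive. The value is invariant under exchanging the two single mutants
and under viewing the cycle from the double-mutant corner; exchanging each
construct with its one-mutation partner (wt↔m1 together with m2↔dm)
negates it. A first-order standard error is propagated from the fit
standard errors of ΔH and Tm, summed in quadrature over the four legs; it
is reported, not interpreted.

Because ΔG_u here comes from van't Hoff fits at ΔCp = 0, cycle energies
inherit the ΔH uncertainty of all four fits; cycles computed at a reference
temperature far from the four Tm values are correspondingly soft.

## Emission maxima and MEWD (`fluor_shift`)

λ_max is the grid argmax refined by a three-point parabola through the
argmax and its neighbours, then rounded to the nearest 0.5 nm — the
resolution at which tryptophan emission maxima are conventionally reported.
Plain argmax is available (`refine=False`), as is an optional odd-width
moving average (off by default; fluorescence spectra are usually already
scan-averaged by the instrument).

MEWD = λ_max(pH 4) − λ_max(pH 6), positive for a blue shift (tryptophan
burial on folding). Constructs that fail the disorder-to-order transition
show MEWD near 2–4 nm rather than ~10 nm.

**Localisation limits.** The precision of any local peak estimator scales
with the peak's curvature relative to the noise. On a 0.5 nm grid the
argmax-plus-parabola estimator recovers a 10 nm-wide peak to ±0.5 nm in
>95% of trials at noise of 2% of peak height (with a 21-point moving
average). A realistic tryptophan envelope is broader (~25 nm), where ±0.5 nm
at 2% noise is not achievable by any local estimator; reported ±0.5 nm
errors on such spectra imply effective noise well below 1% (multi-scan
averaging). The worked-example MEWD values are computed on noiseless
spectra, where the estimator is exact on-grid.

## Inhibition assay (`inhibition_assay`)

Initial rate: OLS slope over the first 25% of points (≥4) of the progress
curve — the early, substrate-unlimited phase; the window is configurable
because instruments and mixing dead-times differ. Negative slopes are
clipped to zero (with a warning when genuinely negative rather than
round-off). Residual activity = 100 × rate_inhibited/rate_control, and
percent reduction is its complement; both are scale-invariant in the raw
fluorescence units. Dose series are ordered by concentration, duplicate
concentrations averaged, and an IC50 interpolated linearly in
log10(concentration) only when the series actually brackets 50%.

E-64 titration assumes the stoichiometric regime: rate falls linearly with
[E-64] and the x-intercept of the OLS line is the active enzyme
concentration. The r² ≥ 0.95 validity flag is an engineering guard against
applying the linear model outside that regime. Tight-binding corrections
and K_i estimation are deliberately out of scope: the assay design here
reports residual percentages, not inhibition constants.

## Motif scanning (`motif_scan`)

Patterns are dash-separated PROSITE-like tokens: a residue letter, a set
`[FYW]`, or `x(n)` meaning exactly n arbitrary residues (no ranges — the
conserved-motif notation uses fixed subscripts). Matching is
case-insensitive, reports all overlapping occurrences with 1-based
coordinates, and is implemented as a direct sliding-window check (sequences
of interest are short propeptides; no automaton needed). `X` in a sequence
satisfies no constrained slot (unknown residues are treated
conservatively) but may occupy gap positions, which impose no constraint.
Alignment input is degapped before scanning and hit coordinates are
remapped to the original columns.

One documented quirk of the conserved aromatic motif
`W-x(2)-[FYW]-x(3)-[FY]-x(3)-Y-x(12)-[FYW]` (span 25): taken literally, the
final aromatic sits 13 residues after the conserved Y, which does not match
every family member's spacing (crammer's own last core aromatic is 12
after). The scanner does not second-guess the pattern; callers who want the
shorter spacing edit the gap.

## Synthetic data (`synthetic_data`)

The generators emulate the acquisition settings of the assays:

| generator | grid / schedule | truth parameters | noise model |
|---|---|---|---|
| `gen_melt` | 4–96 °C, 2 °C steps (47 pts) | ΔH, Tm, four baseline coefficients | i.i.d. Gaussian, sd = fraction of transition amplitude |
| `gen_emission` | 290–400 nm, 0.5 nm (221 pts) | λ_max, F_max, Gaussian width (default 25 nm) | i.i.d. Gaussian, absolute sd |
| `gen_progress` | 300 s, 60 points | rate (AU/s); pairs honour a residual fraction | i.i.d. Gaussian, absolute sd |
| `gen_sequences` | — | length, optional planted motif | uniform residues over the 20 amino acids |

Default baseline coefficients (Yn = −12 mdeg, Mn = +0.01 mdeg/K,
Yd = −2 mdeg, Md = −0.005 mdeg/K) give the gently sloped, well-separated
baselines typical of 208 nm helix melts at 30 µM protein in a 1 mm cuvette.
Noise is Gaussian and i.i.d. because no instrument noise model is specified
for these assays; real CD melts have mildly temperature-dependent noise and
real fluorescence noise is closer to shot-limited (variance ∝ signal).
Consequently, passing parameter-recovery tests here demonstrates estimator
correctness and calibration under the assumed noise, not robustness to
instrument-specific artefacts (drift, lamp flicker, cuvette condensation at
low temperature). All generators take an explicit integer seed and are
bit-reproducible; nothing seeds from the clock.

Sequence generation is uniform over residues, so planted-motif recovery
tests sensitivity, and chance-match rates follow the binomial expectation;
real propeptide composition bias is not modelled.

## Pipeline (`cli_pipeline`, `spectro_io`)

`run_all` tolerates partial panels: any subset of {melt at pH 6, emission
at pH 4/6, progress pair} per variant produces a row with NA for missing
stages, because real mutant panels are heterogeneous. Stage failures are
logged per variant and do not abort the run; a malformed manifest aborts
before any computation. The qualitative molten-globule-transition column is
a user-supplied manifest label (`note`), never computed — it derives from
NMR dispersion, which is outside this package's inputs. Summary tables are
byte-reproducible given identical inputs; timestamps live only in the log.

Trace files are two-column text (comma or tab, decimal point only, `#`
comments, optional single header); temperatures are stored in °C and
converted to Kelvin only inside the thermodynamics. Vendor binary formats
are out of scope.

## Problem sizes used in the shipped checks

The packaged acceptance checks use the native problem sizes of the study
design: 47-point melts, 221-point spectra, 60-point progress curves, 100
replicate noisy melts for the stochastic recovery check, and 200 random
sequences for the scanner-versus-brute-force identity. These sizes are the
natural ones for the assays; none is a scaled-down surrogate.
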
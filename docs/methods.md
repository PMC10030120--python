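# Methods

This note documents the models, numerical choices and limitations of
`fpnbind` in one place. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Fluorescence polarization

Polarization is computed per well as
`FP = 1000·(F∥ − g·F⊥)/(F∥ + g·F⊥)` in millipolarization units (mP).
Plate readers typically report intensities with the instrument g-factor
already applied, so `g = 1` by default; it is accepted as an optional
input for uncalibrated exports. Wells with zero total intensity are
flagged `degenerate`, negative intensities `invalid`; flagged wells are
excluded from fits but never dropped from the table, and the pipeline
report accounts for every input well as used, flagged or
rejected-with-reason.

## Stage 1 — direct binding

Titrations of protein against a fixed tracer concentration are fitted
to a one-site isotherm with a linear nonspecific component:

    Y(x) = B_max·x/(x + K_D) + NS·x + background      [x in nM, Y in mP]

The model treats free and total protein as equal (no ligand
depletion), appropriate when the tracer (10 nM) sits well below the
K_Ds of interest; an exact quadratic isotherm is out of scope.
`B_max` and `background` are shared across all constructs fitted
together — the constraint that makes weak binders identifiable — while
`K_D` and `NS` are per-construct. Control wells containing a large
excess of unlabelled blocker (30 µM) lose the specific term and are
co-fitted as `background + NS·x`, sharing those parameters with the
titration of the same construct.

A construct whose specific amplitude actually reached at the top of
the titration, `B_max·x_max/(x_max + K_D)`, is smaller than twice its
(delta-method) standard error is flagged **no specific binding** and
excluded from stage 2: its signal is indistinguishable from the
nonspecific component.

## Stage 2 — displacement

Displacement series (fixed protein/tracer, variable competitor) are
analysed by two routes.

**Empirical (Hill).** The four-parameter logistic on a log10 dose
axis:

    Y = Bottom + (Top − Bottom)/(1 + 10^((logIC50 − log10 x)·n))

Top and Bottom are shared across competitors of one construct. With
this exponent convention a *decreasing* displacement curve corresponds
to `n < 0`; the fits of competition-generated data return `n = −1`
exactly, i.e. unit Hill slope in magnitude. Zero-competitor wells are
excluded here (log undefined) but retained in the mechanistic fit,
which is defined at `x = 0`. Internally the IC50 is fitted as
`log10 IC50`, so its positivity is structural and the standard error
is mapped back by the delta method. Flat series (an inactive
competitor such as a truncated peptide that cannot engage the
receptor) leave the IC50 unconstrained and are flagged rather than
reported.

**Mechanistic (competition).** FP readings are first converted to
fractional tracer saturation by linear inversion of the stage-1 signal
model at the fixed protein concentration `L`:

    Y = (FP − background − NS·L)/B_max

(the nonspecific term is a constant offset at fixed `L`; values
outside [0, 1] are reported raw with a warning). The converted data
are fitted to

    Y(x) = L/(L + K_D(dis)·(1 + x/K_D(x)))

with `L` and the stage-1 `K_D(dis)` fixed and `K_D(x)` free. The
stage order is strict — the competition fit refuses to run without
stage-1 parameters. Against log10 dose this curve is exactly a Hill
curve of unit slope with `IC50 = K_D(x)·(1 + L/K_D(dis))`; the
package exposes that closed form (`implied_ic50` / `kd_from_ic50`) and
uses the agreement of the two routes as an internal consistency check.

Because `K_D(dis)` enters as a constant, its uncertainty would be
invisible to the competition fit's own covariance. The reported SE of
`K_D(x)` therefore adds, in quadrature, the closed-form sensitivity
`∂K_D(x)/∂K_D(dis) = K_D(x)·L/(K_D(dis)·(K_D(dis)+L))` (obtained by
holding the data-determined IC50 fixed) times the stage-1 SE. Without
this term the 3-SE coverage of the competitor K_Ds falls measurably
short of nominal.

## Fit engine

All stages use one unweighted nonlinear least-squares engine (built on
`lmfit`/MINPACK `leastsq`): parameter sharing via named share groups,
box bounds, per-dataset model functions, and asymptotic standard
errors from the covariance scaled by reduced chi-square. Choices:

- **Unweighted residuals** — the conventional default for these
  dose-response fits; no weighting scheme is part of the protocol.
- **Positivity by log10 transform** — K_D-like parameters are fitted
  as log10 internally and reported on the linear scale with
  delta-method SEs (`SE_lin = ln 10 · value · SE_log`).
- **Multi-start** — concentration-scale parameters are restarted on a
  7-point log-spaced grid spanning the abscissa range; lowest residual
  sum of squares wins, ties broken by fewest function evaluations.
  This makes the fits deterministic and initialization-robust.
- **Tolerances** — 1e−10 relative on the RSS/step, at most 10 000
  function evaluations. Solutions pinned at a bound are flagged.
- **Replicates** are fitted as pooled individual points; means are for
  display only.
- A **case-resampling bootstrap** (whole replicate groups drawn with
  replacement, refit from the full-data solution) is available as a
  cross-check on the asymptotic SEs.

## Thermal stability

Normalized monomer-peak heights (100% at the lowest-temperature
reference, normalized per condition) are fitted to a logistic in
temperature, `bottom + (top − bottom)/(1 + exp(slope·(t − Tm)))`, with
top initialized at 100% and bottom bounded at ≥ 0. A series that does
not decrease has no transition and is rejected; a fitted Tm outside
the sampled range is flagged as extrapolated. The ligand-induced
shift is `ΔTm = Tm(holo) − Tm(apo)` with SEs combined in quadrature
(independent fits).

## Transport

Initial rates are extracted from calcein-quench traces as the slope of
a straight line over the first 30 s (configurable) after CoCl₂
addition, normalized by the quenchable span (baseline mean over the
60 s before CoCl₂ minus the post-calcimycin plateau mean) and negated,
giving a rate in fraction of quenchable signal per second. The
normalization makes the rate invariant to affine rescaling of the raw
fluorescence; without a calcimycin plateau the raw slope is returned
with a warning. Rates vs substrate concentration are fitted to
`v = v_max·s/(K_M + s)` after subtracting the zero-substrate blank;
data that do not saturate (`K_M` at or above the top concentration)
are flagged as poorly constrained.

## SPR

Sensorgram ladders are fitted globally to the 1:1 Langmuir model —
association `R(t) = R_eq·(1 − e^(−(k_on·c + k_off)·t))` with
`R_eq = R_max·c/(c + k_off/k_on)`, dissociation `R(t) = R₀·e^(−k_off·t)`
with `R₀` taken from the model value at the end of association — with
one `k_on`, `k_off`, `R_max` shared across concentrations.
`K_D = k_off/k_on` is reported in nM with a delta-method SE including
the covariance of the log rate constants. A dissociation window with
`k_off·t_diss < 0.1` cannot constrain `k_off` and is flagged.
Mass-transport-limited and heterogeneous-ligand models are out of
scope.

## Synthetic data

The generators emulate the study conditions: 24-point geometric
titration ladders from 13 nM to 6 µM (three replicates), displacement
ladders by two-fold serial dilution from 30 µM plus a zero-competitor
well, Gaussian noise of σ = 5 mP applied on the FP scale and mapped to
an intensity pair at fixed total intensity (an intensity-level
multiplicative mode exists because real plate noise lives on
intensities), melting series from 4 to 75 °C with 2% noise, transport
traces sampled at 4 s with six replicates at 0/1/10 µM Co²⁺ and eight
at 50/200 µM, and seven-concentration sensorgram ladders with ~1 RU
noise.

The FP signal calibration (background 220 mP, nonspecific slope
0.0125 mP/nM, maximal specific signal 102.5 mP) was chosen once so
that a 400 nM displacement series of a 100 nM-K_D construct spans
exactly the shared plateau values of 225–307 mP used in the
displacement analysis; individual values of the three parameters are
not separately constrained by the published summary numbers, only this
combination is.

The transport generator uses a single-exponential approach to the
full-quench plateau whose initial slope equals the Michaelis–Menten
rate scaled to the quenchable span — a generator convenience that
makes the extractor's target quantity exact, not a mechanistic claim.
The default `v_max` (0.002 of the quenchable span per second) and
`K_M` (5 µM, "low micromolar") keep the 30 s linear window's curvature
bias below the 5% extraction tolerance. No numeric K_M is published
for this system, so the transport chain is validated purely against
generator ground truth.

What the generators do **not** emulate: instrument drift, well-position
and edge effects, intensity-dependent noise, liposome size
heterogeneity, tracer depletion at high protein, and baseline drift in
sensorgrams. Passing recovery tests therefore demonstrate correctness
of the inference chain under the stated noise model, not robustness to
every artifact of real plate data.

## Problem sizes

The recovery study in the test suite runs the full two-stage pipeline
on 200 independently seeded plates (six constructs, two competitors,
~1100 wells each) and requires every K_D to fall within 3 asymptotic
SEs of its ground truth in at least 95% of repetitions per quantity.
The closed-form IC50 bridge is checked against a bisection
root-finding oracle to 1e−9 relative on 1000 random parameter triples,
and the zero-noise generator→pipeline round trip is required to be
exact to better than 1e−6 relative (observed ~1e−11).

## Known limitations

- The FP-to-saturation conversion is a linear inversion of the
  stage-1 signal model; any miscalibration of the shared
  `B_max`/`background` propagates into stage-2 K_Ds and is only
  partially captured by the propagated SE.
- The competition model ignores tracer depletion (free ≈ total
  concentrations), as does the direct-binding isotherm.
- Asymptotic SEs assume homoscedastic Gaussian residuals; the
  bootstrap is provided as a cross-check.
- Hill fits report `n < 0` for decreasing curves; consumers expecting
  a positive "Hill coefficient" should take the magnitude.
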
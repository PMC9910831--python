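# Methods

## Two-state switching model

Single cells are responsive or unresponsive; transitions are a
continuous-time two-state Markov process with per-day rates `kon`
(unresponsive → responsive) and `koff` (responsive → unresponsive).
The parameter triple `(kon, koff, f)` is stored self-consistently with
`f = kon/(kon+koff)`; `(koff, f)` is the canonical free pair and `kon`
is always derived. Per-interval switching uses the exact closed-form
transition matrix

    P(RESP→RESP; dt) = f + (1−f) e^(−λ dt),   λ = kon + koff,

never a Bernoulli approximation, so all results hold at any division
interval. Fractions are stored on [0, 1] throughout; percentages appear
only at reporting boundaries.

Default parameter values and their meaning:

| parameter | default | units | meaning |
|---|---|---|---|
| `koff` | 0.29 | /day | responsive → unresponsive rate (fitted) |
| `f` | 0.02134 | — | stationary responsive fraction (measured in regular cultures) |
| `kon` | koff·f/(1−f) ≈ 0.00632 | /day | derived on-rate |
| `division_interval` | 1.0 | day | ~24 h cell cycle; generation g ↔ day g |
| `cv_tech` | 0.32 | — | CV of the responder fraction between independent bulk samples |

The rounded value f = 2% is sometimes quoted for the steady state; the
measured per-cell responder probability in regular cultures is 0.02134,
and this package uses the measured value as its canonical baseline
(`ifnfate.F_MEASURED`). The distinction matters only for one
ill-conditioned quantity (the CV peak day, below).

## Lineage simulator (synthetic fluctuation assay)

Clones grow as synchronous binary trees: the founder divides at day 0,
divisions repeat every interval, daughters copy the mother's state at
division, and each edge evolves independently over one interval by an
exact transition-matrix draw. A generation-g clone is therefore 2^g
leaves observed at day g, correlated only through shared ancestry.
Founders start `RESPONSIVE` by default (isolated cells were observed to
be nearly all responsive), `STATIONARY` draws founders Bernoulli(f).
Technical noise multiplies clone fractions by lognormal factors with
mean 1 and CV `cv_tech` (fractions are positive and only the CV
magnitude is known, which a mean-1 lognormal matches), then clips to
[0, 1]. A fixed seed fully determines all output.

Deliberately not modeled: asynchronous/gamma cell-cycle times, cell
death, density-dependent rates. Consequently, passing tests show that
the inference machinery is correct under the stated model, not that real
colonies divide synchronously; quorum/density effects appear in data
only as stratification, never as dynamics.

## Exact colony moments

For generation g, the inter-clone mean of the responder fraction equals
x(g·T) exactly. The variance follows from decomposing leaf pairs by the
day `a` their most recent common ancestor divided: such a pair shares
the founder's history to day a (ancestor state distributed as the
founder evolved a days) and evolves independently for g−a days, so

    E[s_i s_j | a] = Σ_z P(x0→z; a) · P(z→RESP; g−a)²,

with 2^a·2^(2(g−a−1)) unordered pairs diverging at day a (these sum to
C(2^g, 2) exactly — a tested identity). The implementation is validated
three ways: exact enumeration of the outcome distribution for g ≤ 4,
Monte-Carlo agreement (|Δmean| < 0.005, |ΔCV| < 0.02 at 50,000 clones,
g = 1..6), and structural bounds (0 ≤ Var ≤ m(1−m)). The total CV adds
the technical component in quadrature at the CV level.

### The CV peak day is a flat maximum

At (koff = 0.29, f = 0.02134, responsive founder, cv_tech = 0.32) the
total CV rises to a maximum at day 5 and decays toward the technical
floor. This maximum is numerically flat: days 5 and 6 differ by ~4×10⁻⁴
in total CV (~0.05%), far below what any experiment — or a 50,000-colony
simulation — could resolve. With the rounded f = 0.02 the argmax shifts
to day 6 by that same sliver. The package therefore reports the peak at
the measured baseline f = 0.02134 and documents the sensitivity here;
`cv_peak_day` itself is exact and breaks ties toward the earlier day.

An alternative division-timing convention (founder divides after one
interval, so just-divided sisters are identical at observation) was
evaluated and shows the same flat day-5/6 maximum; the convention above
(founder divides at day 0) is kept because it makes moments and
simulator comparable by construction.

## Parameter estimation

* **Log-linear fit** (`fit_koff_loglinear`): OLS of ln x(t) on t over
  days 0–5 (inclusive; the day-0 point enters as data). Natural log is
  required for the slope to equal −koff. CI: t-distribution on the OLS
  slope with n−2 df. The f offset biases this estimator low by ~2.4% at
  (0.29, 0.02) — negligible against sampling noise at 30
  clones/generation, and its 95% CI covers the truth in ~94% of 500
  simulated replicates.
* **Closed form** (`fit_closed_form`): nonlinear least squares of
  x(t) = f + (x0−f)·exp(−koff·t/(1−f)) over koff with f, x0 fixed;
  exact on noise-free model output. Degenerate inputs (x0 = f, constant
  trajectory) are flagged `unidentifiable` rather than fitted.
* **f estimate** (`estimate_f`): cell-weighted responder fraction
  (Σ responders / Σ cells) over reference generations, defaulting to
  generations ≥ 13 when present (the relaxed, regular-culture proxy),
  else the latest generation — in which case the estimate is biased
  upward because the relaxation has not finished; the full report uses
  the log-linear koff as primary for this reason and reports both.
* Mean trajectories are cell-weighted across clones by default (the
  bulk-fraction interpretation); unweighted per-clone means by flag.
* One generation = one day unless `division_interval` is overridden.

## Design probabilities

The Bernoulli-null calculators (`prob_no_responders` = (1−p)^(2^g),
`expected_responders` = p·n, `neighbor_prob` = 1−(1−p)^k) deliberately
ignore heritability: they are the stochastic baseline the fluctuation
test is read against. `min_generation_for_detection` takes the target
probability as an argument because "considerably high" has no canonical
threshold. Note 1−0.97866⁴ = 0.08267, conventionally quoted truncated
as 8.26%.

## Synthetic images and responder calling

The generator renders cells as disks with concentric disk nuclei on a
sparse field (no touching cytoplasms by default, as with sparse
coverslip seeding): Hoechst fills nuclei, CFP fills cells with
per-cell lognormal baselines (CV 0.35) and nuclear intensity =
true_ratio × baseline (responders: ratio ~ N(1.8, 0.15); non-responders
~ N(1.0, 0.05)), rhodamine marks transfected cells with a diffuse fill
plus bright uptake puncta; Gaussian read noise, 16-bit quantization.
Responders are planted by count (`round(n·fraction)`) so fixtures are
exact; a Bernoulli mode exists. Optional sister pairs place two
responders at separation just under one cell diameter. Absolute
intensity levels are arbitrary (no authoritative magnitudes exist) —
only ratios and contrasts matter, and the translocation ratio is scale
invariant by construction. Not modeled: point-spread functions,
illumination gradients, clumped-cell segmentation, time lapse.

Measurement mirrors the standard primary/secondary/tertiary object
chain: nuclei by global Otsu on the nuclear channel plus a minimum-area
filter; cells by nucleus-seeded watershed on CFP restricted to a
foreground mask (Otsu on log intensity, because cell brightness is
roughly lognormal and a linear Otsu drops the dimmest cells); cytoplasm
= cell − nucleus, with nucleus-fills-cell cases excluded from ratio
statistics. Responder call: translocation ratio strictly greater than
an explicit threshold (default 1.3 — in practice this threshold is
tuned per experiment by eye, so it is a required, recorded parameter
here). Transfection threshold = maximum rhodamine mean over
untransfected controls; efficiency = fraction strictly above it.
Background offset slightly compresses measured ratios toward 1
(a responder with true ratio 1.8 measures ~1.73 at default settings),
which leaves calls at threshold 1.3 unaffected.

**Sister pairs.** The informal rule "two responders within 300 μm with
at most one non-responder between them" has no published geometry, so
"between" is operationalized as non-responder centroids inside a
rectangular corridor (width = one mean cell diameter, 28 μm,
configurable) around the segment joining the pair. Pairing is greedy by
ascending distance with each responder in at most one pair. The
resulting percentage of responding sisters is this package's
operationalized statistic; it is not claimed to reproduce percentages
derived from the unstated visual rule.

## Problem sizes and numerical choices

Simulation-based checks use 50,000 colonies per generation for moment
cross-checks (MC error on CV ≈ 0.005), 500 replicates for CI
calibration, 5,000 chains × 30 days for the steady-state population
check, and 500-cell fields for image recovery — sizes at which the
Monte-Carlo error is several times smaller than the tolerance being
checked, while the whole suite stays fast. Variance round-off at the
frozen-dynamics limit is clipped at 0; CV is NaN when the mean is 0;
`cv_peak_day` ignores NaNs and breaks ties toward the earlier day.
Seeds: every stochastic routine takes an explicit seed and is
deterministic given it; pipeline outputs are byte-identical for
identical config + seed (manifests are deliberately timestamp-free).

## Known limitations

* Synchronous division is a modeling convention; real lineages
  desynchronize over multiple generations, so "generation" is indicative
  for late clones.
* The statement "cells switch off after five generations on average"
  does not numerically reconcile with 1/koff ≈ 3.5 days; this package
  reports 1/koff and leaves the five-generation phrasing uninterpreted.
* Experimental percentages measured on real cells (responders at 7 h,
  responding-sister percentages, per-experiment clone CVs) depend on
  unmodeled biology and unstated measurement choices; simulator outputs
  are compared to them qualitatively only.
* `estimate_f` from datasets lacking late generations is biased upward;
  supply `reference_generations` explicitly when possible.
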
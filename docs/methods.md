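# Methods

## The model

The petal's adaxial epidermis is reduced to a 1D file of cells along the
proximo-distal (PD) axis, justified because both the pattern (a single
boundary) and the quantified data (normalized PD positions) are effectively
one-dimensional. Each cell carries an immutable fate — proximal (future
pigmented bullseye centre, coded 1) or distal (white periphery, coded 0) —
assigned in the initial condition; fate specification itself is not
modelled. Daughters inherit the mother's fate and are inserted adjacent to
it, so the two fate blocks remain contiguous (proximal at the base, distal
at the tip) by construction, and the "boundary position" is simply the
proximal fraction of total length, tl₁/(tl₀+tl₁).

Two rules act on cells:

* **Growth** — logistic in cell length *l*:
  d*l*/d*t* = *r*<sub>g</sub>(*f*) · *l* · (1 − *l*/*l*<sub>max</sub>).
  Small cells grow near-exponentially at rate *r*<sub>g</sub>(*f*); growth
  stalls as *l* approaches the maximum cell length *l*<sub>max</sub>.
* **Division** — a stochastic event at propensity
  *d*(*f*, *L*) = *r*<sub>d</sub>(*f*) · e<sup>−*L*/*L*₀(*f*)</sup>,
  where *L* is the **total** tissue length. The mother of length *r* is
  replaced by two daughters of length *r*/2 (total length is conserved
  exactly), the new cell placed immediately to the mother's right with a
  fresh id. Coupling the propensity to *L* produces the observed two-phase
  development: a division-heavy phase while the petal is short, then an
  expansion phase once *L* ≫ *L*₀. A fate-specific *L*₀ shifts the timing of
  that exit per region.

### Parameters

| name | default | units | meaning |
|---|---|---|---|
| `r_g_distal` | 0.91 | /day | base relative growth rate, distal cells |
| `r_g_ratio` | 1.0 | – | proximal:distal expansion-rate ratio |
| `r_d_distal` | 1.1 | /day | base division rate, distal cells |
| `r_d_ratio` | 1.0 | – | proximal:distal division-rate ratio |
| `l_max` | 20 | μm | maximum cell length |
| `L_max` | 300 | μm | total-length threshold ending a run |
| `L0_distal` | 30 (= 0.1·L_max) | μm | division slow-down scale, distal |
| `L0_ratio` | 0.6 | – | L0(distal)/L0(proximal); < 1 ⇒ proximal cells exit the division phase later |
| `dt` | 0.01 | day | engine step |

The initial state is 21 cells of 0.1 μm (total ≈ 2.1 μm), the first seven
proximal, placing the boundary at one-third. The 300 μm target reproduces
the ~150-fold length increase of a real petal at a computationally
convenient scale; conclusions are about *ratios* of rates between the two
regions and are insensitive to ±20% changes of the absolute base rates (the
acceptance suite re-runs the maintenance, anti-correlation and
growth-dominance checks at 0.8× and 1.2× rates).

All rates are per day. Base rates of exactly zero are accepted as
deliberate degenerate inputs (pure-growth or frozen-length runs used in
tests); a run that cannot reach `L_max` raises a no-progress error after a
configurable step budget instead of spinning forever.

### Engine

The default engine is a fixed-step hybrid: per step of `dt`, (1) every
length is advanced by its deterministic logistic increment evaluated at
start-of-step lengths, clipped so no cell exceeds `l_max`; (2) every cell
independently divides with probability 1 − e^(−d(f, L_start)·dt), divisions
applied at end of step in base-to-tip order with sequentially assigned
fresh ids (deterministic reproducibility); (3) time advances by `dt`. A
warning is emitted if `dt` × max propensity exceeds 0.5. At the default
rates the per-step division probability is ≈ 0.01–0.02, and halving `dt`
moves the ensemble-mean final boundary by < 0.01 (tested).

An exact event-driven mode (`simulate_exact`) is also provided: between
divisions, lengths follow the logistic law in closed form, and division
times are drawn by thinning — valid because *d*(*f*, *L*) only decreases as
*L* grows, so the propensity at the start of an interval bounds the whole
interval. The final threshold crossing is located by bisection. The two
engines agree on ensemble-mean final boundaries within Monte-Carlo error
(tested); the hybrid is the default because it emits the evenly spaced
snapshots the time-binned observables expect. Whether the original
rule-engine treated growth stochastically is not knowable from the model
description; growth is deterministic here in both modes.

Per replicate, the RNG is `numpy` PCG64 seeded with `base_seed + i`, so
ensembles are reproducible and grid points of a scan share replicate seeds
(paired comparisons across parameter sets).

### Observables, binning and the objective

From each snapshot: per-fate counts nc₀, nc₁ and region lengths tl₀, tl₁;
boundary = tl₁/(tl₀+tl₁); length ratio = (tl₁/nc₁)/(tl₀/nc₀); cell-number
ratio = nc₁/nc₀. Trajectories are binned into 100 equal windows of
simulation time (window means of the *raw* aggregates; ratios are recomputed
from averaged aggregates so the stored boundary always equals
tl₁/(tl₀+tl₁) bit-for-bit). Because petal length is the natural
developmental coordinate, each observable is also resampled at the time
window whose total length is nearest each 10% of final length (earlier
window on ties). The objective against a reference frame is the mean
percentage error per observable over those ten samples, averaged with equal
weight over the three observables; it is invariant to rescaling time.
Ensembles default to 50 replicates (the replicate count is configurable;
descriptions of the original protocol give both 50 and 100).

### Scans, maintenance contour, sensitivity

`scan_ratios` runs a seeded ensemble per (r_g_ratio, r_d_ratio) grid point
and records the mean final-boundary deviation (final − initial; positive =
tipward), plus final length and count ratios. The boundary responds ~30×
more strongly to the expansion ratio than to the division ratio (divisions
conserve length; they act on the boundary only through the size structure —
smaller cells sit lower on the logistic curve and grow relatively faster).
Two preset grids reflect that anisotropy:

* shift grid: 5×5 linear over [1, 2]² — the upward-shift regime; maximum
  mean deviation ≥ 0.2, reached at high expansion ratio;
* maintenance grid: 9 log-spaced expansion ratios over [0.90, 1.12] × 5
  log-spaced division ratios over [0.5, 2.0] — fine where the contour
  lives, so `maintenance_contour` (points with |deviation| ≤ 0.05) contains
  enough points for a rank correlation. The Spearman correlation of log
  ratios over the contour is reliably negative (ρ ≈ −0.6): an increase in
  proximal expansion must be offset by a decrease in proximal division to
  hold the boundary.

Sensitivity of an observable to a parameter is the ratio of relative
changes, |Δobs|/obs ÷ |Δθ|/θ, on ensemble means with shared seeds; ±10%
perturbations of `l_max` and `L0_distal` move the boundary far less than
the length ratio, because length-ratio changes are compensated by
cell-number changes that leave regional areas (hence the boundary) stable.

A note on the defaults: even at ratios (1, 1) the model is not fully
symmetric — `L0_ratio` = 0.6 lets proximal cells divide longer, so they end
smaller (and more numerous) than distal cells. This asymmetry barely moves
the boundary (ensemble drift ≈ +0.01, since divisions conserve length), but
it does make per-region median cell lengths differ at maturity; tests of
regional *symmetry* therefore set `L0_ratio` = 1.

## Rate estimation

Between consecutive stages, counts and sizes are treated as exponential, so
the interval rate is k = Δln(v)/Δt (hours converted to days centrally). No
rate is computed into the first stage. Division parameters (r_d, L0) are
recovered by linear least squares on log k against petal length — exact on
noise-free data — with an optional nonlinear refinement on the original
scale; repeated-length designs warn about leverage. Length-based rates are
*effective* rates (they conflate growth with division halving); only the
final interval, where divisions have effectively ceased, approximates the
basal growth rate. Genotype-comparison ratios use the independence moment
formulas E(X/Y) = E(X)·E(1/Y) and Var(X/Y) = E(X²)·E(1/Y²) −
E²(X)·E²(1/Y), verified against a 10⁶-draw Monte-Carlo oracle within 1%;
error bars are the square root of that variance.

## Measurement pipeline

Boundary detection from cell areas: cells are restricted to a central
lateral stripe (default 20% of width), binned into contiguous 5% PD
windows (half-open, last closed; a window's position is its centre), empty
windows filled by linear interpolation, the profile smoothed with a
Savitzky-Golay filter (window 7, order 2 — the original filter lengths are
not recorded; both are exposed), and the boundary taken as the mean centre
of all windows whose smoothed value is within 2.5% of the maximum. The
2.5% rule is read as *relative value* (a positional reading would make the
smoothing irrelevant). The estimate is invariant to uniform area rescaling
and recovers planted peaks within half a window (mean error ≤ 0.025 over
100 noisy synthetic profiles). For pigmented stages the boundary is the
midpoint between the last pigmented and first unpigmented cell, requiring a
contiguous basal pigment block; all-pigmented/none-pigmented inputs return
degenerate flagged estimates rather than errors.

EdU densities use a Gaussian KDE (Silverman bandwidth) with reflection at
0 and 1 so the density integrates to 1 on the unit interval; a 10-bin
histogram is returned alongside for count-based comparisons.

## Synthetic data: what it emulates, and what it does not

Generators are pure functions of (spec, seed) — byte-identical CSV on
repeat. Cell tables plant a Gaussian area bump (or smoothed top-hat for the
overexpressor's plateau) at the preset stage-wise position on a lognormal
noise background (σ = 0.15, matching visual replicate spread); EdU tables
draw from a tip-skewed Beta(3, 1.5) in distal-biased stages and uniformly
otherwise; positions are uniform early and, at mature stages, piecewise-
uniform so the distal region is denser by the preset count ratio (a uniform
marginal cannot coexist with the observed five-fold distal excess). Stage
series forward-simulate the tissue model and sample the snapshot nearest
each stage time after affine rescaling onto the simulation duration,
embedding the ground-truth parameters in the output metadata. Choice tables
interpolate success probability on the logit scale between planted
endpoints.

Passing tests on these data demonstrates that the *pipeline* recovers what
was planted — peak positions, rate orderings, learning endpoints — under
realistic noise. It does not validate the presets against real petals:
per-stage cell counts and area scales beyond the printed landmarks are
plausible placeholders, lateral structure is only a phase-shift caricature
of the croissant-shaped early domain, and segmentation artefacts (missing
cells, merged cells, curved-surface distortion) are absent entirely.

The end-to-end recovery experiment mirrors the real protocol: five
replicate "petals" per pseudo-experiment, per-stage medians pooled across
them, then interval rates contrasted between regions — distal division is
scored on the count rate over S0a→S2E (division-dominated window), proximal
expansion on the median-length rate over S2E→S5 (expansion phase). With
ground truth r_g_ratio = 1.5, r_d_ratio = 0.5 both orderings are recovered
in ≥ 19/20 experiments. Single-petal medians are markedly noisier because
lengths cluster in division cohorts (powers of two × growth), which is why
the pooled-median design is the default.

## Behavioural analyses

Disc bullseye sizes are expressed as 100·(inner/outer)² percent of disc
area. First-choice preferences use the exact two-sided binomial test
against 0.5 (the cleaner equivalent of a one-sample t test on 0/1 data; the
t variant is available via `ttest=True`). Learning curves pool bees and fit
a binomial GLM with logit link of correct choice on visit index, reporting
the likelihood-ratio χ² against the intercept-only model and pointwise 95%
Wald bands computed on the link scale; complete separation falls back to a
lightly L2-penalised fit, flagged on the result. Printed χ² statistics and
endpoint percentages from live-bee assays are not reproduction targets —
raw choice sequences are not available — but the GLM recovers planted
logistic endpoints from synthetic sequences within their confidence bands.

## Problem sizes and budgets

Default experiment sizes — 50-replicate ensembles, 20 replicates per scan
grid point, 16 for the maintenance contour, 10-seed termination checks,
100-profile detector studies, 10⁶-draw moment oracles — were chosen so each
documented experiment completes in seconds to a few minutes on a single
CPU while keeping Monte-Carlo error well below every stated tolerance.

## Known limitations

* The 1D model has no mechanics, signalling or fate re-specification; it
  cannot address *why* fates sit where they do, only whether differential
  growth/division maintains a given boundary.
* Growth is deterministic between divisions; cell-size variability arises
  solely from division timing.
* The hybrid engine's divisions are synchronous within a step (order
  base-to-tip); at default `dt` this is indistinguishable from the exact
  engine in all tested observables, but very large propensities would
  require the exact mode.
* Scan conclusions are reported for the preset grids; the contour's rank
  correlation needs a grid fine enough to resolve the narrow maintenance
  band in the expansion ratio (the package's maintenance grid does).
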
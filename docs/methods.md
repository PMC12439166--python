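# Methods

`flavokit` implements the quantitative analysis used to study how plant
flavonoids (quercetin and its glycosides isoquercitrin and quercitrin)
self-assemble into supramolecular fibers and how that assembly shows up in
enzyme-panel screens and molecular simulations.  Four stages share one
package: dose–response fitting and efficacy ranking of an inhibition
screen; radius-of-gyration (RGYR) statistics of molecular trajectories;
geometric π-stacking assembly graphs; and a weighted-ensemble engine with a
variation-maximising resampler and −ln(p) free-energy profiling.  Synthetic
generators provide every input at desk scale, so the whole pipeline is
testable without external data.

## Dose–response fitting and IC50 categories

Percent inhibition *y* is modelled against log10 molar concentration *x*
with the four-parameter logistic

    y(x) = bottom + (top − bottom) / (1 + 10^(h (m − x)))

fitted by bounded least squares (`scipy.optimize.curve_fit`) jointly over
all replicates (never averaged first, preserving the error structure).  The
reported IC50 is the concentration at which the *fitted* curve crosses 50 %
inhibition — not the inflection parameter *m*; the two coincide only for
symmetric curves (bottom + top = 100).

**Parameterisation.** Bottom is free in [−20, 30] %, the Hill slope in
[0.2, 5], and the crossing may sit up to four decades outside the assay
window.  The upper plateau is pinned at 100 % by default (`fix_top=False`
frees it in [30, 120] %).  The percent-inhibition scale is
assay-normalised, so 100 % is the physical plateau; for partial curves that
never plateau inside the window a free top is unidentifiable, and the least
squares solution can collapse to a shallow plateau that misreads a genuine
partial inhibitor as baseline.  Initialisation: bottom 0, slope 1,
crossing at the concentration whose response is nearest 50 %; up to three
deterministically jittered restarts on non-convergence.

**Categories.** Each fit is classified, in this order:

1. `BASELINE` — optimiser failure, or the fitted maximum response inside
   the assay window is below the baseline threshold (default 25 %, a
   configuration knob; an epsilon of 1e-9 sends exact boundary cases to the
   fit), or the curve never reaches 50 %.  No IC50 is reported.
2. `IN_RANGE` — the 50 % crossing lies within the assay window
   (5 nM – 100 μM by default).  A crossing *below* the assay minimum keeps
   its fitted value and is also labelled in-range: the assay cannot resolve
   potency past its lowest concentration, and inventing a separate class
   for it would split hairs the data cannot support.
3. `EXTRAPOLATED` — the crossing lies strictly above the assay maximum; the
   extrapolated value is reported and flagged by category.

## Efficacy ranking

For enzyme *i*, every successfully determined log10 IC50 is standardised
against that enzyme's panel:

    z_i = (log10 IC50_i − X̄_i) / s_i

`s_i` is the sample standard deviation (n − 1; a `ddof` flag switches to
the population convention).  "Successful" covers in-range and, by default,
extrapolated fits (`include_extrapolated=False` restricts to in-range);
baseline fits are "no readout" and are imputed z = 2 — a deliberately poor
but finite score that keeps very weak inhibitors rankable.  Per compound:

    z̄ = (Σ_i w_i z_i) / panel_size,   w_i = N_i / Σ_i N_i

with `N_i` the successful-readout count for enzyme *i* and `panel_size`
the enzyme-panel size (7 for the screen design).  The division by
`panel_size` is deliberate and implemented literally even though the
weights already sum to one: it is a constant scale that preserves ranks
while keeping z̄ on the screen's published scale.  Enzymes with fewer than
two successful readouts have no defined scale and are dropped from both the
z-scores and the weights.  Compounds screened repeatedly are scored per
screen and their z̄ values averaged.  Ranking is ascending in z̄ (low z̄ =
high efficacy); ties break lexicographically by compound id and are
flagged.

## RGYR statistics

RGYR(t) = √( Σ_k m_k |r_k − r̄|² / Σ_k m_k ), with r̄ the mass-weighted
centre of mass; mass weighting is the default (the common
trajectory-analysis convention), with an unweighted variant by flag.
Selections are atom-tag filters (`protein`, `flavonoid_core`, `glycoside`,
`other`); which atoms enter a published compactness figure is often
unstated, so both protein-only and solute-included selections are one flag
apart.  Window bounds for late-trajectory summaries (default 200–400 ns)
are inclusive on both ends; times are in ns, lengths in nm.

Variance heterogeneity between conditions uses Levene's test
(`scipy.stats.levene`), mean-centred by default as the test is named;
Brown–Forsythe median centring is a flag, since common tooling defaults to
the median.  Duplicate simulations of one condition are pooled
(concatenated) before testing.

## π-stacking assembly graphs

A stacking contact between two rings requires three geometric gates, all
configurable: centroid distance ≤ 4.5 Å, interplanar angle ≤ 30° (between
best-fit plane normals, folded into [0, 90]°), and lateral offset ≤ 2.0 Å.
The defaults are standard parallel (face-to-face) π-stacking geometry.
The lateral offset is the minimum over the two rings of the in-plane
component of the centroid displacement; the minimum makes the gate
symmetric and lets ideal edge-to-face contacts (offset 0 in the
perpendicular ring's plane) pass when the optional T-shaped mode is on.
T-shaped (near-perpendicular) stacking is off by default and admitted
through an angle window [60°, 90°] when enabled.  Hydrogen-bond edges are
out of scope; branching is inferred purely from stacking degree.

Ring-level contacts collapse to one molecule-level edge; connected
components are classified exhaustively and exclusively: `SINGLETON` (one
molecule), `SECONDARY` (any molecule stacks with ≥ 3 partners — a branched
fiber), `CYCLIC` (a closed loop without branching), `PRIMARY` (a simple
linear stack).  Note a branch rooted at the *end* of a stack merely
extends the path and is still PRIMARY; the synthetic-fiber ground truth
accounts for this.

## Weighted-ensemble engine

`n_walkers` trajectories carry weights summing to one; each cycle they are
propagated `steps_per_cycle` dynamics steps and resampled.  The resampler
maximises the ensemble variation

    V = Σ_ij (d_ij / d0)^α

over a pluggable pairwise distance (default: |ΔRGYR|, or |Δx| for scalar
toy states), with characteristic distance `d0` (`char_dist`, default 0.1)
normalising the distance and `α` (`dist_exp`, default 4) sharpening it.
Each greedy iteration proposes: merge the closest eligible pair (pair
distance ≤ `merge_dist` = 0.25, combined weight ≤ `pmax` = 0.5) and clone
the walker with the largest row sum of (d/d0)^α whose half-weight stays
≥ `pmin` = 1e-12 and which is not in the pair; the clone's second copy
fills the freed slot, keeping the walker count constant.  The proposal is
accepted while V strictly increases (ties in the clone choice break to the
lowest walker index).  ΔV is evaluated with the merged walker keeping the
survivor slot's state — a deterministic proxy, since the surviving state is
then drawn weight-proportionally from the pair (standard weighted-ensemble
practice); the proxy keeps proposals reproducible given the seed.  Because
clones copy states and merges keep existing states, V takes finitely many
values and the strict-increase rule terminates (a 10·n iteration guard
backs this).  Cloning halves weights exactly and merging sums them, so
total weight is conserved to machine precision and all weights remain in
[pmin, pmax].

Resampler parameter defaults (50 walkers, 1000 cycles, merge distance
0.25, char_dist 0.1, pmax 0.5, pmin 1e-12, dist_exp 4) mirror the study's
weighted-ensemble configuration.  Novelty weights of the published
variation functional are fixed at 1 (the REVO-style objective reduces to
the pure distance term).  Whether a quoted "total simulation time" counts
per-walker or aggregate walker time is ambiguous in general, so
`WEResult.aggregate_time` reports both.

**Free-energy profiles.**  Pooled per-cycle values and weights (first 20 %
of cycles discarded as burn-in, configurable) are histogrammed — 50
uniform bins over the observed range by default, or fixed edges for
cross-run comparability; p̂_b is the weight fraction in bin b and
F_b = −ln p̂_b on occupied bins, in kT units up to an additive constant.

**Lineages.**  Every resampling records a parent-slot array; walking it
backwards from any final walker yields the continuous value/weight series
of its ancestry, a forest rooted at the initial walkers.

## Synthetic generators: what they emulate, and what they do not

All generators draw from a single `numpy.random.default_rng(seed)` stream
in a documented order, so fixed seeds give bit-identical output.

* **Inhibition panel** — the screen design: 58 compounds × 7 enzymes, 10
  concentrations log-spaced 5 nM – 100 μM, two technical replicates.
  Responses are the 4PL (bottom 0, top 100, Hill 1) plus Gaussian noise
  (default sd 5 percentage points), deliberately *not* clipped to
  [0, 100] — real readouts overshoot, and clipping would flatter the
  fitter.  The default composition places 106 pairs in-range (log-uniform
  10 nM – 10 μM), 49 above-range (log-uniform 150 – 250 μM, so partial
  inhibition is visible in-window but the crossing is not), and leaves 251
  absent — a 26/12/62 % composition to the nearest percent, matching the
  published screen's category mix.  Not emulated: plate effects,
  heteroscedastic noise, compound interference, cooperative slopes.
* **Collapse trajectory** — rigid random molecules in a box (default ten
  6-atom molecules, 4 nm box, emulating a ten-molecule assembly box) whose
  base centres drift toward the ensemble centroid at `collapse_rate`
  (default 0.01/ns) with *non-accumulating* Gaussian thermal jitter about
  the bases (sd 0.05 nm); zero rate therefore yields a trend-free
  stationary RGYR series rather than a diffusive drift.  Placement is
  uniform rejection sampling with a minimum separation (a deliberately
  light stand-in for packing optimisers), erroring after a bounded retry
  budget.  Not emulated: solvent, forces, realistic kinetics.
* **Ring fiber** — ideal planar unit-mass hexagons (circumradius 1.39 Å)
  stacked with given rise and twist; branches grow perpendicular to the
  main axis (directions cycling ±x, ±y, hence at most four branches), with
  branch-ring normals along the branch axis so the sub-stack is itself
  face-to-face stacked and the joint is an ideal edge-to-face contact —
  recovering branch connectivity therefore needs the detector's T-shaped
  mode.  Optional glycoside-like 4-atom clusters sit radially outward.
  The generator tests detector geometry, not chemistry.
* **Double-well propagator** — overdamped Langevin (Euler–Maruyama) on
  U(x) = barrier·((x/a)² − 1)², the standard bistable toy for rare-event
  samplers.  A generic factory accepts any force field; a harmonic-well
  variant (U = k x²/2) provides the analytically solvable Boltzmann
  reference N(0, kT/k) used to validate free-energy profiles.

Passing tests on these generators show the *analysis* is correct under the
statistical structure it assumes; they say nothing about force-field
accuracy, solvent effects, or real assay artefacts.

## Problem sizes and numerical choices

Test and acceptance runs use desk-scale sizes chosen to make the checks
statistically decisive: the full 406-fit screen for the category
composition; 100 seeded 3×2 panels (600 fits per noise level) for IC50
recovery; 1000 random configurations for the RGYR oracle; 1000 null
simulations at n = 400/group (the pooled 200-frame window of duplicate
runs) for the Levene type-I rate; 1000 resampling cycles at the study
parameters for weight conservation; and a 600-cycle harmonic-well run with
1000 steps (one relaxation time, 1/Dk) per cycle so walkers decorrelate
between resampling events before the Boltzmann comparison over the central
80 %-mass region.

Numerical details worth knowing: RGYR clips tiny negative second moments
from cancellation before the square root; the 50 % crossing exists iff
bottom < 50 < top; zero-noise generator paths avoid drawing from the rng
so zero-noise output is exactly the model curve; ring normals come from
the smallest singular vector of the centred ring atoms; the weighted
histogram normalises by total retained weight, making profiles invariant
to weight rescaling.

## Known limitations

* The fitter assumes a monotone sigmoid; bell-shaped (auto-inhibitory)
  dose–response data will be misread.
* Category assignment near the baseline threshold or the assay edge is
  sensitive to noise by construction; the threshold is a knob, and the
  zero-noise path is exact.
* The resampler's ΔV proxy (survivor keeps its slot state) can, rarely,
  accept a proposal whose realised V decrease after the stochastic
  survivor draw; the iteration guard bounds any pathological looping.
* Stacking detection is purely geometric — no energetics, no
  hydrogen-bond edges, no helicity; T-shaped contacts are all-or-nothing
  within the angle window.
* The weighted-ensemble engine propagates toy dynamics (scalars or rigid
  clusters) only; it does not wrap an MD engine.
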
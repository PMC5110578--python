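# Methods

## The problem

*Escherichia coli* NZN111 carries insertional knockouts of *ldhA*
(D-lactate dehydrogenase, reaction `LDH_D`) and *pflB* (pyruvate
formate-lyase, reaction `PFL`). The strain was engineered to divert
anaerobic carbon flow into succinate, yet it fails to grow anaerobically on
glucose. fluxprof reproduces the in-silico analysis of that phenotype:
instead of optimizing a single flux state, it characterizes the *entire*
feasible flux space of each strain by uniform-like Monte Carlo sampling and
asks how knockouts reshape its average behavior — in particular the
turnover of the NADH/NAD⁺ pool that the two deleted fermentation branches
normally regenerate.

## Constraint-based models and strains

A model is a stoichiometric matrix `S` (rows = metabolites, columns =
reactions), flux bounds `l ≤ v ≤ u` (mmol/gDW/h), and GPR rules. The
steady-state flux space is the bounded polytope

    P = { v : S v = 0,  l ≤ v ≤ u }.

Strains are pure structural edits: `del_ldh` removes `LDH_D`, `del_pfl`
removes `PFL`, `nzn` removes both. Metabolites orphaned by a deletion are
kept; their flux-sum is then 0, which is informative in the strain
comparison tables. The anaerobic condition closes the oxygen exchange
(lower bound 0) and touches nothing else; the glucose exchange keeps the
source model's default (−10 for the E. coli core model) and the
ATP-maintenance bound keeps its default (8.39). Cross-strain comparability
comes from *post-hoc* normalization (below), not from re-bounding glucose.

Parsing (SBML L3+FBC, BiGG JSON) is delegated to cobrapy and converted to
package-native dataclasses, so every downstream computation is explicit
linear algebra over `S`, `l`, `u`.

A `reorient_reactions` utility negates a reaction's stoichiometry and
swaps/negates its bounds. Rewriting reaction directionality this way is
presentation-only (it flips the sign of the affected flux coordinates and
of their pairwise correlations); fluxprof never flips reactions
automatically, because any particular choice of rewritten reactions is a
display convention, not part of the model's content.

## ACHR sampling

The sampler draws `n_samples` flux vectors approximately uniformly from
`P` with artificial centering hit-and-run:

1. **Warm-up.** Each reaction is minimized and maximized by LP (flux
   variability analysis), giving `2·n_reactions` vertices that span `P`.
   Each point is shrunk 30% toward the warm-up mean so no starting point
   sits exactly at an extremity, then projected onto the null space of
   `S`. A literal basic-hit-and-run warm-up (`warmup_mode="hit_and_run"`)
   is available as an alternative.
2. **Directions.** At each step a random warm-up point `y` is chosen and
   the walk moves from the current point `x` along `d = y − s`, where `s`
   is the approximate center. The step length is uniform on the exact
   feasible interval `[α_min, α_max]` computed from the bounds
   (`step_limits`).
3. **Center update.** Two schemes are implemented. The default keeps the
   direction set fixed at the warm-up points and takes `s` as the running
   mean of all accepted points (the COBRA-Toolbox convention). With
   `update_warmup=True` each new point replaces a random column of the
   warm-up matrix and the center follows the matrix (the original
   artificial-centering scheme). The default mixes far better across
   wide, loosely-constrained cycles — on the E. coli core network the
   quinone-loop turnover converges to its uniform value only under the
   fixed-direction scheme — and is the variant whose output matches the
   published strain tables; the replacement scheme is retained for
   comparison.

### Numerical choices

* **Thinning** (`steps_per_sample`, default 100): one sample is recorded
  every 100 accepted steps.
* **Reprojection** (`reproject_every`, default 10): floating-point drift
  off the null space accumulates along the walk; every 10 steps the point
  is re-orthogonalized against the row space of `S` via a precomputed
  orthonormal null-space basis. Every returned sample is checked to
  satisfy `max|S v| ≤ 1e−6` (`residual_tolerance`); the observed residual
  on the core model is ~1e−8.
* **Rejection, not clipping.** A step that lands outside the bounds by
  more than `1e−9` is rejected and the walk restarts from the center with
  a fresh direction (bounded retries). Clipping to the bounds instead
  would push the point off the null space and is never done.
* **Degenerate steps.** When `α_min = α_max` (vertex faces, signed zeros)
  the draw `α = α_min + U·max(α_max − α_min, 0)` keeps the current point
  rather than failing.
* **Fixed coordinates.** Reactions whose FVA range is a single point
  (e.g. everything structurally blocked by a knockout) are excluded from
  directions and pinned to their unique value, snapped to exactly 0 when
  |value| < 1e−9. Knockout-blocked exchanges are therefore *exactly* zero
  in every sample, not merely small.
* **Direction tolerance** 1e−7 (absolute): coordinates with smaller
  direction components are ignored in the step-interval computation;
  near-zero directions are resampled.
* **Determinism.** A single seeded generator drives warm-up choice, step
  size, and (in replacement mode) column replacement; identical model +
  config + seed give bit-identical sample sets.

## Downstream statistics

* **Summary.** Per-reaction mean and sample SD over the `n_samples`
  vectors. **Normalization** rescales all means and SDs by
  `target / |mean(reference)|` so the glucose uptake magnitude equals
  exactly 10 mmol/gDW/h; being a uniform rescaling it preserves every
  ratio between fluxes.
* **Flux-sum.** `Φ_i = 0.5 Σ_j |S_ij v_j|`, computed on the (normalized)
  mean flux vector — the turnover of metabolite i, equal to its total
  production and total consumption at steady state. A per-sample variant
  (`flux_sum_per_sample`) averages `Φ` over individual samples; the two
  differ whenever a flux changes sign across samples, and the mean-vector
  form is the default because the strain tables are defined over the
  average flux distribution.
* **Correlations.** Pearson r between all reaction pairs over samples.
  Zero-variance reactions (knockout-blocked neighbors) are reported as
  NaN, not 0: "no defined correlation" and "uncorrelated" are different
  claims.
* **Histograms.** Equal-width bins over the observed range (default 30);
  a constant flux gets one occupied unit-width bin.
* **Constrained scan.** The target exchange's LP maximum `v_max` is
  computed under the strain/condition, `[0, v_max]` is split into equal
  bins, the reaction is constrained to each bin, and the polytope is
  re-sampled per bin. Summaries are re-normalized *per bin* to glucose
  = 10 (each bin is its own conditional flux distribution, so each is
  rescaled on its own mean glucose uptake); flux-sums are computed on the
  per-bin normalized means. Infeasible bins are recorded and skipped.
  On the core-model double knockout at glucose 10 the LP maximum of the
  succinate exchange is 13.9058, so the four bins reproduce the published
  bin boundaries.

## Expression mapping

Raw intensities are log2-transformed. A reaction's expression is the
recursive GPR evaluation with AND → min (a complex is limited by its
scarcest subunit) and OR → max (the strongest isoenzyme carries the
reaction); an OR → sum mode is available. Unmeasured genes leave their
leaf undefined: OR skips undefined children, AND propagates undefinedness;
reactions with no evaluable rule are flagged missing rather than defaulted.
A configurable gene exclusion list is supported (the E. coli spontaneous-
reaction pseudo-gene `s0001` is the canonical exclusion). Two conditions
are compared per reaction as `case/control − 1` and globally by a
two-sample Kolmogorov–Smirnov test (asymptotic p-value; exact for
min(n) < 10). Min/max is a convention choice: published analyses of this
type rarely state their aggregation rule, so the package documents its own
and exposes the alternative, and derived p-values additionally depend on
upstream microarray summarization, which is out of scope (inputs are
already-summarized per-gene tables).

## Synthetic data

* **Toy fermentation network** (22 reactions, 20 metabolites): lumped
  glycolysis producing 2 NADH per glucose; an LDH branch regenerating
  1 NAD⁺ per pyruvate; a PFL→acetyl-CoA→ethanol branch regenerating
  2 NAD⁺ per pyruvate (plus PDH so acetyl-CoA survives the PFL knockout,
  as in the real core network); a PEP-carboxylation route to succinate
  consuming NADH and quinol, recharged by an NADH16-like quinone
  oxidoreductase; exchanges for glucose (default uptake bound 10),
  lactate, formate, ethanol, acetate, succinate, CO₂, water and protons;
  GPRs with synthetic gene ids on LDH/PFL/ADHE/NADH16/FRD (including one
  AND and one OR rule). Deleting LDH (PFL) makes lactate (formate) export
  a structural zero, provable by FVA. The network is deliberately *not* a
  miniature of the core model: it has no biomass reaction, no ATP
  bookkeeping and lumped redox steps, so quantitative agreement with the
  core-model tables is out of its scope — it exists to make knockout
  logic, mass balance and sampler behavior analytically checkable.
* **Box polytopes**: models with bounds but no metabolites, whose uniform
  law is known in closed form (mean = midpoint, variance = width²/12);
  they calibrate the sampler's moments and distribution shape.
* **Expression datasets**: per-gene control values
  Normal(baseline 8.0, sd 0.1) on the log2 scale, the perturbed condition
  drawing independent noise plus specified log2-fold-changes. Defaults
  (8 ± 0.1 log2 units, ±0.5 planted shifts, 136 genes in the detection
  test) match the scale of summarized two-color microarray data. What a
  passing test shows: planted shifts of that size are recovered through
  the GPR mapping and detected by the KS test; it does not validate
  upstream normalization of real arrays.

## Problem sizes and defaults

The package defaults are the study conditions: 2000 samples per polytope,
thinning 100, seed 42, anaerobic condition, normalization target
10 mmol/gDW/h, 4 scan bins. The test suite uses smaller chains
(50–2000 samples) chosen per test to keep each check sharp;
`scripts/acceptance.py` runs the full four-strain profile and scan at the
default 2000 samples.

## Known limitations

* Uniformity is asymptotic; with 2000 thinned samples the slowest
  polytope directions (wide internal cycles) still carry a few percent of
  Monte-Carlo error, visible in the quinone-pool turnover.
* The sampler is not a convergence-diagnosed MCMC suite: only moment and
  autocorrelation checks are built in (no OptGP, no parallel chains, no
  formal R-hat).
* Flux-sums on mean vectors understate the turnover of metabolites whose
  fluxes change sign across the polytope; use the per-sample variant to
  quantify the difference.
* The expression pipeline consumes summarized per-gene tables only; CEL
  processing, array normalization and probe-to-gene mapping are upstream
  concerns.
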
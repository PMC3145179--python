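# Methods

`beringia` reconstructs how Miocene–Pleistocene climate change filtered which
lineages of a Palaearctic-centred clade could cross Beringia into the New
World. Five linked analyses are implemented; each is summarized below with
its assumptions, tunable parameters and numerical choices.

## 1. Trees and units

Trees are rooted, may contain polytomies, and carry an explicit
branch-length unit: `subs/site` (phylogram), `Ma` (chronogram) or
`unitless`. Nodes are addressed by post-order integer IDs fixed at parse
time; all stage outputs reference these IDs. Mixing units across stages is a
hard error — the thermal model needs a phylogram (root-to-tip path-length
variation identifies the directional trend), while range reconstruction runs
on a chronogram.

## 2. Node dating

Two dating methods convert a phylogram into node ages using external
substitution rates (no fossil calibrations):

* **Strict clock** — a node's age is the mean tip-to-node path length across
  its descendant tips divided by the rate. Averaging enforces
  ultrametricity; ages are clamped so a parent is never younger than a
  child.
* **Penalized likelihood** — branch rates `r_b` and node times `t` jointly
  maximize `Σ_b [n_b log(r_b Δt_b) − r_b Δt_b] − λ_s Σ (r_parent −
  r_child)²`, where `n_b` is the expected substitution count (branch length
  × alignment length). Without calibrations the time scale is free, so it is
  pinned by constraining the tree-wide mean rate (total substitutions /
  total branch time) to the configured rate; for a clock-like tree this
  reproduces the strict-clock ages. The optimizer is multi-start L-BFGS-B on
  logit height proportions and log rates (5 restarts, seeded). The
  smoothing value `λ_s` has no data-driven default here (no
  cross-validation); it is an explicit configuration choice.

The canonical rate grid pairs both methods with four rates — 6.5, 7.5 and
9.5 × 10⁻⁹ substitutions·site⁻¹·yr⁻¹ for COI and 11.5 × 10⁻⁹ for
COI+tRNA+COII — and the per-node mean over the eight runs is the consensus
age.

## 3. DEC range reconstruction

Geographic ranges are subsets (≤ `max_range_size`, default 2) of ten areas;
anagenetic evolution is a CTMC in which a range expands into area *a* at
rate `d · Σ_{b∈range} multiplier[b][a]` and loses any area at rate `e`; at
cladogenesis the classic DEC scenarios (identical inheritance for single
areas; single-area sympatric subset and allopatric vicariance otherwise) are
weighted equally. Transition probabilities use `scipy.linalg.expm`
(Padé scaling-and-squaring). The dispersal graph joins land neighbours plus
two transoceanic routes: East Palaearctic↔West Nearctic (north Pacific,
Beringia) and West Palaearctic↔East Nearctic (north Atlantic); the
Africa↔Oriental edge ships enabled and can be removed by supplying a custom
edge list. Dispersal multipliers are constant in time (no stratification):
the crossings of interest post-date the opening of the Bering Strait, so a
permanently open route is the faithful default.

The root prior is uniform over ranges that form a **connected** subgraph of
the dispersal graph. Disjunct ranges are retained as states but excluded
from the prior: no dispersal path can ever assemble them (expansion rates
into non-adjacent areas are zero), so prior mass there lets a maximum-
likelihood history "teleport" a lineage between hemispheres without any
inferred dispersal event.

`d` and `e` are fitted by bounded multi-start ML. Per-node marginal range
probabilities come from an inside–outside pass over the cladogenetic model;
the event list is read off the joint (max-product) history: the set change
along each branch is decomposed into the shortest adjacency-respecting
sequence of single gains/losses (BFS over range space, deterministic
tie-break by area order), and every gain is annotated with its source area
and route. Old-World→New-World crossings are gains whose source lies in the
Palaearctic/Old-World group and whose gained area is Nearctic/Neotropical.

Polytomies are resolved internally with zero-length branches (the
zero-length transition matrix is the identity, so the likelihood is
unchanged); reported node IDs refer to the original tree.

*Identifiability caveat:* under DEC, a gain immediately before a speciation
node is likelihood-equivalent to the same gain immediately after it, so
event attribution is only resolved to a branch neighbourhood; the
simulation-recovery test scores accordingly, and transient gains that are
lost again within a branch are unknowable in principle.

## 4. Thermal tolerance: directional Brownian model

Each taxon's thermal tolerance is the pair (T_cold, T_warm): mean annual
temperature at the coldest and warmest known locality (°C). The pair evolves
as correlated Brownian motion with 2×2 rate matrix Σ on the phylogram,
modified by Pagel transforms applied in the fixed order κ → δ → λ (branch
lengths powered, then node depths powered, then off-diagonal covariance
scaled). Model A is trendless (tip mean α); model B adds a directional term
`α + β · depth` per trait. "Ordered continuous" coding means plain
continuous traits whose columns happen to be ordered per taxon; no ordinal
model is involved. T_cold > T_warm in an input row is reported (warning),
never silently fixed.

Inference is random-walk Metropolis–Hastings over (α, β, Σ, λ[, δ, κ]) with
flat priors on bounded supports: λ ~ U[0,1]; Σ diagonals log-uniform over
±6 decades around the empirical trait-variance/depth scale; correlation
~ U(−1,1); α, β ~ N(0, 10³). δ and κ are fixed to 1 by default (estimating
them is a flag) — freeing them was reported not to change fits appreciably
in this system, and fixing them keeps λ cleanly interpretable. Chain
presets: `desk` 200 000 iterations / burn-in 5 000 / thin 100 (the default
used throughout the tests and the acceptance script); `paper` 5 000 000 /
5 000 / 100 mirrors the published run length; `smoke` 20 000 for integration
checks. Per-block proposal scales default to ~20–50 % acceptance on typical
problems; the covariance Cholesky is cached and only recomputed when a
transform parameter moves, which keeps a 73-tip chain near 3 000
iterations/s.

Ancestral states at an interior node are drawn per retained posterior
sample from the exact conditional bivariate normal given the tips (λ scales
node–tip covariances like any other off-diagonal entry; the node variance
is untouched), then summarized as posterior mean and 2.5/97.5 percentiles.

Model comparison reports both a likelihood-ratio test on ML fits (χ², df =
number of β parameters added) and a stepping-stone log Bayes factor from
power-posterior chains (8 rungs, β_k = (k/K)^{1/0.3}). "Best" defaults to
LRT p < 0.05. The χ² null is asymptotic: at ~20 tips its type-I rate is
visibly inflated, so the calibration simulations use 40-tip trees.

## 5. Paleotemperature

The benthic δ18O record (heavier = colder) is smoothed with a 50-point
(sample-count, not Myr) centered running mean, shrinking the window
symmetrically at the edges. Calibration to Beringian mean annual temperature
is a piecewise-linear map **in δ18O space** through the anchor pairs —
(0 Ma, −9 °C), (9 Ma, 4 °C), (14 Ma, 11 °C) by default — linearly extended
beyond the outer anchors, so each anchor is reproduced exactly (anchor ages
are inserted into the output grid to keep this exact under age
interpolation). A least-squares straight-line alternative is available
behind a flag. Evaluation outside the record's age span raises rather than
extrapolating.

## 6. Gateway tests

* **Cooling trend** — Pearson correlation between colonization age and the
  chosen tolerance character, tested against the exact permutation null
  (exhaustive for n ≤ 7, so with five events the attainable p-values are
  k/120; seeded Monte-Carlo beyond). One-sided in the direction "younger
  colonizer ⇒ colder tolerance"; a rank-based variant is invariant to
  monotone age transforms. With n = 5 an asymptotic t test is dubious, hence
  the permutation default; the t test remains selectable.
* **Beringia match** — an ancestor matches if the calibrated Beringian
  temperature at its crossing age lies inside [T_cold − margin, T_warm +
  margin]; margin defaults to 0 °C and every report carries the
  distance-to-interval so near-misses stay visible.
* **Hostplant parsimony** — unit-cost minimum-change reconstruction of the
  unordered hostplant-family character. The implementation is the unit-cost
  dynamic program (up and down passes), exact for polytomies; per-node sets
  contain precisely the states present in at least one globally most
  parsimonious assignment.

## 7. Synthetic data and the backbone fixture

Simulators (all pure functions of parameters + seed):

* `sim_tree` — birth–death chronogram conditioned on n tips (birth 0.3,
  death 0.1 /Myr by default) via dendropy, with the clock run on to the next
  event after the final speciation so cherries have positive lengths;
  phylogram obtained by multiplying each branch by an independent lognormal
  rate (median 0.0075 subs/site/Ma ≡ 7.5×10⁻⁹ /yr, log-sd 0.3).
* `sim_bm_traits` — joint multivariate-normal draw over all nodes under the
  transformed model (branch-wise recursion cannot represent λ < 1), with
  internal-node truths returned. Default truth used in tests and acceptance:
  α = (−5, 15) °C, β = (−30, −15) °C per unit path, Σ = [[300, 120], [120,
  200]] °C²/unit, λ = 0.925 — chosen to give realistic present-day spreads
  (tip SD ≈ 6–7 °C around a 20 °C cold–warm separation) on trees whose
  phylogram depth is ≈ 0.1–0.2 subs/site.
* `sim_dec_ranges` — Gillespie anagenesis per branch plus uniformly chosen
  cladogenetic scenarios; every gain is recorded with branch, time, source,
  route and whether it persisted to the branch end.
* `sim_delta18o` — linear cooling trend in expectation (1.4‰ at 14 Ma to
  3.6‰ at 0 Ma, the Miocene-to-present benthic range) plus white noise
  (SD 0.25‰), 1000 evenly spaced samples.

The genus-level backbone fixture is a hand-encoded 17-tip chronogram
honouring the published topology: the Chilades group sister to the rest; a
monophyletic Neotropical clade (Pseudolucia, Echinargus, Hemiargus,
Cyclargus as representatives) sister to Holarctic taxa plus Freyeria; and
Icaricia–Plebulina, Lycaeides, Agriades and Vacciniina each paired with an
East Palaearctic sister, with the three Holarctic species that span both
hemispheres (L. idas, A. glandon, V. optilete) split into OW/NW terminals
with disjoint ranges. The five colonization nodes carry the published mean
ages (10.7, 9.3, 2.4, 1.1, 1.0 Ma); all other node ages are interpolated
scaffolding, and hostplant codings condense each genus to its dominant
family. Tip tolerances are hand-set synthetic values running from
warm-adapted Neotropical stock to cold-adapted recent colonizers. The
fixture is a synthetic stand-in: the full 73-taxon phylogeny, its supporting
alignments and the real per-taxon climate survey are not available in
machine-readable form, so the published colonization ages and λ = 0.925 are
**inputs** (fixture constants, simulation truths) here, not quantities the
package re-estimates; reproducing them for real requires the original
sequence data and tree inference, which are out of scope.

## 8. What passing tests do and do not show

The synthetic generator matches the study's structure (tree size, trait
model, area system, cooling curve) but not its irregularities: real
phylograms have correlated rate variation, real tolerance data carry survey
and raster-extraction error, and the real δ18O curve has excursions a linear
ramp lacks. Passing recovery tests therefore demonstrates the estimators
are correct and well calibrated under the stated model, not that the model
captures every feature of the original data.

Problem sizes used by the default test run: 73-tip trees and 10 seeds for
λ recovery (80 000-iteration chains in the test suite; the acceptance script
uses the full `desk` preset), 25–40-tip trees for recovery/calibration
simulations, 15-tip trees for ancestral-state coverage. These sizes give
stable Monte-Carlo behaviour at interactive run times.
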
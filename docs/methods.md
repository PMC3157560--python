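# Methods

## Apparatus models

Both mazes are discrete grids with physical (cm) coordinates and a
designated vertical axis.

* **Pegboard** — a vertical board carrying pegs at 10 cm spacing, analysed
  as a 5 × 5 grid of reward regions (2 × 2 pegs each, 20 cm pitch). Axes:
  X horizontal, Z vertical; origin at the bottom-left region corner. The
  food in a region sits on one of its four pegs, i.e. at ±5 cm from the
  region centre on each axis; the peg choice is drawn uniformly per region
  per trial. All band statistics run at region resolution (the ordinals
  belong to the 25 regions); only route lengths see the peg offsets.
* **Lattice** — a 50 cm cube of 4 × 4 × 4 hollow cubes (12.5 cm edge),
  X/Y horizontal, Z vertical, origin at the front lower-left corner.
  Baited positions are intersection points: per layer, 6 of the 25 nodes
  of the 5 × 5 horizontal node grid, drawn uniformly without replacement.
  For band statistics each node is snapped to the cube whose centre is
  nearest (ties toward the lower index); the physical coordinate keeps the
  node position horizontally and uses the layer's cube-centre height
  vertically (all distance-based results are invariant to that vertical
  translation; only the 12.5 cm layer spacing matters). Two nodes of a
  layer may snap to the same cube; they remain distinct retrievals.

Band partitions: *layers* are constant-Z bands in both mazes; pegboard
*columns* are constant-X bands; lattice *slices* are constant-Y (X–Z
plane) or constant-X (Y–Z plane) slabs. Bands partition the grid with
equal populations (5 cells per pegboard band, 16 per lattice band).

## Synthetic agents

Every agent visits each baited position exactly once (no revisits, no
timeout): the generator emulates the baiting protocols and deliberately
idealised visit behaviour, not fatigue, thigmotaxis or satiety. Strategies:

* `layer_snake` / `column_snake` — exhaust each band before moving to the
  next (boustrophedon), starting from the band containing the start
  corner;
* `random_order` — uniform permutation, first visit fixed at the baited
  position nearest the start;
* `greedy_nearest` — nearest unvisited food by Euclidean distance, ties
  toward the lower linear index.

Trajectories interpolate the visit order at constant speed and a fixed
sampling rate; they exist so the binning/crossing code can be exercised on
timestamped position data of the shape a tracker would emit. Detour
choices are Bernoulli draws per journey direction with per-direction
probabilities; incomplete trials can be represented by a `none` choice and
are excluded from all denominators.

Because agents always complete their trials, passing tests show that the
statistics behave correctly on idealised retrieval sequences; they do not
show that real, possibly truncated rat trials would yield any particular
value (see "Known limitations").

## Ordinal distances

OD_k is the mean absolute pairwise difference of the ordinals within band
k, computed in O(n log n) via the sorted-prefix identity; bands with fewer
than two retrievals are skipped, and a sequence with no usable band (p =
0) is an error at the single-trial level and a logged skip at the pooled
level. ODs are computed per trial and then averaged; ratios are formed per
trial against that trial's own optimised route and then averaged. The
Monte-Carlo null (`od_expectation_random`) reports the mean OD of
uniformly random orders, which is (N+1)/3 on every grouping axis —
about 8.67 for N = 25. Note that a random strategy therefore produces OD
*ratios* well above 1 (≈ 8.67 against optimised ODs of ≈ 5–7), so a ratio
near 1 is not by itself evidence of random foraging; the package reports
the Monte-Carlo null alongside ratios for that reason.

A structural fact worth knowing when interpreting pooled pegboard values:
for any complete visit order of all 25 regions, layer OD + column OD ≥ 12,
with equality exactly at the boustrophedon (2 + 10). The bound was
verified by exhaustive enumeration on the 3 × 3 analogue (minimum sum
16/3, the snake's value) and by simulated annealing on the 5 × 5 (minimum
found 12.0 across restarts). Horizontal and vertical clustering trade off;
no complete sequence is strongly clustered on both axes at once.

## Route optimiser

A mutation-only genetic algorithm over open, fixed-start tours:

* **Anchor** — the first retrieval is the food in the bin adjacent to the
  start corner along X (same indices otherwise); if that bin is empty, the
  food nearest that bin's centre. The anchor never mutates.
* **Generation** — the population (default 100) is randomly partitioned
  into quartets; each quartet's shortest route survives and produces three
  offspring with one shared random segment [i, j]: *flip* (reverse the
  segment), *swap* (exchange the segment's endpoints), *slide* (rotate the
  segment by one).
* **Restarts** — independent re-initialisations; the incumbent best over
  all generations and restarts is returned. Restarts are evolved batched
  in one vectorised population (selection partitions within restart
  blocks), so a full 20-restart × 2000-generation run on a 25-position
  instance takes about two seconds.

Profiles: the full-scale profile (1000 restarts × 10000 generations) is
the class-default; `desk_scale()` (20 × 2000) is used for the pooled
control studies and test suite and returns the same optima on 24–25
position instances (checked against a 50 × 8000 run on sample layouts);
`light()` (4 × 500) is used where only a converged-enough reference OD is
needed, e.g. per-trial ratios inside 100-seed sweeps. On instances with ≤
8 positions the GA matches an exhaustive fixed-start enumeration oracle in
≥ 95% of seeds at `light()` settings.

Distances are Euclidean over the actual food coordinates (jittered pegs /
lattice nodes), not bin centres: the optimiser sees the same geometry the
forager does. Tours are open (no return to start).

An empirically important property: the X-axis anchoring rule breaks the
layer/column symmetry of the optimised routes. On complete pegboard
layouts the pooled optimised layer OD exceeds the column OD (≈ 7.5 vs
≈ 6.1 over 80 layouts); re-running with a Z-adjacent anchor flips the
asymmetry (≈ 6.7 vs ≈ 6.9). Gravity-blindness of the objective therefore
shows cleanly in the crossing counts (pooled optimised X vs Z crossings
≈ 13.4 vs 13.4, not significantly different) but not exactly in the band
ODs of anchored routes.

## Crossing counts

Samples are binned half-open (`floor(coord / cell)`, boundary to the
higher bin, top edge clamped), consecutive duplicates collapsed, and
crossings accumulated as |Δindex| per axis over consecutive bins; a
diagonal change increments every changed axis. For retrieval routes the
inter-retrieval path is the straight segment between cell centres, along
which every axis coordinate is monotone, so its per-axis crossings equal
|Δindex| exactly. Tracker smoothing is not modelled; an optional median
filter over bin indices (default off) is provided for noisy input.

## Group statistics

Means ± SEM, paired t (df = n − 1; identical vectors return t = 0, p = 1;
any other zero-variance difference is rejected as degenerate), balanced
two-factor fixed-effects ANOVA with interaction (statsmodels OLS +
anova_lm; unbalanced designs rejected because F under imbalance depends on
the sum-of-squares type), one-way ANOVA with Bonferroni-multiplied
pairwise t-tests (capped at 1), exact Clopper–Pearson CIs for choice
proportions, and a per-rat one-sample t on choice proportions. The
experimental unit for pooled tests defaults to the rat (per-rat means
across trials); `per_unit_means` lets callers pool per trial-day instead —
both units are defensible for these designs and they give different
degrees of freedom, so the choice is explicit at the call site. Type-I
calibration of all three tests is verified at 10,000 null simulations
(5% ± 1.5%), including the per-rat test under a discrete binomial null.

## Reproducibility

Every stage takes an explicit seed; the pipeline derives child seeds from
one master seed by fixed offsets (layouts: seed + trial index; agents:
+100000; GA: +200000), writes all outputs as CSV with a fixed float
format, and records file checksums, seeds and the package version in
`manifest.json`. Two runs with the same config are byte-identical.

## Problem sizes

The pooled control studies use 80 layouts per maze (matching the pooled
trial counts of the original designs: 8 subjects × 10 pegboard sessions, 8
subjects × 5 lattice days × 2 trials) with the desk-scale GA profile; the
strategy-recovery sweep uses 100 seeds with the light profile; calibration
uses 10,000 null replicates. These sizes give SEMs of ≈ 0.15–0.2 OD units
on pooled controls and were chosen once as the study conditions for all
tests and reported numbers.

## Known limitations

* Agents always complete their trials. Real trials under a time cutoff
  produce retrieval sets with N below the full count, which *scales ODs
  down* (E[OD] = (N+1)/3): pooled ODs from complete sequences are
  systematically larger than pooled ODs from truncated ones, and on the
  pegboard the layer+column sum of any complete sequence is bounded below
  by 12. Comparisons against published values obtained from truncated
  trials must account for this; the package reports what complete
  sequences yield.
* The completion process itself (how many and which positions a truncated
  trial retains) is not modelled, deliberately: no completion statistics
  were available to fit, and inventing them would silently tune results.
* Detour choices are exchangeable Bernoulli draws; no learning, first-trial
  novelty effects, or barrier-geometry costs.
* Linear mixed models for offset-barrier contrasts are out of scope;
  per-condition proportions with exact CIs are reported instead.
* No plotting; all outputs are CSV/Markdown/JSON tables.
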
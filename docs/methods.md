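# Methods

## Ranking and score orientation

Docking engines disagree on sign conventions (binding energies are
lower-is-better, fitness scores higher-is-better), so orientation is an
explicit argument and never inferred. Internally every list is reduced to
ranks with rank 1 = best. Tied scores receive average ranks for AUC and
percentile computations; for window membership a stable sort with the
compound id as tie-break makes reruns reproducible. Record order in files
is preserved on parsing.

## Enrichment metrics

With `N_total` compounds, `Hits_total` actives, and a window of the top
fraction `f`:

* `N_sampled = ceil(f · N_total)` — the ceiling guarantees a non-empty
  window even for 1% of a ~7,000-compound library.
* `EF(f) = (Hits_sampled/Hits_total) / (N_sampled/N_total)`. Bounds:
  `0 ≤ EF(f) ≤ min(1/f, N_total/Hits_total)` and `EF(1) = 1` exactly. For a
  random ranking E[EF] = 1, which the test suite checks by label shuffling.
* Percentile rank of the record at (average) rank r is `100·r/N_total`;
  APR is the mean percentile rank over **all** actives, not only those in
  the window. `EF'(f) = (50/APR) × (Hits_sampled/Hits_total)`, reported as
  0 when the window holds no actives even though the APR term is global.
  An alternative reading computes APR over the sampled actives only and
  yields much larger early-recognition values; the all-actives convention
  is the one adopted here, and EF' values are therefore conservative.
* `EF*(f)` is the mean of EF over the fraction grid `{f/10, 2f/10, …, f}`
  — enrichment integrated over a widening selection window. The difference
  family is pairwise on the same library: `DEF = EF_a − EF_b`,
  `DEF* = EF*_a − EF*_b`, `DEF' = EF'_a − EF'_b`. These four are
  package-fixed definitions (reported with a provenance note in output
  metadata); the literature names them without an agreed formula, so
  values are comparable only within this package.
* AUC is the Mann–Whitney statistic: the probability that a random active
  outranks a random decoy, ties counting one half. Computed via
  scikit-learn; an independent brute-force pairwise count serves as the
  oracle in the tests. Unknown-label records are excluded from ROC/AUC but
  kept in EF windows (they occupy ranks).

Hit classification is `IC50 < threshold` (strict, default 100 µM) with an
explicit override list for borderline calls a team chooses to accept; an
override is flagged in the output rather than silently merged. Hit rates
are reported in percent to two decimals.

## Consensus pose filter

Both programs dock into the same prepared receptor, so the pose-agreement
measure is the **in-place** RMSD — superposition would mask exactly the
disagreement being measured. Hydrogens are dropped first (programs differ
in hydrogen placement conventions); correspondence is file atom order,
validated against the element sequence. Symmetry-equivalent atom
permutations (e.g. a flipped phenyl ring) are *not* corrected, which
overestimates RMSD for symmetric ligands — a documented limitation.
A pose exactly at the threshold is accepted (`rmsd ≤ τ`). Accept sets are
nested in the threshold, which the sweep relies on.

## ADME pre-filter

Pass requires all of: zero Lipinski violations (among MW > 500, logP > 5,
HBD > 5, HBA > 10 — boundaries themselves are compliant), PSA strictly
below 140 Å² (strict, reading "below"; a CNS-optimised 90 Å² cut is a
parameter, not a default), and logBB in the closed interval [−3.0, 1.2].
Failures carry every violated rule. Properties are inputs from a property
calculator; nothing is predicted here.

## QSAR

* **Response**: pIC50 = −log10(IC50 in mol/L); µM inputs are converted as
  −log10(x·10⁻⁶). Molar is the standard convention.
* **Pruning**: drop columns whose modal value frequency exceeds 0.95, then
  scan in input order and drop the *later* column of any pair with
  |Pearson r| > 0.90 — deterministic and order-stable.
* **Fit**: OLS with intercept (statsmodels). `R²adj = 1 − (1−R²)(n−1)/(n−p−1)`;
  t = coefficient / standard error; `VIF_j = 1/(1−R²_j)` from regressing
  descriptor j on the others (with intercept); a single descriptor has
  VIF 1 by convention. Rank-deficient designs raise an error naming the
  dependent columns.
* **LOO Q²** = 1 − PRESS/TSS with PRESS from n literal refits and TSS about
  the full-data mean; the tests cross-check against the hat-matrix PRESS
  identity `e_i/(1−h_ii)`.
* **GA selection** searches fixed-size descriptor subsets maximising LOO
  Q². Defaults: population 50, generations 100, tournament selection of
  size 3, uniform crossover rate 0.8 (child genes drawn from the parents'
  union), per-gene mutation 0.05, elitism 1. These are fixed, seeded
  defaults — selection is bit-for-bit reproducible given the seed, and
  singular candidate subsets score −∞ rather than aborting the search.
  Fitness values are cached per subset.
* **Split**: train size = round(n·frac) of a seeded shuffle; 15 compounds
  at 0.8 give 12/3.
* **Y-randomization** refits on seeded permutations of the response
  (default 200 trials) and reports mean/max R² and Q² next to the original
  model's; failed refits are counted, not fatal.
* **Applicability domain**: leverage `h_i` is the hat-matrix diagonal of
  the intercept-augmented design; query compounds map through
  `x(XᵀX)⁻¹xᵀ`. Critical leverage `h* = 3(p+1)/n` with n defaulting to
  *all* assessed compounds (train + query): for 3 descriptors over a
  15-compound series this gives 0.800 (the training-only alternative,
  n = 12, would give 1.0 and flags nothing — rejected). Standardized
  residuals divide by the training RMSE (√(RSS/n)); QSARINS-style Williams
  plots use the degrees-of-freedom-corrected standard error instead, which
  differs by the factor √(n/(n−p−1)) — the residual limit (default ±2.45)
  is configurable to absorb either convention. In-domain means
  `h < h*` **and** |standardized residual| ≤ limit.

## Synthetic data

The generators define the study conditions under which the pipeline is
exercised; each is a pure function of its seed.

* **Score lists**: decoy "goodness" ~ N(0,1), active ~ N(µ,1) with
  µ = √2·Φ⁻¹(AUC), giving expected pairwise AUC exactly Φ(µ/√2); scores
  are negated goodness (lower-is-better). Equal unit variances keep the
  AUC↔shift map closed-form; a heteroscedastic option is deferred.
  Default shape 169 actives / 6,931 decoys at AUC 0.72 — the scale of a
  DUD-E-style benchmark screen. Calibration: over 50 replicates at
  500/500 the mean empirical AUC is within 0.01 of target.
* **Pose pairs**: pose A is a random 10–30 heavy-atom cloud; pose B is a
  rigid translation along a random unit vector scaled to the requested
  RMSD — exact by construction (< 1e-9), unlike perturb-and-rescale.
* **Activity tables**: response from the fixed linear equation
  pIC50 = 14.588 + 0.197·SHBint2 − 16.205·ETA_Epsilon_5 + 0.181·nAtomP
  plus N(0, noise_sd) noise (default series size 15, noise 0.3).
  Descriptor ranges — SHBint2 ~ U(0,30), ETA_Epsilon_5 ~ U(0.5,0.9),
  nAtomP ~ integer U(4,16) — are invented (no descriptor values are
  published for such series) and keep the response in a plausible
  mid-single-digit pIC50 band. Optional decoy columns give subset
  selection something to reject.
* **Property tables**: exactly `planted_pass` compliant records; every
  other record violates one or two randomly chosen rules.

What passing tests on these generators do **not** show: real docking
scores are not Gaussian, real pose disagreement is not a rigid
translation, real descriptors are discrete/correlated, and real decoys
are property-matched. The generators validate the *computations*, not any
docking protocol.

## Pipeline

Stage order is fixed (simulate/ingest → enrich → consensus → adme → hits
→ qsar); each stage is optional, writes its own CSV, and its seed is
spawned from the master seed via `numpy.random.SeedSequence`, so a stage
can be re-run in isolation. A stage failure writes the partial summary
with the failing stage named, then re-raises. Default problem sizes
(7,100-compound screens, 100 pose pairs, 15-compound QSAR series,
200 randomization trials) keep a full campaign and the whole test suite
in the tens of seconds on one core.

## Known limitations

* No symmetry-corrected RMSD and no inter-receptor alignment.
* EF'/EF*/DEF values are package-specific conventions (see above).
* The ADME stage never computes properties; garbage property inputs pass
  through unvalidated beyond finiteness checks.
* Q² is leave-one-out only; leave-many-out and bootstrap AUC confidence
  intervals are future work.
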
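# screenval

Validation toolkit for consensus-docking virtual-screening campaigns —
built for the kind of study that screens a designed compound library
against two CNS drug targets (e.g. MAO-B and AChE), confirms top-ranked
hits in vitro, and models the confirmed activities by QSAR.

Commercial docking engines are deliberately out of scope: their ranked
score lists and pose files are *inputs*. What `screenval` provides is
everything a screening team needs to decide whether those rankings are any
good, which poses to trust, which compounds to buy or make, and whether
the resulting activity model is statistically defensible:

* **Enrichment analysis** of actives-seeded-in-decoys screens:
  ROC AUC (the Mann–Whitney probability that a random active outranks a
  random decoy, ties counting one half),
  the classical enrichment factor
  `EF(f) = (Hits_sampled/Hits_total) / (N_sampled/N_total)`,
  the early-recognition variant
  `EF'(f) = (50% / APR) × (Hits_sampled/Hits_total)` with APR the average
  percentile rank of all actives, the window-integrated `EF*(f)` (mean EF
  over the grid `{f/10, …, f}`), the difference family DEF/DEF\*/DEF′ for
  comparing two protocols, top-N hit rates, and IC50-threshold hit
  classification with explicit borderline overrides.
* **Consensus-docking filter**: in-place heavy-atom RMSD between the two
  programs' poses of each ligand (no superposition — both poses share the
  receptor frame), accept/reject at a threshold (inclusive boundary, 2–3 Å
  typical) with active/decoy confusion counts and threshold sweeps.
* **ADME pre-filter**: Lipinski Rule-of-Five violation counting, PSA < 140 Å²,
  logBB ∈ [−3.0, 1.2], with per-compound failure reasons.
* **GA-MLR QSAR**: descriptor pruning (near-constant, |r| > 0.90),
  genetic-algorithm subset selection maximising leave-one-out Q²,
  OLS fitting with t statistics and VIFs, external validation,
  Y-randomization, and a leverage-based applicability domain
  (Williams plot, h\* = 3(p+1)/n, standardized residuals within ±2.45).
* **Synthetic-data generators** with known ground truth for every stage,
  so the whole pipeline is testable without any docking licence: score
  lists at a target AUC (binormal model, AUC = Φ(µ/√2)), pose pairs at
  exact RMSDs, activity tables from a known linear equation, property
  tables with a planted pass count.

## Worked example

Simulate a 169-active / 6931-decoy screen at separability 0.72 and score
its enrichment:

```
$ screenval simulate scores --n-actives 169 --n-decoys 6931 --auc 0.72 --seed 1 --out demo
$ screenval enrich --scores demo/scores.csv --fractions 0.01,0.02,0.05,0.1 --out demo
AUC = 0.7178
EF(1%) = 3.550   EF'(1%) = 0.062
EF(2%) = 2.663   EF'(2%) = 0.093
EF(5%) = 2.722   EF'(5%) = 0.237
EF(10%) = 2.722   EF'(10%) = 0.473
```

The empirical AUC lands within sampling error of the 0.72 target. EF(1%) =
3.55 says the top 1% window holds 3.55× more actives than a random pick of
71 compounds would; EF' is small here because it divides by the average
percentile rank of *all* actives, most of which sit far down a
moderately-enriched list.

Fit and validate a QSAR model on a 15-compound activity table (3 true
descriptors hidden among 7 decoy columns, response noise sd 0.3):

```
$ screenval simulate qsar --n 15 --noise 0.3 --decoy-descriptors 7 --seed 2 --out demo
$ screenval qsar validate --table demo/qsar.csv --trials 200 --seed 7 --out demo
selected: SHBint2, ETA_Epsilon_5, nAtomP
R² = 0.989  Q² = 0.975  R²test = 0.965
Y-randomization over 200 trials: mean R² = 0.273, max R² = 0.890
$ screenval qsar fit --table demo/qsar.csv --seed 7 --out demo
selected: SHBint2, ETA_Epsilon_5, nAtomP
R² = 0.988  R²adj = 0.985  Q² = 0.978
$ screenval qsar ad --model demo/model.json --table demo/qsar.csv --out demo
h* = 0.800; 0 of 15 outside the domain
```

The GA recovers exactly the three generating descriptors; no permuted
response comes close to the true model's R², and every compound sits
inside the applicability domain (critical leverage 3·(3+1)/15 = 0.800).

A full campaign — simulate → enrich → consensus → ADME → hits → QSAR —
runs from one YAML config and one master seed:

```
$ screenval run --config campaign.yaml --out results/
```

writing per-stage CSVs plus a machine-readable `run_summary.json`.

## Layout

| module | contents |
| --- | --- |
| `screenval.io` | CSV score tables, XYZ/SDF pose files, reports, config |
| `screenval.enrichment` | ROC/AUC, EF, EF', EF\*, DEF family, hit calls |
| `screenval.consensus` | pose RMSD, accept/reject filter, threshold sweep |
| `screenval.adme` | Rule-of-Five, PSA and logBB pre-filter |
| `screenval.qsar` | GA-MLR, LOO Q², Y-randomization, applicability domain |
| `screenval.synthetic` | seeded generators for every input |
| `screenval.pipeline` | staged campaign runner |
| `screenval.cli` | `screenval` command-line entry point |

See `docs/methods.md` for the statistical conventions and their rationale.
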
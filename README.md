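# refeval

Metrics and ranking machinery for assessing protein **model refinement**:
given a starting model (typically the best server prediction for a target),
refined submissions from many predictor groups, and the experimental target
structure, `refeval` scores every submission, standardises the scores into
per-target z-scores, combines them into composite ranking scores, and asks
the question every refinement assessment turns on: *does a group actually
beat a "naïve predictor" that just resubmits the starting model?*

It is aimed at structure-prediction assessors and methods developers who
want the full evaluation pipeline — metrics, z-score conventions, baselines,
and a synthetic-data generator with known ground truth — as a reusable,
tested library rather than a collection of one-off scripts.

## What it computes

**Structure-similarity metrics** (model vs. target, residues paired strictly
by author residue number):

- **RMS_CA** — sequence-dependent Cα RMSD after least-squares (Kabsch)
  superposition.
- **GDT_TS / GDT_HA** — Global Distance Test: mean over distance cutoffs
  ({1, 2, 4, 8} Å for TS, {0.5, 1, 2, 4} Å for HA) of the maximal fraction
  of Cα atoms superposable within the cutoff, found by a deterministic
  seed-and-refine search over superpositions.
- **lDDT** — superposition-free fraction of target inter-atomic distances
  (≤ 15 Å, different residues) preserved in the model within
  {0.5, 1, 2, 4} Å, averaged over thresholds.
- **SphereGrinder (SG)** — per-residue local-environment score: all-atom
  RMSD of the atoms within 6 Å of each residue's Cα after local
  superposition, summarised as the mean percentage of residues under the
  {2, 4} Å cutoffs.
- **ASE** — accuracy of self-estimates of coordinate error:
  `100 · (1 − mean|S(eᵢ) − S(dᵢ)|)` with `S(d) = 1/(1 + (d/d₀)²)`, d₀ = 5 Å,
  where `eᵢ` is the predicted per-residue error (B-factor column) and `dᵢ`
  the actual Cα deviation. Submissions carrying a constant error column of
  0 or 1 are flagged estimate-free and excluded rather than zero-filled.
- **S_torsion** — torsion-space score: the negated weighted mean of backbone
  (φ/ψ) and side-chain (χ, symmetry-corrected) circular deviations, plus
  good/bad region analysis (a residue is "good" when the starting model's
  mean backbone torsion difference from the target is below 30°).

**Ranking machinery** (the CASP z-score conventions):

- per-target z-scores over the pool of model-1 submissions, two-pass
  (outliers below z = −2 dropped, statistics recomputed, final z floored at
  −2);
- composite scores, with presets

  ```
  S_CASP12 = 0.46·z_RMS_CA + 0.17·z_GDT_HA + 0.20·z_SG + 0.15·z_QCS + 0.02·z_MP
  S_TBM    = ⅓·z_GDT_HA + ⅑·(z_lDDT + z_CADaa + z_SG) + ⅓·z_ASE
  S_TBM′   = ½·z_GDT_HA + ⅙·(z_lDDT + z_CADaa + z_SG)
  ```

  (QCS, MolProbity and CADaa are ingested from external tables, not
  computed natively);
- group ranking by sum of positive z-scores, the naïve-predictor baseline,
  per-group fraction of targets improved, and best-refined vs. best-initial
  comparisons.

The packaged refinement target-definition table (29 targets with residue
ranges, categories, and start-model GDT_HA) ships as a fixture, and a
synthetic-structure generator (ideal-geometry chains plus coordinate noise,
rigid element shifts, register shifts, and side-chain scrambles) provides
ground-truth test scenarios without any external structure data.

## Worked example

Score a refined model against its target, with the starting model for
reference (structures here generated by `refeval.synthetic`):

```bash
refeval score model.pdb target.pdb --start start.pdb
```

```json
{
  "coverage": 36,
  "rms_ca": 0.61,
  "gdt_ts": 99.31,
  "gdt_ha": 87.5,
  "lddt": 0.9148,
  "sg": 100.0,
  "s_torsion": -33.537,
  "ase": null,
  "s_torsion_change_from_start": -66.131
}
```

All 36 residues were paired. The model's fold is essentially correct
(Cα RMSD 0.61 Å; 99.3 GDT_TS, and even under the stringent half-size
cutoffs 87.5 GDT_HA), local environments are intact (SG 100, lDDT 0.91).
Torsion space is less forgiving: the mean weighted torsion deviation from
the target is 33.5° (`s_torsion` is 0 for a perfect model, more negative
with degradation), though the model moved substantially away from the
starting conformation (66.1° mean change). The B-factor column was constant
zero, so the submission is flagged estimate-free and ASE is null.

Summarise a target-definition table, rank groups, and compute the baseline:

```bash
refeval table-stats src/refeval/data/casp13_refinement_targets.tsv
refeval rank metrics.csv --weights casp12
refeval baseline metrics.csv start_metrics.csv --weights casp12
```

The same operations are available as library functions (`target_table_stats`,
`rank_groups`, `naive_baseline`, `fraction_improved`, `best_vs_start`).

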
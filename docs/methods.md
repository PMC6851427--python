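# Methods

This note records how `refeval` defines and computes its scores, the
defaults and why they were chosen, what the synthetic generator does and
does not emulate, and the numerical conventions that matter when comparing
implementations.

## Residue pairing

Model and target residues are paired strictly by author residue number plus
insertion code (`pair_by_residue_number`), optionally restricted to a
residue-range specification ("43-95, 106-181"; both ASCII and typographic
hyphens are accepted). This is the refinement-category convention: model and
target share numbering by construction, so no alignment search is performed
and all metrics are sequence-dependent. Residues lacking a Cα in either
partner are excluded from Cα-based metrics; atoms absent from either partner
are excluded pairwise from all-atom metrics (the count of exclusions is
implicit in the shared-atom sets). Only the first model and first chain of a
PDB file are read; alternate locations are resolved to the
highest-occupancy conformer, ties going to the first encountered.

## Superposition and GDT

`kabsch` is a weighted least-squares rigid superposition via SVD with the
reflection branch excluded; collinear point sets are reported as a warning
with a best-effort fit. The test suite cross-checks it against an
independent quaternion-eigenvalue (Horn) implementation and a direct
numerical minimisation.

GDT has no closed form: the reference implementation (LGA) is a heuristic
search over superpositions. `refeval` defines a deterministic
seed-and-refine approximation: seeds are the global Cα fit plus fits on
every contiguous window of sizes {3, 5, 7}; each seed is iteratively
refitted on the residues within the distance cutoff until the selected
subset repeats (oscillations are broken by a visited-subset check, at most
10 refits); the per-cutoff fraction is the maximum over all seeds and
iterations. GDT_TS averages the fractions at {1, 2, 4, 8} Å, GDT_HA at
{0.5, 1, 2, 4} Å, each × 100. On small instances (≤ 12 residues) the suite
verifies the heuristic against exhaustive enumeration of all Cα subsets of
size ≥ 3; on larger structures absolute values may differ from LGA by a
small margin, which is acceptable here because GDT enters the ranking as a
component score, not as the object of study. The search is deterministic and
invariant under rigid transforms of either input.

## Local scores

**lDDT** follows the distance-map definition: over all target atom pairs at
distance ≤ 15 Å (the inclusion radius), in different residues, with both
atoms present in the model, a pair is preserved at threshold *t* when the
model reproduces the target distance within *t*; the score averages the
preserved fraction over thresholds {0.5, 1, 2, 4} Å. It is computed
stereochemistry-unaware (no penalty term) and symmetry-naive: chemically
ambiguous terminal atoms (OD1/OD2, OE1/OE2, ring carbons) are matched by
label. This slightly penalises models whose deposition swapped equivalent
labels; a known limitation.

**SphereGrinder** centres a sphere of radius 6 Å on each paired residue's
target Cα, collects the target atoms inside it plus the residue's own
atoms, superposes the corresponding model atoms onto them, and records the
all-atom RMSD. The score is the mean over cutoffs {2, 4} Å of the
percentage of residues with sphere RMSD below the cutoff. Spheres with
fewer than three shared atoms are skipped with a warning. Radius and
cutoffs are configurable since published descriptions vary.

**ASE** measures self-assessment, not accuracy:
`ASE = 100·(1 − mean_i |S(e_i) − S(d_i)|)` with the
`S(d) = 1/(1+(d/d₀)²)` sigmoid at d₀ = 5 Å. Predicted errors `e_i` come
from the B-factor column; actual deviations `d_i` are per-residue Cα
deviations under the RMS_CA superposition (Cα rather than all-atom — the
choice is exposed in the deviation helper, and Cα was chosen because the
error estimates themselves are conventionally per-residue). A submission
whose B column is constant 0 or constant 1 plainly carries no estimates; it
is flagged and its ASE is null, excluded from the z-score pool rather than
scored zero, so estimate-free groups are penalised only through ranking
modes that choose to do so (see below).

## Torsion-space scoring

Backbone torsions φ/ψ/ω are computed from consecutive-residue backbone
atoms, nulled at termini and across chain breaks (C–N distance > 2.5 Å);
χ1–χ4 come from the standard side-chain atom quadruples. Two-fold-symmetric
terminal torsions (Phe/Tyr χ2, Asp χ2, Glu χ3) are compared under a
180°-periodic metric, so their deviation never exceeds 90°; the
arginine-head NH1/NH2 ambiguity lies beyond χ4 and never enters. The
per-residue backbone error is the mean circular difference over the φ/ψ
angles defined in both structures; ω is excluded by default (the 30°
good/bad threshold is a φ/ψ criterion) and can be enabled by flag.

The composite torsion score is
`s_torsion = −(w_bb·⟨backbone error⟩ + w_sc·⟨side-chain error⟩)` with
default weights 0.5/0.5: identical conformations score 0 and any
degradation is negative. The exact weighting used in published assessments
is not fixed; both component terms are therefore always reported alongside
the composite, and the weights are configurable. When one term has no
defined angles at all (e.g. poly-alanine has no χ), the score falls back to
the other term with renormalised weight rather than failing.

Region analysis classifies each residue of the *starting* model as "good"
(mean backbone torsion difference from the target < 30°) or "bad";
unclassifiable residues (termini, chain breaks) are excluded from region
summaries rather than defaulted to either region. The six-panel summary —
mean backbone change, side-chain change, and Cα RMSD of the model vs. the
start, and the same three vs. the target, each split by region — computes
Cα RMSDs after alignment on *all* shared Cα atoms, then restricts the RMSD
to the region's residues.

## z-scores, composites, baselines

Within each target, one metric's values over the model-1 submissions are
oriented so that higher is better (RMS_CA and MolProbity are negated),
standardised, and subjected to the two-pass convention: values with z < −2
are dropped, mean and SD recomputed on the survivors (population SD by
default; sample SD available), final z assigned to *all* submissions from
the recomputed statistics, and floored at −2. A pool with zero spread
(including spread at floating-point rounding level) yields z = 0 for
everyone. Composite scores are weighted sums of z-scores; the three presets
are validated to sum to 1. Missing components follow one of three policies:
`strict` (error), `renormalize` (reweight over available components), or
`pool_min` (substitute the pool-minimum z, which reproduces the observed
behaviour that estimate-free groups score below average on the ASE
component).

Group ranking sums max(score, 0) over targets ("sum of positive z-scores");
a mean mode is available, and best-of-5 aggregation is deliberately not the
default since captions of record rank model-1 submissions. Ties break
lexicographically by group id for determinism. The naïve predictor's
metrics are z-scored against the statistics of the real predictions — it
never enters the pool that defines mean/SD, so adding or removing it cannot
change any group's z — and aggregated under the same mode. "Fraction
improved" counts targets where a group's model-1 score *strictly* exceeds
the start's (ties are not improvements); the comparison metric defaults to
the CASP12 composite and may be any single oriented metric.

## Synthetic data

`make_ideal_chain` builds chains from ideal bond lengths and angles with
requested φ/ψ (NeRF construction, trans peptide ω = 180°). Side chains are
linear idealized chains following the χ-angle atom definitions, with a
fixed default rotamer (−60°, 180°, −60°, 180°): correct for torsion
extraction and distance metrics, but non-physical — no branch atoms beyond
the χ chain, no rotamer library, no sterics. Perturbations (coordinate
noise with i.i.d. Gaussian per-component displacement, rigid element
shifts, register shifts that renumber a segment and drop colliding
residues, and side-chain scrambles at fixed backbone) all draw from a
single seeded generator per call; no global random state.

`generate_scenario` emits a full prediction set: per target an ideal chain
(alternating helix- and strand-like backbones), a start model separated
from the target by 1.2 Å coordinate noise, and per-group submissions that
either interpolate the start toward the target (improvement fraction
~N(0.7, 0.15)) or add further noise (~N(1.0, 0.3) Å), according to each
group's improvement bias. Groups with bias ≥ 0.5 provide error estimates
(actual deviation plus 0.25 Å noise); the rest submit constant-zero
columns and are flagged estimate-free. Scenario problem sizes used in tests
and in the acceptance script (3–4 targets, 4–6 groups, 36–48 residues)
keep the full pipeline — including the GDT search per submission — fast
while leaving the ranking statistics non-trivial.

What passing tests on these scenarios show: the metric implementations,
z-machinery, baseline logic and their couplings behave correctly on inputs
whose ground truth is known exactly. What they do not show: agreement with
official assessment pipelines on real submissions (LGA's GDT search, the
official SphereGrinder binary, and stereochemistry-aware lDDT can each
differ in small ways), behaviour on structures with missing density,
non-standard residues, or multiple chains, and anything about the physics
of refinement itself.

## Numerical conventions and degenerate inputs

Angles are degrees in (−180°, 180°]; circular differences in [0°, 180°]
(folded to [0°, 90°] for two-fold-symmetric χ). Superposition requires ≥ 3
points; collinear sets warn. Coordinates round-trip through PDB format at
the format's 10⁻³ Å precision. Pools of fewer than two values cannot be
z-scored and raise; SD = 0 pools give z = 0. A floating-point guard treats
an SD below 10⁻¹² × max|value| as zero so that identical metric columns
(e.g. every group resubmitting the start) never produce spurious z-scores.
Torsion metrics on noise ladders saturate once conformations are fully
randomised (σ ≳ 2 Å of coordinate noise): mean backbone circular deviation
approaches its ~90° plateau, so degradation beyond that point is detected
by rank correlation rather than by strictly decreasing medians.

## Known limitations

Single-chain monomer evaluation only (an oligomeric target is assessed as
its monomeric unit); no mmCIF input; no ligand or metal handling; QCS,
MolProbity and CADaa are ingested columns, never computed; molecular
replacement LLG scoring requires crystallographic likelihood machinery and
diffraction data and is out of scope (the metric-table schema reserves an
`llg` column so externally computed values can be ranked).
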
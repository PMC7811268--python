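# Methods

## Scope and data model

The package operates downstream of lipid quantification and qPCR: its inputs
are (a) a species × sample table of absolute glycerolipid amounts in nmol
per mg dry weight, with condition (LT/NT/HT) and replicate metadata, and
(b) either raw Ct tables or precomputed log₂ fold-change tables for a panel
of TFs and lipid-metabolism genes. Nothing upstream (peak integration,
internal-standard normalization, read mapping) is modelled.

Species names are parsed into (class, total acyl carbons, total double
bonds, optional resolved chains). The class vocabulary is the fourteen
classes of a diacyl/triacyl glycerolipid panel — TAG/DAG/MAG (neutral),
MGDG/DGDG (galactolipid), PC/PI/PE/PG/PS/CL/PA/LPE (phospholipid), DGTS
(betaine). The sulfolipid SQDG is deliberately absent: the target panels do
not measure it, and accepting it silently would corrupt the membrane scope.
Ether/oxidized notations (`O-`, `P-`) are rejected rather than guessed at.
Chain order is preserved as given; no sn-position semantics are inferred.

## Composition statistics

* **Replicate aggregation.** Arithmetic mean per condition, taken before any
  ratio or percentage; SD is reported alongside. Below-detection cells are
  zeros and participate in totals (a `detected` mask is available to exclude
  them from species-level rank tests).
* **mol% and scopes.** Every percentage is relative to an explicit
  denominator scope: all glycerolipids, phospholipids only, membrane lipids
  only (everything except the neutral category), or within-class. Scope
  totals of zero raise a degenerate-scope error instead of emitting
  infinities.
* **Double-bond index.** DBI = Σ mol-fractionᵢ · dᵢ over the scope, with dᵢ
  the *per-molecule* total double-bond count. The alternative — normalizing
  per acyl chain, which would down-weight triacyl species — is defensible,
  but the per-molecule form is the one consistent with quoting a single
  "membrane DBI" over whole species, and class-level DBI changes are
  reported as within-class percentages so the choice cancels inside a class.
* **Fold changes** are ratios of replicate-mean absolute amounts, not of
  mol% (a class can double in content while its mol% falls). A zero control
  mean yields a missing value, never infinity.
* **Kruskal–Wallis.** H uses mid-ranks with the standard tie correction.
  p-values come from the χ² approximation (k−1 df), or from full enumeration
  of all n!/(n₁!…n_k!) assignments of the pooled values to groups when the
  pooled n ≤ 14 (34 650 assignments at the 3 × 4 design; the bound caps
  enumeration cost). At these sample sizes the χ² approximation is rough:
  against the exact enumeration it deviates by up to ~0.08 in p on random
  4+4+4 datasets, which is why the exact mode is the default in the CLI
  whenever the design allows it. An all-constant dataset is reported as
  H = 0, p = 1.
* **Rounding.** Library computations are full precision; the CLI's printed
  summary rounds mol% to 0.1 and DBI to 0.01, the precision such studies
  usually print.

## Expression profiles

Livak 2^−ΔΔCt with the reference Ct collapsed per replicate by arithmetic
mean (geometric-mean option for multi-reference panels). log₂FC = −ΔΔCt
against the same-timepoint NT control. The 0 h sample is excluded from
profiles by construction: every gene's log₂FC is identically zero there, and
including it would anchor all profile pairs at a shared point and inflate
every correlation. Profiles live on the fixed grid LT48, LT96, LT168, HT48,
HT96, HT168; incomplete genes are flagged and excluded from correlation
rather than imputed (with a mandatory warning), mirroring how an undetected
transcript drops out of a panel. Response classification uses |log₂FC| ≥ 1
by default, boundary inclusive, so values printed exactly at the cutoff are
not silently dropped. Differential-expression filtering is strictly
q < 0.05 (q = 0.05 excluded).

## Network construction

Every TF × gene pair is scored by Pearson r of the two 6-point profiles and
a two-sided p from the t transform (df = n−2); |r| = 1 is reported as p = 0.
The default edge criterion is r ≥ 0.9, p < 0.05, positive correlations only,
with both published conventions available as presets: the running-text form
(|R| > 0.9 strict, P < 0.05) and the figure-caption form (R ≥ 0.9,
P < 0.005). Both are exposed because the source study prints both, and its
text and figure legend also disagree on the *sign* of the reported
correlations; the positive-only default follows the figure legend (edges
drawn for positive significant correlations), and a signed mode retains
negative edges for exploration. Duplicate ids across the TF and gene sets
are rejected to keep the network bipartite. p-values are unadjusted by
default (matching practice for small candidate panels); an optional
Benjamini–Hochberg mode adjusts across all evaluated pairs, and can only
remove edges, never add them. Constant profiles cannot support an edge and
are skipped with a warning.

## Synthetic-data generator

The generator emulates the *statistical shape* of the study, not its
biochemistry. Defaults (the conditions under which all recovery statistics
are quoted):

* **Lipidome**: 14 classes, 287 species, LT/NT/HT × 4 replicates. Baseline
  class abundances put TAG at ~41 mol% of total glycerolipids and PC at
  ~64 mol% of phospholipids. Species weights within a class are lognormal
  (σ = 0.8) tilted toward saturated species (exp(−0.20·d)), which places
  baseline membrane DBI near 2.4. Designated "major" species concentrate
  class mass where real panels do: six mid-polyunsaturated TAGs carry 81% of
  TAG, and the 36:6 (18:3/18:3) species carry 45% / 50% of MGDG / DGDG.
  Stress multiplies each class by a planted fold (TAG 2.3 under LT, 3.4
  under HT; major membrane classes ~0.65–0.85) and re-tilts species weights
  by exp(s·d) with the class total preserved (s = 0.25 under LT, 0.03 under
  HT), so the unsaturation shift is planted independently of the fold
  change and lifts membrane DBI to ~3.4 under LT. Replicates are the
  condition mean times mean-one lognormal noise of CV 0.10. Species names
  are emitted in mixed shorthand dialects to exercise the parser.
* **Expression**: 17 TFs × 32 genes on the 6-point grid. TF profiles are
  i.i.d. standard normal per grid point; 16 planted target genes are
  TF + N(0, σ) with σ = 0.3287 = √(1/0.95² − 1), i.e. a planted population
  correlation of 0.95 per edge; the remaining genes and TFs are independent
  decoys. The planted adjacency is 7 hub TFs with out-degrees
  (8, 2, 2, 1, 1, 1, 1) over 16 distinct single-regulator targets.

Everything is reproducible from an explicit seed (no global RNG state), and
every dataset ships with a truth file that round-trips through JSON. What
the generator does **not** emulate: correlated replicate noise, censoring /
limit-of-detection structure, class-correlated measurement error,
autocorrelated time courses, multi-regulator genes, or TF–TF correlation.
Passing recovery tests therefore demonstrate the pipeline's correctness and
sensitivity under clean planted structure, not performance on real data.

## Recovery properties and a known limitation

Problem sizes were chosen to keep the full suite fast while giving stable
rates: fold-change recovery is measured over 200 seeded lipidome
simulations (all 28 planted class × condition folds each; estimates within
15% of truth in well over 95% of cases at CV 10%), and edge recovery over
100 seeded expression simulations.

A six-point profile is very little data for a correlation estimate: under
the null, P(r ≥ 0.9) ≈ 0.7% per pair (so a 17 × 32 panel admits a few
chance decoy edges per run — the acceptance report quantifies this), and
around a planted population correlation of 0.95 the sampling spread of r is
wide enough that only ~83% of planted edges clear the r ≥ 0.9 cutoff.
Pushing per-edge recall to ≥ 90% at n = 6 would require planting population
correlations near 0.975, i.e. stronger truth, not a better estimator — this
is a design limitation of thresholded correlation networks on short
profiles, and the dedicated recall test documents it by failing against a
90% recall bar at the 0.95 calibration. Hub-level conclusions are more
robust than individual edges; treat single-edge presence/absence near the
threshold as unreliable.

## Numerical conventions

Exact-test ties are compared with a 1e-12 slack on H; Pearson r is clipped
to [−1, 1] against rounding; mol% and DBI computations are vectorized
pandas/numpy at float64 throughout; undefined ratios (zero denominators)
are missing values, while undefined *scopes* (empty or zero-total) raise.
All file outputs are TSV with `#` header lines carrying units and scopes,
and runs are manifest-logged (input checksums, parameters, version) with
timestamps confined to the stderr log so outputs are bit-reproducible.
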
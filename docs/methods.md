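# Methods

## The analysis model

The package treats a cold-ischemia/reperfusion proteomic time course as
a fixed-design experiment: an ordered set of conditions (baseline H0,
ischemia H3–H24, reoxygenation R6) with ≥2 independent replicates each,
and a protein × sample matrix of non-negative LC-MS signal intensities
in arbitrary instrument units, with not-detected cells explicitly
missing. All inference is relative: signals are first expressed as
ratios to the protein's own mean baseline signal, so instrument response
factors per protein cancel and only within-protein kinetics remain.

### Reference-stability selection

Label-free intensities carry sample-to-sample scale drift (loading,
ionization). Rather than total-signal normalization, the package ports
the reference-gene strategy from qPCR (geNorm) to proteins:

* **Shortlist.** Candidates must be detected in every sample and are
  ranked by the coefficient of variation of their baseline ratios,
  CV = SD/mean over all samples (the "SD as a percentage of the average"
  reading; an option ranks by SD of log10 ratios instead). The k = 10
  smallest-CV proteins form the shortlist; ties break lexicographically
  by protein id so runs are reproducible.
* **M value.** For candidate *j* within the current set, M(j) is the
  mean over the other candidates *k* of the standard deviation across
  samples of log r_j − log r_k. A protein co-varying with the consensus
  of the pool has low M. Internally log2 is used (geNorm convention);
  the ranking is invariant to the log base, which the tests verify. SD
  is the sample SD (n−1 denominator) — the default of mainstream
  statistics environments; the choice only rescales every M by a common
  factor at fixed sample count and cannot change the exclusion order.
* **Iterative exclusion.** The highest-M candidate is removed (tie:
  remove the lexicographically last id) and M recomputed, down to a
  terminal set of 2. Two is the smallest set for which the pairwise
  stability measure is defined and matches the behaviour of reference
  pools that collapse to a best pair; `stop_size` is configurable for
  datasets that support more references.
* **Normalization factor.** Each sample's factor is the geometric mean
  of the reference ratios in that sample; every ratio is divided by it
  and log10-transformed. The geometric mean is the standard choice for
  combining multiplicative reference signals (and makes the factor
  symmetric in the references); an arithmetic-mean variant is kept
  behind `ref_mean="arithmetic"` for sensitivity analysis. Division by a
  per-sample factor makes the result exactly invariant to rescaling any
  sample column of the ratio matrix, which is tested to machine
  precision.

### Differential segregation

For each consecutive transition the effect size is Δ = mean log10
normalized value at the later condition minus the earlier one, over
detected replicates. Significance uses an **exact two-sided
Mann–Whitney U test** by full enumeration of all C(n+m, n) midrank
assignments; the two-sided p is the probability, under the permutation
null, of a U at least as far from its null mean nm/2 as observed. With
ties the midrank construction keeps the statistic well defined. At
n = m = 3 the smallest achievable two-sided p is 2/20 = 0.1, so the
default α = 0.1 admits exactly the fully separated arrangements — any
stricter α makes "significant" unattainable at this design, any looser
one adds nothing.

A transition is classified *up* when Δ > log10(2) **and** p ≤ α
(conjunction of the fold criterion and the test — the conservative
combination), *down* symmetrically. Detection-pattern overrides: a
protein undetected in all earlier replicates and detected in ≥2 later
ones is **de novo expression**, reported as up; the converse is *lost*,
reported as down. The ≥2 requirement guards against single-spike
artifacts. When one side has exactly one detected replicate the test is
undefined and the fold criterion alone decides, with a logged caveat.
A Benjamini–Hochberg q-value column is emitted for information only and
never gates classification.

The whole-protocol class is upregulated / downregulated when calls occur
in only one direction; when both occur, the direction with the larger
cumulative |Δ| over its classified transitions wins (ties to
upregulated) — a deterministic rule, needed because the heatmap assigns
one class per protein. Proteins with no call anywhere are unchanged,
yielding exactly three possible groups.

Baseline-absent proteins get a pseudo-baseline equal to half the
smallest detected intensity in the matrix (configurable), the standard
half-minimum imputation; it keeps de-novo ratios finite while the
protein stays flagged, and it never enters reference selection (which
requires full detection).

### Ontology kinetics

Per-transition Δ values are averaged over each family's proteins with
equal weights; a multi-family protein contributes to each of its
families; masked Δ values are dropped from that transition's mean, not
imputed. The cumulative series is the prefix sum anchored at 0 at
baseline, so differencing it recovers the independent series exactly.

**Collapse** is operationalized as the earliest ischemia transition
whose family mean change is below −τ with every later ischemia
transition non-positive. The default τ = 0.05 log10 units (≈ 12%
change): with a strict τ = 0, plateau transitions whose mean jitters
infinitesimally below zero under replicate noise are flagged as collapse
onsets, which destroys the onset ordering the statistic exists to
measure; 0.05 sits an order of magnitude below any biologically claimed
collapse step (a 2-fold drop is 0.30) and well above the jitter of a
≥10-protein family mean at the simulated noise levels. τ remains
configurable, and τ = 0 reproduces the strict rule.

Qualitative family patterns: *burst–maintain–collapse* = positive first
ischemia step, an existing collapse onset, and a further drop at
reoxygenation; *collapse–rebound* = negative first step, recovery on the
second, and a rise at reoxygenation; anything else is *other*.

## The synthetic-data generator

The generator emulates the study design — 174 proteins, 7 conditions ×
3 replicates — with planted ground truth so every stage can be scored:

* **Archetypes.** `burst_collapse(T)`: 4-fold rise at H0→H3, plateau to
  the collapse time T, then a 4-fold decline at every later ischemia
  step and a further 4-fold drop at R6. The decline is uncapped on
  purpose: post-collapse family means stay strictly negative, keeping
  collapse detection well posed under noise. `energy_rebound`: 4-fold
  drop at H0→H3, recovery at H3→H6, plateau to H12, decline, 4-fold
  rise at R6. `de_novo(T)`: absent before its onset, constant after.
  `stable`/`unregulated`: constant.
* **Default layout.** Ten stable reference proteins (gene symbols of
  classic abundant proteins; VIM and SCARB2 are the ultra-stable pair),
  left unannotated so family averages are not diluted by the
  normalization pool; 30 burst_collapse(H3) proteins annotated
  Transcription/Translation Regulation, 20 burst_collapse(H12) Ionic
  balance regulation, 20 burst_collapse(H19) Cytoskeleton, 20
  energy_rebound Energy metabolism, 12 de_novo(H3) Interaction with the
  environment, and 62 unregulated background proteins cycled through
  four further families. Group sizes scale proportionally for other
  protein counts.
* **Noise.** Intensities are planted mean × exp(N(0, σ)) with
  σ = √ln(1+CV²), so the natural-scale CV equals the configured value
  exactly. Defaults: CV 0.15 for ordinary proteins (mid-range for
  label-free replicate variation at N = 3), 0.02 for the two
  ultra-stable references. No noise magnitude is reported for the
  modeled protocol; these are simulation choices.
* **Abundance and dropout.** Base abundances are log-uniform over three
  decades (10⁴–10⁷) so the detection floor is exercised; reference
  proteins draw from the upper two decades so the normalization pool
  cannot be lost to dropout. Cells whose planted mean falls in the
  lowest 5% of all planted means are masked (missing-at-low-abundance),
  deterministic given the seed; planted-zero cells are always masked.

**What passing tests show — and do not.** The generator produces clean
multiplicative noise, step-shaped kinetics, deterministic
abundance-threshold dropout and an exactly stable reference pool. Real
LC-MS data add peptide-level aggregation error, correlated run effects,
stochastic (not threshold) missingness, and references that are only
approximately stable. Recovery rates measured here are therefore upper
bounds on real-data behaviour; the oracle-equivalence results (exact
test, M-value iteration, normalization invariances) are
data-independent and carry over as-is.

## Numerical and interface choices

* Problem sizes in the seeded benchmarks: 100 brute-force draws for the
  M-value oracle, 200 runs for reference recovery, 500 proteins for
  label recovery, 100 end-to-end runs for the collapse ordering —
  large enough for the rates' standard errors to sit well inside the
  asserted margins.
* All randomness flows from a single `numpy` `default_rng` seed; the
  same seed gives bit-identical matrices and byte-identical pipeline
  artifacts (hashed in the run manifest).
* Missing-value encoding on input: empty cell, `NA` and `0` all mean
  not detected (`zero_is_missing=False` treats 0 as a measured zero,
  which is then masked at the log step with a warning).
* Exclusion and shortlist ties break lexicographically; the heatmap
  groups rows upregulated → downregulated → unchanged, preserving input
  order within groups.
* The per-transition classification applies no multiplicity correction
  (the q-value column is informational): at n = 3 the exact test is
  already at its resolution limit and the three-class segregation is
  descriptive, not inferential.

## Known limitations

* The exact enumeration is O(C(n+m, n)) per transition — instant at
  n = 3 but not intended for designs with many replicates (switch to a
  large-sample test there).
* Collapse detection assumes a single sustained decline; oscillating
  families map to "no collapse" or a late onset by construction.
* The pipeline analyzes protein-level intensities only; peptide rollup,
  protein inference and enrichment analysis are out of scope.
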
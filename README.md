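# proteokinetics

Analysis of label-free proteomic time courses from cold
ischemia/reperfusion experiments: endothelial-like cells kept in
hypothermic, anoxic preservation solution are sampled at a baseline
(H0), through 3–24 h of cold ischemia (H3, H6, H12, H19, H24) and six
hours after reoxygenation (R6), with a small number of independent
replicates per condition. The package is aimed at proteomics analysts
who receive a wide protein × sample intensity table from such a protocol
and need a reproducible route from raw signal to per-interval
differential calls and ontology-level kinetics.

## What it computes

1. **Baseline ratios.** Every signal is expressed as a ratio to the
   protein's mean detected baseline signal,
   `r_p(s) = I_p(s) / mean_baseline(I_p)`.
2. **Reference selection (geNorm-style M value, adapted to LC-MS
   signals).** Candidates are the k = 10 fully-detected proteins with
   the smallest CV of their ratios. For a candidate *j* in a set *C*,

   ```
   M(j) = mean_{k ∈ C, k≠j}  SD_s( log r_j(s) − log r_k(s) )
   ```

   (sample SD over samples *s*). The highest-M candidate is removed and
   the procedure repeats until a terminal reference pair remains.
3. **Normalization.** Each ratio is divided by the per-sample geometric
   mean of the reference ratios and log10-transformed:
   `y_p(s) = log10( r_p(s) / geomean_{f∈refs} r_f(s) )`.
4. **Differential segregation.** For each consecutive transition
   (H0→H3, …, H24→R6) a protein is *up* when the mean log10 change
   exceeds log10(2) **and** an exact two-sided Mann–Whitney U test
   (full enumeration, midranks; no normal approximation at n = 3 vs 3)
   reaches α = 0.1; *down* symmetrically; appearance from a fully
   undetected baseline is de novo expression (reported as up).
   Whole-protocol classes — upregulated / downregulated / unchanged —
   give the three-group heatmap segregation.
5. **Ontology kinetics.** Per-transition changes are averaged within
   each ontology family (Cytoskeleton, Transcription/Translation
   Regulation, Ionic balance regulation, Energy metabolism, …), as
   independent and cumulative series, with detection of each family's
   collapse onset (first sustained decline during ischemia) and its
   qualitative pattern (burst–maintain–collapse vs collapse–rebound).

A synthetic-data generator with planted ground truth (two kinetic
archetypes, staggered collapse times, ultra-stable references,
low-abundance dropout) makes the whole pipeline testable without
instrument data.

## Worked example

```python
from proteokinetics import TimecourseModel
from proteokinetics.simulate import SimulationConfig, simulate

cfg = SimulationConfig(seed=1)               # 174 proteins, 7 x 3 design
intensities, truth, annotation = simulate(cfg)
res = TimecourseModel(intensities, cfg.design, annotation).fit()
print(res.summary())
```

```
Proteomic time-course analysis
==============================================
Conditions:        H0, H3, H6, H12, H19, H24, R6 (baseline H0)
Proteins analyzed: 174
Shortlist (k=10): SCARB2, VIM, P136, P152, P109, P107, P158, CLTC, P141, LGALS1
Reference set:     SCARB2, VIM (after 8 exclusion rounds)

Whole-protocol segregation:
  upregulated     13
  downregulated   89
  unchanged       72
  de novo calls   17

Ontology kinetics:
  Transcription/Translation Regulation   pattern=burst_maintain_collapse collapse=H3->H6
  Ionic balance regulation               pattern=burst_maintain_collapse collapse=H12->H19
  Cytoskeleton                           pattern=burst_maintain_collapse collapse=H19->H24
  Energy metabolism                      pattern=collapse_rebound       collapse=H12->H19
  ...
```

The terminal reference pair is the two planted ultra-stable proteins
(VIM, SCARB2); the three whole-protocol classes split the inventory into
proteins induced (13, mostly de novo expression), repressed (89, the
collapsing archetypes) and untouched (72) by the protocol; and the
family collapse onsets recover the planted staggering — the
transcription/translation machinery falls first (H3→H6), ionic balance
holds until H12, the cytoskeleton until H19, while energy metabolism
shows the collapse–rebound shape with a strong rise at reoxygenation.

`res` also carries the full per-iteration M values
(`res.stability.iterations`), the normalized matrix, the per-transition
table with exact p-values (`res.transitions`), the class-ordered heatmap
matrix and `res.plot_kinetics()` for the two kinetic panels.

The same pipeline runs from the shell:

```sh
proteokinetics run --seed 1 --outdir out/    # writes TSVs + manifest.json
proteokinetics simulate --n-proteins 174 --seed 1 --outdir sim/
proteokinetics normalize sim/intensity.tsv --outdir norm/
```

Real data enter through `TimecourseModel.from_csv(path, design,
annotation_path=...)` — a delimited wide table, first column the protein
id, columns `H0_r1 … R6_r3`; empty cells, `NA` or `0` mean not detected.

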
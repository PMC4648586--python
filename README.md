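# est454 — digital gene expression from 454 EST libraries

`est454` implements the comparative-transcriptome workflow used in early
454 pyrosequencing EST studies of non-model organisms (the motivating
design: olive root and leaf cDNA libraries under salt stress, two tissues
× treated/untreated). Each library is sequenced with an anchored oligo-dT
protocol so every transcript molecule yields exactly one 3'-anchored read;
read counts per transcript cluster are therefore a direct digital measure
of expression. The package is aimed at anyone who wants a tested,
reproducible implementation of this classic pipeline — or a desk-scale
simulator of it — without the original mix of one-off tools.

The pipeline stages, each available as a library function and a thin CLI
subcommand (`est454 trim|cluster|de|ssr|qpcr|simulate|pipeline`):

- **Trimming** — error-tolerant, ends-free (semi-global) adapter/primer
  matching: an adapter may occur inside a read or run off either end; a
  match needs at most `floor(max_error_rate × overlap)` unit-cost errors.
  IUPAC ambiguity codes (the default anchor primer
  `5'-TTTTTTCTTGTTTTCTTTTCTTV-3'` ends in V = A/C/G) match their
  expansions at zero cost. Reads shorter than 100 nt are then dropped.
- **Clustering** — greedy incremental clustering at a global identity
  threshold (default 95%), both strands, longest-first; each read joins
  the *most similar* qualifying representative, not the first one.
  Identity is identical aligned pairs of a minimum-edit global alignment
  divided by the shorter sequence length.
- **Differential expression** — the likelihood-ratio R statistic per
  cluster *j* with counts x_i over m libraries with totals N_i:

      f = Σᵢ xᵢ / Σᵢ Nᵢ ,   R = Σᵢ xᵢ · ln( xᵢ / (Nᵢ f) ),   0·ln 0 ≔ 0

  R = 0 for perfectly proportional counts. Significance is set by an
  empirical FDR: every cluster total is redistributed multinomially with
  probabilities Nᵢ/ΣN, and the cutoff is the smallest observed R* where
  (mean null exceedances)/(observed exceedances) ≤ the requested FDR.
  Tests run per tissue (m = 2) and across all four libraries (m = 4),
  whose significant clusters are partitioned into cross-tissue categories
  (up/down in both, opposite, tissue-specific).
- **SSR mining** — MISA-style perfect microsatellites (minima: 10× mono,
  6× di, 5× tri–hexa) and compound records (interruption ≤ 100 nt).
- **qPCR** — relative expression by 2^(−ΔΔCt) with multi-reference-gene
  normalisation and t-tests across biological replicates.
- **Simulation** — 454-like 3'-anchored libraries from a random
  transcriptome with planted differential expression, planted SSRs, a
  coarse homopolymer error model, and a truth table, so the whole
  pipeline is verifiable end to end.

## Worked example

`examples/` holds one short script per capability. A planted-truth
differential-expression run (`examples/04_differential_expression.py`):

```
R for counts (10, 0) at depth (100, 100):    6.9315   (= 10 ln 2)
R for counts (30, 10) at depth (1000, 1000): 5.2325
R for proportional counts (5, 5):            0.0000

empirical cutoff at FDR 0.05: R >= 4.93
significant clusters: 11 (10/10 planted, 1 background)
```

Ten clusters with 40 vs 5 reads (8-fold) planted among 190 balanced ones
at 5,000 reads per library all exceed the resampling cutoff; one
background cluster crosses it, consistent with the 5% FDR target. The
full workflow (`examples/07_full_pipeline.py`) prints per-tissue cluster
tables (total / multi-read / singletons), per-tissue up/down counts, and
the combined-test category table, e.g.:

```
leaf: 58 clusters (5 singletons), 10 DE (5 up / 5 down)
root: 56 clusters (4 singletons), 13 DE (6 up / 7 down)
combined m=4 test: 10 clusters significant
cross-tissue categories: {"down_both": 4, "up_both": 6}
```

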
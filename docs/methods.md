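# Methods

## The measurement model

The pipeline targets libraries built with an anchored oligo-dT protocol
for 454 sequencing: each transcript molecule is converted to one cDNA
fragment at its poly(A) end and sequenced once, so a library is a
multinomial sample of transcript molecules and the read count of a
transcript cluster is a direct digital expression measurement. Reads of
the same transcript are 3'-anchored and therefore mutually overlapping —
nested suffixes up to sequencing error — which is what makes
single-linkage-free greedy clustering at high identity an adequate
substitute for assembly.

## Trimming

Adapters are located by ends-free semi-global alignment built on edlib:
an internal occurrence is a full-adapter infix alignment (mode HW); a
partial occurrence hanging off the 3' (5') read end is an
adapter-prefix-to-read-suffix (adapter-suffix-to-read-prefix) alignment,
computed with mode SHW on reversed (plain) strings for every allowed
overlap. A `three_prime` adapter may match internally or off the 3' end
and removes everything from match start onward; a `five_prime` adapter
symmetrically; `both` allows either overhang and trims the anchored side.
Errors are unit-cost substitutions and indels, accepted while
`n_errors <= floor(max_error_rate * overlap)` with `overlap` the number
of adapter bases inside the read; the best match minimises errors, then
maximises overlap, then sits leftmost. IUPAC ambiguity codes match their
expansions at zero cost via edlib's equality pairs. Defaults
(`max_error_rate = 0.1`, `min_overlap = 3`) are the long-standing
defaults of the standard adapter-trimming tool; the adapter list is fully
user-configurable because real "vector contamination" is never fully
enumerated. Adapters are re-applied until no match remains; reads
consumed entirely are dropped, and a 100 nt minimum length (boundary
inclusive) is applied afterwards.

A practical consequence of re-application with `min_overlap = 3`: a read
whose genuine 3' end happens to equal a short prefix of the poly(T)
anchor primer loses those bases. Real 3'-anchored inserts end in poly(A),
which cannot match the poly(T) primer, so this costs nothing on the data
the pipeline is designed for (the synthetic generator reproduces this
property; see below).

## Clustering

Greedy incremental clustering over reads sorted by descending length
(input order breaking ties): each read is scored against every existing
representative on both strands; below the threshold everywhere it founds
a new cluster, otherwise it joins the representative with maximum
identity, ties to the earlier-founded cluster. This reproduces the
classic nucleotide greedy-clustering scheme with the "most similar
cluster" (rather than first-fit) assignment rule, at the study's 95%
cut-off.

Identity is defined as the number of identical aligned base pairs in a
minimum-edit-distance global (NW) alignment divided by the length of the
shorter sequence — the shorter-sequence denominator is the convention of
the reference nucleotide clustering tool, and makes a contained suffix
read score identity 1.0 against its transcript's representative. Among
co-optimal minimum-edit alignments the match count can differ slightly;
the implementation pins it to edlib's deterministic traceback, which the
test suite cross-checks against independent edit-distance bounds
(matches of any minimum-edit alignment lie in `[s-d, s-ceil(d/2)]` for
`d = e - (l - s)`, edit distance `e`, lengths `l >= s`).

The same bound powers a lossless prescreen: a distance-only NW alignment
(capped by the threshold via edlib's `k`) yields an upper bound on
identity, so representatives that cannot beat the current best are
skipped without computing a traceback, and `d == 0` proves identity 1.0,
which allows an early stop under the earliest-founded tie rule. The
prescreen provably never changes the result; an exhaustive
all-representative reference implementation is compared exactly in the
tests. Complexity remains O(reads × representatives) alignments in the
worst case, which is ample at desk scale (12,000 reads cluster in well
under a minute).

## Differential expression

Per cluster the likelihood-ratio statistic
`R = sum_i x_i ln(x_i/(N_i f))`, `f = sum(x)/sum(N)`, `0 ln 0 := 0`, over
the m libraries of the comparison; `m = 2` for each tissue's
treated/untreated pair and `m = 4` for the combined test across all four
libraries, whose significant clusters are then given per-tissue
directions from each tissue's pair. R is non-negative, zero exactly on
proportional counts, permutation-invariant, and degree-1 homogeneous in
counts at fixed proportions (all asserted against a direct-formula oracle).

No analytic null distribution is assumed. The significance cutoff is an
empirical-FDR threshold (default FDR 0.05, 1,000 rounds, seeded): each
cluster's total is redistributed multinomially with probabilities
`N_i/sum(N)` and the cutoff is the smallest observed R value at which
`mean null exceedances / observed exceedances <= fdr`; if no observed
value qualifies the cutoff is +infinity (nothing significant) with a
logged warning. Clusters with fewer than 2 reads in the tested libraries
are excluded from testing (nothing can be inferred from one read); the
motivating study's observation that its significant clusters all held
>= 29 reads is an outcome of power, not a filter, and is not enforced.

Direction is the sign of the proportion difference
`x_t/N_t - x_u/N_u`; a significant tie is reported "up" with a warning
(impossible for a finite positive cutoff at m = 2). For the cross-tissue
category table, a cluster significant in at least one comparison is
assigned by (root direction, leaf direction, tissue-specificity), where
tissue-specific means zero reads of the cluster in the other tissue's
libraries. When one tissue's call is not significant its raw proportion
direction is used, and a raw tie inherits the other tissue's direction —
in the combined m = 4 mode both tissues share one significance flag so
this fallback rarely matters. The eight category counters (the four
shared/opposite combinations and four tissue-specific ones) partition
the significant clusters exactly.

Known limitation: with a large planted effect mass (see the benchmark
below: 10% of transcripts changed 8-fold) the renormalisation of
relative abundances depresses every unchanged transcript's proportion in
the treated libraries. The proportional-to-totals resampling null does
not model this compositional shift, so the realised false-discovery rate
among abundant unchanged clusters runs above the nominal level — the
familiar composition problem of digital expression without
between-sample normalisation, which is deliberately out of scope here
(the method normalises by library totals only, as the original did).

## SSR mining

A perfect SSR is a tandem run of a 1–6 nt motif satisfying, for motif
`m = seq[start:start+p]` with `r` repeats: `r >= min_repeats[p]`
(defaults 10/6/5/5/5/5 for mono- through hexanucleotide); `m` primitive
(not a repetition of a shorter motif — so a run is reported at its
smallest period only, poly(A) never doubles as an AA dinucleotide run);
left-shift-maximality (`start == 0` or
`seq[start-1] != seq[start+p-1]`), which makes `start` the leftmost
phase of its run and prevents one run being reported once per phase; and
right unit-maximality (the next p bases do not repeat the motif; a
trailing partial repeat is allowed but not counted). Coordinates are
1-based inclusive, motifs are reported as they occur on the given strand
(no rotation/complement canonicalisation in records). Perfect runs
separated by at most 100 nt (boundary inclusive, measured end-to-start)
merge transitively into compound records; the summary table reports both
record-level counts and the per-motif-size histogram over compound
components, since conventions differ on whether compound members also
count as perfect. Detection is linear scans of the `seq[i] == seq[i+p]`
equality runs per period; a brute-force every-(start, period) oracle is
compared exactly on random 2 kb sequences in the tests.

## qPCR quantification

Amplification efficiency is fixed at 2 (the ΔΔCt assumption). Technical
replicates are averaged to one Ct per gene and biological sample;
`dCt = Ct_target - mean(Ct_refs)` (the arithmetic mean of reference Cts
equals normalising quantities by their geometric mean);
`ddCt = mean(dCt_stress) - mean(dCt_control)`; fold change `2^-ddCt`.
The p-value is a two-sided independent two-sample t-test on the
per-biological-replicate dCt values, reported as missing when either
condition has fewer than two biological replicates; stars follow the
p < 0.05/0.01/0.001 convention. Sample-wide Ct offsets cancel in dCt;
swapping condition labels inverts the fold change and preserves the
p-value (both property-tested).

## The synthetic generator

`simulate_transcriptome` draws uniform-random transcripts of 400–3,000 nt
ending in an 8-adenine poly(A) stub whose preceding base is forced off A.
The stub emulates the poly(A)-anchored 3' end every real insert has — it
protects trimming from nibbling T-rich insert ends — while staying below
the 10-repeat mononucleotide SSR minimum so that unspiked transcripts
carry essentially no detectable SSRs. Optionally a transcript receives
one random SSR meeting the detection minima (ground truth recorded).

`four_library_design` assigns each transcript a log-normal(σ = 1) base
abundance shared by all four libraries — the realistic skewed expression
profile; a uniform profile would overstate detectability — and changes a
chosen fraction of transcripts by a fixed fold in both treated libraries,
half up and half down, recording the truth table.

`simulate_libraries` draws `depth` molecules per library multinomially;
each molecule yields one read: the transcript's 3'-terminal `L` bases
with `L ~ Normal(360, 25)` truncated to `[150, transcript length]`, plus
the 23-nt anchor primer appended 3' (terminal V instantiated to a random
A/C/G), giving raw reads averaging ≈383 nt — inside the 332–388 nt range
of real 454 titanium cDNA runs. Sequencing error is a coarse 454
caricature: per-base substitutions at `error_rate` plus ±1-base
homopolymer-length errors (runs ≥ 5, probability 0.2 per run).
`error_rate = 0` is the master switch: it disables both channels, so
error-free runs produce exact 3' suffixes — the regime in which trimming
recovery and clustering behaviour can be asserted exactly. What the
generator does **not** emulate: real base composition, polymorphism and
paralogy (near-identical gene families that stress the 95% cut-off),
flowgram-faithful error structure, and library-preparation biases —
passing end-to-end tests therefore demonstrate the pipeline's logic and
calibration, not its behaviour on any particular real transcriptome.

## Benchmarks and the problem sizes used

`est454.benchmark.parameter_recovery` runs the full pipeline on the
four-library design (default: 300 transcripts, 10% DE at 8-fold, 3,000
reads per library, error-free) over several seeds and scores the union of
per-tissue (m = 2) and combined (m = 4) calls against the truth:
clusters map to transcripts by best representative identity (≥ 0.8);
sensitivity is the fraction of planted DE transcripts recovered by a
correctly-directed significant call, observed FDR the fraction of
significant calls mapping to unchanged transcripts (or unmappable), and
direction accuracy is scored over true-positive calls. These sizes keep
a five-seed benchmark in the low minutes on one CPU while leaving ~10
reads per median transcript and library — enough that strong planted
changes are comfortably detectable but, deliberately, not every one:
planted transcripts in the low tail of the log-normal profile receive
too few reads to ever reach significance (the motivating study saw the
same floor — its significant clusters all held ≥ 29 reads). Median
sensitivity accordingly sits around 0.65–0.75 with direction accuracy
≈ 1.0, and observed FDR runs above the nominal 0.05 for the
compositional reason discussed above. `null_calibration` complements
this with pure-null two-library matrices (200 clusters, 5,000 reads per
library), where the cutoff correctly returns +infinity almost always and
the false-positive rate is ≈ 0.

## Numerical and degenerate-input choices

- All randomness flows through `numpy.random.default_rng` from explicit
  seeds; fixed seed implies bit-identical outputs, and the pipeline's
  summary JSON (sorted keys, no timestamps) is byte-reproducible.
- `0 · ln 0 := 0` in R; an all-zero count vector is an error (the
  statistic is undefined), as is a count exceeding its library total.
- Empty inputs are valid where a degenerate result exists: empty FASTA →
  no reads; empty read set → empty clustering; empty clustering → 0×k
  count matrix with zero totals.
- Tie-breaks are fixed everywhere: adapter matches (fewest errors,
  longest overlap, leftmost), clustering (longer read first, input order,
  earlier-founded cluster, "+" strand), categories (fully tied yet
  significant → "up", mirroring the direction tie rule).
- Sequences are uppercased on ingest; `revcomp` maps ambiguity codes to
  their complements and rejects non-IUPAC characters.
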
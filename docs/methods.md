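# Methods

`titrabench` is a self-contained, desk-scale model system for studying how
transcript quantification strategies behave on total RNA-seq data with a
titration design. Everything — reference, abundances, reads, quantifiers,
metrics — is generated and computed inside the package, so every claim the
test suite makes is checkable against ground truth.

## The titration model

Two reference RNA samples A and B are mixed by mass into C = 3A + 1B and
D = 1A + 3B. Working in molar concentrations per unit mass, mixing is linear:
c_i = 3a_i + b_i and d_i = a_i + 3b_i for every transcript i. On the TPM
scale (molar proportions × 10⁶) the C/D fold change of a gene is then a
deterministic function of its A/B fold change:

    log2(C/D) = log2(k1·r + (1 − k1)) − log2(k2·r + (1 − k2)),

where r is the A/B ratio on the TPM scale, k1 = 3z/(3z + 1), k2 = z/(z + 3),
and z is the ratio of total signal per unit mass between A and B (default
1.43, taken as given rather than estimated). This identity is exact in the
generator — `mix_titration` followed by `to_tpm` reproduces it to ~1e-15 —
so any deviation measured downstream is attributable to the quantification
pipeline plus sampling noise, never to the simulation itself.

Agreement is scored with R² = 1 − Σ(y_i − f_i)² / Σ(y_i − ȳ)², where y_i is
the measured and f_i the model-expected log2(C/D) and ȳ is the mean of the
measured values. This is a model-fit statistic, not a squared correlation:
it is negative whenever the model predicts worse than the mean, which is the
informative failure mode here. RMSE per gene stratum complements it.

## The synthetic transcriptome and abundances

The default reference holds 60 protein-coding genes (500–3000 nt; five genes
carry a second isoform produced by an internal deletion, so isoforms share
long exact stretches and generate genuine multi-mapping), 92 ERCC-like
spike-ins (250–2000 nt), 20 tRNA-like transcripts (70–80 nt), 10 snoRNAs,
2 rRNAs, 10 other ncRNAs, and 2 decoy sequences (mutated copies of
protein-coding transcripts standing in for haplotype/patch contigs; they are
part of the alignment reference but carry no abundance and emit no reads).
Sequences are uniform random DNA; at these lengths accidental k-mer sharing
between unrelated transcripts is negligible for k ≥ 15, which is exactly the
regime the mechanism experiments need.

Spike-ins are split into four equal groups at designed A:B molar ratios
0.67:1, 1:1, 1:2 and 1:4, giving 23 true-null and 69 true-DE transcripts —
the truth labels for ROC analysis. Baseline concentrations per gene type are
log10-uniform with tRNA and rRNA set high (as in real total RNA, where small
structural RNAs dominate molar abundance). Background (non-spike-in) log2
A/B ratios are uniform on (−2, 2) and median-centred at zero; an exponential
tilt of the background abundance weights (w_i ∝ ρ_i^λ applied to a_i and b_i
alike) then enforces ΣA/ΣB = z exactly. The tilt preserves every
per-transcript ratio — spike-in design ratios stay exact — and realises z
the way real samples do: through composition, with abundant transcripts
skewed toward the heavier sample.

tRNA transcripts carry 1–4 modification sites drawn from Normal clusters at
positions 20, 30 and 50 (sd 3, clipped to the transcript); the mechanism
scenario instead pins every tRNA to exactly {20, 30, 50}. During read
simulation each covered site substitutes its base with probability
`mis_rate` (misincorporation by the reverse transcriptase at modified
bases); independently every base flips with probability `seq_error`. Errors
are substitution-only; insertions seen in real data are out of scope since
substitutions already break k-mers. The true per-site misincorporation rates
of real modified positions are unknown; `mis_rate` is a free parameter, and
0.8 is used for the mechanism scenario as a "strongly modified site" regime.

Reads are single-end, sense-strand, default 50 nt (transcripts shorter than
the read length yield full-length reads). Replicate noise is gamma jitter of
the sampling weights with dispersion α (marginally negative-binomial counts
with variance μ + αμ²; default α = 0.01); α = 0 in the count simulator draws
a fixed-total multinomial, so a single-transcript library of depth N yields
exactly N counts. All randomness flows through explicit seeds; equal seeds
give byte-identical FASTA/FASTQ/TSV.

What the generator does not emulate: GC and positional bias, fragment-length
distributions, adapters, paired ends, RNA structure effects, and real tRNA
sequence families (sequences are random, so cross-mapping between tRNAs is
absent). Passing tests therefore demonstrate the designed mechanisms, not
performance on real libraries.

## Quantifiers

**K-mer equivalence-class quantifier** (`KmerQuantifier`): an exact-match
k-mer index over the (non-decoy) transcriptome; a read's compatibility set
is the intersection of the transcript sets of its k-mers that are present in
the index, with absent k-mers skipped; a read with no present k-mer or an
empty intersection is unassigned. Reads with equal compatibility sets form
equivalence classes, and abundances maximise the standard class likelihood
∏_c (Σ_{t∈c} θ_t/ℓ_t)^{n_c} by EM from a uniform start (tolerance 1e-8 on
max |Δθ|, ≤ 1000 iterations; when the maximiser is non-unique, the
uniform-start fixed point is the defined answer). θ is the read-fraction
parameter; reported TPM is the length-normalised molar proportion
10⁶·(θ_t/ℓ_t)/Σ(θ_u/ℓ_u). Effective length is max(L − read_length + 1, 1).
There is no error-tolerant matching, skipping heuristic, or bias model: the
mechanism of interest is exact-match error shadowing, which the plain rule
exhibits.

A finding worth recording: unassignment is *not* monotone in k across the
whole grid. Below the collision-free regime (4^k comparable to the indexed
sequence volume, here k ≈ 11) corrupted k-mers start matching unrelated
transcripts and poison the intersection, so k = 11 loses more reads than
k = 15 despite having more error-free windows. Error shadowing makes large
k fail on short modified RNAs; collisions make very small k fail on
everything — the usable window is in between.

**Alignment quantifier** (`AlignmentQuantifier`): end-to-end,
substitution-only alignment against the full reference (decoys included)
within `max_mismatch` (default ⌈0.15 × read length⌉). The public
`align_read` is an exhaustive scan of every offset; the quantifier uses a
pigeonhole seed-and-verify search — the read is cut into max_mismatch + 1
non-overlapping exact seeds, any qualifying alignment must leave one seed
intact — which returns the identical hit set and is tested for equivalence
against the exhaustive scan. Selection mirrors small-RNA-aware pipelines:
hits on tRNA/rRNA transcripts pre-empt all others; then fewest mismatches
(the single-end stand-in for a paired pipeline's smallest-insert rule); then
ribosomal-locus preference; then primary over decoy; remaining ties break by
a seeded uniform draw. Each read contributes at most one count to one gene;
tRNA gene counts aggregate per anticodon. Soft-clip filtering has no
analogue here because alignment is end-to-end; spliced alignment and indels
are out of scope.

## Evaluation

Transcript TPM aggregates to gene level as Σ(TPM × effective length) per
gene, rescaled per library to the library size (length-scaled estimated
counts); gene TPM is the plain sum of transcript TPM; gene length is the
longest transcript. A gene is detected when its TPM strictly exceeds 0.1,
evaluated per library. Genes with zero signal in every library are excluded
from fold-change modelling and logged.

Differential expression is a Welch two-sample t-test on log2(value + 0.5)
(the pseudocount caps fold changes for zero counts). Two normalisations
serve two different purposes:

* **CPM** (per-million scaling) for the titration fold-change model — the
  model's identity lives on the TPM/proportion scale, so per-sample
  rescaling beyond proportions would break it.
* **Median-of-ratios size factors** computed on non-spike-in control genes
  for the spike-in ROC. Because ΣA/ΣB = z ≠ 1, proportion scaling shifts
  every fold change by ≈ log2 z ≈ 0.52, which at these design ratios makes
  the 1:2 group indistinguishable from the 1:1 group. Size factors estimated
  from the (median-centred) background remove the composition shift, the
  same job DESeq2-style normalisation does in real titration analyses. With
  this route, deep error-free counts rank all 69 designed-DE spike-ins ahead
  of all 23 nulls (AUC = 1).

The ROC orders genes by A-vs-B p-value; AUC is the Mann-Whitney probability
that a random true-DE spike-in has a smaller p-value than a random null one,
ties counted ½. Stratified reporting follows the benchmark's layout:
expression strata (all genes, top 1%, 10%, 25%, bottom 75% by mean TPM;
quantile ties break by gene id), gene-length quartiles, and gene-type
categories ("Protein coding", "ERCC", "tRNA", "rRNA", "Other sncRNA",
"Other ncRNA"), plus a cumulative |error| curve over tRNA genes.

The expected fold change f_i is computed from the *measured* A/B fold change
of the same pipeline (point estimate across all replicates), so f_i inherits
measurement error — deliberately so: the statistic asks whether a pipeline
is internally consistent with the mixing design, not whether it knows the
truth.

## Problem sizes and numerical choices

Default benchmark runs use 194 expressed transcripts and 30 000 reads per
library (4 samples × 3 replicates); the mechanism scenario in the acceptance
suite also uses 30 000 reads per library, sized so that the alignment route
measures even low-abundance tRNAs with enough counts that the directional
contrasts reflect quantifier-induced error rather than shot noise. The deep
"exact quantifier" checks (fold-change R² ≥ 0.99, spike-in AUC = 1) use
Poisson counts at 10⁷ reads per library — matching real library depths —
drawn directly from true abundances, because those claims are about the
evaluation machinery under an error-free quantifier, not about read-level
assignment. At desk-scale read depths the overall R² is dominated by shot
noise on low-abundance genes — the all-genes "Total RNA" stratum is always
the hardest one, at any scale; tRNA fold-change
RMSE at heavy dropout is additionally subject to two small-count artifacts
(survivor selection and pseudocount shrinkage toward zero), which is why
the acceptance scenario fixes seeds and reports detection counts alongside
RMSE.

EM ties are resolved by the uniform start; quantile ties by ascending gene
id; multi-map ties by a seeded draw. The Welch test with three replicates is
conservative (empirical type-I error ≈ 0.035 at α = 0.05 on null NB genes),
which is acceptable here because every comparison uses the same test. The
brentq tilt solve brackets λ ∈ [−80, 80] and a final common rescale of both
samples absorbs float round-off so ΣA/ΣB = z holds to 1e-12 relative.

## Known limitations

* Random sequences mean no homology structure: real tRNA isodecoders share
  sequence and multi-map heavily; here multi-mapping arises only from
  designed isoform sharing and decoys.
* The DE test is a t-test, not a count model: no shrinkage, no dispersion
  sharing across genes; fold-change estimates for near-zero counts are
  pseudocount-dominated.
* The alignment quantifier has no indels, splicing, clipping, or quality
  awareness; its mismatch tolerance is the only knob.
* `z` is an input, not an estimate; real titration analyses must estimate it
  or take it from orthogonal measurements.
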
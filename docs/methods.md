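# Methods

## Model

A chromosome of an F1-hybrid replicate is modelled as a first-order hidden
Markov chain whose units are genes in genomic order.  Hidden states are the
two genotype configurations a paternal chromosome segment can take in a
G1/G1 (mother) × G1/G2 (father) cross: homozygous G1/G1 (state 0) and
heterozygous G1/G2 (state 1).  The observation at each gene is one of six
symbols obtained by discretizing the replicate-level mean allelic ratio
r̄ ∈ [0, 1]: symbol 0 for r̄ < 0.5 and symbols 1–5 for the 0.1-wide bins
covering [0.5, 1.0].  Sub-0.5 ratios are pooled into one symbol because they
arise essentially only in heterozygous segments (balanced or G2-biased
expression); the model's discriminative signal is the contrast between
symbols 0–1 (ratios near 0.5) and symbol 5 (ratios near 1).

Assumptions worth stating explicitly:

- **First-order Markov genotype structure.** Crossovers are rare and
  approximately independent, so genotype switches between adjacent genes are
  modelled with a constant per-gene probability.  SNP-density and
  recombination-rate heterogeneity along the genome are not modelled.
- **Conditional independence of emissions.** Given the hidden genotype, each
  gene's symbol is independent of its neighbours.  Shared technical noise
  (e.g. cell-level capture efficiency) violates this mildly in real data.
- **Genes as observation units.** Only expressed, allele-informative genes
  enter the chain; gene deserts, centromeres and non-coding regions are
  invisible to the model and segment boundaries are resolved only to the
  gene scale.

## Parameters, units and defaults

| parameter | default | meaning |
|---|---|---|
| π | (0.5, 0.5) | either genotype equally likely at the chromosome start |
| A diagonal / off-diagonal | 0.998 / 0.002 | per-gene probability of keeping / switching genotype; 0.002 = 2 crossovers / ~1,000 genes per chromosome |
| B (init) | G1/G1 row ramps linearly toward symbol 5; G1/G2 row puts 0.9 of its mass on symbols 0–1 | breaks EM label symmetry; every entry positive |
| `min_cells` | 1 | minimum informative cells for a gene's r̄ to be used |
| `tol` | 1e-4 | EM stop when total log-likelihood improves less than this |
| `max_iter` | 500 | EM iteration cap |
| `pseudocount` | 1e-6 | added to transition/emission expected counts each M-step |

All three parameter blocks are re-estimated by multi-sequence Baum-Welch on
chromosome chains pooled across replicates; 0.998/0.002 is an
initialization, not a constraint.  After fitting, hidden-state labels are
normalized so the state with the higher expected emitted symbol index is
G1/G1 — EM is label-symmetric, the biology is not, and this guarantees a
canonical orientation regardless of initialization.

## Numerical choices

- Forward/backward use **scaled recursions** (probability space with
  per-position renormalization constants), batched over equal-length chains;
  the log-likelihood is the sum of log scale factors.  Viterbi runs in log
  space.
- The EM trace records the log-likelihood of the parameters *entering* each
  iteration, so monotonicity (within 1e-8) is an exact property of the
  implementation, verified on every fit in the test suite.
- **Viterbi ties** are broken toward remaining in the current state
  (switches are rare a priori) and toward G1/G2 when terminal scores tie; in
  a fully degenerate (all-ties) setting the decoded path is therefore
  constant heterozygous.
- A cell with zero allele-assigned reads for a gene is **missing**, not a
  ratio of 0 or 0.5: zero coverage carries no allelic information.  Genes
  with no informative cell are excluded from the chains.
- Bin boundaries are left-closed/right-open with the top bin closed at 1.0,
  making discretization total and deterministic; boundary values (0.5, 0.6,
  …) fall in the upper bin.
- Chains of length 1 are decodable but excluded from carrying transition
  information; a training set consisting only of such chains is rejected.
- Gene order is ascending annotation start coordinate, strand ignored; at
  gene scale the choice of start vs TSS does not change adjacency.
  Input coordinates are 1-based (GTF convention); BED output is 0-based
  half-open.  Segment spans run from the start of their first gene to the
  start of their last gene — extending spans to midpoints between flanking
  genes or to chromosome ends would claim resolution the data does not have.

## Decoding and confidence

The primary genotype assignment is the Viterbi path, which produces the
clean, globally consistent segmentations wanted for segment-restricted
downstream analyses.  Per-gene forward-backward posteriors
P(G1/G2 | observations) are computed alongside as a confidence annotation;
they are deliberately not the primary path, since the posterior-max path
need not be a valid segmentation under rare-switch dynamics.

## Training design

Training pools randomly selected chromosomes across replicates into a single
parameter set (`chains_per_replicate` controls how many per replicate;
sampling is uniform without replacement and seeded).  One shared parameter
set is the right granularity: the emission process reflects the assay, not
the replicate, and pooling is what lets sparse replicates borrow strength.

## Posterior predictive checks

`run_ppc` simulates one synthetic chain per real chain, length-matched, from
the fitted parameters, then compares pooled-symbol mean, population-formula
standard deviation, and the adjacent-pair symbol switch rate (never counted
across chain boundaries), plus two-sample Kolmogorov–Smirnov and
Mann–Whitney U tests with asymptotic p-values.  Statistics are computed on
the integer symbol scale 0–5.  Note an inferential subtlety the test suite
respects: symbols are strongly autocorrelated within a chain (a hidden state
persists for ~1/switch-rate genes), so Monte-Carlo error bars for these
statistics must be computed at the chain level, not the symbol level.

## Downsampling robustness

Reduced heterozygous-SNP coverage is emulated by keeping a random fraction
of gene positions per chromosome — the same subset across all replicates —
then retraining and comparing to the full model: Pearson r, mean absolute
difference and mean squared error over the concatenated 18-entry
(π, A, B) vector (π included for completeness), and decoding consistency:
the fraction of retained genes of one representative replicate (the one
with the most informative genes, configurable) assigned the same genotype
by the reduced and the full model, per chromosome and averaged.
Consistency compares *decoded* states: observed symbols are unchanged by
model choice, so only the decoded assignment can measure model degradation.

## Synthetic data generator

`synthetic_data` emulates the cross design end to end: per replicate and
chromosome a hidden genotype chain with the configured switch rate
(default 0.002, starting heterozygous with probability 0.5); per gene and
cell a total allele-assigned count from a negative-binomial distribution
(default mean 2.0, overdispersion 0.5), an independent dropout mask
(default rate 0.3), and a binomial G1 count whose success probability is
beta-distributed around the block's true ratio (heterozygous centre 0.5,
homozygous centre 0.98 — real G1/G1 segments show residual misassigned
reads — both with concentration 50).  The beta noise around 0.5 produces
the sub-0.5 ratios that motivate pooling them into symbol 0.  Default
problem size is 4 replicates × 5 chromosomes × 200 genes × 120 cells,
a deliberate scale-down of a mouse experiment (~19 autosomes, ~1,000 genes
each) that preserves the statistical regime — per-gene informative-cell
counts, symbol separation, switches-per-chain — while keeping every test
fast.

Dropout uniforms are drawn unconditionally, so simulations differing only in
`dropout_rate` share all other draws and their dropout masks are nested:
raising dropout strictly removes information from the same realization,
which makes "accuracy degrades with dropout" a near-sure property rather
than a coin flip.

What passing tests on this generator do **not** show: robustness to cell-type
expression structure, batch effects, reference-allele mapping bias, or
SNP-density variation along chromosomes.  They do show that the estimator
and decoder are correct (exhaustive-path and independent-implementation
oracles), that parameters of a known generating process are recovered, and
that the full pipeline reconstructs known genotype maps under realistic
sparsity.

## Known limitations

- High allelic dropout inflates apparent switches; below ~1 informative
  cell per gene the chains thin out and segment boundaries blur.
- Only two hidden states: G2/G2 is impossible under this cross design, and
  position-dependent transition or emission probabilities (e.g. modelling
  allelic imbalance per gene) are not implemented.
- The Pearson correlation of two 18-entry probability vectors is dominated
  by the bimodal (near-0 / near-1) entries and is reported mainly for
  comparability; MAD and MSE are the informative agreement measures.
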
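# Methods

## The selection model

A yeast-display MHC-II screen displays a library peptide fused to its MHC;
after protease release of the tether and competitor-driven peptide exchange,
yeast retaining the peptide are selected, re-grown, and re-selected. We model
each round r as independent Bernoulli retention of every displayed read,

    p_keep = sigmoid( s_r * ( score(core) - theta ) ),

where `score(core)` is the planted 20×9 PSSM summed over the 9 core
positions, `theta` the logistic midpoint, and `s_r` the round's stringency.
Survivors are resampled with replacement to a fixed carryover depth,
emulating regrowth and bottlenecking. The logistic is the minimal monotone
retention model: its zero-stringency limit retains every peptide with
probability 1/2 and its infinite-stringency limit is a step function at
`theta`, both of which the tests exercise. Selection never invents peptides:
round r+1 is a subsample of round r.

The planted PSSM is expressed on the log2-enrichment scale: it is
`log2(target/NNK)` for a target frequency profile that concentrates
probability on anchor-position residues (P1 large hydrophobics, P4 acidic,
P6 polar, P9 small, auxiliary P7, with P2-Pro and non-P1 Trp depletions).
Planting on this scale makes the ground truth the same kind of object the
pipeline recovers — a log2-enrichment matrix including the depletion
structure that anchor enrichment necessarily implies — so "motif recovery"
can be quantified as a plain Pearson correlation between planted and
recovered matrices without any rescaling.

The logistic midpoint defaults to the 90th percentile of the null core-score
distribution under NNK residue frequencies (estimated once from a fixed
internal sample of 10,000 draws), so a defined ~10% naive tail is
selectable. Stringencies default to (1.0, 1.2, 1.4, 1.6, 1.8) across five
rounds — positive, non-decreasing, and mild enough that enrichment grows
over several rounds rather than saturating in one.

For the 13mer design the binding register is not fixed by the flanks; each
unique library sequence draws its core offset from a mixture centered on the
designed central register (70% central, 10% at ±1, 5% at ±2), reflecting
that shifted registers occur but the design favors the central one.

## What the generator emulates, and what it does not

Emulated: NNK codon sampling (so Leu/Arg/Ser are ~3× Met at randomized
positions and amber stops appear at 1/32 per codon), template-encoded
constant flanks with one canonical codon per residue, per-round inline
barcodes, substitution errors at a per-base rate, and a two-valued Phred
model (Q15/Q30) — two-valued because the pipeline's only quality rule is the
Phred-20 cut. Not emulated: PCR amplification bias, indels (length-mismatch
filtering removes them anyway), paired-end structure and merge artifacts,
chimeras, cluster-density effects, or biological avidity differences between
yeast clones. Passing tests therefore demonstrate correctness of the
analysis logic under a faithful error *type*, not robustness to every
artifact of a real sequencing run. Default per-run depth is 10^5 reads/round
— the scale at which the property suite runs on one CPU in seconds; real
MiSeq rounds are a few-fold deeper, which only sharpens counts.

Sequencing constants (5'/3' amplicon constants, barcodes, allele-tag
segments) are synthetic stand-ins with the structural features the filters
need (3C-site-encoding sequence, allele-distinguishing segment, unique
per-round barcodes); real designs are supplied as JSON.

## Read processing

The filter cascade keeps a read iff it has the exact expected length, exact
constant-region matches, a known round barcode, Phred ≥ 20 at every
peptide-encoding base, and G/T at every randomized codon's third position.
Attrition at each stage is counted and reported, never silent.

The error collapse discards a sequence s when a retained, strictly more
prevalent sequence t exists with Hamming(s,t) ≤ 1, or ≤ 2 with
count(t) ≥ 100·count(s), or ≤ 3 with count(t) ≥ 10,000·count(s), within the
same round. Sequences are processed in descending count order with a
lexicographic tie-break, so the result is deterministic; ties in count never
collapse (prevalence must be strictly greater). Radius-1 neighbors are
enumerated (3L lookups per sequence); the 100×/10,000× gates are checked by
direct Hamming distance against the short prefix of retained sequences
prevalent enough to trigger them, which keeps the collapse near-linear while
remaining exactly equivalent to the quadratic all-pairs reference — an
equivalence asserted over randomized tables in the test suite. Comparing
against retained sequences only (greedy) is the default; a config switch
compares against all more prevalent sequences instead.

A note on what collapse can achieve: a corrupted read whose error-free
parent is absent, or tied in count, is indistinguishable from a genuine
singleton. Removal rates are therefore reported both over all error children
and over the removable class (parent observed at strictly higher
prevalence); the ≥95% property applies to the latter. At the default
simulation scale, parent peptides are recovered at ~100% and removable error
children removed at ~98%.

## Enrichment and motifs

Frequencies are unweighted (one count per unique peptide), matching the way
selected repertoires are summarized; read counts are kept in the table for
weighting experiments but not used in motifs. The log2 enrichment adds 0.1
percentage points to numerator and denominator — matrices are always finite;
0.1 is below the resolution of a ~10^4-peptide repertoire (one peptide ≈
0.01–0.02 points) yet caps the magnitude of empty-cell enrichments at
plausible values. Significance uses exact two-sided binomial tests on a
seeded sample of up to 10,000 peptides per distribution with a Bonferroni
factor of positions × 20. KL logos use heights
`h_p(a) = f_p(a) log2(f_p(a)/q(a))`, which sum exactly to the positional
information (enriched residues positive, depleted negative); the packaged
background is the UniProtKB average amino-acid composition renormalized over
the 20 canonical residues.

## Register deconvolution

The PSSM is the round-5 log2-enrichment matrix used additively without
positional weighting. Scanning scores all `len − 8` windows; ties prefer the
designed register (the in/out-of-register dichotomy is defined relative to
the design, and ties are vanishingly rare on real-valued matrices), then the
lowest offset.

The Gibbs sampler assigns each peptide a (cluster, offset); moves are
sampled from the per-peptide posterior over all options at temperature T,
annealed linearly from 1.0 to 0 over the sweeps (final sweeps are greedy,
so the objective is non-decreasing at zero temperature). Cluster log-odds
matrices use add-pseudocount frequencies with β = 50 effective pseudocounts
against the data-derived background (+1-smoothed). Model selection maximizes
the size-weighted mean cluster KL information with an additional small-
cluster shrinkage factor n_k/(n_k + β): without it the objective is
near-monotone in the cluster count (splitting off a handful of stray
peptides raises the weighted mean by a hair) and argmax-over-k is unstable.
Defaults: k ∈ 1..6, 5 restarts keeping the best final KLD, 100 sweeps.
Tests and the acceptance script run k ∈ 1..4, 3 restarts, 40 sweeps at
150–300 peptides — sizes at which planted one- and two-motif sets are
resolved in seconds. Peptides whose assigned-cluster log-odds score falls
below the trash threshold (default 0) are flagged outliers and excluded
from the final cluster matrices. Cluster labels are identifiable only up to
permutation; tests compare partitions.

## Predictor

Targets from yeast rounds are `final_round / R` — the minimal monotone map
of the observed selection depth into [0, 1]; naive-only peptides are 0.
Training sets are capped (default 80,000) by seeded stratified subsampling
that preserves per-round proportions, and only randomized residues are
emitted. MS-style sets pair each positive with one uniform scramble of
itself (re-drawn if identical), so negatives match composition exactly.

Members are single-hidden-layer tanh networks with a sigmoid output, trained
by full-batch backpropagation with momentum 0.9 and early stopping on a
held-out partition (patience 20, max 500 epochs). Plain gradient descent is
deliberate: adaptive per-parameter optimizers equalize the learning speed of
signal and memorization directions on sparse one-hot features and fail to
generalize on the small, wide matrices typical here (this is observable as
near-zero training error with chance-level held-out error). During training
the core window of each example longer than 9 residues is re-chosen every
few epochs as the max-scoring window under the current network (register
scanning). The default member grid is hidden {10, 40} × encodings
{sparse, BLOSUM50/10} × 5 CV partitions × 2 seeds = 40 members;
`TrainConfig.small()` (16 hidden, 2 partitions, 4 members) trains in about
a minute on a 12,000-example set and is used by the acceptance runs. An
ensemble's prediction is the mean member output; the reported core offset is
the modal best window (ties to the lowest). Percent rank of a score is the
percentage of calibration scores ≥ it, over seeded background-frequency
random 15mers; higher score = stronger binder, with `1 − score` exposed as
an output option for affinity-style comparisons.

For 13mer-library models, flank context enters as NN-Align-style summary
features: mean encoding of up to two residues on each side of the window
plus two clipped flank-length features.

## Benchmarking

Minimal epitopes keep the innermost member of each substring-nested group
(exact containment only — partial overlaps are distinct peptides) and drop
peptides containing user-supplied exclusion substrings. Decoy tiling draws
each tile's length from the positives' length distribution and steps by
`length − 8` (consecutive peptides overlap by 8 residues); a final tile that
would overrun is shifted back to end exactly at the protein's last residue.
Decoys are drawn only from the positives' source proteins, per length
stratum, rejecting any tile sharing a 9mer with a positive or an
already-chosen decoy; a shortfall raises an explicit "decoy pool exhausted"
error rather than returning an undersized set. AUC is the Mann–Whitney rank
statistic (ties count half) and equals the trapezoidal integral of the ROC
points; PPV takes the top `ceil(0.05·N)` of a 1:19 set after a stable
descending sort (tie composition is deterministic by input order: positives
first). Predictor comparison takes the top decile of each predictor over a
common random-peptide set and tests each core position × residue of the
"only-A"/"only-B" sets against the "both" set by two-sided binomial tests,
Bonferroni over 180 cells.

## IC50 fitting

Relative binding is affine-invariant in the FP readings by construction.
Curves are fit to `y = 1/(1 + c/IC50)` by least squares over `log10(IC50)`
(tested concentrations span 4+ orders of magnitude: five-fold dilutions,
20 µM → 1.28 nM), started from a 41-point coarse grid so the fit is
deterministic; the 95% CI comes from the parameter covariance on the log
scale. Fits outside [min(c)/100, 100·max(c)] are flagged censored and
rendered relative to the tested range ("> 20000 nM") instead of
extrapolated. Two-point estimates invert `IC50_i = c_i·y_i/(1−y_i)` per
concentration and combine by geometric mean (the natural mean on the log
scale the fit itself uses); on noise-free two-point data this equals the
full fit exactly. Predicted-vs-measured regressions default to log10 IC50
(linear is a flag), exclude censored values, and report negative
correlations with an explicit flag rather than hiding the sign in R².

## Limitations

- The simulator's selection is memoryless given the current pool; real
  rounds share yeast growth history and display-level variation.
- Gibbs deconvolution uses fixed-length cores with no insertion/deletion
  moves, and its restart/iteration defaults are sized for desk scale.
- The predictor is allele-specific by construction; no pan-allele sharing.
- External predictors' scores are consumed as input columns only; none of
  their models are reimplemented or invoked.
- Logo rendering is not included; KL information/height matrices (TSV) are
  the contract.
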
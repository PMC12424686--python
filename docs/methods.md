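# Methods

## Repertoire simulation

The generator works at the nucleotide level because the processes it
emulates — junctional trimming, non-templated (N) nucleotide addition, and
somatic hypermutation (SHM) — are nucleotide-native; amino-acid-level
labels are derived afterwards by translation.

**Germline library.** Segments are synthetic stand-ins for IMGT-style
references. V segments are built from stop-free sense codons with fixed,
codon-aligned region boundaries (heavy: FWR1 25 aa, CDR1 8, FWR2 17,
CDR2 8, FWR3 38; light: 23/6/15/3/32) plus a 2-codon CDR3 stub; D segments
(heavy only) are 12–21 random nucleotides; J segments are a 6–18 nt CDR3
tail followed by a fixed 33-nt FWR4 block. All segment lengths are
multiples of 3 so that an edit-free assembly is in frame.

**Recombination.** Heavy chains are `V′ + N1 + D′ + N2 + J′`, light chains
`V′ + N + J′`. V is trimmed only at its 3′ end (never past its CDR3 stub,
so FWR1–FWR3 survive intact), J only at its 5′ end (never into FWR4), and
D at both ends; trims are uniform on `[0, trim_max]`. N-block lengths are
Poisson(4.5) by default — the human-typical few-nucleotide junctional
insert — and N bases are uniform. If the sampled edits break the reading
frame, the frame is restored by deepening the J (then V, then D) trim; the
sampled N lengths are never altered, so N-residue counts are exactly what
the length distribution produced. Draws whose translation contains a stop
codon are resampled, up to 100 retries, then a hard error: silent
distribution shift is worse than a loud failure.

**Regions and provenance.** With these conventions the aa region map is
exact: FWR1–FWR3 come from the V boundaries, CDR3 is
`[end of FWR3, length − 11)`, FWR4 the final 11 residues. A codon's
provenance label is the majority label of its three nucleotides, with
three-way ties resolved junction-ward (N over D over J over V) — a
deterministic, testable rule. Every N-labelled residue necessarily falls
inside CDR3.

**Mutation model.** A pair is unmutated (both chains zero substitutions)
with probability `unmutated_fraction` (default 0.4, roughly the naive
fraction of circulating B cells). Mutated pairs draw (heavy, light)
substitution counts from a common-shock Poisson model: with
λ = `shm_rate` × mean nucleotide chain length and ρ =
`pairing_correlation`, counts are `h = X₀ + X_h`, `l = X₀ + X_l` with
`X₀ ~ Pois(ρλ)` and the idiosyncratic terms `Pois((1−ρ)λ)`. This makes the
Pearson correlation of the two loads exactly ρ and degenerates to `h = l`
at ρ = 1. The common-shock construction was chosen over a gamma-mixed
alternative because its correlation is exact rather than asymptotic.
Defaults `shm_rate = 0.02` and ρ = 0.8 give ~6–7 substitutions per mutated
chain with strongly similar loads within a pair. Substitution positions
are uniform over the chain (no hotspot model); a substitution never
reinstates the original base, and one that creates a stop codon is
individually resampled.

What the simulator does **not** reproduce: real germline alleles and their
usage frequencies, SHM hotspot motifs and indels, clonal lineage
structure, isotypes, and sequencing artefacts. Tests passing on this
generator therefore demonstrate correctness of the *pipeline mechanics*
and the statistical behaviours explicitly built in (provenance structure,
correlated loads, donor structure) — not performance on real repertoires.

## Corpus preparation

Clustering is greedy founder-representative clustering on the concatenated
heavy+light amino-acid string: sequences are processed longest-first (ties
by id), each joining the earliest cluster whose founder it matches at
≥ 90% identity, else founding a new cluster. Identity is matches divided
by alignment columns of a global alignment scored match +1 / mismatch 0 /
gap 0; an infinitesimal gap penalty (−10⁻⁶) breaks ties among
equal-match alignments in favour of mismatch columns, making identity
deterministic. This replaces an MMseqs-style clusterer at desk scale and
makes no attempt to match MMseqs assignments bit-for-bit.

Splits use round-half-up arithmetic: `|train| = rhu(0.96·N)`, with the
remainder split between evaluation and test and the odd element going to
evaluation; nested subsets satisfy `|H| = rhu(|F|/2)`, `|Q| = rhu(|H|/2)`.
On a 1,717,423-pair corpus this yields 1,648,726 / 34,349 / 34,348 and
824,363 / 412,182 — the sizes the pipeline is designed around. Gene-usage
balance between subsets is checked with Pearson χ² on V, J or V×J usage
tables (no continuity correction; zero-total categories dropped; under the
null, p-values from disjoint random halves are uniform, which the suite
verifies by a KS check).

Quality filtering of raw sequencing artefacts is a pass-through hook with
a pluggable predicate: the filters it would host operate on features
synthetic data does not have.

**Tokenizer.** The 33-symbol ESM-2 token inventory ships as a versioned
asset (`data/vocab.txt`). A pair is laid out
`<cls> H₁…Hₙ <cls> <cls> L₁…Lₘ <eos>` — two `<cls>` tokens as the chain
separator, with a leading `<cls>` and trailing `<eos>`; the four special
positions are never maskable.

## Masked-LM training

The encoder is a pre-layer-norm transformer with rotary positional
embeddings applied inside each attention head and a GELU feed-forward
block, implemented entirely in float64 NumPy with hand-derived backward
passes (verified against central-difference gradients in the test suite)
and Adam with linear warmup/decay. Pure NumPy keeps runs bit-reproducible
for a given seed and platform and is ample for the miniature models this
package targets (2–4 layers, d_model 32–128); it is not a throughput
engine.

The masking collator selects each non-special position independently with
probability 0.15; selected positions become the mask token with
probability 0.8, a uniformly random canonical-residue token with 0.1, and
stay unchanged with 0.1. Unselected positions carry an ignore marker and
contribute nothing to the loss, which is the mean cross-entropy over
labelled positions. Evaluation masking uses one fixed dedicated seed so
that losses are comparable across models and runs.

Full-scale schedule defaults mirror the study protocol (500,000 steps,
30,000 warmup, peak LR 10⁻⁴, batch 128, seed 42); tests and examples
scale these down (hundreds of steps, batch 8–16, peak LR 1–3 × 10⁻³,
which suits the much smaller models). Checkpoint selection operationalizes
"onset of overfitting" with a patience window: the earliest recorded step
after which evaluation loss is non-decreasing for `patience` (default 3)
consecutive evaluations while training loss keeps falling; if divergence
never occurs, the minimum-evaluation-loss step. The evaluation cadence and
patience are package choices — recorded in configuration, not presented as
the original protocol's values.

## FixedData profiles and the scaling law

For one data scale, mean loss is regressed on
(log₁₀M)², log₁₀M, 1 by ordinary least squares; the fit must be convex
(a > 0) for the minimum `M* = 10^(−b/2a)` to exist, and R² is reported on
the points actually fitted. Outlier handling makes the qualitative
"keep points around the minimum" rule concrete: keep the minimum-loss
point and its nearest log-size neighbours until at least 3 points are
retained, and drop any point whose loss exceeds 1.5× the minimum. The
power law is fitted by OLS in log–log space (closed-form, matching the
near-unity R² regime this analysis operates in); `predict_optimal_data`
and `predict_optimal_model` evaluate it in both directions. A synthetic
grid generator (`simulate_loss_grid`) produces loss surfaces whose minima
follow a known law, so the whole chain (grid → profiles → minima → power
law) can be checked for parameter recovery; the suite does this across 20
seeded replicates at problem sizes of 3 data scales × 8 model sizes.

## Regional evaluation

"Iterative masking" is interpreted as single-position masking: one
forward pass per heavy-chain residue with exactly that token masked,
yielding a per-position cross-entropy. Positions are summarized as pooled
medians across all positions in a group (region, or V/D/J/N provenance
within CDR3), stratified by mutation status; FWR1–4 are collapsed into one
"FWRs" group for reporting, with the per-FWR detail retained in the raw
records. The 95% CI of a median uses exact binomial order statistics
(ranks l and n−l+1 with l the largest rank whose lower binomial(n, ½)
tail stays within 2.5%); below n = 10 a seeded 2,000-resample bootstrap
is used instead. Model comparisons are two-sided paired t-tests with the
donor dataset as the pairing unit; identical inputs return (t=0, p=1),
while constant non-zero differences raise a degenerate-variance error
rather than fabricating an infinite t.

## Classification

Shuffled pairs are built within donor: half of each donor's pairs (one
dropped at random when odd) have their light chains permuted by a
derangement — a permutation with no fixed points, via Sattolo's
algorithm — so no "shuffled" item silently keeps its native partner, and
the per-donor multisets of heavy and light chains are unchanged. Mutation
counts travel with their chains. Specificity tasks use synthetic classes
that shift heavy V-gene usage and mean N-addition length per class.

The encoder stays frozen; items are pooled to fixed-length vectors
(default: the final hidden state at the leading `<cls>`; mean over residue
positions behind a flag) and a linear softmax head is trained per fold
with Adam under the 10%-warmup linear schedule. Features are standardized
on each training fold. Cross-validation is stratified 5-fold; metrics
(accuracy, F1, AUC, AUPR, MCC) are computed per fold and aggregated as
mean ± standard error, with macro/one-vs-rest averaging for more than two
classes. Mutation-bin accuracy grids tabulate correctness over
(heavy, light) mutation-count cells, with native-only and shuffled-only
views.

## Numerical and design notes

- All randomness flows through `numpy.random.Generator` objects seeded at
  the interface; identical inputs give identical outputs.
- Degenerate inputs fail loudly: non-convex profiles, rank-deficient
  designs, single-class metric requests, empty evaluation sets,
  impossible mutation targets and exhausted resampling budgets all raise
  typed exceptions.
- Desk-scale problem sizes used by the test suite (hundreds of pairs,
  10²–10³ training steps, 10⁵-parameter models) were chosen so the full
  pipeline exercises every code path while each property retains
  statistical power; they are the package's study conditions, not tuning
  knobs.

## Known limitations

- The simulator's germline library is synthetic; absolute loss values and
  cluster structures are not comparable to real-repertoire numbers.
- Light-chain regional scanning is not implemented (heavy-chain only),
  matching the analysis the pipeline reproduces.
- The NumPy trainer is single-threaded float64; models beyond ~10⁶
  parameters are impractical.
- Greedy identity clustering is order-defined (longest-first); it is
  deterministic and permutation-stable under that rule but will not match
  MMseqs cluster assignments.
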
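# ablmkit

Antibody language models (AbLMs) trained on natively paired heavy/light
chain sequences are *data-limited*, not compute-limited: the world's supply
of paired antibody sequences is small, so the practical question is not
"how much compute?" but "given a corpus of N paired sequences, how large a
model should I train — and how much data would an ESM-2-class model need?"

`ablmkit` is a desk-scale, fully seeded pipeline for studying exactly that
question, aimed at computational immunologists and ML-for-biology
researchers who want a controlled, reproducible sandbox rather than a GPU
cluster. It provides:

- **`ablmkit.germline` / `ablmkit.repertoire`** — a nucleotide-level
  simulator of paired repertoires: V(D)J recombination with junctional
  trimming and non-templated (N) additions, somatic hypermutation with
  correlated heavy/light mutation loads, and per-residue region
  (FWR1–4, CDR1–3) and provenance (V/D/J/N) annotation.
- **`ablmkit.corpus`** — greedy 90%-identity clustering, 96/2/2
  train/eval/test splitting, nested full/half/quarter (F/H/Q) training
  subsets, gene-usage χ² balance checks, and an ESM-2-style 33-token
  tokenizer (`<cls> H… <cls> <cls> L… <eos>`).
- **`ablmkit.transformer` / `ablmkit.mlm`** — a miniature pure-NumPy
  transformer encoder (rotary positions, pre-layer norm, hand-derived and
  gradient-checked backprop) trained with the standard masked-LM recipe:
  15% of positions selected, 80/10/10 mask/random/keep.
- **`ablmkit.scaling`** — FixedData profiles: quadratic fits of loss in
  log₁₀(parameters) at fixed data scale, minima extraction with outlier
  exclusion, and the data-optimal power law `D = α · M^β` with forward and
  inverse prediction.
- **`ablmkit.regional`** — per-position masked-residue scoring resolved by
  antibody region and CDRH3 provenance class, with order-statistic median
  CIs and paired t-tests across donor datasets.
- **`ablmkit.classify`** — frozen-base classification (antigen
  specificity, native-vs-shuffled chain pairing) with stratified 5-fold
  CV, the accuracy/F1/AUC/AUPR/MCC metric suite, and mutation-count-bin
  accuracy grids.

## The core relationship

At a fixed training-data scale, evaluation loss as a function of model
size M is modelled as

    loss = a·log₁₀(M)² + b·log₁₀(M) + c,        a > 0

whose minimum `M* = 10^(−b/2a)` is the data-optimal model size for that
scale. Fitting `D = α·M^β` through the (M*, D) minima of several data
scales gives a data-optimal scaling law that extrapolates in both
directions.

## Worked example

```python
import ablmkit as ak
from ablmkit.scaling import PowerLaw

# scaling law fitted on paired-antibody FixedData minima
law = PowerLaw(alpha=0.232, beta=0.8369)
ak.predict_optimal_data(6.5e8, law)       # -> 5508269.4  (~5.5M pairs for a 650M model)
ak.predict_optimal_model(1_648_726, law)  # -> 153798622.5 (~150M params for a 1.6M-pair corpus)

# simulate, cluster and split a small repertoire
lib = ak.build_toy_library(seed=1)
cfg = ak.RepertoireConfig(n_donors=3, pairs_per_donor=30, seed=0)
pairs = ak.generate_repertoire(cfg, lib)
len(pairs)                                # -> 90
pairs[0].heavy_regions["CDR3"]            # -> (96, 111)
pairs[0].heavy_mut_count                  # -> 7

reps = ak.cluster_identity(pairs)         # -> 76 representatives at 90% identity
split = ak.partition_corpus([p.pair_id for p in reps], seed=0)
len(split.train), len(split.eval), len(split.test)   # -> (73, 2, 1)
```

The first two numbers say that a 650M-parameter paired AbLM is data-optimal
at about 5.5 million clustered pairs, and conversely that a 1.65M-pair
corpus optimally supports a ~150M-parameter model. In the simulation block,
90 generated pairs collapse to 76 cluster representatives (the toy germline
library is small, so unmutated pairs sharing V/J genes often exceed 90%
identity), and the 96/2/2 split rounds half-up with the odd remainder
element going to the evaluation set.

The same steps are available from a shell:

```bash
ablmkit simulate --out sim --seed 0
ablmkit prepare --in sim --out prep --seed 0
ablmkit train --data sim --steps 300 --out ckpt
ablmkit regional-eval --ckpt ckpt --data sim --n-per-donor 5 --seed 0 --out regional
ablmkit classify --task pairing --ckpt ckpt --data sim --seed 0
```

## Scope

The simulator is a study instrument, not a germline reference: it uses
synthetic segment libraries, uniform (hotspot-free) hypermutation, and no
insertions/deletions or class switching. Model training is deliberately
miniature (10⁵–10⁶ parameters); see `docs/methods.md` for the modelling
assumptions, parameter defaults, and known limitations.
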
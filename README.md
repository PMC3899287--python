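# aptapair

Sequence-composition features, mRMR feature ranking and incremental feature
selection for predicting whether an aptamer binds a protein target.

Aptamers are short synthetic single-stranded nucleic acids selected (via
SELEX) to bind specific targets. Screening candidate aptamers in the lab is
slow; `aptapair` implements a sequence-only classifier pipeline that scores
(aptamer, protein) pairs as interacting or not, for computational biologists
who want a reproducible baseline predictor, and for method developers who
need a fully synthetic, planted-signal benchmark of the mRMR + IFS
feature-selection recipe.

## The method

An (aptamer, target) pair is encoded into a 290-component vector:

* **Aptamer (20):** mononucleotide fractions over (A, T/U, C, G) with U
  mapped to T, then the 16 overlapping dinucleotide fractions
  (count(xy)/(L−1)).
* **Target (270):** the 20 amino-acid frequencies f_u, plus, for each of
  five physicochemical scales H (polarity, codon diversity, electrostatic
  charge, molecular volume, secondary structure; Atchley factor scores,
  standardized to mean 0 / SD 1 over the 20 residues), the λ = 50
  pseudo-amino-acid (PseAAC) sequence-order components

      θ_j = (1/(L−j)) Σᵢ (H(R_{i+j}) − H(R_i))²,
      p_{20+j} = w·θ_j / (Σ f_u + w·Σ θ_k),      w = 0.05.

Features are discretized to 3 states (cuts at mean ± SD) and ranked by
**mRMR**: greedily select the feature maximizing
I(f, c) − (1/m) Σ_{g∈selected} I(f, g), where I is mutual information with
the class label c (MaxRel ranks by I(f, c) alone). **Incremental feature
selection** then scores every nested top-k subset with a 10-fold
cross-validated random forest (reference configuration: 10 unpruned trees,
⌊log₂ M⌋+1 features per split) and picks the k with the best Matthews
correlation coefficient:

    Sn = TP/(TP+FN)   Sp = TN/(TN+FP)   Ac = (TP+TN)/N
    MCC = (TP·TN − FP·FN) / √((TP+FP)(TP+FN)(TN+FP)(TN+FN))

Negatives are sampled 3:1 by random re-pairing, and the labelled set is
split 80/20 stratified by class.

## Worked example

```python
import numpy as np
from aptapair import *

# the composition encoder, on a 79-base aptamer with counts A=21,T=19,C=17,G=22
seq = "A"*21 + "T"*19 + "C"*17 + "G"*22
print(np.round(encode_aptamer(AptamerRecord("ex", seq)).mono, 4))
# [0.2658 0.2405 0.2152 0.2785]

# evaluation metrics from a pooled confusion matrix (145 pos / 435 neg)
print(compute_metrics(ConfusionCounts(tp=70, fp=56, tn=379, fn=75)))
# Sn=0.4828, Sp=0.8713, Ac=0.7741, MCC=0.3717 (rounded)

# full pipeline on a synthetic corpus with a planted composition signal
aptamers, targets, pairs = generate_corpus(FixtureSpec(seed=7))
vectors = encode_pairs(aptamers, targets, pairs)
split = split_dataset(vectors, test_fraction=0.2, seed=7)
result = run_pipeline(split, config=ClassifierConfig(seed=7),
                      k_values=[1] + list(range(10, 291, 10)))
print(result.optimal.k, round(result.optimal.mcc, 4))
# 20 0.8986
print({k: round(v, 4) for k, v in zip(("Sn","Sp","Ac","MCC"),
                                      result.holdout_metrics)})
# {'Sn': 0.8667, 'Sp': 0.9889, 'Ac': 0.9583, 'MCC': 0.8872}
```

The numbers mean: the cross-validated MCC over nested mRMR-ranked subsets
peaks at k = 20 features (MCC 0.8986), and a forest refit on those 20
features classifies held-out pairs at 95.8% accuracy — far above the 75%
accuracy / 0 MCC of a class-prior guesser on 1:3 data — because the corpus
plants an interaction rule on the aptamer G fraction and the target lysine
frequency, which the ranking recovers.

The same pipeline is scriptable from the shell:

```bash
aptapair simulate --out-dir corpus --seed 1
aptapair encode --aptamers corpus/aptamers.fasta --targets corpus/targets.fasta \
  --positives corpus/pairs_positive.tsv --negatives corpus/pairs_negative.tsv \
  --out matrix.tsv
aptapair rank --matrix matrix.tsv --out-dir run
aptapair ifs --matrix matrix.tsv --ranking run/mrmr.tsv --out-dir run --k-step 10
aptapair report --run-dir run
```

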
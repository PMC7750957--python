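# swikit

Sequence-only prediction and optimization of recombinant protein solubility
in *E. coli*, built around the **Solubility-Weighted Index (SWI)**.

Roughly half of the proteins that express in *E. coli* end up in inclusion
bodies.  SWI scores a protein's chance of staying soluble from nothing but
its amino-acid composition:

```
SWI = ⟨W_i⟩
```

the arithmetic mean of per-residue weights *W<sub>i</sub>* over the
sequence.  The weights descend from normalized crystallographic
*B*-factors — per-residue structural-flexibility propensities — refined
against thousands of binary expression outcomes by maximizing the area
under the ROC curve (AUC) with the derivative-free Nelder–Mead method,
inside a homology-aware cross-validation with class-balanced bootstrap
resampling.  A logistic link converts SWI into a probability of solubility:

```
p(soluble) = 1 / (1 + exp(−(a·SWI + b))),   a = 81.05812, b = −62.7775
```

The package is aimed at protein biochemists planning expression constructs
(which domain to express, whether a solubility tag helps) and at
computational biologists who want the full training pipeline as a tested,
reproducible library.

## What's inside

- `swikit.scoring` — flexibility profiles (9-residue sliding window over
  normalized *B*-factors), global flexibility F and its simplified form
  F′ = ⟨B⟩, SWI, GRAVY, probability of solubility.
- `swikit.scales` — bundled residue scales (Smith 2003, Vihinen 1994,
  Bhaskaran–Ponnuswamy 1988 *B*-factors; final SWI weights; Kyte–Doolittle
  hydropathy) plus a JSON weight-file format.
- `swikit.training` — rank-based AUC, cluster-aware fold construction,
  class-balanced bootstrap, Nelder–Mead weight optimization, logistic
  calibration, and a greedy fixture-grade sequence clusterer.
- `swikit.estimators` — scikit-learn API: `SWIFeaturizer` (sequences →
  feature matrix) and `SWISolubilityClassifier` (the full training
  pipeline behind `fit`/`predict_proba`).
- `swikit.regions` — score any sub-region, extend region boundaries by
  simulated annealing to maximize probability of solubility, score
  solubility-tag fusions.
- `swikit.enrichment` — per-residue log2 bit scores of a sequence group
  against a background, and the 12 000-sequence random control generator.
- `swikit.synthetic` — labeled, clustered synthetic datasets with a
  planted weight vector, for end-to-end validation of the pipeline.
- `swikit` CLI — `score`, `profile`, `train`, `enrich`, `simulate-random`,
  `simulate`, `optimize-region`, `fuse`.

## Worked example

```python
>>> from swikit import score_sequence
>>> r = score_sequence("MRGSHHHHHHTDPALRAMKVIFLQGGSSDGSK")
>>> round(r.swi, 4), round(r.probability, 4), round(r.gravy, 4)
(0.7943, 0.8335, -0.8469)
```

The SWI of 0.7943 sits above the calibration midpoint (−b/a ≈ 0.7745), so
the predicted probability of soluble expression is 0.83; the negative
GRAVY says the sequence is mildly hydrophilic.

Scoring against a weight file and optimizing a region from the shell:

```bash
swikit score proteins.fasta -o scores.tsv
swikit optimize-region proteins.fasta --start 40 --end 120 --seed 1 -o regions.tsv
```

`regions.tsv` lists candidate boundary extensions of the seed region ranked
by probability of solubility (best first).

Training new weights from labeled data:

```python
from swikit import SWISolubilityClassifier
clf = SWISolubilityClassifier(n_folds=3, n_bootstrap=20, n_per_class=100,
                              random_state=0).fit(sequences, labels, clusters=clusters)
clf.weights_        # trained ResidueScale
clf.result_.summary()   # per-fold train/test AUC
clf.predict_proba(new_sequences)
```

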
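# rxnteacher

Semi-supervised prediction of organic reaction outcomes from atom-mapped
reaction SMILES.

Reaction corpora with fully annotated products are expensive to curate, while
reactant-only data are abundant. `rxnteacher` implements a two-stage,
template-free product predictor that can learn from both:

1. **Reaction-center finding.** A Weisfeiler–Lehman network (WLN) with global
   attention embeds every atom of the reactant graph and scores each mapped
   atom pair for each possible new bond type (no bond / single / double /
   aromatic). The model is trained in a **mean-teacher** scheme: a *student*
   sees a perturbed graph in which each atom's feature vector is dropped with
   probability λ, a *teacher* — an exponential moving average (EMA) of the
   student — sees the clean graph, and the student minimizes

   ```
   L_stu = L_CEL + ω · L_MSE
   ```

   where `L_CEL = −Σ_i [y_i log s_i + (1−y_i) log(1−s_i)]` is the
   cross-entropy of the student's pair scores against the true centers
   (labeled data), and `L_MSE = (1/n) Σ_i (s_tea,i − s_stu,i)²` is the
   consistency loss against the teacher's scores, which acts on unlabeled
   data too. After each update, `θ_t ← α·θ_t + (1−α)·θ_s`.

2. **Candidate enumeration and ranking.** The top-5 scored centers yield
   `2⁵ − 1 = 31` candidate products (every non-empty subset of bond edits,
   hydrogens rebalanced by valence rules). A Weisfeiler–Lehman *difference*
   network (WLDN) pools candidate-minus-reactant embedding differences around
   the edited bonds and scores each candidate; training maximizes the softmax
   likelihood of the true product, and evaluation reports top-k accuracy.

A prediction of the center stage counts as correct when the predicted set
R(p) contains every true center TR(p), matched on atom pair *and* new bond
type.

Because the USPTO-scale corpora needed to reproduce published accuracies are
far beyond desk scale, the package ships a **synthetic reaction generator**: a
rule grammar (alkene reduction, halide amination, elimination, composites,
dihydrofuran aromatization) that emits atom-mapped reactions with 1–5 bond
edits and exact ground-truth centers, plus an unlabeled pool with products
stripped. Every pipeline stage is trainable and testable end to end on these
corpora. The models are plain numpy on a small built-in reverse-mode
autodiff core; RDKit handles all chemistry.

## Worked example

```bash
rxnteacher simulate --n-labeled 800 --n-unlabeled 2000 --seed 7 --out corpus
rxnteacher train-center --labeled corpus/labeled.txt --unlabeled corpus/unlabeled.txt \
    --steps 700 --hidden-dim 64 --lr0 0.002 --out center
rxnteacher train-rank --labeled corpus/labeled.txt --center-model center/teacher.npz \
    --epochs 3 --hidden-dim 64 --out rank
rxnteacher evaluate --labeled corpus/labeled.txt \
    --center-model center/teacher.npz --ranker rank/ranker.npz --out eval
```

`evaluate` writes `eval/evaluation.json`; the run above printed

```json
{
  "topk": {
    "1": 0.945,
    "2": 0.98375,
    "3": 0.99875,
    "5": 1.0
  },
  "center_coverage": 1.0,
  "candidate_validity_rate": 0.870241935483871,
  "n_records": 800
}
```

meaning the trained teacher's top-5 centers covered the true center set of
every reaction, 87% of enumerated edit subsets were chemically sanitizable,
and the true product was ranked first for 94.5% of reactions (within the
top 5 for all of them). `predict` emits a ranked TSV of candidate SMILES for reactant-only
input, optionally with a per-atom-pair attention dump for inspecting which
distant atoms the center model attends to.

The same functionality is available as a library:

```python
from rxnteacher import (CorpusSpec, generate_corpus, CenterTrainConfig,
                        train_center_model, center_coverage)
corpus = generate_corpus(CorpusSpec(n_labeled=800, n_unlabeled=2000, seed=7))
result = train_center_model(corpus.labeled, corpus.unlabeled,
                            CenterTrainConfig(hidden_dim=64, steps=700, lr0=0.002))
print(center_coverage(corpus.labeled, result.teacher, k=5))
```

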
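# mifnn

Binary molecular screening with fused dual-branch features and a
swarm-tuned, probability-calibrated SVM.

Virtual screening asks, given a SMILES string, how likely a molecule is to
be active against a target. Single representations miss information: graph
encoders capture connectivity but blur substructure identity, fingerprints
capture substructures but not context. `mifnn` extracts both and fuses them:

- **directed-information branch** — a directed message-passing encoder
  places hidden states on directed bonds, excludes each reverse edge from
  incoming sums (c⁰_pq = ReLU(W_in·cat(a_p, b_pq)); c^{s+1}_pq =
  ReLU(c⁰_pq + W_msg·Σ_{j∈N(p)\q} c^s_jp)), and sum-pools into a 300-d
  molecular vector, which is then refined by a 1-D CNN → mean pooling →
  bidirectional LSTM → attention pooling;
- **fingerprint branch** — a 2048-bit Morgan fingerprint (radius 2) reshaped
  to a 32×64 image and processed by two [3×3 conv → 2×2 average pool]
  blocks;
- the concatenated features pass through an FC layer with dropout and are
  classified by an RBF-kernel SVM whose (C, g) are found by particle swarm
  optimization (v ← U·v + c₁r₁(Pbest−L) + c₂r₂(Gbest−L)) minimizing
  cross-validated error, with decision values mapped to probabilities by
  sigmoid fitting P(y=1|f) = 1/(1+exp(Af+B)).

Performance is read as ROC-AUC. A synthetic-molecule generator with a known
substructure signal (and a known noise ceiling) makes the whole pipeline
testable without downloading any dataset.

Intended users: cheminformatics/ML practitioners who want a transparent,
dependency-light reference implementation of this architecture with testable
invariants, not a production screening service.

## Worked example

```bash
# a small configuration for a seconds-scale demo
cat > quickstart.yaml <<'YAML'
seed: 5
synth: {n: 70, flip_noise: 0.0}
train: {epochs: 10, batch_size: 64}
pso: {n_particles: 8, n_iterations: 5}
evaluation: {test_fraction: 0.2, val_fraction: 0.15}
YAML

# 1. simulate a dataset: 70 molecules, half carrying a nitro motif
mifnn simulate --config quickstart.yaml --out run
# wrote 70 records to run/dataset.csv

# 2. train the extractor + PSO-SVM + calibration (~20 s on one CPU)
mifnn train --config quickstart.yaml --data run/dataset.csv --out run
# C*=34.8 g*=0.002358 val AUC=1.000 test AUC=1.000

# 3. score new molecules
printf 'id,smiles\nm1,CCO[N+](=O)[O-]\nm2,CCCC\n' > query.csv
mifnn predict --checkpoint run/extractor.npz --model run/svm_model.npz \
              --data query.csv --out scored.csv
cat scored.csv
# id,smiles,probability
# m1,CCO[N+](=O)[O-],0.6666296987052426
# m2,CCCC,0.04492799268020882
```

The noiseless 70-molecule toy task is perfectly separable, so validation and
test AUC are 1.0. The nitro-bearing query molecule scores 0.67 against 0.04
for the plain alkane — the calibrated probability is deliberately conservative
here because the sigmoid is fitted on a 10-molecule validation split with
smoothed targets. With label-flip noise the attainable AUC is capped at
roughly 1 − noise (the motif match is the Bayes-optimal classifier), which
the larger synthetic runs respect.

Defaults for every stage live in one YAML config (`mifnn <cmd> --config`);
`mifnn ablate` reruns the component-ablation table (single branches vs
fusion, SVM vs PSO-SVM, with/without the bi-LSTM) under shared splits.

The same pipeline is available as a library:

```python
from mifnn.cli import RunConfig, train_pipeline
from mifnn.synthetic import SynthConfig, generate

records = generate(SynthConfig(n=2000, flip_noise=0.1, seed=7))
result = train_pipeline(records, RunConfig(seed=7))
print(result.test_auc, result.C, result.g)
```

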
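# Methods

## The model

`mifnn` classifies small molecules as active/inactive from two complementary
views of the same structure, fused before classification.

**Directed-information branch (MDIFEN).** A molecule parsed from SMILES
becomes a graph with per-atom features *a_p* (element one-hot over
{C, N, O, S, F, Cl, Br, I, P, other}, heavy-atom degree 0–5 one-hot, formal
charge clipped to [−2, 2] one-hot, aromaticity flag; 22 dims) and per-bond
features *b_pq* (bond-order one-hot over {single, double, triple, aromatic},
ring flag, aromatic flag; 6 dims). A directed message-passing encoder places
a hidden state on every *directed* bond,

    c⁰_pq = ReLU(W_in · cat(a_p, b_pq))
    i^{s+1}_pq = Σ_{j ∈ N(p)\{q}} c^s_jp
    c^{s+1}_pq = ReLU(c⁰_pq + W_msg · i^{s+1}_pq)      (s = 0 … T−1)

— the reverse edge (q, p) is excluded from each incoming sum, so a message
never bounces straight back, and the skip connection re-injects the initial
edge state at every step. The readout sums edge states into their target
atoms, mixes with atom features, and sum-pools atoms:

    i_p = Σ_{j ∈ N(p)} c^T_jp,   c_p = ReLU(W_atom · cat(a_p, i_p)),
    DPI = Σ_p c_p ∈ R^300.

Sum-pooling makes the encoding invariant to atom relabeling and exactly
additive over disconnected components; both properties are tested. No bias
terms are used in the three linear maps. Updates are synchronous (all edges
read step-*s* states). Default depth T = 3.

The 300-vector is then treated as a length-300 sequence of scalars: each
position is lifted by a shared position-wise linear map to an 8-channel
embedding, convolved (1-D, kernel 5, 16 channels, SAME padding, ReLU),
mean-pooled with stride 2 to length 150, read by a bidirectional LSTM
(hidden 64 per direction; gates computed from the previous hidden state and
the current input, memory cell m_t = f_t⊙m_{t−1} + i_t⊙m̃_t, hidden state
c_t = o_t⊙tanh m_t), and pooled by soft attention: η_t = tanh(W_w c_t + β_w),
α_t = softmax_t(η_tᵀ η_w), s = Σ_t α_t c_t with a learned context vector
η_w. Branch output: 128 dims.

**Fingerprint branch (MFFEN).** A 2048-bit Morgan fingerprint (radius 2,
ECFP4-equivalent; computed by RDKit's Morgan generator) is reshaped row-major
to a 32×64 binary image (`matrix[r, c] = bits[64r + c]`; flatten is its exact
inverse) and passed through two blocks of [3×3 SAME conv → ReLU → 2×2 average
pool] with 16 then 32 channels (spatial sizes 32×64 → 16×32 → 8×16), a
row-major flatten, and a linear projection to 128 dims.

**Fusion and classification.** The branch outputs are concatenated (directed
branch first), passed through a fully connected ReLU layer (64 units) with
dropout 0.5 (training only; evaluation is deterministic). Training is
two-stage because the downstream SVM is not differentiable:

1. the whole extractor (encoder + both branches + FC) is trained end-to-end
   against an auxiliary sigmoid head with binary cross-entropy, Adam,
   learning rate 0.001;
2. the head is discarded, frozen 64-d features are extracted, and an RBF
   SVM is fitted on them. Particle-swarm optimization searches (C, g) in
   log₂ space over C ∈ [2⁻⁵, 2¹⁵], g ∈ [2⁻¹⁵, 2³]; particle fitness is the
   3-fold stratified-CV mean squared difference between predicted and true
   0/1 labels (the CV error rate), *minimized*. Velocities are clamped to
   half the box width, positions clipped to the box. The kernel is
   κ(x, x′) = exp(−‖x−x′‖²/2σ²) with g ≡ 1/(2σ²), i.e. the usual RBF gamma.
3. decision values are mapped to posterior probabilities with the
   two-parameter sigmoid P(y=1|f) = 1/(1 + exp(A·f + B)), fitted by damped
   Newton on the regularized likelihood (smoothed targets
   (N₊+1)/(N₊+2) and 1/(N₋+2)), on a held-out validation split to avoid
   optimistic calibration. The map is strictly monotone, so ROC-AUC is
   unchanged by calibration.

Evaluation is ROC-AUC: the curve over all distinct score thresholds,
trapezoid-rule area, tied positive–negative pairs credited ½ (equivalently
the normalized Mann–Whitney statistic).

## Numerical engine

No deep-learning framework is used; the extractor runs on a small in-package
reverse-mode autodiff engine over NumPy arrays (`mifnn.autodiff`).
Convolutions are fused im2col operations with hand-written backward passes;
the bi-LSTM hoists the input-to-gate projection out of the time loop;
gradients of slices scatter directly into lazily allocated buffers; interior
gradients are freed as backpropagation proceeds to bound peak memory.
Analytic gradients of every operation, and of the full MDIFEN branch, are
checked against central finite differences (relative tolerance 1e−4).

Arithmetic runs in float32 by default — the training workload is
memory-bandwidth-bound on a CPU — and can be switched to float64
(`autodiff.default_dtype`), which the tight numerical tests (encoder–oracle
agreement at 1e−6, closed-form identities at 1e−12) use.

Parameters are initialized from a seeded uniform distribution scaled by
1/√fan-in. Training is deterministic given the seed: one seed sequence fans
out to initialization, batch shuffling, and dropout streams. The CLI derives
per-stage seeds from one global seed through fixed spawn keys, so each stage
is independently reproducible from its manifest.

## Synthetic data

The generator assembles molecules by linear concatenation of 2–6 fragments
from a small pool ({CC, CCC, CCO, CCN, c1ccccc1, C(=O)O, CCS, CCCl});
a configurable fraction receives a nitro group ([N+](=O)[O−]) grafted at the
chain terminus, and the label equals motif presence XOR Bernoulli(flip_noise).
Assemblies that would violate valence (a halogen-terminated fragment extended
mid-chain) are redrawn, with labels fixed beforehand so the class balance is
exact. The Bayes-optimal classifier is the motif substructure match; its
expected AUC is capped by the flip noise (≈0.9 at flip 0.1), which gives
every downstream accuracy claim a known ceiling.

What this emulates: the file format, a binary activity signal carried by a
substructure, label noise, and controllable class imbalance
(`make_imbalanced`). What it does not: drug-likeness, scaffold diversity,
activity cliffs, assay batch effects, 3-D structure. Passing the end-to-end
tests shows the pipeline recovers a substructure-borne signal near its noise
ceiling and finds nothing after label permutation — not that it reaches any
particular AUC on real screening data.

## Problem sizes and defaults

Architecture defaults (encoder width 300, depth 3, LSTM hidden 64, branch
width 128, FC 64, dropout 0.5, learning rate 0.001, Adam, epochs 100, batch
32) are the package defaults. The test suite and acceptance script use
smaller optimization budgets chosen once: 4 epochs at batch 256 for the
n = 2000 signal-recovery runs (the fingerprint branch learns the motif within
a few epochs, and the SVM stage does the final discrimination), 7 epochs at
batch 128 with a narrower model (encoder 100, LSTM 32, branches 64) for the
n = 600 ablation table, and a swarm of 8 particles × 8 iterations (6 × 5 in
the ablation) instead of the default 20 × 30. The pipeline's split is
stratified: 20% test, 10% calibration/validation, the rest training.

## Design choices where the design was open

- **"Embedding layer" on a continuous vector** — interpreted as a shared
  position-wise linear lift of each scalar to `embed_dim` channels; there is
  no token vocabulary to embed.
- **Training signal for the extractor** — an auxiliary sigmoid/BCE head,
  discarded after training (stage 1 above); branches are trained jointly.
- **Dichotomization of multi-task labels** — any-active: label 1 if any task
  label is 1.
- **PSO fitness direction** — the fitness is a mean squared label difference
  and is minimized; swarm bookkeeping keeps the global best monotone.
- **Plain-SVM baseline in the ablation** — C = 1 with the "scale" gamma
  heuristic 1/(d·var X).
- **"No bi-LSTM" ablation variant** — the conv/pool output is mean-pooled
  over time and projected linearly, replacing the bi-LSTM + attention stage.
- **Tie handling in ROC** — half credit per tied positive–negative pair.
- **Morgan radius** — 2 (ECFP4-equivalent), exposed in config.

## Known limitations

- The extractor trains on CPU via the in-package engine; it is adequate for
  10³–10⁴ molecules, not for 10⁵-scale screens.
- Fitted SVMs are persisted as (training features, labels, C, g) and refitted
  on load; for very large training sets this trades load time for a simple,
  portable artifact.
- The PSO fitness (CV error rate) is a step function of (C, g); plateaus can
  make the swarm indifferent across wide regions, which is visible on easily
  separable data where many hyperparameters reach zero error.
- Calibration quality depends on the validation split size; with fewer than
  ~50 molecules the sigmoid parameters are noisy (the AUC is unaffected).
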
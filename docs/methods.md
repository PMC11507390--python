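# Methods

## Problem and data model

A candidate off-target site is an aligned sgRNA–DNA pair: a 20-nt
protospacer plus a 3-nt NGG PAM against a genomic sequence of the same
aligned length. Mismatched positions carry both bases; a single 1-bp
bulge (RNA bulge = unpaired guide base, DNA bulge = unpaired target base)
is written as `_` on the strand lacking the base, giving a 24-nt
alignment. The classification target is binary: was the site
experimentally validated as cleaved (positive) or not. Benchmarks in this
field are extremely imbalanced — the bundled manifest of published
datasets spans imbalance ratios (negatives per positive) from ~1.1 to
~7000 — which drives most of the design below.

## Encodings

**7-channel composite (24×7).** Channels 1–4 hold the OR of the two
bases' one-hot codes in the order A, T, G, C — one bit at a match, two at
a mismatch. Channel 5 flags a bulge; channels 6–7 disambiguate
direction: channel 6 is set when the guide base's channel index precedes
the DNA base's (and for RNA bulges), channel 7 for the converse (and DNA
bulges). 23-nt (bulge-free) pairs are padded to 24 with one all-zero
position inserted between the protospacer and the PAM, so the PAM always
occupies the last three rows. At a bulge the unpaired base's one-hot bit
is kept in channels 1–4; the pad row is entirely zero.

**16-channel one-hot (24×16).** One channel per ordered (guide, DNA)
base pair, guide-major blocks A, T, G, C with DNA order A, T, C, G inside
each block — AA is the first channel and CG the last. This scheme is a
bijection on base pairs (the OR composite is not: it cannot distinguish
A-G from G-A without the direction bits), which is what makes base-pair
attribution meaningful. It has no bulge code; bulge and pad rows are
all-zero, and the distillation pipeline therefore accepts mismatch-only
datasets.

## Classifier

Input (24 positions × 7 channels) → four parallel 1-D convolutions over
the position axis (kernel widths 1, 2, 3, 5; 10 filters each; ReLU;
"same" zero padding so position indexing survives to attribution),
concatenated to 40 channels → three stacked bidirectional GRUs of 30, 20
and 10 units, all returning per-position outputs (so the sequence axis is
preserved through the whole recurrent stack) → flatten → dense 128 →
dense 64 (ReLU, dropout 0.35 after each) → 2 sigmoid output neurons
scoring on- and off-target propensity. The off-target neuron (column 2)
is the score for ranking metrics; confusion metrics threshold it at 0.5.
Two ablation variants drop one extractor each: `no_inception` feeds the
raw encoding to the GRU stack, `no_bigru` flattens the convolution output
straight into the dense head.

The GRU uses the "reset-after" formulation with separate input and
recurrent biases (a bidirectional layer of `u` units over `i` channels
has `2·3·(u(u+i)+2u)` parameters; the default model has 96,684). Dense
and convolution weights are Glorot-uniform, recurrent matrices
orthogonal, biases zero. Everything — forward passes, backpropagation
through time, input gradients, Adam — is implemented in numpy; gradient
correctness is asserted against central differences in the test suite.

**Training.** Adam at learning rate 1e-4, 30 epochs, batch size 256.
Batches come from a balanced bootstrap: each batch holds exactly 128
positives and 128 negatives drawn with replacement within class, redrawn
every epoch; epoch length is `ceil(n/256)` batches. One integer seed
fans out (via `SeedSequence.spawn`) to weight initialisation, dropout and
the sampler, making runs bit-reproducible.

**Loss.** The default loss is soft dice on the off-target probability
column, symmetrised over the two classes:
`L = ½[dice(t, p) + dice(1−t, 1−p)]` with
`dice(t, p) = 1 − (2Σtp+ε)/(Σt+Σp+ε)`, ε = 1e-6. The symmetrisation is
load-bearing: the one-sided dice admits a degenerate minimum at all-ones
predictions (the overlap is complete and the denominator merely doubles),
and gradient descent from a sigmoid initialisation reliably reaches it
and then freezes in saturation — observed directly during development.
The complement term removes that attractor while keeping the
batch-overlap character that makes dice robust to imbalance. Tversky is
symmetrised the same way; focal (γ=2, α=0.25), asymmetric (γ+=1, γ−=4,
margin 0.05), hinge (±1 labels, scores 2p−1) and cross-entropy use their
standard one-sided forms. With the overlap losses only the off-target
neuron receives gradient; the on-target neuron stays near its
initialisation and is not used for scoring.

## Evaluation

Precision, recall, F1 and the Matthews correlation coefficient are
computed from explicit confusion counts; degenerate denominators return 0
with a `degenerate` flag instead of NaN. AUROC and PRAUC come from
scikit-learn; PRAUC is the step-wise (non-interpolated) integral, the
honest choice at high imbalance where linear PR interpolation is
optimistic. Split protocols: stratified 85/15 holdout, stratified
five-fold CV, and leave-one-sgRNA-out (one fold per distinct guide id;
stratification is impossible there by construction). Stratification is
used because at imbalance ratios in the hundreds an unstratified fold can
easily contain no positives at all.

## Knowledge distillation

The trained classifier (teacher, 7-channel input) is distilled into a
student roughly 5–6× smaller — one width-3 convolution (10 filters), a
single BiGRU of 10 units, dense 32 — reading the 16-channel encoding.
The student minimises `L_KD = α·SL + (1−α)·DL`, α = 0.2: SL is the
symmetrised dice against the hard labels, DL the cross-entropy between
the teacher's off-target probability (optionally temperature-scaled on
the logit scale; T = 1 by default) and the student's. With α = 1 the
teacher term vanishes exactly and the distilled student is
bit-identical to a plainly trained one from the same seed — the control
used in the direction-of-effect study. The student trains at learning
rate 1e-3: the small network needs (and tolerates) a larger Adam step to
converge within the same epoch budget; the 1e-4 default applies to the
teacher.

Distillation helps precisely when the student's hard-label data is
scarce relative to the teacher's knowledge. The packaged study therefore
trains the teacher on the full 85% split of 2,000 pairs and both
students on a 600-record subset of it: in that regime the distilled
student's held-out MCC exceeds the control's (when both students see
everything the teacher saw, both reach the data's ceiling and the soft
labels have nothing to add — measured during development and the reason
this protocol was chosen).

## Attribution

Attribution uses expected gradients, an additive attribution method in
the Deep SHAP family: φ(x) = E over backgrounds b and path positions
α∼U(0,1) of (x−b)⊙∇f(b+α(x−b)), toward the off-target output neuron.
The path integral uses a midpoint rule (24 steps by default; the
additivity probe uses 48), and every explained input is integrated
against every background row, so per-sample attributions satisfy the
completeness identity Σφ ≈ f(x) − E[f(b)] to ~1e-3. The background is a
seeded random draw of 100 training records (60 in the packaged study);
the explained subset is all positives plus an equal-count seeded random
draw of negatives.

Maps are per-cell means over the explained subset, then z-scored over
the cells active in that subset. The two schemes aggregate differently,
and the difference matters:

* **position × 7-channel maps** use the plain mean — the composite
  channels are dense, and the mean ranks positions consistently with
  planted ground-truth weights (Spearman ≥ 0.8 in the recovery study);
* **position × 16-channel base-pair maps** average each record's
  attribution only over the cells that record actually sets. With strict
  one-hot channels, a base pair that raises the score when present
  necessarily lowers it (relative to background) in every record lacking
  it, so the unmasked mean cancels — and can even invert — exactly the
  cells of interest; masking to active cells recovers the planted
  mismatch cell as the top-ranked entry.

Base-pair maps export as long tables labelled `X-Y:p` (guide base X, DNA
base Y, protospacer position p, 1 = PAM-distal).

## Synthetic data generator

The generator emulates the structure, not the sequence statistics, of
published benchmarks: random 20-nt guides with NGG PAMs, per-pair
mismatch counts from a truncated geometric distribution on 1..6 (success
0.45, matching the empirical dominance of few-mismatch sites), mismatch
positions uniform, optionally one 1-bp bulge (RNA or DNA with equal
probability). Activity follows the planted rule
`s = exp(−Σ w_p·mismatch_p − penalty)`; the default weights rise
strictly from 0.3 (PAM-distal) to 2.5 (position 20) with a power-1.5
ramp, so a single seed-region mismatch suppresses activity ~12-fold —
consistent with the seed region dominating Cas9 specificity — and every
position has a distinct weight, giving recovery tests a tie-free
ranking. A bulge at protospacer position p adds `1.5·(p/20)` to the
penalty (PAM-proximal bulges are least active).

Labels are Bernoulli draws through a logistic link on log-activity with
steepness 12, whose offset is calibrated by bisection so the expected
positive count matches the requested imbalance ratio; the most marginal
draws are then topped up or trimmed so the realised count is exact.
A plain proportional link (label probability ∝ s) was rejected during
design: it spreads label probability so thinly that the Bayes-optimal
AUROC of the generated data caps near 0.7–0.9 under any realistic weight
scale, making the data unlearnable to the standard the planted rule is
meant to support. Afterwards a symmetric noise step (default 1%) swaps
an equal number of positives down and negatives up, perturbing labels
without moving the class balance. Under the defaults the construction's
Bayes-optimal AUROC is ≈0.97 and the full model reaches ≈0.97 on a
held-out split.

What the generator does **not** model: genomic sequence composition (GC
content, repeat context), guide-specific activity differences,
experimental assay noise structure, alternative PAMs, multi-bp indels.
Passing tests therefore demonstrate that the pipeline learns and
explains planted position-weighted mismatch rules — not that it attains
any particular accuracy on real genomes.

## Problem sizes and numerical choices

The packaged studies use 2,000 pairs at imbalance ratio 10 (10 guides ×
200 pairs) for the learning-signal and ablation studies (30 epochs, 5
seeds for means), 1,500 pairs for the attribution study (25 epochs), and
the 600-record student subset described above for distillation. Dice
smoothing ε = 1e-6; logarithms clipped at 1e-7; decision threshold 0.5;
ties in AUROC handled by the rank statistic (trapezoidal over grouped
thresholds). Degenerate metric denominators return 0 with a flag. Empty
prediction batches return an empty (0×2) matrix. Validation rejects
pairs with gaps on both strands, aligned lengths outside {23, 24}, more
than one bulge, or a target PAM not ending in GG.

## Known limitations

* The planted rule weights mismatch positions independently, so it
  contains no multi-position motif structure for the multi-scale
  convolution front end to exploit: on this synthetic data the
  no-convolution ablation matches or slightly beats the full model,
  while removing the BiGRU stack costs a large margin. The architecture
  ablation on synthetic data therefore informs about the recurrent
  stack, not about the convolution branches, whose value rests on real
  sequence context the generator does not model (the corresponding
  ablation-ordering test documents this by failing its first
  inequality).
* The on-target output neuron is untrained under the overlap losses;
  only the off-target column is meaningful.
* The 16-channel scheme (and hence distillation and base-pair maps) is
  defined for mismatch-only data.
* Expected gradients approximates Shapley values under feature
  independence along straight-line paths; with strongly correlated
  one-hot channels the per-cell values are rank-reliable (the recovery
  tests check exactly this) but not unique attributions.
* Position-rank recovery is seed-variable: the planted weight ramp is
  nearly flat over the PAM-distal third, where adjacent weights differ
  by a few percent in activity and their relative ranking is close to
  unidentifiable from 2,000 labelled pairs. Across training seeds the
  Spearman correlation with the planted ranking spans roughly 0.6-0.86;
  the packaged study reports the value at its fixed seed, and the heavy
  (seed-region) positions rank on top throughout.
* Training is CPU-bound numpy; problem sizes in the hundreds of
  thousands of records are out of intended scope.
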
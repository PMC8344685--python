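# Methods

## Problem and model

`acpfuse` is a binary classifier for anticancer peptides (ACPs). Each
peptide — a string over the 20 standard amino-acid letters — is viewed
two ways and the views are fused.

**Integer encoding.** Residues map bijectively to codes 1–20; 0 is the
padding symbol. The letter order is alphabetical (A=1 … Y=20); because
the codes feed a trainable embedding, the particular permutation cannot
affect what is learnable, but it is fixed and exposed
(`acpfuse.encoding.AlphabetMap`) so that matrices are reproducible and an
alternative mapping can be substituted. Sequences are right-padded to
`max_len = 210`, comfortably above typical therapeutic-peptide lengths;
a longer input is an error rather than a silent truncation, since
truncation would score a different molecule. Padding is not masked: the
embedding learns a representation for code 0, which the training signal
quickly drives toward irrelevance.

**Descriptors.** Three classical composition families:

* AAC, `f(a) = N(a)/L`, 20 features, alphabetical order;
* DPC, `D(r,s) = N_rs/(L−1)`, 400 features, row-major alphabetical order;
* CKSAAGP over the five physicochemical groups G1 = {G,A,V,L,M,I}
  (aliphatic), G2 = {F,Y,W} (aromatic), G3 = {K,R,H} (positive),
  G4 = {D,E} (negative), G5 = {S,T,C,P,N,Q} (uncharged): for each gap
  k = 0…5 the 25 ordered group-pair frequencies with denominator
  `L − k − 1`, gap-major order, names like `G3XXG1` (each `X` one
  intervening residue). 150 features.

Each AAC/DPC vector and each CKSAAGP k-block is a probability vector
(sums to 1) whenever its denominator is positive. A sequence shorter than
`kmax + 2` is an error by default because the k=kmax denominator is
undefined; a permissive mode emits all-zero blocks instead for corpora
with very short peptides.

**Network.** The CNN channel embeds the 21 symbols in 32 dimensions
(width chosen as a conventional small-vocabulary default and
config-exposed), applies a valid-mode 1-D convolution (32 filters, kernel
16, ReLU), non-overlapping max pooling (window 8, stride 8 — the common
default), and a 64-unit ReLU dense layer. The handcrafted channel applies
dense 128 → dropout 0.2 → dense 64 to the descriptor vector. The fusion
head concatenates the two 64-d channel outputs (single-channel variants
skip the concatenation) and applies dense 64 → one sigmoid unit. The
decision rule is strict: probability > 0.5 calls ACP. Two-layer
convolution variants ("32-64", "64-128") stack a second convolution with
the same kernel width before pooling.

The stack is implemented directly in NumPy (`acpfuse._network`):
trainable embedding, im2col convolution, pooling with cached argmaxes,
dense layers, inverted dropout, Adam, and a numerically stable
sigmoid/binary-cross-entropy head. At this problem size (hundreds of
peptides, tens of thousands of parameters) CPU NumPy trains a fold in
seconds, and keeping the graph explicit makes seeded runs exactly
reproducible.

## Training

Binary cross-entropy, Adam at learning rate 1e-3, batch 32, up to 100
epochs. A 10% random validation split drives early stopping (patience 10,
best-validation weights restored); when the split would be degenerate
(< 4 samples or one class), the full epoch budget runs against the
training loss. Optimiser, rate, batch size and epoch budget are
conventional choices for data of this scale and are all config-exposed.
All randomness — initialisation, splits, shuffling, dropout — flows from
the single config seed, so a run is bit-reproducible on one machine.

## Evaluation

SE = TP/(TP+FN), SP = TN/(TN+FP), ACC = (TP+TN)/total and
MCC = (TP·TN − FP·FN)/√((TP+FN)(TP+FP)(TN+FN)(TN+FP)) are computed from
the thresholded confusion counts; AUC from the score ranking
(scikit-learn ROC). Conventions for degenerate inputs: SE/SP with an
empty denominator and AUC on one-class data are NaN with a warning; an
MCC with a zero denominator is 0 with a warning (common practice for an
undefined formula).

Cross-validation is stratified with a fixed seed — the benchmark-style
training sets are small and balanced, so stratification controls fold
variance — training one fresh model per fold (fold seeds derived
deterministically from the run seed). Fold-mean metrics with standard
deviations are the primary aggregate; pooled-prediction metrics are also
emitted. The ablation harness (filter grid, seven-way channel
comparison) forces one shared fold assignment across rows so comparisons
are paired. Emitted tables round to two decimals; JSON output keeps full
precision.

## Composition contrasts

Per-feature class differences use a two-sided Mann–Whitney rank test by
default — composition fractions are bounded and zero-inflated, so a rank
test is the safer generic choice — with Welch's t-test switchable.
Features with p < 0.01 are counted without multiple-testing correction,
matching how such counts are usually reported in this literature; a
Benjamini–Hochberg mode exists but is off by default. A feature constant
in both classes gets p = 1 (no evidence of difference).

## Synthetic data

The generator draws residues i.i.d. from a background composition
(uniform by default) multiplicatively tilted toward a class-specific
letter set — weight `1 + effect_size` on enriched letters, renormalised —
with positives enriched in A, F, K, L, W and negatives in D, E, N, Q, S,
mirroring the compositional signature reported for real ACP benchmarks.
Lengths are uniform on 10–50 residues, well under the padding cap and
above the CKSAAGP minimum. Defaults are 250+250 peptides with
`effect_size = 3` (enriched letters 4× the background weight, a strong,
clearly learnable shift); motif mode plants a short positive-specific
k-mer (`KLAK`, a canonical amphipathic cationic motif) in 90% of
positives, giving the CNN channel order information composition
descriptors cannot fully capture — the property that motivates fusion.

What the generator does **not** emulate: real peptide length
distributions, residue autocorrelation, secondary-structure or charge
periodicity, homology between train and test sequences, and realistic
class overlap. Passing tests therefore demonstrate that the pipeline is
correct and can learn planted structure at desk scale, not that the
model attains any particular accuracy on real ACP corpora; the
benchmark-reproduction script exists for the latter.

## Problem sizes used by the checks

The test suite and `scripts/acceptance.py` run entirely on generated
data: the headline cross-validation uses the full study conditions
(250+250, 10 folds, effect 3, motif on) plus a label-shuffled null; the
ablation harness is exercised at 120 peptides with 5 folds and a
shortened epoch budget, sizes at which every configuration still
separates the classes decisively. Descriptor implementations are checked
against naive-loop reference implementations to 1e-12, and the metric
suite against enumeration oracles (brute-force confusion counting and
the Mann–Whitney pairwise-ordering identity for AUC).

## Known limitations

* Non-standard residues (B, J, O, U, X, Z, gaps) are rejected or skipped,
  never imputed; every formula here is defined only over the 20 letters.
* The per-feature tests in the composition contrast are not independent
  (descriptor entries share denominators), so the uncorrected
  significant-feature count is descriptive, not inferential.
* Training is single-threaded NumPy; at corpus scales far beyond ~10^4
  peptides a GPU framework would be the right tool.
* Early stopping monitors an unstratified validation split; on very small
  or very imbalanced datasets the split can be noisy (it then falls back
  to the training loss).
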
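# Methods

## Model

`structgo` treats GO annotation within one namespace as hierarchical
multi-label classification solved as a *single* structured prediction.  A
protein x is mapped to a label y — the ancestor-closed set of non-root GO
terms — by maximizing a compatibility function over a candidate space Y:

    h(x) = argmax_{y ∈ Y} f(x, y).

f is linear in a joint input–output feature space, f(x,y) = wᵀψ(x,y), and
is learned with the margin-rescaling structured SVM: every alternative
label y ≠ yᵢ must be separated from the true label by a margin equal to
its loss Δ(y, yᵢ), softened by one slack ξᵢ per example, with the
objective ½‖w‖² + (C/n)Σξᵢ.

All computation happens in the dual, where only kernels appear.  The joint
kernel factorizes as K((x₁,y₁),(x₂,y₂)) = K_X(x₁,x₂)·K_Y(y₁,y₂): two
example–label pairs are similar when they are similar in *both* spaces.
The output kernel is linear between indicator vectors, K_Y(y₁,y₂) =
|y₁ ∩ y₂|, and the loss is the kernel F1 loss

    Δ(y, ŷ) = 1 − 2 K_Y(y,ŷ) / (K_Y(y,y) + K_Y(ŷ,ŷ)),

which for this kernel equals 1 − F1(y, ŷ).  With dual coefficients α_{iy}
the compatibility expands to

    f(x, y) = Σ_{(i,y′)} α_{iy′} · K_X(xᵢ, x) · (K_Y(yᵢ, y) − K_Y(y′, y)),

so the primal w is never materialized.

**Candidate space.** Y is the set of distinct label sets observed in
training.  This makes the argmax exact and cheap, concentrates predictions
on term combinations that co-occur biologically, and guarantees every
prediction is hierarchically consistent by construction.  The empty label
participates only if it occurs in training.

**Assumptions.** (i) Functionally similar proteins are similar under at
least one input kernel; (ii) plausible annotation sets are well covered by
the training labels; (iii) normalized kernels from different sources are
comparable enough that unweighted summation and unweighted view
combination are sensible.

## Input kernels

Each data source becomes a kernel over proteins: feature tables through a
linear kernel, or a precomputed kernel matrix read as-is.  Every source
kernel is cosine-normalized, K′(a,b) = K(a,b)/√(K(a,a)K(b,b)), so its
diagonal is 1 and sources with different scales contribute comparably; the
sources of a view are then combined by *unweighted summation* and the sum
is deliberately not renormalized (a flag exists for experimentation).
Proteins missing from one source keep all-zero feature rows — their kernel
row is zero rather than the protein being dropped, so the id universe
stays aligned across sources.  Zero-diagonal proteins normalize to zero
rows, never NaN.

Sequence-derived features for the cross-species view:

* **BLAST profile** — one feature per database protein: e-values above
  50.0 are discarded, the rest are divided by 50.0, floored at 1e-10 and
  −log₁₀-transformed, giving features in [0, 10] (base 10 so a feature
  unit is an order of magnitude of e-value).  An e-value of exactly 50.0
  is kept (feature 0).  Self-hits are kept.
* **Termini 3-mers** — 3-mer counts over the first and last 10 residues
  (two separate blocks); shorter sequences use the whole sequence.
* **Low-complexity window** — residue composition of the length-20 window
  with the fewest distinct residues, leftmost on ties.
* **Count indicators** — one-hot encodings of externally predicted counts
  (e.g. transmembrane domains); counts above the bin limit collapse into
  the last bin.  External predictors themselves (BLAST, TMHMM, WoLF
  PSORT) are not run; their tabular outputs are ingested.

For genes with multiple isoforms the longest sequence is used, ties broken
by the lexicographically smallest identifier.

## Training

The dual QP — maximize Σ α_{iy} Δ(y,yᵢ) − ½ αᵀJα subject to α ≥ 0 and
Σ_y α_{iy} ≤ C/n per example, with J the joint-kernel Gram of constraint
differences — is solved over a growing working set:

1. for each example, find the loss-augmented argmax
   ŷ = argmax_{y≠yᵢ} Δ(y,yᵢ) + f(xᵢ,y) by exhaustive scan over Y;
2. add (i, ŷ) when its violation Δ(ŷ,yᵢ) − (f(xᵢ,yᵢ) − f(xᵢ,ŷ)) exceeds
   the example's current slack ξᵢ by more than ε (default 1e-4);
3. re-solve the restricted QP warm-started from the previous coefficients;
4. stop when a full pass adds nothing, i.e. no outside constraint is
   violated more than the working set already allows, up to ε.

The per-example slack comparison (rather than a global one) is the
standard working-set rule for this formulation.  The restricted QP is
solved by cyclic coordinate ascent plus SMO-style pairwise transfers
within each example's coefficient group; the pairwise moves are required
because the per-example cap couples the group's coordinates (a group at
its cap can only improve by shifting mass between constraints).  Sweeps
stop when the largest coefficient move falls below 1e-10; near-zero Gram
diagonals receive a 1e-10 jitter.  The dual objective is recorded after
every solve and is non-decreasing; on small problems the working-set path
reproduces the full-enumeration optimum to ~1e-12 (asserted at 1e-6 in
tests).

**Defaults.** C/n = 1 (the empirically best operating point for this
model family; exposed as `c_over_n`), ε = 1e-4, pass cap 1000 (a warning
and the best-so-far model on overflow).  Coefficients below 1e-12 are
pruned from the compatibility expansion but stay in the working set.  One
model per namespace; no parameter sharing.

**Tie-breaking.** The dual optimum determines f uniquely, but distinct
candidates can tie exactly in f; different optimization paths then perturb
the tie at the ~1e-11 level.  Prediction argmax therefore picks the
earliest candidate whose score is within 1e-9 of the maximum, which makes
predictions identical across solvers and reproducible under candidate
reordering of equal-scoring labels.

## Multi-view and chain combination

Two views are trained independently — a cross-species view (sequence
features, comparable across organisms) and a species-specific view (PPI,
expression, co-mention kernels).  The **multi-view** prediction is
argmax_y f⁽ᶜ⁾(x,y) + f⁽ˢ⁾(x,y); compatibilities are summed raw, with no
per-view weighting (kernel normalization already provides rough scale
comparability).  A protein present in only one view falls back to that
view's compatibility with a logged warning.

The **chain** classifier instead converts the cross-view prediction of
every protein into a binary indicator feature vector over GO terms; the
normalized linear kernel of that table is summed into the
species-specific view like any other source, and the species-specific
prediction is final.  Chain features for training proteins come from the
cross model applied to its own training data (the simplest reading; an
inner-CV variant to de-bias them is a possible extension, off by default).

## Confidence scores and evaluation

Because the classifier scores whole labels, per-term confidences are
compatibility gaps cᵢ(x) = max_{y∋i} f(x,y) − max_{y∌i} f(x,y) computed
over the candidate space via a term → candidate-positions index.  When the
argmax is unique, cᵢ > 0 exactly for the predicted label's terms.  Terms
contained in every candidate, or in none, are unscorable and are excluded
from per-term evaluation rather than given 0.

Per term: ROC AUC (Mann–Whitney with half-credit ties, via
scikit-learn) and precision at 20 % recall — the precision at the first
descending score threshold whose recall reaches 0.2, tied scores entering
together, no interpolation.  Macro averages are unweighted over scorable
terms; AUC is also aggregated by term depth, defined as the *longest*
path to the namespace root.  Terms single-class in the evaluated set are
skipped per fold and reported.

Cross-validation assigns whole sequence-identity clusters (supplied
directly or as single-linkage components of a pairwise-identity table at
the 50 % threshold) to folds, largest-first onto the smallest fold after a
seeded shuffle, so no cluster spans folds.  Pairwise identity itself is
not computed here (it requires alignment; the tool producing it is the
caller's choice).  Nested 4-fold selection of C/n picks the grid value
with the highest inner macro AUC, ties to the smaller value.

## Synthetic benchmark

The generator builds a single-namespace random rooted DAG (each non-root
term has 1–2 parents among earlier terms), draws a fixed number of
distinct consistent labels (random term picks, ancestor-closed), assigns
one label per protein, and emits per-view feature tables: a protein's
features are the sum of its label's per-term prototype vectors (standard
normal, scaled by 1/√|label| to keep row norms comparable) plus Gaussian
noise of σ = 0.5; per view, a corrupted protein subset is replaced by
pure standard-normal noise.  With `complementary=True` the corrupted
subsets are disjoint across views, so the summed compatibility can
recover every protein from at least one clean view — the property that
makes multi-view combination beat each single view on this benchmark.

Defaults (120 proteins, 15 terms, 6 distinct labels, two 20-dimensional
views, 30 % corruption each) are chosen to be solvable but non-trivial:
single views plateau well below the multi-view combination.  The
generator is deterministic given its seed, and writes the same OBO/TSV
dialects the readers consume, so tests exercise the real I/O paths.

What the benchmark does *not* emulate: realistic GO term-frequency and
depth distributions, PPI network topology, BLAST e-value statistics,
correlated noise between views, multi-label proteins beyond a single
candidate set, and real annotation sparsity.  Passing tests therefore
demonstrate correctness of the machinery and the *relative* behaviour of
view combination under complementary noise, not absolute performance on
real proteomes.

## Numerical choices and limitations

* Kernels are stored dense; the intended scale (≲ 10⁴ proteins per view)
  fits memory comfortably.
* Kernel symmetry is validated at 1e-9; summed-kernel PSD-ness is a
  consequence of construction, not re-checked at runtime.
* The loss of two empty labels is defined as 0 (they are identical); one
  empty label against a non-empty one has loss 1.
* `evaluate` treats NaN score cells as "not scored" for that term
  (pooled cross-validation tables may differ in scorable terms per fold).
* Exhaustive argmax over Y is linear in |Y| per protein; output spaces
  with very many distinct training labels make training and inference
  proportionally slower.
* Approximate inference over the unconstrained label space and learned
  kernel/view weights are deliberately out of scope.
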
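# Methods

## Collective factorization model

The model couples one feedforward autoencoder per entity type. For entity
e, the concatenated matrix C^(e) stacks, column-wise, every view touching
e (transposed where e indexes the columns; a square self-view contributes
exactly one block, as-is). Blocks are ordered by the view's position in
the collection, which makes concatenation deterministic — any fixed order
is equivalent for learning. The encoder is a single affine layer to the
bottleneck with tanh activation by default (a linear mode exists for
exact-recovery experiments); the decoder is a single linear layer back to
the input width. Deeper stacks are available through `hidden_sizes`.

Losses are element-mean squared errors: l_E between C^(e) and its
decoding, l_R between each view X_m and U_{r_m} U_{c_m}ᵀ. Normalizing
every term by its element count keeps large views from dominating the
objective — the views in this setting differ by orders of magnitude in
size. The weighted total is w_E·Σl_E + w_R·Σl_R + w_T·l_T with weights
(1, 1, 1) by default. For a square self-view (e.g. a concept–concept
similarity matrix) the reconstruction is U_e U_eᵀ, and its gradient is
(G + Gᵀ)U_e.

The supervised variant attaches one affine layer with a task-dependent
output (sigmoid + binary cross-entropy, softmax + cross-entropy, or
linear + MSE) to the bottleneck of the labelled entity. When a
`labeled_mask` is supplied, only masked rows contribute to l_T while all
rows still participate in the reconstruction terms — the usual protocol
when test rows' inputs are available but their labels are held out. The
head is initialized from a stream independent of the encoder stream, so a
supervised model with w_T = 0 follows the unsupervised training
trajectory bit for bit under a shared seed.

Training is full-batch: one Adam step per epoch over the gradient of the
joint objective across all networks simultaneously. Full batches avoid
the sub-sampling bias that mini-batching over entity instances would
introduce into l_R (both sides of each view appear in every term), and
the desk-scale problems here fit comfortably in memory. Parameters are
initialized uniform in ±1/√fan-in from a seeded generator; runs are
reproducible across processes. The configured default learning rate is
1e-5 with weight decay 1e-6 — appropriate for large cohort-scale
matrices; the experiment harness and the tests use rates around 5e-3
sized to the synthetic problem scale. Multiclass labels are treated as
single-label multiclass (softmax + cross-entropy): diagnosis-category
style labels are mutually exclusive even when the task is described as
multilabel.

Implementation note: the autoencoders, the task head, the denoising
autoencoder baseline, and the Adam/RMSprop update rules are implemented
directly in numpy with explicit backpropagation (`_nn.py`); the model is
small enough that this is both fast and exactly reproducible.

## GRA similarity

For nodes i, j of an undirected graph, each connecting path of length l
contributes 1/Π k(i_t) over its intermediate nodes, damping paths through
high-degree hubs, and contributions are weighted by β^l. Defaults:
β = 0.5, horizon L = 3. The exponential-decay constant and horizon are
exposed because dense clinical graphs make longer horizons explosive;
β = 0.5 matches the convention of path-counting similarity kernels and
satisfies the requirement that shorter paths dominate.

`simple_path` mode (default) enumerates simple paths exactly with a
bounded DFS that accumulates scores to every reachable target in one
traversal; neighbor iteration is sorted so float accumulation order — and
therefore every downstream computation — is identical across processes.
`walk` mode evaluates the truncated series Σ β^l A(D⁻¹A)^(l−1), a
superset of simple paths (entry-wise ≥ at equal parameters) that scales
to large graphs; it is an approximation of the path formulation, not an
alternative definition. A brute-force oracle (`gra_bruteforce`, networkx
path enumeration, guarded at 12 nodes) provides the independent check.

Degrees are counted on the full heterogeneous graph and intermediate
nodes of any type are allowed, so e.g. disease–disease similarity can flow
through a shared medication. The diagonal of a similarity matrix is 0 by
definition (similarity of distinct nodes); when a matrix is destined for
factorization the `rowmax` diagonal option should be used instead — a
zero diagonal otherwise drives the squared-loss Gram fit U_e U_eᵀ ≈ S
toward zero-norm factors.

## Triplet filtering and graph construction

Filtering drops, in order: excluded predicates (defaults PART_OF,
LOCATION_OF, PROCESS_OF — ontological relations not directly clinical),
predicates beginning with the negation prefix NEG (matched on the
upper-cased name), and triplets whose subject or object lies outside the
study vocabulary. Each removal is tallied under the first rule it
violates and the filter is idempotent. Surviving triplets become
undirected edges; parallel assertions between the same pair collapse to
one edge (edges record existence of a relation, not its type), and
self-relations are dropped. Similarity-matrix rows are aligned to
patient-view columns by concept id; concepts absent from the graph keep
zero rows so the square view's dimension matches the patient view.

## Concept matrices and TF-IDF

Disease views are binary (presence of the concept in the episode's
notes); medication, procedure and lab views are counts. TF-IDF treats
each episode as a document and each concept as a term; the default is raw
term frequency times smoothed idf, ln((1+N)/(1+df)) + 1 — the dominant
convention in standard text-vectorization tooling — with plain-idf and
log-tf variants selectable. TF-IDF is applied to all notes-derived views
including the binary disease view (switchable); structured lab and
prescription views are used raw.

## Synthetic data

The generator plants ground truth and returns it alongside every output.
Entity factors U*_e are standard normal, d_e × k*; each view is
U*_r U*_cᵀ plus Gaussian noise, then transformed per value kind: binary
views threshold at a quantile (default the median), count views use
shifted exponentiation and rounding, max(round(exp(0.5·x)) − 1, 0),
giving realistic over-dispersion. Knowledge-graph edges are sampled with
probability floor + (1−floor)·σ(steepness·(cos(U*_u, U*_v) − τ)),
τ = 0.6, steepness 8, floor 0.01, so graph structure genuinely encodes
the planted concept geometry; a small fraction of emitted triplets carry
NEG or excluded predicates to exercise the filter. Labels follow a
logistic model on the patient factors (binary by default, balanced; an
intercept knob produces imbalanced mortality-style label ratios of order
12% positive when wanted), and a Monte-Carlo Bayes-rate reference is
returned with them. Component streams (factors, views, KG, labels) are
seeded independently, so changing the KG seed leaves the views unchanged.

Default study conditions: 500 patients, 50/40/40 disease/medication/
procedure concepts, 25 labs, true rank k* = 3, observation noise
σ = 2.0. The noise level is deliberately high: notes-derived concept
matrices are weak, indirect measurements of patient state, and the
interesting regime for auxiliary knowledge is the one where the
data-driven views only partially determine the latent factors (a linear
probe recovers the planted patient factors at R² ≈ 0.76 at these
settings, not ≈ 1). What the generator does not emulate: realistic text,
temporal structure, missingness, or any dependence of labels on
information outside the planted factors — so passing tests demonstrate
the mechanics and the relative behavior of the methods under the planted
model, not clinical performance.

The three bundle levels mirror a cumulative study design: level 1 the
TF-IDF'd notes-style views, level 2 adds one GRA similarity view per
concept type from the simulated KG (with `rowmax` diagonals), level 3
adds the structured lab and prescription count views.

## Evaluation harness

Repeated random 90/10 train/test splits (3 repeats by default), metrics
averaged over repeats: accuracy, macro-F1 (unweighted mean of per-class
F1 over classes present in the truth), weighted-F1 (support-weighted),
and AUC for binary tasks, computed by scikit-learn behind a narrow
interface. Unsupervised arms learn representations on all instances and
train the downstream classifier (logistic regression or random forest,
library defaults, fixed seeds) on the train split only — a deliberately
transductive protocol. The supervised arm refits per repeat with labels
masked to the train rows and predicts the test rows through its head.
The denoising-autoencoder baseline (single sigmoid-encoding hidden
layer, linear decoding, RMSprop, batch 32, 0.4 corruption, 20 epochs,
embedding 300 by default) applies only to the single concatenated patient
matrix of level 1 — it has no mechanism for absorbing the square
knowledge-graph views. The nonneural CMF arm is a minimal alternating-
least-squares collective factorization with ridge regularization,
written here as a self-contained baseline.

The harness's model defaults (latent_dim = 4, learning rate 5e-3, weight
decay 1e-4, 2000 epochs, task weight 0.25) put the latent budget close to
the generator's intrinsic dimensionality. This scarcity is intentional:
with ample capacity the reconstruction objective alone retains everything
the views contain, and neither label supervision nor auxiliary similarity
views have anything left to add — the comparisons between arms collapse
into ties. With a scarce budget the unsupervised factors must choose what
to keep, which is precisely where end-to-end supervision and
knowledge-graph augmentation earn measurable gains; the gains grow as the
budget shrinks further (at latent_dim = 2 the level-2 augmentation gain
reaches ~10 accuracy points on the default bundles).

## Numerical choices and degenerate inputs

MSE terms are means, so loss magnitudes are comparable across views;
training aborts with a diagnostic naming the epoch and the worst term if
the loss goes non-finite. Softmax is computed with max-subtraction;
sigmoid in a numerically symmetric form; cross-entropy with a 1e-12
floor. `epochs=0` returns the untrained model (empty history, factors
under initial parameters). Empty target sets, entities in no view, width
mismatches, and invalid model/view/classifier combinations raise typed
errors early. A constant-score binary classifier yields AUC 0.5 under
the rank-statistic tie convention.

## Known limitations

Missing-data masks, tensor views, and time-indexed views are out of
scope. The walk-mode similarity is an approximation of the path
formulation and is flagged as such. Full-batch training bounds the
practical cohort size to what fits in memory (tens of thousands of rows).
Hyperparameter selection is explicit configuration plus an optional
seeded random-search helper; no automatic scheduler is provided.
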
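# dcmflearn

Deep collective matrix factorization (DCMF) for learning shared entity
representations from arbitrary collections of relational matrices, with a
path-based knowledge-graph similarity engine so that literature-derived
graph structure can be injected as additional views.

The package targets the setting common in clinical informatics: a patient
cohort is described by several heterogeneous matrices (binary disease
mentions, medication and procedure counts from notes, structured lab and
prescription tables), and auxiliary knowledge about the clinical concepts
themselves is available as subject–predicate–object triplets from a
literature-derived knowledge graph. All of it can be factorized
*collectively* to produce one low-dimensional representation per entity
type — patients, diseases, medications, procedures, labs — usable as
features for downstream prediction, or trained end-to-end against labels.

## The model

Given M matrices X_m relating E entity types (entity e has d_e instances),
each entity receives a *concatenated matrix* C^(e): every view containing e
as its row entity contributes as-is, every view containing e as its column
entity contributes transposed. One autoencoder per entity encodes
U_e = f_θ(C^(e)) (the bottleneck, d_e × k) and decodes C^(e)′. All E
autoencoders are trained together on the joint objective

    L = w_E Σ_e l_E(C^(e), C^(e)′) + w_R Σ_m l_R(X_m, U_{r_m} U_{c_m}ᵀ)
        [+ w_T l_T(y_T, y′)]

with mean-squared-error reconstruction terms, so each view is approximated
by the product of its row- and column-entity factors. The optional task
term attaches a single prediction layer to the bottleneck of one designated
entity (sigmoid/cross-entropy for binary labels, softmax for multiclass,
linear/MSE for regression), turning the factorization into an end-to-end
supervised model.

Knowledge-graph triplets are filtered (ontological predicates such as
PART_OF/LOCATION_OF/PROCESS_OF, NEG-prefixed negations, and
out-of-vocabulary concepts are dropped), collapsed to an undirected
untyped-edge graph, and summarized per concept type by **global resource
allocation (GRA) similarity**: S(i,j) = Σ_paths β^l · c(p), where a path of
length l contributes the reciprocal of the product of its intermediate
nodes' degrees, c(p) = 1 / Π k(i_t). The resulting square similarity
matrices enter the collection as ordinary views and are factorized as
S ≈ U_e U_eᵀ.

## Worked example

```python
import numpy as np
from dcmflearn import synth, dcmf
from dcmflearn.evaluation import run_experiment

# a synthetic three-level study: notes-style concept views (level 1),
# + knowledge-graph similarity views (level 2), + structured views (level 3)
bundle = synth.simulate_three_views(synth.SynthSpec(seed=0))

# unsupervised collective factorization of the level-1 views
cfg = dcmf.DCMFConfig(latent_dim=4, learning_rate=0.005,
                      weight_decay=1e-4, epochs=2000)
model = dcmf.fit(bundle.collections[1], cfg)
print({e: f.values.shape for e, f in model.factors.items()})
print(f"final total loss: {model.history[-1].total:.4f}")

# end-to-end supervised run, labels masked to a train split
report = run_experiment(bundle, view_level=2, model="dcmf_supervised",
                        classifier="none", seed=0)
print(f"held-out accuracy: {report['accuracy']:.3f}")
```

Output:

```
{'patients': (500, 4), 'diseases': (50, 4), 'medications': (40, 4), 'procedures': (40, 4)}
final total loss: 921.8967
held-out accuracy: 0.653
```

The factor shapes show one k=4 representation per entity type present at
level 1 (labs enter only at level 3); the loss is the weighted sum of all
reconstruction terms after 2000 full-batch Adam epochs — its scale is
dominated by the heavy-tailed count views. The accuracy is the mean over
three 90/10 held-out splits of the end-to-end classifier at view level 2;
the generated labels follow a logistic model on the planted patient
factors, so accuracy is bounded by the bundle's Bayes rate,
`bundle.bayes_accuracy` ≈ 0.72 here.

A command-line interface mirrors the library:

```bash
dcmflearn simulate --seed 0 --out bundle/
dcmflearn kg-similarity --triplets bundle/triplets.tsv --vocab bundle/vocab.tsv --out-dir sims/
dcmflearn fit --manifest bundle/view1.yaml --labels bundle/labels.csv --out model.npz
dcmflearn representations --manifest bundle/view1.yaml --out reps/
dcmflearn experiment --seed 0 --views 1 --out results.csv
```

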
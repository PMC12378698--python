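# cognav

Quantifying **mental navigation** on cognitive multiplex networks from
verbal fluency lists.

## What this is for

In a category-fluency task a participant names as many members of a category
as possible ("animals", "synonyms of *hot*") in a fixed time.  The ordered
list they produce is a trace of a memory search over the mental lexicon.
`cognav` models that lexicon as a **multiplex network**: one shared set of
words replicated across several relation layers — free associations,
synonyms, phonological similarity, hypernyms/hyponyms.  Combining the
layers exposes a structural core that no single layer contains, the
**largest viable cluster (LVC)**: the largest set of nodes whose induced
subgraph is connected in *every* layer simultaneously.

Given a fluency list `L_j = (r_1, r_2, …, r_L)`, the package reconstructs
the participant's **collective walk**

```
w^(j) = (s_1,2, s_2,3, …, s_{L−1,L})
```

where `s_{i,i+1}` is the shortest path on the (aggregate) multiplex linking
consecutive responses `r_i → r_{i+1}`.  The walk's interaction with the LVC
— how much of it lies inside the core, how long it stays, how unpredictably
it enters and leaves (binary Shannon entropies), how far responses sit from
the category identifier — is summarized by **17 navigation measures** per
participant.  A feature-selected, leave-one-out cross-validated (LOOCV)
ridge regression then predicts trait scores (creativity, openness,
intelligence, …) from those measures, and single-layer null models (each
layer's largest connected component standing in for the LVC) quantify how
much of the predictive signal is genuinely multiplex.

The package is aimed at cognitive-network researchers who have per-layer
edge lists and fluency CSVs and want the whole chain — multiplex assembly,
LVC detection, walk features, model training and scoring — reproducible
from the command line or from Python.

## Worked example

The canonical three-response walk: responses `dog, cat, lion` on a lexicon
where the shortest paths are `dog–home–cat` and `cat–feline–lion`, with
`{dog, home, cat}` inside the LVC.

```python
import networkx as nx
from cognav import (FluencyList, normalize_responses,
                    build_collective_walk, compute_features)

g = nx.Graph([("dog", "home"), ("home", "cat"),
              ("cat", "feline"), ("feline", "lion")])
fl = FluencyList("p1", ["dog", "cat", "lion"])
norm = normalize_responses(fl, set(g.nodes))
walk = build_collective_walk(norm, g)
print(walk.flattened)
fv = compute_features(fl, norm, walk, {"dog", "home", "cat"}, "dog", g)
print(fv.number_of_responses, fv.fraction_responses_in_lvc,
      fv.fraction_lvc_accesses, fv.max_permanence_lvc, fv.max_out)
```

prints

```
('dog', 'home', 'cat', 'feline', 'lion')
3.0 0.6666666666666666 0.6 3.0 2.0
```

Reading: the flattened walk visits 5 nodes (shared endpoints counted once);
2 of the 3 responses are in the LVC (dog, cat — lion is outside); 3 of the
5 walk nodes are in the LVC; the walk stays inside the core for at most 3
consecutive nodes and outside for at most 2.

## Command-line workflow

```
cognav simulate --out sim --participants 100 --r2 0.6 --seed 5
cognav build --layer assoc=sim/multiplex/layer_layer1.tsv \
             --layer syn=sim/multiplex/layer_layer2.tsv \
             --layer phon=sim/multiplex/layer_layer3.tsv \
             --layer hyper=sim/multiplex/layer_layer4.tsv \
             --lvc --out built
cognav features --multiplex built --fluency sim/fluency.csv \
                --category w000 --out features.csv
cognav train --features features.csv --traits sim/traits.csv \
             --target trait --method auto --seed 5 --out trained
cognav predict --model trained/model_trait.json \
               --features features.csv --out scores.csv
cognav compare-layers --multiplex built --fluency sim/fluency.csv \
                      --traits sim/traits.csv --target trait \
                      --model trained/model_trait.json \
                      --category w000 --out compare.json
```

`train` ranks features (absolute Pearson correlation, or gradient-boosting
importance, or whichever of the two wins on LOOCV error), grows the model
by forward addition, prunes it by backward elimination, and saves the
refit model together with its scaler and training prediction range.
`predict` emits raw scores plus relative 0–1 and 0–100 scores, where 100
means "as high as the highest prediction seen in training".  Weighted edge
lists are filtered with a strict `weight > min_weight` rule (e.g.
`--min-weight 10` keeps association links elicited more than 10 times).

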
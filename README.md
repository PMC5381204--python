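# decoyclust

Identify high-quality (near-native) protein structural models from decoy
ensembles by clustering.

## The problem

Ab initio and comparative protein-structure prediction pipelines generate
hundreds to thousands of candidate conformations ("decoys") per target.
Free energies cannot be computed accurately enough to rank them, so the
standard heuristic is structural clustering: the center of the most
populated conformational cluster is reported as the prediction (*model1*).
The classical workhorse, SPICKER, clusters in a single pass using neighbor
counts under a self-adjusting pairwise-RMSD cutoff; classical K-means is an
alternative, but its random initial centers make its output unstable.

`decoyclust` implements both, plus two seeded K-means variants that remove
the initialization randomness:

* **SK-means** — run a SPICKER-style pass first and use its cluster
  centers as the initial centers of K-means;
* **K-means++** — draw each successive initial center with probability
  proportional to its squared distance from the nearest center already
  chosen.

Because conformations cannot be meaningfully averaged without mutual
superposition, all K-means variants here are *medoid*-based: a cluster
center is always an actual decoy, and the algorithm needs only a pairwise
distance matrix.

## Structural measures

For two residue-wise corresponding CA traces of length *L*:

* raw Euclidean distance `sqrt(Σᵢ |aᵢ − bᵢ|²)` (no superposition);
* RMSD after optimal rigid superposition (closed-form Kabsch/SVD,
  reflections excluded);
* TM-score

  `TM = max (1/L) Σᵢ 1 / (1 + (dᵢ/d₀)²)`,  `d₀ = 1.24 (L − 15)^⅓ − 1.8` (floored at 0.5 Å),

  maximized over superpositions with the standard heuristic (fragment-seeded
  Kabsch fits refined by iterative re-superposition on the close subset).
  TM ∈ (0, 1]; ≳ 0.5 indicates the same fold.

## Worked example

```python
import numpy as np
from decoyclust import (EnsembleSpec, generate_decoy_ensemble,
                        pairwise_distances, sk_means, select_models,
                        score_against_native)

spec = EnsembleSpec(n_residues=80, cluster_sizes=(110, 70, 40), seed=42)
labeled = generate_decoy_ensemble(spec)          # 220 decoys + native
D = pairwise_distances(labeled.ensemble, "rmsd") # superposed-RMSD matrix
clustering = sk_means(D)                         # SPICKER-seeded K-means
model1 = select_models(clustering, D, n_models=1)[0]
print(clustering.k, clustering.sizes().tolist())
print(round(score_against_native(labeled.ensemble, model1), 3))
```

prints

```
3 [110, 70, 40]
0.947
```

All three synthetic basins are recovered exactly, and the selected model1
(the medoid of the largest, near-native basin) has TM-score 0.947 to the
native — far above the ensemble average. The scripts in `examples/` walk
through scoring, clustering, a miniature benchmark, and the packaged
published benchmark table; a thin CLI (`decoyclust simulate | cluster |
score | benchmark`) wraps the same calls for shell use.

## The published benchmark table

The package ships the 56-target small-protein benchmark table
(`load_reference_table()`): per target, the TM-score of the model1 selected
by each method. Its aggregates reproduce the published comparison —
K-means++ and SK-means match or beat SPICKER on 33/56 (59%) and 42/56
(75%) targets while the four column means are nearly equal (SPICKER
0.5745), and the equal-n pooled-variance t-tests against the random
baseline are computed for the full table and the decoy-size < 520
subgroup.

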
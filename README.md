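# simfuse

Multi-space disease similarity fusion: build a *disease map* — a network of
diseases linked at one or more biological levels — from heterogeneous
per-disease feature sets.

Diseases can be described at many levels: ontology terms, phenotypes,
literature co-occurrence, associated genes, differential gene expression,
indicated drugs. Each level ("feature space") sees different relationships,
and their similarity-score distributions differ wildly, so naively averaging
them lets one data type dominate. `simfuse` implements a similarity-fusion
pipeline that combines the levels evenly, for computational biologists
studying disease relationships and drug-repositioning opportunities:

1. **Similarity.** Within each space, pairwise disease similarity is the
   Jaccard index J(A, B) = |A∩B| / |A∪B| of the feature sets; signed
   (expression) spaces use a size-weighted mean of the up-set and down-set
   Jaccard scores.
2. **Quantile normalization.** Each space's off-diagonal pair vector is
   mapped onto a common reference distribution (the mean of the rank-sorted
   vectors, with tie adjustment), so every space contributes evenly.
3. **Fusion.** The fused score of a pair is the (weighted, default uniform)
   mean of its per-space normalized scores.
4. **Significance.** A frequency-preserving randomization null — each
   disease's sets redrawn from the space's feature universe with
   frequency-proportional weights, sizes preserved — is pushed through the
   same pipeline; a high percentile (default 99.99) of the pooled null
   scores is the link threshold.
5. **The map and its evaluation.** Pairs above the threshold form the
   disease map. Edges between diseases sharing no top-level ontology class
   are flagged *novel*. Hold-out evaluators measure how well the fused
   similarities predict drug sharing (mean Jaccard drug overlap versus
   similarity threshold), known disease classes (random-forest
   classification of similarity profiles under stratified Monte-Carlo
   cross-validation), and patient comorbidity (relative-risk contrast of
   linked versus non-linked pairs).

A synthetic-data module generates multi-space collections with planted
class structure, heterogeneous distributions, a signed space and a
drug-like space — plus exact closed-form expected similarities — so the
entire pipeline is testable without external data. See
[docs/methods.md](docs/methods.md) for the model details.

## Worked example

```python
import simfuse as sf

# a 30-disease, 4-space synthetic collection with 3 planted classes
spaces, labels, _ = sf.generate_collection(sf.desk_config(30), seed=1)
diseases = sf.validate_collection(spaces).common_diseases

raw = [sf.similarity_matrix(s, diseases) for s in spaces]
fused, normalized = sf.normalize_and_fuse(raw)

null = sf.null_distribution(spaces, n_iterations=200, seed=2)
result = sf.significance_threshold(null, percentile=99.9)
dmap = sf.annotate_novelty(
    sf.build_map(fused, normalized, result.threshold), labels
)
```

Running [examples/02_disease_map.py](examples/02_disease_map.py), which is
this exact computation, prints:

```
pooled null values: 87000
99.9th-percentile threshold: 0.1212
fraction of iterations whose maximum exceeds it: 0.33

edges above threshold: 110 (of 435 pairs)
isolated diseases: 0
novel-link fraction (edges whose diseases share no class): 0.000
  d01 -- d02: fused 0.162 (alpha=0.192, beta=0.159, gamma=0.155, delta=0.141)
  ...
```

Of the 435 disease pairs, 110 score above the null threshold of 0.1212,
and every one of those links joins two diseases of the same planted class
(novel fraction 0.000): the map recovered exactly the planted structure.
Each edge carries the per-space normalized scores behind it, showing which
levels support the link.

The other example scripts cover raw-versus-normalized distributions and
inter-space correlations (`01`), hold-out drug-overlap curves (`03`) and
class prediction from similarity profiles (`04`).

## Command line

A thin CLI mirrors the pipeline stages:

```
simfuse simulate --profile default --seed 0 --out data/
simfuse similarity --space ont=data/ontological.tsv ... --out matrices/
simfuse normalize --matrix matrices/raw_ont.tsv ... --out matrices/
simfuse fuse --matrix matrices/normalized_ont.tsv ... --out fused.tsv
simfuse null --space ont=data/ontological.tsv ... --iterations 1000 --seed 0 --out null.tsv
simfuse map --fused fused.tsv --threshold 0.12 --labels data/labels.tsv --out map/
simfuse evaluate drugs|classes|comorbidity ...
simfuse run --config manifest.json --out results/   # full pipeline, reproducible
```

Feature-space files are TSVs (`disease_id<TAB>feature_id[<TAB>sign]`); all
matrices are TSVs with JSON provenance sidecars; maps export as edge-list
TSV and GraphML.

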
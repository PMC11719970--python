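# methdeg

DNA-methylation biomarker screening and multi-class degenerative-disease
prediction, as a tested, reusable pipeline. Given beta-value matrices
(samples × CpG probes, values in [0, 1]) with binary or four-class labels, it
runs:

1. **rf_screen** — tree-ensemble importance filter: drop zero-importance
   CpGs, rank the rest in descending order.
2. **feature_scan** — evaluate a multi-scale 1-D CNN (**msdcnn**: parallel
   branches with kernel sizes 3/5/7, sigmoid head, TPR−FPR-optimal decision
   threshold) over an increasing feature-count grid under stratified k-fold
   CV, and pick the minimal count achieving near-optimal MCC.
3. **graph_cluster** — cosine-similarity KNN graph over samples, Louvain
   community detection, and a K = 1..50 stabilization scan.
4. **resdegnet** — residual four-class 1-D CNN (stem conv → maxpool → three
   residual blocks → global average pooling → softmax) with 5-fold CV,
   independent-test evaluation and GAP-embedding extraction for clustering.
5. **attribution** — permutation-sampling Shapley values of each class
   probability per CpG, averaged over training samples (with an exact
   coalition-enumeration mode for small feature counts).

A **synthdata** module generates beta-matrix cohorts with planted
class-specific markers, within-class subtypes, and a bimodal-age healthy
population (with optional age-drifting probes), so the whole pipeline is
testable without any external download. The neural networks run on a small
NumPy engine (`methdeg/_nn.py`) with gradient-checked forward/backward
passes — no deep-learning framework required.

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the property-based acceptance criteria
(metric/threshold/grid oracles, planted-marker recovery, community
recovery, Shapley axioms, byte-identical pipeline determinism); the rest
are per-module unit and property tests.

## CLI

```bash
# full synthetic run with the built-in default config
methdeg --seed 7 --out run_dir run-all

# custom config (YAML, deep-merged over the defaults), stage by stage
methdeg --config my.yaml --out run_dir simulate
methdeg --config my.yaml --out run_dir rf-filter
methdeg --config my.yaml --out run_dir scan
methdeg --config my.yaml --out run_dir cluster
methdeg --config my.yaml --out run_dir classify
methdeg --config my.yaml --out run_dir embed-cluster
methdeg --config my.yaml --out run_dir attribute
```

Artifacts are plain TSV/JSON: the importance ranking, scan results and
selected CpG list, K-scan traces and community assignments (raw betas and
GAP embeddings), CV + independent-test metric reports, the CpG × class
attribution table, and a manifest with the config hash and per-stage seeds.
Rerunning with the same config and seed reproduces every artifact
byte-for-byte.

## Library use

```python
from methdeg.synthdata import CohortConfig, generate_binary_cohort
from methdeg import rf_screen, feature_scan, msdcnn

cohort = generate_binary_cohort(CohortConfig(seed=0))
y = cohort.labels.aligned_to(cohort.beta)
ranking = rf_screen.filter_nonzero(rf_screen.fit_importances(cohort.beta, y))
grid = feature_scan.make_grid(20, 20, len(ranking))
result = feature_scan.scan(cohort.beta, y, ranking, grid[:5], k_folds=5)
n_selected = feature_scan.select_count(result)
```
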
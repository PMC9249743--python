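# cnnforest

A random forest built on CNN margin features for two-class grayscale image
cohorts (e.g. cardiac MR slices grouped by patient), plus a synthetic
cohort generator so the whole pipeline is testable offline.

The method: within each cross-validation training fold, the fold is split
into *n* disjoint class-stratified subsets and *n* lightweight CNNs are
trained, each holding out one subset for validation. Their scalar margin
outputs turn every image into an *n*-dimensional feature vector. A
from-scratch random forest of Gini-impurity decision trees — whose split
candidates are (random feature column, threshold drawn from a random node
row) pairs — is grown on that feature matrix and predicts by majority
vote. An equal-epoch-budget single-CNN comparator is included.

The CNN stack (valid-padding strided convolutions, ReLU, dense layers, a
linear margin head trained with hinge loss + L2, and Adagrad / RMSProp /
Adam updates) is implemented in numpy; no deep-learning framework is
required.

## Library quick start

```python
from cnnforest import (
    CohortConfig, generate_cohort, CnnSpec, ForestParams,
)
from cnnforest.pipeline import PipelineConfig, run_pipeline

cohort = generate_cohort(CohortConfig(seed=1))          # 80 patients, 32x32
config = PipelineConfig(
    n_cnns=4,
    cnn_spec=CnnSpec(input_shape=(32, 32), epochs=2, batch_size=32),
    forest_params=ForestParams(n_trees=15),
    global_seed=1,
)
report = run_pipeline(cohort, config)
print(report.accuracy, report.auc)
```

## CLI

```bash
# generate a synthetic cohort (PNG images + TSV manifest)
cnnforest synth --out cohort/ --seed 1

# cross-validated ensemble run; writes metrics, predictions and models
cnnforest train --images cohort/ --manifest cohort/manifest.tsv \
    --out run/ --image-size 32 32 --n-cnns 4 --epochs 2 --batch-size 32

# equal-epoch-budget single-CNN comparator on the same folds
cnnforest baseline --images cohort/ --out base/ --image-size 32 32 \
    --n-cnns 4 --epochs 2 --batch-size 32

# metrics from saved predictions; apply saved fold models to new images
cnnforest evaluate --predictions run/predictions.tsv
cnnforest predict --models run/models/fold0 --images cohort/ --out preds.tsv
```

All options can also come from a YAML config file (`--config`); CLI flags
win, and the effective configuration is echoed into the output directory.

Real cohorts are loaded from a TSV manifest
(`path  patient_id  label  sequence_tag  view_tag`) or inferred from a
class-subfolder layout with patient ids parsed from filenames. Folds are
always assigned at patient level with class stratification, so a patient's
images never straddle a train/test boundary.

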
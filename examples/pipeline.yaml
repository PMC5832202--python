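# Demo end-to-end run: `promine run --config examples/pipeline.yaml --out results/demo`
seed: 7
generator:
  n_patients: 8
  days_per_patient: [20, 40]
  samples_per_day: 24
subsets:
  - Expert_selection
  - No_activities_avg_and_std_dev
  - No_sparse_features_0.17
imputations:
  - none
  - knn
definitions:
  - "1, 2 vs. 4, 5"
  - "1, 2 x (3/4) vs. 4 x (3/4), 5"
classifiers:
  - majority
  - decision_tree
  - random_forest
cv:
  folds: 10
  repeats: 3
relations_definition: "1, 2 vs. 4, 5"
min_occurrences: 2
include_cross_variants: false
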
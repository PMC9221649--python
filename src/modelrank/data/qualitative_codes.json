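{
  "_comment": "Literature-derived qualitative criterion codes per classifier family, on a 0-1 scale (higher = more favorable). training_samples: how well the family copes with the number of training samples needed; feature_scaling: impact of feature scaling; hyperparameter_tuning: whether tuning materially changes performance (YES/NO); irrelevant_attributes: tolerance to irrelevant attributes.",
  "svm": {
    "training_samples": 0.92,
    "feature_scaling": 0.92,
    "hyperparameter_tuning": "YES",
    "irrelevant_attributes": 0.92
  },
  "random_forest": {
    "training_samples": 0.75,
    "feature_scaling": 0.08,
    "hyperparameter_tuning": "YES",
    "irrelevant_attributes": 0.08
  },
  "logistic_regression": {
    "training_samples": 0.5,
    "feature_scaling": 0.25,
    "hyperparameter_tuning": "NO",
    "irrelevant_attributes": 0.5
  },
  "knn": {
    "training_samples": 0.08,
    "feature_scaling": 0.92,
    "hyperparameter_tuning": "YES",
    "irrelevant_attributes": 0.5
  },
  "naive_bayes": {
    "training_samples": 0.5,
    "feature_scaling": 0.08,
    "hyperparameter_tuning": "NO",
    "irrelevant_attributes": 0.75
  }
}
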
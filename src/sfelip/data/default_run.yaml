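# Default end-to-end run on synthetic inputs: 89 lipids over the bundled
# 12-condition design, all six models, with and without the IDAC feature.
# Grids here are singletons (direct fits at the documented defaults); widen
# them per model to enable grid-search tuning.
seed: 1
output_dir: sfelip-out
n_lipids: 89
representative_method: all
idac: both
holdout: SC5
test_fraction: 0.2
models: [lasso, gaussian_process, svr, random_forest, xgboost, ann]
grids:
  lasso: {model__alpha: [0.01]}
  gaussian_process: {model__alpha: [0.0001]}
  svr: {model__C: [10.0]}
  random_forest: {model__n_estimators: [200]}
  xgboost: {model__max_depth: [6], model__learning_rate: [0.1]}
  ann: {model__hidden_layer_sizes: [[64]]}
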
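"""Train the four classifier kinds and evaluate them with the repeated
balanced-split protocol (pair-disjoint splits).

Each run: re-draw the class balance, 70/30 split, train-only
standardization and constant-feature filtering, CV hyperparameter tuning,
final fit, held-out AUROC/AUPRC.
"""

import warnings

import sbsl

warnings.filterwarnings("ignore")

config = sbsl.planted_config(seed=2, n_genes=120, n_pos_pairs=120, n_neg_pairs=120,
                             n_cell_lines=80, n_patients=120, n_healthy=60)
labels, bundle = sbsl.generate_dataset(config)
features = sbsl.build_feature_table(labels.pairs, bundle, n_perm=150, seed=2)

report = sbsl.run_experiment(
    labels, features,
    kinds=("elastic_net", "l0l2", "muvr_rf", "rrf"),
    mode="none", n_runs=3, seed=0, tune_folds=5, tune_repeats=1,
    model_kwargs={"rrf": {"cv_trees": 50},
                  "muvr_rf": {"n_rep": 1, "n_outer": 5, "inner_trees": 30}},
)
print(report.summary().to_string(index=False))
print()
print("With planted signal in every data channel, all four regularized "
      "models separate SL from non-SL pairs nearly perfectly on held-out "
      "pairs; on real data the spread between models is what matters.")
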
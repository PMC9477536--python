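"""The selection-bias experiment: gene holdout exposes label-graph memorizers.

On block-structured (selection-biased) labels, a baseline that memorizes the
label graph looks excellent under ordinary pair-disjoint splits and collapses
to chance once the test genes never appear in training (double holdout).
Feature-based models keep working because molecular features carry no gene
identity.
"""

import warnings

import numpy as np

import sbsl
from sbsl.baselines import LabelGraphBaseline

warnings.filterwarnings("ignore")

config = sbsl.planted_config(seed=3, n_genes=50, n_pos_pairs=300, n_neg_pairs=300,
                             n_cell_lines=60, n_patients=100, n_healthy=50,
                             bias_mode="block", n_blocks=6, block_noise=0.05)
labels, bundle = sbsl.generate_dataset(config)
features = sbsl.build_feature_table(labels.pairs, bundle, n_perm=150, seed=3)

for mode in ("none", "double"):
    base_aucs = []
    for seed in range(5):
        plan = sbsl.split_pairs(labels, mode=mode, seed=seed)
        baseline = LabelGraphBaseline(plan.train)
        base_aucs.append(sbsl.auroc(baseline.score(plan.test.pairs), plan.test.labels))
    report = sbsl.run_experiment(
        labels, features, kinds=("elastic_net",), mode=mode, n_runs=3, seed=0,
        tune_folds=5, tune_repeats=1,
    )
    feat_auc = report.metric("elastic_net", "auroc").mean()
    print(f"mode={mode:6s}  label-graph memorizer AUROC {np.mean(base_aucs):.3f}   "
          f"feature model AUROC {feat_auc:.3f}")

print()
print("The memorizer's advantage under 'none' is selection bias, not "
      "biology: it vanishes the moment test genes are held out, while the "
      "feature-based model barely moves.")
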
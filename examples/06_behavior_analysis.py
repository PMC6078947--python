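"""Behavioral analyses: response configurations and delayed-recall prediction.

Each item's four-round correctness record becomes a 4-bit configuration
(e.g. 0111 = correct from round 2 on). A cross-validated logistic
regression on these bits predicts one-week delayed recall; a label
permutation test gives significance.
"""

import warnings

warnings.filterwarnings("ignore")

from compdrop import (
    SimulationConfig,
    behavior_permutation_test,
    encode_configurations,
    simulate_behavior,
    summarize_rounds,
)

config = SimulationConfig(n_subjects=20, n_items_s2=60, seed=8)
truth = simulate_behavior(config)
behavior = truth.behavior_table()

configs = encode_configurations(behavior)
print("Most common response configurations (count, delayed recall rate):")
top = (
    configs.groupby("configuration")
    .agg(count=("recalled_s3", "size"), recall_rate=("recalled_s3", "mean"))
    .sort_values("count", ascending=False)
    .head(6)
)
print(top)
print("More correct rounds -> higher delayed recall (the planted behavioral "
      "coupling), and late-acquisition patterns like 0011 are common.")

print("\nRound-by-round accuracy, split by delayed-recall outcome")
print("(mean of within-subject means, SEM over subjects):")
print(summarize_rounds(behavior).to_string(index=False))

res = behavior_permutation_test(configs, n_perm=500, seed=9)
print(f"\nConfiguration classifier: CV accuracy = {res.accuracy:.3f} "
      f"(chance 0.50), permutation p = {res.p:.4f}")
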
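"""Aggregate per-context scores into a final mean rank.

Mimics the multi-context network challenges: four teams are scored in six
contexts (e.g. cell line x stimulus combinations), ranked within each
context (average ranks on ties), and the final score is each team's mean
rank — lower is better.
"""

import numpy as np

from dreambench.scores import aggregate_mean_rank, rank_table_from_scores

rng = np.random.default_rng(5)
teams = ["alpha", "beta", "gamma", "delta"]
contexts = [f"ctx{i + 1}" for i in range(6)]
skill = np.array([0.8, 0.7, 0.6, 0.5])[:, None]
scores = skill + 0.1 * rng.normal(size=(4, 6))  # per-context AUROC-like scores

table = rank_table_from_scores(teams, contexts, scores, greater_is_better=True)
final = aggregate_mean_rank(table)
for team in sorted(final, key=final.get):
    print(f"{team:6s} mean rank = {final[team]:.2f}")
print("Mean rank across contexts; rank 1 is best, ties share the average rank.")
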
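"""Score a multi-network inference submission.

Generates five directed gold networks plus graded-quality ranked edge-list
predictions, builds per-network empirical nulls from random confidence
vectors, and reports the per-network AUROC/AUPR p-values and the combined
mean-neglog10-p final score.
"""

import numpy as np

from dreambench.fixtures import make_network_fixture
from dreambench.metrics import BinaryPrediction, aupr, auroc
from dreambench.nulls import GREATER_IS_BETTER, NullDistribution
from dreambench.scores import edge_prediction_to_binary, score_network_inference

golds, preds, roc_nulls, pr_nulls = [], [], [], []
rng = np.random.default_rng(1)
for i in range(5):
    gold, pred = make_network_fixture(
        n_nodes=10, n_edges=15, topology="erdos_renyi", quality=0.7, seed=i
    )
    golds.append(gold)
    preds.append(pred)
    labels = edge_prediction_to_binary(pred, gold).labels
    rocs, prs = [], []
    for _ in range(200):
        bp = BinaryPrediction(scores=rng.random(labels.size), labels=labels)
        rocs.append(auroc(bp))
        prs.append(aupr(bp))
    roc_nulls.append(NullDistribution(rocs, GREATER_IS_BETTER, name="auroc"))
    pr_nulls.append(NullDistribution(prs, GREATER_IS_BETTER, name="aupr"))

report = score_network_inference(preds, golds, (roc_nulls, pr_nulls))
for i, net in enumerate(report["per_network"], start=1):
    print(
        f"network {i}: AUROC={net['auroc']:.3f} (p={net['p_auroc']:.4g}) "
        f"AUPR={net['aupr']:.3f} (p={net['p_aupr']:.4g})"
    )
print(f"S_AUROC = {report['s_auroc']:.3f}, S_AUPR = {report['s_aupr']:.3f}")
print(f"final score (mean of the two) = {report['final']:.3f}")
print("Each S is the mean -log10 p over the five data sets; higher is better.")
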
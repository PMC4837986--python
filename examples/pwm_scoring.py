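"""Score predicted binding-specificity matrices against mapped PWMs.

Builds three gold position weight matrices and predictions at 70% fidelity,
then scores the family: each Frobenius distance is converted to an
empirical p-value against random PWMs and the family score is the mean
-log10 p.
"""

from dreambench.fixtures import make_pwm_fixture
from dreambench.scores import score_pwm_family

golds, preds = make_pwm_fixture(n_matrices=3, n_rows=4, n_cols=8, quality=0.7, seed=3)
report = score_pwm_family(preds, golds, n_null=500, seed=11)

for k, (d, p) in enumerate(zip(report["distances"], report["pvalues"]), start=1):
    print(f"PWM {k}: Frobenius distance = {d:.4f}, p = {p:.4g}")
print(f"family score (mean -log10 p) = {report['final']:.3f}")
print(
    "p is the fraction of random PWMs at least as close to the gold matrix; "
    "higher final score means the prediction beats chance more decisively."
)
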
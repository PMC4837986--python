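# dreambench

A scoring harness for collaborative prediction challenges in systems
biology. Community challenges (network inference, signaling response
prediction, binding-specificity prediction, survival prognosis, disease
progression ...) withhold a *gold standard* and judge each submission
against it; over the years this produced a corpus of scoring procedures —
ranking metrics, empirical-null p-values, composite log-p formulas, rank
aggregation — scattered across heterogeneous scripts. `dreambench`
re-implements that corpus as one testable Python library with a thin
command-line interface, a plugin framework for new challenges, and
synthetic graded-quality fixtures so everything runs with no downloads.

## What it computes

**Atomic metrics** (`dreambench.metrics`): AUROC (Mann–Whitney identity,
ties ½), step-wise AUPR, Matthews correlation, balanced accuracy, Jaccard,
Pearson/Spearman, Lin's concordance correlation, Harrell's concordance
index C over admissible pairs (the earlier time must be an observed
event), a probabilistic concordance variant where a pair with observed
time gap Δt and pooled noise s votes Φ(Δt/s) instead of 0/1, the
noise-normalized squared error

E = Σᵢ (X̂ᵢ − Xᵢ)² / (σ_b² + σ_s²·Xᵢ²),  σ_b = 0.1, σ_s = 0.2,

RMSE, and the Frobenius distance ‖A−B‖_F for position weight matrices.

**Null models** (`dreambench.nulls`): empirical nulls from shuffled gold
standards or random predictions with add-one-smoothed p-values
p = (1+c)/(N+1) (never zero, so log-p combiners are always defined),
z-scores against randomized-gold nulls, uniform-column random PWMs, and
the exact enumeration null for identity-assignment challenges
(P(k or more of 4 proteins correctly identified among 7 species); all four
correct has p = 1/840).

**Composite scores** (`dreambench.scores`): S = −½ log₁₀(p_T·p_G);
S = −(1/N) Σ log₁₀ pᵢ; the parsimony-penalized S = S_pred − r·N_e;
S_B = −(log₁₀ p₁ + log₁₀ p₂); the literal four-metric product −¼ ∏ p_j
(with a named log-mode alternative); D_param = (1/N_p) Σ [log₁₀(X̂ᵢ/Xᵢ)]²;
the burn-in-aware time-course distance with 1/90 normalization;
S₁ = −log₁₀(p_param·p_tc); mean-rank aggregation across contexts; and
mean-z olfaction-style aggregation. All logs are base 10 (one documented
convention).

**Everything else**: plain-text readers/writers for ranked edge lists,
CSV prediction tables, PWM block files and survival tables
(`dreambench.io`); deterministic graded-quality fixture generators
(`dreambench.fixtures`); and a registry mapping challenge nicknames
(`DXCY`, with `dot` for fractional versions like `D9dot5C1`) to scoring
procedures, ten of them bundled end-to-end with synthetic templates and
gold standards (`dreambench.registry`, `dreambench.challenges`).

## Worked example

```python
from dreambench.fixtures import make_survival_fixture
from dreambench.metrics import concordance_index

records = make_survival_fixture(n=100, censor_rate=0.2, quality=0.5, seed=7)
print(concordance_index(records))
```

prints `0.783...`: the risk prediction orders 78% of the admissible
patient pairs correctly (0.5 would be chance, 1.0 a perfect ranking).
From the shell, the same three-call contract every challenge follows:

```sh
$ dreambench --challenge D3C3 --download-template
~/.config/dreambench/D3C3/main_template.csv
$ dreambench --challenge D3C3 --filename ~/.config/dreambench/D3C3/main_template.csv
D3C3 final score: 1.70012
```

The template is a deliberately mediocre example submission; its Spearman
time- and gene-profiles give combined association p-values
p_T ≈ p_G ≈ 0.02, hence −½ log₁₀(p_T·p_G) ≈ 1.70. Scoring the gold
standard itself maximizes the score. `--info` prints a challenge's title,
summary and sub-challenge names; `--json` emits the full report;
`dreambench-layout --challenge D10C10` scaffolds a plugin challenge that
the CLI discovers via `--plugins`.

Longer narrative scripts live in `examples/` (binary classification,
network inference, PWM scoring, survival concordance, rank aggregation,
registry usage); each prints its numbers with a line on what they mean.

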
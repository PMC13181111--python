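# symptomnet

Network analysis of binary (presence/absence) psychiatric symptoms,
built around the comparison of depressive-symptom networks between two
groups of questionnaire respondents — e.g. PHQ-9 items scored 0–3 and
dichotomized to symptom presence.

The pipeline, end to end:

1. **Ingestion & descriptives** — read a subjects × items table,
   recode scores (0 → absent, 1–3 → present), compute group-wise item
   prevalences, total-score summaries, Mann-Whitney U, Cohen's *d*,
   Cronbach's α.
2. **Network estimation (eLASSO)** — for each symptom *i*, an
   L1-penalized logistic regression of *x_i* on all other symptoms
   along a penalty path; the Extended BIC
   `−2ℓ + k·log n + 2γ·k·log(p−1)` (γ = 0.25) picks the model; the two
   directed coefficients per pair are merged under the AND rule into
   the symmetric edge weights *W* and thresholds τ of a {0,1} Ising
   model `P(x) ∝ exp(Στ_i x_i + Σ_{i<j} W_ij x_i x_j)`.
3. **Centrality** — node strength `Σ_j |W_ij|` and global strength
   `Σ_{i<j} |W_ij|`.
4. **Stability** — edge-weight bootstrap (percentile 95% CIs) and the
   case-dropping bootstrap with the correlation-stability (CS)
   coefficient.
5. **Comparison (NCT)** — permutation test of network-structure
   invariance (`M = max |ΔW_ij|`) and global-strength invariance, with
   full re-estimation inside every permutation.
6. **Power** — Monte-Carlo post-hoc power of the NCT: sample paired
   cohorts from two Ising models, re-run the test, report rejection
   proportions at α = 0.05.

Because studies of this kind often publish margins but not raw data,
the package ships a synthetic-cohort generator whose thresholds are
calibrated (by Newton iteration on exact enumerated marginals) so the
generated groups reproduce published prevalence columns to 1e-4, with
edge structure matching the published strongest-edge and centrality
orderings. Every stage is therefore testable offline.

See `docs/methods.md` for the statistical details and design choices.

## Worked example

```python
import numpy as np
from symptomnet import (
    paper_like_scenario, generate_cohort, dichotomize,
    fit_elasso, edge_list, strength, global_strength, nct,
)

spec = paper_like_scenario(seed=0)          # two calibrated 9-item groups
cohort = generate_cohort(spec, seed=1)      # 1,111 + 160 subjects, scores 0-3
binary = dichotomize(cohort)
groups = binary.by_group()

net = fit_elasso(groups["heterosexual"], labels=binary.items)
print([(a, b, round(w, 3)) for a, b, w in edge_list(net)[:3]])
print(strength(net).top_node(), round(global_strength(net), 2))

res = nct(groups["heterosexual"], groups["sexual_minority"], P=200, seed=1)
print(round(res.m_observed, 3), round(res.p_structure, 3))
```

Output:

```
[('PHQ.6', 'PHQ.9', 2.724), ('PHQ.2', 'PHQ.6', 2.151), ('PHQ.3', 'PHQ.9', 1.173)]
PHQ.6 19.84
2.151 0.378
```

The three strongest estimated edges in the larger group come out in
the generator's designed order — guilt–suicidal ideation
(PHQ.6–PHQ.9), then guilt–depressed mood, then suicidal
ideation–sleep — and the most central symptoms are guilt and suicidal
ideation (their strengths are nearly tied; which one tops the ranking
varies at this sample size because the rare suicidality item is
shrunk hardest — see `docs/methods.md`). The network comparison test
finds no significant structure difference (M is the largest single
edge-weight difference between the two groups' networks; its
permutation p-value here is 0.38), the expected outcome: the power
stage shows structure differences of this magnitude are hard to
detect with a 160-subject second group.

The same workflow is available from the shell:

```bash
symptomnet simulate -o cohort.csv --seed 7
symptomnet fit cohort.csv -o out/
symptomnet stability cohort.csv -o out/ -B 1000
symptomnet compare cohort.csv -o out/ -P 1000
symptomnet power -o out/ --r-reps 60 -P 60
```

writing adjacency/edge-list/threshold/centrality CSVs, GraphML, NCT
JSON + permutation distributions, a power table, and a provenance
record per stage.

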
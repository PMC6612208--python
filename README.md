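# ahpgap

Multi-criteria decision analysis for health technology assessment (HTA),
combining the **analytic hierarchy process (AHP)** with **Likert-scale
satisfaction analysis**. The package targets assessment teams who survey a
panel of experts about a health technology — e.g. which of several assay
platforms a hospital should adopt — and need to turn pairwise importance
judgments, questionnaire answers, and operational logs into defensible
priority weights, alternative rankings, and an improvement agenda.

## The method

A decision is decomposed into a hierarchy: a goal, evaluation criteria
(technical, organizational, economic, clinical, social/ethical/legal),
sub-criterion indicators, and the alternatives under comparison. Each
expert judges sibling importance on Saaty's 1–9 ratio scale; N experts'
judgments for a pair are pooled with the weighted geometric mean
Π aₖ^βₖ (βₖ = 1/N by default), rounded back to the nearest Saaty ratio,
and assembled into a positive reciprocal comparison matrix A.

Priorities are the principal right eigenvector w of A (Aw = λmax·w),
normalized to unit sum. Judgment coherence is screened with the
consistency index CI = (λmax − n)/(n − 1) and consistency ratio
CR = CI/RI(n), acceptable when CR ≤ 0.1. Local weights propagate down the
tree (global leaf weight = local weight × parent weight), operational
indicator models convert exam logs into per-leaf alternative weights, and
the final priority of each alternative is the sum of its leaf
contributions. On the satisfaction side, a Likert questionnaire (with
reverse-coded items) yields a per-item satisfaction index in [0, 1];
crossing AHP importance with Likert satisfaction flags the sub-criteria
with high importance but low satisfaction — the improvement priorities,
scored as importance × (1 − satisfaction).

A built-in worked example ships with the package: the assessment of two
optoelectronic thyroglobulin biosensors (a lab-on-fibre sensor, LOF, and a
long-period-grating sensor, LPG) against conventional cytological
analysis, as judged by a panel of 80 experts. A synthetic-data module
generates complete surveys (judgments, Likert answers, operational
series) around known ground truth so every stage is testable end to end.

## Worked example

```python
from ahpgap import consistency, normalize_weights, principal_eigen
from ahpgap.case_study import criteria_matrix

m = criteria_matrix()           # 5x5 comparison of the assessment dimensions
lam, raw = principal_eigen(m)
print(consistency(m))
for name, w in normalize_weights(raw, m.labels).as_dict().items():
    print(f"{name:22s} {w:.4f}")
```

prints

```
n=5  lambda_max=5.3185  CI=0.0796  RI=1.12  CR=0.0711 (7.11%) -> acceptable
technical              0.0404
organizational         0.0807
economic               0.4935
clinical               0.2412
social_ethical_legal   0.1443
```

i.e. the expert panel's judgments are acceptably consistent (CR = 7.11% <
10%), and economic aspects dominate the assessment (weight 0.4935),
followed by clinical aspects (0.2412). Propagating the sub-criterion
matrices gives the global "hierarchy of needs" — ROS (return on sales,
0.237) and usefulness (0.200) matter most to the panel — and summing the
per-leaf contributions of each alternative ranks the LPG biosensor first
(0.419) ahead of the LOF biosensor (0.36065) and cytological analysis.

The same pipeline runs from the shell on CSV/YAML inputs:

```bash
ahpgap simulate --seed 1 --out study/        # synthetic survey + logs
ahpgap run --hierarchy study/hierarchy.yaml \
           --judgments study/judgments.csv \
           --likert study/likert.csv \
           --timesteps study/timesteps.csv --out report/
```

which writes `report.json`, `weights.csv` and `gap.csv`, and prints the
alternative ranking.

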
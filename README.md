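# stabeval

Evaluation of the **stabilization (immobilization) effect** of
heavy-metal-contaminated farmland soil.

Stabilization remediation adds an amendment (biochar, hydroxyapatite, lime,
zeolite, ...) to contaminated farmland to reduce the *bioavailable* fraction
of heavy metals without removing the total burden. Judging whether a
treatment worked cannot rest on a single number: soil fertility, crop
safety and growth, and the amendment's own properties all matter. stabeval
implements a multi-criteria evaluation pipeline for exactly this problem,
aimed at soil scientists and remediation engineers who have before/after
measurement tables from a pot or field trial:

1. **Weights** — an analytic hierarchy process (AHP) over a
   target → criterion → sub-criterion → indicator tree. Expert
   pairwise-comparison (judgment) matrices on the Saaty 1–9 scale are
   converted to priority weights by the sum-product method, screened by the
   consistency ratio (CR = CI/RI < 0.1 with CI = (λ_max − n)/(n − 1)),
   aggregated across the expert panel, and composed multiplicatively down
   the hierarchy into one comprehensive weight ω_i per indicator.
2. **Derived indicators** — the bio-accumulation factor
   BAF = 100·[X]_crop/[X]_soil (%), the available-metal reduction rate
   α = 100·(X_b − X_a)/X_b (%), and ratios to local references
   (production, biomass, cost/revenue).
3. **Scoring** — three piecewise-linear response curves normalize each
   indicator value x onto [0, 1]: a rising "S" ramp (more is better), a
   falling inverse-"S" ramp (less is better), and a parabolic/midpoint
   curve with a plateau (pH).
4. **Verdict** — the composite score S_i = Σ ω_i·X_i is binned into five
   equidistant grades (I best), and the remediation verdict (excellent /
   good / qualified / poor / very poor) is read off the grade-step change
   from the untreated to the treated soil.

The 16-indicator registry (with response-curve thresholds), the published
weight hierarchy, and the reference pot experiment (a 5 mg/kg Cd-spiked
soil growing ryegrass, treated with 1 % reed biochar or 1 % hydroxyapatite)
ship as packaged fixtures. The comprehensive weights are questionnaire
output and ship as data — they are not recomputed by this package.

## Worked example

Score the packaged pot experiment — untreated control vs hydroxyapatite
(HAP) treatment:

```python
from stabeval import (load_registry, load_table10, paper_weights,
                      evaluate_treatment, compare_treatments)

registry = load_registry()
measurements = load_table10()
weights = paper_weights("printed")

before = evaluate_treatment("control", measurements, registry, weights)
after = evaluate_treatment("HAP", measurements, registry, weights)
print(before.composite, before.grade)   # 0.164... V
print(after.composite, after.grade)     # 0.474... III
print(compare_treatments(before, after).verdict)  # excellent
```

or from the shell:

```
$ stabeval evaluate --before before.csv --after after.csv --report report.json
S_before=0.164 (grade V)  S_after=0.474 (grade III)  verdict: excellent
```

The untreated spiked soil scores S = 0.164 (grade V, the worst band): its
available Cd is unreduced (α = 0), the root bio-accumulation factor is 46 %
(score 0.60), and fertility indicators are mediocre. Hydroxyapatite lifts
the score to S = 0.474 (grade III) — a 47.4 % reduction in available Cd
(score 0.63), higher available K, and full marks on amendment safety and
stability. Two grade steps of improvement is the verdict **excellent**; the
reed-biochar treatment in the same fixture improves one step (0.374,
grade IV), verdict **good**.

One judgment matrix, with its consistency report:

```
$ stabeval ahp --matrix criteria.csv --report
{"consistency": {"CI": 0.0, "CR": 0.0, "RI": 0.58, "lambda_max": 3.0,
                 "passed": true},
 "weights": {"soil": 0.571, "crop": 0.286, "amendment": 0.143}}
```

Other commands: `stabeval weights` (aggregate an expert panel),
`stabeval score` (per-indicator scores as CSV), `stabeval simulate`
(synthetic panels/studies), `stabeval fixtures --list`.

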
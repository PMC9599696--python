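# fmascore

Automated scoring of the 30 voluntary items of the Fugl-Meyer Assessment
for the upper extremity (FMA-UE) from motion-sensor recordings.

The FMA-UE is the standard clinical scale for post-stroke upper-limb
motor impairment: 33 items, each rated 0/1/2 by a therapist.  This
package implements a sensor-based scoring pipeline for the 30 voluntary
(non-reflex) items, for researchers in rehabilitation engineering who
want to study or extend automated assessment without access to
restricted patient data:

* **Registry** — the 30 items, their four categories (Shoulder/Elbow,
  Wrist/Hand, Grasp, Coordination/Speed), the 17 motion tasks that cover
  them, and per-item sensor and scoring-method assignments.
* **Preprocessing** — singular spectrum analysis (SSA) denoising of
  every recorded channel (embed in an L×(N−L+1) Hankel matrix, SVD, keep
  the *k* leading components, reconstruct by anti-diagonal averaging;
  defaults L=15, k=2), plus velocity-threshold motion segmentation
  (first/last frame with endpoint speed above the trial mean).
* **Features** — the 36-entry Shoulder/Elbow kinematic vector
  (endpoint path length and speeds, spectral arc length SPARC,
  dimensionless jerk, ROM/extrema/angular-velocity statistics for four
  degrees of freedom, inter-joint coordination, trunk compensation) and
  the per-item wrist/hand angles, grip-force peaks and finger-to-nose
  features.
* **Scoring** — per-item random-forest classifiers (100 trees, 6
  features per split) for the 13 Shoulder/Elbow items; an auditable
  IF-ELSEIF-ELSE rule layer for the other 17, comparing the paretic
  side with the less-affected side (subscript *h*) or a cohort normal
  constant (subscript *N*) and cutting the performance ratio *x_p/ref*
  at λ₁=1/3 and λ₂=2/3.
* **Evaluation** — Pearson correlation of totals, linear-weighted
  Cohen's κ, per-item accuracy/MAE, macro-averaged F1/precision/
  sensitivity/specificity, leave-one-subject-out and simulated-online
  protocols, and the two-stage sample-size utility for Pearson
  correlation study designs.
* **Simulator** — a synthetic hemiparetic-motion generator (skeleton,
  hand and grip recordings on both sides with planted ground-truth
  scores) standing in for the restricted clinical recordings.

## Worked example

```python
from fmascore import simulate_cohort, score_cohort_loocv, item_metrics

cohort = simulate_cohort(20, seed=42)          # 20 simulated patients
reports = score_cohort_loocv([rec for rec, _ in cohort])
ev = item_metrics([r.scores for r in reports],
                  [truth.scores for _, truth in cohort])
print(f"r={ev.pearson_r:.3f} kappa={ev.kappa_linear:.3f} "
      f"acc={ev.segments['all']['accuracy']:.1f}% "
      f"MAE={ev.segments['all']['mae']:.2f}")
```

prints

```
r=0.989 kappa=0.888 acc=90.2% MAE=0.10
```

meaning: across the cohort the automated totals track the planted
reference totals with Pearson r = 0.989, item-level agreement is
"almost perfect" by weighted κ, 90.2% of the 600 item scores match
exactly, and the average error is 0.10 points on the 0–2 scale.  The
same flow is available from the shell:

```bash
fma run --subjects 20 --seed 42 --out results/demo
```

The `examples/` directory holds short narrative scripts for each
capability (end-to-end scoring, SSA denoising, the rule engine, study
design).

## Layout

```
src/fmascore/      registry, io, preprocess, features, scoring,
                   evaluation, synthetic, pipeline, config, cli
src/fmascore/data/rules.json   auditable rule bindings for the 17
                               rule-based items
docs/methods.md    model assumptions, parameter choices, limitations
examples/          narrative scripts, one per capability
tests/             unit, property and acceptance suites
```
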
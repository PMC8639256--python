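# copsway

Fall-risk analysis of center-of-pressure (COP) sway signals.

Quiet-standing balance is commonly assessed with a force plate: the
trajectory of the center of pressure under the feet (the stabilogram)
quantifies postural sway, and differences in its structure separate
older adults at high risk of falling from their peers.  `copsway`
implements a complete analysis pipeline for such recordings, for
researchers in posturography and biomedical signal processing:

1. **Signal I/O** — COP derivation from the six plate channels
   (`COPx = −My/Fz`, `COPy = Mx/Fz`, with a configurable plate-origin
   height), CSV dialects for raw channels and pre-computed COP, and
   organisation of trials by subject × condition (CR, OR, CF, OF —
   eyes Closed/Open on a Rigid surface or Foam mat) with the pooled
   view C4 = CR + OR + CF + OF.
2. **EMD** — empirical mode decomposition by envelope-mean sifting
   into up to six intrinsic mode functions (IMFs) plus a residual,
   with the classic Cauchy stop criterion (SD < 0.2) and the IMF
   extrema/zero-crossing property.
3. **Features** — five statistics per series, on the raw signal and
   on each IMF of both axes (70 coded features per trial,
   `axis.level.feature`):

   | id | feature | definition |
   |----|---------|------------|
   | 1 | RMSD | √mean((x − x̄)²) |
   | 2 | median frequency | half-power frequency of the periodogram |
   | 3 | total power | ∫ one-sided spectral density = variance |
   | 4 | ApEn(2, 0.2·STD) | Φ₂ − Φ₃, self-matches included |
   | 5 | SampEn(2, 0.2·STD) | −ln(A/B), self-matches excluded |

4. **Group statistics** — per-feature Welch t-tests (fall vs nonfall)
   at α = 0.05, with significant-code counts by signal origin, IMF
   level and feature domain.
5. **Classification** — CART decision trees on the 10 features of one
   decomposition level, repeated 80:20 holdout (20 repeats), reporting
   accuracy = (TP+TN)/N·100, sensitivity = TP/(TP+FN)·100 and
   specificity = TN/(TN+FP)·100 as mean ± SD.
6. **Synthetic cohorts** — a seeded generator of two-group
   posturography datasets (47 nonfall / 29 fall subjects by default)
   with group effects injected into known low-frequency bands and into
   signal regularity, providing ground truth for every stage.

## Worked example

```python
import copsway as cs
from copsway.simulate import CohortSpec, generate_cohort
from copsway.stats import compare_groups, summarize_significance
from copsway.classify import evaluate_repeated

spec = CohortSpec(n_nonfall=12, n_fall=9, trials_per_condition=2,
                  duration=20.0, seed=42)
dataset, truth = generate_cohort(spec)
print(f"{len(dataset.records)} trials "
      f"({spec.n_nonfall} nonfall + {spec.n_fall} fall subjects)")

table = cs.feature_table(dataset.records)
print(summarize_significance({"C4": compare_groups(table)}))

for level in (0, 5):
    report = evaluate_repeated(table, level=level, condition="C4",
                               repeats=20, seed=7)
    acc = report.summary("test")["accuracy"]
    print(f"level {level}: testing accuracy {acc['mean']:.1f}% (SD {acc['sd']:.1f})")
```

prints

```
168 trials (12 nonfall + 9 fall subjects)
             C4
all          44
raw           4
emd_derived  40
imf1          6
imf2          6
imf3          1
imf4          8
imf5         10
imf6          9
time         10
frequency    16
nonlinear    18
level 0: testing accuracy 67.6% (SD 8.6)
level 5: testing accuracy 75.6% (SD 8.8)
```

The generator injected amplitude effects into bands 5–6 (≈1.6 Hz and
0.78 Hz) and a small regularity deficit, so EMD-derived features
dominate the significant-code counts (40 of 44), IMF5 flags all ten of
its codes, and a tree using IMF5-level features classifies unseen
trials ~8 points better than one using raw-signal features.

The same pipeline runs from the shell:

```sh
copsway simulate --out cohort/ --seed 42
copsway features --manifest cohort/manifest.csv --out features.csv
copsway stats --features features.csv --out stats/
copsway classify --features features.csv --level 5 --condition C4 --seed 7
copsway run --out results/          # everything, one report.json
```

Real recordings are consumed through the same manifest scheme
(`path,subject_id,group,condition,trial,sampling_rate`) pointing at
per-trial CSVs in either the `fx,fy,fz,mx,my,mz` or the `cop_x,cop_y`
dialect.

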
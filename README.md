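# octavd

Parafoveal vs. perifoveal macular vessel-density (VD) analysis of en-face
OCTA angiograms, evaluated with patient-grouped SVM classification.

The pipeline mirrors a standard OCTA evaluation chain on 3×3 mm en-face
projections of the three retinal plexuses (SVP, ICP, DCP):

1. **synth** — synthetic fovea-centered angiogram cohorts (random-walk
   vessel networks, avascular center, speckle noise) with a configurable
   two-class structure: "glaucoma" eyes get zone-weighted, plexus-scaled
   segment dropout. No clinical data is required anywhere.
2. **enhance** — multiscale Hessian (Frangi-type) vesselness filtering.
3. **binarize** — global Otsu thresholding of the vesselness map.
4. **regions** — region masks: a parafoveal annulus (default outer radius
   1.45 mm, foveal avascular zone excluded) split into 12 sectors S1–S12,
   and the remaining corner area split into 4 perifoveal quadrants Q1–Q4;
   per-region VD = % vessel pixels.
5. **experiment** — patient-grouped 60/20/20 split, 10 grouped stratified
   folds over the non-test data, SVM hyperparameter selection by mean
   validation AUROC, held-out test evaluation; six methods
   ({SVP, ICP, DCP} × {parafoveal, perifoveal}) share one split and fold
   partition.
6. **stats** — one-way ANOVA over the six methods' fold AUROCs plus
   Bonferroni-corrected pooled-error pairwise t tests.

## CLI

Generate a synthetic cohort (one PNG per eye per plexus + `cohort.csv`):

```sh
octavd synth --config synth.yaml --out scratch/cohort --seed 1
```

`synth.yaml` holds `SynthConfig` field overrides, e.g.

```yaml
image_size_px: 128
pixel_size_mm: 0.0234375   # keeps the 3 mm field of view
n_patients: 75
two_eye_fraction: 0.6
dropout_para: 0.12
dropout_peri: 0.45
plexus_effect_scale: {SVP: 1.0, ICP: 0.65, DCP: 0.4}
```

Run the six-method experiment on that cohort:

```sh
octavd experiment --cohort scratch/cohort --out scratch/results --seed 1
```

This writes `method_metrics.csv` (mean ± SD of AUROC / sensitivity /
specificity / F1 per method, plus test-set metrics), `pairwise_auroc.csv`
and `pairwise_auroc.txt` (Bonferroni-adjusted pairwise comparisons), and a
deterministic `manifest.json`.

## Python API

```python
from octavd import SynthConfig, generate_cohort, run_full_experiment

cfg = SynthConfig(image_size_px=128, pixel_size_mm=3/128,
                  n_patients=75, dropout_peri=0.45, seed=1)
cohort = generate_cohort(cfg)
result = run_full_experiment(cohort, seed=1)
print(result.summary_table())
print(result.pairwise.format_triangle())
```

## Tests

```sh
python -m pytest tests/
```

`tests/test_acceptance.py` holds the acceptance suite (oracle equivalence
for Otsu/AUROC/ANOVA, region partition invariants, leakage guards, null and
designed-effect recovery); the designed-effect criterion re-runs the full
experiment for 10 seeds and dominates the runtime (a few minutes).

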
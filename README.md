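# bvbquant

Quantitative CT morphometry of the bronchovascular bundle (BVB) for staging
diffuse fibrotic occupational lung disease (pneumoconiosis, stages I–III).

Pneumoconiosis distorts the paired bronchus + pulmonary artery and its
connective sheath: airway walls thicken, vascular bifurcation angles drift,
and the peribronchial soft-tissue pattern becomes more complex and diffuse.
`bvbquant` turns these changes into numbers on thin-slice chest CT:

* **MPR / CPR reformation** — trilinear resampling of the HU volume onto
  arbitrary oblique planes, and curved planar reformation perpendicular to a
  smoothed centerline with rotation-minimizing frames, so tortuous bronchi
  are measured in true cross-section.
* **WT/D** — bronchial wall thickness over lumen inner diameter at the
  narrowest cross-section, by full-width-half-maximum (FWHM) ray casting.
* **AVI** — angle variation index: `|θ − 110°|`, the absolute deviation of
  the 3D vascular bifurcation angle (between branch principal directions,
  by the vector method) from the healthy reference of 110°.
* **FD** — box-counting fractal dimension of the supra-threshold (>30 HU)
  soft-tissue pattern in a 2 mm peribronchial annulus.
* **Cuffing sign** — rule-based detector: a >30 HU peribronchial ring
  covering >50% of the circumference, ≥2 mm thick, persisting over more than
  3 consecutive slices.
* **Staging** — z-scoring, L1-penalised (lasso) logistic feature selection
  with 10-fold cross-validated binomial deviance and an unpenalised refit,
  plus the published combined score

  ```
  Logit(P) = 2.327·WT/D + 0.184·AVI + 3.215·FD − 5.871
  ```

  mapped to ordinal stages through two fitted cut-points.
* **Evaluation** — ROC/AUC (Mann–Whitney, DeLong CI, Youden-optimal cutoff),
  Pearson correlation, ICC(2,1), Cohen's/weighted kappa with asymptotic SE,
  and per-stage concordance tables.

No clinical images ship with the package. Instead, `bvbquant.synthetic_data`
generates HU-calibrated digital phantoms (airway tubes with walls and
optional cuffs, bifurcations at exactly known 3D angles, planar textures of
known fractal dimension) and per-patient cohorts drawn from stage-wise
distributions — every measurement stage is validated by recovery against
this machine-readable ground truth.

## Worked example

Simulate a 65-patient cohort (42 stage I, 16 stage II, 7 stage III), score
it with the published combined model, call stages and evaluate:

```sh
bvbquant run --seed 7 --out-dir demo/
```

`demo/report.json` (abridged):

```json
{
 "n": 65,
 "auc": 0.999,
 "auc_ci_95": [0.9961, 1.0],
 "cutoff": 1.4203,
 "sensitivity": 1.0,
 "specificity": 0.9762,
 "youden": 0.9762,
 "per_stage_concordance": {"I": 97.62, "II": 93.75, "III": 100.0},
 "icc": 0.9188,
 "kappa_cuffing": 0.8768
}
```

Reading this: the combined score separates advanced disease (stage II+III)
from stage I with AUC 0.999 on this idealised cohort — higher than on real
patients, because the generator draws features from clean within-stage
normals; the Youden-optimal logit cutoff is 1.42 (sensitivity 100%,
specificity 97.6%); two simulated repeat readings of WT/D agree with
ICC 0.92 and the simulated cuffing-sign readers with κ 0.88. Stage II is
the hardest class for the two-cut ordinal rule, and stage III calls are
perfect — the ordering seen clinically.

The same library functions drive image-side measurements on phantoms:

```python
from bvbquant import (AirwayPhantomSpec, make_airway_phantom)
from bvbquant.pipeline import measure_case
from bvbquant.core_volume import Centerline
import numpy as np

vol = make_airway_phantom(AirwayPhantomSpec(lumen_diameter_mm=4.0,
                                            wall_thickness_mm=1.04))
cl = Centerline(np.outer(np.linspace(-5, 5, 11), [0, 0, 1.0]))
print(measure_case(vol, cl)["wt_d"])   # ~0.26, the phantom's true WT/D
```

## Layout

```
src/bvbquant/
  core_volume.py     volume container, coordinates, windowing, NIfTI I/O
  synthetic_data.py  phantoms, fractal textures, cohort simulation
  reformat.py        oblique MPR, centerline smoothing, CPR
  bvb_metrics.py     WT/D, AVI, FD, cuffing sign
  staging.py         z-scores, lasso selection, combined score, stage calls
  evaluation.py      ROC/AUC, Pearson, ICC, kappa, concordance
  pipeline.py        orchestration + reproducibility manifests
  cli.py             `bvbquant` command-line interface
```

See `docs/methods.md` for the modelling assumptions, parameter defaults and
known limitations.
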
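# nbprox

Quantitative analysis of gene-locus / nuclear-body proximity in 3D
immuno-FISH, with a ground-truth scene simulator, plus the tabular
companions of such a study: cycloheximide-chase half-life fitting,
qPCR relative quantification, dual-reporter folds, grouped Spearman
correlation and promoter/peak interval overlap.

## Who this is for

Labs asking whether a locus (or its transcriptional focus) sits
non-randomly close to a class of nuclear bodies — e.g. a
stress-response gene relative to PML nuclear bodies — and wanting the
measurement chain (segmentation, spot detection, anisotropic-voxel
distances, per-nucleus statistics, CSR null) to be reproducible and
testable without access to the original microscope.

## The statistic

For focus *f* with centroid **x**_f and the bodies **b**_1..**b**_m of
the same nucleus, the observation is the shortest Euclidean distance in
physical micrometres,

    d_f = min_j || x_f − b_j ||,

aggregated per nucleus as the mean over its foci, d̄_n.  Probes are
compared on per-nucleus means (Welch t, two-sided); mean distances
≤ 1.6 µm are classified as associated and ≥ 2.0 µm as unassociated,
the regimes established for this assay family.  A Monte-Carlo null
re-places the foci uniformly over the segmented nucleus (complete
spatial randomness) and reports the add-one empirical p-value
p = (1 + #{null ≤ observed}) / (1 + n_reps).

Because real image stacks of this kind are rarely deposited, every
imaging claim is validated against a synthetic-microscopy simulator
with exact ground truth: ellipsoidal nuclei, Gaussian-PSF point
objects, Poisson + read noise, and either uniform ("csr") or
body-tethered focus placement at a programmed mean distance.

## Worked example

```python
from nbprox.pipeline import PipelineConfig, run_pipeline
from nbprox.scene_sim import SceneConfig
import pandas as pd, json

scene = SceneConfig(field_shape=(32, 352, 352), n_nuclei=3,
                    placement_mode="tethered", tether_mean_um=1.4,
                    n_foci_per_nucleus=3)
cfg = PipelineConfig(out_dir="run", seed=2026, scene=scene, null_reps=999)
report = run_pipeline(cfg)
print(report.counts)
print(pd.read_csv("run/nucleus_summaries.csv"))
print(json.loads(open("run/null_test.json").read()))
```

Running the equivalent driver (`python analysis/02_detect_and_measure.py`)
prints:

```
associated: detected 9 foci / 30 bodies in 3 nucleus; mean distance 1.24 um; CSR-null p = 0.002
   control: detected 9 foci / 30 bodies in 3 nucleus; mean distance 2.79 um; CSR-null p = 0.815
```

Read: in the tethered ("associated") field every simulated focus and
body was recovered, the per-nucleus mean locus-to-body distance is
1.24 µm (associated regime, programmed tether 1.4 µm), and the CSR
null rejects randomness at p = 0.002; in the uniform control the mean
is 2.79 µm and the null is retained (p = 0.815).

## The analysis

Numbered drivers under `analysis/` reproduce the full study at desk
scale, writing tables under `results/`:

| script | what it does |
|---|---|
| `01_simulate_scenes.py` | example associated/control fields with ground truth |
| `02_detect_and_measure.py` | end-to-end pipeline incl. CSR null test |
| `03_proximity_studies.py` | tether-distance recovery, probe-comparison power, null calibration |
| `04_decay_half_life.py` | chase simulation: 10 vs 16 min half-lives, bootstrap comparison |
| `05_tabular_stats.py` | grouped Spearman panel, qPCR folds, reporter folds, promoter/peak overlap |

Each computation lives in `src/nbprox/` (see `docs/methods.md` for the
model, parameter defaults and limitations); the scripts are thin
drivers over `nbprox.studies`.

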
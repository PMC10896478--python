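# fcsconn

Distance-resolved **functional connectivity strength** (FCS) analysis for
resting-state fMRI, with a synthetic-cohort generator that plants known
ground truth.

Cerebral small vessel disease preferentially damages long white-matter
fibres, which predicts that the functional *hubs* of the brain network lose
long-range coupling first. Testing that prediction needs a voxel-wise,
parcellation-free connectivity measure that can be split by anatomical
distance. `fcsconn` provides the full analysis stack for researchers who
want to run — or stress-test — that kind of study:

- **FCS / weighted degree centrality** per grey-matter voxel:
  `FCS(i) = 1/(N−1) Σ_{j≠i, r_ij > r0} atanh(r_ij)` with `r0 = 0.2`,
  computed in streamed blocks (the N×N correlation matrix is never formed);
- the **distance-binned decomposition** `FCS(i,k)` over half-open Euclidean
  distance bins (default 18 × 10 mm, 0–180 mm) sharing the same `1/(N−1)`
  normalization, so bins sum exactly to the full-range map, plus
  short-range (0–100 mm) and long-range (100–180 mm) aggregates;
- temporal preprocessing (volume discard, zero-phase 0.01–0.1 Hz band-pass,
  detrending, nuisance regression);
- voxel-wise **ANCOVA** group maps (group + age + sex + education),
  residual-smoothness estimation, **Monte Carlo cluster-extent correction**
  confined to the analysis mask (per-bin analyses corrected within their
  own bin masks), and voxel-wise **brain–behaviour regression**;
- neuropsychological **composite Z-scores** (direction-aware, control-
  referenced) and cohort-table statistics (pooled t, uncorrected Pearson
  chi-square, ANCOVA);
- a **synthetic two-group cohort generator** with planted hubs,
  distance-dependent coupling, a patient-specific long-range attenuation,
  and a cognitive score generated from each subject's realized hub
  connectivity — so every downstream stage can be validated against ground
  truth.

See `docs/methods.md` for the model, the generator's assumptions, and all
numerical choices.

## Worked example

Simulate a small cohort, run the whole pipeline, and read the report:

```python
from fcsconn.pipeline import PipelineConfig, run_pipeline
from fcsconn.stats import ClusterCorrectionParams
from fcsconn.synthetic import SimulationConfig

config = PipelineConfig(
    simulation=SimulationConfig(
        grid_shape=(56, 12, 10), n_timepoints=160,
        n_patients=12, n_controls=12,
        hub_centers=((4, 5, 4), (12, 5, 4), (40, 5, 4), (48, 5, 4)),
        long_range_attenuation=0.5, seed=1),
    cluster=ClusterCorrectionParams(n_iterations=300),
    seed=1,
)
results = run_pipeline(config, "demo_run")
print(results["cohort_summary"].to_string(index=False))
print(results["bin_counts"].to_string(index=False))
```

The cohort summary is a demographics/cognition table with a group test per
row; the config above prints:

```
                    variable   patients   controls       test        p
                         age 60.3 ± 9.2 70.7 ± 7.5     t-test 0.005981
                   education  9.7 ± 2.6 10.8 ± 4.5     t-test 0.499365
                   sex (M/F)        5/7        3/9 chi-square 0.386476
                        mmse 27.4 ± 3.1 28.6 ± 1.4     ANCOVA 0.098734
             episodic_memory -0.2 ± 0.8  0.4 ± 0.4     ANCOVA 0.006205
                   executive -0.2 ± 0.6  0.1 ± 0.6     ANCOVA 0.409479
information_processing_speed -0.6 ± 0.6  0.9 ± 0.7     ANCOVA 0.000779
                visuospatial -0.4 ± 1.1 -0.1 ± 0.4     ANCOVA 0.971356
```

— patients score significantly lower on information processing speed, the
domain generated from hub connectivity. `bin_counts` is the per-distance-bin
count of cluster-corrected significant voxels; for this cohort it is zero
through the 0–90 mm bins and peaks in the 100–110 mm bin, exactly where the
0.5 attenuation was planted (the attenuated hub pairs sit 108–132 mm apart):

```
 bin  edge_low_mm  edge_high_mm  n_significant_voxels
   9         80.0          90.0                     0
  10         90.0         100.0                   163
  11        100.0         110.0                   773
  12        110.0         120.0                   652
  13        120.0         130.0                   391
  14        130.0         140.0                   204
  15        140.0         150.0                    33
  16        150.0         160.0                     0
```

`demo_run/` also contains the group t-map and cluster table, the
brain–behaviour t-map, per-subject outputs if requested, a PNG of the bin
profile, and a JSON manifest recording every parameter, seed and output.

The same functionality is scriptable from the shell:

```bash
fcsconn simulate --config sim.yaml --out cohort/
fcsconn fcs --in cohort/sub-000_bold.nii.gz --mask cohort/mask.nii.gz \
        --r0 0.2 --bin-width 10 --n-bins 18 --smooth-fwhm 6 --out maps/
fcsconn group-stats --maps ... --mask cohort/mask.nii.gz \
        --design cohort/subjects.tsv --voxel-p 0.05 --alpha 0.05 \
        --iters 1000 --seed 7 --out stats/
fcsconn pipeline --config pipeline.yaml --out run/
```

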
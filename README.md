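# nfbpredict

Multimodal neuroimaging prediction of sensorimotor-rhythm (SMR)
neurofeedback learning performance.

## The problem

EEG neurofeedback (NFB) trains people to up-regulate their own brain
rhythms — here the sensorimotor rhythm, 12–15 Hz over central scalp — by
feeding the band power back to them in real time. A substantial fraction of
trainees never learn to self-regulate, so the practical question is whether
a person's *baseline* brain measurements predict their training success
before a single session is spent. This package implements, as a tested and
reusable pipeline, the full analysis chain needed to study that question:

1. **Feedback engine / learning index.** The online loop band-passes the
   feedback channel (0.5–45 Hz), computes the SMR band power from an FFT of
   the trailing 10-s window every 100 ms, adapts the reward threshold to
   the previous run's median power, and grants a point for every
   above-threshold stretch longer than 1 s. The within-session **learning
   index** is

   `LI = mean over sessions of slope( median SMR power of run r  ~  r )`,

   the OLS slope of per-run median power on run index, averaged across
   sessions.
2. **Baseline features.** Resting EEG relative band powers
   (theta/alpha/SMR/beta over nine scalp ROIs, Welch PSD, per-epoch
   relative power summarized by the across-epoch median); gray/white-matter
   morphometry maps; resting-state fMRI ALFF/fALFF/ReHo maps
   (z-standardized, 6-mm smoothed per convention) and 8-mm spherical-ROI
   functional connectivity with Fisher-z transform.
3. **Screening.** Spearman + Benjamini–Hochberg FDR for the EEG cells;
   mass-univariate regression on LI with age/sex covariates and
   Freedman–Lane permutation inference (voxel p < 0.005, 26-connected
   clusters ≥ 50 voxels) for the maps; partial Spearman (age/sex
   controlled, p < 0.005) for connectome edges.
4. **Prediction.** Leave-one-out cross-validated regression (linear SVR,
   linear regression, ARD regression, random forest) of LI from each
   single-modality feature set and from their concatenation, scored by MAE
   and the Pearson correlation of predicted vs. actual LI; feature sets are
   compared with Steiger's z-test for dependent correlations.

Because no public dataset accompanies the design, the package ships a
first-class **synthetic cohort generator** that plants known
feature–learning relations (via a Gaussian copula on ranks) into raw
signals of every modality, so each stage can be validated against ground
truth.

## Worked example

```python
import warnings
from nfbpredict import (NfbLearningModel, PipelineConfig,
                        CohortConfig, PlantedEffect)

config = CohortConfig(
    n_participants=27, n_sessions=3, runs_per_session=12,
    run_duration_s=30.0, fs_nfb=250.0, fs_eeg=250.0, eeg_duration_s=30.0,
    grid_shape=(12, 12, 12), n_volumes=100, n_rois=10,
    effect_map=(
        PlantedEffect("eeg_power", {"roi": "left central"}, 0.8),
        PlantedEffect("gmv", {"center": (4, 6, 6), "radius": 2.3}, 0.7),
        PlantedEffect("fc", {"edge": ("roi000", "roi003")}, 0.7),
    ),
    seed=1,
)
model, truth = NfbLearningModel.simulate(config)
results = model.fit(PipelineConfig(n_perm=2000, models=("svr_linear",),
                                   nfft=256, seed=1))
print(results.summary())
```

prints

```
NFB learning prediction summary
================================================
participants: 27
positive LI: 21/27
LI Shapiro-Wilk p: 0.6504

selected EEG cells (FDR): 4
gmv clusters: 1 positive, 0 negative
wmv clusters: 0 positive, 0 negative
alff clusters: 0 positive, 0 negative
selected FC edges: 1

feature_set      model    mae  pearson_r  steiger_z_vs_multimodal  steiger_p
        eeg svr_linear 0.6208     0.6255                   2.2302     0.0257
       smri svr_linear 0.6232     0.6601                   1.7837     0.0745
       alff svr_linear 0.8344     0.2091                   3.3595     0.0008
         fc svr_linear 0.7428     0.4357                   2.6357     0.0084
 multimodal svr_linear 0.4464     0.8106                      NaN        NaN
```

Reading the output: 21 of the 27 simulated participants have a positive
learning index (they "learned"); the planted left-central SMR correlate
survives FDR screening; the planted gray-matter cluster and connectome edge
are recovered; and the multimodal feature set predicts the learning index
better (MAE 0.45, r 0.81 on z-scored LI) than any single modality
(MAE 0.62–0.83, r 0.21–0.66), with Steiger tests quantifying each gap. The
estimated LI tracks the planted true slope at Spearman ρ ≈ 0.999.
`results.plot_predictions()` draws the predicted-vs-actual scatter per
feature set.

The same pipeline runs from files via the CLI:

```bash
nfbpredict synth --config cohort.json --out cohort/ --seed 1
nfbpredict all cohort/ --out analysis/ --n-perm 2000
```

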
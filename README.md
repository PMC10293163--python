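# amyeeg

A quantitative-EEG (QEEG) pipeline for screening brain amyloid pathology in
pre-dementia populations — people with subjective cognitive decline (SCD) or
mild cognitive impairment (MCI) — from resting-state, eyes-closed,
19-channel EEG alone.  Amyloid PET is the diagnostic reference for
Alzheimer's disease but is costly and invasive; EEG is cheap, safe and
repeatable.  The pathology leaves a reproducible spectral fingerprint:
**stronger relative theta (4-8 Hz) over frontal/frontotemporal sites and
weaker beta2 (15-20 Hz) over both centroparietal areas**, amplified in MCI
relative to SCD.  `amyeeg` turns that fingerprint into a validated
classifier.

The pipeline, end to end:

1. **Features** — per 4-s Hann-tapered epoch at 0.25 Hz resolution:
   relative band power per channel and band
   (`rp_c,b = P_c(b) / Σ_b' P_c(b')`, 19 x 8 bands), and band-averaged
   imaginary coherence per channel pair
   (`iCoh_ij(f) = |Im( S_ij(f) / √(S_ii S_jj) )|`, 171 pairs x 8 bands),
   which ignores zero-lag volume conduction — 1,520 named features.
2. **Normative z-scoring** — each feature standardized against an age- and
   sex-matched healthy stratum, removing normal-ageing slowing.
3. **Selection** — six methods (Welch t, Mann-Whitney, elastic net, random
   forest, GBM, XGBoost) rank amyloid-discriminative features; features the
   same six methods flag for the SCD-vs-MCI contrast are removed, leaving
   amyloid-specific candidates.
4. **Model grid** — 6 feature sets x 8 classifiers = 48 models, 5-fold
   subject-grouped cross-validation, with amyloid-positive training
   recordings split into halves to balance the classes.
5. **Gated validation** — cells above the CV-accuracy gate are refitted and
   scored once on an untouched held-out set (confusion matrix, sensitivity/
   specificity/accuracy, ROC/AUC, per-diagnosis subgroups, topographic
   difference tables).

Clinical EEG with PET ground truth is not redistributable, so the package
includes a first-class synthetic cohort generator (1/f background, per-band
oscillators, lagged coupled sources, blink/EMG/mains artifacts, age/sex
drift, and the planted amyloid signature) that makes every stage testable
at realistic effect sizes.  See `docs/methods.md` for the model and all
numerical choices.

## Worked example

```bash
python examples/04_full_pipeline.py
```

runs the whole analysis on a reduced synthetic cohort (66 subjects, 60 s
recordings) and prints:

```
train 49 / validation 17 subjects
confound set (cognitive-impairment features removed): 195 features
  ttest         30 features; top: rp_P3_beta2, rp_Fp2_theta, rp_P4_beta2
  mannwhitney   32 features; top: rp_P3_beta2, rp_Cz_beta2, rp_P4_beta2
  elasticnet    29 features; top: rp_Fp2_gamma, rp_Fp2_theta, ic_P4-O1_beta1
  rf            34 features; top: rp_Cz_beta2, rp_P3_beta2, rp_F4_theta
  gbm           39 features; top: ic_Pz-T6_alpha2, ic_Fp1-C3_gamma, ic_T4-O1_beta2
  xgb           13 features; top: ic_Pz-T6_alpha2, rp_Cz_beta2, rp_P3_beta2

best gated model: elasticnet features x adaboost (cross-validated accuracy 0.882)
held-out validation: accuracy 94.1%, sensitivity 100.0%, specificity 90.9%, AUC 1.00
```

The selection lists are dominated by exactly the planted physiology —
centroparietal beta2 and frontal theta relative power — and the gated
winner classifies held-out subjects far above chance.  Other examples
cover simulation (`01`), feature extraction (`02`), normative z-scoring
(`03`) and metric computation from a published confusion table (`05`).

A thin CLI mirrors the library for shell use:

```bash
amyeeg simulate --out cohort/ --seed 1          # recordings + manifest
amyeeg features --in cohort/ --out features.csv
amyeeg run --out run/ --seed 1                  # full pipeline + reports
```

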
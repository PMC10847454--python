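# hemogate

Uncertainty-aware prediction of **hematoma expansion (HE)** from admission
non-contrast head CT, exercised end to end on synthetic phantoms.

Hematoma expansion — absolute growth of an intracerebral hemorrhage between
the admission scan and the ~24 h follow-up, binarized here at **≥3 mL** and
**≥6 mL** — is a modifiable risk factor and a potential treatment target.
`hemogate` implements the full automated pipeline a clinical tool would run:

1. **Preprocessing** — brain window-level (level 40, width 80 HU),
   Hounsfield-threshold + morphology skull stripping, resampling to 1 mm
   isotropic voxels, and a fixed-size crop centered on the lesion;
2. **Segmentation** — a 3D encoder–decoder network (additive skip
   connections, soft-Dice loss, Adam, cosine-annealed learning rate,
   sliding-window inference) that produces the hematoma mask;
3. **Classification** — a dual-input 3D DenseNet-style CNN whose two
   channels are the windowed CT crop and the (dilated) lesion mask, trained
   with static ×4 class-balanced augmentation, dynamic per-epoch
   augmentation, BCE-with-logits, Adam (lr 0.001, weight decay 1e-5), step
   learning-rate decay and early stopping; the output is P(HE);
4. **Uncertainty gating** — Monte Carlo dropout (T = 100 stochastic forward
   passes at rate 0.2) yields a per-patient probability distribution; the
   binary Shannon entropy H(p̄) = −p̄·log₂p̄ − (1−p̄)·log₂(1−p̄) of the mean
   prediction scores uncertainty, and patients are excluded one by one in
   decreasing entropy order until a cohort metric (AUC, accuracy) would
   fall below its initial value — leaving a high-confidence sub-cohort;
5. **Evaluation** — Dice/volume similarity, sensitivity/specificity/F1/MCC,
   Mann-Whitney AUC, the DeLong test for correlated ROC curves, continuous
   net reclassification improvement (NRI) and integrated discrimination
   improvement (IDI) against a logistic baseline built from eight visual CT
   markers (blend, hypodensity, swirl, black hole, island, satellite, fluid
   level, irregular shape), and risk-assessment curves.

Since clinical datasets are not distributable, the package ships a
first-class **phantom generator**: synthetic head CTs (skull > 200 HU, brain
≈ 35 HU, heterogeneous hematomas 25–90 HU under 60 mL) with ground-truth
masks, baseline/follow-up pairs whose volume change follows
`ΔV = exp(μ0 + b·h + σZ)` in the lesion-texture heterogeneity `h`, HE
prevalences calibrated to ≈ 16% (≥6 mL) and ≈ 25% (≥3 mL), and noisy visual
marker raters with pairwise kappa in the reported 0.44–0.61 range. See
`docs/methods.md` for the model and every numerical choice.

## Worked example

```python
from hemogate import experiments as ex

# 260 phantoms: 200 train, 60 held out
cohort = ex.prepare_cohort(seed=0)
run = ex.classifier_gate_experiment(seed=0, cohort=cohort)
print(f"test AUC          {run['auc']:.3f}")
print(f"gated AUC         {run['gated_auc']:.3f} "
      f"({run['n_excluded']} excluded, {run['gate_stop_reason']})")
print(f"marker-model AUC  {run['marker_auc']:.3f}")
print(f"Bayes ceiling     {run['oracle_auc']:.3f}")
```

prints (seed 0, ~5 minutes on one CPU):

```
test AUC          0.738
gated AUC         0.740 (0 excluded, metric-decrease)
marker-model AUC  0.757
Bayes ceiling     0.812
```

The dual-input CNN recovers most of the generative signal (the "Bayes
ceiling" is the AUC of the true heterogeneity against the labels on the
same 60 phantoms); the entropy gate never lowers the AUC of the kept
sub-cohort, by construction of its stopping rule (here it stops before the
first exclusion). On 60 held-out phantoms an AUC carries a sampling noise of
roughly ±0.08, so single-seed values move around their expectations — the
marker baseline's population AUC, for instance, is ≈ 0.62, well below the
CNN's, even though this particular draw puts it at 0.757. Segmentation on
20 phantoms (2 patient-level folds) reaches cross-validated Dice ≈ 0.92:

```python
seg = ex.segmentation_recovery(seed=0)
print(round(seg["cv_dice"], 3), round(seg["cv_vs"], 3))   # 0.917 0.956
```

## Command line

```bash
hemogate generate --n 12 --seed 0 --out-dir cohort/      # NIfTI + manifest
hemogate preprocess --ct scan.nii.gz --mask mask.nii.gz --out dual.npz
hemogate train-seg --cohort cohort/ --out seg.npz --folds 2
hemogate segment --model seg.npz --ct scan.nii.gz --out pred.nii.gz
hemogate gate --samples mc.csv --out gate.json
hemogate compare --scores scores.csv                      # DeLong + NRI/IDI
hemogate run config.yaml                                  # full pipeline
```

`hemogate run` consumes a YAML config (validated with every violation
listed; see `hemogate validate-config`) and emits a JSON report with
per-arm AUC/sensitivity/specificity for the input-ablation arms (CT only,
CT + mask, CT + dilated mask), the gate trajectory and the NRI/IDI against
the visual-marker baseline.

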
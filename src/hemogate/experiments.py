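"""Desk-scale study profiles and reproducible experiments.

These are the package's reference experiments on synthetic phantoms: the
segmentation-recovery study, the classifier + uncertainty-gate study with
its input-ablation arms, and the cohort-calibration checks. The miniature
profiles fix the problem sizes (phantom grid 64×64×32 at 1×1×2 mm, 48³
lesion crops, width-8 networks) so every experiment runs in minutes on one
CPU while exercising the identical code paths as the full-scale pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .classifier import (
    AugmentationPolicy,
    ClfConfig,
    mc_dropout_cohort,
    train_classifier,
)
from .metrics import fit_marker_model, roc_auc
from .phantoms import PhantomSpec, iter_cases, simulate_expansion
from .preprocess import preprocess_case, strip_skull
from .segmenter import SegConfig, train_segmenter
from .uncertainty import gate_cohort


def mini_phantom_spec(volume_range=(1.0, 6.0),
                      texture_mode: str = "interior") -> PhantomSpec:
    """Miniature phantom geometry used by the reference experiments."""
    return PhantomSpec(grid_shape=(64, 64, 32), spacing_mm=(1.0, 1.0, 2.0),
                       baseline_volume_range_mL=volume_range,
                       texture_mode=texture_mode)


def mini_seg_config(seed: int = 0) -> SegConfig:
    """Miniature segmentation profile: width-8 single-pooling network trained
    on lesion-biased 32×32×16 patches, window-matched sliding inference."""
    return SegConfig(input_shape=(32, 32, 16), base_width=8, depth=1,
                     convs_per_stage=2, dropout_prob=0.2, lr=3e-3, epochs=8,
                     batch_size=4, train_patch_shape=(32, 32, 16),
                     patches_per_scan=2, seed=seed)


def mini_clf_config(seed: int = 0, channels: str = "ct+mask",
                    coarse: bool = False) -> ClfConfig:
    """Miniature expansion-classifier profile.

    The stem convolution runs at full 1 mm resolution (the hypodense-fraction
    signal does not survive pre-threshold pooling); static augmentation uses
    axis flips only, since interpolating transforms blur the 3-4 mm texture
    features at phantom scale. ``coarse`` switches to a pooled-input profile
    used by the ablation arms (slightly shorter schedule, identical code
    path).
    """
    flips_only = AugmentationPolicy(zoom_range=(1.0, 1.0), rotate_rad=0.0,
                                    shear=0.0)
    return ClfConfig(
        channels=channels, input_pool=0, width=8, growth=4,
        hidden_dense=16, policy=flips_only, lr=2e-3,
        max_epochs=10 if coarse else 22, patience=10 if coarse else 15,
        batch_size=4 if coarse else 8, seed=seed,
    )


# ---------------------------------------------------------------- cohort data

# Cohort counts as printed in the source study's demographics table
# (training/cross-validation n=634 vs independent test n=159).
COHORT_COUNTS = {
    "train_n": 634, "train_he6": 104, "train_he3": 160,
    "test_n": 159, "test_he6": 26, "test_he3": 41,
}


def cohort_prevalences_pct() -> dict[str, float]:
    """HE prevalences (%) recomputed from the printed cohort counts."""
    c = COHORT_COUNTS
    return {
        "train_he6_prevalence_pct": round(100.0 * c["train_he6"] / c["train_n"], 1),
        "train_he3_prevalence_pct": round(100.0 * c["train_he3"] / c["train_n"], 1),
        "test_he6_prevalence_pct": round(100.0 * c["test_he6"] / c["test_n"], 1),
        "test_he3_prevalence_pct": round(100.0 * c["test_he3"] / c["test_n"], 1),
    }


# ---------------------------------------------------------------- calibration

def expansion_calibration(seed: int, n: int = 5000) -> dict[str, float]:
    """Simulated HE prevalences under the default generator (label level)."""
    spec = PhantomSpec()
    rng = np.random.default_rng(seed)
    alpha, beta = spec.heterogeneity_dist_params
    h = rng.beta(alpha, beta, n)
    dv = np.array([
        simulate_expansion(10.0, float(hi), spec.expansion_params, seed=int(s))[0]
        for hi, s in zip(h, rng.integers(0, 2**31, n))
    ])
    return {"he6_prevalence": float((dv >= 6).mean()),
            "he3_prevalence": float((dv >= 3).mean()), "n": n}


def marker_agreement(seed: int, n: int = 500,
                     rater_noise: float = 0.15) -> dict:
    """Pairwise Cohen's kappa per visual marker over a simulated cohort."""
    from sklearn.metrics import cohen_kappa_score

    from .phantoms import (
        _MARKER_OFFSETS,
        _MARKER_SLOPE,
        _SATELLITE_COEF,
        _SATELLITE_MARKER_IDX,
    )

    spec = PhantomSpec()
    rng = np.random.default_rng(seed)
    alpha, beta = spec.heterogeneity_dist_params
    r1, r2 = [], []
    for _ in range(n):
        h = rng.beta(alpha, beta)
        n_sat = int(np.rint(spec.satellite_rate * h))
        eta = _MARKER_OFFSETS + _MARKER_SLOPE * h
        for i in _SATELLITE_MARKER_IDX:
            eta[i] += _SATELLITE_COEF * n_sat
        true = (rng.random(8) < 1.0 / (1.0 + np.exp(-eta))).astype(np.uint8)
        r1.append(true ^ (rng.random(8) < rater_noise))
        r2.append(true ^ (rng.random(8) < rater_noise))
    r1, r2 = np.array(r1), np.array(r2)
    kappas = [float(cohen_kappa_score(r1[:, j], r2[:, j])) for j in range(8)]
    return {"kappas": kappas,
            "n_in_band": int(sum(0.44 <= k <= 0.61 for k in kappas))}


# ---------------------------------------------------------------- segmentation

def segmentation_recovery(seed: int = 0, n_phantoms: int = 20,
                          folds: int = 2) -> dict:
    """Cross-validated hematoma segmentation on miniature phantoms.

    Trains the miniature network on baseline + follow-up scans of
    ``n_phantoms`` phantoms with patient-level folds and reports the
    fold-held-out Dice and volume similarity.
    """
    spec = mini_phantom_spec(volume_range=(2.0, 10.0))
    cfg = mini_seg_config(seed=seed)
    cases, pids = [], []
    for case in iter_cases(n_phantoms, spec, seed=seed):
        for scan, mask in ((case.baseline_ct, case.baseline_mask),
                           (case.followup_ct, case.followup_mask)):
            vol, _ = strip_skull(scan)
            cases.append((vol, mask))
            pids.append(case.case_id)
    res = train_segmenter(cases, cfg, folds=folds, seed=seed,
                          patient_ids=pids, refit=False)
    dice = float(np.mean([m["dice"] for m in res.fold_metrics]))
    vs = float(np.mean([m["vs"] for m in res.fold_metrics]))
    return {"cv_dice": dice, "cv_vs": vs, "fold_metrics": res.fold_metrics,
            "final_train_loss": res.loss_log[-1]["loss"],
            "n_scans": len(cases), "model": res.model, "config": cfg}


# ---------------------------------------------------------------- classifier

@dataclass
class PreparedCohort:
    duals: list                     # DualInput per case (ct + lesion mask)
    labels: np.ndarray
    h: np.ndarray
    markers: np.ndarray             # adjudicated, (n, 8)
    ids: list


def prepare_cohort(seed: int, n: int = 260, label: str = "he6",
                   texture_mode: str = "interior",
                   volume_range=(1.0, 6.0),
                   crop_shape=(48, 48, 48)) -> PreparedCohort:
    """Generate and preprocess a phantom cohort once for all classifier arms.

    """
    spec = mini_phantom_spec(volume_range=volume_range,
                             texture_mode=texture_mode)
    box = tuple(int(round(c * 1.5)) for c in crop_shape)
    duals, labels, hs, markers, ids = [], [], [], [], []
    for case in iter_cases(n, spec, seed=seed):
        d = preprocess_case(case.baseline_ct, case.baseline_mask,
                            channel2="mask", resample_shape=(64, 64, 64),
                            box_shape=box, crop_shape=crop_shape)
        d.id = case.case_id
        duals.append(d)
        labels.append(int(getattr(case, label)))
        hs.append(case.h)
        markers.append(case.markers)
        ids.append(case.case_id)
    return PreparedCohort(duals=duals, labels=np.array(labels),
                          h=np.array(hs), markers=np.stack(markers), ids=ids)


def _fit_and_score(duals, labels, idx_fit, idx_val, idx_test, cfg: ClfConfig):
    train = [(duals[i], int(labels[i])) for i in idx_fit]
    val = [(duals[i], int(labels[i])) for i in idx_val]
    res = train_classifier(train, val, cfg)
    x_test = np.stack([duals[i].stacked("ct+mask") for i in idx_test])
    if cfg.channels == "ct":
        x_test = x_test[:, :1]
    p = res.model.predict_proba(x_test.astype(np.float32))
    return res, p


def classifier_gate_experiment(seed: int = 0, cohort: PreparedCohort | None = None,
                               n_train: int = 200, n_test: int = 60,
                               gate_t: int = 100) -> dict:
    """Train the miniature dual-input classifier, then entropy-gate the test set.

    Returns test AUC, the gate trajectory summary and the visual-marker
    logistic baseline on the same held-out phantoms.
    """
    cohort = cohort or prepare_cohort(seed)
    y = cohort.labels
    idx_train = np.arange(n_train)
    idx_test = np.arange(n_train, n_train + n_test)
    rng = np.random.default_rng(seed)
    # stratified 80/20 fit/val split of the training phantoms
    pos = idx_train[y[idx_train] == 1]
    neg = idx_train[y[idx_train] == 0]
    rng.shuffle(pos)
    rng.shuffle(neg)
    n_vp = max(len(pos) // 5, 1)
    n_vn = max(len(neg) // 5, 1)
    idx_val = np.concatenate([pos[:n_vp], neg[:n_vn]])
    idx_fit = np.concatenate([pos[n_vp:], neg[n_vn:]])

    cfg = mini_clf_config(seed=seed)
    res, p_test = _fit_and_score(cohort.duals, y, idx_fit, idx_val, idx_test, cfg)
    y_test = y[idx_test].astype(bool)
    auc = roc_auc(y_test, p_test)

    x_test = np.stack([cohort.duals[i].stacked("ct+mask") for i in idx_test])
    samples = mc_dropout_cohort(res.model, x_test.astype(np.float32),
                                [cohort.ids[i] for i in idx_test],
                                t=gate_t, dropout_rate=cfg.dropout, seed=seed)
    gate = gate_cohort(samples, y_test, max_exclude_frac=0.25)

    marker_model = fit_marker_model(cohort.markers[idx_train], y[idx_train])
    p_mark = marker_model.predict_proba(cohort.markers[idx_test])
    return {
        "auc": float(auc),
        "gated_auc": float(gate.final["auc"]),
        "initial_auc": float(gate.initial["auc"]),
        "n_excluded": len(gate.excluded_ids),
        "gate_stop_reason": gate.stop_reason,
        "entropy_threshold": float(gate.entropy_threshold),
        "marker_auc": float(roc_auc(y_test, p_mark)),
        "oracle_auc": float(roc_auc(y_test, cohort.h[idx_test])),
        "epochs_run": len(res.log),
        "p_test": p_test,
        "p_marker": p_mark,
        "y_test": y_test,
        "model": res.model,
    }


def input_ablation(seed: int, cohort: PreparedCohort,
                   n_train: int = 200, n_test: int = 60) -> dict:
    """Dual-input vs CT-only arms on shared phantoms (coarse profile).

    Both arms share the cohort, split and every hyperparameter except the
    input channels, so the comparison isolates the value of the mask channel.
    Run it on a rim-signal cohort (``rim_ablation_cohort``): there the
    discriminative texture sits at the lesion margin, where it is nearly
    invisible without the mask channel delineating the boundary.
    """
    y = cohort.labels
    idx_test = np.arange(len(y) - n_test, len(y))
    idx_train = np.arange(n_train)
    rng = np.random.default_rng(seed)
    pos = idx_train[y[idx_train] == 1]
    neg = idx_train[y[idx_train] == 0]
    rng.shuffle(pos)
    rng.shuffle(neg)
    idx_val = np.concatenate([pos[:max(len(pos) // 5, 1)],
                              neg[:max(len(neg) // 5, 1)]])
    idx_fit = np.setdiff1d(idx_train, idx_val)

    out = {}
    y_test = y[idx_test].astype(bool)
    for arm, channels in (("dual", "ct+mask"), ("ct_only", "ct")):
        cfg = mini_clf_config(seed=seed, channels=channels, coarse=True)
        _, p = _fit_and_score(cohort.duals, y, idx_fit, idx_val, idx_test, cfg)
        out[f"auc_{arm}"] = float(roc_auc(y_test, p))
    return out


def rim_ablation_cohort(seed: int) -> PreparedCohort:
    """Rim-signal cohort for the input-ablation experiment."""
    return prepare_cohort(seed=seed, texture_mode="rim")
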
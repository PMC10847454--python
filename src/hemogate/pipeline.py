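"""End-to-end pipeline wiring and configuration.

Stages: generate phantoms → skull-strip/resample/window → train segmenter →
infer masks → build dual inputs → train expansion classifier (one run per
input arm) → Monte-Carlo-dropout gating on the held-out cohort → evaluation
against the visual-marker logistic baseline (DeLong, NRI/IDI, risk curves).

Every stage's randomness is derived deterministically from the global seed;
stages persist their outputs under a content hash of the configuration that
produced them, so a rerun with an unchanged config resumes instead of
recomputing.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .classifier import (
    AugmentationPolicy,
    ClfConfig,
    mc_dropout_cohort,
    train_classifier,
)
from .errors import ConfigError
from .metrics import (
    ConfusionCounts,
    classification_metrics,
    delong_compare,
    fit_marker_model,
    reclassification_metrics,
    roc_auc,
    youden_cutoff,
)
from .phantoms import PhantomSpec, iter_cases
from .preprocess import (
    apply_window,
    crop_dual_input,
    resample_isotropic,
    strip_skull,
)
from .segmenter import SegConfig, infer_mask, train_segmenter
from .uncertainty import gate_cohort

ARMS = ("ct", "ct+mask", "ct+dilated_mask")


@dataclass
class GateParams:
    t: int = 100
    dropout_rate: float = 0.2
    max_exclude_frac: float = 0.25
    cutoff: float = 0.5
    tolerance: float = 1e-9
    rounded: bool = False


@dataclass
class PreprocParams:
    resample_shape: tuple[int, int, int] = (214, 214, 98)
    box_shape: tuple[int, int, int] = (192, 192, 96)
    crop_shape: tuple[int, int, int] = (128, 128, 96)
    dilation_radius_mm: float = 10.0


@dataclass
class RunConfig:
    out_dir: str = "runs/default"
    n_cases: int = 12
    seed: int = 0
    label: str = "he6"                    # "he6" or "he3"
    test_frac: float = 0.2
    mask_source: str = "auto"             # "auto" (segmenter) or "ground_truth"
    final_arm: str = "ct+dilated_mask"    # arm used for gating
    arms: tuple[str, ...] = ARMS
    seg_folds: int = 2
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    preproc: PreprocParams = field(default_factory=PreprocParams)
    seg: SegConfig = field(default_factory=SegConfig)
    clf: ClfConfig = field(default_factory=ClfConfig)
    gate: GateParams = field(default_factory=GateParams)

    def stage_seed(self, stage: str) -> int:
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "little") % (2**31)


def _build(cls, data: dict, path: str, errors: list):
    kwargs = {}
    names = {f.name: f for f in dataclasses.fields(cls)}
    for key, value in data.items():
        if key not in names:
            errors.append(f"{path}{key}: unknown key")
            continue
        f = names[key]
        if dataclasses.is_dataclass(f.type) or f.name in (
            "phantom", "preproc", "seg", "clf", "gate", "policy", "window",
        ):
            sub_cls = {
                "phantom": PhantomSpec, "preproc": PreprocParams,
                "seg": SegConfig, "clf": ClfConfig, "gate": GateParams,
                "policy": AugmentationPolicy,
            }.get(f.name)
            if sub_cls is None:
                kwargs[key] = value
            elif isinstance(value, dict):
                kwargs[key] = _build(sub_cls, value, f"{path}{key}.", errors)
            else:
                errors.append(f"{path}{key}: expected a mapping")
        elif isinstance(value, list):
            kwargs[key] = tuple(value)
        else:
            kwargs[key] = value
    try:
        return cls(**{k: v for k, v in kwargs.items() if v is not None})
    except (TypeError, ValueError) as exc:
        errors.append(f"{path.rstrip('.') or 'config'}: {exc}")
        return None


def validate_config(raw: str | dict) -> RunConfig:
    """Validate raw YAML text (or a dict) into a :class:`RunConfig`.

    All violations are collected and raised together as
    :class:`ConfigError`; defaults are injected for absent keys.
    """
    if isinstance(raw, str):
        try:
            data = yaml.safe_load(raw) or {}
        except yaml.YAMLError as exc:
            raise ConfigError([f"invalid YAML: {exc}"]) from exc
    else:
        data = dict(raw)
    errors: list[str] = []
    cfg = _build(RunConfig, data, "", errors)
    if cfg is not None:
        if cfg.label not in ("he6", "he3"):
            errors.append(f"label: must be he6 or he3, got {cfg.label!r}")
        if not 0 < cfg.test_frac < 1:
            errors.append(f"test_frac: must be in (0,1), got {cfg.test_frac}")
        if cfg.mask_source not in ("auto", "ground_truth"):
            errors.append(f"mask_source: unknown {cfg.mask_source!r}")
        if cfg.final_arm not in cfg.arms:
            errors.append(f"final_arm: {cfg.final_arm!r} not among arms {cfg.arms}")
        if any(a not in ARMS for a in cfg.arms):
            errors.append(f"arms: must be a subset of {ARMS}")
        if cfg.gate.dropout_rate <= 0 or cfg.clf.dropout <= 0:
            errors.append(
                "gate: MC-dropout gating requires a positive dropout rate "
                "in both gate.dropout_rate and clf.dropout"
            )
    if errors:
        raise ConfigError(errors)
    return cfg


def config_to_yaml(cfg: RunConfig) -> str:
    return yaml.safe_dump(asdict(cfg), sort_keys=True)


def _stage_hash(cfg: RunConfig, stage: str, parts: dict) -> str:
    payload = json.dumps({"stage": stage, "seed": cfg.seed, **parts},
                         sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


class _StageCache:
    def __init__(self, root: Path):
        self.root = root
        root.mkdir(parents=True, exist_ok=True)

    def path(self, stage: str, digest: str) -> Path:
        return self.root / f"{stage}-{digest}.json"

    def load(self, stage: str, digest: str):
        p = self.path(stage, digest)
        if p.exists():
            return json.loads(p.read_text())
        return None

    def store(self, stage: str, digest: str, payload: dict):
        self.path(stage, digest).write_text(
            json.dumps(payload, indent=1, default=float)
        )


def _arm_channels(arm: str) -> str:
    return "ct" if arm == "ct" else "ct+mask"


def _arm_channel2(arm: str) -> str:
    return "mask" if arm == "ct+mask" else "dilated_mask"


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline and return (and persist) the run report."""
    out = Path(config.out_dir)
    cache = _StageCache(out / "stages")
    report: dict = {"config_hash": _stage_hash(config, "all", {"cfg": asdict(config)}),
                    "seed": config.seed, "label": config.label, "stages": {}}

    # ---- stage 1: cohort ---------------------------------------------------
    cases = list(iter_cases(config.n_cases, config.phantom,
                            config.stage_seed("cohort")))
    labels = np.array([getattr(c, config.label) for c in cases], dtype=int)
    report["stages"]["cohort"] = {
        "n": len(cases),
        "prevalence": float(labels.mean()),
    }

    # ---- stage 2: split ----------------------------------------------------
    rng = np.random.default_rng(config.stage_seed("split"))
    order = rng.permutation(len(cases))
    n_test = max(int(round(config.test_frac * len(cases))), 1)
    # simple stratified-ish split: alternate classes into test first
    by_class = {c: [i for i in order if labels[i] == c] for c in (0, 1)}
    test_idx = []
    for c in (0, 1):
        take = max(int(round(n_test * len(by_class[c]) / len(cases))), 1)
        test_idx.extend(by_class[c][:take])
    test_idx = sorted(test_idx)
    train_idx = sorted(set(range(len(cases))) - set(test_idx))

    # ---- stage 3: segmentation --------------------------------------------
    stripped = {}
    for i, case in enumerate(cases):
        vol, _ = strip_skull(case.baseline_ct)
        stripped[i] = vol
    masks = {i: cases[i].baseline_mask for i in range(len(cases))}
    if config.mask_source == "auto":
        from .segmenter import UNet3D

        seg_digest = _stage_hash(config, "seg", {
            "seg": asdict(config.seg), "phantom": asdict(config.phantom),
            "n": config.n_cases, "folds": config.seg_folds,
        })
        ckpt_dir = out / "checkpoints"
        ckpt_dir.mkdir(parents=True, exist_ok=True)
        seg_ckpt = ckpt_dir / f"segmenter-{seg_digest}.npz"
        seg_meta = cache.load("seg", seg_digest)
        if seg_ckpt.exists() and seg_meta is not None:
            seg_model = UNet3D.load(seg_ckpt)
            report["stages"]["segmentation"] = {**seg_meta, "resumed": True}
        else:
            seg_cases, pids = [], []
            for i in train_idx:
                svol, _ = strip_skull(cases[i].followup_ct)
                seg_cases.append((stripped[i], cases[i].baseline_mask))
                seg_cases.append((svol, cases[i].followup_mask))
                pids += [cases[i].case_id] * 2
            seg_res = train_segmenter(seg_cases, config.seg, folds=config.seg_folds,
                                      seed=config.stage_seed("seg"), patient_ids=pids)
            seg_model = seg_res.model
            seg_meta = {
                "fold_metrics": seg_res.fold_metrics,
                "final_loss": seg_res.loss_log[-1]["loss"],
            }
            cache.store("seg", seg_digest, seg_meta)
            seg_model.save(seg_ckpt)
            report["stages"]["segmentation"] = seg_meta
        from scipy import ndimage as ndi

        # automated masks must be usable by the lesion-centered crop; keep
        # the largest component and fall back to ground truth when the
        # prediction is empty, implausibly large, or does not fit the crop
        n_fallback = 0
        crop_mm = np.asarray(config.preproc.crop_shape, dtype=float)
        for i in range(len(cases)):
            pred = infer_mask(seg_model, stripped[i], config.seg)
            vals = pred.mask.values
            lab, nlab = ndi.label(vals)
            if nlab > 1:
                sizes = ndi.sum_labels(np.ones_like(lab), lab,
                                       index=np.arange(1, nlab + 1))
                vals = (lab == 1 + int(np.argmax(sizes))).astype(np.uint8)
            ok = vals.sum() > 0
            if ok:
                idx = np.argwhere(vals)
                sp = np.asarray(cases[i].baseline_ct.spacing_mm)
                com = idx.mean(axis=0)
                reach_mm = np.maximum(idx.max(axis=0) - com,
                                      com - idx.min(axis=0)) * sp
                vol_mL = vals.sum() * np.prod(sp) / 1e3
                # the crop box is centered on the COM: every voxel must lie
                # within half the crop extent of it
                ok = bool(np.all(reach_mm <= crop_mm / 2 - 2) and vol_mL < 60.0)
            if ok:
                masks[i] = dataclasses.replace(pred.mask, values=vals)
            else:
                n_fallback += 1
        report["stages"]["segmentation"]["n_mask_fallbacks"] = n_fallback

    # ---- stage 4+5: dual inputs and classifier arms ------------------------
    pp = config.preproc
    resampled = {}
    for i in range(len(cases)):
        vol_r, mask_r = resample_isotropic(stripped[i], masks[i],
                                           target_shape=pp.resample_shape,
                                           background=-1000.0)
        resampled[i] = (apply_window(vol_r), mask_r)
    arm_results = {}
    duals_by_arm = {}
    for arm in config.arms:
        duals = {}
        for i in range(len(cases)):
            vol_w, mask_r = resampled[i]
            d = crop_dual_input(
                vol_w, mask_r, dilation_radius_mm=pp.dilation_radius_mm,
                box_shape=pp.box_shape, crop_shape=pp.crop_shape,
                channel2=_arm_channel2(arm),
            )
            d.id = cases[i].case_id
            duals[i] = d
        duals_by_arm[arm] = duals

        clf_cfg = dataclasses.replace(
            config.clf, channels=_arm_channels(arm),
            seed=config.stage_seed(f"clf-{arm}"),
        )
        tr = [(duals[i], int(labels[i])) for i in train_idx]
        n_val = max(len(tr) // 5, 2)
        val, tr_fit = tr[:n_val], tr[n_val:]
        if len({l for _, l in val}) < 2 or len({l for _, l in tr_fit}) < 2:
            val, tr_fit = tr, tr                 # tiny smoke cohorts
        clf_res = train_classifier(tr_fit, val, clf_cfg)
        x_test = np.stack([duals[i].stacked("ct+mask") for i in test_idx])
        x_test = x_test[:, :1] if clf_cfg.channels == "ct" else x_test
        p_test = clf_res.model.predict_proba(x_test.astype(np.float32))
        y_test = labels[test_idx].astype(bool)

        auc = roc_auc(y_test, p_test) if 0 < y_test.sum() < y_test.size else float("nan")
        p_val = clf_res.model.predict_proba(
            np.stack([d.stacked("ct+mask") for d, _ in val]).astype(np.float32)[
                :, :1 if clf_cfg.channels == "ct" else 2]
        )
        cut = youden_cutoff([l for _, l in val], p_val)
        cm = classification_metrics(
            ConfusionCounts.from_predictions(y_test, p_test >= cut))
        arm_results[arm] = {
            "auc": float(auc), "cutoff": cut,
            "sensitivity": cm["sensitivity"], "specificity": cm["specificity"],
            "epochs_run": len(clf_res.log), "best_epoch": clf_res.best_epoch,
            "model": clf_res.model, "p_test": p_test,
        }
        ckpt_dir = out / "checkpoints"
        ckpt_dir.mkdir(parents=True, exist_ok=True)
        clf_res.model.save(ckpt_dir / f"classifier-{arm.replace('+','_')}.npz")
    report["stages"]["classification"] = {
        arm: {k: v for k, v in res.items() if k not in ("model", "p_test")}
        for arm, res in arm_results.items()
    }

    # ---- stage 6: MC dropout + gate ---------------------------------------
    final = arm_results[config.final_arm]
    x_test = np.stack([duals_by_arm[config.final_arm][i].stacked("ct+mask")
                       for i in test_idx]).astype(np.float32)
    if _arm_channels(config.final_arm) == "ct":
        x_test = x_test[:, :1]
    ids = [cases[i].case_id for i in test_idx]
    samples = mc_dropout_cohort(
        final["model"], x_test, ids, t=config.gate.t,
        dropout_rate=config.gate.dropout_rate,
        seed=config.stage_seed("mc"),
    )
    y_test = labels[test_idx].astype(bool)
    gate = None
    if y_test.sum() >= 2 and (~y_test).sum() >= 2:
        gate = gate_cohort(samples, y_test,
                           max_exclude_frac=config.gate.max_exclude_frac,
                           cutoff=config.gate.cutoff,
                           tolerance=config.gate.tolerance,
                           rounded=config.gate.rounded)
        report["stages"]["gate"] = {
            "initial": gate.initial, "final": gate.final,
            "n_excluded": len(gate.excluded_ids),
            "entropy_threshold": gate.entropy_threshold,
            "stop_reason": gate.stop_reason,
        }

    # ---- stage 7: marker baseline and comparison ---------------------------
    markers = np.stack([c.markers for c in cases])
    try:
        mm = fit_marker_model(markers[train_idx], labels[train_idx])
        p_mark = mm.predict_proba(markers[test_idx])
        comparison = {}
        if 0 < y_test.sum() < y_test.size:
            comparison["marker_auc"] = roc_auc(y_test, p_mark)
            comparison["dl_auc"] = final["auc"]
            if np.std(final["p_test"] - p_mark) > 0:
                dl = delong_compare(y_test, final["p_test"], p_mark)
                comparison["delong_p"] = dl["p"]
            rs = reclassification_metrics(y_test, p_mark, final["p_test"])
            comparison["nri"] = rs.nri
            comparison["idi"] = rs.idi
        report["stages"]["comparison"] = comparison
    except Exception as exc:  # marker fit can degenerate on tiny smoke cohorts
        report["stages"]["comparison"] = {"error": str(exc)}

    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(json.dumps(report, indent=1, default=float))
    return report
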
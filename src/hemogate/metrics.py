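"""Evaluation statistics for segmentation and expansion prediction.

Overlap metrics (Dice, volume similarity), confusion-matrix metrics
(sensitivity, specificity, precision, accuracy, F1, Matthews correlation),
ROC/AUC with the Mann-Whitney tie convention, the DeLong test for two
correlated ROC curves, continuous (category-free) net reclassification
improvement and integrated discrimination improvement, risk-assessment
curves, the visual-marker logistic baseline, and stratified splitting.

Undefined metrics (zero denominators) are reported as ``nan`` and flagged,
never silently coerced to 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.model_selection import StratifiedKFold, train_test_split

from .errors import (
    DegenerateTestError,
    SeparationError,
    StratificationError,
    UndefinedMetricError,
)


# ---------------------------------------------------------------- overlap

def overlap_metrics(a: np.ndarray, b: np.ndarray,
                    spacing_mm=(1.0, 1.0, 1.0)) -> tuple[float, float]:
    """Dice = 2|A∩B| / (|A|+|B|); VS = 1 − |v1−v2| / (v1+v2).

    ``a`` is the ground-truth foreground mask, ``b`` the prediction. VS
    compares total volumes only and ignores overlap.
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        raise UndefinedMetricError("Dice undefined: both masks empty")
    dice = 2.0 * int((a & b).sum()) / (na + nb)
    vox = float(np.prod(spacing_mm))
    v1, v2 = na * vox, nb * vox
    vs = 1.0 - abs(v1 - v2) / (v1 + v2)
    return dice, vs


# ---------------------------------------------------------------- confusion

@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.tp + self.tn + self.fp + self.fn == 0:
            raise ValueError("confusion table is empty")

    @classmethod
    def from_predictions(cls, labels, predicted) -> "ConfusionCounts":
        y = np.asarray(labels, dtype=bool)
        p = np.asarray(predicted, dtype=bool)
        return cls(tp=int((y & p).sum()), tn=int((~y & ~p).sum()),
                   fp=int((~y & p).sum()), fn=int((y & ~p).sum()))


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def classification_metrics(counts: ConfusionCounts) -> dict[str, float]:
    """Sensitivity, specificity, precision, accuracy, F1 and MCC.

    Any metric whose denominator is zero is returned as ``nan``.
    """
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    sens = _ratio(tp, tp + fn)
    spec = _ratio(tn, tn + fp)
    prec = _ratio(tp, tp + fp)
    acc = _ratio(tp + tn, tp + tn + fp + fn)
    f1 = (2 * prec * sens / (prec + sens)
          if np.isfinite(prec) and np.isfinite(sens) and (prec + sens) > 0
          else float("nan"))
    mcc_den = np.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = ((tp * tn - fp * fn) / mcc_den) if mcc_den > 0 else float("nan")
    return {"sensitivity": sens, "specificity": spec, "precision": prec,
            "accuracy": acc, "f1": f1, "mcc": mcc}


# ---------------------------------------------------------------- ROC / AUC

def _check_two_classes(labels: np.ndarray):
    if labels.all() or not labels.any():
        raise UndefinedMetricError("AUC undefined with a single class")


def roc_auc(labels, scores) -> float:
    """AUC as the Mann-Whitney probability, ties counted 1/2 (midranks)."""
    y = np.asarray(labels, dtype=bool)
    s = np.asarray(scores, dtype=float)
    _check_two_classes(y)
    n1, n0 = int(y.sum()), int((~y).sum())
    ranks = stats.rankdata(s)
    return float((ranks[y].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def roc_curve_points(labels, scores):
    """(fpr, tpr, thresholds) over the unique score cutoffs, plus endpoints."""
    y = np.asarray(labels, dtype=bool)
    s = np.asarray(scores, dtype=float)
    _check_two_classes(y)
    thr = np.concatenate([[np.inf], np.unique(s)[::-1], [-np.inf]])
    tpr = [(s[y] >= t).mean() for t in thr]
    fpr = [(s[~y] >= t).mean() for t in thr]
    return np.asarray(fpr), np.asarray(tpr), thr


def youden_cutoff(labels, scores) -> float:
    """Operating point maximizing sensitivity + specificity − 1."""
    fpr, tpr, thr = roc_curve_points(labels, scores)
    j = tpr - fpr
    best = int(np.argmax(j))
    t = thr[best]
    return float(t) if np.isfinite(t) else 0.5


# ---------------------------------------------------------------- DeLong

def _structural_components(labels: np.ndarray, scores: np.ndarray):
    """Placement values V10 (per positive) and V01 (per negative)."""
    y = labels.astype(bool)
    pos, neg = scores[y], scores[~y]
    # midrank formulation
    v10 = np.array([(s > neg).mean() + 0.5 * (s == neg).mean() for s in pos])
    v01 = np.array([(pos > s).mean() + 0.5 * (pos == s).mean() for s in neg])
    return v10, v01


def delong_compare(labels, scores_a, scores_b) -> dict[str, float]:
    """DeLong test for two correlated (paired) ROC curves.

    Returns AUCs, the structural-components variance of the AUC difference,
    the z statistic and the two-sided normal p-value. Identical scores give
    z = 0, p = 1; zero variance with unequal AUCs raises
    :class:`DegenerateTestError`.
    """
    y = np.asarray(labels, dtype=bool)
    sa = np.asarray(scores_a, dtype=float)
    sb = np.asarray(scores_b, dtype=float)
    if sa.shape != sb.shape or sa.shape[0] != y.shape[0]:
        raise ValueError("scores must be paired per patient")
    _check_two_classes(y)

    v10a, v01a = _structural_components(y, sa)
    v10b, v01b = _structural_components(y, sb)
    auc_a, auc_b = float(v10a.mean()), float(v10b.mean())
    m, n = v10a.size, v01a.size

    # 2x2 placement covariances (ddof=1); a single placement has none
    s10 = np.cov(np.stack([v10a, v10b])) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.stack([v01a, v01b])) if n > 1 else np.zeros((2, 2))
    cov = s10 / m + s01 / n                # covariance of (AUC_a, AUC_b)
    var_diff = float(cov[0, 0] + cov[1, 1] - 2 * cov[0, 1])

    diff = auc_a - auc_b
    if var_diff <= 0:
        if abs(diff) < 1e-12:
            return {"auc_a": auc_a, "auc_b": auc_b, "var_diff": 0.0,
                    "z": 0.0, "p": 1.0}
        raise DegenerateTestError("zero variance of the AUC difference")
    z = diff / np.sqrt(var_diff)
    p = 2.0 * stats.norm.sf(abs(z))
    return {"auc_a": auc_a, "auc_b": auc_b, "var_diff": var_diff,
            "z": float(z), "p": float(p)}


# ---------------------------------------------------------------- NRI / IDI

@dataclass
class ReclassStats:
    nri_event: float
    nri_nonevent: float
    idi_event: float
    idi_nonevent: float
    up_event: np.ndarray = field(repr=False, default=None)
    down_event: np.ndarray = field(repr=False, default=None)

    @property
    def nri(self) -> float:
        return self.nri_event + self.nri_nonevent

    @property
    def idi(self) -> float:
        return self.idi_event + self.idi_nonevent


def reclassification_metrics(labels, p_reference, p_new,
                             cutoffs: tuple[float, ...] | None = None) -> ReclassStats:
    """Continuous NRI and IDI of ``p_new`` over ``p_reference``.

    NRI_event = P(up|event) − P(down|event); NRI_nonevent mirrors it with the
    directions reversed; NRI is their sum (range [−2, 2]). By default "up"
    means any increase in predicted risk (category-free NRI). Supplying
    ``cutoffs`` switches to categorical NRI where up/down are category moves.
    IDI is the change in discrimination slope: (mean new − mean reference
    probability in events) + (mean reference − mean new in nonevents).
    """
    y = np.asarray(labels, dtype=bool)
    pr = np.asarray(p_reference, dtype=float)
    pn = np.asarray(p_new, dtype=float)
    if np.any((pr < 0) | (pr > 1) | (pn < 0) | (pn > 1)):
        raise ValueError("probabilities must be in [0,1]")
    _check_two_classes(y)

    if cutoffs is None:
        up = pn > pr
        down = pn < pr
    else:
        edges = np.sort(np.asarray(cutoffs, dtype=float))
        cr = np.digitize(pr, edges)
        cn = np.digitize(pn, edges)
        up = cn > cr
        down = cn < cr

    nri_event = float(up[y].mean() - down[y].mean())
    nri_nonevent = float(down[~y].mean() - up[~y].mean())
    idi_event = float(pn[y].mean() - pr[y].mean())
    idi_nonevent = float(pr[~y].mean() - pn[~y].mean())
    return ReclassStats(nri_event=nri_event, nri_nonevent=nri_nonevent,
                        idi_event=idi_event, idi_nonevent=idi_nonevent,
                        up_event=up, down_event=down)


def risk_assessment_curves(labels, probabilities, n_thresholds: int = 101):
    """Sensitivity (events) and 1−specificity (nonevents) vs risk threshold.

    Returns a dict with ``thresholds`` in [0, 1], ``event_curve`` (sensitivity
    at each threshold) and ``nonevent_curve`` (1 − specificity). The area
    between the two curves equals the model's discrimination slope, the
    quantity whose between-model difference is the IDI.
    """
    y = np.asarray(labels, dtype=bool)
    p = np.asarray(probabilities, dtype=float)
    _check_two_classes(y)
    thr = np.linspace(0.0, 1.0, n_thresholds)
    event = np.array([(p[y] >= t).mean() for t in thr])
    nonevent = np.array([(p[~y] >= t).mean() for t in thr])
    return {"thresholds": thr, "event_curve": event, "nonevent_curve": nonevent}


def plot_risk_assessment(curve_sets: dict[str, dict], path=None):
    """Risk-assessment plot: event curves (sensitivity) solid, nonevent
    curves (1−specificity) dashed, one color per model.

    ``curve_sets`` maps a model name to the output of
    :func:`risk_assessment_curves`. Returns the matplotlib figure; saves to
    ``path`` when given.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for name, c in curve_sets.items():
        line, = ax.plot(c["thresholds"], c["event_curve"], label=f"{name} (events)")
        ax.plot(c["thresholds"], c["nonevent_curve"], linestyle="--",
                color=line.get_color(), label=f"{name} (nonevents)")
    ax.set_xlabel("risk threshold")
    ax.set_ylabel("proportion at or above threshold")
    ax.legend(fontsize=7)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
    return fig


# ---------------------------------------------------------------- marker model

@dataclass
class MarkerModel:
    """Logistic model over the 8 binary visual markers (plus intercept)."""

    coef: np.ndarray               # intercept first, one slope per kept column
    kept_columns: np.ndarray       # indices of non-constant marker columns
    n_markers: int

    def predict_proba(self, markers) -> np.ndarray:
        x = np.asarray(markers, dtype=float)
        if x.ndim == 1:
            x = x[None, :]
        if x.shape[1] != self.n_markers:
            raise ValueError(f"expected {self.n_markers} marker columns")
        eta = self.coef[0] + x[:, self.kept_columns] @ self.coef[1:]
        return 1.0 / (1.0 + np.exp(-eta))


def fit_marker_model(markers, labels) -> MarkerModel:
    """Maximum-likelihood logistic regression of the expansion label on the
    binary visual markers (no regularization).

    Constant marker columns are dropped (coefficient 0); with all columns
    constant the fit degenerates to an intercept-only model predicting the
    prevalence. Complete separation raises :class:`SeparationError` naming
    the offending marker.
    """
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    x = np.asarray(markers, dtype=float)
    y = np.asarray(labels, dtype=float)
    if x.ndim != 2:
        raise ValueError("markers must be a 2D matrix")
    n, k = x.shape
    kept = np.flatnonzero(x.std(axis=0) > 0)
    if n <= kept.size + 1:
        raise ValueError("need more observations than parameters")

    if kept.size == 0:
        prev = y.mean()
        prev = min(max(prev, 1e-12), 1 - 1e-12)
        coef = np.array([np.log(prev / (1 - prev))])
        return MarkerModel(coef=coef, kept_columns=kept, n_markers=k)

    # name the offending marker on perfect single-marker separation
    for j in kept:
        tab = ConfusionCounts.from_predictions(y, x[:, j] > 0.5)
        if (tab.fp == 0 and tab.fn == 0) or (tab.tp == 0 and tab.tn == 0):
            raise SeparationError(f"marker column {j} perfectly separates the labels")

    design = sm.add_constant(x[:, kept], has_constant="add")
    try:
        with np.errstate(all="ignore"):
            res = sm.Logit(y, design).fit(disp=0, maxiter=200)
    except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
        raise SeparationError(f"logistic fit failed: {exc}") from exc
    fitted = res.predict(design)
    if np.any(fitted <= 1e-10) or np.any(fitted >= 1 - 1e-10):
        raise SeparationError("fitted probabilities at 0/1 indicate separation")
    return MarkerModel(coef=np.asarray(res.params), kept_columns=kept, n_markers=k)


# ---------------------------------------------------------------- splitting

def stratified_split(labels, test_frac: float = 0.2, k_folds: int = 5,
                     seed: int = 0):
    """Stratified test split plus stratified K folds on the remainder.

    Returns ``(test_idx, folds)`` where ``folds`` is a list of ``k_folds``
    disjoint index arrays covering the training portion, each preserving the
    class proportions within one sample.
    """
    y = np.asarray(labels, dtype=int)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise StratificationError("both classes must be present")
    if counts.min() < k_folds:
        raise StratificationError(
            f"smallest class has {counts.min()} samples, fewer than {k_folds} folds"
        )
    idx = np.arange(y.size)
    if test_frac > 0:
        train_idx, test_idx = train_test_split(
            idx, test_size=test_frac, stratify=y, random_state=seed
        )
    else:
        train_idx, test_idx = idx, np.array([], dtype=int)
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    folds = [train_idx[val] for _, val in skf.split(train_idx, y[train_idx])]
    return np.sort(test_idx), [np.sort(f) for f in folds]
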
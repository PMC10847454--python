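"""Monte-Carlo-dropout uncertainty and entropy-gated patient selection.

A trained classifier with dropout re-activated at inference produces, for
each patient, ``T`` stochastic probabilities. Their mean ``p̄`` summarizes
the prediction and the binary Shannon entropy of ``p̄`` (in bits, max 1 at
p̄ = 0.5) quantifies its uncertainty. The gate then excludes patients one by
one in decreasing entropy order, recomputing AUC, accuracy and expansion
prevalence after each exclusion, and stops as soon as a monitored metric
falls below its value on the full cohort (the metric-decreasing exclusion is
reinstated) or an exclusion cap is reached. The entropy threshold reported is
the maximum entropy among kept patients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import UndefinedMetricError
from .metrics import roc_auc


@dataclass
class McDropoutSamples:
    """Per-patient stochastic forward-pass probabilities and their summary."""

    patient_id: str
    probabilities: np.ndarray          # shape (T,)

    def __post_init__(self):
        p = np.asarray(self.probabilities, dtype=float)
        if p.ndim != 1 or p.size < 1:
            raise ValueError("need at least one forward-pass probability")
        if np.any((p < 0) | (p > 1)):
            raise ValueError("probabilities must lie in [0,1]")
        self.probabilities = p

    @property
    def mean_probability(self) -> float:
        return float(self.probabilities.mean())

    @property
    def entropy_bits(self) -> float:
        return binary_entropy(self.mean_probability)


def binary_entropy(p: float | np.ndarray) -> float | np.ndarray:
    """H(p) = −p·log2(p) − (1−p)·log2(1−p), with 0·log2(0) ≡ 0."""
    p = np.asarray(p, dtype=float)
    out = np.zeros_like(p)
    for q in (p, 1.0 - p):
        inner = q > 0
        out = out - np.where(inner, q * np.log2(np.where(inner, q, 1.0)), 0.0)
    return float(out) if out.ndim == 0 else out


def predictive_entropy(samples: McDropoutSamples) -> float:
    """Entropy (bits) of the mean MC-dropout probability (total uncertainty)."""
    return samples.entropy_bits


def mc_dropout_sample(model, dual_input, t: int = 100, dropout_rate: float = 0.2,
                      seed: int = 0, channels: str = "ct+mask") -> McDropoutSamples:
    """T stochastic forward passes for one patient (dropout active at inference).

    ``t`` defaults to 100 passes at dropout rate 0.2. Deterministic given
    ``seed``. A zero dropout rate degenerates to T identical passes and emits
    a warning.
    """
    from .classifier import _select_channels, mc_dropout_cohort

    x = _select_channels(dual_input.stacked("ct+mask")[None], channels)
    return mc_dropout_cohort(model, x.astype(np.float32), [dual_input.id],
                             t=t, dropout_rate=dropout_rate, seed=seed)[0]


def mean_pass_entropy(samples: McDropoutSamples) -> float:
    """Mean of per-pass entropies (aleatoric part); provided as an alternative
    uncertainty score."""
    return float(np.mean(binary_entropy(samples.probabilities)))


@dataclass
class GateResult:
    kept_ids: list[str]
    excluded_ids: list[str]                     # in exclusion order
    entropy_threshold: float                    # max entropy among kept
    trajectory: list[dict] = field(repr=False)  # metrics after each exclusion
    stop_reason: str = ""

    @property
    def initial(self) -> dict:
        return self.trajectory[0]

    @property
    def final(self) -> dict:
        return self.trajectory[-1]


def _cohort_metrics(p_mean: np.ndarray, labels: np.ndarray, cutoff: float) -> dict:
    y = labels.astype(bool)
    if y.all() or not y.any():
        raise UndefinedMetricError("a class was emptied by exclusion")
    return {
        "auc": roc_auc(y, p_mean),
        "accuracy": float(((p_mean >= cutoff) == y).mean()),
        "prevalence": float(y.mean()),
        "n": int(y.size),
    }


def gate_cohort(samples: list[McDropoutSamples], labels,
                max_exclude_frac: float = 0.25,
                cutoff: float = 0.5,
                tolerance: float = 1e-9,
                rounded: bool = False,
                stop_metrics: tuple[str, ...] = ("auc", "accuracy")) -> GateResult:
    """Iterative highest-entropy exclusion with a metric-decrease stopping rule.

    After each exclusion the AUC, the accuracy at ``cutoff`` and the HE
    prevalence of the remaining cohort are recorded. The loop stops — and the
    last exclusion is reinstated — as soon as any metric named in
    ``stop_metrics`` falls more than ``tolerance`` below its full-cohort
    value (``rounded=True`` compares values rounded to 2 decimals instead),
    or when ``max_exclude_frac`` of the cohort has been excluded, or when a
    class would be emptied.

    ``stop_metrics`` defaults to AUC and accuracy. Prevalence is always
    recorded; adding ``"prevalence"`` enforces the literal rule that the HE
    rate must not drop, which halts at the first excluded HE-positive patient.

    Ties in entropy are broken by stable patient order.
    """
    if not 0.0 < max_exclude_frac <= 1.0:
        raise ValueError("max_exclude_frac must be in (0, 1]")
    y = np.asarray(labels, dtype=bool)
    if y.sum() < 2 or (~y).sum() < 2:
        raise ValueError("need at least 2 patients per class")
    unknown = set(stop_metrics) - {"auc", "accuracy", "prevalence"}
    if unknown:
        raise ValueError(f"unknown stop metrics: {sorted(unknown)}")

    ids = [s.patient_id for s in samples]
    p_mean = np.array([s.mean_probability for s in samples])
    ent = np.array([s.entropy_bits for s in samples])
    n = y.size
    cap = int(np.floor(max_exclude_frac * n))

    def compare(value: float, reference: float) -> bool:
        """True when ``value`` has decreased below ``reference``."""
        if rounded:
            return round(value, 2) < round(reference, 2)
        return value < reference - tolerance

    active = np.ones(n, dtype=bool)
    initial = _cohort_metrics(p_mean, y, cutoff)
    trajectory = [initial]
    excluded: list[int] = []
    stop_reason = "cap" if cap == 0 else ""

    while len(excluded) < cap:
        # highest entropy among active; argmax is stable (first max wins)
        cand_idx = np.flatnonzero(active)
        k = cand_idx[int(np.argmax(ent[cand_idx]))]
        active[k] = False
        try:
            m = _cohort_metrics(p_mean[active], y[active], cutoff)
        except UndefinedMetricError:
            active[k] = True
            stop_reason = "class-emptied"
            break
        if any(compare(m[name], initial[name]) for name in stop_metrics):
            active[k] = True
            stop_reason = "metric-decrease"
            break
        excluded.append(k)
        trajectory.append(m)
    else:
        stop_reason = stop_reason or "cap"

    kept = [ids[i] for i in np.flatnonzero(active)]
    thr = float(ent[active].max())
    return GateResult(
        kept_ids=kept,
        excluded_ids=[ids[i] for i in excluded],
        entropy_threshold=thr,
        trajectory=trajectory,
        stop_reason=stop_reason,
    )
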
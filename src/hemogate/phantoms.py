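"""Synthetic head-CT phantom cohorts.

The generator produces baseline/follow-up scan pairs with ground-truth
hematoma masks, expansion labels and noisy visual-marker reads, so that the
whole prediction pipeline can be exercised without patient data. A phantom
consists of an air background (≈ −1000 HU), an ellipsoidal "brain" of soft
tissue around 35 HU, a closed skull shell above 200 HU, and one intracerebral
hematoma whose internal texture is controlled by a heterogeneity parameter
``h`` in [0, 1]:

* a fraction ``0.4·h`` of lesion voxels are hypodense (subacute clot,
  25–40 HU), the remainder hyperdense acute clot (50–90 HU);
* ``round(satellite_rate·h)`` small satellite blobs accompany the main lesion.

Hematoma growth between baseline and follow-up is drawn from a lognormal
model, ``ΔV = exp(μ0 + b·h + σ·Z)`` mL with ``Z ~ N(0,1)``: texture
heterogeneity is the predictive signal, mirroring the clinical premise that
heterogeneous-appearing hematomas are the ones that expand. The default
parameters are calibrated so the simulated prevalence of ≥6 mL expansion is
≈ 16% and of ≥3 mL expansion ≈ 25% (the cohort rates the pipeline assumes)
while heterogeneity carries a usable predictive signal (the Bayes AUC of
``h`` against the ≥6 mL label is ≈ 0.83).

Expansion labels use the absolute-growth definitions: HE≥3 mL and HE≥6 mL,
thresholds inclusive; HE≥6 implies HE≥3 for every case.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import CtVolume, LesionMask, save_nifti
from .errors import SizingError

MARKER_NAMES = (
    "blend",
    "hypodensity",
    "swirl",
    "black_hole",
    "island",
    "satellite",
    "fluid_level",
    "irregular_shape",
)

# logistic propensity of each visual marker: sigmoid(offset + slope*h [+ sat_coef*n_sat])
_MARKER_OFFSETS = np.array([-0.8, -0.4, -0.2, -0.9, -1.0, -1.1, -0.7, -0.3])
_MARKER_SLOPE = 2.0
_SATELLITE_COEF = 0.5          # extra logit for the island / satellite signs
_SATELLITE_MARKER_IDX = (4, 5)

MANIFEST_COLUMNS = (
    ["case_id", "h", "n_satellites", "baseline_mL", "followup_mL",
     "delta_v_mL", "he3", "he6"] + [f"marker_{m}" for m in MARKER_NAMES]
)


@dataclass
class PhantomSpec:
    """Geometry and statistical parameters of the synthetic cohort.

    Defaults are desk-scale: a 160×160×64 grid at 1×1×2 mm (clinical scans
    are 512×512 in-plane; the phantom keeps proportions, not matrix size).
    """

    grid_shape: tuple[int, int, int] = (160, 160, 64)
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 2.0)
    brain_hu_mean: float = 35.0
    brain_hu_sd: float = 5.0
    skull_hu_range: tuple[float, float] = (700.0, 1200.0)
    hematoma_core_hu_range: tuple[float, float] = (50.0, 90.0)
    hypodense_hu_range: tuple[float, float] = (25.0, 40.0)
    baseline_volume_range_mL: tuple[float, float] = (1.0, 30.0)
    heterogeneity_dist_params: tuple[float, float] = (2.0, 5.0)  # Beta(α, β)
    expansion_params: tuple[float, float, float] = (-2.6, 8.0, 1.72)  # (μ0, b, σ)
    satellite_rate: float = 3.0
    # "interior": hypodense voxels follow a smooth random field inside the
    # lesion; "rim": they concentrate at the lesion boundary (subacute clot
    # at the margin), which makes the mask channel decisive for reading the
    # texture fraction
    texture_mode: str = "interior"

    def __post_init__(self):
        lo, hi = self.skull_hu_range
        if lo <= 200.0:
            raise ValueError(f"skull HU range must be entirely >200, got {self.skull_hu_range}")
        for name in ("hematoma_core_hu_range", "hypodense_hu_range"):
            a, b = getattr(self, name)
            if not (0.0 < a < b < 200.0):
                raise ValueError(f"{name} must lie within (0, 200), got {(a, b)}")
        a, b = self.baseline_volume_range_mL
        if not (0.0 < a <= b < 60.0):
            raise ValueError(f"baseline volume range must lie within (0, 60) mL, got {(a, b)}")
        alpha, beta = self.heterogeneity_dist_params
        if alpha <= 0 or beta <= 0:
            raise ValueError("Beta parameters must be positive")
        if self.texture_mode not in ("interior", "rim"):
            raise ValueError(f"unknown texture_mode {self.texture_mode!r}")
        if self.expansion_params[2] < 0:
            raise ValueError("expansion σ must be non-negative")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing must be positive")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))


@dataclass
class PhantomCase:
    """One simulated patient: baseline scan (and optionally its follow-up)."""

    case_id: str
    baseline_ct: CtVolume
    baseline_mask: LesionMask
    h: float
    n_satellites: int
    brain_mask: np.ndarray              # ground-truth construction mask
    skull_mask: np.ndarray
    followup_ct: CtVolume | None = None
    followup_mask: LesionMask | None = None
    delta_v_mL: float | None = None
    he3: bool | None = None
    he6: bool | None = None
    markers: np.ndarray | None = None          # adjudicated, shape (8,)
    rater_markers: np.ndarray | None = None    # shape (n_raters, 8)


@dataclass
class CohortManifest:
    out_dir: Path
    manifest_path: Path
    table: pd.DataFrame
    seed: int


def _grids_mm(spec: PhantomSpec):
    axes = [
        (np.arange(n) - (n - 1) / 2.0) * s
        for n, s in zip(spec.grid_shape, spec.spacing_mm)
    ]
    return np.meshgrid(*axes, indexing="ij", sparse=True)


def _brain_semiaxes_mm(spec: PhantomSpec) -> np.ndarray:
    half_extent = np.array(
        [n * s / 2.0 for n, s in zip(spec.grid_shape, spec.spacing_mm)]
    )
    return 0.78 * half_extent


def simulate_phantom(spec: PhantomSpec, h: float, target_volume_mL: float,
                     seed: int) -> PhantomCase:
    """Simulate the baseline scan of one phantom.

    Builds air background, brain ellipsoid, closed skull shell, one connected
    hematoma of ``target_volume_mL`` (within 10%) plus ``round(satellite_rate·h)``
    satellites; a fraction ≈ ``0.4·h`` of lesion voxels are hypodense.
    """
    if not 0.0 <= h <= 1.0:
        raise ValueError(f"h must be in [0,1], got {h}")
    if not 0.0 < target_volume_mL < 60.0:
        raise ValueError(f"target volume must be in (0, 60) mL, got {target_volume_mL}")
    rng = np.random.default_rng(seed)

    x, y, z = _grids_mm(spec)
    semi = _brain_semiaxes_mm(spec)
    r2 = (x / semi[0]) ** 2 + (y / semi[1]) ** 2 + (z / semi[2]) ** 2
    brain = r2 <= 1.0
    skull = (r2 > 1.0) & (r2 <= 1.18)

    vol = np.full(spec.grid_shape, -1000.0, dtype=np.float32)
    vol[brain] = rng.normal(spec.brain_hu_mean, spec.brain_hu_sd, int(brain.sum()))
    vol[skull] = rng.uniform(*spec.skull_hu_range, int(skull.sum()))

    n_sat = int(np.rint(spec.satellite_rate * h))
    sat_volume = 0.02 * target_volume_mL          # each satellite ≈ 2% of target
    main_volume = target_volume_mL - n_sat * sat_volume

    # main lesion: axis-aligned ellipsoid with mild random axis ratios
    ratios = rng.uniform(0.75, 1.3, 3)
    r_eff = (3.0 * main_volume * 1000.0 / (4.0 * np.pi * np.prod(ratios))) ** (1 / 3)
    lesion_semi = r_eff * ratios
    if np.any(lesion_semi > 0.8 * semi):
        raise SizingError(
            f"lesion semi-axes {lesion_semi} mm exceed the brain "
            f"(semi-axes {semi} mm) on grid {spec.grid_shape}"
        )
    # place the center so the whole lesion stays inside the brain:
    # sufficient condition ||c/S|| + max(l/S) <= 1 for sub-ellipsoid containment
    margin = 0.95 - np.max(lesion_semi / semi)
    if margin <= 0:
        raise SizingError(
            f"lesion semi-axes {lesion_semi} mm too large for brain {semi} mm"
        )
    for _ in range(200):
        u = rng.uniform(-1, 1, 3)
        if np.linalg.norm(u) > 1:
            continue
        center = u * margin * semi
        if np.linalg.norm(center / semi) + np.max(lesion_semi / semi) <= 0.95:
            break
    else:  # pragma: no cover - extremely unlikely with the sizing guard above
        raise SizingError("could not place lesion inside the brain")

    l2 = (
        ((x - center[0]) / lesion_semi[0]) ** 2
        + ((y - center[1]) / lesion_semi[1]) ** 2
        + ((z - center[2]) / lesion_semi[2]) ** 2
    )
    mask = (l2 <= 1.0) & brain

    # satellites: small spheres offset from the main lesion
    sat_r = max((3.0 * sat_volume * 1000.0 / (4.0 * np.pi)) ** (1 / 3), 1.5)
    for _ in range(n_sat):
        for _ in range(100):
            direction = rng.standard_normal(3)
            direction /= np.linalg.norm(direction)
            # satellites sit adjacent to the main lesion (small separation,
            # as in the radiological satellite-sign definition)
            offset = center + direction * (np.max(lesion_semi) + sat_r + rng.uniform(1, 4))
            if np.sum(((np.abs(offset) + sat_r) / semi) ** 2) <= 0.95:
                break
        s2 = ((x - offset[0]) ** 2 + (y - offset[1]) ** 2 + (z - offset[2]) ** 2)
        mask |= (s2 <= sat_r**2) & brain

    got = mask.sum() * spec.voxel_volume_mm3 / 1000.0
    if abs(got - target_volume_mL) > 0.10 * target_volume_mL:
        raise SizingError(
            f"voxelized lesion volume {got:.2f} mL deviates >10% from "
            f"target {target_volume_mL:.2f} mL; grid too coarse for this size"
        )

    _texture_lesion(vol, mask, h, spec, rng)

    case_id = f"case_{seed}"
    return PhantomCase(
        case_id=case_id,
        baseline_ct=CtVolume(vol, spec.spacing_mm, id=f"{case_id}_baseline"),
        baseline_mask=LesionMask(mask.astype(np.uint8), spec.spacing_mm,
                                 id=f"{case_id}_baseline"),
        h=float(h),
        n_satellites=n_sat,
        brain_mask=brain,
        skull_mask=skull,
    )


def _texture_lesion(vol: np.ndarray, mask: np.ndarray, h: float,
                    spec: PhantomSpec, rng: np.random.Generator) -> None:
    """Paint hematoma HU values in-place: hyperdense core with a smooth
    hypodense sub-region covering a fraction ≈ 0.4·h of the lesion."""
    idx = np.flatnonzero(mask)
    n = idx.size
    core_lo, core_hi = spec.hematoma_core_hu_range
    base = rng.uniform(core_lo + 5, core_hi - 15)
    hu = np.clip(rng.normal(base, 4.0, n), core_lo, core_hi)

    frac = 0.4 * h
    if frac > 0 and n > 0:
        if spec.texture_mode == "rim":
            # hypodense voxels concentrate at the lesion margin: rank by
            # depth below the boundary, jittered so the rim is irregular
            depth = ndimage.distance_transform_edt(mask, sampling=spec.spacing_mm)
            vals = depth.flat[idx] + 0.4 * rng.standard_normal(n)
        else:
            noise = rng.standard_normal(vol.shape)
            vals = ndimage.gaussian_filter(noise, sigma=2.0).flat[idx]
        thr = np.quantile(vals, frac)
        hypo = vals <= thr
        lo, hi = spec.hypodense_hu_range
        hu[hypo] = np.clip(rng.normal((lo + hi) / 2.0, 3.0, int(hypo.sum())), lo, hi)
    vol.flat[idx] = hu


def simulate_expansion(baseline_volume_mL: float, h: float,
                       params: tuple[float, float, float], seed: int):
    """Draw the interval volume change ΔV (mL) and the expansion labels.

    ``ΔV = exp(μ0 + b·h + σ·Z)`` with ``Z ~ N(0,1)``; HE labels use the
    inclusive ≥3 mL / ≥6 mL absolute-growth definitions.

    Returns ``(delta_v_mL, followup_volume_mL, he3, he6)``.
    """
    mu0, b, sigma = params
    if sigma < 0:
        raise ValueError("σ must be non-negative")
    if not np.all(np.isfinite([baseline_volume_mL, h, mu0, b, sigma])):
        raise ValueError("inputs must be finite")
    z = np.random.default_rng(seed).standard_normal() if sigma > 0 else 0.0
    delta = float(np.exp(mu0 + b * h + sigma * z))
    return delta, baseline_volume_mL + delta, delta >= 3.0, delta >= 6.0


def grow_mask(mask: LesionMask, delta_v_mL: float,
              allowed: np.ndarray | None = None) -> LesionMask:
    """Grow a lesion mask outward by exactly the voxel count nearest to
    ``delta_v_mL``, adding the closest eligible voxels first (Euclidean
    distance with anisotropic spacing). ``allowed`` restricts growth (e.g. to
    the brain)."""
    extra = int(np.rint(delta_v_mL * 1000.0 / mask.voxel_volume_mm3))
    if extra <= 0:
        return LesionMask(mask.values.copy(), mask.spacing_mm, id=mask.id)
    dist = ndimage.distance_transform_edt(mask.values == 0, sampling=mask.spacing_mm)
    eligible = mask.values == 0
    if allowed is not None:
        eligible &= allowed
    cand = np.flatnonzero(eligible)
    if cand.size < extra:
        raise SizingError(
            f"not enough room to grow lesion by {delta_v_mL:.2f} mL "
            f"({extra} voxels needed, {cand.size} eligible)"
        )
    order = np.argsort(dist.flat[cand], kind="stable")[:extra]
    grown = mask.values.copy()
    grown.flat[cand[order]] = 1
    return LesionMask(grown, mask.spacing_mm, id=mask.id)


def simulate_markers(case: PhantomCase, rater_noise: float = 0.15,
                     n_raters: int = 2, seed: int = 0):
    """Simulate the eight visual CT markers of expansion risk for one case.

    Each marker's true value is Bernoulli with a logistic propensity
    increasing in ``h`` (the island/satellite signs also increase with the
    satellite count). Every rater reads the true marker flipped independently
    with probability ``rater_noise``. The adjudicated read is the first
    rater's, overridden wherever a strict majority of all raters disagrees
    with it (emulating expert consensus review).

    Returns ``(adjudicated (8,), raters (n_raters, 8), true (8,))`` as uint8.
    """
    if not 0.0 <= rater_noise <= 0.5:
        raise ValueError(f"rater_noise must be in [0, 0.5], got {rater_noise}")
    if n_raters < 1:
        raise ValueError("need at least one rater")
    rng = np.random.default_rng(seed)
    eta = _MARKER_OFFSETS + _MARKER_SLOPE * case.h
    for i in _SATELLITE_MARKER_IDX:
        eta[i] += _SATELLITE_COEF * case.n_satellites
    p = 1.0 / (1.0 + np.exp(-eta))
    true = (rng.random(8) < p).astype(np.uint8)
    flips = rng.random((n_raters, 8)) < rater_noise
    raters = (true[None, :] ^ flips).astype(np.uint8)
    votes = raters.sum(axis=0)
    adjudicated = raters[0].copy()
    majority_one = votes * 2 > n_raters
    majority_zero = votes * 2 < n_raters
    adjudicated[majority_one] = 1
    adjudicated[majority_zero] = 0
    return adjudicated, raters, true


def simulate_case(spec: PhantomSpec, seed: int, case_id: str | None = None,
                  rater_noise: float = 0.15, n_raters: int = 2) -> PhantomCase:
    """Simulate one complete baseline + follow-up case with labels and markers."""
    ss = np.random.SeedSequence(seed)
    s_scene, s_h, s_exp, s_mark = (s.generate_state(1)[0] for s in ss.spawn(4))
    rng = np.random.default_rng(s_h)
    alpha, beta = spec.heterogeneity_dist_params
    h = float(rng.beta(alpha, beta))
    target = float(rng.uniform(*spec.baseline_volume_range_mL))

    case = simulate_phantom(spec, h, target, seed=int(s_scene))
    if case_id is not None:
        case.case_id = case_id

    baseline_mL = case.baseline_mask.volume_mL()
    delta, _, he3, he6 = simulate_expansion(
        baseline_mL, h, spec.expansion_params, seed=int(s_exp)
    )
    # growth cannot exceed the skull: cap ΔV at half the free intracranial
    # room (the cap only binds far above both HE thresholds, so labels are
    # recomputed from the capped value without changing their distribution)
    room_mL = (int((case.brain_mask & (case.baseline_mask.values == 0)).sum())
               * spec.voxel_volume_mm3 / 1000.0)
    if delta > 0.5 * room_mL:
        delta = 0.5 * room_mL
        he3, he6 = delta >= 3.0, delta >= 6.0
    fu_mask = grow_mask(case.baseline_mask, delta, allowed=case.brain_mask)

    fu_vol = case.baseline_ct.values.copy()
    new_vox = (fu_mask.values == 1) & (case.baseline_mask.values == 0)
    rng_fu = np.random.default_rng(int(s_exp) + 1)
    lo, hi = spec.hematoma_core_hu_range
    fu_vol[new_vox] = np.clip(
        rng_fu.normal((lo + hi) / 2.0, 4.0, int(new_vox.sum())), lo, hi
    )

    adjudicated, raters, _ = simulate_markers(case, rater_noise, n_raters, seed=int(s_mark))

    case.followup_ct = CtVolume(fu_vol, spec.spacing_mm, id=f"{case.case_id}_followup")
    case.followup_mask = replace(fu_mask, id=f"{case.case_id}_followup")
    case.delta_v_mL = delta
    case.he3 = bool(he3)
    case.he6 = bool(he6)
    case.markers = adjudicated
    case.rater_markers = raters
    return case


def case_seeds(n: int, seed: int) -> list[int]:
    """Per-case seeds derived from one cohort seed (stable prefix property)."""
    ss = np.random.SeedSequence(seed)
    return [int(child.generate_state(1)[0] % (2**31)) for child in ss.spawn(n)]


def iter_cases(n: int, spec: PhantomSpec, seed: int, **kwargs):
    """Yield ``n`` reproducible cases; case ``i`` depends only on (seed, i)."""
    for i, cs in enumerate(case_seeds(n, seed)):
        yield simulate_case(spec, cs, case_id=f"case_{i:04d}", **kwargs)


def manifest_row(case: PhantomCase) -> dict:
    row = {
        "case_id": case.case_id,
        "h": round(case.h, 6),
        "n_satellites": case.n_satellites,
        "baseline_mL": round(case.baseline_mask.volume_mL(), 4),
        "followup_mL": round(case.followup_mask.volume_mL(), 4),
        "delta_v_mL": round(case.delta_v_mL, 4),
        "he3": int(case.he3),
        "he6": int(case.he6),
    }
    for name, v in zip(MARKER_NAMES, case.markers):
        row[f"marker_{name}"] = int(v)
    return row


def generate_cohort(n: int, spec: PhantomSpec, seed: int, out_dir) -> CohortManifest:
    """Write ``n`` baseline+follow-up scan/mask pairs (NIfTI) and a manifest CSV.

    Fully reproducible from ``seed``; the seed is recorded in a comment line
    at the top of the manifest.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create cohort directory {out}: {exc}") from exc

    rows = []
    for case in iter_cases(n, spec, seed):
        stem = out / case.case_id
        save_nifti(f"{stem}_baseline_ct.nii.gz", case.baseline_ct.values, spec.spacing_mm)
        save_nifti(f"{stem}_baseline_mask.nii.gz", case.baseline_mask.values, spec.spacing_mm)
        save_nifti(f"{stem}_followup_ct.nii.gz", case.followup_ct.values, spec.spacing_mm)
        save_nifti(f"{stem}_followup_mask.nii.gz", case.followup_mask.values, spec.spacing_mm)
        rows.append(manifest_row(case))

    table = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    buf = io.StringIO()
    buf.write(f"# seed={seed}\n")
    table.to_csv(buf, index=False)
    manifest_path = out / "manifest.csv"
    manifest_path.write_text(buf.getvalue())
    return CohortManifest(out_dir=out, manifest_path=manifest_path, table=table, seed=seed)


def read_manifest(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
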
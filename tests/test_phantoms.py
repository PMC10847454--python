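"""Synthetic cohort generator: geometry, labels, markers, reproducibility."""

import numpy as np
import pytest
from sklearn.metrics import cohen_kappa_score

from hemogate.errors import SizingError
from hemogate.phantoms import (
    MANIFEST_COLUMNS,
    PhantomSpec,
    generate_cohort,
    grow_mask,
    iter_cases,
    read_manifest,
    simulate_case,
    simulate_expansion,
    simulate_markers,
    simulate_phantom,
)

MINI = dict(grid_shape=(64, 64, 32), spacing_mm=(1.0, 1.0, 2.0),
            baseline_volume_range_mL=(1.0, 6.0))


@pytest.fixture(scope="module")
def mini_spec():
    return PhantomSpec(**MINI)


class TestSpecValidation:
    def test_defaults_valid(self):
        PhantomSpec()

    @pytest.mark.parametrize("bad", [
        dict(skull_hu_range=(150.0, 1200.0)),
        dict(hematoma_core_hu_range=(50.0, 250.0)),
        dict(hypodense_hu_range=(-5.0, 40.0)),
        dict(baseline_volume_range_mL=(1.0, 80.0)),
        dict(heterogeneity_dist_params=(0.0, 5.0)),
        dict(expansion_params=(0.0, 1.0, -0.1)),
    ])
    def test_invariants_rejected(self, bad):
        with pytest.raises(ValueError):
            PhantomSpec(**{**MINI, **bad})


class TestSimulatePhantom:
    def test_homogeneous_lesion_has_tight_hu_spread(self, mini_spec):
        case = simulate_phantom(mini_spec, h=0.0, target_volume_mL=5.0, seed=1)
        hu = case.baseline_ct.values[case.baseline_mask.values == 1]
        assert hu.std() < 8.0

    def test_tissue_hu_ranges_by_construction(self, mini_spec):
        case = simulate_phantom(mini_spec, h=0.6, target_volume_mL=4.0, seed=2)
        vals = case.baseline_ct.values
        assert np.all(vals[case.skull_mask] > 200.0)
        lesion_hu = vals[case.baseline_mask.values == 1]
        assert np.all((lesion_hu > 0.0) & (lesion_hu < 200.0))
        outside = vals[~(case.brain_mask | case.skull_mask)]
        assert np.all(outside == -1000.0)

    def test_hypodense_fraction_tracks_heterogeneity(self, mini_spec):
        case = simulate_phantom(mini_spec, h=1.0, target_volume_mL=10.0, seed=7)
        hu = case.baseline_ct.values[case.baseline_mask.values == 1]
        lo, hi = mini_spec.hypodense_hu_range
        frac = ((hu >= lo) & (hu <= hi)).mean()
        assert 0.3 <= frac <= 0.5

    def test_mask_volume_within_tolerance(self, mini_spec):
        for seed, target in [(3, 2.0), (4, 5.0), (5, 10.0)]:
            case = simulate_phantom(mini_spec, h=0.5, target_volume_mL=target,
                                    seed=seed)
            got = case.baseline_mask.volume_mL()
            assert abs(got - target) <= 0.10 * target

    def test_mask_connected_plus_satellites(self, mini_spec):
        from scipy import ndimage
        case = simulate_phantom(mini_spec, h=1.0, target_volume_mL=8.0, seed=9)
        _, n_comp = ndimage.label(case.baseline_mask.values)
        assert 1 <= n_comp <= 1 + case.n_satellites
        assert case.n_satellites == round(mini_spec.satellite_rate * 1.0)

    def test_rim_texture_concentrates_at_boundary(self):
        from scipy import ndimage
        spec = PhantomSpec(**{**MINI, "texture_mode": "rim"})
        case = simulate_phantom(spec, h=1.0, target_volume_mL=5.0, seed=7)
        mask = case.baseline_mask.values.astype(bool)
        hu = case.baseline_ct.values
        lo, hi = spec.hypodense_hu_range
        hypo = mask & (hu >= lo) & (hu <= hi)
        frac = hypo.sum() / mask.sum()
        assert 0.3 <= frac <= 0.5
        # hypodense voxels sit shallower (nearer the boundary) than the rest
        depth = ndimage.distance_transform_edt(mask, sampling=spec.spacing_mm)
        assert depth[hypo].mean() < depth[mask & ~hypo].mean()

    def test_oversized_lesion_raises(self, mini_spec):
        spec = PhantomSpec(**{**MINI, "baseline_volume_range_mL": (1.0, 59.0)})
        with pytest.raises(SizingError):
            simulate_phantom(spec, h=0.0, target_volume_mL=59.0, seed=0)

    def test_preconditions(self, mini_spec):
        with pytest.raises(ValueError):
            simulate_phantom(mini_spec, h=1.5, target_volume_mL=5.0, seed=0)
        with pytest.raises(ValueError):
            simulate_phantom(mini_spec, h=0.5, target_volume_mL=70.0, seed=0)


class TestSimulateExpansion:
    DEFAULTS = PhantomSpec().expansion_params

    def test_closed_form_no_noise_high_h(self):
        # ΔV = exp(μ0 + b·h) when σ=0: with μ0=log 0.5, b=3.5, h=1 the
        # growth is 0.5·e^3.5 ≈ 16.55 mL, above both HE thresholds
        dv, fu, he3, he6 = simulate_expansion(10.0, 1.0, (np.log(0.5), 3.5, 0.0),
                                              seed=0)
        assert dv == pytest.approx(0.5 * np.exp(3.5), rel=1e-12)
        assert he6 and he3
        assert fu == pytest.approx(10.0 + dv)

    def test_closed_form_no_noise_zero_h(self):
        dv, _, he3, he6 = simulate_expansion(10.0, 0.0, (np.log(0.5), 3.5, 0.0),
                                             seed=0)
        assert dv == pytest.approx(0.5)
        assert not he3 and not he6

    def test_he6_prevalence_matches_cohort_rate(self):
        # defaults, h ~ Beta(2,5), n=5000: calibrated to the ~16% rate of
        # >=6 mL expansion (and he6 => he3 everywhere)
        rng = np.random.default_rng(1)
        h = rng.beta(2.0, 5.0, 5000)
        dv = np.array([
            simulate_expansion(10.0, hi, self.DEFAULTS, seed=int(s))[0]
            for hi, s in zip(h, rng.integers(0, 2**31, 5000))
        ])
        he6 = (dv >= 6).mean()
        he3 = (dv >= 3).mean()
        assert 0.13 <= he6 <= 0.20
        assert 0.21 <= he3 <= 0.30

    def test_monotone_expansion_signal_in_h(self):
        # mean ΔV nondecreasing over a 5-point h grid, 200 draws each
        mu0, b, sigma = self.DEFAULTS
        rng = np.random.default_rng(2)
        means = []
        for h in np.linspace(0, 1, 5):
            dvs = [simulate_expansion(5.0, h, (mu0, b, sigma), seed=int(s))[0]
                   for s in rng.integers(0, 2**31, 200)]
            means.append(np.mean(dvs))
        assert all(a <= b for a, b in zip(means, means[1:]))


class TestGrowMask:
    def test_exact_voxel_growth(self, mini_spec):
        case = simulate_phantom(mini_spec, h=0.2, target_volume_mL=4.0, seed=11)
        grown = grow_mask(case.baseline_mask, 3.0, allowed=case.brain_mask)
        added = int(grown.values.sum()) - int(case.baseline_mask.values.sum())
        vox_mL = case.baseline_mask.voxel_volume_mm3 / 1000.0
        assert abs(added * vox_mL - 3.0) <= vox_mL
        assert np.all(grown.values >= case.baseline_mask.values)

    def test_growth_confined_to_brain(self, mini_spec):
        case = simulate_phantom(mini_spec, h=0.2, target_volume_mL=4.0, seed=12)
        grown = grow_mask(case.baseline_mask, 8.0, allowed=case.brain_mask)
        assert not np.any(grown.values.astype(bool) & ~case.brain_mask)

    def test_no_room_raises(self, mini_spec):
        case = simulate_phantom(mini_spec, h=0.0, target_volume_mL=4.0, seed=13)
        with pytest.raises(SizingError):
            grow_mask(case.baseline_mask, 500.0, allowed=case.brain_mask)


class TestMarkers:
    def test_zero_noise_identical_raters(self, mini_spec):
        case = simulate_phantom(mini_spec, h=0.7, target_volume_mL=5.0, seed=3)
        adj, raters, true = simulate_markers(case, rater_noise=0.0, n_raters=3,
                                             seed=5)
        assert np.array_equal(raters[0], raters[1])
        assert np.array_equal(raters[0], raters[2])
        assert np.array_equal(adj, true)

    def test_pairwise_kappa_in_reported_range(self, mini_spec):
        # simulated raters should agree like the human readers did
        # (kappa 0.44-0.61) for most markers
        rng = np.random.default_rng(3)
        r1, r2 = [], []
        for s in rng.integers(0, 2**31, 500):
            case = simulate_case(mini_spec, int(s), n_raters=2)
            r1.append(case.rater_markers[0])
            r2.append(case.rater_markers[1])
        r1, r2 = np.array(r1), np.array(r2)
        in_band = sum(
            0.44 <= cohen_kappa_score(r1[:, j], r2[:, j]) <= 0.61
            for j in range(8)
        )
        assert in_band >= 6

    def test_marker_prevalence_increases_with_h(self, mini_spec):
        rng = np.random.default_rng(6)
        prev = {}
        for h in (0.0, 1.0):
            reads = []
            for s in rng.integers(0, 2**31, 300):
                case = simulate_phantom(mini_spec, h=h, target_volume_mL=4.0,
                                        seed=int(s) % (2**31))
                adj, _, _ = simulate_markers(case, seed=int(s))
                reads.append(adj)
            prev[h] = np.mean(reads, axis=0)
        assert np.all(prev[1.0] > prev[0.0])

    def test_adjudication_majority_overrides_first_rater(self, mini_spec):
        case = simulate_phantom(mini_spec, h=0.5, target_volume_mL=5.0, seed=4)
        # high noise, many raters: adjudicated = majority, not rater 1
        adj, raters, _ = simulate_markers(case, rater_noise=0.45, n_raters=9,
                                          seed=8)
        votes = raters.sum(axis=0)
        expect = np.where(votes * 2 > 9, 1, np.where(votes * 2 < 9, 0, raters[0]))
        assert np.array_equal(adj, expect)

    def test_noise_range_validated(self, mini_spec):
        case = simulate_phantom(mini_spec, h=0.5, target_volume_mL=5.0, seed=4)
        with pytest.raises(ValueError):
            simulate_markers(case, rater_noise=0.7)


class TestCohort:
    def test_case_invariants(self, mini_spec):
        for case in iter_cases(8, mini_spec, seed=5):
            vox_mL = case.baseline_mask.voxel_volume_mm3 / 1000.0
            dv_mask = case.followup_mask.volume_mL() - case.baseline_mask.volume_mL()
            assert abs(dv_mask - case.delta_v_mL) <= vox_mL + 1e-9
            assert (not case.he6) or case.he3            # he6 => he3
            assert case.baseline_mask.values.sum() > 0
            assert case.followup_mask.values.sum() > 0

    def test_generate_cohort_files_and_manifest(self, mini_spec, tmp_path):
        man = generate_cohort(6, mini_spec, seed=2, out_dir=tmp_path / "c")
        files = sorted((tmp_path / "c").glob("*.nii.gz"))
        assert len(files) == 24                       # 2 scans + 2 masks each
        assert list(man.table.columns) == MANIFEST_COLUMNS
        assert len(man.table) == 6
        header = man.manifest_path.read_text().splitlines()[0]
        assert header == "# seed=2"
        loaded = read_manifest(man.manifest_path)
        assert loaded.shape == man.table.shape

    def test_manifest_byte_identical_across_runs(self, mini_spec, tmp_path):
        a = generate_cohort(4, mini_spec, seed=3, out_dir=tmp_path / "a")
        b = generate_cohort(4, mini_spec, seed=3, out_dir=tmp_path / "b")
        assert a.manifest_path.read_bytes() == b.manifest_path.read_bytes()

    def test_roundtrip_through_nifti(self, mini_spec, tmp_path):
        from hemogate.core import load_ct, load_mask
        generate_cohort(1, mini_spec, seed=4, out_dir=tmp_path)
        vol = load_ct(tmp_path / "case_0000_baseline_ct.nii.gz")
        msk = load_mask(tmp_path / "case_0000_baseline_mask.nii.gz")
        assert vol.spacing_mm == mini_spec.spacing_mm
        assert vol.values.shape == mini_spec.grid_shape
        assert set(np.unique(msk.values)) <= {0, 1}

    def test_case_prefix_stability(self, mini_spec):
        short = [c.delta_v_mL for c in iter_cases(3, mini_spec, seed=6)]
        longer = [c.delta_v_mL for c in iter_cases(5, mini_spec, seed=6)]
        assert short == longer[:3]
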
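"""Synthetic cohort generator: fidelity, determinism and calibration."""

import numpy as np
import pytest
from scipy import ndimage

from segdosim.masks import dice_coefficient, mask_volume
from segdosim.synthetic import (
    CohortConfig,
    DegenerateContourError,
    RadialField,
    fibonacci_directions,
    generate_cohort,
    generate_dose_map,
    generate_true_lesion,
    perturb_mask,
    read_design,
)

from conftest import small_cohort_config


class _ConstantField(RadialField):
    def __init__(self, value):
        super().__init__({})
        self.value = value

    def __call__(self, dirs):
        return np.full(len(np.atleast_2d(dirs)), self.value)


class TestRadialField:
    def test_rms_normalization(self):
        rng = np.random.default_rng(0)
        f = RadialField.random(2.0, rng, lmax=4)
        vals = f(fibonacci_directions(20000))
        assert np.sqrt(np.mean(vals**2)) == pytest.approx(2.0, rel=0.02)
        assert abs(vals.mean()) < 0.05  # degree-0 excluded: mean-zero field

    def test_zero_rms(self):
        f = RadialField.random(0.0, np.random.default_rng(1))
        assert np.allclose(f(fibonacci_directions(100)), 0.0)


class TestGenerateTrueLesion:
    def test_sphere_volume(self):
        t = generate_true_lesion(1.0, 0.0, (1, 1, 1), seed=0)
        assert abs(t.mask.n_voxels - 1000) < 60  # ~1000 voxels, sphere-like
        assert t.true_volume_ml == pytest.approx(1.0, rel=0.05)

    def test_irregular_volume_within_tolerance(self):
        t = generate_true_lesion(50.0, 0.3, (1.5, 1.5, 2.5), seed=7)
        assert 47.5 <= t.true_volume_ml <= 52.5

    def test_connected(self):
        t = generate_true_lesion(20.0, 0.4, (1.5, 1.5, 2.5), seed=3)
        _, n = ndimage.label(t.mask.occupancy)
        assert n == 1

    def test_deterministic(self):
        a = generate_true_lesion(5.0, 0.3, (2, 2, 2), seed=11)
        b = generate_true_lesion(5.0, 0.3, (2, 2, 2), seed=11)
        assert np.array_equal(a.mask.occupancy, b.mask.occupancy)

    def test_volume_below_resolution_rejected(self):
        with pytest.raises(ValueError, match="below grid resolution"):
            generate_true_lesion(0.05, 0.0, (2, 2, 2.5), seed=0)

    def test_size_classes(self):
        small = generate_true_lesion(4.0, 0.0, (1.5, 1.5, 2.5), seed=1)
        large = generate_true_lesion(30.0, 0.0, (1.5, 1.5, 2.5), seed=1)
        assert small.size_class == "small" and large.size_class == "large"


class TestPerturbMask:
    def test_identity_when_unperturbed(self, small_lesion):
        m = perturb_mask(small_lesion, None, 0.0, seed=0)
        assert dice_coefficient(m, small_lesion.mask) == 1.0
        assert np.array_equal(m.occupancy, small_lesion.mask.occupancy)

    def test_session_noise_changes_mask(self, small_lesion):
        rng = np.random.default_rng(0)
        bias = RadialField.random(1.5, rng)
        m1 = perturb_mask(small_lesion, bias, 1.0, seed=1)
        m2 = perturb_mask(small_lesion, bias, 1.0, seed=2)
        assert dice_coefficient(m1, m2) < 1.0

    def test_mean_intra_dice_non_increasing_in_sigma(self, small_lesion):
        """Monte-Carlo sweep: more session noise -> lower intra-pair Dice."""
        sigmas = (0.5, 1.5, 3.0)
        means = []
        for sigma in sigmas:
            vals = []
            for s in range(20):
                a = perturb_mask(small_lesion, None, sigma, seed=(10_000 + s))
                b = perturb_mask(small_lesion, None, sigma, seed=(20_000 + s))
                vals.append(dice_coefficient(a, b))
            means.append(np.mean(vals))
        assert means[0] >= means[1] >= means[2]

    def test_degenerate_contour_raises(self, small_lesion):
        killer = _ConstantField(-1000.0)
        with pytest.raises(DegenerateContourError, match="degenerate contour"):
            perturb_mask(small_lesion, killer, 0.0, seed=0)


class TestGenerateDoseMap:
    def test_uniform_interior_mean(self, small_lesion):
        dm = generate_dose_map(small_lesion, 120.0, 0.0, seed=0, texture_sigma=0.0)
        inside = dm.dose[small_lesion.mask.occupancy]
        assert inside.mean() == pytest.approx(120.0)

    def test_blur_conserves_integral(self):
        t = generate_true_lesion(6.0, 0.2, (2, 2, 2), seed=4, margin_mm=25.0)
        sharp = generate_dose_map(t, 100.0, 0.0, background_fraction=0.0,
                                  seed=1, texture_sigma=0.2)
        blurred = generate_dose_map(t, 100.0, 4.0, background_fraction=0.0,
                                    seed=1, texture_sigma=0.2)
        assert blurred.dose.sum() == pytest.approx(sharp.dose.sum(), rel=1e-3)

    def test_blur_lowers_interior_mean(self, small_lesion):
        means = []
        for psf in (0.0, 3.0, 6.0):
            dm = generate_dose_map(small_lesion, 100.0, psf, background_fraction=0.0,
                                   seed=2, texture_sigma=0.0)
            means.append(dm.dose[small_lesion.mask.occupancy].mean())
        assert means[0] > means[1] > means[2]

    def test_texture_orders_dvh(self, small_lesion):
        dm = generate_dose_map(small_lesion, 100.0, 2.0, seed=3, texture_sigma=0.4)
        inside = dm.dose[small_lesion.mask.occupancy]
        d10 = np.percentile(inside, 90)
        d90 = np.percentile(inside, 10)
        assert d90 < inside.mean() < d10

    def test_oversized_psf_rejected(self, small_lesion):
        with pytest.raises(ValueError, match="psf kernel"):
            generate_dose_map(small_lesion, 100.0, 100.0, seed=0)


class TestGenerateCohort:
    def test_default_design_counts(self):
        cfg = CohortConfig()
        design = read_design(cfg)
        assert len(design) == 140
        assert cfg.reads_per_lesion == 7
        per_lesion = design.groupby("lesion_id").size()
        assert (per_lesion == 7).all()

    def test_single_read_cohort(self):
        cfg = CohortConfig(n_lesions=1, readers={"A": 1}, volume_range_ml=(5.0, 5.0),
                           grid_spacing_mm=(2, 2, 2.5), psf_sigma_mm=3.0, seed=1)
        cohort = generate_cohort(cfg)
        assert len(cohort.reads) == 1
        assert cohort.reads[0].lesion_id == "L01"

    def test_deterministic_volume_tables(self):
        cfg = small_cohort_config(seed=9, n_lesions=2)
        a = generate_cohort(cfg).reads_table()
        b = generate_cohort(small_cohort_config(seed=9, n_lesions=2)).reads_table()
        assert a.equals(b)

    def test_appending_lesions_keeps_existing(self):
        t2 = generate_cohort(small_cohort_config(seed=9, n_lesions=2)).reads_table()
        t3 = generate_cohort(small_cohort_config(seed=9, n_lesions=3)).reads_table()
        assert t3.iloc[: len(t2)].equals(t2)

    def test_reads_match_design(self, small_cohort):
        tab = small_cohort.reads_table()
        design = read_design(small_cohort.config)
        assert (
            tab[["lesion_id", "reader_id", "round"]].to_numpy().tolist()
            == design.to_numpy().tolist()
        )

    def test_volume_fidelity_small_sigmas(self):
        """Mean read volume within 10% of truth when both sigmas <= 1 mm."""
        errs = []
        for seed in range(5):
            cfg = small_cohort_config(seed=100 + seed, n_lesions=2)
            cfg.sigma_inter = 1.0
            cfg.sigma_intra = 0.5
            cohort = generate_cohort(cfg)
            truth = {t.lesion_id: t.true_volume_ml for t in cohort.lesions}
            means = cohort.reads_table().groupby("lesion_id")["volume_ml"].mean()
            errs.extend(abs(means[k] / truth[k] - 1.0) for k in means.index)
        assert np.mean(errs) < 0.10

    def test_intra_dice_one_when_no_session_noise(self):
        cfg = small_cohort_config(seed=77, n_lesions=2)
        cfg.sigma_intra = 0.0
        cohort = generate_cohort(cfg)
        from segdosim.variability import dice_pairs

        intra = dice_pairs(cohort.reads, "intra")
        inter = dice_pairs(cohort.reads, "inter")
        assert all(p.dice == 1.0 for p in intra)
        assert np.mean([p.dice for p in inter]) < 1.0

    def test_lesion_error_carries_id(self):
        cfg = CohortConfig(n_lesions=1, volume_range_ml=(0.01, 0.01),
                           grid_spacing_mm=(2, 2, 2.5), seed=0)
        with pytest.raises(ValueError, match="lesion L01"):
            generate_cohort(cfg)
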
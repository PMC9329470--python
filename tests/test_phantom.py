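"""Phantom generator: geometry, measurement and disease-simulation behavior."""

import numpy as np
import pandas as pd
import pytest
from scipy.ndimage import label as cc_label

from silfat import phantom as ph

COARSE = (6.0, 6.0, 6.0)


class TestGeneratePhantom:
    def test_determinism(self, male_params):
        a = ph.generate_phantom(male_params, spacing=COARSE, seed=3)
        b = ph.generate_phantom(male_params, spacing=COARSE, seed=3)
        assert np.array_equal(a.voxels, b.voxels)
        assert np.array_equal(a.labels, b.labels)

    def test_single_connected_component(self, male_phantom):
        _, n = cc_label(male_phantom.labels > 0, structure=np.ones((3, 3, 3)))
        assert n == 1

    def test_size_factor_grows_every_cross_section(self, male_params):
        import dataclasses

        small = ph.generate_phantom(male_params, spacing=COARSE, seed=3)
        big = ph.generate_phantom(
            dataclasses.replace(male_params, size_factor=2.0), spacing=COARSE, seed=3)
        a_small = (small.labels > 0).sum(axis=(1, 2))
        a_big = (big.labels > 0).sum(axis=(1, 2))
        occ = a_small > 0
        n = min(a_small.size, a_big.size)
        assert (a_big[:n][occ[:n]] > a_small[:n][occ[:n]]).all()

    def test_shape_axis_moves_ratio_not_waist(self):
        """Raising the fat-distribution axis raises VAT/ASAT strictly while the
        abdominal perimeter (tape-measure waist) moves by less than 1%."""
        ratios, waists = [], []
        shapes = np.linspace(-1.2, 1.2, 10)
        for s in shapes:
            p = ph.PhantomParams(sex="male", height_mm=1763.0, vat_asat_shape=float(s),
                                 noise_sd=0.0)
            vol = ph.generate_phantom(p, seed=1)
            ratios.append(ph.measure_truth_depots(vol)[3])
            waists.append(ph.measure_anthropometrics(vol, p)["waist_cm"])
        assert np.all(np.diff(ratios) > 0)
        assert (max(waists) - min(waists)) / np.mean(waists) < 0.01

    def test_depot_monotone_in_generating_factors(self):
        import dataclasses

        base = ph.PhantomParams(sex="female", height_mm=1628.0, noise_sd=0.0)
        grid = [0.8, 1.0, 1.3]
        vats = [ph.measure_truth_depots(ph.generate_phantom(
            dataclasses.replace(base, size_factor=g), spacing=COARSE, seed=1))[0]
            for g in grid]
        gfats = [ph.measure_truth_depots(ph.generate_phantom(
            dataclasses.replace(base, gfat_factor=g), spacing=COARSE, seed=1))[2]
            for g in grid]
        assert np.all(np.diff(vats) > 0)
        assert np.all(np.diff(gfats) > 0)

    def test_vat_interior_to_asat_on_abdominal_slices(self, male_phantom):
        lab = male_phantom.labels
        L = ph.LABELS
        for sl in lab:
            vat_rows = np.argwhere(sl == L["vat"])
            if vat_rows.size == 0:
                continue
            asat = sl == L["asat"]
            assert asat.any()
            # every VAT voxel is strictly inside the ASAT ring's bounding box
            (ymin, xmin), (ymax, xmax) = np.argwhere(asat).min(0), np.argwhere(asat).max(0)
            assert vat_rows[:, 0].min() > ymin and vat_rows[:, 0].max() < ymax
            assert vat_rows[:, 1].min() > xmin and vat_rows[:, 1].max() < xmax

    def test_degenerate_params_rejected(self):
        with pytest.raises(ValueError):
            ph.PhantomParams(sex="male", height_mm=900.0)
        with pytest.raises(ValueError):
            ph.PhantomParams(sex="male", height_mm=1763.0, size_factor=-1.0)
        p = ph.PhantomParams(sex="male", height_mm=1763.0)
        with pytest.raises(ValueError, match="empty phantom"):
            ph.generate_phantom(p, spacing=(400.0, 6.0, 6.0), seed=0)


class TestMeasurements:
    def test_voxel_volume_arithmetic(self):
        # 1000 VAT voxels at (3.0, 2.232, 2.232) mm -> 0.014945 L
        lab = np.zeros((11, 10, 10), np.uint8)
        lab.ravel()[:1000] = ph.LABELS["vat"]
        lab.ravel()[1000:1001] = ph.LABELS["asat"]
        vol = ph.BodyVolume(voxels=lab.astype(np.float32),
                            spacing_mm=(3.0, 2.232, 2.232), labels=lab)
        vat, asat, gfat, _ = ph.measure_truth_depots(vol)
        assert vat == pytest.approx(1000 * 3.0 * 2.232 * 2.232 / 1e6, abs=1e-6)
        assert gfat == 0.0

    def test_ratio_undefined_without_asat(self):
        lab = np.zeros((4, 4, 4), np.uint8)
        lab[0, 0, 0] = ph.LABELS["vat"]
        vol = ph.BodyVolume(voxels=lab.astype(float), spacing_mm=(1, 1, 1), labels=lab)
        with pytest.raises(ValueError, match="ratio undefined"):
            ph.measure_truth_depots(vol)

    def test_volume_conservation(self, male_phantom):
        vols = ph.label_volumes_l(male_phantom)
        total_body = sum(v for k, v in vols.items() if k != "background")
        counted = (male_phantom.labels > 0).sum() * male_phantom.voxel_volume_l
        assert abs(total_body - counted) <= 1e-9 * counted

    def test_cylinder_waist_perimeter(self):
        # circle radius 150 mm -> circumference 2*pi*15 cm, marching squares
        lab = np.zeros((60, 160, 160), np.uint8)
        yy, xx = np.meshgrid(np.arange(160), np.arange(160), indexing="ij")
        disc = ((yy - 80) ** 2 + (xx - 80) ** 2) <= (150 / 2.232) ** 2
        lab[:, disc] = ph.LABELS["lean"]
        perim_cm = ph.slice_perimeter_mm(lab[30] > 0, (2.232, 2.232)) / 10.0
        assert perim_cm == pytest.approx(2 * np.pi * 15.0, abs=1.5)

    def test_scaling_laws(self, male_params):
        vol1 = ph.generate_phantom(male_params, spacing=(6.0, 6.0, 6.0), seed=1)
        # doubling all voxel linear dimensions: same grid, doubled spacing
        vol2 = ph.BodyVolume(voxels=vol1.voxels, spacing_mm=(12.0, 12.0, 12.0),
                             labels=vol1.labels)
        a1 = ph.measure_anthropometrics(vol1, male_params)
        a2 = ph.measure_anthropometrics(vol2, male_params)
        assert a2["height_cm"] == pytest.approx(2 * a1["height_cm"], rel=1e-9)
        assert a2["weight_kg"] == pytest.approx(8 * a1["weight_kg"], rel=1e-9)
        assert a2["bmi"] == pytest.approx(2 * a1["bmi"], rel=1e-9)

    def test_bmi_formula(self):
        # reference male means: 83.8 kg at 176.3 cm -> BMI 26.96
        assert 83.8 / 1.763**2 == pytest.approx(26.96, abs=0.005)

    def test_cohort_bmi_consistency(self, small_cohort):
        _, table = small_cohort
        bmi = table["weight_kg"] / (table["height_cm"] / 100.0) ** 2
        assert np.allclose(bmi, table["bmi"], atol=1e-6)
        assert np.allclose(table["ratio"], table["vat_l"] / table["asat_l"], rtol=1e-12)


class TestDiseaseSimulation:
    def test_null_model_prevalence(self):
        rng = np.random.default_rng(0)
        n = 5000
        df = pd.DataFrame({
            "sex": np.where(rng.uniform(size=n) < 0.5, "male", "female"),
            "ratio": rng.normal(1, 0.2, n), "bmi": rng.normal(27, 3, n),
            "age_years": rng.normal(65, 8, n), "center": rng.integers(0, 1, n)})
        eff = {"null": ph.DiseaseEffects((0.05, 0.05), (1.0, 1.0), 1.0, 1.0,
                                         0.0, (1.0, 1.0), 1.0, 1.0)}
        out = ph.simulate_diseases(df, effects=eff, seed=1)
        prev = out["null_prevalent"].mean()
        assert abs(prev - 0.05) < 3 * np.sqrt(0.05 * 0.95 / n)
        assert out["null_incident"].sum() == 0  # zero baseline hazard

    def test_nonfinite_coefficients_rejected(self, small_cohort):
        _, table = small_cohort
        eff = {"bad": ph.DiseaseEffects((0.05, np.nan), (1.0, 1.0), 1.0, 1.0,
                                        0.0, (1.0, 1.0), 1.0, 1.0)}
        with pytest.raises(ValueError, match="nonfinite"):
            ph.simulate_diseases(table, effects=eff)

    def test_follow_up_median(self, analytic_20k):
        fu = analytic_20k.loc[analytic_20k["t2d_prevalent"] == 0, "t2d_follow_up_years"]
        assert fu.median() == pytest.approx(2.8, rel=0.05)

    def test_incident_event_times_within_follow_up(self, analytic_20k):
        t = analytic_20k
        inc = t["t2d_incident"] == 1
        assert (t.loc[inc, "t2d_prevalent"] == 0).all()
        assert (t.loc[inc, "t2d_event_time_years"]
                <= t.loc[inc, "t2d_follow_up_years"] + 1e-12).all()


class TestCohort:
    def test_reproducible_hash(self):
        cfg = ph.PopulationConfig(spacing_mm=COARSE)
        _, t1 = ph.generate_cohort(10, cfg, seed=4)
        _, t2 = ph.generate_cohort(10, cfg, seed=4)
        assert ph.cohort_hash(t1) == ph.cohort_hash(t2)

    def test_n_below_two_rejected(self):
        with pytest.raises(ValueError):
            ph.generate_cohort(1, seed=0)

    def test_female_fraction(self):
        _, base = ph.sample_params(10000, ph.PopulationConfig(), seed=8)
        assert (base["sex"] == "female").mean() == pytest.approx(0.51, abs=0.02)

    def test_analytic_depot_means_match_reference(self, analytic_20k):
        for sex in ("male", "female"):
            ref = ph.POPULATION_REFERENCE[sex]
            grp = analytic_20k[analytic_20k.sex == sex]
            for col, key in (("vat_l", "vat_l"), ("asat_l", "asat_l"), ("gfat_l", "gfat_l")):
                assert grp[col].mean() == pytest.approx(ref[key], rel=0.15)

    def test_ratio_nearly_independent_of_bmi(self, analytic_20k):
        for sex in ("male", "female"):
            grp = analytic_20k[analytic_20k.sex == sex]
            assert abs(np.corrcoef(grp["bmi"], grp["ratio"])[0, 1]) < 0.3
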
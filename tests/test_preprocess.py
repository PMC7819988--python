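"""Recalibration, TIC normalization and ppm binning."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_sample
from msimet.chem import ion_mz, parse_formula
from msimet.dataset import MSIDataset
from msimet.preprocess import (
    CalibrationError,
    FeatureMatrix,
    bin_features,
    concat_feature_matrices,
    greedy_bin_indices,
    load_calibrants,
    recalibrate,
    recalibrate_dataset,
    tic_normalize,
)

ATP_MZ = ion_mz(parse_formula("C10H16N5O13P3"), "[M-H]-")


class TestCalibrants:
    def test_packaged_list_recomputed_from_formulas(self):
        cals = load_calibrants()
        assert len(cals) == 14
        atp = next(c for c in cals if c.name == "ATP")
        assert atp.mz == pytest.approx(505.988470, abs=1e-5)
        neg = load_calibrants(mode="negative")
        assert all(c.mode == "negative" for c in neg) and len(neg) == 5

    def test_stored_mz_must_agree_with_formula(self, tmp_path):
        f = tmp_path / "cal.tsv"
        f.write_text(
            "name\tformula\tadduct\tmode\tmz\n"
            "ATP\tC10H16N5O13P3\t[M-H]-\tnegative\t505.98900\n"
        )
        with pytest.raises(CalibrationError, match="disagrees"):
            load_calibrants(f)


class TestRecalibrate:
    def test_single_point_removes_constructed_drift(self):
        cals = load_calibrants(mode="negative")
        theoretical = np.array([300.0, ATP_MZ, 700.0])
        drifted = theoretical * (1 + 1e-6)
        res = recalibrate(drifted, np.array([1.0, 10.0, 1.0]), cals)
        assert res.offset_ppm == pytest.approx(1.0, abs=1e-6)
        assert res.mz[1] == pytest.approx(505.988470, abs=1e-5)
        assert not res.flagged

    def test_already_calibrated_spectrum_is_identity(self):
        cals = load_calibrants(mode="negative")
        mz = np.array([ATP_MZ, 600.0])
        res = recalibrate(mz, np.array([5.0, 1.0]), cals)
        assert res.offset_ppm == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(res.mz, mz, rtol=0, atol=1e-12)

    def test_no_calibrant_flags_and_passes_through(self):
        cals = load_calibrants(mode="negative")
        mz = np.array([777.7, 888.8])
        res = recalibrate(mz, None, cals)
        assert res.flagged and res.offset_ppm is None
        assert np.array_equal(res.mz, mz)

    def test_linear_model_recovers_mass_dependent_drift(self):
        cals = load_calibrants(mode="negative")
        theo = np.array([c.mz for c in cals])
        drift_ppm = 0.5 + 0.002 * theo  # intercept + slope
        drifted = theo * (1 + drift_ppm * 1e-6)
        res = recalibrate(drifted, None, cals, model="linear")
        assert res.offset_ppm == pytest.approx(0.5, abs=0.01)
        assert res.slope_ppm_per_da == pytest.approx(0.002, rel=0.01)
        assert np.allclose(res.mz, theo, atol=2e-5)

    def test_dataset_level_per_sample_offset(self):
        theo = np.array([ATP_MZ, 650.0])
        s = make_sample(
            np.tile(theo * (1 + 2e-6), 2),
            np.ones(4),
            pixel_index=[0, 0, 1, 1],
        )
        ds = MSIDataset(samples=[s], mode="negative")
        out, report = recalibrate_dataset(ds)
        assert report.loc["S1", "offset_ppm"] == pytest.approx(2.0, abs=1e-6)
        assert np.allclose(np.sort(out.samples[0].mz)[:2], ATP_MZ, atol=1e-5)


class TestTicNormalize:
    def test_unit_target_sums_to_one(self):
        s = make_sample([500.0, 600.0, 500.0], [4.0, 6.0, 20.0], [0, 0, 1])
        ds = tic_normalize(MSIDataset(samples=[s]), target="unit")
        tic = ds.samples[0].tic()
        assert np.allclose(tic, [1.0, 1.0])

    def test_relative_intensities_preserved(self):
        s = make_sample([500.0, 600.0], [4.0, 6.0], [0, 0])
        ds = tic_normalize(MSIDataset(samples=[s]), target="mean")
        i = ds.samples[0].intensity
        assert i[1] / i[0] == pytest.approx(1.5)

    def test_mean_tic_target_zeroes_tic_variance(self):
        from msimet.synthetic import default_study_config, generate_dataset

        cfg = default_study_config(seed=2, grid_shape=(4, 4))["positive"]
        ds, _ = generate_dataset(cfg)
        before = np.concatenate([s.tic() for s in ds])
        norm = tic_normalize(ds, target="mean")
        after = np.concatenate([s.tic() for s in norm])
        assert np.std(before) / np.mean(before) > 0.1
        assert np.std(after) / np.mean(after) < 1e-12
        assert np.mean(after) == pytest.approx(np.mean(before))

    def test_zero_tic_pixel_excluded_and_logged(self, caplog):
        s = make_sample([500.0], [5.0], [0], n_pixels=2)
        with caplog.at_level("WARNING"):
            ds = tic_normalize(MSIDataset(samples=[s]), target="unit")
        assert "zero-TIC" in caplog.text
        assert ds.samples[0].tic()[1] == 0.0


def single_linkage_bins(mz, tol_ppm):
    """Brute-force oracle: merge adjacent clusters while the closest pair
    across the boundary is within tolerance."""
    order = np.argsort(mz)
    clusters = [[i] for i in order]
    merged = True
    while merged:
        merged = False
        for k in range(len(clusters) - 1):
            left, right = clusters[k], clusters[k + 1]
            gap = mz[right[0]] - mz[left[-1]]
            if gap <= mz[left[-1]] * tol_ppm * 1e-6:
                clusters[k] = left + right
                del clusters[k + 1]
                merged = True
                break
    return [np.array(c) for c in clusters]


class TestBinFeatures:
    def two_sample_ds(self, mz1, mz2):
        s1 = make_sample([mz1], [5.0], sample_id="A", group="control")
        s2 = make_sample([mz2], [5.0], sample_id="B", group="patient", age=6.0)
        return MSIDataset(samples=[s1, s2], mode="negative")

    def test_sub_ppm_peaks_form_one_feature(self):
        fm = bin_features(self.two_sample_ds(505.988470, 505.988720))  # ~0.49 ppm
        assert fm.n_features == 1
        assert fm.features.iloc[0]["n_samples"] == 2

    def test_separated_peaks_form_two_features(self):
        fm = bin_features(self.two_sample_ds(505.988470, 505.990))  # ~3 ppm
        assert fm.n_features == 2

    def test_empty_dataset_yields_empty_matrix(self):
        s = make_sample([], [], pixel_index=np.array([], int), n_pixels=1)
        fm = bin_features(MSIDataset(samples=[s]))
        assert fm.n_features == 0 and fm.n_samples == 1

    def test_invalid_tolerance(self):
        with pytest.raises(ValueError):
            bin_features(self.two_sample_ds(500.0, 500.0), tolerance_ppm=0)

    def test_members_within_tolerance_of_consensus(self):
        rng = np.random.default_rng(3)
        mz = np.sort(500.0 * (1 + rng.normal(0, 0.4e-6, size=400)))
        w = rng.uniform(0.5, 2.0, size=400)
        for cl in greedy_bin_indices(mz, w, 1.0):
            consensus = np.average(mz[cl], weights=w[cl])
            assert np.all(np.abs(mz[cl] - consensus) <= consensus * 1.000001e-6)

    def test_matches_single_linkage_oracle_on_separated_instances(self):
        rng = np.random.default_rng(17)
        for trial in range(30):
            n_clusters = rng.integers(1, 6)
            centers = np.sort(rng.uniform(200, 900, n_clusters))
            # enforce > 3 ppm separation so both algorithms must agree
            centers = centers[np.r_[True, np.diff(centers) / centers[:-1] > 3e-6]]
            mz, w = [], []
            for c in centers:
                k = rng.integers(1, 10)
                mz.extend(c * (1 + rng.uniform(-0.4e-6, 0.4e-6, k)))
                w.extend(rng.uniform(0.5, 2.0, k))
            mz, w = np.array(mz), np.array(w)
            order = np.argsort(mz)
            mz, w = mz[order], w[order]
            ours = [frozenset(c.tolist()) for c in greedy_bin_indices(mz, w, 1.0)]
            oracle = [frozenset(c.tolist()) for c in single_linkage_bins(mz, 1.0)]
            assert set(ours) == set(oracle)

    def test_sample_order_permutation_invariant(self):
        from msimet.synthetic import default_study_config, generate_dataset

        cfg = default_study_config(seed=4, grid_shape=(2, 2), n_per_group=3)["positive"]
        ds, _ = generate_dataset(cfg)
        fm1 = bin_features(ds)
        shuffled = MSIDataset(samples=list(reversed(ds.samples)), mode=ds.mode)
        fm2 = bin_features(shuffled)
        pd.testing.assert_frame_equal(fm1.intensities, fm2.intensities)
        pd.testing.assert_frame_equal(fm1.features, fm2.features)

    def test_recalibrated_default_study_gives_one_feature_per_compound(self):
        from msimet.synthetic import default_study_config, generate_dataset

        for mode in ("positive", "negative"):
            cfg = default_study_config(seed=8, grid_shape=(8, 8))[mode]
            ds, truth = generate_dataset(cfg)
            recal, _ = recalibrate_dataset(ds, load_calibrants(mode=mode))
            fm = bin_features(tic_normalize(recal))
            assert fm.n_features == len(truth)
            got = np.sort(fm.features["mz"].to_numpy())
            want = np.sort(truth["mz"].to_numpy())
            assert np.allclose(got / want, 1.0, atol=5e-7)


class TestFeatureMatrix:
    def small(self):
        intensities = pd.DataFrame(
            [[0.0, 4.0], [2.0, 8.0]],
            index=pd.Index(["f1", "f2"], name="feature"),
            columns=["A", "B"],
        )
        features = pd.DataFrame(
            {"mz": [500.0, 600.0], "mode": "positive", "n_peaks": 2, "n_samples": 2},
            index=intensities.index,
        )
        samples = pd.DataFrame(
            {"group": ["control", "patient"], "age": [40.0, 6.0]},
            index=pd.Index(["A", "B"], name="sample"),
        )
        return FeatureMatrix(intensities=intensities, features=features, samples=samples)

    def test_impute_zeros_half_min_positive(self):
        fm = self.small().impute_zeros()
        assert fm.intensities.loc["f1", "A"] == 1.0  # half of min positive (2.0)

    def test_round_trip_through_csv_dir(self, tmp_path):
        fm = self.small()
        fm.to_dir(tmp_path / "fm")
        back = FeatureMatrix.from_dir(tmp_path / "fm")
        pd.testing.assert_frame_equal(fm.intensities, back.intensities)
        pd.testing.assert_frame_equal(fm.samples, back.samples)
        assert back.log is False

    def test_concat_requires_shared_samples(self):
        fm = self.small()
        other = self.small()
        other.samples = other.samples.rename(index={"B": "C"})
        other.intensities.columns = ["A", "C"]
        with pytest.raises(ValueError):
            concat_feature_matrices([fm, other])

    def test_axis_mismatch_rejected(self):
        fm = self.small()
        with pytest.raises(ValueError):
            FeatureMatrix(
                intensities=fm.intensities,
                features=fm.features.iloc[:1],
                samples=fm.samples,
            )
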
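"""Synthetic study generator: determinism, noise calibration, hierarchy."""

import numpy as np
import pytest

from ventralenc import (
    SyntheticStudyConfig,
    default_rois,
    make_layer_features,
    make_study,
    make_voxel_responses,
)
from ventralenc.synthetic import HVC_ROIS, LVC_ROIS, ROI_NAMES, ROISpec


class TestLayerFeatures:
    def test_single_layer_base_case(self):
        fs = make_layer_features(10, 4, [4], seed=0)
        assert fs.layer_ids == [1]
        assert fs.train[1].shape == (10, 4)
        assert fs.val[1].shape == (4, 4)
        assert np.allclose(fs.train[1].var(axis=0), 1.0)

    def test_deterministic_given_seed(self):
        a = make_layer_features(20, 5, [6, 6], seed=9)
        b = make_layer_features(20, 5, [6, 6], seed=9)
        for l in (1, 2):
            assert np.array_equal(a.train[l], b.train[l])
            assert np.array_equal(a.val[l], b.val[l])
        c = make_layer_features(20, 5, [6, 6], seed=10)
        assert not np.array_equal(a.train[1], c.train[1])

    def test_layers_share_but_do_not_duplicate_information(self):
        """Mean canonical correlation between consecutive layers is in (0, 1):
        the ReLU cascade nests information without copying it."""
        fs = make_layer_features(300, 10, [100, 100], seed=1)
        q1, _ = np.linalg.qr(fs.train[1] - fs.train[1].mean(0))
        q2, _ = np.linalg.qr(fs.train[2] - fs.train[2].mean(0))
        cc = np.linalg.svd(q1.T @ q2, compute_uv=False)
        assert 0.0 < cc.mean() < 1.0
        assert cc.max() <= 1.0 + 1e-9

    def test_invalid_dims_raise(self):
        with pytest.raises(ValueError):
            make_layer_features(10, 2, [], seed=0)
        with pytest.raises(ValueError):
            make_layer_features(10, 2, [4, 1], seed=0)

    def test_train_statistics_applied_to_validation(self):
        """Validation rows go through the train-fitted maps: extending the
        validation split never changes the training matrices."""
        a = make_layer_features(30, 5, [8, 8], seed=3)
        b = make_layer_features(30, 15, [8, 8], seed=3)
        assert np.array_equal(a.train[2], b.train[2])


@pytest.fixture(scope="module")
def features():
    return make_layer_features(1200, 50, [40, 40, 40], seed=2)


class TestVoxelResponses:

    def test_noiseless_limit(self, features):
        roi = ROISpec("V1", 5, [1.0, 0.0, 0.0])
        resp, truth = make_voxel_responses(features, roi, 4, 1e6, 3, 0.0, seed=0)
        for v in range(5):
            c = np.corrcoef(resp.clean_train[:, v], resp.train[:, v])[0, 1]
            assert c > 0.999
        assert np.allclose(resp.runs[0], resp.runs[1])

    def test_point_mass_preference(self, features):
        roi = ROISpec("X", 20, [0.0, 0.0, 1.0])
        _, truth = make_voxel_responses(features, roi, 4, 2.0, 2, 1.0, seed=1)
        assert np.all(truth.generating_layer == 3)

    def test_noise_calibration_matches_closed_form(self, features):
        """corr(clean, observed) = snr / sqrt(snr^2 + 1); at snr=1 this is
        1/sqrt(2), checked empirically over 1200 samples."""
        roi = ROISpec("X", 30, [1 / 3, 1 / 3, 1 / 3])
        resp, _ = make_voxel_responses(features, roi, 4, 1.0, 2, 1.0, seed=7)
        corrs = [
            np.corrcoef(resp.clean_train[:, v], resp.train[:, v])[0, 1]
            for v in range(30)
        ]
        assert np.mean(corrs) == pytest.approx(1 / np.sqrt(2), abs=0.03)

    def test_run_noise_variance_calibrated(self, features):
        """Across-run variance approximates run_noise_sd^2 within 10% when
        averaged over 50 stimuli and >= 50 voxels at 35 runs."""
        roi = ROISpec("X", 60, [1 / 3, 1 / 3, 1 / 3])
        resp, _ = make_voxel_responses(features, roi, 4, 2.0, 35, 0.8, seed=8)
        v = resp.runs.var(axis=0, ddof=1).mean()
        assert v == pytest.approx(0.64, rel=0.10)

    def test_k_true_exceeding_dim_raises(self, features):
        roi = ROISpec("X", 2, [1.0, 0.0, 0.0])
        with pytest.raises(ValueError):
            make_voxel_responses(features, roi, 41, 1.0, 2, 1.0, seed=0)


class TestStudy:
    def test_default_roi_layout(self):
        cfg = SyntheticStudyConfig(
            n_subjects=1, n_train=40, n_val=10, n_layers=4,
            layer_dims=[20] * 4, k_true=3, n_runs=35,
            rois=default_rois(4, n_voxels=4), seed=0,
        )
        study = make_study(cfg)
        ds = study.subjects[0]
        assert tuple(ds.rois) == ROI_NAMES
        for roi in ds.rois.values():
            assert roi.runs.shape == (35, 10, 4)

    def test_minimal_study_shapes(self):
        cfg = SyntheticStudyConfig(
            n_subjects=1, n_train=20, n_val=8, n_layers=1, layer_dims=[10],
            rois=[ROISpec("V1", 1, [1.0])], k_true=2, n_runs=2, seed=0,
        )
        study = make_study(cfg)
        roi = study.subjects[0].rois["V1"]
        assert roi.train.shape == (20, 1)
        assert roi.val.shape == (8, 1)
        assert study.subjects[0].truth["V1"].support.shape == (1, 2)

    def test_seed_contract(self):
        base = dict(
            n_subjects=1, n_train=20, n_val=8, n_layers=2, layer_dims=[10, 10],
            rois=[ROISpec("V1", 5, [0.5, 0.5])], k_true=2, n_runs=2,
        )
        s1 = make_study(SyntheticStudyConfig(**base, seed=1))
        s1b = make_study(SyntheticStudyConfig(**base, seed=1))
        s2 = make_study(SyntheticStudyConfig(**base, seed=2))
        assert np.array_equal(
            s1.subjects[0].rois["V1"].train, s1b.subjects[0].rois["V1"].train
        )
        assert not np.array_equal(
            s1.subjects[0].truth["V1"].support, s2.subjects[0].truth["V1"].support
        )

    def test_adding_subject_preserves_earlier_subjects(self):
        base = dict(
            n_train=20, n_val=8, n_layers=2, layer_dims=[10, 10],
            rois=[ROISpec("V1", 5, [0.5, 0.5])], k_true=2, n_runs=2, seed=4,
        )
        two = make_study(SyntheticStudyConfig(n_subjects=2, **base))
        three = make_study(SyntheticStudyConfig(n_subjects=3, **base))
        for s in range(2):
            assert np.array_equal(
                two.subjects[s].rois["V1"].train, three.subjects[s].rois["V1"].train
            )

    def test_lvc_prefers_earlier_layers_than_hvc(self):
        rois = {r.name: r for r in default_rois(8)}
        mean_layer = lambda r: (np.arange(1, 9) * r.layer_preference).sum()
        assert max(mean_layer(rois[n]) for n in LVC_ROIS) < min(
            mean_layer(rois[n]) for n in HVC_ROIS
        )

    @pytest.mark.parametrize(
        "bad",
        [
            dict(snr=-1.0),
            dict(n_subjects=0),
            dict(layer_dims=[10]),  # wrong length for n_layers=2
        ],
    )
    def test_invalid_config_raises(self, bad):
        params = dict(
            n_subjects=1, n_train=10, n_val=5, n_layers=2, layer_dims=[10, 10],
            rois=[ROISpec("V1", 3, [0.5, 0.5])], k_true=2, n_runs=2, seed=0,
        )
        params.update(bad)
        with pytest.raises(ValueError):
            SyntheticStudyConfig(**params)

    def test_preference_not_summing_to_one_rejected(self):
        with pytest.raises(ValueError):
            ROISpec("V1", 3, [0.5, 0.4])
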
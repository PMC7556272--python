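"""Synthetic cohort generator: planted covariance, determinism, scores."""

import numpy as np
import pandas as pd
import pytest

from mcinet import cohort as ch
from mcinet import connectivity as cn


def spec_no_effects(**kwargs):
    defaults = dict(
        group_effect=ch.GroupEffect.null(),
        score_models={
            k: ch.ScoreModel(intercept=v.intercept, coef=0.0, noise_sd=v.noise_sd, case_shift=0.0)
            for k, v in ch.default_score_models().items()
        },
    )
    defaults.update(kwargs)
    return ch.CohortSpec(**defaults)


class TestBuildCovariance:
    def test_two_blocks_no_hubs(self):
        spec = spec_no_effects(
            n_rois=4, n_modules=2, rho_in=0.5, rho_out=0.0, hub_rois=(), hub_boost=0.0
        )
        expected = np.array(
            [[1, 0.5, 0, 0], [0.5, 1, 0, 0], [0, 0, 1, 0.5], [0, 0, 0.5, 1]]
        )
        np.testing.assert_allclose(ch.build_covariance(spec, "NC"), expected)

    def test_zero_correlations_give_identity(self):
        spec = spec_no_effects(n_rois=6, rho_in=0.0, rho_out=0.0, hub_rois=(), hub_boost=0.0)
        np.testing.assert_allclose(ch.build_covariance(spec, "NC"), np.eye(6))

    def test_hub_boost_on_off_block_entries(self):
        spec = spec_no_effects(
            n_rois=4, n_modules=2, rho_in=0.6, rho_out=0.1, hub_rois=(0,), hub_boost=0.2
        )
        cov = ch.build_covariance(spec, "NC")
        # off-block entries touching the hub carry rho_out + hub_boost
        assert cov[0, 2] == pytest.approx(0.3)
        assert cov[0, 3] == pytest.approx(0.3)
        assert cov[1, 2] == pytest.approx(0.1)
        assert np.linalg.eigvalsh(cov).min() >= -1e-10

    def test_case_group_module_split_and_lost_hub(self):
        spec = ch.CohortSpec(n_rois=16, n_modules=4, hub_rois=(0, 8))
        assert spec.group_partition("NC").max() == 4
        assert spec.group_partition("MCI").max() == 5
        assert spec.group_hubs("NC") == (0, 8)
        assert spec.group_hubs("MCI") == (8,)

    def test_psd_repair_restores_unit_diagonal(self):
        spec = ch.CohortSpec()  # defaults are deliberately slightly non-PSD
        cov = ch.build_covariance(spec, "NC")
        np.testing.assert_allclose(np.diag(cov), 1.0, atol=1e-12)
        assert np.linalg.eigvalsh(cov).min() >= -1e-8


class TestSpecValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(n_timepoints=2),
            dict(rho_in=0.5, rho_out=0.6),
            dict(rho_in=0.5, rho_out=0.5),
            dict(hub_boost=0.95),
            dict(gender_prob={"NC": 1.2, "MCI": 0.5}),
        ],
    )
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ch.CohortSpec(**kwargs)

    def test_partition_labels_must_be_contiguous(self):
        with pytest.raises(ValueError):
            ch.CohortSpec(n_rois=4, partition_truth=np.array([1, 1, 3, 3]))


class TestGenerateCohort:
    def test_same_seed_identical_cohorts(self):
        spec = ch.CohortSpec(n_per_group=3, n_rois=10, seed=7)
        a, _ = ch.generate_cohort(spec)
        b, _ = ch.generate_cohort(ch.CohortSpec(n_per_group=3, n_rois=10, seed=7))
        for sa, sb in zip(a, b):
            assert sa.subject_id == sb.subject_id
            assert sa.gender == sb.gender
            assert sa.scores == sb.scores
            np.testing.assert_array_equal(sa.timeseries, sb.timeseries)

    def test_shapes_counts_and_score_presence(self):
        spec = ch.CohortSpec(n_per_group=4, n_rois=12, seed=3)
        subjects, truth = ch.generate_cohort(spec)
        assert len(subjects) == 8
        assert sum(s.group == "MCI" for s in subjects) == 4
        for s in subjects:
            assert s.timeseries.shape == (135, 12)
            assert set(s.scores) == set(ch.SCORE_NAMES)
        assert set(truth.partition) == {"NC", "MCI"}

    def test_within_module_correlation_exceeds_between_at_large_t(self):
        spec = spec_no_effects(
            n_per_group=1, n_rois=12, n_modules=3, n_timepoints=5000,
            rho_in=0.6, rho_out=0.1, hub_rois=(), hub_boost=0.0, seed=11,
        )
        subjects, truth = ch.generate_cohort(spec)
        fc = cn.compute_fc(subjects[0].timeseries).values
        part = truth.partition["NC"]
        labels = np.unique(part)
        off = ~np.eye(12, dtype=bool)
        for a in labels:
            for b in labels:
                ia, ib = part == a, part == b
                block = fc[np.ix_(ia, ib)]
                mean = block[off[np.ix_(ia, ib)]].mean() if a == b else block.mean()
                if a == b:
                    assert mean > 0.4
                else:
                    assert mean < 0.3

    def test_empirical_fc_converges_to_planted_covariance(self):
        t = 8000
        spec = spec_no_effects(
            n_per_group=1, n_rois=8, n_modules=2, n_timepoints=t,
            rho_in=0.5, rho_out=0.1, hub_rois=(), hub_boost=0.0, seed=5,
        )
        subjects, _ = ch.generate_cohort(spec)
        cov = ch.build_covariance(spec, "NC")
        fc = cn.compute_fc(subjects[0].timeseries).values
        target = np.abs(cov.copy())
        np.fill_diagonal(target, 0.0)
        assert np.max(np.abs(fc - target)) < 3.0 / np.sqrt(t)

    def test_case_shifts_follow_clinical_direction(self):
        subjects, _ = ch.generate_cohort(ch.CohortSpec(n_per_group=60, n_rois=10, seed=9))
        df = pd.DataFrame([{"group": s.group, **s.scores} for s in subjects])
        means = df.groupby("group").mean()
        assert means.loc["MCI", "ADAS13"] > means.loc["NC", "ADAS13"]
        assert means.loc["MCI", "CDRSB"] > means.loc["NC", "CDRSB"]
        assert means.loc["MCI", "FAQ"] > means.loc["NC", "FAQ"]
        assert means.loc["MCI", "MMSE"] < means.loc["NC", "MMSE"]

    def test_too_few_timepoints_rejected(self):
        with pytest.raises(ValueError):
            ch.CohortSpec(n_timepoints=2)


class TestFeatureTableSimulation:
    def test_null_table_shape_and_columns(self):
        feats, y, info = ch.simulate_feature_table(10, seed=0)
        assert feats.shape == (20, 124)
        assert list(feats.columns[:8]) == ["ADAS13", "CDRSB", "MMSE", "FAQ", "C", "L", "GE", "SW"]
        assert y.sum() == 10
        assert info == ()

    def test_planted_shift_lands_on_named_column(self):
        feats, y, _ = ch.simulate_feature_table(200, seed=1, informative={"L": 2.0})
        delta = feats.loc[y == 1, "L"].mean() - feats.loc[y == 0, "L"].mean()
        assert delta == pytest.approx(2.0, abs=0.3)

    def test_unknown_feature_rejected(self):
        with pytest.raises(ValueError):
            ch.simulate_feature_table(5, seed=0, informative={"bogus": 1.0})


def test_cohort_round_trip(tmp_path):
    spec = ch.CohortSpec(n_per_group=2, n_rois=6, seed=21)
    subjects, truth = ch.generate_cohort(spec)
    ch.write_cohort(subjects, truth, tmp_path)
    loaded, meta = ch.read_cohort(tmp_path)
    assert len(loaded) == 4
    assert list(meta.columns[:3]) == ["subject_id", "group", "gender"]
    np.testing.assert_allclose(loaded[0].timeseries, subjects[0].timeseries, atol=1e-12)
    assert loaded[2].scores == pytest.approx(subjects[2].scores)
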
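import numpy as np
import pandas as pd
import pytest

from conftest import make_matrix
from phosdiff import preprocess
from phosdiff.model import GROUPS, AnalysisParams, PhosphoSiteAnnotation, SampleMetadata
from phosdiff.simulate import SynthConfig, simulate_cohort


def _meta(assignments):
    rows = [{"sample_id": s, "group": g} for s, g in assignments]
    return SampleMetadata(pd.DataFrame(rows).set_index("sample_id"))


class TestLog2Transform:
    def test_known_values(self):
        m = preprocess.log2_transform(make_matrix([[8.0, 1.0]], scale="raw"))
        np.testing.assert_allclose(m.values.to_numpy(), [[3.0, 0.0]])
        assert m.scale == "log2"

    def test_mask_cardinality_preserved(self):
        m0 = make_matrix([[8.0, np.nan], [np.nan, 4.0]], scale="raw")
        m1 = preprocess.log2_transform(m0)
        assert m1.missing_mask.equals(m0.missing_mask)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError, match="nonpositive"):
            preprocess.log2_transform(make_matrix([[-1.0]], scale="raw"))

    def test_double_transform_rejected(self):
        m = preprocess.log2_transform(make_matrix([[2.0]], scale="raw"))
        with pytest.raises(ValueError):
            preprocess.log2_transform(m)


class TestPresenceFilter:
    def _cohort(self, obs_counts, params):
        """One feature observed obs_counts times per group (6/23/31/22)."""
        sizes = {"EML4_ALK": 6, "EGFR": 23, "KRAS": 31, "WT": 22}
        cols, vals = [], []
        for g in GROUPS:
            n = sizes[g]
            k = obs_counts.get(g, 0)
            cols += [(f"{g}_{i}", g) for i in range(n)]
            vals += [20.0] * k + [np.nan] * (n - k)
        m = make_matrix([vals], sample_ids=[c[0] for c in cols])
        return m, _meta(cols)

    @pytest.mark.parametrize(
        "obs,kept",
        [
            ({"EGFR": 12}, True),   # 12/23 >= 50%
            ({"EML4_ALK": 3}, False),  # needs 4/6
            ({"EML4_ALK": 4}, True),
            ({"WT": 11}, True),     # exactly 50%, inclusive
            ({"WT": 10}, False),
            ({"KRAS": 15}, False),  # 15/31 < 50%
            ({"KRAS": 16}, True),
        ],
    )
    def test_presence_rule(self, obs, kept, params):
        m, meta = self._cohort(obs, params)
        filtered, summary = preprocess.presence_filter(m, meta, params)
        assert (filtered.n_features == 1) == kept
        total = sum(obs.values())
        assert summary.filter(like="count_").iloc[0].sum() == total

    def test_sample_order_invariance(self, params):
        rng = np.random.default_rng(0)
        vals = rng.normal(20, 2, size=(50, 82))
        vals[rng.random(vals.shape) < 0.5] = np.nan
        sizes = [("EML4_ALK", 6), ("EGFR", 23), ("KRAS", 31), ("WT", 22)]
        assignments = [(f"s{i}", g) for i, (g, n) in
                       ((i, gn) for i, gn in enumerate(
                           [(g, n) for g, n in sizes for _ in range(n)]))]
        assignments = []
        i = 0
        for g, n in sizes:
            for _ in range(n):
                assignments.append((f"s{i}", g))
                i += 1
        m = make_matrix(vals, sample_ids=[a[0] for a in assignments])
        meta = _meta(assignments)
        kept1, _ = preprocess.presence_filter(m, meta, params)
        perm = rng.permutation(m.sample_ids)
        m2 = make_matrix(m.values[perm].to_numpy(), feature_ids=m.feature_ids,
                         sample_ids=list(perm))
        kept2, _ = preprocess.presence_filter(m2, meta, params)
        assert kept1.feature_ids == kept2.feature_ids


class TestLocalizationFilter:
    def test_boundary_inclusive(self, params):
        m = make_matrix([[1.0], [2.0], [3.0]], feature_ids=["A;S1", "B;S2", "C;S3"])
        ann = [
            PhosphoSiteAnnotation("A;S1", "A", 0.6),
            PhosphoSiteAnnotation("B;S2", "B", 0.75),
            PhosphoSiteAnnotation("C;S3", "C", 0.9),
        ]
        out = preprocess.localization_filter(ann, m, params)
        assert out.feature_ids == ["B;S2", "C;S3"]

    def test_missing_annotation_is_error(self, params):
        m = make_matrix([[1.0]], feature_ids=["A;S1"])
        with pytest.raises(ValueError, match="A;S1"):
            preprocess.localization_filter([], m, params)

    def test_all_pass_is_identity(self, params):
        m = make_matrix([[1.0], [2.0]], feature_ids=["A;S1", "B;S2"])
        ann = [PhosphoSiteAnnotation(f, f.split(";")[0], 1.0) for f in m.feature_ids]
        assert preprocess.localization_filter(ann, m, params).feature_ids == m.feature_ids


class TestImputeProteomic:
    def test_low_presence_uses_sample_5th_percentile(self, params):
        """Feature observed 3/8 in its group -> missing cells filled with the
        recipient sample's 5th percentile; {20,22,...,38} -> 20.9."""
        n_feat, n_samp = 11, 8
        vals = np.full((n_feat, n_samp), 30.0)
        vals[:10, 0] = np.arange(20, 40, 2, dtype=float)  # S0's observed vector
        vals[10] = np.nan
        vals[10, 5:] = 25.0  # observed 3/8 in the group
        vals[10, 5] = 25.0
        m = make_matrix(vals, sample_ids=[f"S{i}" for i in range(8)])
        meta = _meta([(f"S{i}", "WT") for i in range(8)])
        out = preprocess.impute_proteomic(m, meta, params)
        assert out.values.iloc[10, 0] == pytest.approx(20.9)

    def test_fully_observed_feature_untouched(self, params):
        vals = np.array([[20.0, 21.0, 22.0, 23.0], [np.nan, 25.0, 25.0, np.nan]])
        m = make_matrix(vals, sample_ids=["a", "b", "c", "d"])
        meta = _meta([("a", "WT"), ("b", "WT"), ("c", "WT"), ("d", "WT")])
        out = preprocess.impute_proteomic(m, meta, params)
        np.testing.assert_array_equal(out.values.iloc[0], vals[0])
        assert not out.values.isna().any().any()

    def test_knn_mean_of_constant_neighbours(self, params):
        """Feature observed 5/8; 12 identical-profile neighbours all equal
        30.0 in the target sample -> imputed exactly 30.0."""
        rng = np.random.default_rng(1)
        base = np.array([20, 21, 22, 23, 24, 25, 26, 27], dtype=float)
        rows = [base.copy() for _ in range(12)]
        for r in rows:
            r[0] = 30.0
        target = base.copy()
        target[0] = np.nan  # missing in the target sample, observed 7/8 >= 1/2
        far = rng.normal(100, 5, size=(10, 8))
        vals = np.vstack([np.array(rows), target[None, :], far])
        m = make_matrix(vals, sample_ids=[f"S{i}" for i in range(8)])
        meta = _meta([(f"S{i}", "KRAS") for i in range(8)])
        out = preprocess.impute_proteomic(m, meta, params)
        assert out.values.iloc[12, 0] == pytest.approx(30.0)

    def test_observed_cells_never_change(self, params):
        cfg = SynthConfig(n_features=120, seed=9)
        m, meta, _ = simulate_cohort(cfg)
        m = preprocess.log2_transform(m)
        m, _ = preprocess.presence_filter(m, meta, params)
        out = preprocess.impute_proteomic(m, meta, params)
        observed = ~m.values.isna()
        np.testing.assert_array_equal(
            out.values.to_numpy()[observed.to_numpy()],
            m.values.to_numpy()[observed.to_numpy()],
        )
        assert not out.values.isna().any().any()

    def test_left_censored_fill_sits_below_sample_mean(self, params):
        """Under MNAR dropout the percentile branch imputes below the sample
        mean (left-censoring behaviour)."""
        cfg = SynthConfig(n_features=2000, seed=4)
        m, meta, _ = simulate_cohort(cfg)
        m = preprocess.log2_transform(m)
        m, _ = preprocess.presence_filter(m, meta, params)
        out = preprocess.impute_proteomic(m, meta, params)
        was_missing = m.values.isna()
        imputed_mean = out.values.to_numpy()[was_missing.to_numpy()].mean()
        assert imputed_mean < m.values.stack().mean()


class TestImputePhospho:
    def test_degenerate_group_sd_fills_exact_mean(self, params):
        vals = np.array([[10.0, 10.0, 10.0, 10.0, np.nan]])
        m = make_matrix(vals, sample_ids=[f"S{i}" for i in range(5)])
        meta = _meta([(f"S{i}", "EGFR") for i in range(5)])
        out = preprocess.impute_phospho(m, meta, params, seed=0)
        assert out.values.iloc[0, 4] == pytest.approx(10.0)

    def test_tail_fill_distribution(self, params):
        """Sample mean 25, SD 2 -> tail fills ~ Normal(25-1.8*2, 0.3*2) =
        Normal(21.4, 0.6); empirical mean over 10^4 draws within 0.05."""
        rng = np.random.default_rng(7)
        n_fill = 10_000
        obs = rng.normal(25, 2, size=2000)
        obs = (obs - obs.mean()) / obs.std(ddof=1) * 2 + 25  # exact moments
        col = np.concatenate([obs, np.full(n_fill, np.nan)])
        # second sample fully observed so every group has >= 2 samples
        vals = np.column_stack([col, np.full_like(col, 25.0)])
        vals[len(obs):, 1] = np.nan
        m = make_matrix(vals, sample_ids=["S0", "S1"])
        meta = _meta([("S0", "WT"), ("S1", "WT")])
        out = preprocess.impute_phospho(m, meta, params, seed=11)
        fills = out.values.iloc[len(obs):, 0]
        assert abs(fills.mean() - 21.4) < 0.05
        assert abs(fills.std(ddof=1) - 0.6) < 0.05

    def test_same_seed_identical(self, params):
        rng = np.random.default_rng(2)
        vals = rng.normal(25, 2, size=(40, 10))
        vals[rng.random(vals.shape) < 0.4] = np.nan
        m = make_matrix(vals, sample_ids=[f"S{i}" for i in range(10)])
        meta = _meta([(f"S{i}", "KRAS" if i < 5 else "WT") for i in range(10)])
        out1 = preprocess.impute_phospho(m, meta, params, seed=5)
        out2 = preprocess.impute_phospho(m, meta, params, seed=5)
        pd.testing.assert_frame_equal(out1.values, out2.values)
        assert not out1.values.isna().any().any()

    def test_observed_cells_never_change(self, params):
        rng = np.random.default_rng(3)
        vals = rng.normal(25, 2, size=(30, 8))
        vals[rng.random(vals.shape) < 0.3] = np.nan
        m = make_matrix(vals, sample_ids=[f"S{i}" for i in range(8)])
        meta = _meta([(f"S{i}", "EGFR" if i < 4 else "WT") for i in range(8)])
        out = preprocess.impute_phospho(m, meta, params, seed=1)
        observed = ~m.values.isna()
        np.testing.assert_array_equal(
            out.values.to_numpy()[observed.to_numpy()],
            m.values.to_numpy()[observed.to_numpy()],
        )


class TestMedianScale:
    def test_two_sample_medians_meet_at_grand_median(self):
        vals = np.array([[18.0, 22.0], [20.0, 24.0], [22.0, 26.0]])
        out = preprocess.median_scale(make_matrix(vals, sample_ids=["a", "b"]))
        medians = out.values.median(axis=0)
        np.testing.assert_allclose(medians, [22.0, 22.0])

    def test_single_sample_identity(self):
        m = make_matrix([[20.0], [21.0], [22.0]], sample_ids=["a"])
        out = preprocess.median_scale(m)
        pd.testing.assert_frame_equal(out.values, m.values)

    def test_shift_invariance(self):
        """Adding a constant to the sample with the highest median (which
        leaves the grand median untouched) must not change the output."""
        rng = np.random.default_rng(5)
        vals = rng.normal(25, 2, size=(21, 5))
        top = int(np.argmax(np.median(vals, axis=0)))
        m1 = preprocess.median_scale(make_matrix(vals.copy()))
        vals2 = vals.copy()
        vals2[:, top] += 7.0
        m2 = preprocess.median_scale(make_matrix(vals2))
        np.testing.assert_allclose(m1.values.to_numpy(), m2.values.to_numpy(), atol=1e-9)

    def test_all_medians_equal_after(self):
        rng = np.random.default_rng(6)
        vals = rng.normal(25, 3, size=(101, 7))
        out = preprocess.median_scale(make_matrix(vals))
        medians = out.values.median(axis=0).to_numpy()
        np.testing.assert_allclose(medians, medians[0], atol=1e-12)

    def test_missing_cells_rejected(self):
        with pytest.raises(ValueError):
            preprocess.median_scale(make_matrix([[1.0, np.nan]]))
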
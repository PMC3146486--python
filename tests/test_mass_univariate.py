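import numpy as np
import pytest
from scipy import ndimage, stats

from voxelage.age_detrend import apply_correction, fit_age_model
from voxelage.errors import RankDeficient
from voxelage.io_cohort import VolumeStack
from voxelage.masking import MaskVolume
from voxelage.mass_univariate import (
    DesignMatrix,
    age_correlation_map,
    cluster_fwe,
    glm_t_map,
    group_design,
    label_clusters,
)
from voxelage.synthetic import BoxRegion, PhantomSpec, SphereRegion, generate_cohort


MASK2 = MaskVolume.full((2, 2, 2))


def _stack(values_per_subject):
    arr = np.asarray(values_per_subject, dtype=float)
    data = np.broadcast_to(arr[:, None, None, None], (len(arr), 2, 2, 2)).copy()
    return VolumeStack(data, np.eye(4))


class TestDesignMatrix:
    def test_rank_deficient_rejected(self):
        X = np.column_stack([np.ones(5), np.ones(5)])
        with pytest.raises(RankDeficient):
            DesignMatrix(X, np.array([1.0, 0.0]))

    def test_df_is_n_minus_rank(self):
        d = group_design(["a", "a", "b", "b", "b"], "a")
        assert d.df == 3

    def test_contrast_length_checked(self):
        with pytest.raises(ValueError):
            DesignMatrix(np.eye(3), np.array([1.0, 0.0]))


class TestGlmTMap:
    def test_identical_groups_give_zero(self):
        stack = _stack([0.5, 0.5, 0.5, 0.5, 0.5, 0.5])
        design = group_design(["a"] * 3 + ["b"] * 3, "a")
        out = glm_t_map(stack, design, MASK2)
        np.testing.assert_array_equal(out.t, 0.0)

    def test_matches_explicit_normal_equation_oracle(self, rng):
        # 6 subjects, group + intercept + one covariate, single effective voxel
        y = rng.normal(size=6)
        covar = rng.normal(size=6)
        labels = ["a", "a", "a", "b", "b", "b"]
        design = group_design(labels, "a", {"z": covar})
        out = glm_t_map(_stack(y), design, MASK2)

        X, c = design.X, design.contrast
        XtX_inv = np.linalg.inv(X.T @ X)
        beta = XtX_inv @ X.T @ y
        resid = y - X @ beta
        df = 6 - 3
        t_oracle = (c @ beta) / np.sqrt(resid @ resid / df * (c @ XtX_inv @ c))
        np.testing.assert_allclose(out.t[MASK2.data], t_oracle, atol=1e-10)
        assert out.df == df

    def test_no_covariates_equals_pooled_two_sample_t(self, rng):
        y = rng.normal(0.5, 0.1, size=10)
        labels = np.array(["a"] * 5 + ["b"] * 5)
        out = glm_t_map(_stack(y), group_design(labels, "a"), MASK2)
        t_classic, _ = stats.ttest_ind(y[:5], y[5:], equal_var=True)
        np.testing.assert_allclose(out.t[MASK2.data], t_classic, atol=1e-10)

    def test_subject_count_mismatch(self):
        design = group_design(["a", "a", "b", "b"], "a")
        with pytest.raises(Exception):
            glm_t_map(_stack([1.0, 2.0, 3.0]), design, MASK2)


class TestAgeCorrelationMap:
    def test_null_phantom_false_positive_rate(self):
        # pure-noise controls: |t| > t_crit(p=0.001, two-tailed ~0.002) at ~0.1%/tail
        n, reps = 20, 200
        mask = MaskVolume.full((12, 12, 12))
        crit = stats.t.ppf(0.999, n - 3)
        exceed = 0
        total = 0
        rng = np.random.default_rng(99)
        for _ in range(reps):
            data = rng.normal(0.6, 0.02, size=(n, 12, 12, 12))
            stack = VolumeStack(data, np.eye(4))
            ages = rng.uniform(60, 90, size=n)
            sex = rng.integers(0, 2, size=n).astype(float)
            out = age_correlation_map(stack, ages, sex, mask)
            exceed += int((out.values > crit).sum())
            total += mask.n_in
        rate = exceed / total
        se = np.sqrt(0.001 * 0.999 / total)
        assert abs(rate - 0.001) < 5 * se

    def test_negative_slope_region_concentrates_negative_t(self):
        spec = PhantomSpec(
            n_controls=40,
            n_patients=3,
            beta_age=-0.006,
            beta_age_region=BoxRegion((2, 2, 2), (8, 8, 8)),
            noise_sd=0.01,
            seed=5,
        )
        stack, table, truth = generate_cohort(spec)
        idx = np.flatnonzero(table.groups == "control")
        controls = stack.subset(idx)
        sex = (table.sexes[idx] == "F").astype(float)
        mask = MaskVolume.full((16, 16, 16))
        out = age_correlation_map(controls, table.ages[idx], sex, mask)
        active = truth.beta_age_map < -1e-4
        assert out.t[active].mean() < -5
        assert abs(out.t[~active & mask.data].mean()) < 1

    def test_two_controls_rank_deficient(self):
        stack = VolumeStack(np.zeros((2, 2, 2, 2)), np.eye(4))
        with pytest.raises(RankDeficient):
            age_correlation_map(stack, np.array([60.0, 80.0]), np.array([0.0, 1.0]), MASK2)


class TestClusterLabeling:
    @pytest.mark.parametrize("connectivity", [6, 18, 26])
    def test_agrees_with_flood_fill_oracle(self, connectivity, rng):
        offsets = []
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                for dk in (-1, 0, 1):
                    dist = abs(di) + abs(dj) + abs(dk)
                    if dist == 0:
                        continue
                    if connectivity == 6 and dist > 1:
                        continue
                    if connectivity == 18 and dist > 2:
                        continue
                    offsets.append((di, dj, dk))

        def flood_sizes(grid):
            seen = np.zeros_like(grid, dtype=bool)
            sizes = []
            coords = np.argwhere(grid)
            for start in map(tuple, coords):
                if seen[start]:
                    continue
                stack_ = [start]
                seen[start] = True
                size = 0
                while stack_:
                    i, j, k = stack_.pop()
                    size += 1
                    for di, dj, dk in offsets:
                        ni, nj, nk = i + di, j + dj, k + dk
                        if 0 <= ni < 10 and 0 <= nj < 10 and 0 <= nk < 10:
                            if grid[ni, nj, nk] and not seen[ni, nj, nk]:
                                seen[ni, nj, nk] = True
                                stack_.append((ni, nj, nk))
                sizes.append(size)
            return sorted(sizes)

        for _ in range(5):
            grid = rng.random((10, 10, 10)) < 0.25
            labels, n = label_clusters(grid, connectivity)
            got = sorted(np.bincount(labels.ravel())[1:].tolist()) if n else []
            assert got == flood_sizes(grid)


def _noise_cohort(n_per_group, shape, rng, effect=0.0, region=None):
    n = 2 * n_per_group
    data = rng.normal(0.6, 0.05, size=(n,) + shape)
    if effect:
        sl = region.indicator(shape)
        data[n_per_group:, sl] -= effect  # second group = patients, atrophic
    labels = np.array(["control"] * n_per_group + ["patient"] * n_per_group)
    sex = rng.integers(0, 2, size=n).astype(float)
    return VolumeStack(data, np.eye(4)), labels, sex


class TestClusterFwe:
    def test_subthreshold_map_gives_empty_report(self, rng):
        stack, labels, sex = _noise_cohort(8, (8, 8, 8), rng)
        mask = MaskVolume.full((8, 8, 8))
        design = group_design(labels, "control", {"sex": sex})
        stat_map = glm_t_map(stack, design, mask)
        stat_map.t[:] = 0.0
        report = cluster_fwe(stat_map, stack, design, n_perm=100, seed=0)
        assert report.clusters == []
        assert report.significant() == []

    def test_planted_blob_detected(self, rng):
        # ~100-voxel sphere with a 3-sigma offset must survive FWE
        region = SphereRegion((7, 7, 7), 2.9)  # 93 voxels
        stack, labels, sex = _noise_cohort(15, (14, 14, 14), rng, effect=0.15, region=region)
        mask = MaskVolume.full((14, 14, 14))
        design = group_design(labels, "control", {"sex": sex})
        stat_map = glm_t_map(stack, design, mask)
        report = cluster_fwe(stat_map, stack, design, n_perm=500, seed=1)
        sig = report.significant(0.05)
        assert len(sig) >= 1
        assert sig[0].p_fwe <= 0.05
        # peak of the top cluster sits inside the planted region
        assert region.indicator((14, 14, 14))[sig[0].peak_ijk]

    def test_fixed_seed_bit_identical(self, rng):
        region = SphereRegion((6, 6, 6), 2.5)
        stack, labels, sex = _noise_cohort(10, (12, 12, 12), rng, effect=0.12, region=region)
        mask = MaskVolume.full((12, 12, 12))
        design = group_design(labels, "control", {"sex": sex})
        stat_map = glm_t_map(stack, design, mask)
        r1 = cluster_fwe(stat_map, stack, design, n_perm=120, seed=42)
        r2 = cluster_fwe(stat_map, stack, design, n_perm=120, seed=42)
        assert r1.clusters == r2.clusters

    def test_validates_parameters(self, rng):
        stack, labels, sex = _noise_cohort(5, (6, 6, 6), rng)
        design = group_design(labels, "control")
        stat_map = glm_t_map(stack, design, MaskVolume.full((6, 6, 6)))
        with pytest.raises(ValueError):
            cluster_fwe(stat_map, stack, design, n_perm=10)
        with pytest.raises(ValueError):
            cluster_fwe(stat_map, stack, design, voxel_p=1.5)


class TestCovariateRegimes:
    """Age-as-covariate vs detrended-input analyses."""

    def _confounded(self, seed):
        spec = PhantomSpec(
            n_controls=25,
            n_patients=25,
            beta_age=-0.004,
            atrophy_delta=-0.04,
            atrophy_region=SphereRegion((11, 11, 11), 3),
            noise_sd=0.02,
            patient_age_shift=-10.0,
            seed=seed,
        )
        return generate_cohort(spec)

    def test_covariate_and_detrended_coincide_when_fit_jointly(self, rng):
        # orthogonal construction: identical age multisets in both groups and a
        # detrending fit on ALL analysis subjects; with df adjusted for the
        # pre-regression, the age-covariate GLM and the detrended-input GLM
        # produce identical t maps.
        shape = (8, 8, 8)
        mask = MaskVolume.full(shape)
        ages_half = rng.uniform(60, 90, size=10)
        ages = np.concatenate([ages_half, ages_half])
        labels = np.array(["control"] * 10 + ["patient"] * 10)
        data = rng.normal(0.6, 0.05, size=(20,) + shape)
        data += -0.003 * ages[:, None, None, None]
        stack = VolumeStack(data, np.eye(4))

        design_b = group_design(labels, "control", {"age": ages})
        t_with_covariate = glm_t_map(stack, design_b, mask)

        model = fit_age_model(stack, ages, mask)  # joint fit, deliberately
        corrected = apply_correction(stack, ages, model, mask)
        design_c = group_design(labels, "control")
        t_detrended = glm_t_map(corrected, design_c, mask, df_adjust=1)

        assert t_detrended.df == t_with_covariate.df
        np.testing.assert_allclose(
            t_detrended.t[mask.data], t_with_covariate.t[mask.data], atol=1e-8
        )

    def test_regimes_differ_on_confounded_phantom(self):
        # controls-only fit + unequal age distributions: no such equivalence
        stack, table, _ = self._confounded(13)
        mask = MaskVolume.full((16, 16, 16))
        is_control = table.groups == "control"
        controls = stack.subset(np.flatnonzero(is_control))
        model = fit_age_model(controls, table.ages[is_control], mask)
        corrected = apply_correction(stack, table.ages, model, mask)

        design_b = group_design(table.groups, "control", {"age": table.ages})
        design_c = group_design(table.groups, "control")
        t_b = glm_t_map(stack, design_b, mask).t
        t_c = glm_t_map(corrected, design_c, mask).t
        assert np.abs(t_b - t_c).max() > 0.1
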
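"""Feature extraction, standardization, linear kernels and the FPC."""

import numpy as np
import pytest

import lesiondecode as ld
from lesiondecode.features import ExtractionError, normalize_rows
from oracles import fpc_oracle


def _vol(arr, sid="s"):
    return ld.LesionProbabilityVolume(np.asarray(arr, float), sid)


class TestVoxelPatterns:
    def test_shape_contract(self, atlas):
        mask = ld.RoiMask(np.zeros(atlas.shape, bool), "m", "atlas_subset")
        mask.mask.ravel()[:5] = True
        probs = [ld.simulate_lesion(atlas, seed=s, subject_id=f"s{s}") for s in range(3)]
        fm = ld.extract_voxel_patterns(probs, mask)
        assert fm.values.shape == (3, 5)
        assert len(fm.column_map) == 5

    def test_zero_subject_gives_zero_row(self, atlas):
        mask = ld.RoiMask(atlas.labels > 0, "m", "atlas_all")
        fm = ld.extract_voxel_patterns([_vol(np.zeros(atlas.shape))], mask)
        assert not fm.values.any()

    def test_declared_column_order_read_off(self):
        vol = np.zeros((2, 2, 1))
        vol[0, 0, 0] = 0.2
        vol[1, 1, 0] = 0.7
        mask = np.zeros((2, 2, 1), bool)
        mask[0, 0, 0] = mask[1, 1, 0] = True
        fm = ld.extract_voxel_patterns(
            [_vol(vol)], ld.RoiMask(mask, "m", "atlas_subset")
        )
        # ascending flat C-order index: (0,0,0) before (1,1,0)
        assert fm.values.tolist() == [[0.2, 0.7]]

    def test_empty_mask_rejected(self):
        with pytest.raises(ExtractionError):
            ld.extract_voxel_patterns(
                [_vol(np.zeros((2, 2, 2)))],
                ld.RoiMask(np.zeros((2, 2, 2), bool), "m", "atlas_subset"),
            )


class TestLesionLoad:
    def _region(self, shape, sl):
        m = np.zeros(shape, bool)
        m[sl] = True
        return ld.RoiMask(m, "r", "atlas_subset")

    def test_full_cover_and_disjoint(self):
        region = self._region((4, 4, 4), np.s_[:2])
        full = ld.BinaryLesionMask(region.mask.copy(), "a")
        off = ld.BinaryLesionMask(~region.mask, "b")
        fm = ld.extract_lesion_load([full, off], [region])
        assert fm.values[:, 0].tolist() == [1.0, 0.0]

    def test_fractional_load(self):
        region = self._region((4, 4, 4), np.s_[0, :2, :4])  # 8 voxels
        les = np.zeros((4, 4, 4), bool)
        les[0, 0, :2] = True  # 2 of them
        fm = ld.extract_lesion_load([ld.BinaryLesionMask(les, "a")], [region])
        assert fm.values[0, 0] == pytest.approx(0.25)

    def test_atlas_gives_one_column_per_region(self, atlas, cohort):
        fm = ld.extract_lesion_load(cohort.lesion_masks[:4], atlas)
        assert fm.values.shape == (4, len(atlas.regions))
        assert (fm.values >= 0).all() and (fm.values <= 1).all()

    def test_whole_brain_load_equals_volume_fraction(self, atlas, cohort):
        whole = ld.RoiMask(np.ones(atlas.shape, bool), "wb", "whole_brain")
        fm = ld.extract_lesion_load(cohort.lesion_masks, [whole])
        for i, m in enumerate(cohort.lesion_masks):
            assert fm.values[i, 0] == pytest.approx(m.n_voxels / m.mask.size)

    def test_zero_voxel_region_rejected(self):
        empty = ld.RoiMask(np.zeros((3, 3, 3), bool), "e", "atlas_subset")
        with pytest.raises(ExtractionError, match="zero voxels"):
            ld.extract_lesion_load(
                [ld.BinaryLesionMask(np.zeros((3, 3, 3), bool), "a")], [empty]
            )


class TestStandardize:
    def _fm(self, values):
        v = np.asarray(values, float)
        return ld.FeatureMatrix(v, [f"s{i}" for i in range(len(v))],
                                "voxel_pattern", "test", np.arange(v.shape[1]))

    def test_row_normalization_3_4(self):
        out = normalize_rows(np.array([[3.0, 4.0]]))
        assert out.tolist() == [[0.6, 0.8]]

    def test_zero_rows_pass_through(self):
        out = normalize_rows(np.array([[0.0, 0.0], [3.0, 4.0]]))
        assert out[0].tolist() == [0.0, 0.0]

    def test_train_columns_zero_mean_unit_sd(self):
        rng = np.random.default_rng(2)
        tr, _, _ = ld.standardize(self._fm(rng.uniform(size=(10, 6))))
        assert np.allclose(tr.values.mean(axis=0), 0, atol=1e-10)
        assert np.allclose(tr.values.std(axis=0), 1, atol=1e-10)

    def test_constant_column_centred_unscaled(self):
        # column 1 is constant (zero) even after row normalization
        tr, _, params = ld.standardize(
            self._fm([[1.0, 0.0], [2.0, 0.0], [4.0, 0.0]])
        )
        assert params.sd[1] == 1.0
        assert np.allclose(tr.values[:, 1], 0.0)

    def test_test_row_equal_to_train_row_maps_identically(self):
        rng = np.random.default_rng(4)
        X = rng.uniform(size=(6, 5))
        tr, te, _ = ld.standardize(self._fm(X), self._fm(X[2:3]))
        assert np.allclose(te.values[0], tr.values[2])

    def test_single_training_row_rejected(self):
        with pytest.raises(ValueError):
            ld.standardize(self._fm([[1.0, 2.0]]))


class TestLinearKernel:
    def _fm(self, values):
        v = np.asarray(values, float)
        return ld.FeatureMatrix(v, [f"s{i}" for i in range(len(v))],
                                "voxel_pattern", "t", np.arange(v.shape[1]))

    def test_orthonormal_rows_give_identity(self):
        K = ld.linear_kernel(self._fm(np.eye(3)))
        assert np.allclose(K.values, np.eye(3))
        assert K.symmetric

    def test_hand_example(self):
        K = ld.linear_kernel(self._fm([[1.0, 0.0], [1.0, 1.0]]))
        assert K.values.tolist() == [[1.0, 1.0], [1.0, 2.0]]

    def test_self_kernel_psd(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            X = rng.normal(size=(8, 4))
            K = ld.linear_kernel(self._fm(X)).values
            assert np.linalg.eigvalsh(K).min() >= -1e-8 * np.trace(K)

    def test_column_mismatch_rejected(self):
        a, b = self._fm(np.ones((2, 3))), self._fm(np.ones((2, 4)))
        with pytest.raises(ValueError):
            ld.linear_kernel(a, b)

    def test_kernel_invariant_to_uniform_row_rescaling(self):
        rng = np.random.default_rng(6)
        X = rng.uniform(0.1, 1.0, size=(7, 5))
        tr1, _, _ = ld.standardize(self._fm(X))
        tr2, _, _ = ld.standardize(self._fm(X * 37.5))
        K1 = ld.linear_kernel(tr1).values
        K2 = ld.linear_kernel(tr2).values
        assert np.allclose(K1, K2, atol=1e-10)


class TestFpcScores:
    def test_identical_columns_symmetric_loadings(self):
        rng = np.random.default_rng(7)
        col = rng.normal(size=12)
        Y = np.tile(col[:, None], (1, 4))
        res = ld.fpc_scores(Y)
        assert np.allclose(res.loadings, 0.5)
        r = np.corrcoef(res.train_scores, col)[0, 1]
        assert r == pytest.approx(1.0)

    def test_leading_direction_dominates_random_projections(self):
        rng = np.random.default_rng(8)
        Y = rng.normal(size=(30, 4)) @ np.diag([3.0, 1.0, 0.5, 0.2])
        res = ld.fpc_scores(Y)
        var_fpc = res.train_scores.var()
        centred = Y - Y.mean(axis=0)
        for _ in range(100):
            u = rng.normal(size=4)
            u /= np.linalg.norm(u)
            assert var_fpc >= (centred @ u).var() - 1e-12

    def test_matches_svd_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            Y = rng.normal(size=(5, 4)) * [5, 2, 1, 0.3]
            res = ld.fpc_scores(Y)
            oracle_scores, oracle_load = fpc_oracle(Y)
            assert np.allclose(res.loadings, oracle_load, atol=1e-8)
            assert np.allclose(res.train_scores, oracle_scores, atol=1e-8)

    def test_test_rows_centred_with_training_means(self):
        rng = np.random.default_rng(10)
        Y = rng.normal(size=(10, 4))
        T = rng.normal(size=(3, 4)) + 50.0  # far off the training mean
        res = ld.fpc_scores(Y, T)
        expect = (T - Y.mean(axis=0)) @ res.loadings
        assert np.allclose(res.test_scores, expect)

    def test_degenerate_eigenvalues_warn(self):
        Y = np.array([[1, 0, 0, 0], [-1, 0, 0, 0], [0, 1, 0, 0], [0, -1, 0, 0]], float)
        with pytest.warns(RuntimeWarning, match="degenerate"):
            ld.fpc_scores(Y)

    def test_single_voxel_region_degenerate_agreement(self, atlas):
        # binary probabilities + single-voxel region: voxel pattern entries
        # equal lesion-load entries
        v = np.argwhere(atlas.labels == 1)[0]
        region = np.zeros(atlas.shape, bool)
        region[tuple(v)] = True
        binary = np.zeros(atlas.shape)
        binary[tuple(v)] = 1.0
        probs = [_vol(binary, "a"), _vol(np.zeros(atlas.shape), "b")]
        masks = [
            ld.BinaryLesionMask(binary.astype(bool), "a"),
            ld.BinaryLesionMask(np.zeros(atlas.shape, bool), "b"),
        ]
        vp = ld.extract_voxel_patterns(probs, ld.RoiMask(region, "r", "atlas_subset"))
        llo = ld.extract_lesion_load(masks, [ld.RoiMask(region, "r", "atlas_subset")])
        assert np.allclose(vp.values, llo.values)
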
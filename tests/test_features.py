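"""Union masks, feature assembly, PCA, imputation, confound regression."""

import numpy as np
import pandas as pd
import pytest

from mmlnm import (
    GridSpec,
    Volume,
    assemble_matrix,
    build_union_mask,
    concat_modalities,
    impute_behavior,
    pca_features,
    regress_confounds,
)
from mmlnm.features import LOG_EPS
from mmlnm.synthetic import CONFOUND_COLUMNS, SCORE_COLUMNS


@pytest.fixture(scope="module")
def tiny_grid():
    return GridSpec((5, 4, 4), (2.0, 2.0, 2.0))


def _vol(grid, voxels, values=1.0):
    data = np.zeros(grid.shape)
    vals = values if np.iterable(values) else [values] * len(voxels)
    for v, x in zip(voxels, vals):
        data[v] = x
    return Volume(data, grid)


class TestUnionMask:
    def test_disjoint_supports_add(self, tiny_grid):
        a = _vol(tiny_grid, [(0, 0, 0), (1, 1, 1)])
        b = _vol(tiny_grid, [(2, 2, 2)])
        mask = build_union_mask([a, b])
        assert mask.data.sum() == 3

    def test_identical_supports(self, tiny_grid):
        a = _vol(tiny_grid, [(0, 0, 0), (1, 1, 1)])
        mask = build_union_mask([a, a, a])
        assert mask.data.sum() == 2

    def test_matches_set_union_oracle(self, tiny_grid):
        rng = np.random.default_rng(0)
        maps = [Volume((rng.random(tiny_grid.shape) > 0.7) * rng.random(tiny_grid.shape), tiny_grid)
                for _ in range(4)]
        mask = build_union_mask(maps)
        oracle = set()
        for m in maps:
            oracle |= {tuple(v) for v in np.argwhere(m.data != 0)}
        assert int(mask.data.sum()) == len(oracle)

    def test_monotone_under_new_patient(self, tiny_grid):
        rng = np.random.default_rng(1)
        maps = [Volume((rng.random(tiny_grid.shape) > 0.8).astype(float), tiny_grid)
                for _ in range(3)]
        base = build_union_mask(maps[:2]).data
        grown = build_union_mask(maps).data
        assert np.all(grown >= base)

    def test_all_zero_rejected(self, tiny_grid):
        zero = Volume(np.zeros(tiny_grid.shape), tiny_grid)
        with pytest.raises(ValueError, match="empty"):
            build_union_mask([zero])


class TestAssembleMatrix:
    def test_sc_log_transform_of_zero(self, tiny_grid):
        maps = [_vol(tiny_grid, [(0, 0, 0)], 2.0), _vol(tiny_grid, [(1, 0, 0)], 1.0)]
        mask = build_union_mask(maps)
        fs = assemble_matrix(maps, mask, "SC")
        assert np.min(fs.matrix) == pytest.approx(np.log(LOG_EPS))

    def test_standardized_columns(self, tiny_grid):
        rng = np.random.default_rng(2)
        maps = [Volume(rng.random(tiny_grid.shape), tiny_grid) for _ in range(3)]
        mask = build_union_mask(maps)
        fs = assemble_matrix(maps, mask, "FC", standardize=True)
        np.testing.assert_allclose(fs.matrix.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(fs.matrix.std(axis=0), 1.0, atol=1e-12)

    def test_constant_column_zeroed_and_flagged(self, tiny_grid):
        maps = [_vol(tiny_grid, [(0, 0, 0), (1, 0, 0)], [1.0, 5.0]) for _ in range(3)]
        mask = build_union_mask(maps)
        fs = assemble_matrix(maps, mask, "FC", standardize=True)
        assert fs.constant_columns.all()
        np.testing.assert_array_equal(fs.matrix, 0.0)

    def test_lesion_mode_binary(self, tiny_grid):
        maps = [_vol(tiny_grid, [(0, 0, 0)], 3.0), _vol(tiny_grid, [(1, 0, 0)], 1.0)]
        mask = build_union_mask(maps)
        fs = assemble_matrix(maps, mask, "LESION")
        assert set(np.unique(fs.matrix)) <= {0.0, 1.0}

    def test_nan_rejected_with_report(self, tiny_grid):
        bad = np.zeros(tiny_grid.shape)
        bad[0, 0, 0] = np.nan
        maps = [Volume(bad, tiny_grid), _vol(tiny_grid, [(0, 0, 0)])]
        mask = build_union_mask([_vol(tiny_grid, [(0, 0, 0)])])
        with pytest.raises(ValueError, match="NaN"):
            assemble_matrix(maps, mask, "FC")


class TestConcat:
    def _fs(self, tiny_grid, n_vox, seed):
        rng = np.random.default_rng(seed)
        maps = [Volume(rng.random(tiny_grid.shape) * (rng.random(tiny_grid.shape) > 0.3),
                       tiny_grid) for _ in range(4)]
        mask = build_union_mask(maps)
        return assemble_matrix(maps, mask, "FC", standardize=True)

    def test_widths_and_boundary(self, tiny_grid):
        sc = self._fs(tiny_grid, 10, 0)
        fc = self._fs(tiny_grid, 15, 1)
        out = concat_modalities(sc, fc)
        assert out.matrix.shape[1] == sc.matrix.shape[1] + fc.matrix.shape[1]
        assert out.boundary == sc.matrix.shape[1]
        np.testing.assert_array_equal(out.matrix[:, : out.boundary], sc.matrix)
        np.testing.assert_array_equal(out.matrix[:, out.boundary :], fc.matrix)
        np.testing.assert_allclose(out.matrix.mean(axis=0), 0.0, atol=1e-12)

    def test_unstandardized_rejected(self, tiny_grid):
        rng = np.random.default_rng(3)
        maps = [Volume(rng.random(tiny_grid.shape), tiny_grid) for _ in range(4)]
        mask = build_union_mask(maps)
        raw = assemble_matrix(maps, mask, "FC")
        std = assemble_matrix(maps, mask, "FC", standardize=True)
        with pytest.raises(ValueError, match="standardized"):
            concat_modalities(raw, std)


class TestPCA:
    def _fs(self, X, tiny_grid):
        n, p = X.shape
        mask_data = np.zeros(tiny_grid.shape, dtype=np.uint8)
        mask_data.ravel()[:p] = 1
        maps = []
        for row in X:
            d = np.zeros(tiny_grid.shape)
            d.ravel()[:p] = row
            maps.append(Volume(d, tiny_grid))
        mask = Volume(mask_data, tiny_grid)
        return assemble_matrix(maps, mask, "FC")

    def test_rank_one_single_component(self, tiny_grid):
        rng = np.random.default_rng(0)
        X = np.outer(rng.standard_normal(10), rng.standard_normal(6))
        pca = pca_features(self._fs(X, tiny_grid))
        assert pca.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-9)

    def test_isotropic_noise_flat_spectrum(self, tiny_grid):
        # sample spectra of isotropic noise are only approximately flat:
        # Marchenko-Pastur puts the max/min eigenvalue ratio near
        # ((1+sqrt(p/n))/(1-sqrt(p/n)))^2 ~ 7 at n=50, p=10, far below any
        # low-rank spike, and no component should dominate
        rng = np.random.default_rng(1)
        X = rng.standard_normal((50, 10))
        pca = pca_features(self._fs(X, tiny_grid), k_max=10)
        ratios = pca.explained_variance_ratio
        assert ratios[0] / ratios[-1] < 12
        assert ratios[0] < 0.35

    def test_scores_covariance_diagonal(self, tiny_grid):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((20, 8))
        pca = pca_features(self._fs(X, tiny_grid))
        cov = np.cov(pca.scores, rowvar=False)
        off = cov - np.diag(np.diag(cov))
        assert np.max(np.abs(off)) < 1e-8

    def test_loadings_orthonormal_and_reconstruction(self, tiny_grid):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((12, 9))
        fs = self._fs(X, tiny_grid)
        pca = pca_features(fs)
        gram = pca.loadings @ pca.loadings.T
        np.testing.assert_allclose(gram, np.eye(gram.shape[0]), atol=1e-8)
        np.testing.assert_allclose(pca.reconstruct(), fs.matrix, atol=1e-6)

    def test_k_max_too_large_rejected(self, tiny_grid):
        X = np.random.default_rng(4).standard_normal((6, 9))
        with pytest.raises(ValueError, match="k_max"):
            pca_features(self._fs(X, tiny_grid), k_max=9)


class TestImputation:
    def _table(self, n=20, seed=0, missing=None):
        rng = np.random.default_rng(seed)
        base = rng.integers(5, 50, n).astype(float)
        table = pd.DataFrame(
            {
                "ARAT": base + rng.integers(-3, 4, n),
                "FMA_UE": base + rng.integers(-3, 4, n),
                "EM_NSA": rng.integers(0, 41, n).astype(float),
                "PTT": rng.uniform(1, 10, n),
                "age": rng.uniform(30, 90, n),
                "tbsaa": rng.uniform(4, 64, n),
                "lesion_size": rng.uniform(1, 200, n),
            }
        )
        for row, col in missing or []:
            table.loc[row, col] = np.nan
        return table

    def test_complete_table_identity(self):
        table = self._table()
        out, log = impute_behavior(table, seed=0)
        pd.testing.assert_frame_equal(out, table)
        assert len(log) == 0

    def test_collinear_scores_recovered_within_one_unit(self):
        table = self._table(n=30, seed=1)
        table["FMA_UE"] = table["ARAT"]  # exactly collinear
        true_val = table.loc[5, "ARAT"]
        table.loc[5, "ARAT"] = np.nan
        out, log = impute_behavior(table, seed=1)
        assert abs(out.loc[5, "ARAT"] - true_val) <= 1.0
        assert len(log) == 1

    def test_observed_cells_untouched(self):
        table = self._table(n=25, seed=2, missing=[(3, "PTT"), (7, "EM_NSA")])
        out, _ = impute_behavior(table, seed=2)
        observed = ~table[list(SCORE_COLUMNS)].isna()
        for col in SCORE_COLUMNS:
            rows = observed[col]
            pd.testing.assert_series_equal(
                out.loc[rows, col], table.loc[rows, col], check_names=False
            )

    def test_cohort_missingness_pattern_filled_exactly(self):
        # 0 missing ARAT, 3 FMA-UE, 2 Em-NSA, 2 PTT -> 7 cells imputed
        missing = [(1, "FMA_UE"), (4, "FMA_UE"), (9, "FMA_UE"),
                   (2, "EM_NSA"), (11, "EM_NSA"), (6, "PTT"), (13, "PTT")]
        table = self._table(n=54, seed=3, missing=missing)
        out, log = impute_behavior(table, seed=3)
        assert len(log) == 7
        assert not out[list(SCORE_COLUMNS)].isna().any().any()

    def test_deterministic_given_seed(self):
        table = self._table(n=25, seed=4, missing=[(3, "PTT"), (8, "ARAT")])
        out1, _ = impute_behavior(table, seed=7)
        out2, _ = impute_behavior(table, seed=7)
        pd.testing.assert_frame_equal(out1, out2)

    def test_entirely_missing_column_rejected(self):
        table = self._table(n=10, seed=5)
        table["PTT"] = np.nan
        with pytest.raises(ValueError, match="entirely missing"):
            impute_behavior(table)


class TestConfoundRegression:
    def _table(self, n=40, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            {
                "ARAT": rng.uniform(0, 57, n),
                "FMA_UE": rng.uniform(0, 66, n),
                "EM_NSA": rng.uniform(0, 40, n),
                "PTT": rng.uniform(1, 11, n),
                "age": rng.uniform(30, 90, n),
                "tbsaa": rng.uniform(4, 64, n),
                "lesion_size": rng.uniform(1, 200, n),
            }
        )

    def test_output_standardized_and_orthogonal(self):
        table = self._table()
        prep = regress_confounds(table)
        np.testing.assert_allclose(prep.Y.mean(axis=0), 0.0, atol=1e-8)
        np.testing.assert_allclose(prep.Y.std(axis=0), 1.0, atol=1e-8)
        C = table[list(CONFOUND_COLUMNS)].to_numpy()
        Cc = C - C.mean(axis=0)
        assert np.max(np.abs(Cc.T @ prep.Y)) < 1e-8

    def test_score_equal_to_confound_flagged(self):
        table = self._table(seed=1)
        table["ARAT"] = 2.0 * table["age"]
        prep = regress_confounds(table)
        assert prep.zero_variance[0]
        np.testing.assert_allclose(prep.Y[:, 0], 0.0, atol=1e-8)

    def test_orthogonal_scores_equal_centered_zscored(self):
        rng = np.random.default_rng(2)
        table = self._table(seed=2)
        C = table[list(CONFOUND_COLUMNS)].to_numpy()
        Cc = np.column_stack([np.ones(len(table)), C])
        # build a score orthogonal to the confound design
        y = rng.standard_normal(len(table))
        y -= Cc @ np.linalg.lstsq(Cc, y, rcond=None)[0]
        table["ARAT"] = y
        prep = regress_confounds(table)
        expected = (y - y.mean()) / y.std()
        np.testing.assert_allclose(prep.Y[:, 0], expected, atol=1e-8)

    def test_missing_scores_rejected(self):
        table = self._table(seed=3)
        table.loc[0, "PTT"] = np.nan
        with pytest.raises(ValueError, match="impute"):
            regress_confounds(table)
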
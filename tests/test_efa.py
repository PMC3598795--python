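"""Factor extraction, rotations, and the simple-structure reduction screen."""

import numpy as np
import pandas as pd
import pytest

from psychfield.efa import (
    LoadingMatrix,
    efa_from_dataset,
    principal_axis_factoring,
    promax,
    reduction_candidates,
    simple_structure_flags,
    varimax,
    varimax_criterion,
)
from psychfield.simulate import SimulationConfig, simulate, uniform_factor_corr

from conftest import make_instrument


def one_factor_R(lam, p):
    R = np.full((p, p), lam * lam)
    np.fill_diagonal(R, 1.0)
    return R


def block_R(block_loading, sizes):
    p = sum(sizes)
    R = np.eye(p)
    start = 0
    for k in sizes:
        R[start:start + k, start:start + k] = block_loading**2
        start += k
    np.fill_diagonal(R, 1.0)
    return R


def procrustes_rmse(L, target):
    """RMSE after the best orthogonal alignment of L to target."""
    U, _, Vt = np.linalg.svd(target.T @ L)
    aligned = L @ (U @ Vt).T
    return float(np.sqrt(np.mean((aligned - target) ** 2)))


class TestPAF:
    def test_identity_matrix_has_no_common_variance(self):
        lm = principal_axis_factoring(np.eye(6), n_factors=2)
        assert np.allclose(lm.loadings.to_numpy(), 0, atol=1e-6)
        assert np.allclose(lm.communalities.to_numpy(), 0, atol=1e-6)

    def test_one_factor_loadings_recovered(self):
        lm = principal_axis_factoring(one_factor_R(0.8, 6), n_factors=1)
        assert np.allclose(lm.loadings.to_numpy().ravel(), 0.8, atol=1e-3)
        assert lm.converged

    def test_two_block_structure_recovered(self):
        R = block_R(0.8, [3, 3])
        lm = principal_axis_factoring(R, n_factors=2)
        target = np.zeros((6, 2))
        target[:3, 0] = 0.8
        target[3:, 1] = 0.8
        assert procrustes_rmse(lm.loadings.to_numpy(), target) < 0.02

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            principal_axis_factoring(np.array([[1.0, 0.5], [0.2, 1.0]]), 1)
        with pytest.raises(ValueError, match="unit diagonal"):
            principal_axis_factoring(np.array([[2.0, 0.5], [0.5, 2.0]]), 1)
        with pytest.raises(ValueError, match="n_factors"):
            principal_axis_factoring(np.eye(4), 4)

    def test_eigenvalue_diagnostics_present(self):
        lm = principal_axis_factoring(one_factor_R(0.8, 5), 1)
        assert lm.eigenvalues is not None
        # one dominant eigenvalue 1 + (p-1)lam^2, rest 1 - lam^2
        assert lm.eigenvalues[0] == pytest.approx(1 + 4 * 0.64, abs=1e-10)
        assert np.allclose(lm.eigenvalues[1:], 0.36, atol=1e-10)


class TestVarimax:
    def test_simple_blocks_are_a_fixed_point(self):
        lm = principal_axis_factoring(block_R(0.8, [3, 3]), 2)
        vm = varimax(lm)
        assert varimax_criterion(vm.loadings.to_numpy()) == pytest.approx(
            varimax_criterion(lm.loadings.to_numpy()), abs=1e-9
        ) or varimax_criterion(vm.loadings.to_numpy()) >= varimax_criterion(
            lm.loadings.to_numpy()
        )

    def test_communalities_preserved(self):
        rng = np.random.default_rng(41)
        L = rng.normal(size=(10, 3))
        lm = LoadingMatrix(
            loadings=pd.DataFrame(L, columns=["F1", "F2", "F3"]),
            communalities=pd.Series((L**2).sum(axis=1)),
        )
        vm = varimax(lm)
        assert np.allclose(
            (vm.loadings.to_numpy() ** 2).sum(axis=1), (L**2).sum(axis=1), atol=1e-10
        )

    def test_criterion_never_decreases(self):
        rng = np.random.default_rng(42)
        L = rng.normal(size=(10, 2))
        lm = LoadingMatrix(
            loadings=pd.DataFrame(L, columns=["F1", "F2"]),
            communalities=pd.Series((L**2).sum(axis=1)),
        )
        vm = varimax(lm, normalize=False)
        assert varimax_criterion(vm.loadings.to_numpy()) >= varimax_criterion(L) - 1e-12

    def test_single_factor_returned_unchanged(self):
        lm = principal_axis_factoring(one_factor_R(0.7, 5), 1)
        vm = varimax(lm)
        pd.testing.assert_frame_equal(vm.loadings, lm.loadings)


class TestPromax:
    def make_block_varimax(self):
        lm = principal_axis_factoring(block_R(0.8, [4, 4]), 2)
        return varimax(lm)

    def test_orthogonal_input_keeps_factors_uncorrelated(self):
        vm = self.make_block_varimax()
        pm = promax(vm)
        phi = pm.factor_corr.to_numpy()
        off = phi[~np.eye(2, dtype=bool)]
        assert np.all(np.abs(off) < 0.05)
        assert np.allclose(
            np.abs(pm.loadings.to_numpy()), np.abs(vm.loadings.to_numpy()), atol=0.05
        )

    def test_kappa_one_is_near_identity(self):
        vm = self.make_block_varimax()
        pm = promax(vm, kappa=1)
        assert np.allclose(pm.loadings.to_numpy(), vm.loadings.to_numpy(), atol=1e-8)
        assert np.allclose(pm.factor_corr.to_numpy(), np.eye(2), atol=1e-8)

    def test_factor_correlation_matrix_is_proper(self):
        vm = self.make_block_varimax()
        pm = promax(vm)
        phi = pm.factor_corr.to_numpy()
        assert np.allclose(phi, phi.T)
        assert np.allclose(np.diag(phi), 1.0)
        assert np.linalg.eigvalsh(phi).min() >= -1e-8

    def test_recovers_inter_factor_correlation(self):
        """Two-block data with latent rho=0.5 -> promax phi within +-0.1."""
        inst = make_instrument([6, 6])
        cfg = SimulationConfig(
            n_respondents=2000, instrument=inst,
            factor_corr=uniform_factor_corr(2, 0.5), loadings=0.8,
            item_missing_rate=0.0, sensitive_block_missing_rate=0.0,
            group_shifts=(0.0, 0.0, 0.0), seed=43,
        )
        ds, _ = simulate(cfg)
        lm = efa_from_dataset(ds, inst, n_factors=2, rotation="promax")
        phi = lm.factor_corr.to_numpy()
        assert abs(abs(phi[0, 1]) - 0.5) < 0.1


class TestSimpleStructure:
    def lm_from(self, rows):
        L = np.asarray(rows, dtype=float)
        cols = [f"F{j + 1}" for j in range(L.shape[1])]
        return LoadingMatrix(
            loadings=pd.DataFrame(L, columns=cols, index=[f"i{r}" for r in range(len(L))]),
            communalities=pd.Series((L**2).sum(axis=1)),
        )

    @pytest.mark.parametrize(
        "row,expected",
        [
            ([0.8, 0.05], "simple"),
            ([0.35, 0.31], "cross-loading"),
            ([0.29, 0.29], "no-salient-loading"),
            ([0.30, 0.05], "simple"),  # cutoff inclusive
            ([-0.8, 0.05], "simple"),  # absolute loadings
        ],
    )
    def test_status_partition(self, row, expected):
        rep = simple_structure_flags(self.lm_from([row]))
        assert rep.table["status"].iloc[0] == expected

    def test_invariant_to_column_permutation_and_sign(self):
        rows = [[0.8, 0.1], [0.2, 0.6], [0.4, 0.4]]
        base = simple_structure_flags(self.lm_from(rows)).table["status"]
        flipped = [[r[1], -r[0]] for r in rows]
        perm = simple_structure_flags(self.lm_from(flipped)).table["status"]
        assert base.tolist() == perm.tolist()


class TestReductionCandidates:
    def test_noise_item_ranked_first(self):
        inst = make_instrument([5, 3])
        lam = {i: 0.85 for i in inst.item_ids}
        lam["s1i5"] = 0.0  # pure-noise item inside Scale1
        cfg = SimulationConfig(
            n_respondents=800, instrument=inst, factor_corr=np.eye(2),
            loadings=lam, item_missing_rate=0.0, sensitive_block_missing_rate=0.0,
            group_shifts=(0.0, 0.0, 0.0), seed=44,
        )
        ds, _ = simulate(cfg)
        lm = efa_from_dataset(ds, inst, n_factors=2)
        ss = simple_structure_flags(lm)
        from psychfield import alpha_if_item_deleted, cronbach_alpha
        from psychfield.scoring import transform_item

        block = pd.DataFrame(
            transform_item(ds.raw[list(inst.subscale("Scale1").item_ids)].to_numpy()),
            columns=list(inst.subscale("Scale1").item_ids),
        )
        gains = alpha_if_item_deleted(block)["alpha_if_deleted"] - cronbach_alpha(block)
        out = reduction_candidates(ss, gains)
        assert out["candidate"].any()
        assert out.index[0] == "s1i5"

    def test_all_simple_and_no_gain_gives_no_candidates(self):
        lm = LoadingMatrix(
            loadings=pd.DataFrame(
                [[0.8, 0.0], [0.7, 0.1], [0.0, 0.75]],
                columns=["F1", "F2"], index=["a", "b", "c"],
            ),
            communalities=pd.Series([0.64, 0.5, 0.5625], index=["a", "b", "c"]),
        )
        ss = simple_structure_flags(lm)
        gains = pd.Series({"a": -0.02, "b": -0.01, "c": -0.03})
        out = reduction_candidates(ss, gains)
        assert not out["candidate"].any()

    def test_rule_is_a_conjunction(self):
        lm = LoadingMatrix(
            loadings=pd.DataFrame(
                [[0.4, 0.4], [0.8, 0.0]], columns=["F1", "F2"], index=["x", "y"]
            ),
            communalities=pd.Series([0.32, 0.64], index=["x", "y"]),
        )
        ss = simple_structure_flags(lm)
        # x is cross-loading but deleting it lowers alpha -> flag-only
        out = reduction_candidates(ss, pd.Series({"x": -0.05, "y": 0.02}))
        assert not out.loc["x", "candidate"]
        assert not out.loc["y", "candidate"]  # simple, despite the gain


def test_low_case_to_item_ratio_warns(spec, ds134):
    with pytest.warns(UserWarning, match="5:1"):
        efa_from_dataset(ds134, spec, n_factors=5)
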
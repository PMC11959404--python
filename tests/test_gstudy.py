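import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mvgt.errors import (
    IdentifiabilityError,
    MvgtError,
    UnbalancedDesignError,
    UndefinedStatisticError,
)
from mvgt.gstudy import (
    GStudyComponents,
    estimate,
    estimate_balanced,
    estimate_unbalanced,
    proportion_table,
)
from mvgt.simulate import generate_dataset
from mvgt.tables import SCORE_COLUMNS

from .conftest import make_config
from .oracles import naive_balanced_components


def grid_table(y):
    """Build a fully crossed table from an (n_t, n_p, 4) score array."""
    n_t, n_p, _ = y.shape
    rows = []
    for i in range(n_t):
        for j in range(n_p):
            rows.append(
                (f"T{i:03d}", f"P{j:03d}", 5, "average", *y[i, j]))
    return pd.DataFrame(
        rows,
        columns=["trainee_id", "procedure_id", "pgy", "complexity", *SCORE_COLUMNS],
    )


def components_from_diags(t, p, tp):
    return GStudyComponents(
        sigma_t=np.diag(np.broadcast_to(t, (4,)).astype(float)),
        sigma_p=np.diag(np.broadcast_to(p, (4,)).astype(float)),
        sigma_tp=np.diag(np.broadcast_to(tp, (4,)).astype(float)),
        n_trainees=100,
        n_procedures_mean=3.0,
        estimator_tag="manual",
    )


class TestBalanced:
    def test_constant_table_all_zero(self):
        y = np.full((4, 3, 4), 3.0)
        comp = estimate_balanced(grid_table(y))
        for eff in ("t", "p", "tp"):
            np.testing.assert_array_equal(comp.matrix(eff), np.zeros((4, 4)))

    def test_hand_computable_3x3_additive(self):
        # y_ij = trainee index (1, 2, 3), no procedure effect, no residual:
        # MS_t = 3 * var(1,2,3) = 3, MS_p = MS_tp = 0 => sigma_t = 3/3 = 1
        y = np.zeros((3, 3, 4))
        for i in range(3):
            y[i, :, :] = i + 1.0
        comp = estimate_balanced(grid_table(y))
        oracle_t, oracle_p, oracle_tp = naive_balanced_components(grid_table(y))
        assert comp.sigma_t[0, 0] == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(comp.raw["t"], oracle_t, atol=1e-12)
        np.testing.assert_allclose(comp.raw["p"], oracle_p, atol=1e-12)
        np.testing.assert_allclose(comp.raw["tp"], oracle_tp, atol=1e-12)

    @settings(max_examples=40, deadline=None)
    @given(
        n_t=st.integers(3, 6),
        n_p=st.integers(3, 6),
        seed=st.integers(0, 2**31 - 1),
    )
    def test_matches_brute_force_oracle(self, n_t, n_p, seed):
        rng = np.random.default_rng(seed)
        y = rng.normal(size=(n_t, n_p, 4)) + rng.normal(size=(n_t, 1, 4))
        table = grid_table(y)
        comp = estimate_balanced(table)
        oracle = naive_balanced_components(table)
        for raw, exp in zip((comp.raw["t"], comp.raw["p"], comp.raw["tp"]), oracle):
            np.testing.assert_allclose(raw, exp, atol=1e-10)

    def test_translation_invariance(self):
        table = generate_dataset(make_config(seed=31))
        shifted = table.copy()
        shifted["score_ta"] = shifted["score_ta"] + 7.5
        a, b = estimate_balanced(table), estimate_balanced(shifted)
        for eff in ("t", "p", "tp"):
            np.testing.assert_allclose(a.matrix(eff), b.matrix(eff), atol=1e-10)

    def test_scale_equivariance(self):
        table = generate_dataset(make_config(seed=32))
        c = 3.0
        scaled = table.copy()
        scaled["score_fa"] = scaled["score_fa"] * c
        a, b = estimate_balanced(table), estimate_balanced(scaled)
        for eff in ("t", "p", "tp"):
            expect = a.matrix(eff).copy()
            expect[0, :] *= c
            expect[:, 0] *= c
            expect[0, 0] = a.matrix(eff)[0, 0] * c * c
            np.testing.assert_allclose(b.matrix(eff), expect, atol=1e-9)

    def test_raw_matrices_symmetric(self):
        table = generate_dataset(make_config(seed=33))
        comp = estimate_balanced(table)
        for eff in ("t", "p", "tp"):
            np.testing.assert_allclose(comp.raw[eff], comp.raw[eff].T, atol=0)

    def test_truncation_invariants(self):
        table = generate_dataset(make_config(seed=34))
        comp = estimate_balanced(table)
        for eff in ("t", "p", "tp"):
            m = comp.matrix(eff)
            d = np.diag(m)
            assert (d >= 0).all()
            bound = np.sqrt(np.outer(d, d))
            assert (np.abs(m) <= bound + 1e-12).all()

    def test_refuses_unbalanced(self):
        table = generate_dataset(make_config(seed=35)).iloc[1:]
        with pytest.raises(UnbalancedDesignError):
            estimate_balanced(table)

    def test_too_small_design(self):
        y = np.zeros((1, 3, 4))
        with pytest.raises(IdentifiabilityError):
            estimate_balanced(grid_table(y))


class TestUnbalanced:
    def test_agrees_with_balanced_on_crossed_data(self):
        table = generate_dataset(make_config(seed=1))
        cb = estimate_balanced(table)
        cu = estimate_unbalanced(table)
        scale = max(np.abs(cb.matrix(e)).max() for e in ("t", "p", "tp"))
        for eff in ("t", "p", "tp"):
            assert np.abs(cb.matrix(eff) - cu.matrix(eff)).max() <= 1e-6 * scale

    def test_diagonal_recovery_after_thinning(self):
        # pool several independent thinned datasets to tame sampling noise
        est = []
        for seed in range(4):
            cfg = make_config(
                n_trainees=90,
                n_procedures=10,
                procedures_per_trainee=3,
                sigma_t=np.diag([0.06, 0.09, 0.03, 0.10]),
                sigma_p=np.diag([0.04, 0.08, 0.01, 0.02]),
                sigma_tp=np.diag([0.32, 0.31, 0.22, 0.15]),
                seed=100 + seed,
            )
            comp = estimate_unbalanced(generate_dataset(cfg))
            est.append([np.diag(comp.matrix(e)) for e in ("t", "p", "tp")])
        mean_est = np.mean(est, axis=0)
        np.testing.assert_allclose(mean_est[0], [0.06, 0.09, 0.03, 0.10], atol=0.06)
        np.testing.assert_allclose(mean_est[2], [0.32, 0.31, 0.22, 0.15], atol=0.07)

    def test_covariance_recovery_sum_difference(self):
        sigma_t = np.diag([0.08, 0.08, 0.03, 0.10]).astype(float)
        sigma_t[0, 1] = sigma_t[1, 0] = 0.05
        cfg = make_config(
            n_trainees=120,
            n_procedures=10,
            procedures_per_trainee=4,
            sigma_t=sigma_t,
            sigma_p=np.diag([0.02, 0.02, 0.01, 0.02]),
            sigma_tp=np.diag([0.20, 0.20, 0.22, 0.15]),
            seed=55,
        )
        comp = estimate_unbalanced(generate_dataset(cfg))
        assert comp.sigma_t[0, 1] == pytest.approx(0.05, abs=0.035)

    def test_single_procedure_not_identifiable(self):
        cfg = make_config(n_trainees=10, n_procedures=1)
        with pytest.raises(IdentifiabilityError):
            estimate_unbalanced(generate_dataset(cfg))

    def test_duplicate_cells_rejected(self):
        table = generate_dataset(make_config(seed=3))
        dup = pd.concat([table, table.iloc[:1]], ignore_index=True)
        with pytest.raises(MvgtError):
            estimate_unbalanced(dup)

    def test_estimate_dispatch(self):
        crossed = generate_dataset(make_config(seed=4))
        assert estimate(crossed).estimator_tag == "balanced-EMS"
        thinned = generate_dataset(
            make_config(n_trainees=40, n_procedures=8, procedures_per_trainee=3, seed=4)
        )
        assert estimate(thinned).estimator_tag == "unbalanced-iterative"


class TestProportions:
    def test_printed_faculty_autonomy_column(self):
        comp = components_from_diags(0.064, 0.041, 0.317)
        props = proportion_table(comp, 0)
        assert props[0] == 15.2

    def test_printed_trainee_performance_column(self):
        comp = components_from_diags(0.097, 0.017, 0.152)
        props = proportion_table(comp, 3)
        assert props[0] == 36.5

    def test_single_source(self):
        comp = components_from_diags(1.0, 0.0, 0.0)
        assert proportion_table(comp, 2) == (100.0, 0.0, 0.0)

    def test_zero_total_variance_errors(self):
        comp = components_from_diags(0.0, 0.0, 0.0)
        with pytest.raises(UndefinedStatisticError):
            proportion_table(comp, 0)

    def test_proportions_sum_to_100(self):
        comp = components_from_diags(0.064, 0.041, 0.317)
        assert sum(proportion_table(comp, 0)) == pytest.approx(100.0, abs=0.15)


def test_serialization_round_trip(tmp_path):
    comp = estimate_balanced(generate_dataset(make_config(seed=41)))
    d = comp.to_dict()
    back = GStudyComponents.from_dict(d)
    for eff in ("t", "p", "tp"):
        np.testing.assert_allclose(back.matrix(eff), comp.matrix(eff))
    assert back.estimator_tag == comp.estimator_tag
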
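"""Differential screen: preprocessing, tests, BH adjustment, thresholds."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mirsynet import diffexpr
from mirsynet.simulate import SimulationConfig, generate_expression

from conftest import make_matrix

# Moderated-t oracle values for the conftest toy matrix, computed with an
# external empirical-Bayes microarray fit (linear model + variance
# shrinkage) on the identical 6x8 fixture; frozen here.
LIMMA_P = [
    0.00199546177159,
    0.630435166304,
    0.000964935304675,
    0.405155871611,
    0.44942339751,
    5.29769167635e-06,
]
LIMMA_LFC = [0.70675, -0.142, -1.93625, 0.262, 0.27225, 2.337]


# ---------------------------------------------------------------------------
# preprocess

def test_preprocess_drops_gappy_rows_and_imputes_median():
    values = np.array([
        [1.0, np.nan, 3.0, 4.0],       # 25% missing -> kept, NA -> median
        [np.nan, np.nan, 1.0, 2.0],    # 50% missing -> dropped at 0.3
        [5.0, 6.0, 7.0, 8.0],
    ])
    matrix = make_matrix(values, n_case=2)
    clean = diffexpr.preprocess(matrix, max_missing_frac=0.3)
    assert clean.mirna_ids == ["m0", "m2"]
    assert clean.values.at["m0", "s1"] == pytest.approx(3.0)  # median of 1,3,4
    assert clean.n_missing == 0


def test_preprocess_identity_without_missing(toy_matrix):
    clean = diffexpr.preprocess(toy_matrix, 0.2)
    assert clean.values.equals(toy_matrix.values)


def test_preprocess_all_rows_removed_errors():
    matrix = make_matrix(np.full((2, 4), np.nan), n_case=2)
    with pytest.raises(ValueError, match="every row"):
        diffexpr.preprocess(matrix, 0.5)


# ---------------------------------------------------------------------------
# differential tests

def test_welch_matches_direct_formula_oracle():
    case = np.array([[10.1, 9.8, 10.4, 10.0], [5.0, 5.5, 4.5, 5.2]])
    control = np.array([[9.0, 9.2, 8.8, 9.1], [5.1, 5.4, 4.9, 5.0]])
    matrix = make_matrix(np.hstack([case, control]), n_case=4)
    res = diffexpr.differential_test(matrix, method="welch_t")
    for i in range(2):
        m1, m2 = case[i].mean(), control[i].mean()
        v1, v2 = case[i].var(ddof=1), control[i].var(ddof=1)
        se2 = v1 / 4 + v2 / 4
        t = (m1 - m2) / math.sqrt(se2)
        df = se2**2 / ((v1 / 4) ** 2 / 3 + (v2 / 4) ** 2 / 3)
        p = 2 * stats.t.sf(abs(t), df)
        assert res["p_value"].iloc[i] == pytest.approx(p, rel=1e-12)
        assert res["log2fc"].iloc[i] == pytest.approx(m1 - m2, rel=1e-12)


@pytest.mark.parametrize("method", ["welch_t", "moderated_t"])
def test_identical_constant_groups_degenerate_contract(method):
    values = np.vstack([np.full(8, 7.0), np.arange(8.0)])
    matrix = make_matrix(values, n_case=4)
    res = diffexpr.differential_test(matrix, method=method)
    assert res["log2fc"].iloc[0] == 0.0
    assert res["p_value"].iloc[0] == 1.0


def test_moderated_t_matches_frozen_external_oracle(toy_matrix):
    res = diffexpr.differential_test(toy_matrix, method="moderated_t")
    np.testing.assert_allclose(res["log2fc"], LIMMA_LFC, rtol=1e-9)
    np.testing.assert_allclose(res["p_value"], LIMMA_P, rtol=1e-6)


def test_moderated_shrinks_toward_pooled_variance(toy_matrix):
    # the moderated statistic is less extreme than Welch for the noisiest
    # probe and at least as extreme for quiet ones with real effects
    welch = diffexpr.differential_test(toy_matrix, "welch_t")
    moderated = diffexpr.differential_test(toy_matrix, "moderated_t")
    # probe m5 has a strong effect: both call it, moderated at least as firmly
    assert moderated["p_value"]["m5"] < 1e-4
    assert welch["p_value"]["m5"] < 1e-2


def test_planted_strong_effect_has_tiny_p():
    cfg = SimulationConfig(n_mirnas=200, n_de=1, effect_log2=2.0,
                           missing_frac=0.0, noise_sd=0.5, seed=9)
    matrix, truth = generate_expression(cfg)
    res = diffexpr.differential_test(matrix, "moderated_t")
    (planted,) = truth.de_ids
    assert res["p_value"][planted] < 1e-10


def test_two_samples_per_group_required():
    matrix = make_matrix(np.random.default_rng(0).normal(size=(3, 3)), n_case=1)
    with pytest.raises(ValueError, match="2 samples"):
        diffexpr.differential_test(matrix)


# ---------------------------------------------------------------------------
# BH adjustment

def _bh_brute_force(p):
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    for rank_pos, idx in enumerate(order):
        candidates = [
            p[order[j]] * m / (j + 1) for j in range(rank_pos, m)
        ]
        q[idx] = min(1.0, min(candidates))
    return q


def test_bh_step_up_examples():
    np.testing.assert_allclose(
        diffexpr.bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
    )
    np.testing.assert_allclose(diffexpr.bh_adjust([0.42]), [0.42])
    np.testing.assert_allclose(diffexpr.bh_adjust([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])


def test_bh_equals_brute_force_on_random_vectors():
    rng = np.random.default_rng(123)
    for _ in range(1000):
        p = rng.random(rng.integers(1, 40))
        np.testing.assert_allclose(diffexpr.bh_adjust(p), _bh_brute_force(p), rtol=1e-12)


def test_bh_agrees_with_statsmodels():
    from statsmodels.stats.multitest import multipletests

    rng = np.random.default_rng(5)
    p = rng.random(200)
    expected = multipletests(p, method="fdr_bh")[1]
    np.testing.assert_allclose(diffexpr.bh_adjust(p), expected, rtol=1e-12)


def test_bh_is_monotone_in_sorted_order_and_bounds_raw_p():
    rng = np.random.default_rng(42)
    p = rng.random(500)
    q = diffexpr.bh_adjust(p)
    order = np.argsort(p)
    assert np.all(np.diff(q[order]) >= -1e-15)
    assert np.all(q >= p - 1e-15)


def test_bh_rejects_out_of_range():
    with pytest.raises(ValueError):
        diffexpr.bh_adjust([0.5, 1.5])
    with pytest.raises(ValueError):
        diffexpr.bh_adjust([-0.1])


# ---------------------------------------------------------------------------
# thresholds

def _results(p, lfc, fdr):
    return pd.DataFrame(
        {"log2fc": [lfc], "p_value": [p], "fdr": [fdr]}, index=["x"]
    )


@pytest.mark.parametrize(
    "p,lfc,fdr,kept",
    [
        (0.04, 0.9, 0.03, True),
        (0.04, 0.79, 0.03, False),   # |log2fc| boundary is >=
        (0.05, 0.9, 0.03, False),    # p boundary is strict <
        (0.04, 0.8, 0.03, True),     # exactly at the fold-change boundary
        (0.04, -0.9, 0.03, True),    # down-regulation counts too
        (0.04, 0.9, 0.05, False),    # FDR boundary is strict <
    ],
)
def test_demirs_joint_threshold_boundaries(p, lfc, fdr, kept):
    out = diffexpr.filter_demirs(_results(p, lfc, fdr))
    assert bool(out["passes"].iloc[0]) is kept


def test_direction_follows_sign():
    out = diffexpr.filter_demirs(_results(0.01, -1.2, 0.01))
    assert out["direction"].iloc[0] == "down"
    assert bool(out["passes"].iloc[0])


def test_filter_requires_columns_and_nonempty():
    with pytest.raises(ValueError):
        diffexpr.filter_demirs(pd.DataFrame())
    with pytest.raises(ValueError, match="fdr"):
        diffexpr.filter_demirs(pd.DataFrame({"log2fc": [1.0], "p_value": [0.01]}))
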
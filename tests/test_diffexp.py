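"""Screening statistics against hand arithmetic and brute-force oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform

from starchnet import (
    ConfigError,
    InputError,
    ScreenParams,
    SimulationConfig,
    estimate_s0,
    fold_change,
    hierarchical_cluster,
    load_fixture,
    permutation_q_values,
    sam_d_statistic,
    screen_degs,
    simulate_expression,
    to_newick,
)
from conftest import make_matrix


def swap_groups(matrix):
    """Same values, CK/RS labels exchanged."""
    from starchnet import ExpressionMatrix
    groups = matrix.groups.map({"CK": "RS", "RS": "CK"})
    return ExpressionMatrix(matrix.values.copy(), groups)


# --- fold change ---------------------------------------------------------

def test_fold_change_identical_means_is_one():
    m = make_matrix([[5, 7]], [[6, 6]])
    assert fold_change(m).iloc[0] == pytest.approx(1.0)


def test_fold_change_hand_case():
    m = make_matrix([[100, 120]], [[220, 220]])
    assert fold_change(m).iloc[0] == pytest.approx(2.0)  # 220 / 110


def test_fold_change_label_swap_gives_reciprocal(small_sim):
    _, matrix, _ = small_sim
    r = fold_change(matrix)
    r_swapped = fold_change(swap_groups(matrix))
    np.testing.assert_allclose(r_swapped.to_numpy(), 1.0 / r.to_numpy())


# --- SAM d-statistic -----------------------------------------------------

def test_d_zero_for_equal_group_means():
    m = make_matrix([[4, 6, 5]], [[5, 4, 6]])
    assert sam_d_statistic(m, s0=0.5).iloc[0] == pytest.approx(0.0)


def test_d_hand_case_zero_pooled_se():
    # CK log2 = (1,1,1), RS log2 = (3,3,3): difference 2, pooled SE 0
    m = make_matrix([[2, 2, 2]], [[8, 8, 8]])
    assert sam_d_statistic(m, s0=0.1).iloc[0] == pytest.approx(20.0)


def test_d_antisymmetric_under_label_swap(small_sim):
    _, matrix, _ = small_sim
    d = sam_d_statistic(matrix, s0=0.2)
    d_swapped = sam_d_statistic(swap_groups(matrix), s0=0.2)
    np.testing.assert_allclose(d_swapped.to_numpy(), -d.to_numpy(), atol=1e-12)


def test_d_requires_two_samples_per_group():
    m = make_matrix([[2]], [[8, 8]])
    with pytest.raises(InputError, match="fold-change-only"):
        sam_d_statistic(m, s0=0.1)


def test_d_sign_matches_log2_mean_difference(small_sim):
    # d is computed on the log2 scale, so its sign follows the difference of
    # log2 group means (the geometric-mean ratio)
    _, matrix, _ = small_sim
    d = sam_d_statistic(matrix, s0=0.1)
    X = np.log2(matrix.values)
    lr = X[matrix.samples_of("RS")].mean(axis=1) - X[matrix.samples_of("CK")].mean(axis=1)
    nz = np.abs(lr) > 1e-9
    assert np.all(np.sign(d[nz]) == np.sign(lr[nz]))


# --- s0 selection --------------------------------------------------------

def _oracle_s0(matrix):
    """Independent grid search over the same percentile candidates."""
    X = np.log2(matrix.values.to_numpy())
    ck = [i for i, s in enumerate(matrix.sample_ids) if matrix.groups[s] == "CK"]
    rs = [i for i, s in enumerate(matrix.sample_ids) if matrix.groups[s] == "RS"]
    a, b = X[:, ck], X[:, rs]
    diff = b.mean(1) - a.mean(1)
    ss = ((a - a.mean(1, keepdims=True)) ** 2).sum(1) + \
         ((b - b.mean(1, keepdims=True)) ** 2).sum(1)
    se = np.sqrt((1 / len(ck) + 1 / len(rs)) * ss / (len(ck) + len(rs) - 2))
    n_bins = int(min(100, max(2, len(se) // 10)))
    best, best_cv = None, math.inf
    for p in range(0, 100, 5):
        s0 = float(np.percentile(se, p))
        d = diff / (se + s0)
        order = np.argsort(se, kind="stable")
        mads = []
        for chunk in np.array_split(order, n_bins):
            db = d[chunk]
            mads.append(np.median(np.abs(db - np.median(db))) / 0.64)
        mads = np.asarray(mads)
        cv = math.inf if mads.mean() == 0 else mads.std() / mads.mean()
        if cv < best_cv - 1e-15:
            best_cv, best = cv, s0
    return best


def test_s0_matches_brute_force_grid_search():
    cfg = SimulationConfig(n_genes=500, n_per_group=4, seed=3)
    matrix, _ = simulate_expression(cfg)
    assert estimate_s0(matrix) == pytest.approx(_oracle_s0(matrix), abs=1e-12)


def test_s0_zero_for_noiseless_matrix(caplog):
    cfg = SimulationConfig(n_genes=50, noise_sd_log2=0.0, baseline_log2_sd=0.0,
                           n_per_group=3, seed=1)
    matrix, _ = simulate_expression(cfg)
    with caplog.at_level("WARNING", logger="starchnet"):
        assert estimate_s0(matrix) == 0.0


# --- permutation Q-values ------------------------------------------------

def _oracle_exhaustive_q(matrix, s0):
    """All label assignments enumerated; the FDR/min rule written directly."""
    X = np.log2(matrix.values.to_numpy())
    samples = matrix.sample_ids
    n_ck = sum(matrix.groups[s] == "CK" for s in samples)

    def dvec(ck_idx):
        rs_idx = [i for i in range(len(samples)) if i not in ck_idx]
        a, b = X[:, list(ck_idx)], X[:, rs_idx]
        diff = b.mean(1) - a.mean(1)
        ss = ((a - a.mean(1, keepdims=True)) ** 2).sum(1) + \
             ((b - b.mean(1, keepdims=True)) ** 2).sum(1)
        se = np.sqrt((1 / a.shape[1] + 1 / b.shape[1]) * ss / (len(samples) - 2))
        out = np.zeros(len(diff))
        pos = (se + s0) > 0
        out[pos] = diff[pos] / (se + s0)[pos]
        out[~pos & (diff != 0)] = np.sign(diff[~pos & (diff != 0)]) * 1e12
        return out

    obs_ck = tuple(i for i, s in enumerate(samples) if matrix.groups[s] == "CK")
    d_obs = np.abs(dvec(obs_ck))
    perm_abs = [np.abs(dvec(c))
                for c in itertools.combinations(range(len(samples)), n_ck)]

    def fdr(t):
        obs = np.sum(d_obs >= t)
        med = np.median([np.sum(p >= t) for p in perm_abs])
        return med / obs

    qs = []
    for t_i in d_obs:
        # regions containing the gene: thresholds at or below its |d|
        cand = [fdr(t) for t in d_obs if t <= t_i]
        qs.append(min(1.0, max(0.0, min(cand))))
    return np.array(qs)


@pytest.mark.parametrize("n_ck,n_rs", [(2, 2), (2, 3), (3, 3), (3, 4), (4, 4)])
def test_q_values_match_exhaustive_oracle(n_ck, n_rs):
    rng = np.random.default_rng(1234 + 10 * n_ck + n_rs)
    n_genes = 40
    ck = 2 ** rng.normal(8, 1, size=(n_genes, n_ck))
    rs = 2 ** rng.normal(8, 1, size=(n_genes, n_rs))
    rs[:5] *= 4  # a few genuine effects
    matrix = make_matrix(ck, rs)
    s0 = estimate_s0(matrix)
    q = permutation_q_values(matrix, ScreenParams(seed=0, n_permutations=1000), s0=s0)
    np.testing.assert_allclose(q.to_numpy(), _oracle_exhaustive_q(matrix, s0),
                               atol=1e-12)


def test_largest_abs_d_has_smallest_q(small_sim):
    _, matrix, _ = small_sim
    params = ScreenParams(seed=0)
    d = sam_d_statistic(matrix, estimate_s0(matrix))
    q = permutation_q_values(matrix, params)
    top = d.abs().idxmax()
    assert q[top] == q.min()
    # monotone nonincreasing in |d|
    ordered = q[d.abs().sort_values(ascending=False).index].to_numpy()
    assert np.all(np.diff(ordered) >= -1e-15)


def test_q_deterministic_under_seed(small_sim):
    _, matrix, _ = small_sim
    q1 = permutation_q_values(matrix, ScreenParams(seed=7))
    q2 = permutation_q_values(matrix, ScreenParams(seed=7))
    pd.testing.assert_series_equal(q1, q2)


# --- the compound screen -------------------------------------------------

def test_table2_ratios_screen_to_7_up_10_down():
    t2 = load_fixture("table2")
    ratios = pd.Series(t2["ratio"].to_numpy(), index=list(t2["gene_symbol"]))
    q = pd.Series(0.0, index=ratios.index)
    table = screen_degs(ratios, q, ScreenParams())
    counts = table["call"].value_counts()
    assert counts.get("up", 0) == 7
    assert counts.get("down", 0) == 10
    assert len(table) == 17


@pytest.mark.parametrize("ratio,q,expected", [
    (1.99, 0.0, "unchanged"),   # FC gate strict at the printed bound
    (2.0, 0.0, "up"),
    (3.0, 0.051, "unchanged"),  # Q gate fails
    (3.0, 0.05, "up"),
    (0.5, 0.05, "down"),
    (0.51, 0.0, "unchanged"),
])
def test_screen_boundaries_inclusive(ratio, q, expected):
    table = screen_degs(pd.Series({"g": ratio}), pd.Series({"g": q}), ScreenParams())
    assert table.loc["g", "call"] == expected


def test_screen_rejects_mismatched_gene_sets():
    with pytest.raises(InputError, match="differ"):
        screen_degs(pd.Series({"a": 2.0}), pd.Series({"b": 0.0}), ScreenParams())


def test_screen_monotone_in_thresholds(small_sim):
    _, matrix, _ = small_sim
    ratios = fold_change(matrix)
    q = permutation_q_values(matrix, ScreenParams(seed=0))

    def n_called(fc_up, fc_down, q_max):
        t = screen_degs(ratios, q, ScreenParams(fc_up=fc_up, fc_down=fc_down,
                                                q_max=q_max))
        return (t["call"] != "unchanged").sum()

    base = n_called(2.0, 0.5, 0.05)
    assert n_called(2.0, 0.5, 0.01) <= base          # shrink q_max
    assert n_called(2.5, 0.4, 0.05) <= base          # widen FC bounds
    assert n_called(1.5, 0.6, 0.05) >= base          # loosen FC bounds


def test_label_swap_duality_of_calls(small_sim):
    _, matrix, _ = small_sim
    params = ScreenParams(fc_up=2.0, fc_down=0.5, seed=0)  # fc_down = 1/fc_up
    t1 = screen_degs(fold_change(matrix),
                     permutation_q_values(matrix, params), params)
    sw = swap_groups(matrix)
    t2 = screen_degs(fold_change(sw), permutation_q_values(sw, params), params)
    assert set(t1.index[t1["call"] == "up"]) == set(t2.index[t2["call"] == "down"])
    assert set(t1.index[t1["call"] == "down"]) == set(t2.index[t2["call"] == "up"])


def test_screen_params_validation():
    with pytest.raises(ConfigError):
        ScreenParams(fc_up=0.8)
    with pytest.raises(ConfigError):
        ScreenParams(q_max=1.5)
    with pytest.raises(ConfigError):
        ScreenParams(n_permutations=0)


# --- hierarchical clustering --------------------------------------------

def test_identical_profiles_merge_at_height_zero():
    m = make_matrix([[1, 2, 4], [2, 4, 8], [8, 4, 2]],
                    [[8, 9, 10], [16, 18, 20], [1, 2, 1]])
    dend = hierarchical_cluster(m, axis="genes")
    a, b, h, size = dend.merges[0]
    assert {int(a), int(b)} == {0, 1}  # perfectly correlated pair first
    assert h == pytest.approx(0.0, abs=1e-12)
    assert size == 2


def test_anticorrelated_item_merges_last():
    m = make_matrix([[1, 2], [1, 2], [4, 2]], [[4, 8], [4, 8], [1, 1]])
    dend = hierarchical_cluster(m, axis="genes")
    assert {int(dend.merges[0][0]), int(dend.merges[0][1])} == {0, 1}
    assert sorted(dend.leaf_order) == ["g0", "g1", "g2"]


def test_merge_heights_match_scipy_average_linkage():
    rng = np.random.default_rng(12)
    ck = 2 ** rng.normal(8, 1, size=(12, 3))
    rs = 2 ** rng.normal(8, 1, size=(12, 3))
    m = make_matrix(ck, rs)
    dend = hierarchical_cluster(m, axis="genes")

    X = np.log2(m.values.to_numpy())
    D = 1 - np.corrcoef(X)
    np.fill_diagonal(D, 0.0)
    Z = sch.linkage(squareform(np.clip(D, 0, None), checks=False), method="average")
    np.testing.assert_allclose(np.sort(dend.merges[:, 2]), np.sort(Z[:, 2]),
                               atol=1e-10)


def test_cluster_samples_heights_nondecreasing_and_leaves_complete(small_sim):
    _, matrix, _ = small_sim
    dend = hierarchical_cluster(matrix, axis="samples")
    heights = dend.merges[:, 2]
    assert np.all(np.diff(heights) >= -1e-12)
    assert sorted(dend.leaf_order) == sorted(matrix.sample_ids)


def test_newick_export_is_well_formed(small_sim):
    _, matrix, _ = small_sim
    nwk = to_newick(hierarchical_cluster(matrix, axis="samples"))
    assert nwk.endswith(";")
    for s in matrix.sample_ids:
        assert s in nwk
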
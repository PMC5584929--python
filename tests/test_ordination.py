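"""Bray-Curtis, nMDS, envfit and the exhaustive BIOENV search."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from scipy.stats import spearmanr

import phagestate as ps
from phagestate.containers import DataError
from tests.conftest import expression_from_array


# ---------------------------------------------------------------- Bray-Curtis

def test_bray_curtis_spot_values():
    em = expression_from_array(np.array([[2.0, 1.0], [0.0, 1.0]]))
    d = ps.bray_curtis(em)
    assert d.d[0, 1] == pytest.approx(0.5)
    em_same = expression_from_array(np.array([[3.0, 3.0], [1.0, 1.0]]))
    assert ps.bray_curtis(em_same).d[0, 1] == pytest.approx(0.0)
    em_disjoint = expression_from_array(np.array([[1.0, 0.0], [0.0, 1.0]]))
    assert ps.bray_curtis(em_disjoint).d[0, 1] == pytest.approx(1.0)


def test_bray_curtis_after_sqrt_matches_hand_evaluation():
    # samples [4,0] and [1,1] -> sqrt -> [2,0], [1,1] -> d = (1+1)/(3+1) = 0.5
    counts = pd.DataFrame({"sA": [4.0, 0.0], "sB": [1.0, 1.0]}, index=["g1", "g2"])
    em = ps.sqrt_transform(ps.ExpressionMatrix(values=counts))
    assert ps.bray_curtis(em).d[0, 1] == pytest.approx(0.5)


def test_bray_curtis_properties(study_scale_dataset):
    _, _, _, counts = study_scale_dataset
    em1 = ps.sqrt_transform(ps.libsize_normalize(counts, scale=1e6))
    em2 = ps.sqrt_transform(ps.libsize_normalize(counts, scale=1e4))
    d1, d2 = ps.bray_curtis(em1), ps.bray_curtis(em2)
    assert np.allclose(d1.d, d2.d)  # scale-factor invariance
    assert np.all(d1.d >= 0) and np.all(d1.d <= 1)
    assert np.allclose(d1.d, d1.d.T) and np.allclose(np.diag(d1.d), 0)


def test_bray_curtis_all_zero_pair_defined_as_zero():
    em = expression_from_array(np.array([[0.0, 0.0, 1.0], [0.0, 0.0, 2.0]]))
    d = ps.bray_curtis(em)
    assert d.d[0, 1] == 0.0


def test_bray_curtis_rejects_negative():
    with pytest.raises(DataError):
        ps.bray_curtis(expression_from_array(np.array([[-1.0, 1.0]])))


# ----------------------------------------------------------------------- nMDS

def _planted_distances(n, seed=1):
    rng = np.random.default_rng(seed)
    P = rng.standard_normal((n, 2))
    return ps.DistanceMatrix(
        labels=[f"s{i}" for i in range(n)], d=squareform(pdist(P))
    )


def test_nmds_embeds_planted_2d_points():
    dm = _planted_distances(10)
    o = ps.nmds(dm, n_restarts=20, seed=0)
    assert o.stress <= 0.02
    assert all(a >= b - 1e-12 for a, b in zip(o.stress_trace, o.stress_trace[1:]))


def test_nmds_three_points_exact():
    dm = _planted_distances(3, seed=2)
    o = ps.nmds(dm, n_restarts=10, seed=0)
    assert o.stress <= 1e-6


def test_nmds_rank_invariance_under_scaling():
    dm = _planted_distances(12, seed=3)
    o1 = ps.nmds(dm, n_restarts=10, seed=0)
    o2 = ps.nmds(
        ps.DistanceMatrix(labels=dm.labels, d=3.0 * dm.d), n_restarts=10, seed=0
    )
    assert o1.stress == pytest.approx(o2.stress, abs=1e-9)
    c1, c2 = o1.coordinates.to_numpy(), o2.coordinates.to_numpy()
    # same configuration up to overall scale
    s = np.linalg.norm(c2) / np.linalg.norm(c1)
    assert np.allclose(c1 * s, c2, atol=1e-6 * np.linalg.norm(c2))


def test_nmds_centered_and_best_restart():
    dm = _planted_distances(15, seed=4)
    o = ps.nmds(dm, n_restarts=8, seed=5)
    assert np.allclose(o.coordinates.to_numpy().mean(axis=0), 0.0, atol=1e-9)
    single = ps.nmds(dm, n_restarts=1, seed=5)
    assert o.stress <= single.stress + 1e-12


# --------------------------------------------------------------------- envfit

def test_envfit_perfect_alignment():
    dm = _planted_distances(20, seed=6)
    o = ps.nmds(dm, n_restarts=5, seed=0)
    env = pd.DataFrame(
        {"axis_var": o.coordinates["axis1"]}, index=o.coordinates.index
    )
    fit = ps.envfit(o, env, n_perm=199, seed=0)
    assert fit.loc["axis_var", "R"] == pytest.approx(1.0, abs=1e-9)
    assert abs(fit.loc["axis_var", "dy"]) < 1e-6
    assert fit.loc["axis_var", "p_value"] <= 0.01


def test_envfit_sign_equivariance():
    dm = _planted_distances(20, seed=7)
    o = ps.nmds(dm, n_restarts=5, seed=0)
    rng = np.random.default_rng(8)
    v = rng.standard_normal(20)
    env = pd.DataFrame({"v": v, "neg_v": -v}, index=o.coordinates.index)
    fit = ps.envfit(o, env, n_perm=199, seed=1)
    assert fit.loc["v", "R"] == pytest.approx(fit.loc["neg_v", "R"])
    assert fit.loc["v", "dx"] == pytest.approx(-fit.loc["neg_v", "dx"])
    assert fit.loc["v", "dy"] == pytest.approx(-fit.loc["neg_v", "dy"])
    assert fit.loc["v", "p_value"] == pytest.approx(fit.loc["neg_v", "p_value"])


def test_envfit_null_p_uniform():
    """Pure-noise variables yield ~uniform permutation p-values."""
    from scipy.stats import kstest

    dm = _planted_distances(33, seed=9)
    o = ps.nmds(dm, n_restarts=3, seed=0)
    rng = np.random.default_rng(10)
    pvals = []
    for r in range(200):
        env = pd.DataFrame(
            {"noise": rng.standard_normal(33)}, index=o.coordinates.index
        )
        fit = ps.envfit(o, env, n_perm=199, seed=r)
        pvals.append(fit.loc["noise", "p_value"])
    assert kstest(pvals, "uniform").pvalue > 0.01


def test_envfit_constant_variable_skipped():
    dm = _planted_distances(10, seed=11)
    o = ps.nmds(dm, n_restarts=3, seed=0)
    env = pd.DataFrame({"const": np.ones(10)}, index=o.coordinates.index)
    fit = ps.envfit(o, env, n_perm=99, seed=0)
    assert fit.empty


# --------------------------------------------------------------------- BIOENV

def _brute_force_bioenv(dist, env, max_size):
    """Independent oracle: naive enumeration with scipy.spearmanr."""
    target = dist.condensed()
    z = (env - env.mean()) / env.std(ddof=0)
    best = (None, -np.inf)
    for k in range(1, max_size + 1):
        for sub in itertools.combinations(env.columns, k):
            d = pdist(z[list(sub)].to_numpy())
            rho = spearmanr(d, target)[0]
            if rho > best[1]:
                best = (tuple(sub), rho)
    return best


def test_bioenv_single_generating_variable_recovered():
    rng = np.random.default_rng(12)
    n = 15
    v = rng.standard_normal(n)
    labels = [f"s{i}" for i in range(n)]
    dm = ps.DistanceMatrix(labels=labels, d=squareform(pdist(v[:, None])))
    env = pd.DataFrame(
        {"gen": v, "n1": rng.standard_normal(n), "n2": rng.standard_normal(n)},
        index=labels,
    )
    res = ps.best_bioenv(dm, env, n_perm=0, seed=0)
    assert res.best_subset == ("gen",)
    assert res.rho == pytest.approx(1.0, abs=1e-9)


def test_bioenv_matches_brute_force_enumerator():
    """50 random 5-variable x 12-sample instances agree with the oracle."""
    rng = np.random.default_rng(13)
    for r in range(50):
        n = 12
        labels = [f"s{i}" for i in range(n)]
        X = rng.standard_normal((n, 3))
        dm = ps.DistanceMatrix(labels=labels, d=squareform(pdist(X)))
        env = pd.DataFrame(
            rng.standard_normal((n, 5)),
            columns=[f"v{j}" for j in range(5)],
            index=labels,
        )
        # correlate a couple of variables with the generating coordinates
        env["v0"] += X[:, 0]
        env["v1"] += 0.5 * X[:, 1]
        res = ps.best_bioenv(dm, env, max_subset_size=5, n_perm=0, seed=r)
        oracle_sub, oracle_rho = _brute_force_bioenv(dm, env, 5)
        assert res.best_subset == oracle_sub
        assert res.rho == pytest.approx(oracle_rho, abs=1e-9)


def test_bioenv_matches_skbio_reference():
    """Cross-check the subset ranking against scikit-bio's bioenv."""
    import skbio
    from skbio.stats.distance import bioenv as skbio_bioenv

    rng = np.random.default_rng(14)
    n = 14
    labels = [f"s{i}" for i in range(n)]
    X = rng.standard_normal((n, 2))
    dm_sk = skbio.DistanceMatrix(squareform(pdist(X)), ids=labels)
    env = pd.DataFrame(
        rng.standard_normal((n, 4)),
        columns=list("abcd"),
        index=labels,
    )
    env["a"] += X[:, 0]
    res = ps.best_bioenv(
        ps.DistanceMatrix(labels=labels, d=dm_sk.data), env, n_perm=0, seed=0
    )
    ref = skbio_bioenv(dm_sk, env)
    for (k, subset, rho), (ref_vars, ref_row) in zip(res.per_size_best, ref.iterrows()):
        assert set(subset) == set(str(ref_vars).split(", "))
        assert rho == pytest.approx(ref_row["correlation"], abs=1e-9)
    assert res.rho == pytest.approx(ref["correlation"].max(), abs=1e-9)


def test_bioenv_per_size_consistency():
    rng = np.random.default_rng(15)
    n = 12
    labels = [f"s{i}" for i in range(n)]
    dm = ps.DistanceMatrix(
        labels=labels, d=squareform(pdist(rng.standard_normal((n, 2))))
    )
    env = pd.DataFrame(
        rng.standard_normal((n, 4)), columns=list("wxyz"), index=labels
    )
    res = ps.best_bioenv(dm, env, n_perm=0, seed=0)
    assert res.rho == pytest.approx(max(r for _, _, r in res.per_size_best))


def test_bioenv_null_p_is_insignificant():
    rng = np.random.default_rng(16)
    insignificant = 0
    n_rep = 30
    for r in range(n_rep):
        n = 14
        labels = [f"s{i}" for i in range(n)]
        dm = ps.DistanceMatrix(
            labels=labels, d=squareform(pdist(rng.standard_normal((n, 3))))
        )
        env = pd.DataFrame(
            rng.standard_normal((n, 4)), columns=list("abcd"), index=labels
        )
        res = ps.best_bioenv(dm, env, n_perm=99, seed=r)
        insignificant += res.p_global >= 0.05
    assert insignificant >= 0.8 * n_rep


def test_bioenv_missing_values_refused():
    labels = ["s0", "s1", "s2"]
    dm = ps.DistanceMatrix(labels=labels, d=squareform(pdist(np.arange(3)[:, None])))
    env = pd.DataFrame({"a": [1.0, np.nan, 2.0]}, index=labels)
    with pytest.raises(DataError):
        ps.best_bioenv(dm, env)


def test_similarity_groups_structure(study_scale_dataset):
    _, models, _, counts = study_scale_dataset
    phage = [g.gene_id for g in models if g.genome_id == "phage_MaLMM01like"]
    em = ps.sqrt_transform(ps.libsize_normalize(counts))
    em.values = em.values.loc[phage]
    dist = ps.bray_curtis(em)
    groups = ps.similarity_groups(dist)
    assert list(groups.columns) == ["sim_40", "sim_60", "sim_80"]
    # higher similarity threshold -> finer partition
    assert groups["sim_40"].nunique() <= groups["sim_60"].nunique() <= groups["sim_80"].nunique()
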
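import numpy as np
import pandas as pd
import pytest

import cohealth as ch
from cohealth.network import scale_free_fit_index
from conftest import random_adjacency, tom_brute_force


def _df(arr, prefix="g"):
    arr = np.asarray(arr, dtype=float)
    names = [f"{prefix}{i}" for i in range(arr.shape[0])]
    return pd.DataFrame(arr, index=names,
                        columns=[f"s{j}" for j in range(arr.shape[1])])


# -- correlation -------------------------------------------------------------

def test_correlation_identical_opposite_and_hand_value():
    x = np.array([1.0, 2.0, 3.0])
    m = _df([x, x, -x, [1.0, 2.0, 4.0]])
    cor, dropped = ch.correlation_matrix(m)
    assert dropped == []
    assert cor.iloc[0, 1] == pytest.approx(1.0)
    assert cor.iloc[0, 2] == pytest.approx(-1.0)
    assert cor.iloc[0, 3] == pytest.approx(0.98198, abs=1e-5)


def test_constant_gene_dropped_with_warning_not_fatal():
    m = _df([[1.0, 2.0, 3.0], [5.0, 5.0, 5.0]])
    cor, dropped = ch.correlation_matrix(m)
    assert dropped == ["g1"]
    assert cor.shape == (1, 1)


# -- adjacency and connectivity ----------------------------------------------

def test_adjacency_values():
    cor = pd.DataFrame([[1.0, -0.9], [-0.9, 1.0]], index=["a", "b"], columns=["a", "b"])
    adj = ch.adjacency(cor, 6)
    assert adj.loc["a", "b"] == pytest.approx(0.531441)
    assert adj.loc["a", "a"] == 1.0
    zero = cor.replace(-0.9, 0.0)
    assert ch.adjacency(zero, 3).loc["a", "b"] == 0.0


def test_adjacency_monotone_in_correlation_and_power():
    rng = np.random.default_rng(0)
    c = rng.uniform(0.05, 0.95, size=50)
    a3, a6 = np.abs(c) ** 3, np.abs(c) ** 6
    assert (a6 <= a3).all()  # higher power never increases a_ij for |cor| < 1
    order = np.argsort(c)
    assert (np.diff(a3[order]) >= 0).all()  # monotone in |cor|


def test_soft_connectivity_hand_sums(toy_adjacency):
    k = ch.soft_connectivity(toy_adjacency)
    assert k.tolist() == pytest.approx([1.3, 1.2, 0.9])


def test_soft_connectivity_ignores_isolated_added_gene(toy_adjacency):
    bigger = toy_adjacency.copy()
    bigger.loc["gene4"] = 0.0
    bigger["gene4"] = 0.0
    bigger.loc["gene4", "gene4"] = 1.0
    k = ch.soft_connectivity(bigger)
    assert k.loc[["gene1", "gene2", "gene3"]].tolist() == pytest.approx([1.3, 1.2, 0.9])
    assert k.loc["gene4"] == 0.0


# -- TOM ----------------------------------------------------------------------

def test_tom_three_gene_hand_value(toy_adjacency):
    tom = ch.topological_overlap(toy_adjacency)
    assert tom.loc["gene1", "gene2"] == pytest.approx(1.0 / 1.4, abs=1e-9)
    assert np.allclose(np.diag(tom), 1.0)


def test_tom_zero_offdiagonal_stays_zero():
    adj = pd.DataFrame(np.eye(4), index=list("abcd"), columns=list("abcd"))
    tom = ch.topological_overlap(adj)
    assert np.allclose(tom.to_numpy()[~np.eye(4, dtype=bool)], 0.0)


def test_tom_identical_neighbourhoods_give_unit_overlap():
    # two genes fully adjacent to each other and fully to a shared neighbor:
    # shared = 1, k = 2, TOM = (1 + 1) / (2 + 1 - 1) = 1
    a = np.array([[1.0, 1.0, 1.0], [1.0, 1.0, 1.0], [1.0, 1.0, 1.0]])
    tom = ch.topological_overlap(pd.DataFrame(a, index=list("xyz"), columns=list("xyz")))
    assert tom.loc["x", "y"] == pytest.approx(1.0)
    # with a weaker shared neighbor (0.6) the overlap drops below 1
    a2 = np.array([[1.0, 1.0, 0.6], [1.0, 1.0, 0.6], [0.6, 0.6, 1.0]])
    tom2 = ch.topological_overlap(pd.DataFrame(a2, index=list("xyz"), columns=list("xyz")))
    assert tom2.loc["x", "y"] == pytest.approx((0.36 + 1.0) / 1.6)


def test_tom_matches_brute_force_oracle():
    rng = np.random.default_rng(7)
    for _ in range(10):
        a = random_adjacency(rng, 15)
        df = pd.DataFrame(a)
        assert np.allclose(ch.topological_overlap(df), tom_brute_force(a), atol=1e-10)


# -- scale-free fit ----------------------------------------------------------

def test_power_law_degrees_fit_nearly_perfectly():
    # inverse-CDF sample of a density p(k) ~ 1/k on [1, 100]
    u = (np.arange(2000) + 0.5) / 2000
    k = 100.0 ** u
    r2, slope = scale_free_fit_index(k, n_bins=10)
    assert r2 > 0.97
    assert slope < 0


def test_degenerate_equal_degrees_raise_not_scale_free_flag():
    cor = pd.DataFrame(np.ones((40, 40)))
    fit = ch.pick_soft_power(cor)
    assert fit.not_scale_free


def test_power_choice_matches_independent_binning_oracle():
    cfg = ch.SimulationConfig(species=["worm"], experiments_per_species=1, seed=21,
                              modules=[ch.ModuleSpec(size=40)], n_noise_genes=80)
    exp, _ = ch.generate_experiment(cfg, "worm", 0)
    cor, _ = ch.correlation_matrix(exp.expression)
    fit = ch.pick_soft_power(cor, target_r2=0.8)

    def oracle_fit(k, n_bins=10):
        k = np.sort(k[k > 0])
        edges = np.unique(np.quantile(k, np.linspace(0, 1, n_bins + 1)))
        xs, ys = [], []
        for lo, hi, last in zip(edges[:-1], edges[1:],
                                [False] * (len(edges) - 2) + [True]):
            sel = (k >= lo) & ((k <= hi) if last else (k < hi))
            if sel.sum() == 0 or hi == lo:
                continue
            xs.append(np.log10(k[sel].mean()))
            ys.append(np.log10(sel.sum() / (k.size * (hi - lo))))
        xs, ys = np.array(xs), np.array(ys)
        b, a = np.polyfit(xs, ys, 1)
        ss_res = ((ys - (a + b * xs)) ** 2).sum()
        ss_tot = ((ys - ys.mean()) ** 2).sum()
        return 1 - ss_res / ss_tot, b

    abs_cor = np.abs(cor.to_numpy())
    np.fill_diagonal(abs_cor, 0.0)
    chosen = None
    for beta in range(1, 21):
        r2, slope = oracle_fit((abs_cor ** beta).sum(axis=1))
        if r2 >= 0.8 and slope < 0:
            chosen = beta
            break
    assert chosen == fit.power


# -- module detection --------------------------------------------------------

def _planted_tom(sizes, seed=0):
    cfg = ch.SimulationConfig(
        species=["worm"], experiments_per_species=1, seed=seed, n_samples=60,
        n_noise_genes=0, noise_scale=0.0,
        modules=[ch.ModuleSpec(size=s, score_cor=None, n_hubs=0) for s in sizes])
    exp, truth = ch.generate_experiment(cfg, "worm", 0)
    cor, _ = ch.correlation_matrix(exp.expression)
    return ch.topological_overlap(ch.adjacency(cor, 6)), truth


def test_detect_modules_recovers_planted_blocks():
    tom, truth = _planted_tom([40, 35])
    labels = ch.detect_modules(tom, min_module_size=30)
    sizes = labels.value_counts()
    assert sorted(sizes[sizes.index != 0].tolist(), reverse=True) == [40, 35]
    # each planted module lands in exactly one detected module
    for planted in ("M1", "M2"):
        genes = truth.module_of[truth.module_of == planted].index
        assert labels.loc[genes].nunique() == 1


def test_too_few_genes_all_unassigned():
    rng = np.random.default_rng(1)
    a = random_adjacency(rng, 20)
    tom = ch.topological_overlap(pd.DataFrame(a))
    labels = ch.detect_modules(tom, min_module_size=30)
    assert (labels == 0).all()


def test_module_partition_invariant_to_gene_order():
    tom, _ = _planted_tom([40, 35], seed=3)
    rng = np.random.default_rng(0)
    perm = rng.permutation(len(tom))
    shuffled = tom.iloc[perm, perm]
    l1 = ch.detect_modules(tom, min_module_size=30)
    l2 = ch.detect_modules(shuffled, min_module_size=30)
    parts1 = {frozenset(l1.index[l1 == m]) for m in set(l1) if m != 0}
    parts2 = {frozenset(l2.index[l2 == m]) for m in set(l2) if m != 0}
    assert parts1 == parts2


# -- eigengene and membership ------------------------------------------------

def test_eigengene_of_identical_genes_explains_everything():
    profile = np.array([3.0, 1.0, 4.0, 1.0, 5.0])
    m = _df([profile, profile, profile])
    eg = ch.module_eigengene(m, m.index)
    assert eg.variance_explained == pytest.approx(1.0)
    r = np.corrcoef(eg.values, profile)[0, 1]
    assert r == pytest.approx(1.0)
    assert np.linalg.norm(eg.values) == pytest.approx(1.0)


def test_eigengene_sign_deterministic_for_balanced_module():
    x = np.array([1.0, -2.0, 0.5, 3.0])
    m = _df([x, x, -x, -x])
    eg1 = ch.module_eigengene(m, m.index)
    eg2 = ch.module_eigengene(m.iloc[::-1], list(m.index))
    assert eg1.variance_explained == pytest.approx(1.0)
    assert np.allclose(eg1.values, eg2.values)  # orientation rule breaks the tie


def test_eigengene_matches_svd_oracle():
    rng = np.random.default_rng(9)
    m = _df(rng.normal(size=(10, 8)))
    eg = ch.module_eigengene(m, m.index)
    X = m.to_numpy()
    X = (X - X.mean(1, keepdims=True)) / X.std(1, ddof=1, keepdims=True)
    w, _ = np.linalg.eigh((X @ X.T))
    assert eg.variance_explained == pytest.approx(w[-1] / w.sum(), abs=1e-10)
    _, _, vt = np.linalg.svd(X)
    assert min(np.linalg.norm(eg.values - vt[0]),
               np.linalg.norm(eg.values + vt[0])) < 1e-8


def test_module_membership_extremes():
    rng = np.random.default_rng(3)
    base = rng.normal(size=12)
    m = _df([base, base + rng.normal(size=12) * 0.1, rng.normal(size=12)])
    eg = ch.module_eigengene(m, ["g0", "g1"])
    kme = ch.module_membership(m, eg)
    e = eg.values.to_numpy()
    assert kme.loc["g0"] == pytest.approx(np.corrcoef(base, e)[0, 1], abs=1e-12)
    ec = e - e.mean()
    perp = rng.normal(size=12)
    perp -= perp.mean()
    perp -= (perp @ ec) / (ec @ ec) * ec  # project out the eigengene
    m2 = _df([perp])
    assert abs(ch.module_membership(m2, eg).iloc[0]) < 1e-10


def test_noise_free_factor_module_has_unit_membership():
    cfg = ch.SimulationConfig(species=["worm"], experiments_per_species=1, seed=2,
                              noise_scale=0.0, n_noise_genes=0,
                              modules=[ch.ModuleSpec(size=30)])
    exp, _ = ch.generate_experiment(cfg, "worm", 0)
    eg = ch.module_eigengene(exp.expression, exp.expression.index)
    kme = ch.module_membership(exp.expression, eg)
    assert np.allclose(kme.abs(), 1.0, atol=1e-9)


def test_network_invariant_under_genewise_affine_transforms():
    cfg = ch.SimulationConfig(species=["worm"], experiments_per_species=1, seed=13,
                              modules=[ch.ModuleSpec(size=30)], n_noise_genes=40)
    exp, _ = ch.generate_experiment(cfg, "worm", 0)
    rng = np.random.default_rng(0)
    scale = rng.uniform(0.5, 3.0, size=(exp.expression.shape[0], 1))
    offset = rng.normal(size=(exp.expression.shape[0], 1))
    transformed = exp.expression * scale + offset
    n1 = ch.build_network(exp.expression, power=6)
    n2 = ch.build_network(transformed, power=6)
    assert np.allclose(n1.adjacency, n2.adjacency, atol=1e-10)
    assert n1.modules.tolist() == n2.modules.tolist()
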
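import math

import dendropy
import numpy as np
import pytest

from repeatskim.ancestral import (
    boxcox,
    compute_1cx,
    estimate_mrca,
    fit_trait_model,
    inv_boxcox,
    reconstruct_over_trees,
)
from repeatskim.simulate import random_trees, simulate_traits_on_tree

import oracles


def _tree(nwk):
    return dendropy.Tree.get(data=nwk, schema="newick")


FIXTURE_NWK = "((A:1.0,B:2.0):0.5,((C:0.7,D:1.3):0.4,E:2.5):0.3);"
FIXTURE_TRAITS = {"A": 1.2, "B": 0.7, "C": 2.4, "D": 2.0, "E": 3.3}
# hand-derived node depths and pairwise MRCA depths for the fixture
FIXTURE_DEPTHS = {"A": 1.5, "B": 2.5, "C": 1.4, "D": 2.0, "E": 2.8}
FIXTURE_MRCA = {
    ("A", "B"): 0.5, ("C", "D"): 0.7, ("C", "E"): 0.3, ("D", "E"): 0.3,
    ("A", "C"): 0.0, ("A", "D"): 0.0, ("A", "E"): 0.0,
    ("B", "C"): 0.0, ("B", "D"): 0.0, ("B", "E"): 0.0,
}


def _fixture_cov():
    taxa = sorted(FIXTURE_TRAITS)
    n = len(taxa)
    C = np.zeros((n, n))
    for i, a in enumerate(taxa):
        C[i, i] = FIXTURE_DEPTHS[a]
        for j in range(i + 1, n):
            b = taxa[j]
            C[i, j] = C[j, i] = FIXTURE_MRCA[tuple(sorted((a, b)))]
    y = np.array([FIXTURE_TRAITS[t] for t in taxa])
    d = np.array([FIXTURE_DEPTHS[t] for t in taxa])
    return taxa, C, y, d


@pytest.mark.parametrize(
    "x,lam,want",
    [(5.0, 1.0, 4.0), (2.0, -2.0, 0.375), (math.e, 0.0, 1.0)],
)
def test_boxcox_values(x, lam, want):
    assert boxcox(x, lam) == pytest.approx(want)


def test_boxcox_roundtrip_and_domain_errors():
    for x in (0.5, 1.0, 44.94):
        assert inv_boxcox(boxcox(x, -2.0), -2.0) == pytest.approx(x)
    assert inv_boxcox(0.375, -2.0) == pytest.approx(2.0)
    assert inv_boxcox(4.0, 1.0) == pytest.approx(5.0)
    with pytest.raises(ValueError):
        boxcox(-1.0, -2.0)
    with pytest.raises(ValueError):
        inv_boxcox(1.0, -2.0)  # lam*y + 1 < 0


def test_compute_1cx():
    assert compute_1cx(89.88, 2) == pytest.approx(44.94)
    assert compute_1cx(120, 4) == 30
    assert compute_1cx(0, 2) == 0.0
    with pytest.raises(ValueError):
        compute_1cx(10.0, 0)


def test_bm_closed_forms_on_symmetric_trees():
    fit = fit_trait_model(_tree("(A:1.0,B:1.0);"), {"A": 2.0, "B": 6.0}, "bm")
    assert fit.root_state == pytest.approx(4.0)
    star = fit_trait_model(
        _tree("(A:1,B:1,C:1,D:1);"), {"A": 1.0, "B": 2.0, "C": 3.0, "D": 10.0}, "bm"
    )
    assert star.root_state == pytest.approx(4.0)


@pytest.mark.parametrize("model", ["bm", "directional"])
def test_gls_fit_equals_matrix_oracle(model):
    taxa, C, y, d = _fixture_cov()
    fit = fit_trait_model(_tree(FIXTURE_NWK), FIXTURE_TRAITS, model)
    X = np.ones((5, 1)) if model == "bm" else np.column_stack([np.ones(5), d])
    beta, sigma2, loglik = oracles.gls_fit(C, X, y)
    assert fit.root_state == pytest.approx(beta[0], abs=1e-8)
    if model == "directional":
        assert fit.trend == pytest.approx(beta[1], abs=1e-8)
    assert fit.sigma2 == pytest.approx(sigma2, abs=1e-8)
    assert fit.loglik == pytest.approx(loglik, abs=1e-8)


def test_directional_loglik_dominates_bm():
    tree = _tree(FIXTURE_NWK)
    bm = fit_trait_model(tree, FIXTURE_TRAITS, "bm")
    directional = fit_trait_model(tree, FIXTURE_TRAITS, "directional")
    assert directional.loglik >= bm.loglik - 1e-10


def test_mrca_blup_equals_conditional_normal_oracle():
    taxa, C, y, d = _fixture_cov()
    tree = _tree(FIXTURE_NWK)
    fit = fit_trait_model(tree, FIXTURE_TRAITS, "directional")
    est = estimate_mrca(tree, FIXTURE_TRAITS, fit, {"C", "D"})
    # node depth 0.7; covariance with tips: 0.7 for C,D; 0.3 for E; 0 for A,B
    X = np.column_stack([np.ones(5), d])
    beta, _, _ = oracles.gls_fit(C, X, y)
    c = np.array([0.0, 0.0, 0.7, 0.7, 0.3])
    want = np.array([1.0, 0.7]) @ beta + c @ np.linalg.inv(C) @ (y - X @ beta)
    assert est == pytest.approx(float(want), abs=1e-8)


def test_mrca_degenerate_cases():
    tree = _tree("((A:1.0,B:1.0):1.0,(C:1.0,D:1.0):1.0);")
    traits = {"A": 1.0, "B": 2.0, "C": 3.0, "D": 6.0}
    fit = fit_trait_model(tree, traits, "bm")
    assert estimate_mrca(tree, traits, fit, {"A", "B", "C", "D"}) == pytest.approx(
        fit.root_state
    )
    assert estimate_mrca(tree, traits, fit, {"B"}) == pytest.approx(2.0)


def test_gls_invariances():
    tree_a = _tree(FIXTURE_NWK)
    fit_a = fit_trait_model(tree_a, FIXTURE_TRAITS, "bm")
    # tip relabelling/order cannot matter: feed traits in reversed order
    reordered = dict(reversed(list(FIXTURE_TRAITS.items())))
    fit_b = fit_trait_model(_tree(FIXTURE_NWK), reordered, "bm")
    assert fit_a.root_state == pytest.approx(fit_b.root_state)
    # rescaling every branch length leaves the BM root estimate unchanged
    scaled = FIXTURE_NWK.replace(":1.0", ":3.0").replace(":2.0", ":6.0").replace(
        ":0.5", ":1.5"
    ).replace(":0.7", ":2.1").replace(":1.3", ":3.9").replace(":0.4", ":1.2").replace(
        ":2.5", ":7.5"
    ).replace(":0.3", ":0.9")
    fit_c = fit_trait_model(_tree(scaled), FIXTURE_TRAITS, "bm")
    assert fit_c.root_state == pytest.approx(fit_a.root_state)


def test_reconstruct_over_identical_trees_has_zero_width_ci():
    trees = [_tree(FIXTURE_NWK) for _ in range(10)]
    queries = {"cd": {"C", "D"}, "root": set(FIXTURE_TRAITS)}
    estimates = reconstruct_over_trees(trees, FIXTURE_TRAITS, queries, lam=1.0)
    for e in estimates:
        lo, hi = e.ci95_gb
        assert hi - lo == pytest.approx(0.0, abs=1e-9)
        assert e.mean_gb == pytest.approx(e.per_tree_gb[0])


def test_constant_traits_reconstruct_to_the_constant():
    trees = random_trees(5, 8, seed=4)
    traits = {f"T{i + 1}": 3.0 for i in range(8)}
    estimates = reconstruct_over_trees(
        trees, traits, {"some": {"T1", "T2", "T3"}}, lam=-2.0
    )
    assert estimates[0].mean_gb == pytest.approx(3.0)


def test_missing_trait_raises():
    trees = random_trees(2, 6, seed=9)
    traits = {f"T{i + 1}": 2.0 for i in range(5)}  # T6 missing
    with pytest.raises(ValueError):
        reconstruct_over_trees(trees, traits, {"q": {"T1", "T2"}})


def test_root_error_shrinks_with_tip_count():
    """BM parameter recovery: median |root error| decreases from 8 to 128 tips."""
    lam, root, sigma2 = -2.0, 35.0, 1e-9
    med = []
    for size_i, n_tips in enumerate((8, 32, 128)):
        errors = []
        for rep in range(12):
            tree = random_trees(1, n_tips, seed=1000 * size_i + rep)[0]
            tips, _ = simulate_traits_on_tree(
                tree, root, sigma2, lam=lam, seed=7000 + 100 * size_i + rep
            )
            yt = {sp: float(boxcox(v, lam)) for sp, v in tips.items()}
            fit = fit_trait_model(tree, yt, "bm")
            errors.append(abs(fit.root_state - boxcox(root, lam)))
        med.append(float(np.median(errors)))
    assert med[2] < med[0]
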
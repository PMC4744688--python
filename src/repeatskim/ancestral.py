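"""Ancestral monoploid genome-size reconstruction on phylogenies.

Continuous traits (1Cx genome sizes in Gb) are Box-Cox transformed
(default lambda = -2), modelled as Brownian motion — optionally with a
directional trend proportional to root-to-tip path length — and fitted per
tree by maximum-likelihood GLS.  Ancestral states at named MRCA nodes are
best linear unbiased predictions under the fitted model.  Uncertainty over
phylogeny is handled by averaging node estimates over a sample of input
trees; the 95% confidence interval is the t-interval over per-tree
estimates, with mean and interval back-transformed to Gb at the end.

Trees are not assumed ultrametric.  On an exactly ultrametric tree the
directional trend is unidentifiable (root-to-tip depth is constant and
collinear with the intercept); the fit then degenerates to Brownian motion
with trend 0, which keeps the nested-model likelihood ordering intact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
from scipy import special, stats

DEFAULT_LAMBDA = -2.0
MODEL_BM = "bm"
MODEL_DIRECTIONAL = "directional"
_ZERO_BRANCH_JITTER = 1e-9


def boxcox(x: float, lam: float = DEFAULT_LAMBDA) -> float:
    """Box-Cox power transform: (x^lam - 1)/lam, or ln x at lam = 0."""
    if np.any(np.asarray(x) <= 0):
        raise ValueError("Box-Cox requires positive values")
    return special.boxcox(x, lam)


def inv_boxcox(y: float, lam: float = DEFAULT_LAMBDA) -> float:
    """Inverse Box-Cox: (lam*y + 1)^(1/lam), or exp(y) at lam = 0."""
    if lam != 0 and np.any(lam * np.asarray(y) + 1 <= 0):
        raise ValueError("value outside the Box-Cox image for this lambda")
    return special.inv_boxcox(y, lam)


def compute_1cx(two_c_value: float, ploidy: int) -> float:
    """Monoploid genome size: the 2C DNA amount divided by ploidy."""
    if ploidy <= 0:
        raise ValueError("ploidy must be positive")
    if two_c_value < 0:
        raise ValueError("2C value must be non-negative")
    return two_c_value / ploidy


# ---------------------------------------------------------------------------
# Tree helpers
# ---------------------------------------------------------------------------

def _prepare_tree(tree: dendropy.Tree) -> dict:
    """Node depths, tip order and subtree tip sets, with zero-length branches
    jittered by 1e-9 x tree height so the trait covariance stays invertible."""
    depths: dict = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            depths[node] = 0.0
        else:
            bl = node.edge.length if node.edge.length is not None else 0.0
            depths[node] = depths[node.parent_node] + bl
    height = max(depths.values()) if depths else 1.0
    if height <= 0:
        height = 1.0
    jitter = _ZERO_BRANCH_JITTER * height
    changed = False
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            bl = node.edge.length if node.edge.length is not None else 0.0
            if bl <= 0:
                node.edge.length = jitter
                changed = True
    if changed:
        return _prepare_tree(tree)

    tipsets: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            tipsets[node] = frozenset([node.taxon.label])
        else:
            tipsets[node] = frozenset().union(*(tipsets[c] for c in node.child_nodes()))
    taxa = sorted(tipsets[tree.seed_node])
    return {"depths": depths, "tipsets": tipsets, "taxa": taxa}


def _vcv(tree: dendropy.Tree, info: dict) -> np.ndarray:
    """Brownian trait covariance: C[i, j] = depth of MRCA(tip_i, tip_j)."""
    taxa = info["taxa"]
    idx = {t: i for i, t in enumerate(taxa)}
    n = len(taxa)
    C = np.zeros((n, n))
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            C[idx[node.taxon.label], idx[node.taxon.label]] = info["depths"][node]
            continue
        children = node.child_nodes()
        for a in range(len(children) - 1):
            for b in range(a + 1, len(children)):
                for ta in info["tipsets"][children[a]]:
                    for tb in info["tipsets"][children[b]]:
                        C[idx[ta], idx[tb]] = C[idx[tb], idx[ta]] = info["depths"][node]
    return C


def find_mrca(tree: dendropy.Tree, info: dict, tip_set: set[str]) -> dendropy.Node:
    query = frozenset(tip_set)
    if not query:
        raise ValueError("empty tip set")
    missing = query - frozenset(info["taxa"])
    if missing:
        raise ValueError(f"tips not in tree: {sorted(missing)}")
    best = None
    for node in tree.postorder_node_iter():
        if query <= info["tipsets"][node]:
            if best is None or info["depths"][node] > info["depths"][best]:
                best = node
    return best


# ---------------------------------------------------------------------------
# GLS fitting and BLUP node prediction
# ---------------------------------------------------------------------------

@dataclass
class TraitModelFit:
    model: str
    root_state: float
    trend: float
    sigma2: float
    loglik: float
    taxa: list[str]
    y: np.ndarray = field(repr=False)
    C: np.ndarray = field(repr=False)
    Cinv: np.ndarray = field(repr=False)
    X: np.ndarray = field(repr=False)
    beta: np.ndarray = field(repr=False)
    tip_depths: np.ndarray = field(repr=False)


def fit_trait_model(
    tree: dendropy.Tree,
    traits_transformed: dict[str, float],
    model: str = MODEL_BM,
) -> TraitModelFit:
    """ML generalized-least-squares fit of a Brownian (or directional
    random-walk) trait model on one tree.

    Under BM the design is an intercept only; the directional model adds a
    mean trend beta * (root-to-tip path length).  sigma2 is the ML estimate
    (residual quadratic form / n).
    """
    info = _prepare_tree(tree)
    taxa = info["taxa"]
    missing = [t for t in taxa if t not in traits_transformed]
    if missing:
        raise ValueError(f"traits missing for tips: {missing}")
    y = np.array([traits_transformed[t] for t in taxa], dtype=float)
    n = len(taxa)
    depth_by_taxon = {
        node.taxon.label: info["depths"][node]
        for node in tree.leaf_node_iter()
    }
    d = np.array([depth_by_taxon[t] for t in taxa])
    C = _vcv(tree, info)
    Cinv = np.linalg.inv(C)

    degenerate_directional = False
    if model == MODEL_DIRECTIONAL:
        if n < 3:
            raise ValueError("directional model needs >= 3 tips")
        if np.ptp(d) <= 1e-10 * max(d.max(), 1.0):
            degenerate_directional = True
            X = np.ones((n, 1))
        else:
            X = np.column_stack([np.ones(n), d])
    elif model == MODEL_BM:
        X = np.ones((n, 1))
    else:
        raise ValueError(f"unknown model {model!r}")

    XtCi = X.T @ Cinv
    beta = np.linalg.solve(XtCi @ X, XtCi @ y)
    resid = y - X @ beta
    sigma2 = float(resid @ Cinv @ resid) / n
    sigma2 = max(sigma2, 1e-300)
    sign, logdet = np.linalg.slogdet(C)
    loglik = -0.5 * (n * np.log(2 * np.pi * sigma2) + logdet + n)
    trend = float(beta[1]) if (model == MODEL_DIRECTIONAL and not degenerate_directional) else 0.0
    return TraitModelFit(
        model=model,
        root_state=float(beta[0]),
        trend=trend,
        sigma2=sigma2,
        loglik=float(loglik),
        taxa=taxa,
        y=y,
        C=C,
        Cinv=Cinv,
        X=X,
        beta=beta,
        tip_depths=d,
    )


def estimate_mrca(
    tree: dendropy.Tree,
    traits_transformed: dict[str, float],
    fit: TraitModelFit,
    tip_set: set[str],
) -> float:
    """BLUP of the MRCA state of ``tip_set`` under the fitted model: the
    conditional-normal mean of the node state given the tip values."""
    info = _prepare_tree(tree)
    node = find_mrca(tree, info, set(tip_set))
    taxa = fit.taxa
    idx = {t: i for i, t in enumerate(taxa)}
    node_depth = info["depths"][node]
    # covariance of the node state with each tip = depth of their MRCA
    c = np.empty(len(taxa))
    assigned: set[str] = set()
    anc = node
    while anc is not None:
        for t in info["tipsets"][anc]:
            if t not in assigned:
                c[idx[t]] = info["depths"][anc]
                assigned.add(t)
        anc = anc.parent_node
    if fit.X.shape[1] == 2:
        x_node = np.array([1.0, node_depth])
    else:
        x_node = np.array([1.0])
    mean = float(x_node @ fit.beta + c @ fit.Cinv @ (fit.y - fit.X @ fit.beta))
    return mean


@dataclass
class AncestralEstimate:
    node_name: str
    mean_gb: float
    ci95_gb: tuple[float, float] | None
    n_trees: int
    per_tree_gb: list[float]
    model_counts: dict[str, int]


def reconstruct_over_trees(
    trees: list[dendropy.Tree],
    traits_gb: dict[str, float],
    mrca_queries: dict[str, set[str]],
    lam: float = DEFAULT_LAMBDA,
    model_selection: str = "by_loglik",
    alpha: float = 0.05,
) -> list[AncestralEstimate]:
    """Transform traits, fit a model per tree, predict each queried MRCA,
    then average over trees and back-transform mean and 95% CI.

    ``model_selection="by_loglik"`` picks the directional model per tree
    when a likelihood-ratio test rejects BM at level alpha; ``"bm"`` or
    ``"directional"`` force a model.
    """
    if not trees:
        raise ValueError("need at least one tree")
    yt = {sp: float(boxcox(v, lam)) for sp, v in traits_gb.items()}
    lrt_cut = stats.chi2.ppf(1 - alpha, df=1)
    per_node: dict[str, list[float]] = {name: [] for name in mrca_queries}
    model_counts: dict[str, int] = {MODEL_BM: 0, MODEL_DIRECTIONAL: 0}
    for tree in trees:
        if model_selection == "by_loglik":
            fit_bm = fit_trait_model(tree, yt, MODEL_BM)
            try:
                fit_dir = fit_trait_model(tree, yt, MODEL_DIRECTIONAL)
            except ValueError:  # < 3 tips: trend not identifiable
                fit_dir = None
            if fit_dir is not None and 2 * (fit_dir.loglik - fit_bm.loglik) > lrt_cut:
                fit = fit_dir
            else:
                fit = fit_bm
        elif model_selection in (MODEL_BM, MODEL_DIRECTIONAL):
            fit = fit_trait_model(tree, yt, model_selection)
        else:
            raise ValueError(f"unknown model_selection {model_selection!r}")
        model_counts[fit.model] += 1
        for name, tips in mrca_queries.items():
            per_node[name].append(estimate_mrca(tree, yt, fit, set(tips)))

    out = []
    n_trees = len(trees)
    for name in mrca_queries:
        vals = np.array(per_node[name])
        mean_t = float(vals.mean())
        if n_trees > 1:
            se = float(vals.std(ddof=1)) / np.sqrt(n_trees)
            tq = stats.t.ppf(0.975, n_trees - 1)
            ci_t = (mean_t - tq * se, mean_t + tq * se)
            ci = (float(inv_boxcox(ci_t[0], lam)), float(inv_boxcox(ci_t[1], lam)))
            ci = (min(ci), max(ci))
        else:
            ci = None
        out.append(
            AncestralEstimate(
                node_name=name,
                mean_gb=float(inv_boxcox(mean_t, lam)),
                ci95_gb=ci,
                n_trees=n_trees,
                per_tree_gb=[float(inv_boxcox(v, lam)) for v in vals],
                model_counts=dict(model_counts),
            )
        )
    return out


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def load_trees(path) -> list[dendropy.Tree]:
    trees = dendropy.TreeList.get(path=str(path), schema="newick")
    return list(trees)


def load_traits_tsv(path) -> dict[str, float]:
    """Trait TSV with columns species, value_gb (extra columns ignored)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["species"], df["value_gb"].astype(float)))


def write_estimates_tsv(estimates: list[AncestralEstimate], path) -> None:
    with open(path, "w") as fh:
        fh.write("node_name\tmean_gb\tci_lo_gb\tci_hi_gb\tn_trees\n")
        for e in estimates:
            lo, hi = e.ci95_gb if e.ci95_gb else ("NA", "NA")
            fmt = lambda v: f"{v:.3f}" if isinstance(v, float) else v
            fh.write(f"{e.node_name}\t{e.mean_gb:.3f}\t{fmt(lo)}\t{fmt(hi)}\t{e.n_trees}\n")
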
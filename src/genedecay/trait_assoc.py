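"""Phylogenetic logistic regression and Brownian-motion ancestral states.

Gene retention is a binary tip trait assumed to evolve by a two-state Markov
process along the tree whose stationary probability at tip *i* is
``logit P(y_i = 1) = beta0 + beta1 * x_i``.  The switching intensity ``alpha``
controls phylogenetic signal: correlation between tips decays as
``exp(-alpha * d_ij)`` in (normalized) patristic distance, so large ``alpha``
means independent tips.  Two estimators are provided:

``mple``
    Penalized maximum pseudo-likelihood: Bernoulli log-likelihood plus a
    Firth-type penalty ``0.5 * logdet(X' A^{1/2} R^{-1} A^{1/2} X)``, where
    ``A = diag(p(1-p))`` and ``R = exp(-alpha D)``.  On a star phylogeny
    (R = I) this is exactly Firth-penalized logistic regression, which keeps
    coefficients finite under separation.

``ig10``
    Quasi-likelihood estimating equations with working covariance
    ``V = A^{1/2} R A^{1/2}``, the binary-trait mean-reversion working model
    of phylogenetic logistic regression.

``alpha`` is profiled on a log grid and refined; p-values for the slope come
from a parametric bootstrap under the fitted null (retention simulated by the
same two-state process) with a Wald test as cross-check.

Continuous fiber proportions are reconstructed at internal nodes by
generalized least squares under Brownian motion (the closed-form
weighted-average solution of the tree Laplacian), componentwise, then
renormalized to sum to 100.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize, minimize_scalar
from scipy.stats import norm

from genedecay.event_inference import StatusTree

ALPHA_BOUNDS = (1e-4, 1e4)


@dataclass
class PhyloGLMFit:
    """Fitted phylogenetic logistic regression."""

    method: str
    beta0: float
    beta1: float
    alpha: float
    se_beta0: float
    se_beta1: float
    p_wald: float
    p_boot: float | None
    n_boot: int
    converged: bool
    alpha_boundary: bool
    n: int


@dataclass
class AncestralStates:
    """Estimated continuous states at internal nodes.

    ``estimates``/``variances``: node key (frozenset of descendant leaf
    labels) -> {component: value}.
    """

    estimates: dict
    variances: dict
    sigma2: dict  # component -> ML rate estimate


# ---------------------------------------------------------------------------
# tree geometry helpers
# ---------------------------------------------------------------------------


def _patristic_matrix(tree: StatusTree, species: Sequence[str]) -> np.ndarray:
    dtree = tree.dendropy_tree
    pdm = dtree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in dtree.taxon_namespace}
    missing = [s for s in species if s not in taxa]
    if missing:
        raise ValueError(f"species not on the tree: {missing}")
    n = len(species)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = pdm.patristic_distance(taxa[species[i]], taxa[species[j]])
    return D


def simulate_binary_on_tree(
    tree: StatusTree,
    p_by_tip: Mapping[str, float],
    rate: float,
    rng: np.random.Generator,
    distance_scale: float = 1.0,
) -> dict[str, int]:
    """Simulate the two-state retention process down the tree.

    On the branch into a node with stationary probability ``p`` the state
    switches toward 1 at rate ``rate * p`` and toward 0 at ``rate * (1 - p)``
    (rates per unit of ``branch length / distance_scale``), so the total
    switching intensity is ``rate`` and tip correlation decays as
    ``exp(-rate * d)`` in scaled distance.  The root starts at its stationary
    probability.
    """
    dtree = tree.dendropy_tree
    states: dict[int, int] = {}

    def stationary_p(node) -> float:
        leaves = [lf.taxon.label for lf in node.leaf_iter()]
        vals = [p_by_tip[l] for l in leaves if l in p_by_tip]
        return float(np.mean(vals)) if vals else 0.5

    root = dtree.seed_node
    states[id(root)] = int(rng.random() < stationary_p(root))
    for node in dtree.preorder_node_iter():
        if node.parent_node is None:
            continue
        t = (node.edge.length or 0.0) / distance_scale
        p = stationary_p(node)
        rt = rate * t
        decay = np.exp(-rt) if np.isfinite(rt) else 0.0
        parent_state = states[id(node.parent_node)]
        prob_one = p + (parent_state - p) * decay
        states[id(node)] = int(rng.random() < prob_one)
    return {
        leaf.taxon.label: states[id(leaf)] for leaf in dtree.leaf_node_iter()
    }


# ---------------------------------------------------------------------------
# phylogenetic logistic regression
# ---------------------------------------------------------------------------


def _corr_inverse(D: np.ndarray, alpha: float):
    if np.isinf(alpha):
        R = np.eye(len(D))
    else:
        R = np.exp(-alpha * D)
    R[np.diag_indices_from(R)] = 1.0
    # nugget for numerical safety at tiny alpha
    factor = cho_factor(R + 1e-10 * np.eye(len(R)))
    logdet = 2.0 * np.sum(np.log(np.diag(factor[0])))
    return R, factor, logdet


def _fit_beta_mple(X, y, factor, start):
    def negobj(beta):
        eta = np.clip(X @ beta, -30, 30)
        p = 1.0 / (1.0 + np.exp(-eta))
        loglik = float(y @ np.log(p) + (1 - y) @ np.log(1 - p))
        a_half = np.sqrt(p * (1 - p))
        M = (X * a_half[:, None]).T @ cho_solve(factor, X * a_half[:, None])
        sign, logdet = np.linalg.slogdet(M)
        if sign <= 0:
            return 1e10
        return -(loglik + 0.5 * logdet)

    res = minimize(negobj, start, method="BFGS", options={"gtol": 1e-8, "maxiter": 200})
    return res.x, res.success or res.status == 2  # precision loss near optimum is fine


def _fit_beta_ig10(X, y, factor, start):
    beta = start.copy()
    converged = False
    for _ in range(100):
        eta = np.clip(X @ beta, -30, 30)
        p = 1.0 / (1.0 + np.exp(-eta))
        a = np.clip(p * (1 - p), 1e-10, None)
        a_half = np.sqrt(a)
        Xw = X * a_half[:, None]
        info = Xw.T @ cho_solve(factor, Xw)
        score = Xw.T @ cho_solve(factor, (y - p) / a_half)
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            break
        # damp to keep the quasi-score iteration stable under near-separation
        norm_step = np.linalg.norm(step)
        if norm_step > 5.0:
            step *= 5.0 / norm_step
        beta = beta + step
        if np.abs(beta).max() > 30:
            beta = np.clip(beta, -30, 30)
            break
        if norm_step < 1e-8:
            converged = True
            break
    return beta, converged


def _profile_alpha(X, y, D, method, alphas=None):
    """Profile the correlation decay rate on a log grid, then refine.

    On a star phylogeny (constant off-diagonal distance) the exchangeable
    correlation is confounded with the intercept and the identified limit is
    independence (alpha = inf).
    """
    offdiag = D[~np.eye(len(D), dtype=bool)]
    if len(offdiag) == 0 or np.ptp(offdiag) < 1e-9:
        return np.inf
    if alphas is None:
        alphas = np.logspace(np.log10(ALPHA_BOUNDS[0]), np.log10(ALPHA_BOUNDS[1]), 13)

    def q_of_alpha(alpha):
        # REML-flavoured Gaussian pseudo-likelihood of standardized residuals;
        # the logdet(X'V^-1 X) term stops an equicorrelation component from
        # absorbing what the intercept already explains
        R, factor, logdet = _corr_inverse(D, alpha)
        beta, ok = _fit(X, y, factor, method)
        eta = np.clip(X @ beta, -30, 30)
        p = 1.0 / (1.0 + np.exp(-eta))
        a_half = np.sqrt(np.clip(p * (1 - p), 1e-10, None))
        e = (y - p) / a_half
        Xw = X * a_half[:, None]
        sign, logdet_info = np.linalg.slogdet(Xw.T @ cho_solve(factor, Xw))
        if sign <= 0:
            return -np.inf, beta, False
        q = -0.5 * logdet - 0.5 * logdet_info - 0.5 * float(e @ cho_solve(factor, e))
        return q, beta, ok

    results = [q_of_alpha(a) for a in alphas]
    best = int(np.argmax([r[0] for r in results]))
    lo = alphas[max(best - 1, 0)]
    hi = alphas[min(best + 1, len(alphas) - 1)]
    refine = minimize_scalar(
        lambda la: -q_of_alpha(np.exp(la))[0],
        bounds=(np.log(lo), np.log(hi)),
        method="bounded",
        options={"xatol": 1e-3},
    )
    alpha = float(np.exp(refine.x))
    if q_of_alpha(alpha)[0] < results[best][0]:
        alpha = float(alphas[best])
    return alpha


def _fit(X, y, factor, method):
    start = np.zeros(X.shape[1])
    if method == "mple":
        return _fit_beta_mple(X, y, factor, start)
    return _fit_beta_ig10(X, y, factor, start)


def fit_phylo_logistic(
    tree: StatusTree,
    y: Mapping[str, int],
    x: Mapping[str, float],
    method: str = "mple",
    *,
    n_boot: int = 499,
    seed: int = 0,
) -> PhyloGLMFit:
    """Phylogenetic logistic regression of retention on a continuous trait.

    ``method`` is ``'mple'`` (Firth-type penalized pseudo-likelihood, the
    ``logistic_MPLE`` flavour) or ``'ig10'`` (estimating equations, the
    ``logistic_IG10`` flavour).  ``n_boot = 0`` skips the parametric
    bootstrap and reports only the Wald p-value.
    """
    if method not in ("mple", "ig10"):
        raise ValueError(f"unknown method {method!r}")
    species = sorted(y)
    if set(x) != set(species):
        raise ValueError(
            f"species mismatch between y and x: {sorted(set(y) ^ set(x))}"
        )
    n = len(species)
    if n < 10:
        raise ValueError(f"need at least 10 species, got {n}")
    yv = np.array([float(y[s]) for s in species])
    if yv.min() == yv.max():
        raise ValueError("retention is constant; regression undefined")
    xv = np.array([float(x[s]) for s in species])
    X = np.column_stack([np.ones(n), xv])

    D = _patristic_matrix(tree, species)
    scale = D.max() if D.max() > 0 else 1.0
    Dn = D / scale

    alpha = _profile_alpha(X, yv, Dn, method)
    boundary = np.isfinite(alpha) and not (
        ALPHA_BOUNDS[0] * 1.01 < alpha < ALPHA_BOUNDS[1] * 0.99
    )
    R, factor, _ = _corr_inverse(Dn, alpha)
    beta, converged = _fit(X, yv, factor, method)

    eta = np.clip(X @ beta, -30, 30)
    p = 1.0 / (1.0 + np.exp(-eta))
    a_half = np.sqrt(np.clip(p * (1 - p), 1e-10, None))
    Xw = X * a_half[:, None]
    info = Xw.T @ cho_solve(factor, Xw)
    cov = np.linalg.inv(info)
    se = np.sqrt(np.clip(np.diag(cov), 0, None))
    z = beta[1] / se[1] if se[1] > 0 else np.inf
    p_wald = float(2.0 * norm.sf(abs(z)))

    p_boot = None
    used_boot = 0
    if n_boot > 0:
        p_boot, used_boot = _bootstrap_pvalue(
            tree, species, X, yv, Dn, scale, method, beta, n_boot, seed
        )

    return PhyloGLMFit(
        method=method,
        beta0=float(beta[0]),
        beta1=float(beta[1]),
        alpha=alpha,
        se_beta0=float(se[0]),
        se_beta1=float(se[1]),
        p_wald=p_wald,
        p_boot=p_boot,
        n_boot=used_boot,
        converged=converged,
        alpha_boundary=boundary,
        n=n,
    )


def _wald_z(X, y, beta, factor) -> float:
    eta = np.clip(X @ beta, -30, 30)
    p = 1.0 / (1.0 + np.exp(-eta))
    a_half = np.sqrt(np.clip(p * (1 - p), 1e-10, None))
    Xw = X * a_half[:, None]
    cov = np.linalg.inv(Xw.T @ cho_solve(factor, Xw))
    se = np.sqrt(max(cov[1, 1], 1e-12))
    return float(beta[1] / se)


def _bootstrap_pvalue(tree, species, X, yv, Dn, scale, method, beta_hat, n_boot, seed):
    """Parametric bootstrap of the studentized slope under the fitted
    intercept-only null.

    The statistic is |beta1/se| rather than |beta1|: replicates close to
    separation yield arbitrarily large raw slopes with equally large standard
    errors, and studentizing keeps them from fattening the null tail.
    """
    X0 = X[:, :1]
    alpha0 = _profile_alpha(X0, yv, Dn, method)
    _, factor0, _ = _corr_inverse(Dn, alpha0)
    beta0, _ = _fit(X0, yv, factor0, method)
    p_null = float(1.0 / (1.0 + np.exp(-np.clip(beta0[0], -30, 30))))
    p_by_tip = {s: p_null for s in species}

    rng = np.random.default_rng(seed)
    exceed = 0
    used = 0
    target = abs(_wald_z(X, yv, beta_hat, factor0))
    for _ in range(n_boot):
        ystar_map = simulate_binary_on_tree(
            tree, p_by_tip, rate=alpha0, rng=rng, distance_scale=scale
        )
        ystar = np.array([float(ystar_map[s]) for s in species])
        if ystar.min() == ystar.max():
            continue  # uninformative draw: slope undefined
        # alpha held at its null estimate across replicates (its resampling
        # variability is second-order for the slope and reprofiling would
        # dominate the cost)
        beta_b, _ = _fit(X, ystar, factor0, method)
        used += 1
        if abs(_wald_z(X, ystar, beta_b, factor0)) >= target:
            exceed += 1
    if used == 0:
        return None, 0
    return float((1 + exceed) / (1 + used)), used


# ---------------------------------------------------------------------------
# ancestral continuous states
# ---------------------------------------------------------------------------


def ancestral_continuous(
    tree: StatusTree,
    tip_values: pd.DataFrame | Mapping[str, float],
    renormalize_to: float | None = None,
) -> AncestralStates:
    """Brownian-motion GLS estimates of internal-node states.

    ``tip_values`` is either one mapping species -> value or a DataFrame with
    species as index and one column per component.  Components are estimated
    independently; with ``renormalize_to`` (e.g. 100 for fiber percentages,
    the default when there are >= 2 components) estimates at each node are
    rescaled to that total.  Internal estimates are the weighted-average
    solution of the tree's edge-weight Laplacian, hence always inside the
    convex hull of the tip values.
    """
    if not isinstance(tip_values, pd.DataFrame):
        tip_values = pd.DataFrame({"value": dict(tip_values)})
    if renormalize_to is None and tip_values.shape[1] >= 2:
        renormalize_to = 100.0

    dtree = tree.dendropy_tree
    leaves = {leaf.taxon.label: leaf for leaf in dtree.leaf_node_iter()}
    missing = set(tip_values.index) ^ set(leaves)
    if missing:
        raise ValueError(f"tip values do not match tree leaves: {sorted(missing)}")

    internal = [n for n in dtree.preorder_node_iter() if not n.is_leaf()]
    index = {id(n): k for k, n in enumerate(internal)}
    m = len(internal)

    lengths = {}
    for node in dtree.preorder_node_iter():
        if node.parent_node is None:
            continue
        t = node.edge.length or 0.0
        if t <= 0:
            warnings.warn("zero-length branch perturbed by 1e-8 for BM solve")
            t = 1e-8
        lengths[id(node)] = t

    lap = np.zeros((m, m))
    rhs_template = []
    for node in internal:
        k = index[id(node)]
        neighbors = list(node.child_nodes())
        if node.parent_node is not None:
            neighbors.append(node.parent_node)
        for nb in neighbors:
            t = lengths[id(nb)] if nb is not node.parent_node else lengths[id(node)]
            w = 1.0 / t
            lap[k, k] += w
            if not nb.is_leaf() and id(nb) in index:
                lap[k, index[id(nb)]] -= w
            elif nb.is_leaf():
                rhs_template.append((k, nb.taxon.label, w))

    lap_inv = np.linalg.inv(lap)

    estimates: dict = {}
    variances: dict = {}
    sigma2: dict = {}
    node_keys = [tree.branch_key(n) for n in internal]
    for key in node_keys:
        estimates[key] = {}
        variances[key] = {}

    for comp in tip_values.columns:
        yv = tip_values[comp].astype(float)
        rhs = np.zeros(m)
        for k, label, w in rhs_template:
            rhs[k] += w * yv[label]
        states = lap_inv @ rhs
        s2 = _bm_sigma2(dtree, lengths, yv)
        sigma2[comp] = s2
        for k, key in enumerate(node_keys):
            estimates[key][comp] = float(states[k])
            variances[key][comp] = float(s2 * lap_inv[k, k])

    if renormalize_to is not None:
        for key in node_keys:
            total = sum(estimates[key].values())
            if total > 0:
                factor = renormalize_to / total
                for comp in estimates[key]:
                    estimates[key][comp] *= factor
    return AncestralStates(estimates=estimates, variances=variances, sigma2=sigma2)


def _bm_sigma2(dtree, lengths, tip_series) -> float:
    """ML Brownian rate from phylogenetically independent contrasts."""
    vals: dict[int, float] = {}
    depths: dict[int, float] = {}
    contrasts = []
    for node in dtree.postorder_node_iter():
        if node.is_leaf():
            vals[id(node)] = float(tip_series[node.taxon.label])
            depths[id(node)] = lengths.get(id(node), 0.0)
            continue
        children = node.child_nodes()
        # reduce multifurcations pairwise
        cv = [vals[id(c)] for c in children]
        cd = [depths[id(c)] for c in children]
        while len(cv) > 1:
            v1, v2 = cv.pop(), cv.pop()
            d1, d2 = cd.pop(), cd.pop()
            contrasts.append((v1 - v2) ** 2 / (d1 + d2))
            cv.append((v1 / d1 + v2 / d2) / (1 / d1 + 1 / d2))
            cd.append(d1 * d2 / (d1 + d2))
        extra = lengths.get(id(node), 0.0)
        vals[id(node)] = cv[0]
        depths[id(node)] = cd[0] + extra
    return float(np.mean(contrasts)) if contrasts else 0.0
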
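"""Phylogenetic signal tests for a tip trait (here: drought response ratios).

Three complementary statistics ask whether closely related ZOTUs respond to
drought more similarly than expected at random:

* **Pagel's λ** — maximum-likelihood multiplier of the off-diagonal
  Brownian-motion covariance; λ=0 means no signal, λ=1 full BM.  Tested with
  a likelihood-ratio test against λ=0 (χ² with 1 df).
* **Blomberg's K** — observed vs BM-expected partitioning of trait variance;
  K≈1 under BM.  Tested by permuting trait values across tips (one-sided
  high).
* **Abouheif's C_mean** — a Moran-type autocorrelation using a purely
  topological proximity matrix, also permutation-tested.

All three accept the trait as a ``pandas.Series`` indexed by tip label (any
order) or as an array already in tree tip order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats
from skbio import TreeNode

from .io import RhizosignalError

__all__ = [
    "PhyloSignalResult",
    "bm_covariance",
    "lambda_transform",
    "pagels_lambda",
    "blombergs_K",
    "abouheif_proximity",
    "abouheif_cmean",
    "phylosignal_suite",
]


@dataclass
class PhyloSignalResult:
    method: str  # "lambda" | "K" | "cmean"
    statistic: float
    p_value: float
    n_tips: int
    n_perm: int | None = None
    lr_statistic: float | None = None
    log_likelihood: float | None = None

    def as_dict(self) -> dict:
        return {
            "method": self.method,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "n_tips": self.n_tips,
            "n_perm": self.n_perm,
            "lr_statistic": self.lr_statistic,
        }


# ---------------------------------------------------------------------------
# Brownian-motion covariance
# ---------------------------------------------------------------------------


def tip_order(tree: TreeNode) -> list[str]:
    return [t.name for t in tree.tips()]


def bm_covariance(tree: TreeNode) -> pd.DataFrame:
    """Tip covariance under Brownian motion: V_ij = root-to-MRCA path length.

    Diagonal entries are root-to-tip depths.  Returned as a DataFrame with
    tip labels so traits can be aligned by name.
    """
    tips = list(tree.tips())
    if len(tips) < 3:
        raise RhizosignalError("need at least 3 tips")
    names = [t.name for t in tips]
    index = {id(t): i for i, t in enumerate(tips)}
    n = len(tips)
    V = np.zeros((n, n))

    depth: dict[int, float] = {id(tree): 0.0}
    for node in tree.preorder(include_self=False):
        length = node.length or 0.0
        depth[id(node)] = depth[id(node.parent)] + length

    # postorder: tips under each node; cross-child pairs share that node's depth
    tipsets: dict[int, list[int]] = {}
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            tipsets[id(node)] = [index[id(node)]]
            continue
        groups = [tipsets.pop(id(c)) for c in node.children]
        d = depth[id(node)]
        for a in range(len(groups)):
            for b in range(a + 1, len(groups)):
                ia = np.array(groups[a])
                ib = np.array(groups[b])
                V[np.ix_(ia, ib)] = d
                V[np.ix_(ib, ia)] = d
        merged = [i for g in groups for i in g]
        tipsets[id(node)] = merged
    for tip in tips:
        i = index[id(tip)]
        V[i, i] = depth[id(tip)]
        if depth[id(tip)] == 0:
            warnings.warn(f"tip {tip.name!r} has zero root-to-tip depth")
    return pd.DataFrame(V, index=names, columns=names)


def lambda_transform(V: np.ndarray, lam: float) -> np.ndarray:
    """Scale off-diagonal entries of V by λ, keeping the diagonal."""
    C = lam * np.asarray(V, dtype=float)
    np.fill_diagonal(C, np.diag(V))
    return C


def _align_trait(x, names: list[str]) -> np.ndarray:
    if isinstance(x, pd.Series):
        missing = [n for n in names if n not in x.index]
        if missing:
            raise RhizosignalError(f"trait missing for tips: {missing[:5]}")
        x = x.loc[names].to_numpy(dtype=float)
    else:
        x = np.asarray(x, dtype=float)
        if x.shape != (len(names),):
            raise RhizosignalError(
                f"trait length {x.shape} does not match {len(names)} tips"
            )
    if not np.all(np.isfinite(x)):
        raise RhizosignalError("trait contains non-finite values")
    return x


# ---------------------------------------------------------------------------
# Pagel's lambda
# ---------------------------------------------------------------------------


def _profile_loglik(C: np.ndarray, x: np.ndarray) -> float:
    """Gaussian log-likelihood with GLS-profiled mean and variance."""
    n = len(x)
    cho = linalg.cho_factor(C, lower=True)
    ones = np.ones(n)
    Ci_x = linalg.cho_solve(cho, x)
    Ci_1 = linalg.cho_solve(cho, ones)
    a_hat = (ones @ Ci_x) / (ones @ Ci_1)
    r = x - a_hat
    sigma2 = (r @ linalg.cho_solve(cho, r)) / n
    logdet = 2.0 * np.sum(np.log(np.diag(cho[0])))
    return -0.5 * (n * np.log(2 * np.pi * sigma2) + logdet + n)


def pagels_lambda(
    tree: TreeNode,
    x,
    lambda_max: float = 1.0,
    tol: float = 1e-8,
    V: pd.DataFrame | None = None,
) -> PhyloSignalResult:
    """ML estimate of Pagel's λ with a χ²(1) likelihood-ratio test vs λ=0.

    The likelihood is profiled analytically over the ancestral mean and the
    BM rate; λ is then optimised on [0, ``lambda_max``] by bounded scalar
    search.  For ultrametric trees ``lambda_max=1`` keeps the covariance
    positive definite.
    """
    if V is None:
        V = bm_covariance(tree)
    names = list(V.index)
    xv = _align_trait(x, names)
    if np.ptp(xv) == 0:
        raise RhizosignalError("zero variance trait")
    Vm = V.to_numpy()

    def neg_ll(lam: float) -> float:
        return -_profile_loglik(lambda_transform(Vm, lam), xv)

    res = optimize.minimize_scalar(
        neg_ll, bounds=(0.0, lambda_max), method="bounded", options={"xatol": tol}
    )
    candidates = [(res.x, -res.fun), (0.0, -neg_ll(0.0)), (lambda_max, -neg_ll(lambda_max))]
    lam_hat, ll_hat = max(candidates, key=lambda c: c[1])
    ll0 = -neg_ll(0.0)
    lr = max(0.0, 2.0 * (ll_hat - ll0))
    p = float(stats.chi2.sf(lr, df=1))
    p = min(max(p, np.finfo(float).tiny), 1.0)
    return PhyloSignalResult(
        method="lambda",
        statistic=float(lam_hat),
        p_value=p,
        n_tips=len(xv),
        lr_statistic=float(lr),
        log_likelihood=float(ll_hat),
    )


# ---------------------------------------------------------------------------
# Blomberg's K
# ---------------------------------------------------------------------------


def blombergs_K(
    tree: TreeNode,
    x,
    n_perm: int = 999,
    seed: int | None = None,
    V: pd.DataFrame | None = None,
) -> PhyloSignalResult:
    """Blomberg's K with a one-sided tip-permutation test.

    K = (MSE0/MSE) / E[MSE0/MSE], where MSE0 uses the raw deviations from
    the phylogenetically weighted mean and MSE the V⁻¹-weighted ones; the
    expectation term makes K ≈ 1 for traits evolved under BM on the tree.
    """
    if V is None:
        V = bm_covariance(tree)
    names = list(V.index)
    xv = _align_trait(x, names)
    if np.ptp(xv) == 0:
        raise RhizosignalError("zero variance trait")
    Vm = V.to_numpy()
    n = len(xv)
    try:
        cho = linalg.cho_factor(Vm, lower=True)
    except linalg.LinAlgError as exc:
        raise RhizosignalError(f"singular BM covariance: {exc}") from exc
    ones = np.ones(n)
    Vi_1 = linalg.cho_solve(cho, ones)
    denom_1V1 = ones @ Vi_1
    expected_ratio = (np.trace(Vm) - n / denom_1V1) / (n - 1)

    def k_stat(cols: np.ndarray) -> np.ndarray:
        # cols: n × m matrix of trait vectors
        a_hat = (Vi_1 @ cols) / denom_1V1
        r = cols - a_hat[np.newaxis, :]
        mse0 = np.sum(r * r, axis=0) / (n - 1)
        Vi_r = linalg.cho_solve(cho, r)
        mse = np.sum(r * Vi_r, axis=0) / (n - 1)
        return (mse0 / mse) / expected_ratio

    k_obs = float(k_stat(xv[:, np.newaxis])[0])
    rng = np.random.default_rng(seed)
    perms = np.empty((n, n_perm))
    for b in range(n_perm):
        perms[:, b] = rng.permutation(xv)
    k_null = k_stat(perms)
    p = (1.0 + np.sum(k_null >= k_obs)) / (1.0 + n_perm)
    return PhyloSignalResult(
        method="K", statistic=k_obs, p_value=float(p), n_tips=n, n_perm=n_perm
    )


# ---------------------------------------------------------------------------
# Abouheif's C_mean
# ---------------------------------------------------------------------------


def abouheif_proximity(tree: TreeNode) -> pd.DataFrame:
    """Topological proximity A: A_ij = 1 / Π dd(v) over the internal nodes on
    the nodal path between tips i and j (the union of their ancestor chains up
    to the root), where dd(v) is the number of direct descendants of v.
    Diagonal is zero.
    """
    tips = list(tree.tips())
    names = [t.name for t in tips]
    n = len(tips)
    node_id: dict[int, int] = {}
    log_dd: list[float] = []
    for node in tree.traverse(include_self=True):
        if not node.is_tip():
            node_id[id(node)] = len(log_dd)
            log_dd.append(np.log(len(node.children)))
    log_dd_arr = np.array(log_dd)
    anc_sets: list[frozenset[int]] = []
    for tip in tips:
        anc = set()
        node = tip.parent
        while node is not None:
            anc.add(node_id[id(node)])
            node = node.parent
        anc_sets.append(frozenset(anc))
    A = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            union = anc_sets[i] | anc_sets[j]
            A[i, j] = A[j, i] = np.exp(-log_dd_arr[list(union)].sum())
    return pd.DataFrame(A, index=names, columns=names)


def abouheif_cmean(
    tree: TreeNode,
    x,
    n_perm: int = 999,
    seed: int | None = None,
    A: pd.DataFrame | None = None,
) -> PhyloSignalResult:
    """Abouheif's C_mean: Moran autocorrelation of the standardised trait
    under the row-normalised topological proximity, with a one-sided
    (observed ≥ null) tip-permutation test.
    """
    if A is None:
        A = abouheif_proximity(tree)
    names = list(A.index)
    xv = _align_trait(x, names)
    if np.ptp(xv) == 0:
        raise RhizosignalError("zero variance trait")
    W = A.to_numpy() / A.to_numpy().sum(axis=1, keepdims=True)
    n = len(xv)
    z = (xv - xv.mean()) / xv.std(ddof=0)
    c_obs = float(z @ W @ z) / n
    rng = np.random.default_rng(seed)
    Z = np.empty((n, n_perm))
    for b in range(n_perm):
        Z[:, b] = rng.permutation(z)
    c_null = np.sum(Z * (W @ Z), axis=0) / n
    p = (1.0 + np.sum(c_null >= c_obs)) / (1.0 + n_perm)
    return PhyloSignalResult(
        method="cmean", statistic=c_obs, p_value=float(p), n_tips=n, n_perm=n_perm
    )


def phylosignal_suite(
    tree: TreeNode,
    x,
    methods: tuple[str, ...] = ("lambda", "K", "cmean"),
    n_perm: int = 999,
    seed: int | None = None,
) -> pd.DataFrame:
    """Run the three signal tests and return a Stat / P-value table."""
    V = bm_covariance(tree) if {"lambda", "K"} & set(methods) else None
    rows = []
    for method in methods:
        if method == "lambda":
            r = pagels_lambda(tree, x, V=V)
        elif method == "K":
            r = blombergs_K(tree, x, n_perm=n_perm, seed=seed, V=V)
        elif method == "cmean":
            r = abouheif_cmean(tree, x, n_perm=n_perm, seed=seed)
        else:
            raise RhizosignalError(f"unknown method {method!r}")
        rows.append(r.as_dict())
    return pd.DataFrame(rows).set_index("method")
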
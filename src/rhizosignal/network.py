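"""Compositional association networks and drought-vs-ambient comparison.

SparCC estimates linear correlations between the latent (basis) abundances
underlying compositional count data: per Dirichlet resample of the
fractions, the log-ratio variance t_ij = var(log(x_i/x_j)) is converted to
basis variances ω via the sparsity approximation t_ij ≈ ω_i + ω_j, giving
ρ_ij = (ω_i + ω_j − t_ij) / (2√(ω_i ω_j)); strongly correlated pairs are
iteratively excluded from the approximation and the final ρ averages the
Dirichlet draws.

The differential comparison builds a network per treatment group at a
taxonomic rank, ranks edges by the larger of the two association magnitudes,
and permutation-tests each selected edge's difference by reassigning samples
to groups and recomputing both networks, with BH correction across the
selected set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .io import CountTable, RhizosignalError, SampleMetadata, aggregate_to_rank  # noqa: F401  (re-exported)

__all__ = [
    "aggregate_to_rank",
    "AssociationNetwork",
    "sparcc",
    "select_top_edges",
    "DifferentialEdge",
    "differential_network",
    "write_edge_list",
]


@dataclass
class AssociationNetwork:
    nodes: list[str]
    rho: np.ndarray  # symmetric, unit diagonal
    group: str = ""
    settings: dict | None = None

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.rho, index=self.nodes, columns=self.nodes)


def _basis_variances(T: np.ndarray, include: np.ndarray) -> np.ndarray:
    """Solve Σ_j M_ij (ω_i + ω_j) = Σ_j M_ij t_ij for the basis variances,
    with M the pair-inclusion mask (sparsity approximation)."""
    p = T.shape[0]
    M = include.astype(float)
    np.fill_diagonal(M, 0.0)
    A = np.diag(M.sum(axis=1)) + M
    b = (M * T).sum(axis=1)
    try:
        omega = np.linalg.solve(A, b)
        if not np.all(np.isfinite(omega)):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        # exclusion patterns on few taxa can make A exactly singular;
        # fall back to the minimum-norm least-squares solution
        omega = np.linalg.lstsq(A, b, rcond=None)[0]
    return np.maximum(omega, 1e-12)


def _rho_from_T(T: np.ndarray, threshold: float, iters: int) -> np.ndarray:
    p = T.shape[0]
    include = np.ones((p, p), dtype=bool)
    np.fill_diagonal(include, False)
    for _ in range(iters + 1):
        omega = _basis_variances(T, include)
        denom = 2.0 * np.sqrt(np.outer(omega, omega))
        rho = (omega[:, None] + omega[None, :] - T) / denom
        rho = np.clip(rho, -1.0, 1.0)
        np.fill_diagonal(rho, 1.0)
        # exclude the strongest pair, but never isolate a node (degree < 2
        # rows make the basis-variance system singular)
        degree = include.sum(axis=1)
        eligible = include & (degree > 2)[:, None] & (degree > 2)[None, :]
        masked = np.where(eligible, np.abs(rho), 0.0)
        i, j = np.unravel_index(np.argmax(masked), masked.shape)
        if masked[i, j] <= threshold:
            break
        include[i, j] = include[j, i] = False
    return rho


def sparcc(
    table: CountTable,
    n_dirichlet: int = 20,
    exclusion_threshold: float = 0.1,
    exclusion_iters: int = 10,
    seed: int | None = None,
    group: str = "",
) -> AssociationNetwork:
    """SparCC basis correlations for a count table (taxa × samples).

    Fractions are drawn from per-sample Dirichlet posteriors with a unit
    prior (``n_dirichlet`` draws); the returned ρ is the draw average.
    ``n_dirichlet=0`` skips the resampling and uses the posterior-mean
    fractions ``(c+1)/Σ(c+1)`` directly — deterministic and exactly
    invariant to sample order, at the cost of ignoring count uncertainty.
    All-zero taxa are dropped with a warning; fewer than 4 remaining taxa is
    an error, and below 25 the sparsity assumption is flagged as weak.
    """
    nonzero = table.counts.sum(axis=1) > 0
    if not nonzero.all():
        dropped = [t for t, keep in zip(table.taxon_ids, nonzero) if not keep]
        warnings.warn(f"{len(dropped)} all-zero taxa dropped from SparCC")
        table = table.select_taxa([t for t, k in zip(table.taxon_ids, nonzero) if k])
    p = table.n_taxa
    if p < 4:
        raise RhizosignalError("SparCC needs at least 4 taxa")
    if p < 25:
        warnings.warn("fewer than 25 taxa: SparCC sparsity assumption is weak")
    rng = np.random.default_rng(seed)
    counts = table.counts.T + 1.0  # unit prior, samples × taxa

    def one_rho(frac: np.ndarray) -> np.ndarray:
        logf = np.log(frac)
        # t_ij = var(log f_i - log f_j) over samples
        cov = np.cov(logf, rowvar=False)
        var = np.diag(cov)
        T = var[:, None] + var[None, :] - 2.0 * cov
        return _rho_from_T(T, exclusion_threshold, exclusion_iters)

    if n_dirichlet == 0:
        rho = one_rho(counts / counts.sum(axis=1, keepdims=True))
    else:
        rho_sum = np.zeros((p, p))
        for _ in range(n_dirichlet):
            gamma = rng.standard_gamma(counts)
            rho_sum += one_rho(gamma / gamma.sum(axis=1, keepdims=True))
        rho = rho_sum / n_dirichlet
    rho = np.clip((rho + rho.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(rho, 1.0)
    return AssociationNetwork(
        list(table.taxon_ids),
        rho,
        group=group,
        settings={
            "n_dirichlet": n_dirichlet,
            "exclusion_threshold": exclusion_threshold,
            "exclusion_iters": exclusion_iters,
        },
    )


def select_top_edges(
    net1: AssociationNetwork, net2: AssociationNetwork, k: int = 50
) -> list[tuple[str, str]]:
    """Top-k node pairs by max(|ρ₁|, |ρ₂|); ties break lexicographically."""
    if net1.nodes != net2.nodes:
        raise RhizosignalError("networks must share an identical node set")
    nodes = net1.nodes
    pairs = []
    for i in range(len(nodes)):
        for j in range(i + 1, len(nodes)):
            strength = max(abs(net1.rho[i, j]), abs(net2.rho[i, j]))
            pairs.append((-strength, nodes[i], nodes[j]))
    pairs.sort()
    if k > len(pairs):
        warnings.warn(f"k={k} exceeds {len(pairs)} pairs; returning all")
        k = len(pairs)
    return [(a, b) for _, a, b in pairs[:k]]


@dataclass
class DifferentialEdge:
    node_a: str
    node_b: str
    rho_group1: float
    rho_group2: float
    difference: float
    p_value: float
    p_adjusted: float
    sign_pattern: str


_SIGN_PATTERNS = {
    (1, 1): "always_positive",
    (-1, -1): "always_negative",
    (1, -1): "positive_to_negative",
    (-1, 1): "negative_to_positive",
}


def _sign_pattern(r1: float, r2: float) -> str:
    key = (1 if r1 >= 0 else -1, 1 if r2 >= 0 else -1)
    return _SIGN_PATTERNS[key]


def differential_network(
    table: CountTable,
    metadata: SampleMetadata,
    group_pair: tuple[str, str] = ("severe", "ambient"),
    k: int = 50,
    n_perm: int = 1000,
    seed: int | None = None,
    alpha: float = 0.05,
    timepoint: str = "T2",
    n_dirichlet: int = 20,
    exclusion_threshold: float = 0.1,
    exclusion_iters: int = 10,
    significant_only: bool = False,
) -> tuple[list[DifferentialEdge], AssociationNetwork, AssociationNetwork]:
    """Permutation comparison of SparCC associations between two treatments.

    The ``k`` strongest candidate edges (by either group's magnitude) are
    tested: group labels are reshuffled ``n_perm`` times, both networks
    recomputed, and each edge's |Δρ| compared with its null; BH correction
    runs across the selected edges.  Returns the edge list (all selected
    edges unless ``significant_only``) plus the two observed networks.
    """
    g1_label, g2_label = group_pair
    g1 = metadata.select(treatment=g1_label, timepoint=timepoint)
    g2 = metadata.select(treatment=g2_label, timepoint=timepoint)
    g1 = [s for s in g1 if s in table.sample_ids]
    g2 = [s for s in g2 if s in table.sample_ids]
    if len(g1) < 3 or len(g2) < 3:
        raise RhizosignalError("need at least 3 samples in each group")
    rng = np.random.default_rng(seed)
    sub = lambda: int(rng.integers(2**31 - 1))  # noqa: E731

    kwargs = dict(
        n_dirichlet=n_dirichlet,
        exclusion_threshold=exclusion_threshold,
        exclusion_iters=exclusion_iters,
    )
    pooled = table.select_samples(g1 + g2)
    # keep taxa observed in the pooled data so both groups share a node set
    nonzero = pooled.counts.sum(axis=1) > 0
    pooled = pooled.select_taxa(
        [t for t, keep in zip(pooled.taxon_ids, nonzero) if keep]
    )
    n1 = len(g1)

    def both_networks(sample_order: list[str]) -> tuple[np.ndarray, np.ndarray]:
        t1 = pooled.select_samples(sample_order[:n1])
        t2 = pooled.select_samples(sample_order[n1:])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r1 = sparcc(t1, seed=sub(), **kwargs)
            r2 = sparcc(t2, seed=sub(), **kwargs)
        d1 = pd.DataFrame(r1.rho, index=r1.nodes, columns=r1.nodes)
        d2 = pd.DataFrame(r2.rho, index=r2.nodes, columns=r2.nodes)
        nodes = pooled.taxon_ids
        return (
            d1.reindex(index=nodes, columns=nodes).fillna(0.0).to_numpy(),
            d2.reindex(index=nodes, columns=nodes).fillna(0.0).to_numpy(),
        )

    rho1, rho2 = both_networks(g1 + g2)
    net1 = AssociationNetwork(list(pooled.taxon_ids), rho1, group=g1_label)
    net2 = AssociationNetwork(list(pooled.taxon_ids), rho2, group=g2_label)
    edges = select_top_edges(net1, net2, k=k)
    idx = {t: i for i, t in enumerate(pooled.taxon_ids)}
    eij = np.array([(idx[a], idx[b]) for a, b in edges])
    obs_diff = rho1[eij[:, 0], eij[:, 1]] - rho2[eij[:, 0], eij[:, 1]]

    # canonical pooled order so the same seed draws the same partitions
    # whichever way the group pair is written
    all_samples = sorted(g1 + g2)
    exceed = np.zeros(len(edges))
    for _ in range(n_perm):
        order = [all_samples[i] for i in rng.permutation(len(all_samples))]
        p1, p2 = both_networks(order)
        null_diff = p1[eij[:, 0], eij[:, 1]] - p2[eij[:, 0], eij[:, 1]]
        exceed += np.abs(null_diff) >= np.abs(obs_diff)
    p_values = (1.0 + exceed) / (1.0 + n_perm)
    p_adj = multipletests(p_values, method="fdr_bh")[1]

    results = []
    for e, (a, b) in enumerate(edges):
        if significant_only and p_adj[e] >= alpha:
            continue
        i, j = eij[e]
        results.append(
            DifferentialEdge(
                node_a=a,
                node_b=b,
                rho_group1=float(rho1[i, j]),
                rho_group2=float(rho2[i, j]),
                difference=float(obs_diff[e]),
                p_value=float(p_values[e]),
                p_adjusted=float(p_adj[e]),
                sign_pattern=_sign_pattern(rho1[i, j], rho2[i, j]),
            )
        )
    return results, net1, net2


def edges_to_dataframe(edges: list[DifferentialEdge]) -> pd.DataFrame:
    return pd.DataFrame([e.__dict__ for e in edges])


def write_edge_list(edges: list[DifferentialEdge], path: str | Path, dot: bool = False) -> None:
    """Write a differential edge list as TSV, or as a simple DOT graph."""
    path = Path(path)
    if not dot:
        edges_to_dataframe(edges).to_csv(path, sep="\t", index=False)
        return
    lines = ["graph diffnet {"]
    for e in edges:
        lines.append(
            f'  "{e.node_a}" -- "{e.node_b}" '
            f'[label="{e.difference:+.2f}", pattern="{e.sign_pattern}"];'
        )
    lines.append("}")
    path.write_text("\n".join(lines) + "\n")
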
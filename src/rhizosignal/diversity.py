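"""Community diversity and ordination statistics.

Alpha diversity (richness, Shannon in nats, Faith's PD), unweighted UniFrac
beta diversity, principal coordinates analysis, multi-factor PERMANOVA with
sequential (Type I) sums of squares and free label permutation, a
beta-dispersion (PERMDISP-style) homogeneity test, and rank-level unpaired
comparisons of relative abundance between the pretreatment and
post-treatment ambient samples.

UniFrac and Faith's PD are delegated to scikit-bio; PERMANOVA, PCoA and the
dispersion test are implemented here because the multi-factor sequential
decomposition and the negative-eigenvalue-aware centroid distances are not
available one-way wrappers can provide.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from skbio import DistanceMatrix, TreeNode
from skbio.diversity import beta_diversity
from skbio.diversity.alpha import faith_pd
from statsmodels.stats.multitest import multipletests

from .io import CountTable, RhizosignalError, SampleMetadata, TaxonomyTable, aggregate_to_rank, to_relative_abundance

__all__ = [
    "alpha_diversity",
    "unweighted_unifrac",
    "pcoa",
    "PcoaResult",
    "permanova",
    "PermanovaResult",
    "beta_dispersion",
    "DispersionResult",
    "time_comparison",
]


# ---------------------------------------------------------------------------
# Alpha diversity
# ---------------------------------------------------------------------------


def alpha_diversity(table: CountTable, tree: TreeNode | None = None) -> pd.DataFrame:
    """Per-sample richness, Shannon diversity (natural log) and Faith's PD.

    Faith's PD is the total branch length of the minimal subtree connecting
    the present tips and the root; it requires ``tree`` and every taxon to be
    a tip.  Samples with no taxa get zeros across the board.
    """
    tip_names = None
    if tree is not None:
        tip_names = {t.name for t in tree.tips()}
        missing = [t for t in table.taxon_ids if t not in tip_names]
        if missing:
            raise RhizosignalError(f"taxa absent from tree: {missing[:5]}")
    rows = []
    counts = table.counts
    for j, sample in enumerate(table.sample_ids):
        col = counts[:, j]
        present = col > 0
        richness = int(present.sum())
        if richness == 0:
            rows.append((sample, 0, 0.0, 0.0))
            continue
        p = col[present] / col[present].sum()
        shannon = float(-(p * np.log(p)).sum())
        pd_value = 0.0
        if tree is not None:
            pd_value = float(
                faith_pd(col, taxa=list(table.taxon_ids), tree=tree, validate=False)
            )
        rows.append((sample, richness, shannon, pd_value))
    return pd.DataFrame(
        rows, columns=["sample_id", "richness", "shannon", "faith_pd"]
    ).set_index("sample_id")


# ---------------------------------------------------------------------------
# Unweighted UniFrac
# ---------------------------------------------------------------------------


def unweighted_unifrac(table: CountTable, tree: TreeNode) -> DistanceMatrix:
    """Presence/absence UniFrac: unshared over total spanned branch length."""
    sums = table.counts.sum(axis=0)
    if (sums == 0).any():
        j = int(np.argmax(sums == 0))
        raise RhizosignalError(f"sample {table.sample_ids[j]!r} has no taxa present")
    return beta_diversity(
        "unweighted_unifrac",
        table.counts.T,
        ids=list(table.sample_ids),
        taxa=list(table.taxon_ids),
        tree=tree,
        validate=True,
    )


# ---------------------------------------------------------------------------
# PCoA (keeps negative eigenvalues for the dispersion test)
# ---------------------------------------------------------------------------


@dataclass
class PcoaResult:
    sample_ids: list[str]
    eigenvalues: np.ndarray  # descending, may include negatives
    coordinates: np.ndarray  # n × n_axes, axes ordered by eigenvalue
    gower_trace: float

    def axes(self, k: int) -> pd.DataFrame:
        cols = [f"PCo{i + 1}" for i in range(k)]
        return pd.DataFrame(self.coordinates[:, :k], index=self.sample_ids, columns=cols)


def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d**2
    row = a.mean(axis=1, keepdims=True)
    col = a.mean(axis=0, keepdims=True)
    return a - row - col + a.mean()


def pcoa(d: DistanceMatrix | np.ndarray, sample_ids: list[str] | None = None) -> PcoaResult:
    """Classical (metric) multidimensional scaling via Gower centering.

    Coordinates for axes with negative eigenvalues are stored as
    ``sqrt(|λ|)``-scaled eigenvectors; callers needing only a real embedding
    should take the leading positive axes via :meth:`PcoaResult.axes`.
    """
    if isinstance(d, DistanceMatrix):
        sample_ids = list(d.ids)
        d = d.data
    d = np.asarray(d, dtype=float)
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T):
        raise RhizosignalError("distance matrix must be square and symmetric")
    n = d.shape[0]
    if n < 3:
        raise RhizosignalError("need at least 3 samples")
    if sample_ids is None:
        sample_ids = [str(i) for i in range(n)]
    G = _gower_center(d)
    eigval, eigvec = np.linalg.eigh(G)
    order = np.argsort(eigval)[::-1]
    eigval = eigval[order]
    eigvec = eigvec[:, order]
    coords = eigvec * np.sqrt(np.abs(eigval))[np.newaxis, :]
    return PcoaResult(sample_ids, eigval, coords, float(np.trace(G)))


# ---------------------------------------------------------------------------
# PERMANOVA with sequential sums of squares
# ---------------------------------------------------------------------------


@dataclass
class PermanovaResult:
    table: pd.DataFrame  # index: term names + Residual + Total
    n_perm: int

    def __str__(self) -> str:  # pragma: no cover - display helper
        return self.table.to_string()


def _parse_formula(formula: str | list) -> list[tuple[str, ...]]:
    if isinstance(formula, str):
        terms = [t.strip() for t in formula.split("+") if t.strip()]
    else:
        terms = list(formula)
    parsed = []
    for term in terms:
        if isinstance(term, str):
            parsed.append(tuple(f.strip() for f in term.split(":")))
        else:
            parsed.append(tuple(term))
    if not parsed:
        raise RhizosignalError("empty model formula")
    return parsed


def _term_columns(meta: pd.DataFrame, term: tuple[str, ...]) -> np.ndarray:
    blocks = []
    for factor in term:
        if factor not in meta.columns:
            raise RhizosignalError(f"unknown factor {factor!r} in formula")
        dummies = pd.get_dummies(meta[factor].astype(str)).to_numpy(dtype=float)
        blocks.append(dummies)
    cols = blocks[0]
    for block in blocks[1:]:
        cols = np.einsum("ij,ik->ijk", cols, block).reshape(cols.shape[0], -1)
    return cols


def _incremental_basis(
    meta: pd.DataFrame, terms: list[tuple[str, ...]]
) -> tuple[np.ndarray, list[int]]:
    """Orthonormal columns for the sequential model; returns the stacked
    basis and the number of new columns (df) contributed by each term."""
    n = len(meta)
    basis = [np.full((n, 1), 1.0 / np.sqrt(n))]
    dfs: list[int] = []
    for term in terms:
        X = _term_columns(meta, term)
        Q = np.hstack(basis)
        added = 0
        for k in range(X.shape[1]):
            v = X[:, k] - Q @ (Q.T @ X[:, k])
            norm = np.linalg.norm(v)
            if norm > 1e-8 * max(1.0, np.linalg.norm(X[:, k])):
                v = v / norm
                # re-orthogonalise for numerical hygiene
                v = v - Q @ (Q.T @ v)
                v = v / np.linalg.norm(v)
                basis.append(v[:, np.newaxis])
                Q = np.hstack(basis)
                added += 1
        dfs.append(added)
    if len(basis) == 1:
        return np.zeros((n, 0)), dfs
    return np.hstack(basis[1:]), dfs  # drop the intercept column


def permanova(
    d: DistanceMatrix,
    metadata: SampleMetadata | pd.DataFrame,
    formula: str | list = "treatment + timepoint + microhabitat",
    n_perm: int = 999,
    seed: int | None = None,
    exhaustive: bool = False,
) -> PermanovaResult:
    """Multi-factor PERMANOVA (pseudo-F on a distance matrix).

    Terms are fit sequentially (Type I) in formula order; interactions are
    written ``a:b``.  Sample labels are permuted freely; each term's p-value
    is ``(1 + #{F* ≥ F}) / (1 + n_perm)``.  With ``exhaustive=True`` every
    relabeling is enumerated (small n only) and the p-value is the exact
    fraction ``#{F* ≥ F} / n!`` (the identity counts itself).
    """
    if not exhaustive and n_perm < 1:
        raise RhizosignalError("n_perm must be >= 1")
    meta = metadata.table if isinstance(metadata, SampleMetadata) else metadata
    ids = list(d.ids)
    missing = [s for s in ids if s not in meta.index]
    if missing:
        raise RhizosignalError(f"samples missing from metadata: {missing[:5]}")
    meta = meta.loc[ids]
    terms = _parse_formula(formula)
    Q, dfs = _incremental_basis(meta, terms)
    n = len(ids)
    rank_full = sum(dfs)
    df_resid = n - 1 - rank_full
    if df_resid <= 0:
        raise RhizosignalError("model leaves no residual degrees of freedom")
    if any(df == 0 for df in dfs):
        bad = terms[dfs.index(0)]
        raise RhizosignalError(f"term {':'.join(bad)} adds no degrees of freedom")

    G = _gower_center(d.data)
    total_ss = float(np.trace(G))

    boundaries = np.cumsum(dfs)

    def term_stats(Gp: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        contrib = np.einsum("ni,nm,mi->i", Q, Gp, Q)
        cum = np.concatenate([[0.0], np.cumsum(contrib)])
        ss_terms = cum[boundaries] - cum[np.concatenate([[0], boundaries[:-1]])]
        ss_resid = np.trace(Gp) - cum[-1]
        F = (ss_terms / np.array(dfs)) / (ss_resid / df_resid)
        return ss_terms, F

    ss_terms, F_obs = term_stats(G)
    ss_resid = total_ss - ss_terms.sum()

    if exhaustive:
        from itertools import permutations as _all_perms
        from math import factorial

        if factorial(n) > 50_000:
            raise RhizosignalError("exhaustive enumeration limited to small n")
        exceed = np.zeros(len(terms))
        for p in _all_perms(range(n)):
            p = np.array(p)
            _, F_p = term_stats(G[np.ix_(p, p)])
            exceed += F_p >= F_obs - 1e-12
        p_values = exceed / factorial(n)
        n_perm = factorial(n)
    else:
        rng = np.random.default_rng(seed)
        exceed = np.zeros(len(terms))
        for _ in range(n_perm):
            p = rng.permutation(n)
            _, F_p = term_stats(G[np.ix_(p, p)])
            exceed += F_p >= F_obs
        p_values = (1.0 + exceed) / (1.0 + n_perm)

    rows = []
    for k, term in enumerate(terms):
        rows.append(
            {
                "term": ":".join(term),
                "df": dfs[k],
                "sum_sq": ss_terms[k],
                "r2": ss_terms[k] / total_ss,
                "pseudo_F": F_obs[k],
                "p_value": p_values[k],
            }
        )
    rows.append(
        {
            "term": "Residual",
            "df": df_resid,
            "sum_sq": ss_resid,
            "r2": ss_resid / total_ss,
            "pseudo_F": np.nan,
            "p_value": np.nan,
        }
    )
    rows.append(
        {
            "term": "Total",
            "df": n - 1,
            "sum_sq": total_ss,
            "r2": 1.0,
            "pseudo_F": np.nan,
            "p_value": np.nan,
        }
    )
    return PermanovaResult(pd.DataFrame(rows).set_index("term"), n_perm)


# ---------------------------------------------------------------------------
# Beta dispersion (PERMDISP-style)
# ---------------------------------------------------------------------------


@dataclass
class DispersionResult:
    distances: pd.Series  # per-sample distance to its group centroid
    group_means: pd.Series
    f_statistic: float
    p_value: float
    n_perm: int


def beta_dispersion(
    d: DistanceMatrix,
    groups: pd.Series | dict,
    n_perm: int = 999,
    seed: int | None = None,
) -> DispersionResult:
    """Homogeneity of multivariate dispersion via distances to group
    centroids in the full PCoA embedding (negative-eigenvalue axes enter
    with a negative sign, floored at zero), with a permutation test on the
    one-way F statistic.
    """
    groups = pd.Series(groups)
    ids = list(d.ids)
    groups = groups.loc[ids]
    levels = [lv for lv in groups.unique()]
    sizes = groups.value_counts()
    usable = [lv for lv in levels if sizes[lv] > 1]
    for lv in levels:
        if sizes[lv] == 1:
            warnings.warn(f"group {lv!r} has a single sample; excluded from F")
    if len(usable) < 2:
        raise RhizosignalError("need at least 2 groups with >= 2 samples")

    res = pcoa(d)
    pos = res.eigenvalues > 1e-8 * max(1.0, abs(res.eigenvalues[0]))
    neg = res.eigenvalues < -1e-8 * max(1.0, abs(res.eigenvalues[0]))
    Xp = res.coordinates[:, pos]
    Xn = res.coordinates[:, neg]

    dist = np.zeros(len(ids))
    for lv in levels:
        mask = (groups == lv).to_numpy()
        cp = Xp[mask].mean(axis=0)
        cn = Xn[mask].mean(axis=0) if Xn.shape[1] else np.zeros(0)
        d2 = ((Xp[mask] - cp) ** 2).sum(axis=1)
        if Xn.shape[1]:
            d2 = d2 - ((Xn[mask] - cn) ** 2).sum(axis=1)
        dist[mask] = np.sqrt(np.maximum(d2, 0.0))
    distances = pd.Series(dist, index=ids, name="centroid_distance")

    mask_usable = groups.isin(usable).to_numpy()
    z = dist[mask_usable]
    g = groups.to_numpy()[mask_usable]

    def f_stat(values: np.ndarray) -> float:
        grand = values.mean()
        ss_between = ss_within = 0.0
        df_b = len(usable) - 1
        df_w = len(values) - len(usable)
        for lv in usable:
            v = values[g == lv]
            ss_between += len(v) * (v.mean() - grand) ** 2
            ss_within += ((v - v.mean()) ** 2).sum()
        if ss_within == 0:
            raise RhizosignalError("all centroid distances identical; F undefined")
        return (ss_between / df_b) / (ss_within / df_w)

    F_obs = f_stat(z)
    rng = np.random.default_rng(seed)
    exceed = sum(f_stat(rng.permutation(z)) >= F_obs for _ in range(n_perm))
    p = (1.0 + exceed) / (1.0 + n_perm)
    means = pd.Series({lv: distances[groups == lv].mean() for lv in levels})
    return DispersionResult(distances, means, float(F_obs), float(p), n_perm)


# ---------------------------------------------------------------------------
# T1 vs T2 comparisons per clade
# ---------------------------------------------------------------------------


def time_comparison(
    table: CountTable,
    metadata: SampleMetadata,
    taxonomy: TaxonomyTable,
    rank: str = "phylum",
    paired: bool = False,
    min_prevalence: int = 1,
) -> pd.DataFrame:
    """Rank-based comparison of clade relative abundances between the
    pretreatment samples (T1) and the ambient samples at T2.

    The groups are unpaired in the study design (15 vs 5 replicates), so the
    default test is the two-sample rank-sum (Mann-Whitney); ``paired=True``
    exposes the signed-rank form for genuinely paired designs.  P-values are
    BH-adjusted across clades.
    """
    t1 = metadata.select(timepoint="T1")
    t2_ambient = metadata.select(timepoint="T2", treatment="ambient")
    if not t1 or not t2_ambient:
        raise RhizosignalError("both time groups must be non-empty")
    agg = aggregate_to_rank(table, taxonomy, rank=rank)
    rel = to_relative_abundance(agg)
    rows = []
    skipped = []
    for clade in agg.taxon_ids:
        a = rel.loc[clade, t1].to_numpy(dtype=float)
        b = rel.loc[clade, t2_ambient].to_numpy(dtype=float)
        if (a > 0).sum() + (b > 0).sum() < min_prevalence:
            skipped.append(clade)
            continue
        if paired:
            if len(a) != len(b):
                raise RhizosignalError("paired test requires equal group sizes")
            diff = a - b
            if np.all(diff == 0):
                stat, p = 0.0, 1.0
            else:
                stat, p = stats.wilcoxon(a, b)
        else:
            stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
        rows.append(
            {
                "clade": clade,
                "mean_T1": a.mean(),
                "mean_T2_ambient": b.mean(),
                "statistic": stat,
                "p_value": p,
            }
        )
    if skipped:
        warnings.warn(f"{len(skipped)} clades below detection threshold; skipped")
    df = pd.DataFrame(rows)
    if len(df):
        df["p_adjusted"] = multipletests(df["p_value"], method="fdr_bh")[1]
        df = df.set_index("clade")
    return df
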
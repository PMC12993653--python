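"""Root exudate ↔ community coupling.

Vector fitting of compound concentrations onto ordination axes (envfit-style
least squares with permutation significance and BH correction across
compounds), Mantel correlation between the community distance matrix and a
Euclidean distance on z-scored exudate profiles, exhaustive bioenv-style
subset search for the compound set maximising the Mantel correlation, and
Pearson correlations between clade abundances and individual compounds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from statsmodels.stats.multitest import multipletests

from .io import RhizosignalError

__all__ = [
    "envfit",
    "mantel",
    "MantelResult",
    "exudate_distance",
    "best_subset",
    "clade_exudate_correlation",
]


def envfit(
    ordination: pd.DataFrame,
    exudates: pd.DataFrame,
    n_perm: int = 999,
    seed: int | None = None,
) -> pd.DataFrame:
    """Least-squares fit of each compound onto the ordination axes.

    r² is the coefficient of determination of the centered compound
    regressed on the axis scores; the arrow is the unit-scaled coefficient
    vector.  Significance is by permuting the compound across samples;
    p-values are BH-adjusted across compounds.
    """
    if ordination.shape[1] < 2:
        raise RhizosignalError("need at least 2 ordination axes")
    common = [s for s in ordination.index if s in exudates.index]
    if len(common) < 3:
        raise RhizosignalError("fewer than 3 matched samples")
    X = ordination.loc[common].to_numpy(dtype=float)
    X = X - X.mean(axis=0)
    Q, _ = np.linalg.qr(X)
    rng = np.random.default_rng(seed)
    rows = []
    for compound in exudates.columns:
        y = exudates.loc[common, compound].to_numpy(dtype=float)
        if np.ptp(y) == 0:
            raise RhizosignalError(f"compound {compound!r} has zero variance")
        yc = y - y.mean()
        sst = yc @ yc

        def r2_of(v: np.ndarray) -> float:
            proj = Q.T @ (v - v.mean())
            return float(proj @ proj) / float((v - v.mean()) @ (v - v.mean()))

        r2 = float((Q.T @ yc) @ (Q.T @ yc)) / sst
        beta, *_ = np.linalg.lstsq(X, yc, rcond=None)
        norm = np.linalg.norm(beta)
        arrow = beta / norm if norm > 0 else beta
        exceed = sum(r2_of(rng.permutation(y)) >= r2 for _ in range(n_perm))
        p = (1.0 + exceed) / (1.0 + n_perm)
        rows.append(
            {
                "compound": compound,
                "r2": r2,
                "p_value": p,
                **{f"arrow_{ax}": a for ax, a in zip(ordination.columns, arrow)},
            }
        )
    df = pd.DataFrame(rows).set_index("compound")
    df["p_adjusted"] = multipletests(df["p_value"], method="fdr_bh")[1]
    return df


@dataclass
class MantelResult:
    r: float
    r_squared: float
    p_value: float
    n_perm: int
    n: int


def _upper(d: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(d.shape[0], k=1)
    return d[iu]


def mantel(
    d_community: DistanceMatrix | np.ndarray,
    d_exudate: DistanceMatrix | np.ndarray,
    n_perm: int = 999,
    seed: int | None = None,
    exhaustive: bool = False,
) -> MantelResult:
    """Mantel test: Pearson correlation of the two distance matrices' upper
    triangles, one-sided (observed ≥ null) significance by permuting one
    matrix's sample order.  Both r and r² are reported since squared Mantel
    statistics appear in the literature this pipeline mirrors.  With
    ``exhaustive=True`` all n! sample orders are enumerated and the p-value
    is the exact fraction (the identity counts itself).
    """
    ids = None
    if isinstance(d_community, DistanceMatrix):
        ids = list(d_community.ids)
        d_community = d_community.data
    if isinstance(d_exudate, DistanceMatrix):
        if ids is not None:
            d_exudate = d_exudate.filter(ids).data
        else:
            d_exudate = d_exudate.data
    x = np.asarray(d_community, dtype=float)
    y = np.asarray(d_exudate, dtype=float)
    if x.shape != y.shape or x.shape[0] < 4:
        raise RhizosignalError("matched distance matrices with n >= 4 required")
    xv = _upper(x)
    if np.ptp(xv) == 0 or np.ptp(_upper(y)) == 0:
        raise RhizosignalError("constant distance matrix")
    r_obs = float(np.corrcoef(xv, _upper(y))[0, 1])
    n = x.shape[0]
    if exhaustive:
        from itertools import permutations as _all_perms
        from math import factorial

        if factorial(n) > 50_000:
            raise RhizosignalError("exhaustive enumeration limited to small n")
        exceed = 0
        for p in _all_perms(range(n)):
            p = np.array(p)
            exceed += np.corrcoef(xv, _upper(y[np.ix_(p, p)]))[0, 1] >= r_obs - 1e-12
        return MantelResult(r_obs, r_obs**2, exceed / factorial(n), factorial(n), n)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        p = rng.permutation(n)
        r_null = np.corrcoef(xv, _upper(y[np.ix_(p, p)]))[0, 1]
        exceed += r_null >= r_obs
    p_value = (1.0 + exceed) / (1.0 + n_perm)
    return MantelResult(r_obs, r_obs**2, float(p_value), n_perm, n)


def exudate_distance(exudates: pd.DataFrame, columns: list[str] | None = None) -> np.ndarray:
    """Euclidean distance on z-scored concentrations (bioenv convention)."""
    sub = exudates if columns is None else exudates[list(columns)]
    z = (sub - sub.mean()) / sub.std(ddof=1)
    return squareform(pdist(z.to_numpy(dtype=float)))


def best_subset(
    d_community: DistanceMatrix,
    exudates: pd.DataFrame,
    max_subset_size: int = 5,
    n_perm: int = 999,
    seed: int | None = None,
    greedy: bool = False,
) -> pd.DataFrame:
    """bioenv-style search for the compound subset maximising Mantel r.

    Every non-empty subset up to ``max_subset_size`` is scored by the Mantel
    correlation between the community distances and the Euclidean distance
    on the z-scored subset; subsets are returned sorted by r, with a
    permutation p-value attached to the winner.  More than 15 compounds
    requires ``greedy`` forward selection (the exhaustive budget explodes).
    """
    ids = list(d_community.ids)
    missing = [s for s in ids if s not in exudates.index]
    if missing:
        raise RhizosignalError(f"samples missing from exudates: {missing[:5]}")
    ex = exudates.loc[ids]
    compounds = list(ex.columns)
    if len(compounds) > 15 and not greedy:
        raise RhizosignalError(
            "more than 15 compounds: pass greedy=True for forward selection"
        )
    dc = d_community.data
    xv = _upper(dc)

    def score(cols: tuple[str, ...]) -> float:
        dy = exudate_distance(ex, list(cols))
        return float(np.corrcoef(xv, _upper(dy))[0, 1])

    rows = []
    if greedy and len(compounds) > 15:
        chosen: list[str] = []
        while len(chosen) < max_subset_size:
            best = max(
                (c for c in compounds if c not in chosen),
                key=lambda c: score(tuple(chosen + [c])),
            )
            chosen.append(best)
            rows.append({"subset": tuple(chosen), "size": len(chosen), "mantel_r": score(tuple(chosen))})
    else:
        for size in range(1, min(max_subset_size, len(compounds)) + 1):
            for cols in combinations(compounds, size):
                rows.append({"subset": cols, "size": size, "mantel_r": score(cols)})
    df = pd.DataFrame(rows).sort_values("mantel_r", ascending=False).reset_index(drop=True)
    top = tuple(df.loc[0, "subset"])
    dy = exudate_distance(ex, list(top))
    top_p = mantel(dc, dy, n_perm=n_perm, seed=seed).p_value
    df["p_value"] = np.nan
    df.loc[0, "p_value"] = top_p
    return df


def clade_exudate_correlation(
    clade_abundances: pd.DataFrame,
    exudates: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pearson correlations between clade abundances and compounds.

    ``clade_abundances`` is samples × clades (e.g. relative abundances of
    the clades with significant clade-wide response ratios).  Each (clade,
    compound) pair gets r and a t-based p-value; BH correction runs across
    all pairs.  Zero-variance series are skipped with a note.
    """
    common = [s for s in clade_abundances.index if s in exudates.index]
    if len(common) < 4:
        raise RhizosignalError("need at least 4 matched observations")
    ca = clade_abundances.loc[common]
    ex = exudates.loc[common]
    rows = []
    for clade in ca.columns:
        a = ca[clade].to_numpy(dtype=float)
        if np.ptp(a) == 0:
            warnings.warn(f"clade {clade!r} has zero variance; skipped")
            continue
        for compound in ex.columns:
            b = ex[compound].to_numpy(dtype=float)
            if np.ptp(b) == 0:
                warnings.warn(f"compound {compound!r} has zero variance; skipped")
                continue
            r, p = stats.pearsonr(a, b)
            rows.append(
                {"clade": clade, "compound": compound, "r": float(r), "p_value": float(p)}
            )
    df = pd.DataFrame(rows)
    if len(df):
        df["p_adjusted"] = multipletests(df["p_value"], method="fdr_bh")[1]
        df["significant"] = df["p_adjusted"] < alpha
    return df
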
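"""Drought response ratios: the per-ZOTU trait at the heart of the pipeline.

For each taxon the response ratio contrasts its read counts under a drought
treatment against the ambient controls: per matched replicate pair,
``r = (t - a) / (t + a)``, a bounded statistic in [-1, 1] that is +1 when
the taxon appears only under drought and -1 when it appears only under
ambient conditions.  A per-taxon permutation null (group labels shuffled,
pairs re-formed) yields an empirical two-sided p-value; clade-wide one-sample
t-tests with Benjamini-Hochberg correction then flag clades whose members
shift coherently, and the per-taxon / per-clade positive-negative-neutral
calls feed the iTOL colour-strip export.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import CountTable, RhizosignalError, SampleMetadata, TaxonomyTable

__all__ = [
    "response_ratio",
    "ResponseRatioResult",
    "response_ratio_null",
    "clade_response_test",
    "call_directions",
]


def _pair_ratios(t: np.ndarray, a: np.ndarray) -> np.ndarray:
    """Per-pair (t-a)/(t+a); 0 where both counts are 0. Works on stacked
    2-D inputs (taxa × replicates) as well as single vectors."""
    t = np.asarray(t, dtype=float)
    a = np.asarray(a, dtype=float)
    total = t + a
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(total > 0, (t - a) / np.where(total > 0, total, 1.0), 0.0)
    return r


def response_ratio(
    treat_counts, amb_counts, pairing: str = "index"
) -> tuple[np.ndarray, float]:
    """Response ratios for one taxon from replicate count vectors.

    ``pairing="index"`` matches replicates positionally and requires equal
    group sizes; ``pairing="mean"`` collapses each group to its summed counts
    and returns a single ratio.  Returns ``(per_pair_ratios, mean_ratio)``.
    """
    t = np.asarray(treat_counts, dtype=float)
    a = np.asarray(amb_counts, dtype=float)
    if pairing == "mean":
        r = _pair_ratios(np.array([t.sum()]), np.array([a.sum()]))
        return r, float(r[0])
    if pairing != "index":
        raise RhizosignalError(f"unknown pairing {pairing!r}")
    if t.shape != a.shape:
        raise RhizosignalError(
            "unequal replicate numbers; use pairing='mean' for unbalanced groups"
        )
    r = _pair_ratios(t, a)
    return r, float(r.mean())


@dataclass
class ResponseRatioResult:
    """Per-taxon observed mean RR, replicate ratios, and permutation null."""

    table: pd.DataFrame  # index taxon; columns observed_rr, null_mean, null_sd, p_value
    pair_ratios: pd.DataFrame  # taxa × pairs
    contrast: tuple[str, str]
    n_perm: int

    @property
    def observed(self) -> pd.Series:
        return self.table["observed_rr"]


def response_ratio_null(
    table: CountTable,
    metadata: SampleMetadata,
    contrast: tuple[str, str] = ("severe", "ambient"),
    n_perm: int = 999,
    seed: int | None = None,
    timepoint: str = "T2",
    microhabitat: str = "rhizosphere",
    pairing: str = "index",
    exhaustive: bool = False,
) -> ResponseRatioResult:
    """Observed mean RR per taxon plus an empirical permutation null.

    Samples are restricted to one timepoint × microhabitat (post-drought
    rhizosphere by default); replicates are paired by sorted sample id.  For
    each of ``n_perm`` permutations the pooled sample labels are shuffled,
    pairs re-formed, and the mean RR recomputed; the two-sided p-value is
    ``(1 + #{|null| >= |obs|}) / (1 + n_perm)``.
    """
    drought, ambient = contrast
    g1 = sorted(
        metadata.select(treatment=drought, timepoint=timepoint, microhabitat=microhabitat)
    )
    g0 = sorted(
        metadata.select(treatment=ambient, timepoint=timepoint, microhabitat=microhabitat)
    )
    g1 = [s for s in g1 if s in table.sample_ids]
    g0 = [s for s in g0 if s in table.sample_ids]
    if len(g1) < 2 or len(g0) < 2:
        raise RhizosignalError("need at least 2 samples per contrast group")
    if pairing == "index" and len(g1) != len(g0):
        raise RhizosignalError(
            "unequal group sizes; use pairing='mean' for unbalanced contrasts"
        )
    sub = table.select_samples(g1 + g0)
    X = sub.counts.astype(float)
    n1 = len(g1)

    def mean_rr(cols: np.ndarray) -> np.ndarray:
        t, a = cols[:, :n1], cols[:, n1:]
        if pairing == "mean":
            return _pair_ratios(t.sum(axis=1), a.sum(axis=1))
        return _pair_ratios(t, a).mean(axis=1)

    obs = mean_rr(X)
    pair_df = pd.DataFrame(
        _pair_ratios(X[:, :n1], X[:, n1:]) if pairing == "index" else obs[:, None],
        index=list(table.taxon_ids),
    )
    total_counts = X.sum(axis=1)

    n = X.shape[1]
    if exhaustive:
        from itertools import permutations as _all_perms
        from math import factorial

        if factorial(n) > 50_000:
            raise RhizosignalError("exhaustive enumeration limited to small n")
        null = np.stack(
            [mean_rr(X[:, np.array(p)]) for p in _all_perms(range(n))], axis=1
        )
        exceed = (np.abs(null) >= np.abs(obs)[:, np.newaxis] - 1e-12).sum(axis=1)
        p = exceed / factorial(n)  # identity relabeling counts itself
        n_perm = factorial(n)
    else:
        rng = np.random.default_rng(seed)
        null = np.empty((len(table.taxon_ids), n_perm))
        for b in range(n_perm):
            null[:, b] = mean_rr(X[:, rng.permutation(n)])
        exceed = (np.abs(null) >= np.abs(obs)[:, np.newaxis]).sum(axis=1)
        p = (1.0 + exceed) / (1.0 + n_perm)
    out = pd.DataFrame(
        {
            "observed_rr": obs,
            "null_mean": null.mean(axis=1),
            "null_sd": null.std(axis=1, ddof=1),
            "p_value": p,
            "contrast_total": total_counts,
        },
        index=list(table.taxon_ids),
    )
    return ResponseRatioResult(out, pair_df, (drought, ambient), n_perm)


def clade_response_test(
    rr: ResponseRatioResult | pd.Series,
    taxonomy: TaxonomyTable,
    rank: str = "phylum",
    alpha: float = 0.05,
    min_clade_size: int = 5,
) -> pd.DataFrame:
    """One-sample t-tests of member response ratios against zero, per clade.

    Clades at ``rank`` with at least ``min_clade_size`` members and nonzero
    RR variance are tested two-sided; p-values are BH-adjusted across clades
    and a direction (positive / negative / none) is assigned from the sign
    of the mean RR where the adjusted p clears ``alpha``.

    Members never observed in any contrast sample carry no information about
    the response (their ratios are 0 by convention) and are excluded before
    testing when the full :class:`ResponseRatioResult` is supplied.
    """
    if isinstance(rr, ResponseRatioResult):
        observed = rr.table
        values = observed.loc[observed["contrast_total"] > 0, "observed_rr"]
    else:
        values = rr
    labels = taxonomy.rank_labels(rank)
    rows = []
    for clade, members in values.groupby(labels.reindex(values.index)):
        if len(members) < min_clade_size:
            continue
        if members.std(ddof=1) == 0:
            continue
        t, p = stats.ttest_1samp(members.to_numpy(), 0.0)
        rows.append(
            {
                "clade": clade,
                "n_members": len(members),
                "mean_rr": members.mean(),
                "t_statistic": float(t),
                "p_value": float(p),
            }
        )
    if not rows:
        warnings.warn("no clade reached the minimum size; empty test table")
        return pd.DataFrame(
            columns=["n_members", "mean_rr", "t_statistic", "p_value", "p_adjusted", "direction"]
        )
    df = pd.DataFrame(rows).set_index("clade")
    df["p_adjusted"] = multipletests(df["p_value"], method="fdr_bh")[1]
    df["direction"] = np.where(
        df["p_adjusted"] < alpha,
        np.where(df["mean_rr"] > 0, "positive", "negative"),
        "none",
    )
    return df


def call_directions(
    rr: ResponseRatioResult,
    clade_table: pd.DataFrame | None = None,
    alpha: float = 0.05,
    significance_filter: bool = True,
) -> tuple[pd.Series, pd.Series]:
    """Positive / negative / neutral calls for iTOL colouring.

    Per taxon: the sign of the observed RR, downgraded to neutral when the
    ratio is exactly zero or (with ``significance_filter``) its permutation
    p-value fails ``alpha``.  Per clade: taken from the clade test table's
    direction column (``none`` mapped to ``neutral``).
    """
    obs = rr.table["observed_rr"]
    p = rr.table["p_value"]
    cat = np.where(obs > 0, "positive", np.where(obs < 0, "negative", "neutral"))
    if significance_filter:
        cat = np.where(p < alpha, cat, "neutral")
    taxon_calls = pd.Series(cat, index=obs.index, name="direction")
    clade_calls = pd.Series(dtype=object, name="direction")
    if clade_table is not None and len(clade_table):
        clade_calls = clade_table["direction"].replace({"none": "neutral"})
    return taxon_calls, clade_calls
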
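"""Synthetic drought-study generator with known ground truth.

Emulates the greenhouse design that motivates the pipeline: three drought
treatments (ambient, mild, severe — entering as a scalar dose s ∈ {0, 0.5,
1}), two microhabitats (bulk, rhizosphere), a pretreatment timepoint T1
(15 replicates per microhabitat) and a post-treatment timepoint T2 (5
replicates per treatment × microhabitat), i.e. 60 samples per marker
community.  Per-taxon drought effects are drawn on a simulated ultrametric
phylogeny with tunable Pagel-λ structure, optionally shifted in planted
responder clades; counts follow a Dirichlet-multinomial around
compositional expectations; exudate vectors are partially coupled to the
community via per-compound slopes.  Every run records a
:class:`SyntheticTruth` so downstream tests can score recovery.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode

from .io import (
    RANKS,
    TREATMENT_SCORE,
    UNASSIGNED,
    CountTable,
    RhizosignalError,
    SampleMetadata,
)
from .phylosignal import bm_covariance, lambda_transform

__all__ = [
    "SyntheticTruth",
    "simulate_tree",
    "simulate_taxonomy",
    "simulate_effect_trait",
    "simulate_counts",
    "simulate_exudates",
    "simulate_lognormal_counts",
    "make_design",
    "pick_clade",
    "simulate_study",
]


# ---------------------------------------------------------------------------
# Tree
# ---------------------------------------------------------------------------


def simulate_tree(n_tips: int, seed: int | None = None) -> TreeNode:
    """Ultrametric pure-birth (Yule) tree scaled to root-to-tip height 1.

    Lineages split at unit rate; after the ``n_tips``-th lineage appears the
    clock runs one further exponential waiting time so terminal branches are
    never zero.  Tips are named ``t0001`` …; deterministic given ``seed``.
    """
    if n_tips < 3:
        raise RhizosignalError("need n_tips >= 3")
    rng = np.random.default_rng(seed)
    root = TreeNode()
    first, second = TreeNode(), TreeNode()
    root.extend([first, second])
    birth = {id(root): 0.0, id(first): 0.0, id(second): 0.0}
    active = [first, second]  # the root splits at time 0
    t = 0.0
    while len(active) < n_tips:
        k = len(active)
        t += rng.exponential(1.0 / k)
        node = active.pop(rng.integers(k))
        left, right = TreeNode(), TreeNode()
        birth[id(left)] = birth[id(right)] = t
        node.extend([left, right])
        active.extend([left, right])
    t += rng.exponential(1.0 / n_tips)
    total = t
    # branch length = lifespan; internal nodes end at their split time
    for node in root.traverse(include_self=False):
        end = birth[id(node.children[0])] if node.children else total
        node.length = (end - birth[id(node)]) / total
    root.length = None
    width = max(4, len(str(n_tips)))
    for i, tip in enumerate(root.tips(), start=1):
        tip.name = f"t{i:0{width}d}"
    return root


def pick_clade(
    tree: TreeNode, min_size: int, max_size: int, seed: int | None = None
) -> list[str]:
    """Pick a random monophyletic tip set with size in [min_size, max_size]."""
    rng = np.random.default_rng(seed)
    candidates = []
    for node in tree.non_tips(include_self=False):
        tips = [t.name for t in node.tips()]
        if min_size <= len(tips) <= max_size:
            candidates.append(tips)
    if not candidates:
        raise RhizosignalError(
            f"no clade with between {min_size} and {max_size} tips"
        )
    return candidates[rng.integers(len(candidates))]


# ---------------------------------------------------------------------------
# Taxonomy from tree cuts
# ---------------------------------------------------------------------------

_RANK_PREFIX = {"phylum": "p", "class": "c", "order": "o", "family": "f", "genus": "g"}


def simulate_taxonomy(
    tree: TreeNode, cut_depths: tuple[float, ...] = (0.2, 0.5, 0.65, 0.8, 0.9)
) -> "TaxonomyTable":
    """Monophyletic ranked taxonomy by cutting the tree at fixed depths.

    Each cut depth partitions the tips into the subtrees hanging below the
    edges that cross that depth; the shallowest cut labels phyla, successive
    cuts the finer ranks.  Cuts must be strictly increasing and inside
    (0, 1); fewer than five cuts leave the deepest ranks unassigned.
    """
    from .io import TaxonomyTable  # local import to avoid cycle at module load

    cuts = tuple(float(d) for d in cut_depths)
    if any(not (0 < d < 1) for d in cuts):
        raise RhizosignalError("cut depths must lie strictly inside (0, 1)")
    if any(b <= a for a, b in zip(cuts, cuts[1:])):
        raise RhizosignalError("cut depths must be strictly increasing")
    if len(cuts) > 5:
        raise RhizosignalError("at most 5 cut depths (phylum..genus)")

    depth = {id(tree): 0.0}
    for node in tree.preorder(include_self=False):
        depth[id(node)] = depth[id(node.parent)] + (node.length or 0.0)

    tip_names = [t.name for t in tree.tips()]
    data = {taxon: [UNASSIGNED] * len(RANKS) for taxon in tip_names}
    for taxon in tip_names:
        data[taxon][0] = "synthetic"

    cut_ranks = RANKS[1 : 1 + len(cuts)]
    for d, rank in zip(cuts, cut_ranks):
        prefix = _RANK_PREFIX[rank]
        group_no = 0
        for node in tree.preorder(include_self=False):
            parent_depth = depth[id(node.parent)]
            if parent_depth < d <= depth[id(node)]:
                group_no += 1
                label = f"{prefix}{group_no:03d}"
                members = [node.name] if node.is_tip() else [t.name for t in node.tips()]
                for taxon in members:
                    data[taxon][RANKS.index(rank)] = label
    df = pd.DataFrame.from_dict(data, orient="index", columns=list(RANKS))
    return TaxonomyTable(df.loc[tip_names])


# ---------------------------------------------------------------------------
# Phylogenetically structured drought effect
# ---------------------------------------------------------------------------


def simulate_effect_trait(
    tree: TreeNode,
    lambda_true: float,
    effect_sd: float,
    responder_clades: list[tuple[list[str], float]] | None = None,
    seed: int | None = None,
    V: pd.DataFrame | None = None,
) -> pd.Series:
    """Per-tip log2-fold-change drought effect with Pagel-λ covariance.

    Drawn from N(0, σ²·V(λ)) where V(λ) keeps the BM diagonal and scales
    off-diagonals by ``lambda_true``; each ``(tips, delta)`` responder clade
    then receives an additive mean shift δ.
    """
    if not 0 <= lambda_true <= 1:
        raise RhizosignalError("lambda_true must lie in [0, 1]")
    if effect_sd < 0:
        raise RhizosignalError("effect_sd must be nonnegative")
    rng = np.random.default_rng(seed)
    if V is None:
        V = bm_covariance(tree)
    names = list(V.index)
    C = effect_sd**2 * lambda_transform(V.to_numpy(), lambda_true)
    if effect_sd == 0:
        e = np.zeros(len(names))
    else:
        L = np.linalg.cholesky(C + 1e-12 * np.eye(len(names)))
        e = L @ rng.standard_normal(len(names))
    trait = pd.Series(e, index=names, name="effect")
    for tips, delta in responder_clades or []:
        trait.loc[list(tips)] += delta
    return trait


# ---------------------------------------------------------------------------
# Counts
# ---------------------------------------------------------------------------


def expected_proportions(
    effect: pd.Series, baseline: pd.Series, dose: float
) -> pd.Series:
    """Per-taxon expected proportion at a drought dose: ∝ b·2^(e·dose)."""
    w = baseline * np.power(2.0, effect * dose)
    return w / w.sum()


def simulate_counts(
    effect: pd.Series,
    design: SampleMetadata,
    depth_mean: int = 10_000,
    theta: float = 0.01,
    baseline_sd: float = 1.0,
    depth_sd: float = 0.15,
    seed: int | None = None,
    baseline: pd.Series | None = None,
) -> CountTable:
    """Treatment-structured Dirichlet-multinomial counts.

    Taxon baselines are log-normal; each sample's expected proportions scale
    the baseline by ``2^(e_i · s)`` where s is the drought dose of its
    treatment (0 at the pretreatment timepoint T1).  Counts are multinomial
    when ``theta == 0`` and Dirichlet-multinomial with concentration
    ``p/theta`` otherwise; sequencing depth is log-normal around
    ``depth_mean``.
    """
    if theta < 0:
        raise RhizosignalError("theta must be nonnegative")
    rng = np.random.default_rng(seed)
    taxa = list(effect.index)
    if baseline is None:
        baseline = pd.Series(
            np.exp(rng.normal(0.0, baseline_sd, len(taxa))), index=taxa
        )
    counts = np.zeros((len(taxa), len(design.sample_ids)), dtype=np.int64)
    meta = design.table
    for j, sample in enumerate(design.sample_ids):
        treatment = meta.loc[sample, "treatment"]
        dose = TREATMENT_SCORE[treatment] if meta.loc[sample, "timepoint"] == "T2" else 0.0
        p = expected_proportions(effect, baseline, dose).to_numpy()
        depth = max(1, int(round(rng.lognormal(np.log(depth_mean), depth_sd))))
        if theta == 0:
            counts[:, j] = rng.multinomial(depth, p)
        else:
            frac = rng.dirichlet(p / theta)
            counts[:, j] = rng.multinomial(depth, frac)
    return CountTable(taxa, list(design.sample_ids), counts)


def simulate_lognormal_counts(
    n_taxa: int,
    n_samples: int,
    planted_pairs: list[tuple[int, int, float]] | None = None,
    latent_taxa: list[int] | None = None,
    latent_loading: float = 0.0,
    log_sd: float = 1.0,
    mean_log_sd: float = 0.0,
    depth: int = 50_000,
    seed: int | None = None,
    return_basis: bool = False,
):
    """Compositional counts from log-normal basis abundances.

    The basis log-abundances are iid N(0, ``log_sd``²) except for
    ``planted_pairs`` (i, j, ρ) which receive pairwise correlation ρ, and an
    optional shared latent factor loading onto ``latent_taxa`` — the
    generators used to exercise compositional association estimators.
    ``mean_log_sd > 0`` adds per-taxon mean-abundance heterogeneity (rare
    taxa make the log-ratio variances noisier).
    """
    rng = np.random.default_rng(seed)
    cov = np.eye(n_taxa) * log_sd**2
    for i, j, rho in planted_pairs or []:
        cov[i, j] = cov[j, i] = rho * log_sd**2
    L = np.linalg.cholesky(cov + 1e-12 * np.eye(n_taxa))
    Y = (L @ rng.standard_normal((n_taxa, n_samples)))
    if latent_taxa and latent_loading:
        f = rng.standard_normal(n_samples)
        Y[np.asarray(latent_taxa)] += latent_loading * f[np.newaxis, :]
    mu = rng.normal(0.0, mean_log_sd, n_taxa) if mean_log_sd else np.zeros(n_taxa)
    W = np.exp(Y + mu[:, np.newaxis])
    P = W / W.sum(axis=0, keepdims=True)
    counts = np.stack(
        [rng.multinomial(depth, P[:, j]) for j in range(n_samples)], axis=1
    )
    taxa = [f"x{i:04d}" for i in range(n_taxa)]
    samples = [f"s{j:03d}" for j in range(n_samples)]
    table = CountTable(taxa, samples, counts)
    if return_basis:
        basis = pd.DataFrame(Y + mu[:, np.newaxis], index=taxa, columns=samples)
        return table, basis
    return table


# ---------------------------------------------------------------------------
# Design & exudates
# ---------------------------------------------------------------------------


def make_design(n_t2_reps: int = 5, n_t1_reps: int = 15) -> SampleMetadata:
    """The study layout: 15 pretreatment samples (T1) per microhabitat —
    plants already carry their assigned treatment-group label but have not
    been droughted — and 5 post-treatment replicates (T2) per treatment ×
    microhabitat; 60 samples at the defaults."""
    if n_t1_reps % 3:
        raise RhizosignalError("n_t1_reps must split evenly across 3 treatment groups")
    rows = []
    for treatment in ("ambient", "mild", "severe"):
        for hab in ("bulk", "rhizosphere"):
            for r in range(1, n_t1_reps // 3 + 1):
                rows.append((f"T1_{treatment}_{hab}_r{r:02d}", treatment, "T1", hab, r))
    for treatment in ("ambient", "mild", "severe"):
        for hab in ("bulk", "rhizosphere"):
            for r in range(1, n_t2_reps + 1):
                rows.append(
                    (f"T2_{treatment}_{hab}_r{r:02d}", treatment, "T2", hab, r)
                )
    df = pd.DataFrame(
        rows, columns=["sample_id", "treatment", "timepoint", "microhabitat", "replicate"]
    ).set_index("sample_id")
    return SampleMetadata(df)


def simulate_exudates(
    community_scores: pd.Series | pd.DataFrame,
    coupling: dict[str, float | tuple[float, ...]],
    noise_sd: float = 1.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Exudate concentrations: slope·score + noise per compound, shifted to
    be nonnegative.  Compounds with slope 0 are pure noise.

    ``community_scores`` may be a single score vector or a samples × axes
    frame (e.g. leading ordination axes); a per-compound coupling may then be
    a tuple of slopes, one per axis, so different compounds can track
    different community gradients.
    """
    if noise_sd <= 0:
        raise RhizosignalError("noise_sd must be positive")
    rng = np.random.default_rng(seed)
    scores = pd.DataFrame(community_scores)
    S = scores.to_numpy(dtype=float)
    n = S.shape[0]
    data = {}
    for compound, slope in coupling.items():
        slopes = np.atleast_1d(np.asarray(slope, dtype=float))
        if len(slopes) > S.shape[1]:
            raise RhizosignalError(
                f"compound {compound!r}: {len(slopes)} slopes for {S.shape[1]} score axes"
            )
        x = S[:, : len(slopes)] @ slopes + rng.normal(0.0, noise_sd, n)
        data[compound] = x - x.min()
    return pd.DataFrame(data, index=list(scores.index))


# Ten compounds echoing the drought-associated exudates measured in the
# motivating greenhouse system; the first two are coupled by default.
DEFAULT_COMPOUNDS = (
    "sucrose",
    "D-arabinose",
    "pyruvic_acid",
    "D-mannose",
    "sedoheptulose_anhydride",
    "tagatose",
    "D-glucose",
    "L-threonine",
    "4-guanidinobutyric_acid",
    "myoinositol",
)


# ---------------------------------------------------------------------------
# Full study + truth record
# ---------------------------------------------------------------------------


@dataclass
class SyntheticTruth:
    seed: int
    n_tips: int
    lambda_true: float
    effect_sd: float
    responder_clades: list[tuple[list[str], float]]
    depth_mean: int
    theta: float
    n_t2_reps: int
    n_t1_reps: int
    exudate_coupling: dict[str, float] = field(default_factory=dict)
    exudate_noise_sd: float = 1.0

    def to_json(self, path: str | Path) -> None:
        payload = {
            **{k: v for k, v in self.__dict__.items() if k != "responder_clades"},
            "responder_clades": [
                {"tips": list(tips), "delta": delta}
                for tips, delta in self.responder_clades
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        payload = json.loads(Path(path).read_text())
        clades = [(c["tips"], c["delta"]) for c in payload.pop("responder_clades")]
        return cls(responder_clades=clades, **payload)


def simulate_study(
    n_tips: int = 200,
    lambda_true: float = 0.9,
    effect_sd: float = 1.0,
    responder_deltas: tuple[float, ...] = (),
    responder_size: tuple[int, int] = (8, 25),
    depth_mean: int = 10_000,
    theta: float = 0.01,
    baseline_sd: float = 2.0,
    n_t2_reps: int = 5,
    n_t1_reps: int = 15,
    coupled_compounds: tuple[str, ...] = ("myoinositol", "D-arabinose"),
    coupling_slope: float = 1.5,
    exudate_noise_sd: float = 0.7,
    seed: int = 0,
) -> dict:
    """One marker-gene community end to end.

    Returns a dict with the tree, taxonomy, effect trait, counts, metadata,
    exudates (over T2 rhizosphere samples) and the :class:`SyntheticTruth`.
    Exudates are coupled to the community itself: the post-drought
    rhizosphere samples are ordinated (PCoA of unweighted UniFrac) and each
    coupled compound tracks one standardised leading axis — complementary
    gradients, so only the full coupled set reconstructs the community
    structure.
    """
    rng = np.random.default_rng(seed)
    sub = lambda: int(rng.integers(2**31 - 1))  # noqa: E731
    tree = simulate_tree(n_tips, seed=sub())
    taxonomy = simulate_taxonomy(tree)
    V = bm_covariance(tree)
    clades: list[tuple[list[str], float]] = []
    used: set[str] = set()
    for delta in responder_deltas:
        for _ in range(50):
            tips = pick_clade(tree, *responder_size, seed=sub())
            if not used & set(tips):
                break
        used |= set(tips)
        clades.append((tips, delta))
    effect = simulate_effect_trait(
        tree, lambda_true, effect_sd, responder_clades=clades, seed=sub(), V=V
    )
    design = make_design(n_t2_reps=n_t2_reps, n_t1_reps=n_t1_reps)
    counts = simulate_counts(
        effect, design, depth_mean=depth_mean, theta=theta,
        baseline_sd=baseline_sd, seed=sub(),
    )
    t2_rhizo = design.select(timepoint="T2", microhabitat="rhizosphere")
    from .diversity import pcoa, unweighted_unifrac  # deferred: avoids hard cycle

    dm = unweighted_unifrac(counts.select_samples(t2_rhizo), tree)
    axes = pcoa(dm).axes(2)  # raw eigen-scaled coordinates
    # two rotated mixtures of the top-2 ordination plane: each coupled
    # compound sees an equally informative but distinct community gradient,
    # so only the pair spans the plane
    mixes = pd.DataFrame(
        {
            "mix1": axes["PCo1"] + axes["PCo2"],
            "mix2": axes["PCo1"] - axes["PCo2"],
        },
        index=axes.index,
    )
    scores = (mixes - mixes.mean()) / mixes.std(ddof=0)
    coupling: dict[str, tuple[float, ...]] = {}
    for i, c in enumerate(DEFAULT_COMPOUNDS):
        if c in coupled_compounds:
            slopes = [0.0, 0.0]
            slopes[coupled_compounds.index(c) % 2] = coupling_slope
            coupling[c] = tuple(slopes)
        else:
            coupling[c] = (0.0, 0.0)
    exudates = simulate_exudates(scores, coupling, noise_sd=exudate_noise_sd, seed=sub())
    truth = SyntheticTruth(
        seed=seed,
        n_tips=n_tips,
        lambda_true=lambda_true,
        effect_sd=effect_sd,
        responder_clades=clades,
        depth_mean=depth_mean,
        theta=theta,
        n_t2_reps=n_t2_reps,
        n_t1_reps=n_t1_reps,
        exudate_coupling=coupling,
        exudate_noise_sd=exudate_noise_sd,
    )
    return {
        "tree": tree,
        "taxonomy": taxonomy,
        "effect": effect,
        "counts": counts,
        "metadata": design,
        "exudates": exudates,
        "truth": truth,
    }
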
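"""Data model and file plumbing shared by all pipeline stages.

The pipeline operates on four tabular inputs — a ZOTU-by-sample count table,
a ranked taxonomy, per-sample metadata describing the drought study design,
and an exudate concentration matrix — plus a rooted phylogeny whose tips are
the ZOTU identifiers.  Everything is plain TSV / Newick on disk; in memory
counts live in a validated :class:`CountTable` and trees are scikit-bio
``TreeNode`` objects.

Also here: the taxonomy-based read removal (e.g. chloroplast / non-fungal
eukaryote lineages), seeded rarefaction to even depth, conversion to relative
abundances, rank-level aggregation, and export of iTOL colour-strip
annotation files used to paint per-taxon drought response calls onto trees.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from skbio import TreeNode

TREATMENTS = ("ambient", "mild", "severe")
TIMEPOINTS = ("T1", "T2")
MICROHABITATS = ("bulk", "rhizosphere")
#: drought dose score used by the generator and the response contrasts
TREATMENT_SCORE = {"ambient": 0.0, "mild": 0.5, "severe": 1.0}

RANKS = ("domain", "phylum", "class", "order", "family", "genus")
UNASSIGNED = "unassigned"


class RhizosignalError(ValueError):
    """Raised for malformed inputs or violated data invariants."""


# ---------------------------------------------------------------------------
# CountTable
# ---------------------------------------------------------------------------


@dataclass
class CountTable:
    """Nonnegative integer taxa × samples matrix with aligned identifiers.

    ``counts[i, j]`` is the read count of ``taxon_ids[i]`` in
    ``sample_ids[j]``.  Identifiers are unique and order is preserved by all
    round trips.
    """

    taxon_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.taxon_ids = [str(t) for t in self.taxon_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if len(set(self.taxon_ids)) != len(self.taxon_ids):
            raise RhizosignalError("duplicate taxon ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise RhizosignalError("duplicate sample ids")
        counts = np.asarray(self.counts)
        if counts.shape != (len(self.taxon_ids), len(self.sample_ids)):
            raise RhizosignalError(
                f"counts shape {counts.shape} inconsistent with "
                f"{len(self.taxon_ids)} taxa × {len(self.sample_ids)} samples"
            )
        if counts.size and not np.issubdtype(counts.dtype, np.integer):
            if not np.allclose(counts, np.round(counts)):
                raise RhizosignalError("counts must be integers")
            counts = np.round(counts).astype(np.int64)
        else:
            counts = counts.astype(np.int64)
        if counts.size and counts.min() < 0:
            i, j = np.argwhere(counts < 0)[0]
            raise RhizosignalError(
                f"negative count for taxon {self.taxon_ids[i]!r} in "
                f"sample {self.sample_ids[j]!r}"
            )
        self.counts = counts

    # -- constructors / views ----------------------------------------------

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "CountTable":
        return cls(list(df.index), list(df.columns), df.to_numpy())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts.copy(), index=list(self.taxon_ids), columns=list(self.sample_ids)
        )

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def sample_sums(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def select_samples(self, sample_ids: Iterable[str]) -> "CountTable":
        wanted = list(sample_ids)
        idx = {s: j for j, s in enumerate(self.sample_ids)}
        missing = [s for s in wanted if s not in idx]
        if missing:
            raise RhizosignalError(f"unknown sample ids: {missing}")
        cols = [idx[s] for s in wanted]
        return CountTable(list(self.taxon_ids), wanted, self.counts[:, cols])

    def select_taxa(self, taxon_ids: Iterable[str]) -> "CountTable":
        wanted = list(taxon_ids)
        idx = {t: i for i, t in enumerate(self.taxon_ids)}
        missing = [t for t in wanted if t not in idx]
        if missing:
            raise RhizosignalError(f"unknown taxon ids: {missing}")
        rows = [idx[t] for t in wanted]
        return CountTable(wanted, list(self.sample_ids), self.counts[rows, :])


def read_count_table(path: str | Path) -> CountTable:
    """Read a TSV count table (first column taxon ids, header sample ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.shape[0] == 0:
        raise RhizosignalError(f"{path}: no taxa")
    try:
        values = df.astype(float).to_numpy()
    except ValueError as exc:
        raise RhizosignalError(f"{path}: non-numeric count cell ({exc})") from exc
    if not np.allclose(values, np.round(values)):
        bad = np.argwhere(~np.isclose(values, np.round(values)))[0]
        raise RhizosignalError(
            f"{path}: non-integer count at row {df.index[bad[0]]!r}, "
            f"column {df.columns[bad[1]]!r}"
        )
    return CountTable(list(df.index), list(df.columns), values)


def write_count_table(table: CountTable, path: str | Path) -> None:
    df = table.to_dataframe()
    df.index.name = "taxon_id"
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Taxonomy
# ---------------------------------------------------------------------------


@dataclass
class TaxonomyTable:
    """taxon_id → fixed-length ranked lineage (domain … genus).

    Unassigned ranks carry the literal marker ``"unassigned"``; once a rank is
    unassigned every deeper rank must be unassigned too (prefix property).
    """

    lineages: pd.DataFrame  # index taxon_id, columns RANKS

    def __post_init__(self) -> None:
        df = self.lineages
        if list(df.columns) != list(RANKS):
            raise RhizosignalError(f"taxonomy columns must be {RANKS}, got {list(df.columns)}")
        if df.index.duplicated().any():
            raise RhizosignalError("duplicate taxon ids in taxonomy")
        arr = df.to_numpy(dtype=str)
        unassigned = arr == UNASSIGNED
        # prefix property: no assigned rank after an unassigned one
        bad = unassigned[:, :-1] & ~unassigned[:, 1:]
        if bad.any():
            i = np.argwhere(bad)[0][0]
            raise RhizosignalError(
                f"taxon {df.index[i]!r}: assigned rank follows an unassigned rank"
            )

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.lineages.index)

    def rank_labels(self, rank: str) -> pd.Series:
        if rank not in RANKS:
            raise RhizosignalError(f"unknown rank {rank!r}; expected one of {RANKS}")
        return self.lineages[rank]


def read_taxonomy(path: str | Path) -> TaxonomyTable:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df = df.fillna(UNASSIGNED)
    return TaxonomyTable(df[list(RANKS)])


def write_taxonomy(taxonomy: TaxonomyTable, path: str | Path) -> None:
    df = taxonomy.lineages.copy()
    df.index.name = "taxon_id"
    df.to_csv(path, sep="\t")


def filter_by_taxonomy(
    table: CountTable,
    taxonomy: TaxonomyTable,
    banned: Iterable[str],
    missing: str = "error",
) -> CountTable:
    """Drop taxa whose lineage contains any banned rank value.

    Matching is case-insensitive exact rank-value equality at any rank, so
    ``banned={"chloroplast"}`` removes taxa classified to Chloroplast
    whichever rank the classifier placed it at.  ``missing`` controls taxa
    absent from the taxonomy: ``"error"`` (default) or ``"drop"``.
    """
    banned_lc = {str(b).lower() for b in banned}
    lin = taxonomy.lineages
    keep: list[str] = []
    for taxon in table.taxon_ids:
        if taxon not in lin.index:
            if missing == "drop":
                warnings.warn(f"taxon {taxon!r} missing from taxonomy; dropped")
                continue
            raise RhizosignalError(f"taxon {taxon!r} missing from taxonomy")
        lineage = {str(v).lower() for v in lin.loc[taxon]}
        if lineage & banned_lc:
            continue
        keep.append(taxon)
    return table.select_taxa(keep)


# ---------------------------------------------------------------------------
# Sample metadata & exudates
# ---------------------------------------------------------------------------


@dataclass
class SampleMetadata:
    """Per-sample design: treatment, timepoint, microhabitat, replicate."""

    table: pd.DataFrame  # index sample_id

    def __post_init__(self) -> None:
        df = self.table
        required = {"treatment", "timepoint", "microhabitat", "replicate"}
        if not required.issubset(df.columns):
            raise RhizosignalError(f"metadata needs columns {sorted(required)}")
        if df.index.duplicated().any():
            raise RhizosignalError("duplicate sample ids in metadata")
        for col, allowed in (
            ("treatment", TREATMENTS),
            ("timepoint", TIMEPOINTS),
            ("microhabitat", MICROHABITATS),
        ):
            bad = set(df[col]) - set(allowed)
            if bad:
                raise RhizosignalError(f"invalid {col} values: {sorted(bad)}")
        reps = df["replicate"].astype(int)
        if (reps < 1).any():
            raise RhizosignalError("replicate ids must be positive integers")
        df = df.copy()
        df["replicate"] = reps
        self.table = df

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def select(self, **conditions: str) -> list[str]:
        """Sample ids matching all equality conditions, in table order."""
        mask = pd.Series(True, index=self.table.index)
        for col, value in conditions.items():
            mask &= self.table[col].astype(str) == str(value)
        return list(self.table.index[mask])


def read_metadata(path: str | Path) -> SampleMetadata:
    return SampleMetadata(pd.read_csv(path, sep="\t", index_col=0))


def write_metadata(metadata: SampleMetadata, path: str | Path) -> None:
    df = metadata.table.copy()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


def read_exudates(path: str | Path) -> pd.DataFrame:
    """Samples × compounds concentration matrix; nonnegative reals."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.to_numpy() < 0).any():
        raise RhizosignalError("negative exudate concentration")
    return df


def write_exudates(exudates: pd.DataFrame, path: str | Path) -> None:
    df = exudates.copy()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------


def read_tree(path: str | Path) -> TreeNode:
    tree = TreeNode.read(str(path), format="newick")
    tips = [t.name for t in tree.tips()]
    if len(set(tips)) != len(tips):
        raise RhizosignalError("duplicate tip labels in tree")
    for node in tree.traverse(include_self=False):
        if node.length is not None and node.length < 0:
            raise RhizosignalError("negative branch length")
    return tree


def write_tree(tree: TreeNode, path: str | Path) -> None:
    tree.write(str(path), format="newick")


# ---------------------------------------------------------------------------
# Rarefaction & relative abundance
# ---------------------------------------------------------------------------


def rarefy(
    table: CountTable, depth: int | str = "min", seed: int | None = None
) -> CountTable:
    """Subsample every sample to even depth without replacement.

    ``depth="min"`` uses the smallest sample sum (the study's convention of
    subsampling to the shallowest sample).  With an explicit integer depth,
    samples whose total falls below it are dropped with a warning; a depth
    exceeding every sample's total is an error.  Draws are multivariate
    hypergeometric and deterministic given ``seed``.
    """
    sums = table.sample_sums
    if isinstance(depth, str):
        if depth != "min":
            raise RhizosignalError(f"depth must be an integer or 'min', got {depth!r}")
        target = int(sums.min())
    else:
        target = int(depth)
        if target <= 0:
            raise RhizosignalError("depth must be positive")
        if target > sums.max():
            raise RhizosignalError(
                f"depth {target} exceeds the deepest sample ({int(sums.max())})"
            )
    rng = np.random.default_rng(seed)
    keep_cols: list[int] = []
    out = np.zeros_like(table.counts)
    for j in range(table.n_samples):
        if sums[j] < target:
            warnings.warn(
                f"sample {table.sample_ids[j]!r} has {int(sums[j])} < depth {target}; dropped"
            )
            continue
        out[:, j] = rng.multivariate_hypergeometric(table.counts[:, j], target)
        keep_cols.append(j)
    kept = [table.sample_ids[j] for j in keep_cols]
    return CountTable(list(table.taxon_ids), kept, out[:, keep_cols])


def to_relative_abundance(table: CountTable) -> pd.DataFrame:
    """Taxa × samples proportions; each sample column sums to 1."""
    sums = table.sample_sums
    if (sums == 0).any():
        j = int(np.argmax(sums == 0))
        raise RhizosignalError(f"sample {table.sample_ids[j]!r} has zero total count")
    rel = table.counts / sums[np.newaxis, :]
    return pd.DataFrame(rel, index=list(table.taxon_ids), columns=list(table.sample_ids))


def aggregate_to_rank(
    table: CountTable, taxonomy: TaxonomyTable, rank: str = "class", kingdom: str = ""
) -> CountTable:
    """Sum counts within each clade label at ``rank``.

    Taxa unassigned at that rank pool under ``unassigned_<kingdom>`` (or
    plain ``unassigned``).  Total reads are conserved.
    """
    labels = taxonomy.rank_labels(rank)
    pooled = f"{UNASSIGNED}_{kingdom}" if kingdom else UNASSIGNED
    order: list[str] = []
    rows: dict[str, np.ndarray] = {}
    for i, taxon in enumerate(table.taxon_ids):
        if taxon not in labels.index:
            raise RhizosignalError(f"taxon {taxon!r} missing from taxonomy")
        label = str(labels.loc[taxon])
        if label == UNASSIGNED:
            label = pooled
        elif kingdom:
            label = f"{label}_{kingdom}"
        if label not in rows:
            rows[label] = np.zeros(table.n_samples, dtype=np.int64)
            order.append(label)
        rows[label] += table.counts[i]
    return CountTable(order, list(table.sample_ids), np.array([rows[k] for k in order]))


# ---------------------------------------------------------------------------
# iTOL colour-strip export
# ---------------------------------------------------------------------------

_ITOL_SEPARATORS = {"TAB": "\t", "COMMA": ",", "SPACE": " "}


def export_itol_colorstrip(
    assignments: Mapping[str, str],
    colors: Mapping[str, str],
    dataset_label: str,
    path: str | Path | None = None,
    separator: str = "TAB",
) -> str:
    """Emit an iTOL colour-strip annotation file for response-direction calls.

    ``assignments`` maps taxon id → category (``positive`` / ``negative`` /
    ``neutral``); ``colors`` maps each category to a hex colour.  Returns the
    file text; also writes it when ``path`` is given.
    """
    for cat in ("positive", "negative", "neutral"):
        if cat not in colors:
            raise RhizosignalError(f"no colour defined for category {cat!r}")
    sep = _ITOL_SEPARATORS[separator]
    lines = [
        "DATASET_COLORSTRIP",
        f"SEPARATOR {separator}",
        f"DATASET_LABEL{sep}{dataset_label}",
        f"COLOR{sep}#999999",
        "DATA",
    ]
    for taxon, category in assignments.items():
        if sep in taxon:
            raise RhizosignalError(f"taxon id {taxon!r} contains the separator")
        if category not in colors:
            raise RhizosignalError(f"category {category!r} has no colour")
        lines.append(f"{taxon}{sep}{colors[category]}")
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


def parse_itol_colorstrip(text: str) -> dict[str, str]:
    """Inverse of :func:`export_itol_colorstrip`: taxon id → hex colour."""
    lines = text.strip().split("\n")
    if not lines or lines[0] != "DATASET_COLORSTRIP":
        raise RhizosignalError("not an iTOL colour-strip file")
    sep = "\t"
    in_data = False
    result: dict[str, str] = {}
    for line in lines[1:]:
        if line.startswith("SEPARATOR"):
            sep = _ITOL_SEPARATORS[line.split(" ", 1)[1].strip()]
        elif line == "DATA":
            in_data = True
        elif in_data and line.strip():
            taxon, color = line.split(sep)
            result[taxon] = color
    return result
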
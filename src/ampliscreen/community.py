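"""Community statistics: ASV table, beta diversity, and PCoA ordination.

The ASV table joins the depth-filtered 16S unique-sequence table with sample
metadata and per-ASV taxonomy.  Bray-Curtis is computed on raw counts (the
default of the ecology software family this pipeline follows); weighted
UniFrac delegates to scikit-bio's tree traversal.  PCoA uses Gower
double-centering with negative eigenvalues excluded from coordinates and from
the variance-proportion denominator.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix, TreeNode
from skbio.diversity import beta_diversity

from .seqtable import UniqueSeqTable, sample_depth_filter

MIN_COMMUNITY_DEPTH = 5000
AGGREGATE_BELOW = 0.01
RANKS = ("kingdom", "phylum", "genus")


@dataclass
class AbundanceTable:
    """ASV x sample counts plus taxonomy and per-sample factor metadata."""

    counts: pd.DataFrame  # index: ASV id (or sequence); columns: samples
    taxonomy: pd.Series  # ASV id -> rank-delimited string ("Bacteria;Proteobacteria;...")
    metadata: pd.DataFrame  # index: sample id; factor columns

    def __post_init__(self):
        missing = set(self.counts.columns) - set(self.metadata.index)
        if missing:
            raise ValueError(f"metadata missing for samples: {sorted(missing)}")
        zero = self.counts.columns[self.counts.sum(axis=0) == 0]
        if len(zero):
            raise ValueError(f"all-zero samples in abundance table: {list(zero)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)


def build_asv_table(
    unique_16s: UniqueSeqTable,
    metadata: pd.DataFrame,
    taxonomy: pd.Series | None = None,
    min_depth: int = MIN_COMMUNITY_DEPTH,
) -> AbundanceTable:
    """Depth-filter the 16S table and join metadata (and optional taxonomy).

    Samples below ``min_depth`` total reads are discarded as likely
    cross-contamination.  An empty result or a retained sample without
    metadata is an error.
    """
    filtered, _excluded = sample_depth_filter(unique_16s, threshold=min_depth)
    if filtered.counts.shape[1] == 0:
        raise ValueError(f"no samples reach the {min_depth}-read community depth floor")
    counts = filtered.counts
    if taxonomy is None:
        taxonomy = pd.Series("", index=counts.index)
    taxonomy = taxonomy.reindex(counts.index).fillna("")
    missing = set(counts.columns) - set(metadata.index)
    if missing:
        raise ValueError(f"metadata missing for samples: {sorted(missing)}")
    return AbundanceTable(counts, taxonomy, metadata.loc[list(counts.columns)])


def relative_abundance(
    table: AbundanceTable,
    rank: str = "phylum",
    group_by: str = "location",
    aggregate_below: float = AGGREGATE_BELOW,
    ranks: tuple[str, ...] = RANKS,
) -> pd.DataFrame:
    """Mean per-sample proportions of each taxon at ``rank``, per sample group.

    Taxa whose overall mean proportion is under ``aggregate_below`` are pooled
    into one remainder category.  Rows (groups) sum to 1.
    """
    if rank not in ranks:
        raise ValueError(f"unknown rank {rank!r}; expected one of {ranks}")
    level = ranks.index(rank)
    labels = [
        parts[level] if len(parts := t.split(";")) > level and parts[level] else "unclassified"
        for t in table.taxonomy
    ]
    props = table.counts.div(table.counts.sum(axis=0), axis=1)  # per-sample proportions
    by_taxon = props.groupby(pd.Index(labels, name=rank)).sum()
    groups = table.metadata[group_by]
    site_mean = by_taxon.T.groupby(groups).mean()  # group x taxon
    overall = site_mean.mean(axis=0)
    minor = overall.index[overall < aggregate_below]
    if len(minor):
        pooled = site_mean[minor].sum(axis=1)
        site_mean = site_mean.drop(columns=minor)
        site_mean[f"<{aggregate_below:.0%} abund."] = pooled
    return site_mean


def bray_curtis(table: AbundanceTable | pd.DataFrame) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity between samples, on raw counts."""
    counts = table.counts if isinstance(table, AbundanceTable) else table
    if counts.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    if (counts.sum(axis=0) == 0).any():
        raise ValueError("zero-sum sample; apply the depth filter first")
    X = counts.T.to_numpy(dtype=float)  # samples x ASVs
    return DistanceMatrix(squareform(pdist(X, metric="braycurtis")), ids=list(counts.columns))


def weighted_unifrac(
    table: AbundanceTable | pd.DataFrame,
    tree: TreeNode | str,
    normalized: bool = False,
) -> DistanceMatrix:
    """Weighted UniFrac between samples on the ASV phylogeny.

    Raw (unnormalized) by default: the branch-length-weighted sum of absolute
    differences in the proportion of each sample's reads descending from each
    branch.  Every ASV must be a tip of the tree.
    """
    counts = table.counts if isinstance(table, AbundanceTable) else table
    if isinstance(tree, str):
        tree = TreeNode.read(io.StringIO(tree))
    tips = {t.name for t in tree.tips()}
    missing = sorted(set(counts.index) - tips)
    if missing:
        raise ValueError(f"ASVs missing from the tree: {missing}")
    X = counts.T.to_numpy(dtype=float)
    return beta_diversity(
        "weighted_unifrac",
        X,
        ids=list(counts.columns),
        taxa=list(counts.index),
        tree=tree,
        normalized=normalized,
        validate=True,
    )


@dataclass
class PCoAResult:
    coordinates: pd.DataFrame  # samples x axes (PC1, PC2, ...)
    eigenvalues: np.ndarray  # positive eigenvalues, descending
    proportion_explained: np.ndarray  # eigenvalue / sum of positive eigenvalues


def gower_center(d: np.ndarray) -> np.ndarray:
    """Gower's double-centered matrix G = -1/2 C D^2 C with C = I - 11'/n."""
    n = d.shape[0]
    a = -0.5 * d ** 2
    row = a.mean(axis=0, keepdims=True)
    col = a.mean(axis=1, keepdims=True)
    return a - row - col + a.mean()


def pcoa(dm: DistanceMatrix | np.ndarray, ids=None, eig_tol: float = 1e-9) -> PCoAResult:
    """Principal coordinates of a dissimilarity matrix.

    Coordinates are eigenvectors scaled by sqrt(eigenvalue) for positive
    eigenvalues only; negative eigenvalues (non-Euclidean metrics) are dropped
    from both the coordinates and the variance-proportion denominator.
    """
    if isinstance(dm, DistanceMatrix):
        d = dm.data
        ids = list(dm.ids)
    else:
        d = np.asarray(dm, dtype=float)
        ids = list(ids) if ids is not None else list(range(d.shape[0]))
    n = d.shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples for ordination")
    G = gower_center(d)
    vals, vecs = np.linalg.eigh(G)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    scale = max(abs(vals[0]), 1.0)
    pos = vals > eig_tol * scale
    vals_pos = vals[pos]
    coords = vecs[:, pos] * np.sqrt(vals_pos)
    cols = [f"PC{i + 1}" for i in range(coords.shape[1])]
    if coords.shape[1] == 0:  # all-zero distances
        coords = np.zeros((n, 1))
        cols = ["PC1"]
        return PCoAResult(pd.DataFrame(coords, index=ids, columns=cols), np.array([0.0]), np.array([1.0]))
    return PCoAResult(
        pd.DataFrame(coords, index=ids, columns=cols),
        vals_pos,
        vals_pos / vals_pos.sum(),
    )
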
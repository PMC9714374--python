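"""Marker polymorphism scoring and two-sided genotype heatmap clustering.

Genotypes are agarose-band allele calls coded as small integers (band
sizes abstracted away); missing lanes are NaN.  Polymorphism is purely
categorical: a marker is polymorphic over an accession subset when it
shows >=2 distinct non-missing alleles there.  Rates are reported over a
caller-supplied denominator because marker panels routinely quote rates
over designed pairs, amplified pairs, or scored pairs.

Two-sided clustering follows common heatmap-package defaults: allele
calls are one-hot encoded per marker, accession rows are Z-scored,
distances are (NaN-aware) Euclidean, linkage is complete; both axes are
clustered and the accession tree cut at k=2 yields the group call.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from sklearn.metrics import adjusted_rand_score
from sklearn.metrics.pairwise import nan_euclidean_distances

from ._util import round_half_up


@dataclass
class GenotypeMatrix:
    """Accession x marker allele calls with optional group labels."""

    calls: pd.DataFrame  # float codes, NaN = missing
    groups: Optional[pd.Series] = None  # index = accessions

    def __post_init__(self) -> None:
        if self.calls.shape[0] < 1 or self.calls.shape[1] < 1:
            raise ValueError("genotype matrix must be non-empty")
        if self.groups is not None:
            self.groups = self.groups.reindex(self.calls.index)

    @property
    def accessions(self) -> list[str]:
        return list(self.calls.index)

    @property
    def markers(self) -> list[str]:
        return list(self.calls.columns)

    @classmethod
    def from_csv(cls, path) -> "GenotypeMatrix":
        df = pd.read_csv(path, index_col=0)
        groups = None
        if "group" in df.columns:
            groups = df.pop("group").astype(str)
        return cls(calls=df.astype(float), groups=groups)

    def to_csv(self, path) -> None:
        out = self.calls.copy()
        if self.groups is not None:
            out.insert(0, "group", self.groups)
        out.to_csv(path)


@dataclass
class PolymorphismReport:
    per_marker: pd.DataFrame  # n_alleles, polymorphic
    n_polymorphic: int
    denominator: int
    rate: float  # percent, 1 decimal


def score_polymorphism(
    gm: GenotypeMatrix,
    subset: Optional[Sequence[str]] = None,
    denominator: Optional[int] = None,
) -> PolymorphismReport:
    """Flag polymorphic markers over an accession subset and compute the
    polymorphism rate 100 * n_polymorphic / denominator (1 decimal).

    ``denominator`` defaults to the number of markers in the matrix but
    may be larger (e.g. the number of designed primer pairs when some
    failed to amplify and never entered the matrix).
    """
    calls = gm.calls if subset is None else gm.calls.loc[list(subset)]
    if calls.shape[0] == 0:
        raise ValueError("empty accession subset")
    n_alleles = calls.nunique(axis=0, dropna=True)
    poly = n_alleles >= 2
    denom = denominator if denominator is not None else calls.shape[1]
    if denom < 1:
        raise ValueError("denominator must be positive")
    per_marker = pd.DataFrame({"n_alleles": n_alleles, "polymorphic": poly})
    n_poly = int(poly.sum())
    return PolymorphismReport(
        per_marker=per_marker,
        n_polymorphic=n_poly,
        denominator=denom,
        rate=round_half_up(100.0 * n_poly / denom, 1),
    )


def zscore_rows(matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Standardise each row to mean 0, sample (ddof=1) SD 1.

    Rows with zero spread (or fewer than 2 finite values) are set to 0
    and flagged.  Returns (z, constant_row_flags).
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2:
        raise ValueError("expected a 2-D matrix")
    z = np.zeros_like(m)
    flags = np.zeros(m.shape[0], dtype=bool)
    for i in range(m.shape[0]):
        row = m[i]
        finite = np.isfinite(row)
        vals = row[finite]
        sd = vals.std(ddof=1) if vals.size > 1 else 0.0
        if sd == 0.0 or vals.size < 2:
            flags[i] = True
            z[i, ~finite] = np.nan
        else:
            z[i] = (row - vals.mean()) / sd
    return z, flags


def _one_hot(calls: pd.DataFrame) -> np.ndarray:
    """Per-marker one-hot allele encoding; missing calls propagate NaN
    across that marker's indicator block."""
    blocks = []
    for col in calls.columns:
        v = calls[col]
        levels = sorted(set(v.dropna()))
        block = np.zeros((len(v), max(len(levels), 1)))
        for j, lv in enumerate(levels):
            block[:, j] = (v == lv).astype(float)
        block[v.isna().to_numpy(), :] = np.nan
        blocks.append(block)
    return np.hstack(blocks)


@dataclass
class BiclusterResult:
    accession_linkage: np.ndarray
    marker_linkage: np.ndarray
    accession_order: list[str]
    marker_order: list[str]
    ordered_matrix: pd.DataFrame  # column-standardised calls, both axes ordered
    groups_k2: pd.Series  # accession -> 1 or 2
    dropped_markers: list[str]


def bicluster(
    gm: GenotypeMatrix,
    linkage_method: str = "complete",
    max_missing_fraction: float = 0.5,
) -> BiclusterResult:
    """Hierarchical clustering of both axes of a genotype matrix.

    Markers missing in more than ``max_missing_fraction`` of accessions
    are dropped.  Accessions are clustered on Z-scored one-hot allele
    indicators with NaN-aware Euclidean distances; markers are clustered
    on their per-marker standardised call profiles.  The accession tree
    cut at k=2 gives the two-group assignment.  A single accession yields
    the identity grouping and no trees.
    """
    calls = gm.calls
    missing_frac = calls.isna().mean(axis=0)
    dropped = [m for m in calls.columns if missing_frac[m] > max_missing_fraction]
    calls = calls.drop(columns=dropped)
    if calls.shape[1] < 1:
        raise ValueError("no markers left after missingness filter")
    n_acc = calls.shape[0]

    # display matrix: calls standardised within each marker (column)
    col_z, _ = zscore_rows(calls.to_numpy().T)
    display = pd.DataFrame(col_z.T, index=calls.index, columns=calls.columns)

    if n_acc < 2:
        groups = pd.Series([1], index=calls.index, name="group")
        return BiclusterResult(
            accession_linkage=np.empty((0, 4)),
            marker_linkage=np.empty((0, 4)),
            accession_order=list(calls.index),
            marker_order=list(calls.columns),
            ordered_matrix=display,
            groups_k2=groups,
            dropped_markers=dropped,
        )

    feats, _ = zscore_rows(_one_hot(calls))
    acc_link = _linkage_from_features(feats, linkage_method)
    if calls.shape[1] >= 2:
        marker_link = _linkage_from_features(np.nan_to_num(col_z), linkage_method)
        marker_order = [calls.columns[i] for i in hierarchy.leaves_list(marker_link)]
    else:
        marker_link = np.empty((0, 4))
        marker_order = list(calls.columns)

    acc_order = [calls.index[i] for i in hierarchy.leaves_list(acc_link)]
    labels = hierarchy.fcluster(acc_link, t=2, criterion="maxclust")
    groups = pd.Series(labels, index=calls.index, name="group")
    return BiclusterResult(
        accession_linkage=acc_link,
        marker_linkage=marker_link,
        accession_order=acc_order,
        marker_order=marker_order,
        ordered_matrix=display.loc[acc_order, marker_order],
        groups_k2=groups,
        dropped_markers=dropped,
    )


def _linkage_from_features(feats: np.ndarray, method: str) -> np.ndarray:
    d = nan_euclidean_distances(feats)
    np.fill_diagonal(d, 0.0)
    condensed = d[np.triu_indices_from(d, k=1)]
    return hierarchy.linkage(condensed, method=method)


def group_concordance(predicted: Sequence, truth: Sequence) -> float:
    """Adjusted Rand index between two partitions of the same accessions."""
    if len(predicted) != len(truth):
        raise ValueError("partition length mismatch")
    return float(adjusted_rand_score(list(truth), list(predicted)))


def linkage_to_newick(link: np.ndarray, labels: Sequence[str]) -> str:
    """Serialise a scipy linkage matrix as a newick string with branch
    lengths derived from merge heights."""
    tree = hierarchy.to_tree(link)

    def rec(node, parent_height):
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = rec(node.left, node.dist)
        right = rec(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return rec(tree, tree.dist) + ";"
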
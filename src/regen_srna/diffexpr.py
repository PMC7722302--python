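"""Per-class RPM expression matrices, hierarchical clustering, candidates.

Counts for one small-RNA class (miRNA genes, source tRNAs, or piRNA
cluster loci) are scaled per library to reads-per-million of that
class's total, so expression changes are compared within the class's
own pool.  Retained entities (>= 100 RPM in at least one timepoint) are
hierarchically clustered with average linkage on the Pearson
correlation distance d = 1 - r, on both rows and columns; the two
clusters from the final row merge define group-a (the group with the
higher mean row Z-score at 24 h, i.e. the amputation-induced group) and
group-b.  Heatmap colours use row Z-scores; clustering itself runs on
the raw RPM rows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

TIMEPOINTS = ("0h", "24h", "72h", "120h")


class ClusteringError(ValueError):
    pass


@dataclass
class DendroGroups:
    groups: pd.Series            # entity -> 'group-a' | 'group-b'
    row_linkage: np.ndarray
    col_linkage: np.ndarray | None
    row_z: pd.DataFrame
    row_order: list[str]
    constant_rows: list[str]


def build_matrix(counts: pd.DataFrame, min_rpm: float = 100.0) -> pd.DataFrame:
    """Scale per-class counts to RPM and drop never-expressed entities.

    ``counts``: entities x libraries raw read counts for ONE class; each
    column is scaled to reads per million of its own column total.
    Entities below ``min_rpm`` in every library are removed.
    """
    totals = counts.sum(axis=0)
    rpm = counts.divide(totals.replace(0, np.nan), axis=1) * 1e6
    rpm = rpm.fillna(0.0)
    keep = (rpm >= min_rpm).any(axis=1)
    return rpm.loc[keep]


def row_zscores(matrix: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Row Z-scores (sample sd); constant rows become all-zero and flagged."""
    mean = matrix.mean(axis=1)
    sd = matrix.std(axis=1, ddof=1)
    constant = sd[sd == 0].index.tolist()
    z = matrix.sub(mean, axis=0).div(sd.replace(0, np.nan), axis=0).fillna(0.0)
    return z, constant


def _correlation_distance(matrix: np.ndarray) -> np.ndarray:
    """Condensed Pearson distance 1 - r; constant vectors get distance 1."""
    n = matrix.shape[0]
    sd = matrix.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(matrix)
    out = []
    for i in range(n):
        for j in range(i + 1, n):
            if sd[i] == 0 or sd[j] == 0:
                out.append(1.0)
            else:
                out.append(1.0 - corr[i, j])
    return np.asarray(out)


def cluster_rows(matrix: pd.DataFrame, cluster_columns: bool = True) -> DendroGroups:
    """Average-linkage / Pearson-distance clustering with a 2-way row split."""
    if len(matrix) < 2:
        raise ClusteringError("need at least 2 retained entities to cluster")
    row_link = hierarchy.linkage(_correlation_distance(matrix.to_numpy()),
                                 method="average")
    col_link = None
    if cluster_columns and matrix.shape[1] >= 2:
        col_link = hierarchy.linkage(_correlation_distance(matrix.to_numpy().T),
                                     method="average")
    z, constant = row_zscores(matrix)
    labels = hierarchy.fcluster(row_link, 2, criterion="maxclust")
    order = [matrix.index[i] for i in hierarchy.leaves_list(row_link)]
    ref_col = "24h" if "24h" in matrix.columns else matrix.columns[min(1, matrix.shape[1] - 1)]
    means = {c: z.loc[labels == c, ref_col].mean() for c in np.unique(labels)}
    if len(means) == 1:  # all rows merged into one flat cluster
        a_label = next(iter(means))
    else:
        a_label = max(means, key=lambda c: (means[c], -c))
    groups = pd.Series(["group-a" if l == a_label else "group-b" for l in labels],
                       index=matrix.index, name="group")
    return DendroGroups(groups, row_link, col_link, z, order, constant)


def select_upregulated(matrix: pd.DataFrame, fold: float = 2.0,
                       min_mean_rpm: float = 100.0,
                       baseline: str = "0h") -> list[str]:
    """Entities >= ``fold``-fold up after amputation with mean RPM >= 100.

    Upregulation compares the maximum post-amputation RPM against the
    pre-amputation (0 h) value; a zero baseline with any later expression
    counts as upregulated.  Monotone in ``fold``.
    """
    post_cols = [c for c in matrix.columns if c != baseline]
    out = []
    for entity, row in matrix.iterrows():
        base = row[baseline]
        peak = row[post_cols].max()
        up = (peak > 0) if base == 0 else (peak >= fold * base)
        if up and row.mean() >= min_mean_rpm:
            out.append(entity)
    return out
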
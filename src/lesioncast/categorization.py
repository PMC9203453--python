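"""Unsupervised categorization of subjects on the (occurrence, sparsity) plane.

Subjects are clustered by k-means (k = 3 by default) on their two lesion
characteristics.  Both coordinates already live in [0, 1], so the raw values
are clustered without standardization.  Cluster labels are then relabeled
canonically — subset 1 is the cluster with the lowest mean occurrence,
subset k the highest — so that "subset 1/2/3" means the same thing across
runs and seeds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

__all__ = ["SubsetAssignment", "cluster_subjects"]


@dataclass(frozen=True)
class SubsetAssignment:
    subject_id: str
    subset_label: int  # 1-based; 1 = lowest-occurrence cluster
    occurrence: float
    sparsity: float


def cluster_subjects(
    characteristics: pd.DataFrame, k: int = 3, seed: int = 0, n_restarts: int = 10
) -> pd.DataFrame:
    """k-means on the (occurrence, sparsity) plane with canonical label order.

    Parameters
    ----------
    characteristics : DataFrame indexed by subject id with columns
        ``occurrence`` and ``sparsity``.
    k : number of subsets (3 reproduces the low / low-to-moderate /
        moderate-to-high occurrence stratification).
    seed : controls the k-means restarts; same seed, same assignment.

    Returns
    -------
    DataFrame with columns ``subset`` (1..k), ``occurrence``, ``sparsity``.
    """
    pts = characteristics[["occurrence", "sparsity"]].to_numpy(dtype=float)
    if not np.all(np.isfinite(pts)):
        raise ValueError("characteristics must be finite")
    if len(pts) < k:
        raise ValueError(f"need at least k={k} subjects, got {len(pts)}")
    if np.allclose(pts, pts[0]):
        raise ValueError("degenerate clustering input: all points identical")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    raw = km.fit_predict(pts)
    # canonical order: subset 1 = lowest mean occurrence centroid
    order = np.argsort(km.cluster_centers_[:, 0], kind="stable")
    relabel = {int(old): rank + 1 for rank, old in enumerate(order)}
    out = characteristics[["occurrence", "sparsity"]].copy()
    out.insert(0, "subset", [relabel[int(c)] for c in raw])
    return out
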
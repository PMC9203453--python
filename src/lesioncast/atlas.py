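"""Brain-region registry, inter-region distances, and multi-resolution hierarchy.

The registry describes a three-level parcellation: fine anatomical regions
(AAL-style, 116 by default), anatomical lobes (level 2, 18 by default) and
hemispheric divisions (level 1, 5 by default).  Every fine region has exactly
one lobe parent and one hemispheric parent, so predictions made at the fine
resolution can be aggregated upward without ambiguity.

The bundled default registry (``data/aal116_synthetic_registry.csv``) is a
synthetic stand-in: it carries the standard AAL-116 region names and an
anatomically plausible hierarchy, but its centroid coordinates are
approximate.  Users with a real template can substitute their own CSV with
the same columns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "RegionAtlas",
    "DistanceMatrix",
    "load_atlas",
    "default_atlas",
    "build_distance_matrix",
    "rollup_map",
    "extract_region_degrees",
    "load_nifti_pair",
]

_REGISTRY_COLUMNS = ["region_id", "name", "cx", "cy", "cz", "level2_parent", "level1_parent"]


@dataclass(frozen=True)
class RegionAtlas:
    """An ordered region registry with centroids and a two-step hierarchy.

    Attributes
    ----------
    region_ids : integer array, unique, in registry order.
    names : region names aligned with ``region_ids``.
    centroids : ``(n, 3)`` array of centroid coordinates (mm or arbitrary
        Cartesian units; only relative geometry matters downstream).
    level2_parent, level1_parent : parent label per region (lobe /
        hemispheric division).
    """

    region_ids: np.ndarray
    names: tuple[str, ...]
    centroids: np.ndarray
    level2_parent: tuple[str, ...]
    level1_parent: tuple[str, ...]

    def __post_init__(self) -> None:
        ids = np.asarray(self.region_ids)
        if len(np.unique(ids)) != len(ids):
            raise ValueError("region ids must be unique")
        if self.centroids.shape != (len(ids), 3):
            raise ValueError("centroids must be an (n_regions, 3) array")
        # hierarchy consistency: a lobe may not straddle two hemispheric divisions
        l2_to_l1: dict[str, str] = {}
        for l2, l1 in zip(self.level2_parent, self.level1_parent):
            if l2 in l2_to_l1 and l2_to_l1[l2] != l1:
                raise ValueError(f"level-2 region {l2!r} has conflicting level-1 parents")
            l2_to_l1[l2] = l1

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    @property
    def n_level2(self) -> int:
        return len(set(self.level2_parent))

    @property
    def n_level1(self) -> int:
        return len(set(self.level1_parent))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "region_id": self.region_ids,
                "name": list(self.names),
                "cx": self.centroids[:, 0],
                "cy": self.centroids[:, 1],
                "cz": self.centroids[:, 2],
                "level2_parent": list(self.level2_parent),
                "level1_parent": list(self.level1_parent),
            }
        )


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric matrix of min-max normalized inter-centroid distances.

    Off-diagonal entries span [0, 1] (the closest pair maps to 0, the
    farthest to 1); the diagonal is 0.
    """

    values: np.ndarray
    region_ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]


def load_atlas(path: str | Path) -> RegionAtlas:
    """Read a region registry CSV (columns region_id,name,cx,cy,cz,level2_parent,level1_parent)."""
    df = pd.read_csv(path)
    missing = [c for c in _REGISTRY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"registry file missing columns: {missing}")
    return RegionAtlas(
        region_ids=df["region_id"].to_numpy(dtype=int),
        names=tuple(df["name"].astype(str)),
        centroids=df[["cx", "cy", "cz"]].to_numpy(dtype=float),
        level2_parent=tuple(df["level2_parent"].astype(str)),
        level1_parent=tuple(df["level1_parent"].astype(str)),
    )


def default_atlas() -> RegionAtlas:
    """The bundled 116-region registry (18 lobes, 5 hemispheric divisions)."""
    ref = resources.files("lesioncast.data") / "aal116_synthetic_registry.csv"
    with resources.as_file(ref) as path:
        return load_atlas(path)


def build_distance_matrix(atlas: RegionAtlas) -> DistanceMatrix:
    """Pairwise Euclidean centroid distances, min-max normalized to [0, 1].

    Normalization uses the off-diagonal upper triangle: the smallest
    inter-region distance maps to 0 and the largest to 1.  A two-region atlas
    is degenerate (min == max); its single pair is set to 0 with a warning.
    Identical centroids for *all* pairs raise ``ValueError``.
    """
    c = np.asarray(atlas.centroids, dtype=float)
    if c.shape[0] < 2:
        raise ValueError("need at least 2 regions with finite centroids")
    if not np.all(np.isfinite(c)):
        raise ValueError("centroids must be finite")
    diff = c[:, None, :] - c[None, :, :]
    d = np.sqrt((diff**2).sum(axis=-1))
    iu = np.triu_indices_from(d, k=1)
    dmin, dmax = d[iu].min(), d[iu].max()
    if dmax == dmin:
        if c.shape[0] == 2:
            warnings.warn(
                "two-region atlas: single pair distance normalizes to 0", stacklevel=2
            )
            norm = np.zeros_like(d)
        else:
            raise ValueError("degenerate geometry: all pairwise distances equal")
    else:
        norm = (d - dmin) / (dmax - dmin)
        np.fill_diagonal(norm, 0.0)
        norm = np.clip(norm, 0.0, 1.0)
        norm = (norm + norm.T) / 2.0
    return DistanceMatrix(values=norm, region_ids=np.asarray(atlas.region_ids))


def rollup_map(atlas: RegionAtlas, level: str) -> dict[int, str]:
    """Total mapping from fine region id to its coarse parent label.

    ``level`` is ``"level2"`` (lobes) or ``"level1"`` (hemispheric
    divisions).
    """
    if level == "level2":
        parents = atlas.level2_parent
    elif level == "level1":
        parents = atlas.level1_parent
    else:
        raise ValueError(f"unknown level {level!r}; expected 'level2' or 'level1'")
    return {int(rid): parent for rid, parent in zip(atlas.region_ids, parents)}


def extract_region_degrees(
    mask_volume: np.ndarray, label_volume: np.ndarray, atlas: RegionAtlas
) -> np.ndarray:
    """Per-region lesion degree (%) from a binary lesion mask and a label volume.

    Degree of region *r* is ``100 * (lesioned voxels labeled r) / (voxels
    labeled r)``.  Regions absent from the label volume get degree 0 with a
    warning.  Label 0 is background.
    """
    mask = np.asarray(mask_volume)
    labels = np.asarray(label_volume)
    if mask.shape != labels.shape:
        raise ValueError("mask and label volumes must have identical shapes")
    uniq = np.unique(mask)
    if not np.all(np.isin(uniq, [0, 1])):
        raise ValueError("mask must be binary (0/1)")
    known = set(int(v) for v in np.unique(labels)) - {0}
    atlas_ids = set(int(i) for i in atlas.region_ids)
    unknown = known - atlas_ids
    if unknown:
        raise ValueError(f"label volume contains ids not in atlas: {sorted(unknown)}")
    degrees = np.zeros(atlas.n_regions, dtype=float)
    absent = []
    for i, rid in enumerate(atlas.region_ids):
        in_region = labels == int(rid)
        total = int(in_region.sum())
        if total == 0:
            absent.append(int(rid))
            continue
        degrees[i] = 100.0 * mask[in_region].sum() / total
    if absent:
        warnings.warn(
            f"{len(absent)} atlas region(s) absent from label volume; degree set to 0",
            stacklevel=2,
        )
    return degrees


def load_nifti_pair(mask_path: str | Path, label_path: str | Path):
    """Load a binary lesion mask and an integer label volume from NIfTI files."""
    import nibabel as nib  # optional dependency

    mask = np.asarray(nib.load(str(mask_path)).dataobj)
    labels = np.asarray(nib.load(str(label_path)).dataobj).astype(int)
    mask = (mask > 0).astype(int)
    return mask, labels
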
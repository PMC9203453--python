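"""Per-subject lesion occurrence and sparsity, and per-region dispersion.

A subject's lesion profile is the vector of lesion degrees (percentage of
lesioned voxels) over the atlas regions.  Two scalar characteristics
summarize it:

* **occurrence** — the fraction of regions with any lesion (degree > 0%);
* **sparsity** — the mean *normalized inter-region distance* taken over all
  unordered pairs of regions that are *both* lesioned (the Hadamard product
  of the mutual-occurrence indicator, 1 under AND and excluded otherwise,
  with the normalized distance matrix).  High sparsity means the lesioned
  regions are spread far apart; subjects with fewer than two lesioned
  regions have no valid pair and are assigned sparsity 0.

Across subjects, a region's dispersion is summarized by the coefficient of
variation (sample SD / mean) of its degrees, with an all-zero region
reported as CV 0 (no lesion found).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .atlas import DistanceMatrix, RegionAtlas

__all__ = [
    "LesionProfile",
    "LesionCharacteristics",
    "binarize",
    "occurrence",
    "sparsity",
    "coefficient_of_variation",
    "characterize_cohort",
]


@dataclass(frozen=True)
class LesionProfile:
    """Lesion degrees (percent, in [0, 100]) for one subject over all regions."""

    subject_id: str
    degrees: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.degrees, dtype=float)
        if not np.all(np.isfinite(d)):
            raise ValueError("lesion degrees must be finite")
        if np.any(d < 0) or np.any(d > 100):
            raise ValueError("lesion degrees must lie in [0, 100] percent")
        object.__setattr__(self, "degrees", d)


@dataclass(frozen=True)
class LesionCharacteristics:
    subject_id: str
    occurrence: float
    sparsity: float
    n_lesioned: int


def binarize(profile: LesionProfile | np.ndarray) -> np.ndarray:
    """0/1 lesion absence/presence per region; presence is strictly degree > 0%."""
    d = profile.degrees if isinstance(profile, LesionProfile) else np.asarray(profile, float)
    return (d > 0).astype(int)


def occurrence(profile: LesionProfile, atlas: RegionAtlas | None = None) -> float:
    """Fraction of atlas regions with a lesion (degree > 0%)."""
    b = binarize(profile)
    n = atlas.n_regions if atlas is not None else len(b)
    if atlas is not None and len(b) != atlas.n_regions:
        raise ValueError("profile length does not match atlas size")
    return float(b.sum()) / n


def sparsity(profile: LesionProfile, dist: DistanceMatrix) -> float:
    """Mean normalized distance over unordered pairs of mutually lesioned regions.

    Pairs where either region is intact contribute nothing (they are
    excluded, not zero).  Returns 0 when fewer than two regions are
    lesioned.
    """
    b = binarize(profile)
    if len(b) != dist.n_regions:
        raise ValueError("profile and distance matrix dimensions disagree")
    idx = np.flatnonzero(b)
    if len(idx) < 2:
        return 0.0
    sub = dist.values[np.ix_(idx, idx)]
    iu = np.triu_indices(len(idx), k=1)
    return float(sub[iu].mean())


def coefficient_of_variation(degrees_across_subjects: np.ndarray) -> float:
    """Sample SD (ddof=1) divided by mean of one region's degrees across subjects.

    Defined as 0 for an all-zero vector (no lesion found in the region) and
    0 for any constant vector.
    """
    x = np.asarray(degrees_across_subjects, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least 2 subjects")
    mu = x.mean()
    if mu == 0:
        return 0.0
    sd = x.std(ddof=1)
    return float(sd / mu)


def characterize_cohort(
    lesion_table: pd.DataFrame, dist: DistanceMatrix
) -> pd.DataFrame:
    """(occurrence, sparsity, n_lesioned) per subject of a wide lesion table.

    ``lesion_table`` is subjects x regions with percent degrees; the column
    order must match the distance matrix's region order.
    """
    if lesion_table.shape[1] != dist.n_regions:
        raise ValueError("lesion table width does not match distance matrix")
    rows = []
    for sid, row in lesion_table.iterrows():
        prof = LesionProfile(subject_id=str(sid), degrees=row.to_numpy(dtype=float))
        b = binarize(prof)
        rows.append(
            {
                "subject_id": str(sid),
                "occurrence": occurrence(prof),
                "sparsity": sparsity(prof, dist),
                "n_lesioned": int(b.sum()),
            }
        )
    return pd.DataFrame(rows).set_index("subject_id")
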
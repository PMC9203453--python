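"""Synthetic cohorts with the statistical structure the pipeline assumes.

No public lesion/clinical dataset accompanies this problem, so every stage
is exercised on generated cohorts that emulate the relevant structure:

* three planted patient subsets distinguished on the (occurrence, sparsity)
  plane — few spatially adjacent lesions (subset 1, including a fraction of
  single-lesion subjects), a moderate number of moderately spread lesions
  (subset 2), and many widely spread lesions (subset 3);
* right-skewed lesion degrees conditional on presence (most lesioned regions
  have small percentage involvement);
* a wide non-imaging feature table grouped under clinical-test family names,
  in which a planted minority of features shift with the lesion presence of
  a specific region (a logistic signal) while the rest are nuisance noise,
  with missing values injected at a configurable rate.

The planted ground truth (subset labels, informative feature -> region map
with signed effects) is returned alongside the data so recovery tests can
score the pipeline without reaching into generator internals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .atlas import DistanceMatrix, RegionAtlas, build_distance_matrix
from .lesion_metrics import characterize_cohort

__all__ = ["CohortSpec", "generate_atlas", "generate_cohort", "generate_features"]

# clinical-test families used to label generated features (realistic I/O only)
FEATURE_FAMILIES = (
    "BIT", "CAT", "MMSE", "RBMT", "TMT", "FIM", "BRS",
    "Apathy", "HADS", "JPSS", "Blood", "Demographic", "Medication",
)


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions for one synthetic cohort.

    Defaults emulate a rehabilitation-ward stroke cohort: subset sizes 67/86/42 on a
    116-region atlas, with subset-specific lesioned-region counts and
    spatial clustering strengths chosen so the subsets occupy the low /
    moderate / high corners of the (occurrence, sparsity) plane; 241
    candidate non-imaging features of which one per region carries a
    logistic signal about that region's lesion presence.
    """

    n_subjects: tuple[int, int, int] = (67, 86, 42)
    # lesioned-region count range (inclusive) per planted subset
    region_count_ranges: tuple[tuple[int, int], ...] = ((1, 3), (5, 12), (16, 26))
    # spatial clustering strength per subset: length scale (normalized
    # distance units) of the lesion-growth kernel; None = uniform growth
    clustering_scales: tuple[float | None, ...] = (0.04, 0.10, None)
    # achieved-sparsity band per subset (low / moderate / high); the lesion
    # set is re-drawn until its sparsity lands in band, so the subsets
    # occupy distinguishable strata of the (occurrence, sparsity) plane
    sparsity_bands: tuple[tuple[float, float], ...] = (
        (0.0, 0.12), (0.18, 0.34), (0.42, 0.58),
    )
    single_lesion_fraction: float = 23 / 67  # of subset 1
    degree_shape: tuple[float, float] = (0.8, 5.0)  # Beta params, right-skewed
    n_features: int = 241
    n_informative_per_region: int = 1
    effect_size: float = 2.0  # standardized shift under lesion presence
    missingness: float = 0.05
    noise_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n <= 0 for n in self.n_subjects):
            raise ValueError("subset sizes must be positive")
        if self.n_features <= 0 or self.n_informative_per_region < 0:
            raise ValueError("feature counts must be positive")
        if not np.isfinite(self.effect_size):
            raise ValueError("effect size must be finite")

    def scaled_to(self, n_regions: int, reference: int = 116) -> "CohortSpec":
        """The same study conditions on a smaller atlas: lesioned-region
        count ranges are scaled proportionally (keeping at least 1)."""
        from dataclasses import replace

        factor = n_regions / reference
        ranges = tuple(
            (max(1, round(lo * factor)), max(1, round(hi * factor)))
            for lo, hi in self.region_count_ranges
        )
        ranges = tuple((lo, max(lo, hi)) for lo, hi in ranges)
        if max(hi for _, hi in ranges) > n_regions:
            raise ValueError("atlas too small to scale the lesion count ranges")
        return replace(self, region_count_ranges=ranges)


def generate_atlas(
    n_regions: int = 116,
    seed: int = 0,
    n_lobes: int | None = None,
    n_hemis: int | None = None,
    preset: str | None = None,
) -> RegionAtlas:
    """Random region registry with a consistent 3-level hierarchy.

    Centroids are sampled in a 3-D box; regions are grouped into lobes and
    lobes into hemispheric divisions by k-means on the centroids, so the
    hierarchy is spatially coherent and total.  ``preset='aal-like'`` gives
    the 116/18/5 level counts of the bundled registry.
    """
    from sklearn.cluster import KMeans

    if preset == "aal-like":
        n_regions, n_lobes, n_hemis = 116, 18, 5
    if n_regions < 4:
        raise ValueError("need n_regions >= 4")
    if n_lobes is None:
        n_lobes = min(18, max(1, n_regions // 6))
    if n_hemis is None:
        n_hemis = min(5, max(1, n_lobes // 3))
    rng = np.random.default_rng(seed)
    centroids = rng.uniform(0.0, 100.0, size=(n_regions, 3))
    lobe_of = KMeans(n_clusters=n_lobes, n_init=5, random_state=seed).fit_predict(centroids)
    lobe_centers = np.array(
        [centroids[lobe_of == j].mean(axis=0) for j in range(n_lobes)]
    )
    if n_hemis < n_lobes:
        hemi_of_lobe = KMeans(n_clusters=n_hemis, n_init=5, random_state=seed).fit_predict(
            lobe_centers
        )
    else:
        hemi_of_lobe = np.arange(n_lobes)
    return RegionAtlas(
        region_ids=np.arange(1, n_regions + 1),
        names=tuple(f"region_{i:03d}" for i in range(1, n_regions + 1)),
        centroids=centroids,
        level2_parent=tuple(f"lobe_{lobe_of[i]:02d}" for i in range(n_regions)),
        level1_parent=tuple(f"hemi_{hemi_of_lobe[lobe_of[i]]}" for i in range(n_regions)),
    )


def _grow_lesion_set(
    n_target: int, dist: np.ndarray, scale: float | None, rng: np.random.Generator
) -> np.ndarray:
    """Seed one region and grow to ``n_target`` regions.

    With a finite ``scale``, the next region is drawn with probability
    proportional to exp(-d_min/scale) where d_min is its normalized distance
    to the current set (small scale -> tight spatial clusters -> low
    sparsity); ``scale=None`` draws uniformly (wide spread).
    """
    n = dist.shape[0]
    chosen = [int(rng.integers(n))]
    while len(chosen) < n_target:
        remaining = np.setdiff1d(np.arange(n), chosen)
        if scale is None:
            nxt = int(rng.choice(remaining))
        else:
            dmin = dist[np.ix_(remaining, chosen)].min(axis=1)
            w = np.exp(-dmin / scale)
            w = w / w.sum()
            nxt = int(rng.choice(remaining, p=w))
        chosen.append(nxt)
    return np.array(sorted(chosen))


def _set_sparsity(idx: np.ndarray, dist: np.ndarray) -> float:
    if len(idx) < 2:
        return 0.0
    sub = dist[np.ix_(idx, idx)]
    iu = np.triu_indices(len(idx), k=1)
    return float(sub[iu].mean())


def _draw_lesion_set_in_band(
    n_target: int,
    dist: np.ndarray,
    scale: float | None,
    band: tuple[float, float],
    rng: np.random.Generator,
    max_attempts: int = 50,
) -> np.ndarray:
    """Draw a lesion set whose achieved sparsity lies in ``band``.

    The growth kernel alone only loosely controls sparsity, so sets are
    re-drawn until one lands inside the subset's band; after
    ``max_attempts`` the draw closest to the band midpoint is kept (a
    single-region set always qualifies: its sparsity is 0).
    """
    lo, hi = band
    mid = (lo + hi) / 2.0
    best, best_gap = None, np.inf
    for _ in range(max_attempts):
        idx = _grow_lesion_set(n_target, dist, scale, rng)
        s = _set_sparsity(idx, dist)
        if lo <= s <= hi or n_target < 2:
            return idx
        gap = abs(s - mid)
        if gap < best_gap:
            best, best_gap = idx, gap
    return best


def generate_cohort(
    spec: CohortSpec, atlas: RegionAtlas, dist: DistanceMatrix | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Lesion-degree table plus planted labels and achieved characteristics.

    Returns ``(lesion_table, truth)``: the lesion table is subjects x
    regions (percent degrees, columns are atlas region ids); ``truth`` holds
    the planted subset label and the achieved (occurrence, sparsity) pair
    per subject.
    """
    if dist is None:
        dist = build_distance_matrix(atlas)
    max_count = max(hi for _, hi in spec.region_count_ranges)
    if max_count > atlas.n_regions:
        raise ValueError("infeasible spec: lesion count range exceeds region count")
    rng = np.random.default_rng(spec.seed)
    a, b = spec.degree_shape
    rows, labels = [], []
    sid = 0
    for subset_i, (n_sub, (lo, hi), scale, band) in enumerate(
        zip(
            spec.n_subjects,
            spec.region_count_ranges,
            spec.clustering_scales,
            spec.sparsity_bands,
        ),
        start=1,
    ):
        for j in range(n_sub):
            if subset_i == 1 and j < round(spec.single_lesion_fraction * n_sub):
                count = 1
            else:
                count = int(rng.integers(lo, hi + 1))
            idx = _draw_lesion_set_in_band(count, dist.values, scale, band, rng)
            degrees = np.zeros(atlas.n_regions)
            # right-skewed degree conditional on presence, bounded away from 0
            degrees[idx] = np.maximum(rng.beta(a, b, size=len(idx)) * 100.0, 0.01)
            sid += 1
            rows.append(degrees)
            labels.append(subset_i)
    index = pd.Index([f"S{i:04d}" for i in range(1, sid + 1)], name="subject_id")
    lesion = pd.DataFrame(rows, index=index, columns=[int(r) for r in atlas.region_ids])
    chars = characterize_cohort(lesion, dist)
    truth = chars.assign(subset=labels)[["subset", "occurrence", "sparsity", "n_lesioned"]]
    return lesion, truth


def generate_features(
    lesion_table: pd.DataFrame, spec: CohortSpec
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Non-imaging feature table with planted region-wise logistic signal.

    For each region (cycling through the feature pool), ``spec.
    n_informative_per_region`` features get their mean shifted by
    ``spec.effect_size`` (random sign) in subjects where that region is
    lesioned; all other features are pure noise.  Features are named
    ``FAMILY_k`` after clinical-test families.  Missing values are injected
    completely at random at rate ``spec.missingness``.

    Returns ``(features, truth_map)`` where ``truth_map`` has one row per
    informative (feature, region) pair with the signed planted effect.
    """
    n_subjects, n_regions = lesion_table.shape
    n_needed = n_regions * spec.n_informative_per_region
    if spec.n_informative_per_region > 0 and n_needed > spec.n_features:
        raise ValueError(
            f"{n_needed} informative features requested but only {spec.n_features} available"
        )
    rng = np.random.default_rng(spec.seed + 1)
    names = [
        f"{FEATURE_FAMILIES[k % len(FEATURE_FAMILIES)]}_{k // len(FEATURE_FAMILIES) + 1:02d}"
        for k in range(spec.n_features)
    ]
    x = rng.normal(0.0, spec.noise_scale, size=(n_subjects, spec.n_features))
    presence = (lesion_table.to_numpy() > 0).astype(float)
    truth_rows = []
    feat_idx = 0
    for r_pos, rid in enumerate(lesion_table.columns):
        for _ in range(spec.n_informative_per_region):
            sign = 1.0 if rng.random() < 0.5 else -1.0
            x[:, feat_idx] += sign * spec.effect_size * presence[:, r_pos]
            truth_rows.append(
                {"feature": names[feat_idx], "region_id": rid,
                 "effect": sign * spec.effect_size}
            )
            feat_idx += 1
    if spec.missingness > 0:
        mask = rng.random(size=x.shape) < spec.missingness
        x = np.where(mask, np.nan, x)
    features = pd.DataFrame(x, index=lesion_table.index, columns=names)
    truth_map = pd.DataFrame(truth_rows, columns=["feature", "region_id", "effect"])
    return features, truth_map
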
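"""Moving lesion estimates between atlas resolutions.

Two routes to lobe- (level 2) and hemisphere-level (level 1) estimates:

* **modified estimation** — predictions made at the fine resolution are
  rolled up by OR logic: a coarse region is predicted lesioned iff any of
  its constituent fine regions is.  True coarse occurrence is derived the
  same way from the binarized fine truth.
* **direct estimation** — the full per-region modeling pipeline is run
  directly on the coarse truth, one model per lobe or hemisphere.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .region_models import FitConfig, RegionFitResult, fit_all_regions

__all__ = ["rollup_predictions", "direct_fit_at_level"]


def rollup_predictions(pred: pd.DataFrame, mapping: dict) -> pd.DataFrame:
    """OR roll-up of a subject x fine-region 0/1 matrix to coarse regions.

    ``mapping`` sends every fine-region column to its coarse parent; columns
    missing from the mapping raise.  Works identically for predictions and
    for binarized truth.
    """
    missing = [c for c in pred.columns if c not in mapping]
    if missing:
        raise ValueError(f"regions missing from mapping: {missing}")
    parents = sorted({mapping[c] for c in pred.columns}, key=str)
    out = {}
    for parent in parents:
        members = [c for c in pred.columns if mapping[c] == parent]
        out[parent] = (pred[members].to_numpy() > 0).any(axis=1).astype(int)
    return pd.DataFrame(out, index=pred.index)


def direct_fit_at_level(
    lesion_table: pd.DataFrame,
    features: pd.DataFrame,
    mapping: dict,
    config: FitConfig,
) -> tuple[RegionFitResult, pd.DataFrame]:
    """Fit the per-region pipeline directly at a coarse resolution.

    Coarse truth is the OR roll-up of the binarized fine truth (a lobe is
    lesioned iff any of its fine regions is); the usual pipeline then runs
    per coarse region.  Returns the fit result and the coarse truth table
    (0/1, scaled to percent degrees for the fitting interface).
    """
    fine_binary = (lesion_table > 0).astype(int)
    coarse_truth = rollup_predictions(fine_binary, mapping)
    coarse_degrees = coarse_truth * 100.0  # presence as 100%, absence 0
    result = fit_all_regions(coarse_degrees, features, config)
    return result, coarse_truth
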
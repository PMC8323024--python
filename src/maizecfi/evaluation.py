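"""Agreement between image-extracted traits and ground truth.

For every shared numeric trait the report carries the coefficient of
determination about the identity line (1 - SS_res/SS_tot with residuals taken
to y = x, the natural reading of estimate-vs-truth agreement), the ordinary
least-squares R^2 as a secondary column (the two differ when the estimates are
biased), the root-mean-squared error, and the mean bias (estimate - truth).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputError

__all__ = ["evaluate", "trait_metrics"]

#: traits evaluated when present in both tables
DEFAULT_TRAITS = [
    "height_cm",
    "width_cm",
    "projected_area_cm2",
    "stem_height_cm",
    "stem_diameter_cm",
    "n_leaves",
    "leaf_area_cm2",
    "leaf_angle_deg",
]


def trait_metrics(estimate: np.ndarray, truth: np.ndarray) -> dict:
    """R^2 (identity-line and regression), RMSE, and mean bias for one trait."""
    estimate = np.asarray(estimate, dtype=float)
    truth = np.asarray(truth, dtype=float)
    ok = np.isfinite(estimate) & np.isfinite(truth)
    estimate, truth = estimate[ok], truth[ok]
    n = len(truth)
    if n < 2:
        raise InputError("need >= 2 matched records per trait")
    resid = estimate - truth
    ss_tot = float(np.sum((truth - truth.mean()) ** 2))
    r2_identity = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else float("nan")
    if ss_tot > 0 and np.var(estimate) > 0:
        r = float(np.corrcoef(estimate, truth)[0, 1])
        r2_regression = r * r
    else:
        r2_regression = float("nan")
    return {
        "n": n,
        "r2": r2_identity,
        "r2_regression": r2_regression,
        "rmse": float(np.sqrt(np.mean(resid**2))),
        "bias": float(np.mean(resid)),
    }


def evaluate(
    pred: pd.DataFrame | str | Path,
    truth: pd.DataFrame | str | Path,
    keys: list[str] | None = None,
    traits: list[str] | None = None,
) -> pd.DataFrame:
    """Per-trait agreement report between predicted and ground-truth tables.

    ``pred`` and ``truth`` are DataFrames or CSV paths sharing the join
    ``keys`` (default ``["plant_id"]``) and one column per trait.
    """
    if not isinstance(pred, pd.DataFrame):
        pred = pd.read_csv(pred)
    if not isinstance(truth, pd.DataFrame):
        truth = pd.read_csv(truth)
    keys = keys or ["plant_id"]
    merged = pred.merge(truth, on=keys, suffixes=("_est", "_true"))
    if merged.empty:
        raise InputError("no overlap between prediction and truth tables on keys")
    rows = []
    for trait in traits or DEFAULT_TRAITS:
        est_col, true_col = f"{trait}_est", f"{trait}_true"
        if est_col not in merged or true_col not in merged:
            continue
        rows.append({"trait": trait, **trait_metrics(merged[est_col], merged[true_col])})
    if not rows:
        raise InputError("no shared numeric traits to evaluate")
    return pd.DataFrame(rows)
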
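"""Mean-impact-value feature analysis and cumulative-contribution selection.

The mean impact value (MIV) of a feature is the mean change in model output
when that feature is perturbed by +/-10% across the training set: the sign
gives the direction of association, the magnitude the strength. Features
are ranked by |MIV|; each feature's relative contribution ratio is
``|MIV_i| / sum_j |MIV_j|`` and the model keeps the largest rank-prefix
whose cumulative contribution stays within the retention threshold
(90% by default).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["compute_miv", "contribution_table", "select_features", "miv_analysis"]


def compute_miv(model, X_train: np.ndarray, delta: float = 0.10) -> np.ndarray:
    """Signed MIV per feature of any fitted predictor.

    For each feature j the training matrix is copied with column j scaled by
    (1 + delta) and (1 - delta); the MIV is the mean difference of the two
    prediction vectors. The perturbation acts on the model's input space,
    i.e. on normalized features when the model was trained on them.
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    if not hasattr(model, "predict"):
        raise ValueError("model must be fitted and expose .predict")
    X = np.asarray(X_train, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    mivs = np.empty(p)
    for j in range(p):
        up = X.copy()
        dn = X.copy()
        up[:, j] *= 1.0 + delta
        dn[:, j] *= 1.0 - delta
        mivs[j] = float(np.mean(model.predict(up) - model.predict(dn)))
    return mivs


def contribution_table(
    mivs: np.ndarray, feature_names: list[str] | None = None
) -> pd.DataFrame:
    """Rank features by |MIV| and tabulate relative and cumulative
    contribution ratios (percent).

    Columns: ``rank, feature, miv, relative_pct, cumulative_pct``; relative
    ratios sum to 100 and cumulative ratios are nondecreasing, ending at 100.
    """
    mivs = np.asarray(mivs, dtype=float)
    if np.all(mivs == 0):
        raise ValueError("all MIVs are zero; nothing to rank")
    p = mivs.size
    names = feature_names or [f"x{j}" for j in range(p)]
    if len(names) != p:
        raise ValueError("feature_names length mismatch")
    order = np.argsort(-np.abs(mivs), kind="stable")
    abs_sorted = np.abs(mivs[order])
    rel = abs_sorted / abs_sorted.sum() * 100.0
    return pd.DataFrame(
        {
            "rank": np.arange(1, p + 1),
            "feature": [names[i] for i in order],
            "miv": mivs[order],
            "relative_pct": rel,
            "cumulative_pct": np.cumsum(rel),
        }
    )


def select_features(table: pd.DataFrame, threshold_pct: float = 90.0) -> list[str]:
    """Retain the largest rank-prefix with cumulative contribution <= the
    threshold; never empty (the top-ranked feature is always kept)."""
    if not 0 < threshold_pct <= 100:
        raise ValueError("threshold_pct must lie in (0, 100]")
    # small tolerance so e.g. a cumulative 100 + eps is retained at threshold 100
    keep = table.loc[
        table["cumulative_pct"] <= threshold_pct + 1e-9, "feature"
    ].tolist()
    if not keep:
        keep = [table.iloc[0]["feature"]]
    return keep


def miv_analysis(
    model,
    X_train: np.ndarray,
    feature_names: list[str],
    threshold_pct: float = 90.0,
    delta: float = 0.10,
) -> tuple[pd.DataFrame, list[str]]:
    """Convenience: MIVs -> contribution table -> retained feature list."""
    mivs = compute_miv(model, X_train, delta=delta)
    table = contribution_table(mivs, feature_names)
    return table, select_features(table, threshold_pct)
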
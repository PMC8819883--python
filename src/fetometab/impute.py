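"""missForest-style random-forest imputation of remaining missing values.

QC injections must be removed before imputation (enforced here, so pooled
technical replicates cannot bias the fill-in) and the per-mode tables are
expected to be merged first. The imputer follows the missForest loop:
features are initial-filled with their observed mean, then visited in order
of increasing missingness; each is regressed on all other features with a
random forest trained on the rows where it was observed, and its missing
entries are replaced by the forest's predictions. Sweeps repeat until the
sum of squared changes in the imputed cells stops decreasing (or a sweep
cap is hit). Observed values are never altered.

The reported out-of-bag (OOB) error is the mean over imputed features of
the forest's OOB mean-squared error divided by the variance of the observed
values — the NRMSE-style statistic missForest prints.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .model import FeatureTable

MAX_ITER = 10


class ImputationError(ValueError):
    pass


def impute_rf(
    table: FeatureTable,
    seed: int = 0,
    n_estimators: int = 50,
    log_scale: bool = True,
    max_iter: int = MAX_ITER,
) -> tuple[FeatureTable, float]:
    """Fill all missing cells; returns ``(complete_table, oob_error)``.

    Runs on the log scale by default (intensities are log-normal-ish).
    Deterministic for a fixed ``seed``. A feature with no detected
    biological value cannot be imputed and is an error — such features
    cannot survive the detection criteria of the cleanup stage.
    """
    if (table.injections["sample_type"] == "qc").any():
        table = table.drop_qc()
    X = table.intensities.to_numpy(float).T  # samples x features
    n_samples, n_features = X.shape
    miss = np.isnan(X)
    all_missing = miss.all(axis=0)
    if all_missing.any():
        bad = table.intensities.index[all_missing].tolist()
        raise ImputationError(
            f"feature(s) missing in all biological injections: {bad[:5]} - "
            "run the cleanup stage first; such features cannot pass its "
            "detection criteria"
        )
    if not miss.any():
        return table.copy(), 0.0

    if log_scale:
        with np.errstate(divide="ignore"):
            X = np.log(X)

    rng = np.random.RandomState(seed)
    col_means = np.nanmean(X, axis=0)
    X_imp = X.copy()
    for j in range(n_features):
        X_imp[miss[:, j], j] = col_means[j]

    target_cols = np.where(miss.any(axis=0))[0]
    # visit features with least missingness first (missForest convention)
    target_cols = target_cols[np.argsort(miss[:, target_cols].sum(axis=0), kind="stable")]

    prev_delta = np.inf
    oob_errors: dict[int, float] = {}
    best = X_imp.copy()
    for _ in range(max_iter):
        X_old = X_imp.copy()
        for j in target_cols:
            obs = ~miss[:, j]
            predictors = np.delete(np.arange(n_features), j)
            y = X_imp[obs, j]
            if np.var(y) == 0.0:
                X_imp[miss[:, j], j] = y[0]
                oob_errors[j] = 0.0
                continue
            forest = RandomForestRegressor(
                n_estimators=n_estimators,
                max_features="sqrt",
                oob_score=True,
                bootstrap=True,
                random_state=rng.randint(0, 2**31 - 1),
                n_jobs=1,
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                forest.fit(X_imp[np.ix_(obs, predictors)], y)
                oob_pred = forest.oob_prediction_
            oob_errors[j] = float(
                np.mean((oob_pred - y) ** 2) / np.var(y)
            )
            X_imp[miss[:, j], j] = forest.predict(
                X_imp[np.ix_(miss[:, j], predictors)]
            )
        delta = float(np.sum((X_imp[miss] - X_old[miss]) ** 2))
        if delta >= prev_delta:
            X_imp = best  # change criterion stalled: keep the previous sweep
            break
        best = X_imp.copy()
        prev_delta = delta

    if log_scale:
        X_imp = np.exp(X_imp)
        X_obs = table.intensities.to_numpy(float).T
        X_imp[~miss] = X_obs[~miss]  # exact observed-value preservation

    out = table.copy()
    out.intensities = pd.DataFrame(
        X_imp.T, index=table.intensities.index, columns=table.intensities.columns
    )
    oob_error = float(np.mean(list(oob_errors.values()))) if oob_errors else 0.0
    return out, oob_error
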
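"""LOOCV prediction of the learning index from screened features.

Four feature sets — resting-EEG power cells, morphometry cluster means,
ALFF cluster means, connectome edges — plus their column-wise concatenation
("multimodal") are fed to regression models (linear SVR, ordinary linear
regression, Bayesian ARD regression, random forest) under leave-one-out
cross-validation.  Performance is the mean absolute error and the Pearson
correlation between actual and predicted LI, and prediction accuracies of
two feature sets are compared with Steiger's z-test for dependent
correlations sharing the actual-LI variable.

Following the emulated analysis, feature screening and across-individual
normalization happen once on the full cohort before the LOOCV loop (the
selection bias this induces is deliberate — it reproduces the published
procedure); flags switch to per-fold normalization for honest benchmarking.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import ARDRegression, LinearRegression
from sklearn.svm import SVR

from .screening import ScreenResult

__all__ = [
    "FeatureSet",
    "PredictionReport",
    "assemble_features",
    "loocv_predict",
    "evaluate",
    "compare_dependent_correlations",
    "predict_all_sets",
    "MODELS",
]

MODELS = ("svr_linear", "linear", "ardr", "rfr")


@dataclass
class FeatureSet:
    """A named participants x features matrix of screened predictors."""

    name: str
    table: pd.DataFrame
    provenance: list[ScreenResult] = field(default_factory=list)
    degenerate: bool = False

    @property
    def n_features(self) -> int:
        return self.table.shape[1]


@dataclass
class PredictionReport:
    """LOOCV outcome per feature set (one model).

    ``comparisons[name] = (z, p)`` is Steiger's test of the multimodal
    prediction correlation against feature set ``name``.
    """

    model: str
    predictions: dict[str, np.ndarray]
    mae: dict[str, float]
    r: dict[str, float]
    comparisons: dict[str, tuple[float, float]] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name in self.predictions:
            z, p = self.comparisons.get(name, (np.nan, np.nan))
            rows.append({"feature_set": name, "model": self.model,
                         "mae": self.mae[name], "pearson_r": self.r[name],
                         "steiger_z_vs_multimodal": z, "steiger_p": p})
        return pd.DataFrame(rows)


def _zscore(x: np.ndarray, axis: int = 0) -> np.ndarray:
    sd = x.std(axis=axis, ddof=0)
    return (x - x.mean(axis=axis)) / np.where(sd > 0, sd, 1.0)


def assemble_features(modality_tables: dict[str, pd.DataFrame],
                      screen_results: dict[str, list[ScreenResult]],
                      normalize: bool = True) -> list[FeatureSet]:
    """Build single-modality feature sets plus the multimodal concatenation.

    Parameters
    ----------
    modality_tables : dict
        ``modality -> participants x candidate-features`` DataFrame; the
        screened columns are looked up by their ``ScreenResult.feature``.
    screen_results : dict
        Per modality, the screening output; only ``selected`` entries
        contribute columns.
    normalize : bool
        Z-score each column across participants (the across-individual
        normalization of the emulated analysis).

    A modality with no selected feature yields a single-column fallback
    (the z-scored mean of all its candidate columns) flagged
    ``degenerate=True`` so downstream reporting can mark it.
    """
    sets: list[FeatureSet] = []
    blocks = []
    for name, table in modality_tables.items():
        selected = [r for r in screen_results.get(name, []) if r.selected]
        cols = [r.feature for r in selected]
        if cols:
            sub = table[cols].copy()
            degenerate = False
        else:
            sub = table.mean(axis=1).to_frame(name=f"{name}_mean")
            degenerate = True
        vals = sub.to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ValueError(f"non-finite feature values in modality {name!r}")
        if normalize:
            sub = pd.DataFrame(_zscore(vals), index=sub.index, columns=sub.columns)
        fs = FeatureSet(name=name, table=sub, provenance=selected,
                        degenerate=degenerate)
        sets.append(fs)
        blocks.append(sub.add_prefix(f"{name}::"))
    multi = pd.concat(blocks, axis=1)
    sets.append(FeatureSet(name="multimodal", table=multi,
                           provenance=[r for rs in screen_results.values()
                                       for r in rs if r.selected],
                           degenerate=all(s.degenerate for s in sets)))
    return sets


def _make_model(name: str, seed: int | None, n_trees: int = 500):
    if name == "svr_linear":
        return SVR(kernel="linear", C=1.0, epsilon=0.1)
    if name == "linear":
        return LinearRegression()
    if name == "ardr":
        return ARDRegression()
    if name == "rfr":
        return RandomForestRegressor(n_estimators=n_trees, random_state=seed)
    raise ValueError(f"unknown model {name!r}; choose from {MODELS}")


def loocv_predict(features: pd.DataFrame | np.ndarray, li: np.ndarray,
                  model: str = "svr_linear", seed: int | None = 0,
                  per_fold_norm: bool = False, n_trees: int = 500) -> np.ndarray:
    """Leave-one-out predictions of LI.

    For each participant the model is fit on the remaining n-1 and used to
    predict the held-out value; the held-out row never influences its own
    prediction.  With ``per_fold_norm`` the feature normalization statistics
    are refit inside every fold (default off: normalization is done once
    globally upstream, matching the emulated procedure).
    """
    x = features.to_numpy(dtype=float) if isinstance(features, pd.DataFrame) \
        else np.asarray(features, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    y = np.asarray(li, dtype=float)
    n = y.size
    if n < 3:
        raise ValueError("need at least 3 participants for LOOCV")
    if x.shape[0] != n:
        raise ValueError("feature rows must match LI length")
    preds = np.empty(n)
    for i in range(n):
        tr = np.arange(n) != i
        x_tr, x_te = x[tr], x[~tr]
        if per_fold_norm:
            mu = x_tr.mean(axis=0)
            sd = x_tr.std(axis=0, ddof=0)
            sd = np.where(sd > 0, sd, 1.0)
            x_tr = (x_tr - mu) / sd
            x_te = (x_te - mu) / sd
        est = _make_model(model, seed, n_trees)
        est.fit(x_tr, y[tr])
        preds[i] = est.predict(x_te)[0]
    return preds


def evaluate(predictions: np.ndarray, li: np.ndarray) -> tuple[float, float]:
    """Mean absolute error and Pearson r of predicted versus actual LI."""
    predictions = np.asarray(predictions, dtype=float)
    li = np.asarray(li, dtype=float)
    mae = float(np.mean(np.abs(predictions - li)))
    if predictions.std() == 0 or li.std() == 0:
        return mae, 0.0
    return mae, float(stats.pearsonr(predictions, li)[0])


def compare_dependent_correlations(r_a: float, r_b: float, r_ab: float,
                                   n: int) -> tuple[float, float]:
    """Steiger's z-test for two dependent correlations sharing one variable.

    ``r_a`` and ``r_b`` correlate two predictors with a common criterion
    (actual LI); ``r_ab`` is the correlation between the two predictors
    (here: the two prediction vectors).  Two-sided p; ``sign(z) =
    sign(r_a - r_b)``.
    """
    if n < 4:
        raise ValueError("need n >= 4")
    if r_a == r_b:
        return 0.0, 1.0
    clip = 1 - 1e-12
    z_a = np.arctanh(np.clip(r_a, -clip, clip))
    z_b = np.arctanh(np.clip(r_b, -clip, clip))
    rm2 = (r_a ** 2 + r_b ** 2) / 2.0
    f = min((1.0 - r_ab) / (2.0 * (1.0 - rm2)), 1.0)
    h = (1.0 - f * rm2) / (1.0 - rm2)
    z = (z_a - z_b) * np.sqrt((n - 3.0) / (2.0 * (1.0 - r_ab) * h))
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


def predict_all_sets(feature_sets: list[FeatureSet], li: np.ndarray,
                     model: str = "svr_linear", seed: int | None = 0,
                     eeg_single_uses_linear: bool = True,
                     per_fold_norm: bool = False,
                     n_trees: int = 500) -> PredictionReport:
    """LOOCV over every feature set, with multimodal-vs-single comparisons.

    Mirrors the emulated analysis detail that a one-column EEG set is fit
    with plain linear regression instead of the SVR
    (``eeg_single_uses_linear``).  LI is z-scored across participants
    before fitting, like the features.
    """
    li = np.asarray(li, dtype=float)
    li_z = _zscore(li)
    preds: dict[str, np.ndarray] = {}
    mae: dict[str, float] = {}
    r: dict[str, float] = {}
    for fs in feature_sets:
        m = model
        if eeg_single_uses_linear and fs.name == "eeg" and fs.n_features == 1:
            m = "linear"
        p = loocv_predict(fs.table, li_z, model=m, seed=seed,
                          per_fold_norm=per_fold_norm, n_trees=n_trees)
        preds[fs.name] = p
        mae[fs.name], r[fs.name] = evaluate(p, li_z)
    comparisons: dict[str, tuple[float, float]] = {}
    if "multimodal" in preds:
        n = li.size
        for name, p in preds.items():
            if name == "multimodal":
                continue
            if p.std() == 0 or preds["multimodal"].std() == 0:
                comparisons[name] = (np.nan, np.nan)
                continue
            r_ab = float(stats.pearsonr(preds["multimodal"], p)[0])
            comparisons[name] = compare_dependent_correlations(
                r["multimodal"], r[name], r_ab, n)
    return PredictionReport(model=model, predictions=preds, mae=mae, r=r,
                            comparisons=comparisons)
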
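"""Shapley-value attribution and feature-importance reporting.

For a fitted model f and a sample x, the Shapley value of feature i is
its average marginal contribution to f over all orderings of the
feature set; the attributions satisfy *local accuracy*: base value +
sum of per-feature attributions = model output for every sample.

Tree ensembles get exact tree-path Shapley values through the boosted
tree library's native contribution predictor; the linear baselines get
interventional Shapley values in closed form (coef_j * (x_j - E[x_j]),
which is exact for additive models).  Classifier attributions are
computed in margin (log-odds) space, where additivity is exact for
tree ensembles; probability-space attribution is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xgboost as xgb
from sklearn.linear_model import LinearRegression, LogisticRegression, Ridge
from sklearn.pipeline import Pipeline

from xgboost import XGBClassifier, XGBRegressor


@dataclass
class AttributionSet:
    """Per-sample, per-feature Shapley values (per-class for classifiers).

    ``values`` has shape (n, features) for regressors and
    (n, classes, features) for classifiers; ``base`` is the expected
    model output (per class for classifiers).
    """

    values: np.ndarray
    base: np.ndarray  # shape () or (classes,)
    feature_names: list[str]
    class_names: list[str] | None = None

    @property
    def reconstruction(self) -> np.ndarray:
        """base + sum of attributions, per sample (and class)."""
        return self.values.sum(axis=-1) + self.base

    def importance(self) -> pd.Series:
        """Mean |attribution| per feature, averaged over samples and,
        for classifiers, over classes."""
        absval = np.abs(self.values)
        while absval.ndim > 1:
            absval = absval.mean(axis=0)
        return pd.Series(absval, index=self.feature_names, name="importance")


def _unwrap(model):
    if isinstance(model, Pipeline):
        transform = lambda X: model[:-1].transform(X)  # noqa: E731
        return model[-1], transform
    return model, (lambda X: X)


def attribute(model, X: pd.DataFrame) -> AttributionSet:
    """Shapley attributions of ``model`` over the samples in ``X``.

    ``X`` doubles as the background distribution for the linear
    (interventional) case.  Deterministic given model and data.
    """
    feature_names = list(X.columns)
    inner, transform = _unwrap(model)

    if isinstance(inner, (XGBRegressor, XGBClassifier)):
        booster = inner.get_booster()
        dm = xgb.DMatrix(np.asarray(X, dtype=float), feature_names=feature_names)
        contribs = booster.predict(dm, pred_contribs=True)
        if contribs.ndim == 2:  # regression / binary: (n, f+1)
            values = contribs[:, :-1]
            base = np.asarray(contribs[0, -1])
            class_names = None
            if isinstance(inner, XGBClassifier):
                # binary task: a single margin column for the positive class
                values = values[:, None, :]
                base = base[None]
                class_names = [str(inner.classes_[-1])]
            return AttributionSet(values, base, feature_names, class_names)
        # multiclass: (n, classes, f+1)
        values = contribs[:, :, :-1]
        base = contribs[0, :, -1]
        class_names = [str(c) for c in inner.classes_]
        return AttributionSet(values, base, feature_names, class_names)

    if isinstance(inner, (LinearRegression, Ridge)):
        Z = np.asarray(transform(X), dtype=float)
        mu = Z.mean(axis=0)
        coef = np.asarray(inner.coef_, dtype=float).ravel()
        values = (Z - mu) * coef
        base = np.asarray(inner.intercept_ + coef @ mu)
        return AttributionSet(values, base, feature_names)

    if isinstance(inner, LogisticRegression):
        Z = np.asarray(transform(X), dtype=float)
        mu = Z.mean(axis=0)
        coef = np.asarray(inner.coef_, dtype=float)  # (classes|1, f)
        values = (Z[:, None, :] - mu) * coef[None, :, :]
        base = np.asarray(inner.intercept_) + coef @ mu
        return AttributionSet(values, base, feature_names,
                              [str(c) for c in inner.classes_])

    raise TypeError(f"unsupported model type for attribution: {type(inner).__name__}")


def model_margin(model, X: pd.DataFrame) -> np.ndarray:
    """Model output in the space the attributions live in (raw margin
    for trees, decision function for logistic, prediction for OLS)."""
    inner, transform = _unwrap(model)
    if isinstance(inner, (XGBRegressor, XGBClassifier)):
        dm = xgb.DMatrix(np.asarray(X, dtype=float), feature_names=list(X.columns))
        return inner.get_booster().predict(dm, output_margin=True)
    Z = transform(X)
    if isinstance(inner, LogisticRegression):
        return inner.decision_function(Z)
    return inner.predict(Z)


def check_local_accuracy(model, X: pd.DataFrame, rtol: float = 1e-4) -> float:
    """Max relative reconstruction error of base + sum(attributions)
    against the model margin; raises if it exceeds ``rtol``."""
    attr = attribute(model, X)
    margin = np.asarray(model_margin(model, X), dtype=float)
    recon = attr.reconstruction
    scale = max(1.0, float(np.max(np.abs(margin))))
    err = float(np.max(np.abs(recon - margin.reshape(recon.shape))) / scale)
    if err > rtol:
        raise AssertionError(f"local accuracy violated: rel err {err:.2e} > {rtol}")
    return err


def rank_features(attr: AttributionSet, k: int = 20) -> pd.DataFrame:
    """Top-``k`` features by mean |attribution|, descending; ties break
    lexicographically by name.  ``k`` beyond the feature count returns
    every feature."""
    imp = attr.importance()
    df = imp.rename_axis("feature").reset_index()
    df = df.sort_values(["importance", "feature"],
                        ascending=[False, True], kind="stable")
    return df.head(k).reset_index(drop=True)


def summary_views(attr: AttributionSet, ranking: pd.DataFrame, outdir,
                  prefix: str = "shap") -> list[str]:
    """Write the importance bar chart and attribution-vs-value views
    (per class for classifiers), plus the deterministic plot-data CSV
    behind them.  Returns the written paths; empty rankings no-op with
    a warning."""
    import logging
    from pathlib import Path

    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    logger = logging.getLogger(__name__)
    if ranking.empty:
        logger.warning("empty feature ranking: nothing to plot")
        return []
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[str] = []

    data_path = outdir / f"{prefix}_ranking.csv"
    ranking.to_csv(data_path, index=False)
    written.append(str(data_path))

    fig, ax = plt.subplots(figsize=(7, 0.4 * len(ranking) + 1.5))
    ax.barh(ranking["feature"][::-1], ranking["importance"][::-1], color="#d62728")
    ax.set_xlabel("mean |Shapley value|")
    ax.set_title("Feature importance")
    fig.tight_layout()
    bar_path = outdir / f"{prefix}_importance.png"
    fig.savefig(bar_path, dpi=120)
    plt.close(fig)
    written.append(str(bar_path))

    n_classes = attr.values.shape[1] if attr.values.ndim == 3 else 1
    for c in range(n_classes):
        vals = attr.values[:, c, :] if attr.values.ndim == 3 else attr.values
        fig, ax = plt.subplots(figsize=(7, 0.4 * len(ranking) + 1.5))
        for row, feat in enumerate(ranking["feature"]):
            j = attr.feature_names.index(feat)
            v = vals[:, j]
            jitter = (np.arange(len(v)) % 7 - 3) * 0.04
            ax.scatter(v, np.full_like(v, len(ranking) - 1 - row) + jitter,
                       c=v, cmap="coolwarm", s=8)
        ax.set_yticks(range(len(ranking)))
        ax.set_yticklabels(list(ranking["feature"])[::-1])
        ax.set_xlabel("Shapley value (impact on model output)")
        suffix = f"_class_{attr.class_names[c]}" if attr.class_names else ""
        fig.tight_layout()
        path = outdir / f"{prefix}_beeswarm{suffix}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(str(path))
    return written
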
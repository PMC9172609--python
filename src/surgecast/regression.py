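"""Pluggable regression forecasters over the calendar features.

The estimator families are adapters around standard implementations
(scikit-learn for the linear, tree, SVR, bagging and boosting families;
statsmodels GLM for the Poisson and negative-binomial count families;
xgboost if installed). Each family is registered under a stable id and
accepts an arbitrary hyperparameter map — no tuner is built here. The
``ENSEMBLE`` family is a uniform-weight vote (unweighted mean) over Random
Forest, Bagging and Gradient Boosting base models.

Stochastic families are seeded (default seed 1) so that two fits on
identical data give identical predictions. Predictions are clipped at zero
before use: the target is a daily count.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .calendar import HolidayCalendar
from .errors import ConfigurationError, InsufficientHistoryError
from .features import FEATURE_COLUMNS, SeasonalityConfig, design_matrix
from .io import DailyDemandSeries

__all__ = [
    "EstimatorSpec",
    "FittedForecaster",
    "fit_forecaster",
    "ensemble_predict",
    "available_families",
    "FAMILIES",
    "ENSEMBLE_BASES",
]

#: the three base families of the uniform-vote ensemble
ENSEMBLE_BASES = ("RANDOM_FOREST", "BAGGING", "GRADIENT_BOOSTING")


@dataclass(frozen=True)
class EstimatorSpec:
    """An estimator family id, its hyperparameters, and a seed (default 1)."""

    family: str
    hyperparams: dict = field(default_factory=dict)
    seed: int = 1

    def __post_init__(self) -> None:
        fam = self.family.upper()
        object.__setattr__(self, "family", fam)
        if fam == "ENSEMBLE" and self.hyperparams:
            bad = set(self.hyperparams) - {"random_forest", "bagging", "gradient_boosting"}
            if bad:
                raise ConfigurationError(
                    "ENSEMBLE accepts only per-base hyperparameter maps "
                    f"(random_forest/bagging/gradient_boosting), got {sorted(bad)}"
                )


# ---------------------------------------------------------------------------
# estimator adapters: each builder returns an object with fit(X, y) / predict(X)


class _SklearnAdapter:
    def __init__(self, est):
        self.est = est

    def fit(self, X: pd.DataFrame, y: np.ndarray) -> None:
        self.est.fit(X.values, y)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return np.asarray(self.est.predict(X.values), dtype=float)


class _GLMAdapter:
    """statsmodels GLM with a log link; exposes coefficients and their
    standard errors for inference-style checks."""

    def __init__(self, family_builder: Callable, **fit_kwargs):
        self.family_builder = family_builder
        self.fit_kwargs = fit_kwargs
        self.result = None

    def fit(self, X: pd.DataFrame, y: np.ndarray) -> None:
        import statsmodels.api as sm

        self.result = sm.GLM(y, X, family=self.family_builder()).fit(**self.fit_kwargs)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return np.asarray(self.result.predict(X), dtype=float)

    @property
    def params(self) -> pd.Series:
        return self.result.params

    @property
    def bse(self) -> pd.Series:
        return self.result.bse


def _linear(hp: dict, seed: int):
    from sklearn.linear_model import LinearRegression

    # the 8 day-type indicators sum to 1 and act as the intercept
    return _SklearnAdapter(LinearRegression(fit_intercept=False, **hp))


def _poisson(hp: dict, seed: int):
    import statsmodels.api as sm

    return _GLMAdapter(lambda: sm.families.Poisson(), **hp)


def _negbin(hp: dict, seed: int):
    import statsmodels.api as sm

    hp = dict(hp)
    alpha = hp.pop("alpha", 1.0)
    return _GLMAdapter(lambda: sm.families.NegativeBinomial(alpha=alpha), **hp)


def _tree(hp: dict, seed: int):
    from sklearn.tree import DecisionTreeRegressor

    return _SklearnAdapter(DecisionTreeRegressor(random_state=seed, **hp))


def _random_forest(hp: dict, seed: int):
    from sklearn.ensemble import RandomForestRegressor

    return _SklearnAdapter(RandomForestRegressor(random_state=seed, **hp))


def _svr(kernel: str):
    def build(hp: dict, seed: int):
        from sklearn.svm import SVR

        return _SklearnAdapter(SVR(kernel=kernel, **hp))

    return build


def _bagging(hp: dict, seed: int):
    from sklearn.ensemble import BaggingRegressor

    return _SklearnAdapter(BaggingRegressor(random_state=seed, **hp))


def _gradient_boosting(hp: dict, seed: int):
    from sklearn.ensemble import GradientBoostingRegressor

    return _SklearnAdapter(GradientBoostingRegressor(random_state=seed, **hp))


def _xgboost(hp: dict, seed: int):
    try:
        from xgboost import XGBRegressor
    except ImportError as exc:  # keep the core dependency-light
        raise ConfigurationError(
            "XGBOOST family requested but xgboost is not installed; "
            f"available families: {', '.join(available_families())}"
        ) from exc
    return _SklearnAdapter(XGBRegressor(random_state=seed, **hp))


class _EnsembleAdapter:
    """Uniform-weight vote over Random Forest, Bagging and Gradient Boosting."""

    def __init__(self, hp: dict, seed: int):
        self.bases = [
            _random_forest(hp.get("random_forest", {}), seed),
            _bagging(hp.get("bagging", {}), seed),
            _gradient_boosting(hp.get("gradient_boosting", {}), seed),
        ]

    def fit(self, X: pd.DataFrame, y: np.ndarray) -> None:
        for b in self.bases:
            b.fit(X, y)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        preds = np.vstack([b.predict(X) for b in self.bases])
        return np.array([ensemble_predict(preds[:, j]) for j in range(preds.shape[1])])


FAMILIES: dict[str, Callable] = {
    "LINEAR": _linear,
    "POISSON": _poisson,
    "NEGBIN": _negbin,
    "TREE": _tree,
    "RANDOM_FOREST": _random_forest,
    "SVR_LINEAR": _svr("linear"),
    "SVR_RBF": _svr("rbf"),
    "SVR_SIGMOID": _svr("sigmoid"),
    "SVR_POLY": _svr("poly"),
    "BAGGING": _bagging,
    "GRADIENT_BOOSTING": _gradient_boosting,
    "XGBOOST": _xgboost,
    "ENSEMBLE": _EnsembleAdapter,
}


def available_families() -> list[str]:
    """Registered family ids, with XGBOOST only if its backend is importable."""
    out = []
    for fam in FAMILIES:
        if fam == "XGBOOST":
            try:
                import xgboost  # noqa: F401
            except ImportError:
                continue
        out.append(fam)
    return out


def ensemble_predict(base_predictions: Sequence[float]) -> float:
    """Uniform-weight combination of exactly three base predictions.

    The combiner is the unweighted arithmetic mean, hence symmetric in its
    inputs and bounded by their min and max.
    """
    vals = np.asarray(base_predictions, dtype=float)
    if vals.shape != (3,):
        raise ConfigurationError(
            f"ensemble_predict expects exactly 3 base predictions, got shape {vals.shape}"
        )
    if not np.all(np.isfinite(vals)):
        raise ConfigurationError(f"non-finite base prediction in {vals!r}")
    return float(vals.mean())


# ---------------------------------------------------------------------------


@dataclass
class FittedForecaster:
    """A fitted regression forecaster: predicts daily counts for any date
    on or after its feature origin."""

    spec: EstimatorSpec
    origin: dt.date
    holidays: HolidayCalendar | None
    season: SeasonalityConfig
    _impl: object
    training_start: dt.date
    training_end: dt.date

    def predict(self, dates: Sequence[dt.date]) -> np.ndarray:
        """Point forecasts, clipped at zero, one per date."""
        X = design_matrix(dates, self.origin, self.holidays, self.season)
        return np.clip(self._impl.predict(X), 0.0, None)

    def predict_one(self, date: dt.date) -> float:
        return float(self.predict([date])[0])

    @property
    def params_(self) -> pd.Series:
        """Fitted coefficients (GLM families only)."""
        return self._impl.params

    @property
    def bse_(self) -> pd.Series:
        """Coefficient standard errors (GLM families only)."""
        return self._impl.bse


def fit_forecaster(
    spec: EstimatorSpec,
    training: DailyDemandSeries,
    origin: dt.date | None = None,
    holidays: HolidayCalendar | None = None,
    season: SeasonalityConfig = SeasonalityConfig(),
) -> FittedForecaster:
    """Fit a registered estimator family on a daily demand series.

    The daily counts are the regression targets; the feature matrix is built
    row-per-day from the calendar features. ``origin`` defaults to the
    training series start and anchors the relative day index ``t``.
    """
    if len(training) == 0:
        raise InsufficientHistoryError("cannot fit on an empty training series")
    fam = spec.family
    if fam not in FAMILIES:
        raise ConfigurationError(
            f"unknown estimator family {fam!r}; registry: {', '.join(sorted(FAMILIES))}"
        )
    origin = origin or training.start
    dates = training.dates()
    X = design_matrix(dates, origin, holidays, season)
    y = training.counts.values.astype(float)
    impl = FAMILIES[fam](spec.hyperparams, spec.seed)
    impl.fit(X, y)
    return FittedForecaster(
        spec=spec,
        origin=origin,
        holidays=holidays,
        season=season,
        _impl=impl,
        training_start=training.start,
        training_end=training.end,
    )
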
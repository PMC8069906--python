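"""Irrigation-input PLS model: statsmodels-style Model / Results pair.

:class:`IrrigationPLS` bundles a daily table with a time-lag/time-series
design and the calibration choices (latent-vector count, SPXY model-set
fraction, cross-validation scheme).  :meth:`IrrigationPLS.fit` runs the full
training pipeline —

  build lagged matrix → autoscale → SPXY 80/20 split → NIPALS PLS on the
  model set → leave-one-out cross-validation → calibration and external
  validation metrics

— and returns an :class:`IrrigationPLSResults` carrying the folded
regression coefficients (raw and autoscaled space), the partition, the
metric suite (RMSEC, RMSECV, SEP, bias, RPD, r for model and test sets) and
``summary()`` / serialisation helpers.  Everything is deterministic given the
inputs: SPXY is a deterministic max–min selection and NIPALS has no random
initialisation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import chemometrics as chem
from .design import TLTSDesign, FeatureMatrix, build_tlts_matrix, DEFAULT_DESIGN
from .io import read_daily_csv
from .lags import LagSpec

__all__ = ["IrrigationPLS", "IrrigationPLSResults", "PipelineMetrics", "train_pipeline"]

MODEL_SCHEMA_VERSION = 1


@dataclass(frozen=True)
class PipelineMetrics:
    """Calibration / validation metric suite of a fitted pipeline."""

    n_samples: int
    n_model: int
    n_test: int
    n_lv: int
    rmsec: float
    rmsecv: float
    bias: float            # external (test-set) bias, mm
    sep_model: float
    sep_test: float
    rpd_model: float
    rpd_test: float
    r_model: float
    r_test: float

    def frame(self) -> pd.DataFrame:
        """One-column report table (metric name → value)."""
        d = asdict(self)
        return pd.DataFrame(
            {"value": list(d.values())}, index=pd.Index(d.keys(), name="metric")
        )


class IrrigationPLS:
    """PLS model of daily irrigation water input from weather and lagged
    soil moisture.

    Parameters
    ----------
    daily : DataFrame
        Canonical daily table (see :mod:`irripls.io`), date-indexed.
    design : TLTSDesign
        Lag/window recipe; defaults to the published configuration
        (30 cm lag 1, 60/90 cm lag 2, 2-day window, weather at lag 0).
    n_components : int
        Latent vectors to extract (default 8).
    ms_fraction : float
        SPXY model-set share of the analysis dataset (default 0.8).
    cv_scheme : {"loo", "blocks", None}
        Internal cross-validation of the model set; None skips RMSECV.
    """

    def __init__(
        self,
        daily: pd.DataFrame,
        design: TLTSDesign = DEFAULT_DESIGN,
        n_components: int = 8,
        ms_fraction: float = 0.8,
        cv_scheme: str | None = "loo",
    ) -> None:
        self.daily = daily
        self.design = design
        self.n_components = n_components
        self.ms_fraction = ms_fraction
        self.cv_scheme = cv_scheme

    @classmethod
    def from_csv(cls, path: str | Path, **kwargs) -> "IrrigationPLS":
        return cls(read_daily_csv(path), **kwargs)

    def fit(self) -> "IrrigationPLSResults":
        fm = build_tlts_matrix(self.daily, self.design)
        # a predictor with no variance carries no information and cannot be
        # autoscaled (e.g. a decoupled deep layer in a noise-free scenario):
        # drop it with a warning rather than poison the scaling
        stds = fm.X.std(ddof=1)
        dead = list(fm.X.columns[stds <= 1e-12 * (fm.X.abs().mean() + 1.0)])
        if dead:
            import warnings

            warnings.warn(f"dropping constant predictor column(s): {dead}")
            fm = FeatureMatrix(X=fm.X.drop(columns=dead), y=fm.y, dates=fm.dates)
        X = fm.X.to_numpy()
        y = fm.y.to_numpy()
        n = X.shape[0]

        # SPXY distances are measured in autoscaled joint x–y space of the
        # full analysis dataset; the model's own scaling is then re-estimated
        # on the model set only, so the test set never leaks into calibration.
        Xs_all, _ = chem.autoscale(X, tuple(fm.X.columns))
        ys_all, _ = chem.autoscale(y)
        if self.ms_fraction >= 1.0 or int(round(self.ms_fraction * n)) >= n:
            part = chem.Partition(np.arange(n), np.array([], dtype=int), self.ms_fraction)
        else:
            part = chem.spxy_partition(Xs_all, ys_all, self.ms_fraction)

        Xm, ym = X[part.model_set], y[part.model_set]
        Xs, x_params = chem.autoscale(Xm, tuple(fm.X.columns))
        ys, y_params = chem.autoscale(ym)
        n_lv = min(self.n_components, Xm.shape[0] - 1, Xm.shape[1])
        fit = chem.fit_pls(Xs, ys, n_lv)

        pred_model = chem.inverse_scale(fit.predict(Xs), y_params)
        m_model = chem.compute_metrics(ym, pred_model)

        if part.test_set.size >= 2:
            Xt, yt = X[part.test_set], y[part.test_set]
            pred_test = chem.inverse_scale(
                fit.predict(chem.apply_scaling(Xt, x_params)), y_params
            )
            m_test = chem.compute_metrics(yt, pred_test)
        else:
            m_test = None

        rmsecv = float("nan")
        rmsecv_by_lv = None
        if self.cv_scheme:
            rmsecv_by_lv = chem.cross_validate(Xm, ym, n_lv, scheme=self.cv_scheme)
            rmsecv = float(rmsecv_by_lv[n_lv - 1])

        metrics = PipelineMetrics(
            n_samples=n,
            n_model=part.model_set.size,
            n_test=part.test_set.size,
            n_lv=fit.n_lv,
            rmsec=m_model.rmse,
            rmsecv=rmsecv,
            bias=m_test.bias if m_test else m_model.bias,
            sep_model=m_model.sep,
            sep_test=m_test.sep if m_test else float("nan"),
            rpd_model=m_model.rpd,
            rpd_test=m_test.rpd if m_test else float("nan"),
            r_model=m_model.r,
            r_test=m_test.r if m_test else float("nan"),
        )
        return IrrigationPLSResults(
            model=self,
            feature_matrix=fm,
            partition=part,
            pls=fit,
            x_scaling=x_params,
            y_scaling=y_params,
            metrics=metrics,
            rmsecv_by_lv=rmsecv_by_lv,
        )


class IrrigationPLSResults:
    """Fitted irrigation PLS pipeline: estimates, diagnostics, prediction."""

    def __init__(
        self,
        model: IrrigationPLS | None,
        feature_matrix: FeatureMatrix | None,
        partition: chem.Partition,
        pls: chem.PLSFit,
        x_scaling: chem.ScalingParams,
        y_scaling: chem.ScalingParams,
        metrics: PipelineMetrics,
        rmsecv_by_lv: np.ndarray | None = None,
    ) -> None:
        self.model = model
        self.feature_matrix = feature_matrix
        self.partition = partition
        self.pls = pls
        self.x_scaling = x_scaling
        self.y_scaling = y_scaling
        self.metrics = metrics
        self.rmsecv_by_lv = rmsecv_by_lv

    # -- parameters ---------------------------------------------------------

    @property
    def columns(self) -> tuple[str, ...]:
        return tuple(self.x_scaling.columns)

    @property
    def design(self) -> TLTSDesign:
        return self.model.design if self.model is not None else self._design

    @property
    def _y_mean(self) -> float:
        return float(np.ravel(self.y_scaling.mean)[0])

    @property
    def _y_std(self) -> float:
        return float(np.ravel(self.y_scaling.std)[0])

    @property
    def params(self) -> pd.Series:
        """Raw-space regression coefficients (mm of irrigation per unit of
        each predictor), scaling folded in."""
        beta = self.pls.coef * self._y_std / self.x_scaling.std
        return pd.Series(beta, index=list(self.columns), name="coef")

    @property
    def intercept(self) -> float:
        beta = self.params.to_numpy()
        return float(self._y_mean - beta @ self.x_scaling.mean)

    # -- prediction ---------------------------------------------------------

    def predict_rows(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        """Predict irrigation (mm/day, unclipped) for pre-built feature rows.

        Accepts a DataFrame with the training columns (any order) or a bare
        array in training column order.
        """
        if isinstance(X, pd.DataFrame):
            X = X[list(self.columns)].to_numpy()
        X = np.atleast_2d(np.asarray(X, dtype=float))
        scaled = chem.apply_scaling(X, self.x_scaling)
        return chem.inverse_scale(self.pls.predict(scaled), self.y_scaling)

    def predict(self, daily: pd.DataFrame) -> pd.Series:
        """Predict irrigation for each usable day of a daily table."""
        fm = build_tlts_matrix(daily, self.design)
        return pd.Series(self.predict_rows(fm.X), index=fm.dates, name="predicted_mm")

    def fittedvalues(self) -> pd.Series:
        fm = self.feature_matrix
        return pd.Series(self.predict_rows(fm.X), index=fm.dates, name="fitted_mm")

    # -- reporting ----------------------------------------------------------

    def summary(self) -> str:
        m = self.metrics
        lags = ", ".join(
            f"{d} cm: {l} d" for d, l in sorted(self.design.soil_lags.lags.items())
        )
        lines = [
            "Irrigation water input — PLS (time-lag / time-series)",
            "=" * 56,
            f"No. of samples            {m.n_samples}",
            f"Model set / test set      {m.n_model} / {m.n_test}",
            f"Preprocessing             autoscale",
            f"No. of LVs                {m.n_lv}",
            f"Soil-moisture lags        {lags}",
            f"TimeSeries window         {self.design.ts_window} d",
            "-" * 56,
            f"RMSEC        (mm)         {m.rmsec:8.3f}",
            f"RMSECV       (mm)         {m.rmsecv:8.3f}",
            f"Bias (test)  (mm)         {m.bias:8.3f}",
            f"SEP model    (mm)         {m.sep_model:8.3f}",
            f"SEP test     (mm)         {m.sep_test:8.3f}",
            f"RPD model                 {m.rpd_model:8.3f}",
            f"RPD test                  {m.rpd_test:8.3f}",
            f"r model ({100 * (1 - (m.n_test / m.n_samples if m.n_samples else 0)):.0f}%)             {m.r_model:8.3f}",
            f"r test                    {m.r_test:8.3f}",
            "=" * 56,
        ]
        return "\n".join(lines)

    # -- serialisation ------------------------------------------------------

    def to_dict(self) -> dict:
        d = self.design
        return {
            "schema_version": MODEL_SCHEMA_VERSION,
            "design": {
                "weather_vars": list(d.weather_vars),
                "soil_lags": {str(k): v for k, v in d.soil_lags.lags.items()},
                "ts_window": d.ts_window,
                "response": d.response,
            },
            "columns": list(self.columns),
            "x_mean": self.x_scaling.mean.tolist(),
            "x_std": self.x_scaling.std.tolist(),
            "y_mean": self._y_mean,
            "y_std": self._y_std,
            "coef_scaled": self.pls.coef.tolist(),
            "n_lv": self.pls.n_lv,
            "metrics": asdict(self.metrics),
            "model_set": self.partition.model_set.tolist(),
            "test_set": self.partition.test_set.tolist(),
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "IrrigationPLSResults":
        d = json.loads(Path(path).read_text())
        if d.get("schema_version") != MODEL_SCHEMA_VERSION:
            raise ValueError(f"unsupported model schema: {d.get('schema_version')}")
        design = TLTSDesign(
            weather_vars=tuple(d["design"]["weather_vars"]),
            soil_lags=LagSpec({int(k): v for k, v in d["design"]["soil_lags"].items()}),
            ts_window=d["design"]["ts_window"],
            response=d["design"]["response"],
        )
        cols = tuple(d["columns"])
        x_params = chem.ScalingParams(
            np.array(d["x_mean"]), np.array(d["x_std"]), cols
        )
        y_params = chem.ScalingParams(
            np.array(d["y_mean"]), np.array(d["y_std"]), None
        )
        coef = np.array(d["coef_scaled"])
        p = coef.size
        pls = chem.PLSFit(
            n_lv=d["n_lv"],
            weights=np.zeros((p, 0)),
            x_loadings=np.zeros((p, 0)),
            y_loadings=np.zeros(0),
            scores=np.zeros((0, 0)),
            coef=coef,
            explained_x_variance=np.zeros(0),
        )
        metrics = PipelineMetrics(**d["metrics"])
        part = chem.Partition(
            np.array(d["model_set"], dtype=int),
            np.array(d["test_set"], dtype=int),
            fraction=len(d["model_set"]) / max(1, len(d["model_set"]) + len(d["test_set"])),
        )
        obj = cls(
            model=None,
            feature_matrix=None,
            partition=part,
            pls=pls,
            x_scaling=x_params,
            y_scaling=y_params,
            metrics=metrics,
        )
        obj._design = design
        return obj


def train_pipeline(
    daily: pd.DataFrame,
    design: TLTSDesign = DEFAULT_DESIGN,
    fraction: float = 0.8,
    n_lv: int = 8,
    cv_scheme: str | None = "loo",
) -> IrrigationPLSResults:
    """Functional wrapper: build → autoscale → SPXY → fit → CV → metrics."""
    return IrrigationPLS(
        daily, design=design, n_components=n_lv,
        ms_fraction=fraction, cv_scheme=cv_scheme,
    ).fit()
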
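"""Sparse prediction of pitch-labeling ability from FFR features.

The estimator is L1-penalised least squares in the parameterisation

    L(beta) = SSE(beta) + lambda * sum_j |beta_j|,

fit by coordinate descent (:mod:`ffrpitch._solver`). The penalty weight is
chosen by leave-one-out cross-validation over a log-spaced grid spanning
0.01 to 1e10, and generalisation is measured by repeated random 2/3-1/3
train/test splits: on each of (by default) 1000 runs the model is tuned
and refit on the training two-thirds and scored by the Pearson
correlation r between its predictions and the held-out truth. The full
r distribution feeds the Fisher-z inference in :mod:`ffrpitch.inference`.

The user-facing surface follows the familiar model/results pattern::

    model = LassoPitchModel.from_dataframe(df, response="ap_logit")
    res = model.fit()          # full-data sparse fit, normalised units
    print(res.summary())
    cv = model.fit_repeated_cv(n_runs=1000, base_seed=1)

Predictors are z-scored and the response standardised internally, so
coefficients are in normalised units and the full-data intercept is zero
to machine precision.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._solver import cd_lasso, loocv_mse_path

__all__ = [
    "LassoFit",
    "CVResultSet",
    "LassoPitchModel",
    "LassoPitchResults",
    "default_lambda_grid",
    "lasso_fit",
    "select_lambda_loocv",
    "cv_run",
    "repeated_cv",
    "fit_full_model",
]


def default_lambda_grid(num: int = 50) -> np.ndarray:
    """Log-spaced penalty grid spanning 0.01 to 1e10 (ascending)."""
    return np.logspace(-2.0, 10.0, num)


# ---------------------------------------------------------------------------
# functional layer


@dataclass(frozen=True)
class LassoFit:
    """A single penalised fit: coefficients in the units of the (scaled)
    design, the intercept, and the penalty weight used."""

    coefficients: pd.Series
    intercept: float
    lam: float

    @property
    def support(self) -> list:
        """Names of predictors with nonzero coefficients."""
        return list(self.coefficients.index[self.coefficients != 0.0])


@dataclass(frozen=True)
class CVResultSet:
    """Per-run held-out correlations from repeated train/test evaluation."""

    r_values: np.ndarray = field(repr=False)
    chosen_lambdas: np.ndarray = field(repr=False)
    split_seeds: np.ndarray = field(repr=False)
    model_label: str = ""

    def __post_init__(self):
        if np.any(np.abs(self.r_values) > 1.0 + 1e-12):
            raise ValueError("correlations must lie in [-1, 1]")
        if not (len(self.r_values) == len(self.chosen_lambdas) == len(self.split_seeds)):
            raise ValueError("per-run arrays must share a length")

    @property
    def n_runs(self) -> int:
        return len(self.r_values)

    @property
    def mean_r(self) -> float:
        return float(np.mean(self.r_values))

    def to_dict(self) -> dict:
        return {
            "model_label": self.model_label,
            "r_values": self.r_values.tolist(),
            "chosen_lambdas": self.chosen_lambdas.tolist(),
            "split_seeds": self.split_seeds.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CVResultSet":
        return cls(
            r_values=np.asarray(d["r_values"], float),
            chosen_lambdas=np.asarray(d["chosen_lambdas"], float),
            split_seeds=np.asarray(d["split_seeds"]),
            model_label=d.get("model_label", ""),
        )

    def save_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def load_json(cls, path) -> "CVResultSet":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _as_matrix(X):
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(float), list(X.columns)
    X = np.asarray(X, float)
    return X, [f"x{j}" for j in range(X.shape[1])]


def lasso_fit(X, y, lam: float) -> LassoFit:
    """Minimise ``SSE(beta) + lam * sum|beta|`` on the given design.

    ``X`` is expected z-scored per column and ``y`` centered (the solver
    fits no intercept); zero-variance columns are rejected.
    """
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    Xm, names = _as_matrix(X)
    y = np.asarray(y, float)
    if np.any(Xm.std(axis=0) == 0.0):
        bad = [names[j] for j in np.flatnonzero(Xm.std(axis=0) == 0.0)]
        raise ValueError(f"zero-variance predictor column(s): {bad}")
    beta = cd_lasso(Xm, y, lam)
    return LassoFit(coefficients=pd.Series(beta, index=names), intercept=0.0, lam=lam)


def select_lambda_loocv(X, y, lambda_grid=None) -> float:
    """Penalty minimising the leave-one-out mean squared prediction error.

    Ties (within a 1e-10 relative band of the minimum) break toward the
    largest, i.e. sparsest, penalty.
    """
    Xm, _ = _as_matrix(X)
    y = np.asarray(y, float)
    if len(y) < 3:
        raise ValueError("need at least 3 observations for LOOCV selection")
    if np.std(y) == 0.0:
        raise ValueError("response has zero variance")
    grid = default_lambda_grid() if lambda_grid is None else np.asarray(lambda_grid, float)
    mse = loocv_mse_path(Xm, y, grid)
    best = mse.min()
    ok = mse <= best * (1.0 + 1e-10) + 1e-300
    return float(grid[ok].max())


def _standardize_train(Xtr, ytr):
    mx = Xtr.mean(axis=0)
    sx = Xtr.std(axis=0)
    degenerate = sx == 0.0
    sx = np.where(degenerate, 1.0, sx)
    my = ytr.mean()
    sy = ytr.std()
    return mx, sx, degenerate, my, sy


def cv_run(X, y, seed: int, lambda_grid=None) -> tuple:
    """One train/test evaluation round.

    Random 2/3-1/3 split (train size = ceil(2n/3)), LOOCV penalty choice
    and refit on the training set, Pearson r between predictions and truth
    on the test set. A constant prediction (or constant test response)
    yields r = 0 with a warning. Returns ``(r, chosen_lambda)``.
    """
    Xm, _ = _as_matrix(X)
    yv = np.asarray(y, float)
    n = len(yv)
    if n < 6:
        raise ValueError("need at least 6 observations for a 2/3-1/3 split")
    grid = default_lambda_grid() if lambda_grid is None else np.asarray(lambda_grid, float)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(np.ceil(2 * n / 3))
    tr, te = perm[:n_train], perm[n_train:]

    mx, sx, degenerate, my, sy = _standardize_train(Xm[tr], yv[tr])
    if sy == 0.0:
        raise ValueError("training response has zero variance")
    Ztr = (Xm[tr] - mx) / sx
    Ztr[:, degenerate] = 0.0  # constant-in-train columns carry no signal
    Zte = (Xm[te] - mx) / sx
    Zte[:, degenerate] = 0.0
    ytr = (yv[tr] - my) / sy

    mse = loocv_mse_path(Ztr, ytr, grid)
    ok = mse <= mse.min() * (1.0 + 1e-10) + 1e-300
    lam = float(grid[ok].max())
    beta = cd_lasso(Ztr, ytr, lam)
    pred = Zte @ beta
    if np.std(pred) == 0.0 or np.std(yv[te]) == 0.0:
        warnings.warn("constant prediction on test set; r set to 0")
        return 0.0, lam
    r = float(np.corrcoef(pred, yv[te])[0, 1])
    return r, lam


def repeated_cv(X, y, n_runs: int = 1000, base_seed: int = 0,
                lambda_grid=None, model_label: str = "") -> CVResultSet:
    """Repeat :func:`cv_run` with fresh random splits, retaining the full
    distribution of held-out r values."""
    seeds = np.random.SeedSequence(base_seed).generate_state(n_runs)
    rs = np.empty(n_runs)
    lams = np.empty(n_runs)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant-prediction runs are expected under the null
        for i, s in enumerate(seeds):
            rs[i], lams[i] = cv_run(X, y, int(s), lambda_grid)
    return CVResultSet(r_values=rs, chosen_lambdas=lams,
                       split_seeds=seeds, model_label=model_label)


def fit_full_model(X, y, lambda_grid=None) -> LassoFit:
    """Sparse fit on the full dataset in normalised units.

    Predictors are z-scored and the response standardised, the penalty is
    chosen by LOOCV over the full data, and the fit is reported on that
    normalised scale (intercept is zero up to machine precision).
    """
    Xm, names = _as_matrix(X)
    yv = np.asarray(y, float)
    sx = Xm.std(axis=0)
    if np.any(sx == 0.0):
        bad = [names[j] for j in np.flatnonzero(sx == 0.0)]
        raise ValueError(f"zero-variance predictor column(s): {bad}")
    if yv.std() == 0.0:
        raise ValueError("response has zero variance")
    Z = (Xm - Xm.mean(axis=0)) / sx
    yz = (yv - yv.mean()) / yv.std()
    lam = select_lambda_loocv(pd.DataFrame(Z, columns=names), yz, lambda_grid)
    beta = cd_lasso(Z, yz, lam)
    intercept = float(yz.mean() - Z.mean(axis=0) @ beta)
    return LassoFit(coefficients=pd.Series(beta, index=names), intercept=intercept, lam=lam)


# ---------------------------------------------------------------------------
# model / results objects


class LassoPitchModel:
    """Penalised linear model of a (logit-scale) ability score.

    Parameters
    ----------
    y : array-like or Series
        Response (e.g. logit-transformed conservative AP score).
    X : DataFrame or 2-D array
        Predictor table (e.g. harmonic powers F0, H2, ...; raw scale --
        standardisation happens inside each fit).
    lambda_grid : array-like, optional
        Penalty grid; defaults to 50 log-spaced values in [0.01, 1e10].
    """

    def __init__(self, y, X, lambda_grid=None, label: str = ""):
        self.X = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, float))
        self.y = pd.Series(np.asarray(y, float), index=self.X.index, name="y")
        if len(self.y) != len(self.X):
            raise ValueError("y and X must have the same number of rows")
        self.lambda_grid = (default_lambda_grid() if lambda_grid is None
                            else np.asarray(lambda_grid, float))
        self.label = label
        self.exog_names = list(self.X.columns)

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, response: str,
                       predictors=None, **kw) -> "LassoPitchModel":
        """Build from one table holding the response and predictor columns."""
        if predictors is None:
            predictors = [c for c in data.columns if c != response]
        return cls(data[response], data[predictors], **kw)

    def fit(self, lam: float | None = None) -> "LassoPitchResults":
        """Full-data fit in normalised units; ``lam`` defaults to the
        LOOCV-selected penalty."""
        if lam is None:
            fit = fit_full_model(self.X, self.y, self.lambda_grid)
        else:
            Z = (self.X - self.X.mean()) / self.X.std(ddof=0)
            yz = (self.y - self.y.mean()) / self.y.std(ddof=0)
            fit = lasso_fit(Z, yz, lam)
        return LassoPitchResults(self, fit)

    def fit_repeated_cv(self, n_runs: int = 1000, base_seed: int = 0) -> CVResultSet:
        """Repeated nested cross-validation; see :func:`repeated_cv`."""
        return repeated_cv(self.X, self.y, n_runs=n_runs, base_seed=base_seed,
                           lambda_grid=self.lambda_grid,
                           model_label=self.label)


class LassoPitchResults:
    """Results wrapper: sparse coefficients plus convenience accessors."""

    def __init__(self, model: LassoPitchModel, fit: LassoFit):
        self.model = model
        self._fit = fit
        self.params = fit.coefficients
        self.intercept = fit.intercept
        self.lam = fit.lam

    @property
    def support(self) -> list:
        return self._fit.support

    def predict(self, X_new=None) -> pd.Series:
        """Predictions on the original response scale."""
        X = self.model.X if X_new is None else X_new[self.model.exog_names]
        mx = self.model.X.mean()
        sx = self.model.X.std(ddof=0).replace(0.0, 1.0)
        Z = (X - mx) / sx
        yz = Z @ self.params + self.intercept
        return self.model.y.mean() + self.model.y.std(ddof=0) * yz

    def summary(self) -> str:
        """Plain-text summary table (normalised-unit coefficients)."""
        lines = [
            f"Penalised linear model{': ' + self.model.label if self.model.label else ''}",
            f"  n = {len(self.model.y)}, p = {len(self.params)}, "
            f"lambda = {self.lam:.6g}",
            f"  intercept = {self.intercept:.3e} (normalised units)",
            "",
            f"  {'predictor':<16}{'coef':>12}",
            "  " + "-" * 28,
        ]
        for name, b in self.params.items():
            mark = "" if b == 0.0 else "  *"
            lines.append(f"  {name:<16}{b:>12.4g}{mark}")
        lines.append("")
        lines.append(f"  nonzero predictors: {self.support or 'none'}")
        return "\n".join(lines)

    def __repr__(self):
        return (f"<LassoPitchResults n={len(self.model.y)} "
                f"support={self.support}>")
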
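"""Presence-background maximum-entropy model (Gibbs / inhomogeneous Poisson).

The model estimates a probability distribution over landscape cells from
presence records and a background sample by maximizing the penalized
log-likelihood

    sum_presence beta.f(x)  -  n_p * log sum_background exp(beta.f(x))
                             -  lambda * ||beta||_1,

the standard maximum-entropy objective for presence-background data (the
Gibbs form of an inhomogeneous Poisson point process intensity). Features
``f`` are built from standardized predictors: linear and quadratic terms by
default, optionally pairwise products and hinge basis functions with knots
at training quantiles.

The API follows the Model/Results convention: construct a
:class:`MaxentModel` from presence and background predictor values, call
``fit()`` to obtain a :class:`MaxentResults` carrying coefficients,
normalization, diagnostics, permutation importances, response curves,
presence-only AICc and a ``summary()`` table.

The L1 penalty is handled exactly by splitting ``beta = beta+ - beta-`` with
nonnegativity bounds, which turns the non-smooth problem into a smooth
bound-constrained one solved by L-BFGS-B; the fit is deterministic given the
inputs.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

from .metrics import auc
from .raster import PredictorStack, Raster

logger = logging.getLogger(__name__)

__all__ = ["FeatureSpec", "MaxentModel", "MaxentResults", "fit", "default_lambda"]


def default_lambda(n_presence: int) -> float:
    """Default L1 weight: 0.05 * sqrt(ln n_p), shrinking noise coefficients
    while leaving strong effects nearly unpenalized on the standardized scale."""
    return 0.05 * float(np.sqrt(np.log(max(n_presence, 2))))


@dataclass
class FeatureSpec:
    """Feature expansion recipe applied to standardized predictors."""

    classes: frozenset = frozenset({"linear", "quadratic"})
    n_hinge_knots: int = 8

    def __post_init__(self):
        classes = frozenset(self.classes)
        unknown = classes - {"linear", "quadratic", "product", "hinge"}
        if unknown:
            raise ValueError(f"unknown feature classes: {sorted(unknown)}")
        if "linear" not in classes:
            raise ValueError("feature classes must include 'linear'")
        object.__setattr__(self, "classes", classes)


@dataclass
class _Expansion:
    """Frozen feature map: standardization constants, hinge knots, pruning."""

    variables: list
    means: np.ndarray
    sds: np.ndarray
    spec: FeatureSpec
    hinge_knots: dict = field(default_factory=dict)
    feature_names: list = field(default_factory=list)
    feature_variable: list = field(default_factory=list)  # source variable per column
    keep: np.ndarray | None = None  # post-pruning column selector

    def transform(self, X: np.ndarray) -> np.ndarray:
        Z = (np.asarray(X, float) - self.means) / self.sds
        cols, names, src = [], [], []
        for j, v in enumerate(self.variables):
            cols.append(Z[:, j]); names.append(v); src.append(v)
        if "quadratic" in self.spec.classes:
            for j, v in enumerate(self.variables):
                cols.append(Z[:, j] ** 2); names.append(f"{v}^2"); src.append(v)
        if "product" in self.spec.classes:
            for j in range(len(self.variables)):
                for k in range(j + 1, len(self.variables)):
                    cols.append(Z[:, j] * Z[:, k])
                    names.append(f"{self.variables[j]}*{self.variables[k]}")
                    src.append(self.variables[j])
        if "hinge" in self.spec.classes:
            for j, v in enumerate(self.variables):
                for q, knot in enumerate(self.hinge_knots.get(v, [])):
                    cols.append(np.maximum(Z[:, j] - knot, 0.0))
                    names.append(f"hinge({v},{q})"); src.append(v)
        F = np.column_stack(cols)
        if not self.feature_names:
            self.feature_names = names
            self.feature_variable = src
        if self.keep is not None:
            F = F[:, self.keep]
        return F


class MaxentModel:
    """Presence-background maximum-entropy model.

    Parameters
    ----------
    presence : (n_p, n_vars) array
        Predictor values at presence cells.
    background : (n_b, n_vars) array
        Predictor values at the background sample.
    variables : sequence of str
        Predictor names, one per column.
    features : FeatureSpec, optional
        Feature expansion; default linear + quadratic.
    reg_lambda : float, optional
        L1 penalty weight; default ``0.05 * sqrt(ln n_p)``.
    """

    def __init__(self, presence, background, variables, features: FeatureSpec | None = None,
                 reg_lambda: float | None = None, metadata: dict | None = None):
        presence = np.atleast_2d(np.asarray(presence, float))
        background = np.atleast_2d(np.asarray(background, float))
        if presence.shape[0] < 2:
            raise ValueError("need at least 2 presence records")
        if presence.shape[1] != background.shape[1]:
            raise ValueError("presence and background must share columns")
        variables = list(variables)
        if len(variables) != presence.shape[1]:
            raise ValueError("one variable name per column required")
        ok_p = np.isfinite(presence).all(axis=1)
        ok_b = np.isfinite(background).all(axis=1)
        if not ok_p.all() or not ok_b.all():
            logger.warning("dropping %d presence / %d background rows with missing values",
                           int((~ok_p).sum()), int((~ok_b).sum()))
            presence, background = presence[ok_p], background[ok_b]
        if presence.shape[0] < 2:
            raise ValueError("fewer than 2 complete presence records")

        # drop predictors constant across presence AND background
        pooled = np.vstack([presence, background])
        sd = pooled.std(axis=0)
        keep_vars = sd > 0
        if not keep_vars.all():
            dropped = [v for v, k in zip(variables, keep_vars) if not k]
            logger.warning("dropping constant predictor(s): %s", dropped)
            variables = [v for v, k in zip(variables, keep_vars) if k]
            presence, background = presence[:, keep_vars], background[:, keep_vars]
            pooled = pooled[:, keep_vars]
            sd = sd[keep_vars]
        if not variables:
            raise ValueError("all predictors are constant")

        self.presence = presence
        self.background = background
        self.variables = variables
        self.features = features or FeatureSpec()
        self.reg_lambda = (default_lambda(len(presence))
                           if reg_lambda is None else float(reg_lambda))
        self.metadata = dict(metadata or {})

        exp_ = _Expansion(variables=variables, means=pooled.mean(axis=0),
                          sds=sd.astype(float), spec=self.features)
        if "hinge" in self.features.classes:
            Zp = (pooled - exp_.means) / exp_.sds
            qs = np.linspace(0, 1, self.features.n_hinge_knots + 2)[1:-1]
            for j, v in enumerate(variables):
                exp_.hinge_knots[v] = list(np.quantile(Zp[:, j], qs))
        F_all = exp_.transform(pooled)
        exp_.keep = _prune_collinear(F_all)
        n_drop = int((~exp_.keep).sum())
        if n_drop:
            logger.warning("pruned %d collinear/degenerate feature column(s)", n_drop)
        self.expansion = exp_
        self.F_presence = exp_.transform(presence)
        self.F_background = exp_.transform(background)

    @classmethod
    def from_dataframe(cls, presence_df, background_df, variables=None, **kw):
        """Build from presence/background DataFrames sharing predictor columns."""
        if variables is None:
            variables = [c for c in presence_df.columns if c in background_df.columns]
        return cls(presence_df[variables].to_numpy(float),
                   background_df[variables].to_numpy(float), variables, **kw)

    # objective -------------------------------------------------------------

    def loglike(self, beta: np.ndarray) -> float:
        """Unpenalized log-likelihood of the Gibbs model."""
        sp = self.F_presence @ beta
        lse = logsumexp(self.F_background @ beta)
        return float(sp.sum() - len(sp) * lse)

    def _negloglike_grad(self, beta):
        n_p = self.F_presence.shape[0]
        sb = self.F_background @ beta
        lse = logsumexp(sb)
        w = np.exp(sb - lse)  # Gibbs probabilities over background
        nll = -(self.F_presence @ beta).sum() + n_p * lse
        grad = -self.F_presence.sum(axis=0) + n_p * (w @ self.F_background)
        return nll, grad

    def fit(self, maxiter: int = 500, tol: float = 1e-8, seed: int | None = None,
            start_params: np.ndarray | None = None) -> "MaxentResults":
        """Maximize the penalized log-likelihood; deterministic given inputs.

        ``seed`` is recorded in the metadata for provenance; the optimizer
        itself is deterministic.
        """
        k = self.F_presence.shape[1]
        lam = self.reg_lambda  # penalty applies to the summed log-likelihood
        x0 = np.zeros(2 * k)
        if start_params is not None:
            x0[:k] = np.maximum(start_params, 0)
            x0[k:] = np.maximum(-start_params, 0)

        def objective(x):
            beta = x[:k] - x[k:]
            nll, grad = self._negloglike_grad(beta)
            val = nll + lam * x.sum()
            g = np.concatenate([grad + lam, -grad + lam])
            return val, g

        res = minimize(objective, x0, jac=True, method="L-BFGS-B",
                       bounds=[(0, None)] * (2 * k),
                       options={"maxiter": maxiter, "ftol": tol, "gtol": 1e-10})
        beta = res.x[:k] - res.x[k:]
        beta[np.abs(beta) < 1e-10] = 0.0
        if not res.success and "MAXITER" not in str(res.message).upper():
            logger.warning("optimizer stopped: %s", res.message)
        sb = self.F_background @ beta
        log_alpha = float(logsumexp(sb))
        log_raw_bg = sb - log_alpha
        entropy = float(-(np.exp(log_raw_bg) * log_raw_bg).sum())
        meta = dict(self.metadata)
        if seed is not None:
            meta["seed"] = seed
        meta.update(n_iter=int(res.nit), converged=bool(res.success),
                    reg_lambda=self.reg_lambda)
        return MaxentResults(self, beta=beta, log_alpha=log_alpha,
                             entropy=entropy, metadata=meta)


def _prune_collinear(F: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    """Greedy rank-revealing selector: keep columns that add rank; drop
    constants and exact/near duplicates."""
    n, k = F.shape
    keep = np.zeros(k, bool)
    basis = []
    for j in range(k):
        col = F[:, j]
        if col.std() <= tol * (1 + np.abs(col).max()):
            continue
        v = col - col.mean()
        v = v / np.linalg.norm(v)
        for b in basis:
            v = v - (v @ b) * b
        nv = np.linalg.norm(v)
        if nv > 1e-6:
            basis.append(v / nv)
            keep[j] = True
    return keep


class MaxentResults:
    """Fitted maximum-entropy model: coefficients, normalization, diagnostics."""

    def __init__(self, model: MaxentModel, beta, log_alpha, entropy, metadata):
        self.model = model
        self.params = np.asarray(beta, float)
        self.log_alpha = float(log_alpha)
        self.entropy = float(entropy)
        self.metadata = metadata

    @property
    def feature_names(self) -> list[str]:
        names = self.model.expansion.feature_names
        keep = self.model.expansion.keep
        return [n for n, k in zip(names, keep) if k]

    @property
    def df_model(self) -> int:
        """K for information criteria: count of nonzero coefficients."""
        return int(np.count_nonzero(self.params))

    # prediction ------------------------------------------------------------

    def linpred(self, X) -> np.ndarray:
        F = self.model.expansion.transform(np.atleast_2d(np.asarray(X, float)))
        return F @ self.params

    def predict(self, X=None, scale: str = "raw") -> np.ndarray:
        """Predict at predictor rows ``X`` (default: training background).

        ``raw`` is the Gibbs probability normalized over the training
        background (sums to 1 there); ``cloglog`` is the bounded (0, 1)
        suitability scale ``1 - exp(-exp(H) * raw)`` with H the entropy of
        the raw training distribution.
        """
        if X is None:
            X = self.model.background
        log_raw = self.linpred(X) - self.log_alpha
        if scale == "raw":
            return np.exp(log_raw)
        if scale == "cloglog":
            # cap the inner exponent: beyond ~50 the output is 1 to machine precision
            return 1.0 - np.exp(-np.exp(np.minimum(self.entropy + log_raw, 50.0)))
        raise ValueError(f"unknown scale {scale!r}")

    def predict_raster(self, stack: PredictorStack, scale: str = "cloglog") -> Raster:
        """Predict over every valid cell of a predictor stack."""
        missing = [v for v in self.model.variables if v not in stack.layers]
        if missing:
            raise KeyError(f"stack is missing model variable(s): {missing}")
        sub = stack.subset(self.model.variables)
        X, idx = sub.table()
        pred = self.predict(X, scale=scale)
        template = stack.template
        out = np.full(template.values.size, np.nan)
        out[idx] = pred
        return Raster(out.reshape(template.shape), x0=template.x0,
                      y0=template.y0, cell=template.cell, nodata=None)

    # diagnostics -----------------------------------------------------------

    def training_auc(self) -> float:
        return auc(self.predict(self.model.presence), self.predict(self.model.background))

    def permutation_importance(self, seed: int = 0) -> dict[str, float]:
        """AUC-drop permutation importance, normalized to percentages.

        Each predictor's values are permuted jointly across the pooled
        training presence and background rows; the drop in training AUC
        (floored at zero) is recorded and the drops are normalized to sum
        to 100.
        """
        rng = np.random.default_rng(seed)
        n_p = len(self.model.presence)
        pooled = np.vstack([self.model.presence, self.model.background])
        base_auc = self.training_auc()
        drops = {}
        for j, v in enumerate(self.model.variables):
            perm = pooled.copy()
            perm[:, j] = rng.permutation(perm[:, j])
            pred = self.predict(perm)
            a = auc(pred[:n_p], pred[n_p:])
            drops[v] = max(0.0, base_auc - a)
        total = sum(drops.values())
        if total <= 0:
            # no variable matters (e.g. null model): spread evenly
            return {v: 100.0 / len(drops) for v in drops}
        return {v: 100.0 * d / total for v, d in drops.items()}

    def response_curve(self, variable: str, n_points: int = 100) -> tuple[np.ndarray, np.ndarray]:
        """cloglog suitability along one predictor's observed training range,
        all other predictors held at their training means."""
        if variable not in self.model.variables:
            raise KeyError(f"unknown variable {variable!r}")
        j = self.model.variables.index(variable)
        pooled = np.vstack([self.model.presence, self.model.background])
        grid = np.linspace(pooled[:, j].min(), pooled[:, j].max(), n_points)
        X = np.tile(pooled.mean(axis=0), (n_points, 1))
        X[:, j] = grid
        return grid, self.predict(X, scale="cloglog")

    def aicc(self, presence=None, background=None) -> float:
        """Presence-only AICc with K = nonzero coefficients.

        The likelihood normalizes the raw prediction over the supplied
        background (by default the training background); returns NaN when
        the correction is undefined (n <= K + 1).
        """
        X_p = self.model.presence if presence is None else np.atleast_2d(presence)
        X_b = self.model.background if background is None else np.atleast_2d(background)
        n = len(X_p)
        K = self.df_model
        if n <= K + 1:
            return float("nan")
        sp = self.linpred(X_p)
        lse = logsumexp(self.linpred(X_b))
        ll = float(sp.sum() - n * lse)
        aic = 2 * K - 2 * ll
        return aic + 2 * K * (K + 1) / (n - K - 1)

    # reporting / serialization ----------------------------------------------

    def summary(self) -> str:
        lines = [
            "Maximum-entropy presence-background model",
            "=" * 57,
            f"presence records:   {len(self.model.presence)}",
            f"background records: {len(self.model.background)}",
            f"feature classes:    {', '.join(sorted(self.model.features.classes))}",
            f"L1 weight:          {self.model.reg_lambda:.5f}",
            f"nonzero features:   {self.df_model} / {len(self.params)}",
            f"training AUC:       {self.training_auc():.4f}",
            f"background entropy: {self.entropy:.4f}",
            "-" * 57,
            f"{'feature':<32}{'coef':>12}",
        ]
        for name, b in zip(self.feature_names, self.params):
            lines.append(f"{name:<32}{b:>12.5f}")
        lines.append("=" * 57)
        return "\n".join(lines)

    def to_json(self, path=None):
        exp_ = self.model.expansion
        obj = {
            "variables": self.model.variables,
            "feature_classes": sorted(self.model.features.classes),
            "n_hinge_knots": self.model.features.n_hinge_knots,
            "hinge_knots": {k: list(v) for k, v in exp_.hinge_knots.items()},
            "means": list(exp_.means),
            "sds": list(exp_.sds),
            "keep": [bool(k) for k in exp_.keep],
            "beta": list(self.params),
            "log_alpha": self.log_alpha,
            "entropy": self.entropy,
            "reg_lambda": self.model.reg_lambda,
            "metadata": {k: v for k, v in self.metadata.items()
                         if isinstance(v, (int, float, str, bool, type(None)))},
        }
        if path is None:
            return json.dumps(obj, indent=2)
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=2)


def fit(presence_values, background_values, variables=None,
        features: FeatureSpec | None = None, reg_lambda: float | None = None,
        seed: int | None = None) -> MaxentResults:
    """Convenience one-call fit; see :class:`MaxentModel`."""
    presence_values = np.atleast_2d(np.asarray(presence_values, float))
    if variables is None:
        variables = [f"x{j}" for j in range(presence_values.shape[1])]
    model = MaxentModel(presence_values, background_values, variables,
                        features=features, reg_lambda=reg_lambda)
    return model.fit(seed=seed)
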
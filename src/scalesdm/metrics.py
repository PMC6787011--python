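"""Accuracy metrics for presence-background models and cross-extent transfer.

AUC is computed in its rank (Mann-Whitney) form with mid-rank tie handling;
the true skill statistic is maximized exactly over all unique predicted
values; the "correlation coefficient" is the point-biserial Pearson
correlation between predictions and the presence/background label on the
pooled test sample. Fold results are averaged metric-wise (thresholds are
never re-optimized on the average).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "EvalResult",
    "auc",
    "max_tss",
    "point_biserial",
    "evaluate",
    "evaluate_folds",
    "transfer_evaluate",
]


def auc(pred_presence, pred_background) -> float:
    """Rank-based AUC: P(presence prediction > background prediction),
    ties counted half."""
    p = np.asarray(pred_presence, float).ravel()
    b = np.asarray(pred_background, float).ravel()
    if p.size == 0 or b.size == 0:
        raise ValueError("auc requires non-empty presence and background predictions")
    ranks = rankdata(np.concatenate([p, b]))
    u = ranks[: p.size].sum() - p.size * (p.size + 1) / 2
    return float(u / (p.size * b.size))


def max_tss(pred_presence, pred_background) -> tuple[float, float]:
    """Maximum true skill statistic and the smallest maximizing threshold.

    Sweeps every unique predicted value as a candidate threshold t with
    sensitivity = fraction of presence >= t and specificity = fraction of
    background < t.
    """
    p = np.asarray(pred_presence, float).ravel()
    b = np.asarray(pred_background, float).ravel()
    if p.size == 0 or b.size == 0:
        raise ValueError("max_tss requires non-empty presence and background predictions")
    thresholds = np.unique(np.concatenate([p, b]))
    # counts >= t via sorted searchsorted
    ps = np.sort(p)
    bs = np.sort(b)
    sens = 1.0 - np.searchsorted(ps, thresholds, side="left") / p.size
    spec = np.searchsorted(bs, thresholds, side="left") / b.size
    tss = sens + spec - 1.0
    i = int(np.argmax(tss))  # argmax returns the first (smallest) maximizer
    return float(tss[i]), float(thresholds[i])


def point_biserial(pred_presence, pred_background) -> float:
    """Pearson correlation between predictions and the binary label
    (presence = 1, background = 0) on the pooled sample; NaN if degenerate."""
    p = np.asarray(pred_presence, float).ravel()
    b = np.asarray(pred_background, float).ravel()
    x = np.concatenate([p, b])
    y = np.concatenate([np.ones(p.size), np.zeros(b.size)])
    if x.size < 3 or np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


@dataclass
class EvalResult:
    """One evaluation: discrimination, skill, correlation, parsimony."""

    auc: float
    tss_max: float
    tss_threshold: float
    cor: float
    n_presence_test: int
    n_background: int
    aicc: float = float("nan")
    per_fold: list = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "auc": self.auc,
            "tss_max": self.tss_max,
            "tss_threshold": self.tss_threshold,
            "cor": self.cor,
            "n_presence_test": self.n_presence_test,
            "n_background": self.n_background,
            "aicc": self.aicc,
        }


def evaluate(pred_presence, pred_background, aicc: float = float("nan")) -> EvalResult:
    """All metrics for one set of test predictions."""
    tss, thr = max_tss(pred_presence, pred_background)
    return EvalResult(
        auc=auc(pred_presence, pred_background),
        tss_max=tss,
        tss_threshold=thr,
        cor=point_biserial(pred_presence, pred_background),
        n_presence_test=int(np.size(pred_presence)),
        n_background=int(np.size(pred_background)),
        aicc=aicc,
    )


def evaluate_folds(fold_results) -> EvalResult:
    """Metric-wise arithmetic mean over per-fold :class:`EvalResult` rows.

    Per-fold values are retained in ``per_fold``; NaN AICc values propagate
    (the mean is over computable folds, NaN if none are).
    """
    folds = list(fold_results)
    if not folds:
        raise ValueError("evaluate_folds needs at least one fold result")
    missing = [i for i, f in enumerate(folds) if f is None]
    if missing:
        raise ValueError(f"missing fold result(s) at position(s) {missing}")

    def _mean(vals):
        vals = np.asarray(vals, float)
        ok = np.isfinite(vals)
        return float(vals[ok].mean()) if ok.any() else float("nan")

    out = EvalResult(
        auc=_mean([f.auc for f in folds]),
        tss_max=_mean([f.tss_max for f in folds]),
        tss_threshold=_mean([f.tss_threshold for f in folds]),
        cor=_mean([f.cor for f in folds]),
        n_presence_test=int(sum(f.n_presence_test for f in folds)),
        n_background=folds[0].n_background,
        aicc=_mean([f.aicc for f in folds]),
        per_fold=folds,
    )
    return out


def transfer_evaluate(results, target_stack, test_presence_xy, background_xy,
                      source_rect=None) -> EvalResult:
    """Evaluate a model trained at a larger extent on a nested target extent.

    The model predicts at the target's own test presence and background
    locations (identical test data for every source model). If
    ``source_rect`` is given, the target stack footprint must be nested in
    it.
    """
    template = target_stack.template
    if source_rect is not None:
        # tolerate one cell of grid snapping at the target's edges
        tol = template.cell
        xmin, ymin, xmax, ymax = template.bounds
        sxmin, symin, sxmax, symax = source_rect
        if not (sxmin - tol <= xmin and symin - tol <= ymin
                and xmax <= sxmax + tol and ymax <= symax + tol):
            raise ValueError(
                f"target extent {template.bounds} is not nested in source {source_rect}"
            )
    sub = target_stack.subset(results.model.variables)
    Xp = sub.sample(np.asarray(test_presence_xy)[:, 0], np.asarray(test_presence_xy)[:, 1])
    Xb = sub.sample(np.asarray(background_xy)[:, 0], np.asarray(background_xy)[:, 1])
    Xp = Xp[np.isfinite(Xp).all(axis=1)]
    Xb = Xb[np.isfinite(Xb).all(axis=1)]
    if len(Xp) == 0 or len(Xb) == 0:
        raise ValueError("no valid test presences or background inside the target extent")
    return evaluate(results.predict(Xp, scale="cloglog"),
                    results.predict(Xb, scale="cloglog"))
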
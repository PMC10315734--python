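"""Diagnostic-accuracy meta-analysis: ROC, Youden cutoffs, pooled
sensitivity/specificity and the Moses-Littenberg summary ROC curve.

Per study, the target's expression is treated as a diagnostic score.  The
AUC is the Mann-Whitney statistic; the operating point is chosen by
maximizing Youden's J over all midpoints between adjacent unique scores.
The resulting 2x2 tables are pooled on the logit scale with the same
fixed/random machinery as the effect-size module, and summarized into an
SROC curve by the Moses-Littenberg linear model
D = a + b S with D = logit(TPR) - logit(FPR), S = logit(TPR) + logit(FPR).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import expit, logit

from targetmeta.meta import EffectSize, MetaError, PooledEffect, pool_auto


class DiagnosticsError(ValueError):
    pass


@dataclass(frozen=True)
class RocResult:
    auc: float
    p: float
    n_pos: int
    n_neg: int


@dataclass(frozen=True)
class ConfusionCounts:
    tp: float
    fp: float
    fn: float
    tn: float
    cutoff: float
    sens: float
    spec: float


@dataclass(frozen=True)
class PooledProportion:
    value: float
    ci_low: float
    ci_high: float
    pooled: PooledEffect


@dataclass(frozen=True)
class SrocResult:
    moses_intercept: float
    moses_slope: float
    auc: float
    pooled_sens: PooledProportion
    pooled_spec: PooledProportion
    reliable: bool


def _split_scores(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if labels.dtype.kind in "biuf":
        pos, neg = scores[labels == 1], scores[labels == 0]
    else:
        pos, neg = scores[labels == "pos"], scores[labels == "neg"]
    if len(pos) == 0 or len(neg) == 0:
        raise DiagnosticsError("need at least one score of each class")
    return pos, neg


def roc_auc(scores, labels) -> RocResult:
    """Rank-based AUC with a Mann-Whitney two-sided p value.

    AUC = U / (n_pos * n_neg) with ties counted one half; labels are 1/0
    or "pos"/"neg"; positives are expected to score higher.
    """
    pos, neg = _split_scores(scores, labels)
    res = stats.mannwhitneyu(pos, neg, alternative="two-sided", method="asymptotic")
    auc = float(res.statistic) / (len(pos) * len(neg))
    return RocResult(auc, float(res.pvalue), len(pos), len(neg))


def youden_cutoff(scores, labels) -> ConfusionCounts:
    """Best operating point by Youden's J over midpoints of adjacent scores.

    A score >= cutoff is classified positive.  Ties in J are broken toward
    the smallest cutoff.  With a single unique score no midpoint exists;
    the degenerate table classifies every sample positive (J = 0).
    """
    pos, neg = _split_scores(scores, labels)
    uniq = np.unique(np.concatenate([pos, neg]))
    if len(uniq) == 1:
        cut = float(uniq[0])
        return ConfusionCounts(len(pos), len(neg), 0, 0, cut, 1.0, 0.0)
    cuts = (uniq[:-1] + uniq[1:]) / 2.0
    best = None
    for cut in cuts:
        tp = int((pos >= cut).sum())
        fn = len(pos) - tp
        fp = int((neg >= cut).sum())
        tn = len(neg) - fp
        sens = tp / len(pos)
        spec = tn / len(neg)
        J = sens + spec - 1.0
        if best is None or J > best[0] + 1e-15:
            best = (J, float(cut), tp, fp, fn, tn, sens, spec)
    J, cut, tp, fp, fn, tn, sens, spec = best
    return ConfusionCounts(tp, fp, fn, tn, cut, sens, spec)


def _corrected(t: ConfusionCounts):
    """Apply the 0.5 continuity correction to every cell if any cell is zero."""
    cells = np.array([t.tp, t.fp, t.fn, t.tn], dtype=float)
    if (cells == 0).any():
        cells = cells + 0.5
    return cells


def pool_diagnostics(tables: list[ConfusionCounts]):
    """Pool per-study sensitivity and specificity on the logit scale.

    Any table containing a zero cell gets 0.5 added to all four cells.
    Each study's logit proportion is weighted by 1/(1/a + 1/b); pooling
    follows the fixed/random heterogeneity rule, then the pooled mean and
    CI are transformed back to the probability scale.

    Returns ``(pooled_sens, pooled_spec)`` as :class:`PooledProportion`.
    """
    if len(tables) < 2:
        raise DiagnosticsError("pooling requires k >= 2 tables")
    out = []
    for which in ("sens", "spec"):
        effects = []
        for i, t in enumerate(tables):
            tp, fp, fn, tn = _corrected(t)
            if which == "sens":
                a, b = tp, fn
            else:
                a, b = tn, fp
            y = float(np.log(a / b))
            se = float(np.sqrt(1.0 / a + 1.0 / b))
            effects.append(EffectSize(f"study{i}", y, se, y - 1.96 * se, y + 1.96 * se))
        try:
            pooled = pool_auto(effects)
        except MetaError as exc:
            raise DiagnosticsError(str(exc)) from exc
        out.append(PooledProportion(float(expit(pooled.mean)),
                                    float(expit(pooled.ci_low)),
                                    float(expit(pooled.ci_high)), pooled))
    return tuple(out)


def sroc_curve_tpr(a: float, b: float, fpr):
    """TPR(FPR) implied by the fitted Moses-Littenberg line.

    From D = a + b S: logit(TPR) = (a + (1+b) logit(FPR)) / (1-b).
    """
    fpr = np.asarray(fpr, dtype=float)
    out = np.empty_like(fpr)
    interior = (fpr > 0) & (fpr < 1)
    v = logit(fpr[interior])
    out[interior] = expit((a + (1.0 + b) * v) / (1.0 - b))
    out[fpr <= 0] = 0.0
    out[fpr >= 1] = 1.0
    return out


def sroc_moses(tables: list[ConfusionCounts], grid: float = 1e-3) -> SrocResult:
    """Moses-Littenberg summary ROC from per-study 2x2 tables.

    D = logit(TPR) - logit(FPR) is regressed on S = logit(TPR) + logit(FPR)
    by unweighted least squares; the implied TPR(FPR) curve is integrated
    over FPR in [0, 1] by the trapezoid rule on a ``grid`` spacing.  When
    the studies share a single operating point (var(S) = 0) the slope is
    fixed at 0; |b| >= 1 yields an ill-defined curve and the result is
    marked unreliable (AUC = nan).
    """
    if len(tables) < 3:
        raise DiagnosticsError("SROC requires k >= 3 tables")
    D, S = [], []
    for t in tables:
        tp, fp, fn, tn = _corrected(t)
        tpr = tp / (tp + fn)
        fpr = fp / (fp + tn)
        D.append(float(logit(tpr) - logit(fpr)))
        S.append(float(logit(tpr) + logit(fpr)))
    D = np.array(D)
    S = np.array(S)
    if np.ptp(S) < 1e-12:
        a, b = float(D.mean()), 0.0
    else:
        X = np.column_stack([np.ones(len(S)), S])
        (a, b), *_ = np.linalg.lstsq(X, D, rcond=None)
        a, b = float(a), float(b)

    pooled_sens, pooled_spec = pool_diagnostics(tables)
    if abs(b) >= 1.0:
        return SrocResult(a, b, float("nan"), pooled_sens, pooled_spec, False)
    fpr = np.arange(0.0, 1.0 + grid / 2, grid)
    tpr = sroc_curve_tpr(a, b, fpr)
    auc = float(np.trapezoid(tpr, fpr))
    return SrocResult(a, b, auc, pooled_sens, pooled_spec, True)
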
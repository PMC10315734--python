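"""Standardized-mean-difference meta-analysis.

Per-study effects are Hedges' g (Cohen's d with the small-sample correction
J = 1 - 3/(4 df - 1)).  Studies are pooled by inverse-variance weighting
under a fixed-effect model or a DerSimonian-Laird random-effects model;
the model is selected by heterogeneity (random iff I^2 > 50% or the
Cochran Q test has p < 0.05).  Funnel asymmetry is assessed with Egger's
regression, robustness with leave-one-out re-pooling, and the whole genome
can be screened with forced random-effects pooling, flagging a gene as
up-regulated when both the pooled mean and the lower 95% confidence bound
exceed zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from targetmeta.cohorts import ExpressionCohort, GroupSummary, summarize_groups

logger = logging.getLogger(__name__)

Z95 = 1.959963984540054  # normal 97.5% quantile

I2_CUTOFF = 50.0
PQ_CUTOFF = 0.05


class MetaError(ValueError):
    pass


@dataclass(frozen=True)
class EffectSize:
    study_id: str
    g: float
    se: float
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class PooledEffect:
    k: int
    model: str  # "fixed" | "random"
    mean: float
    se: float
    ci_low: float
    ci_high: float
    Q: float
    df: int
    p_Q: float
    I2: float
    tau2: float


@dataclass(frozen=True)
class EggerResult:
    intercept: float
    se: float
    t: float
    p: float
    k: int


@dataclass(frozen=True)
class ScreenRecord:
    gene: str
    pooled: PooledEffect
    up_regulated: bool


def hedges_g(summary: GroupSummary) -> EffectSize:
    """Hedges' g with its standard error and normal 95% CI.

    d = (exp_mean - ctrl_mean) / pooled SD, J = 1 - 3/(4(n1+n2-2)-1),
    g = J d, se = sqrt((n1+n2)/(n1 n2) + g^2 / (2(n1+n2))).
    """
    n1, n2 = summary.exp_n, summary.ctrl_n
    if n1 < 2 or n2 < 2:
        raise MetaError(f"gene {summary.gene}: each arm needs n >= 2")
    sp2 = ((n1 - 1) * summary.exp_sd**2 + (n2 - 1) * summary.ctrl_sd**2) / (n1 + n2 - 2)
    if sp2 <= 0:
        raise MetaError(f"gene {summary.gene}: zero pooled SD (degenerate)")
    d = (summary.exp_mean - summary.ctrl_mean) / np.sqrt(sp2)
    J = 1.0 - 3.0 / (4.0 * (n1 + n2 - 2) - 1.0)
    g = J * d
    se = np.sqrt((n1 + n2) / (n1 * n2) + g**2 / (2.0 * (n1 + n2)))
    return EffectSize(summary.gene, float(g), float(se),
                      float(g - Z95 * se), float(g + Z95 * se))


def _heterogeneity(g: np.ndarray, w: np.ndarray):
    mean = float((w * g).sum() / w.sum())
    Q = float((w * (g - mean) ** 2).sum())
    df = len(g) - 1
    p_Q = float(stats.chi2.sf(Q, df)) if df > 0 else 1.0
    I2 = max(0.0, (Q - df) / Q) * 100.0 if Q > 0 else 0.0
    return mean, Q, df, p_Q, I2


def pool_fixed(effects: list[EffectSize]) -> PooledEffect:
    """Inverse-variance fixed-effect pooling with Cochran Q heterogeneity."""
    if len(effects) < 2:
        raise MetaError("pooling requires k >= 2 studies")
    g = np.array([e.g for e in effects])
    w = 1.0 / np.array([e.se for e in effects]) ** 2
    mean, Q, df, p_Q, I2 = _heterogeneity(g, w)
    se = 1.0 / np.sqrt(w.sum())
    return PooledEffect(len(effects), "fixed", mean, float(se),
                        float(mean - Z95 * se), float(mean + Z95 * se),
                        Q, df, p_Q, I2, 0.0)


def pool_random_dl(effects: list[EffectSize]) -> PooledEffect:
    """DerSimonian-Laird random-effects pooling.

    tau^2 = max(0, (Q - df) / (sum w - sum w^2 / sum w)) from the fixed
    weights, then studies are re-weighted by 1/(se^2 + tau^2).
    """
    if len(effects) < 2:
        raise MetaError("pooling requires k >= 2 studies")
    g = np.array([e.g for e in effects])
    se2 = np.array([e.se for e in effects]) ** 2
    w = 1.0 / se2
    _, Q, df, p_Q, I2 = _heterogeneity(g, w)
    c = w.sum() - (w**2).sum() / w.sum()
    tau2 = max(0.0, (Q - df) / c) if c > 0 else 0.0
    ws = 1.0 / (se2 + tau2)
    mean = float((ws * g).sum() / ws.sum())
    se = 1.0 / np.sqrt(ws.sum())
    return PooledEffect(len(effects), "random", mean, float(se),
                        float(mean - Z95 * se), float(mean + Z95 * se),
                        Q, df, p_Q, I2, float(tau2))


def select_model(pooled_fixed: PooledEffect) -> str:
    """Heterogeneity rule: random iff I^2 > 50 or p_Q < 0.05, else fixed."""
    if pooled_fixed.I2 > I2_CUTOFF or pooled_fixed.p_Q < PQ_CUTOFF:
        return "random"
    return "fixed"


def pool_auto(effects: list[EffectSize]) -> PooledEffect:
    """Pool with the model chosen by the heterogeneity rule."""
    fixed = pool_fixed(effects)
    if select_model(fixed) == "random":
        return pool_random_dl(effects)
    return fixed


def egger_test(effects: list[EffectSize]) -> EggerResult:
    """Egger's regression test for funnel-plot asymmetry.

    OLS of the standardized effect g_i/se_i on precision 1/se_i; the
    intercept's t statistic is referred to t(k-2), two-sided.
    """
    k = len(effects)
    if k < 3:
        raise MetaError("Egger's test requires k >= 3 studies")
    y = np.array([e.g / e.se for e in effects])
    x = np.array([1.0 / e.se for e in effects])
    X = np.column_stack([np.ones(k), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    sigma2 = float(resid @ resid) / (k - 2)
    cov = sigma2 * np.linalg.inv(X.T @ X)
    se_int = float(np.sqrt(cov[0, 0]))
    t = float(beta[0] / se_int) if se_int > 0 else 0.0
    p = float(2.0 * stats.t.sf(abs(t), k - 2))
    return EggerResult(float(beta[0]), se_int, t, p, k)


def leave_one_out(effects: list[EffectSize]) -> list[PooledEffect]:
    """Sensitivity analysis: re-pool k times, omitting one study each time.

    Model selection is re-applied per subset.
    """
    if len(effects) < 3:
        raise MetaError("leave-one-out requires k >= 3 studies")
    return [pool_auto(effects[:i] + effects[i + 1:]) for i in range(len(effects))]


def _arm_stats(cohort: ExpressionCohort, genes: pd.Index):
    vals = cohort.values.loc[genes]
    out = {}
    for arm, samples in (("exp", cohort.tumor_samples), ("ctrl", cohort.control_samples)):
        X = vals[samples].to_numpy(dtype=float)
        out[arm] = (X.shape[1], X.mean(axis=1), X.std(axis=1, ddof=1))
    return out


def _hedges_arrays(n1, m1, s1, n2, m2, s2):
    """Vectorized Hedges' g over genes; returns (g, se, valid mask)."""
    sp2 = ((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2)
    valid = sp2 > 0
    sp2 = np.where(valid, sp2, 1.0)
    d = (m1 - m2) / np.sqrt(sp2)
    J = 1.0 - 3.0 / (4.0 * (n1 + n2 - 2) - 1.0)
    g = J * d
    se = np.sqrt((n1 + n2) / (n1 * n2) + g**2 / (2.0 * (n1 + n2)))
    return g, se, valid


def genomewide_smd_screen(
    cohorts: list[ExpressionCohort], min_cohorts: int = 2
) -> list[ScreenRecord]:
    """Random-effects SMD pooling of every shared gene across cohorts.

    Random-effects pooling is applied to every gene regardless of its
    heterogeneity; a gene is flagged ``up_regulated`` when the pooled mean
    and its lower 95% bound are both above zero.  Genes usable (both arms
    n >= 2, non-degenerate pooled SD) in fewer than ``min_cohorts`` cohorts
    are skipped with a logged warning.
    """
    if len(cohorts) < 2:
        raise MetaError("screen requires >= 2 cohorts")
    genes = cohorts[0].genes
    for c in cohorts[1:]:
        genes = genes.intersection(c.genes)
    genes = genes.sort_values()
    if len(genes) == 0:
        raise MetaError("no shared genes across cohorts")

    G = len(genes)
    gs, ses, valids = [], [], []
    for c in cohorts:
        arms = _arm_stats(c, genes)
        n1, m1, s1 = arms["exp"]
        n2, m2, s2 = arms["ctrl"]
        if n1 < 2 or n2 < 2:
            valids.append(np.zeros(G, dtype=bool))
            gs.append(np.zeros(G))
            ses.append(np.ones(G))
            continue
        g, se, valid = _hedges_arrays(n1, m1, s1, n2, m2, s2)
        gs.append(g)
        ses.append(se)
        valids.append(valid)
    g = np.array(gs)          # (K, G)
    se = np.array(ses)
    valid = np.array(valids)

    usable = valid.sum(axis=0)
    keep = usable >= min_cohorts
    n_skipped = int((~keep).sum())
    if n_skipped:
        logger.warning("screen: skipped %d genes with < %d usable cohorts",
                       n_skipped, min_cohorts)

    w = np.where(valid, 1.0 / se**2, 0.0)
    sw = w.sum(axis=0)
    mu_f = (w * g).sum(axis=0) / sw
    Q = (w * (g - mu_f) ** 2 * valid).sum(axis=0)
    df = usable - 1
    c_ = sw - (w**2).sum(axis=0) / sw
    with np.errstate(invalid="ignore", divide="ignore"):
        tau2 = np.maximum(0.0, (Q - df) / np.where(c_ > 0, c_, 1.0))
        ws = np.where(valid, 1.0 / (se**2 + tau2[None, :]), 0.0)
        mean = (ws * g).sum(axis=0) / ws.sum(axis=0)
        pse = 1.0 / np.sqrt(ws.sum(axis=0))
        p_Q = stats.chi2.sf(Q, np.maximum(df, 1))
        I2 = np.where(Q > 0, np.maximum(0.0, (Q - df) / np.where(Q > 0, Q, 1.0)) * 100.0, 0.0)

    records = []
    for i, gene in enumerate(genes):
        if not keep[i]:
            continue
        lo, hi = mean[i] - Z95 * pse[i], mean[i] + Z95 * pse[i]
        pooled = PooledEffect(int(usable[i]), "random", float(mean[i]), float(pse[i]),
                              float(lo), float(hi), float(Q[i]), int(df[i]),
                              float(p_Q[i]), float(I2[i]), float(tau2[i]))
        records.append(ScreenRecord(str(gene), pooled,
                                    bool(mean[i] > 0 and lo > 0)))
    return records


def screen_to_frame(records: list[ScreenRecord]) -> pd.DataFrame:
    rows = [
        {"gene": r.gene, "k": r.pooled.k, "model": r.pooled.model,
         "smd": r.pooled.mean, "ci_low": r.pooled.ci_low, "ci_high": r.pooled.ci_high,
         "Q": r.pooled.Q, "I2": r.pooled.I2, "tau2": r.pooled.tau2,
         "up_regulated": r.up_regulated}
        for r in records
    ]
    return pd.DataFrame(rows)


# clinical subgroup dichotomies among tumor samples; "exp" level listed first
_SUBGROUP_LEVELS = {
    "age": ("age", lambda v: pd.to_numeric(v, errors="coerce") > 60),
    "sex": ("sex", lambda v: v.astype(str).str.lower() == "male"),
    "tnm": ("tnm_stage", lambda v: v.astype(str).isin(["III", "IV", "3", "4"])),
    "grade": ("grade", lambda v: v.astype(str).str.lower().isin(["low", "lowly", "g3", "poor"])),
}


def subgroup_smd(
    cohorts: list[ExpressionCohort], variable: str, target_gene: str
) -> PooledEffect:
    """Pooled SMD of the target gene between two clinical subgroups.

    Within the tumor samples of each cohort, the chosen clinical variable is
    dichotomized (age > 60 vs <= 60, male vs female, TNM III-IV vs I-II, low
    vs high differentiation grade) and a Hedges' g computed between the two
    levels; per-cohort effects are pooled with the heterogeneity-driven
    model selection.  At least two cohorts must have >= 2 tumor samples on
    each level.
    """
    if variable not in _SUBGROUP_LEVELS:
        raise MetaError(f"unknown subgroup variable {variable!r}")
    column, exp_mask_fn = _SUBGROUP_LEVELS[variable]
    effects = []
    for c in cohorts:
        if c.clinical is None or column not in c.clinical.columns:
            continue
        tumor = c.tumor_samples
        if target_gene not in c.genes:
            continue
        vals = c.values.loc[target_gene, tumor].astype(float)
        mask = exp_mask_fn(c.clinical.loc[tumor, column]).to_numpy(dtype=bool)
        x1 = vals[mask].to_numpy()
        x2 = vals[~mask].to_numpy()
        if len(x1) < 2 or len(x2) < 2:
            continue
        summ = GroupSummary(target_gene, len(x1), float(x1.mean()), float(x1.std(ddof=1)),
                            len(x2), float(x2.mean()), float(x2.std(ddof=1)))
        try:
            effects.append(hedges_g(summ))
        except MetaError:
            continue
    if len(effects) < 2:
        raise MetaError(
            f"subgroup {variable!r}: fewer than 2 cohorts with both levels populated"
        )
    return pool_auto(effects)


def effects_per_cohort(cohorts: list[ExpressionCohort], gene: str) -> list[EffectSize]:
    """Hedges' g of one gene in every cohort where it is estimable."""
    effects = []
    for c in cohorts:
        try:
            es = hedges_g(summarize_groups(c, gene))
        except (MetaError, ValueError) as exc:
            logger.warning("gene %s skipped in %s: %s", gene, c.study_id, exc)
            continue
        effects.append(EffectSize(c.study_id, es.g, es.se, es.ci_low, es.ci_high))
    return effects
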
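"""Single-sample gene-set enrichment (ssGSEA), differential pathway
statistics, target-gene correlation and the pathway selection rule.

The per-sample score of a gene set is the sum over the ranked gene list of
the difference between the weighted in-set cumulative step function
(weights |rank|^alpha, alpha = 0.25 by default) and the unweighted out-set
step function.  Scores are min-max normalized across the whole
pathways x samples matrix.  A pathway is selected as target-related only
when it is higher in tumor (Welch t, Benjamini-Hochberg adjusted p < 0.05,
positive mean difference) and positively Pearson-correlated with the
target's expression among tumor samples (r > 0, p < 0.05).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from targetmeta.cohorts import ExpressionCohort, GROUP_TUMOR

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.25


class PathwayError(ValueError):
    pass


@dataclass
class GeneSetCatalog:
    """Named gene sets; order-preserving, names unique, members non-empty."""

    sets: dict[str, list[str]]

    def __post_init__(self):
        for name, members in self.sets.items():
            if not members:
                raise PathwayError(f"gene set {name!r} is empty")

    def __len__(self):
        return len(self.sets)

    @classmethod
    def read_gmt(cls, path) -> "GeneSetCatalog":
        sets: dict[str, list[str]] = {}
        with open(path) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 3 or not parts[0]:
                    continue
                sets[parts[0]] = [g for g in parts[2:] if g]
        return cls(sets)

    def write_gmt(self, path, description: str = "na") -> None:
        with open(path, "w") as fh:
            for name, members in self.sets.items():
                fh.write("\t".join([name, description, *members]) + "\n")


@dataclass
class EnrichmentMatrix:
    """Pathways x samples score matrix; ``normalized`` marks min-max scaling."""

    scores: pd.DataFrame
    normalized: bool = False


@dataclass
class PathwayDiffRecord:
    pathway: str
    logFC: float
    p: float
    adj_p: float
    r_target: float = float("nan")
    p_r: float = 1.0
    valid_r: bool = True
    selected: bool = False


def _ranked_order(expression: pd.Series) -> np.ndarray:
    """Indices ordering genes by descending expression, ties by gene id."""
    idx = np.lexsort((expression.index.to_numpy(), -expression.to_numpy(dtype=float)))
    return idx


def ssgsea_score(expression: pd.Series, members, alpha: float = DEFAULT_ALPHA) -> float:
    """ssGSEA enrichment score of one gene set in one sample.

    Genes are ranked by descending expression (ties broken by gene id);
    position i (0-based) carries rank value N - i so the top gene weighs
    N^alpha.  The score is the sum over positions of the difference between
    the in-set weighted cumulative distribution and the out-set unweighted
    one.
    """
    members = set(members)
    genes = expression.index
    in_mask = genes.isin(members)
    n_in = int(in_mask.sum())
    if n_in == 0:
        raise PathwayError("gene set has no overlap with the sample's genes")
    if n_in == len(genes):
        raise PathwayError("gene set covers every gene; complement is empty")
    order = _ranked_order(expression)
    in_ordered = in_mask[order]
    N = len(genes)
    ranks = (N - np.arange(N)).astype(float)
    w = np.where(in_ordered, ranks**alpha, 0.0)
    P_in = np.cumsum(w) / w.sum()
    out_steps = (~in_ordered).astype(float)
    P_out = np.cumsum(out_steps) / (N - n_in)
    return float((P_in - P_out).sum())


def score_catalog(
    cohort: ExpressionCohort, catalog: GeneSetCatalog, alpha: float = DEFAULT_ALPHA
) -> EnrichmentMatrix:
    """Score every catalog set in every sample, then min-max normalize globally.

    Sets with no member among the cohort's genes are dropped with a warning.
    """
    genes = cohort.genes
    kept: dict[str, np.ndarray] = {}
    for name, members in catalog.sets.items():
        mask = np.asarray(genes.isin(set(members)))
        if not mask.any():
            logger.warning("gene set %s dropped: no overlap with cohort genes", name)
            continue
        if mask.all():
            logger.warning("gene set %s dropped: covers all cohort genes", name)
            continue
        kept[name] = mask
    if not kept:
        raise PathwayError("no catalog set overlaps the cohort")

    X = cohort.values.to_numpy(dtype=float)
    N = X.shape[0]
    gene_names = genes.to_numpy()
    ranks = (N - np.arange(N)).astype(float)
    out = np.empty((len(kept), X.shape[1]))
    masks = np.array(list(kept.values()))          # (n_sets, N)
    sizes = masks.sum(axis=1)
    for j in range(X.shape[1]):
        order = np.lexsort((gene_names, -X[:, j]))
        m_ord = masks[:, order]                    # (n_sets, N)
        w = np.where(m_ord, ranks[None, :] ** alpha, 0.0)
        P_in = np.cumsum(w, axis=1) / w.sum(axis=1, keepdims=True)
        P_out = np.cumsum((~m_ord).astype(float), axis=1) / (N - sizes)[:, None]
        out[:, j] = (P_in - P_out).sum(axis=1)

    lo, hi = out.min(), out.max()
    if hi - lo > 0:
        out = (out - lo) / (hi - lo)
    else:
        out = np.zeros_like(out)
    scores = pd.DataFrame(out, index=list(kept.keys()), columns=cohort.samples)
    return EnrichmentMatrix(scores, normalized=True)


def differential_pathways(em: EnrichmentMatrix, groups: pd.Series) -> list[PathwayDiffRecord]:
    """Welch-t tumor vs control per pathway with Benjamini-Hochberg adjustment.

    ``logFC`` is the tumor-minus-control mean score difference (the scores
    are not logged; the conventional field name is kept).
    """
    groups = groups.loc[em.scores.columns]
    t_mask = (groups == GROUP_TUMOR).to_numpy()
    if t_mask.sum() < 2 or (~t_mask).sum() < 2:
        raise PathwayError("both groups need >= 2 samples")
    X = em.scores.to_numpy(dtype=float)
    tum, ctl = X[:, t_mask], X[:, ~t_mask]
    logfc = tum.mean(axis=1) - ctl.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(tum, ctl, axis=1, equal_var=False)
        pvals = np.where(np.isnan(res.pvalue), 1.0, res.pvalue)
    adj = multipletests(pvals, method="fdr_bh")[1]
    return [
        PathwayDiffRecord(str(name), float(logfc[i]), float(pvals[i]), float(adj[i]))
        for i, name in enumerate(em.scores.index)
    ]


def correlate_with_target(
    em: EnrichmentMatrix, target_expression: pd.Series
) -> list[tuple[str, float, float, bool]]:
    """Pearson correlation of every pathway score with the target's expression.

    Only the samples present in ``target_expression`` are used (callers pass
    tumor samples).  Returns ``(pathway, r, p, valid)`` tuples; a pathway
    whose score vector has zero variance is flagged invalid.
    """
    samples = target_expression.index
    if len(samples) < 3:
        raise PathwayError("correlation needs >= 3 samples")
    y = target_expression.to_numpy(dtype=float)
    out = []
    for name in em.scores.index:
        x = em.scores.loc[name, samples].to_numpy(dtype=float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            out.append((str(name), float("nan"), 1.0, False))
            continue
        r, p = stats.pearsonr(x, y)
        out.append((str(name), float(r), float(p), True))
    return out


def select_target_pathways(records: list[PathwayDiffRecord],
                           alpha: float = 0.05) -> list[PathwayDiffRecord]:
    """Keep pathways up in tumor and positively correlated with the target.

    selected <=> logFC > 0 and adj_p < alpha and r > 0 and p_r < alpha.
    """
    selected = []
    for rec in records:
        rec.selected = bool(
            rec.valid_r
            and rec.logFC > 0
            and rec.adj_p < alpha
            and rec.r_target > 0
            and rec.p_r < alpha
        )
        if rec.selected:
            selected.append(rec)
    return selected


def pathway_analysis(
    cohort: ExpressionCohort,
    catalog: GeneSetCatalog,
    target_gene: str,
    alpha: float = DEFAULT_ALPHA,
    sig_alpha: float = 0.05,
) -> list[PathwayDiffRecord]:
    """Full pathway stage: score, differential test, correlation, selection."""
    em = score_catalog(cohort, catalog, alpha=alpha)
    records = differential_pathways(em, cohort.groups)
    target_expr = cohort.values.loc[target_gene, cohort.tumor_samples].astype(float)
    corr = {name: (r, p, ok) for name, r, p, ok in correlate_with_target(em, target_expr)}
    for rec in records:
        r, p, ok = corr[rec.pathway]
        rec.r_target, rec.p_r, rec.valid_r = r, p, ok
    select_target_pathways(records, alpha=sig_alpha)
    return records


def records_to_frame(records: list[PathwayDiffRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"pathway": r.pathway, "logFC": r.logFC, "p": r.p, "adj_p": r.adj_p,
          "r_target": r.r_target, "p_r": r.p_r, "selected": r.selected}
         for r in records]
    )
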
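"""Co-expression screening around the target gene, set intersection and
degree-based hub ranking on a caller-supplied interaction edge list.

A gene passes the co-expression screen when its Pearson correlation with
the target across tumor samples is positive with p < 0.05 (raw p, no
multiplicity correction — a deliberate fidelity choice for this screening
style).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from targetmeta.cohorts import ExpressionCohort


class ScreenError(ValueError):
    pass


@dataclass(frozen=True)
class CoexprRecord:
    gene: str
    r: float
    p: float
    passes: bool


@dataclass(frozen=True)
class IntersectionResult:
    set_names: list[str]
    set_sizes: list[int]
    members: list[str]

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class HubRanking:
    ranking: list[tuple[str, int]]  # (gene, degree), degrees non-increasing


def coexpression_screen(cohort: ExpressionCohort, target_gene: str,
                        tumor_only: bool = True,
                        alpha: float = 0.05) -> list[CoexprRecord]:
    """Pearson-correlate every other gene with the target across tumor samples.

    Returns one record per gene (target excluded), flagged ``passes`` when
    r > 0 and p < ``alpha``.  Zero-variance genes get r = 0, p = 1.
    """
    if target_gene not in cohort.genes:
        raise ScreenError(f"target gene {target_gene!r} not in cohort")
    samples = cohort.tumor_samples if tumor_only else cohort.samples
    if len(samples) < 3:
        raise ScreenError("need >= 3 samples for correlation")
    X = cohort.values[samples].to_numpy(dtype=float)
    genes = cohort.genes.to_numpy()
    ti = int(np.where(genes == target_gene)[0][0])
    y = X[ti]
    if np.ptp(y) == 0:
        raise ScreenError("target gene has zero variance across the selected samples")
    n = len(samples)

    Xc = X - X.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    num = Xc @ yc
    den = np.sqrt((Xc**2).sum(axis=1) * (yc**2).sum())
    zero_var = (Xc**2).sum(axis=1) == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(zero_var, 0.0, num / np.where(den > 0, den, 1.0))
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        tstat = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(tstat), n - 2)
    p = np.where(zero_var, 1.0, p)

    records = []
    for i, gene in enumerate(genes):
        if i == ti:
            continue
        records.append(CoexprRecord(str(gene), float(r[i]), float(p[i]),
                                    bool(r[i] > 0 and p[i] < alpha)))
    return records


def intersect_sets(named_sets: dict[str, set]) -> IntersectionResult:
    """Exact intersection of >= 2 named gene sets, members sorted."""
    if len(named_sets) < 2:
        raise ScreenError("intersection needs >= 2 sets")
    for name, members in named_sets.items():
        if not members:
            raise ScreenError(f"input set {name!r} is empty")
    names = list(named_sets.keys())
    sets = [set(named_sets[n]) for n in names]
    inter = set.intersection(*sets)
    return IntersectionResult(names, [len(s) for s in sets],
                              sorted(str(g) for g in inter))


def hub_rank_degree(edges, k: int = 10) -> HubRanking:
    """Top-k nodes by undirected degree.

    Self-loops are ignored and duplicate edges counted once; ties are
    broken lexicographically; k beyond the node count returns all nodes.
    """
    if k < 1:
        raise ScreenError("k must be >= 1")
    uniq = set()
    for a, b in edges:
        if a == b:
            continue
        uniq.add((str(a), str(b)) if str(a) < str(b) else (str(b), str(a)))
    if not uniq:
        raise ScreenError("edge list contains no usable edges")
    degree: dict[str, int] = {}
    for a, b in uniq:
        degree[a] = degree.get(a, 0) + 1
        degree[b] = degree.get(b, 0) + 1
    ranked = sorted(degree.items(), key=lambda kv: (-kv[1], kv[0]))
    return HubRanking(ranked[:k])


def coexpr_to_frame(records: list[CoexprRecord]) -> pd.DataFrame:
    return pd.DataFrame([{"gene": r.gene, "r": r.r, "p": r.p, "passes": r.passes}
                         for r in records])
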
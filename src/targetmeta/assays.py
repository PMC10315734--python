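"""Bench-assay statistics: IHC composite scoring and group tests, qPCR
relative quantification (2^-ddCt), and transwell optical-density tests.

The IHC composite score is the product of a staining-proportion bin (0-4:
<5%, 5-25%, 25-50%, 50-75%, >75% of positive cells) and a staining-intensity
grade (0-3: none, light yellow, brown, dark brown), giving a 0-12 ordinal
scale.  Relative qPCR quantification follows the ddCt method: dCt =
Ct_target - Ct_reference per group, ddCt = dCt_treated - dCt_control,
fold change = 2^-ddCt.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from targetmeta.diagnostics import RocResult, roc_auc

INTENSITY_GRADES = {"none": 0, "light": 1, "brown": 2, "dark": 3}


class AssayError(ValueError):
    pass


@dataclass(frozen=True)
class FoldChange:
    ddct: float
    fold: float  # 2 ** -ddct


def proportion_bin(percent: float) -> int:
    """Bin percent positive cells: <5 -> 0, [5,25) -> 1, [25,50) -> 2,
    [50,75] -> 3, >75 -> 4."""
    if not 0.0 <= percent <= 100.0:
        raise AssayError(f"percent positive {percent} outside [0, 100]")
    if percent < 5:
        return 0
    if percent < 25:
        return 1
    if percent < 50:
        return 2
    if percent <= 75:
        return 3
    return 4


def ihc_composite_score(percent: float, intensity: str) -> tuple[int, int, int]:
    """(proportion bin, intensity grade, composite = product, range 0-12)."""
    if intensity not in INTENSITY_GRADES:
        raise AssayError(
            f"unknown intensity {intensity!r}; expected one of {sorted(INTENSITY_GRADES)}"
        )
    p = proportion_bin(percent)
    i = INTENSITY_GRADES[intensity]
    return p, i, p * i


def score_ihc_table(table: pd.DataFrame) -> pd.DataFrame:
    """Add proportion_score / intensity_score / composite columns to an IHC
    table with ``percent_positive`` and ``intensity`` columns."""
    scored = table.copy()
    triples = [ihc_composite_score(row.percent_positive, row.intensity)
               for row in table.itertuples()]
    scored["proportion_score"] = [t[0] for t in triples]
    scored["intensity_score"] = [t[1] for t in triples]
    scored["composite"] = [t[2] for t in triples]
    return scored


def compare_score_groups(scores_a, scores_b) -> float:
    """Mann-Whitney U two-sided p for ordinal scores between two levels."""
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise AssayError("both levels need >= 1 observation")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(res.pvalue)


def ihc_group_difference(scores, tissue_labels) -> tuple[float, RocResult]:
    """Independent-samples Welch t on composite scores plus their ROC.

    ``tissue_labels`` mark cancer (1/"pos") vs non-cancer (0/"neg") tissue;
    both groups need >= 3 cases.  Returns (t-test p, RocResult).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(tissue_labels)
    pos = scores[(labels == 1) | (labels == "pos")]
    neg = scores[(labels == 0) | (labels == "neg")]
    if len(pos) < 3 or len(neg) < 3:
        raise AssayError("both tissue groups need >= 3 cases")
    t = stats.ttest_ind(pos, neg, equal_var=False)
    p = float(t.pvalue)
    if np.isnan(p):
        p = 1.0
    roc = roc_auc(scores, np.where((labels == 1) | (labels == "pos"), 1, 0))
    return p, roc


def compare_od_groups(od_a, od_b) -> float:
    """Welch t two-sided p for transwell OD590 readouts across wells."""
    a = np.asarray(od_a, dtype=float)
    b = np.asarray(od_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise AssayError("both groups need >= 2 wells")
    p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
    return 1.0 if np.isnan(p) else p


def ddct_fold_change(treated_target_ct, treated_ref_ct,
                     control_target_ct, control_ref_ct) -> FoldChange:
    """Relative quantification by the ddCt method on group-mean Ct values."""
    arrays = [np.asarray(a, dtype=float) for a in
              (treated_target_ct, treated_ref_ct, control_target_ct, control_ref_ct)]
    for arr in arrays:
        if arr.size == 0:
            raise AssayError("empty Ct group")
        if not np.isfinite(arr).all():
            raise AssayError("non-finite Ct value")
    dct_treated = arrays[0].mean() - arrays[1].mean()
    dct_control = arrays[2].mean() - arrays[3].mean()
    ddct = float(dct_treated - dct_control)
    return FoldChange(ddct, float(2.0 ** (-ddct)))


def ddct_from_table(table: pd.DataFrame, target_gene: str, reference_gene: str,
                    treated_group: str, control_group: str) -> FoldChange:
    """ddCt fold change from a long table with group / gene / ct columns."""
    def _cts(group, gene):
        sel = table[(table["group"] == group) & (table["gene"] == gene)]["ct"]
        if sel.empty:
            raise AssayError(f"no Ct rows for group {group!r}, gene {gene!r}")
        return sel.to_numpy(dtype=float)

    return ddct_fold_change(
        _cts(treated_group, target_gene), _cts(treated_group, reference_gene),
        _cts(control_group, target_gene), _cts(control_group, reference_gene),
    )
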
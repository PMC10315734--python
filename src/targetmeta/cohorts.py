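"""Expression-cohort containers, I/O, same-platform merging and batch adjustment.

A cohort is one study's genes x samples matrix on log2 scale together with a
tumor/control label and a batch label per sample.  Studies profiled on the
same platform can be merged on their shared genes and the per-study batch
effect removed with a gene-wise location-scale adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

GROUP_TUMOR = "tumor"
GROUP_CONTROL = "control"

#: Variance floor for batch standardization, on the log2 scale.
VARIANCE_FLOOR = 1e-8


class CohortError(ValueError):
    """Invalid cohort construction or operation precondition."""


@dataclass
class ExpressionCohort:
    """One study's expression matrix plus per-sample annotations.

    Parameters
    ----------
    study_id, platform_id : str
        Identifiers of the study and its profiling platform.
    values : pandas.DataFrame
        Genes in rows (unique ids), samples in columns, log2-scale reals.
    groups : pandas.Series
        ``"tumor"`` / ``"control"`` per sample, indexed by sample id.
    batch : pandas.Series
        Batch label per sample (defaults to the study id).
    clinical : pandas.DataFrame, optional
        Per-sample clinical covariates (age, sex, tnm_stage, grade, ...).
    """

    study_id: str
    platform_id: str
    values: pd.DataFrame
    groups: pd.Series
    batch: pd.Series = None
    clinical: pd.DataFrame | None = None

    def __post_init__(self):
        if self.values.shape[1] < 1:
            raise CohortError(f"cohort {self.study_id}: at least one sample required")
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][0]
            raise CohortError(f"cohort {self.study_id}: duplicate gene id {dup!r}")
        if self.batch is None:
            self.batch = pd.Series(self.study_id, index=self.values.columns)
        for name, ann in (("groups", self.groups), ("batch", self.batch)):
            if not ann.index.equals(self.values.columns):
                raise CohortError(
                    f"cohort {self.study_id}: {name} index does not match sample columns"
                )
        bad = set(self.groups.unique()) - {GROUP_TUMOR, GROUP_CONTROL}
        if bad:
            raise CohortError(f"cohort {self.study_id}: unknown group labels {sorted(bad)}")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def group_samples(self, group: str) -> pd.Index:
        return self.samples[self.groups.values == group]

    @property
    def tumor_samples(self) -> pd.Index:
        return self.group_samples(GROUP_TUMOR)

    @property
    def control_samples(self) -> pd.Index:
        return self.group_samples(GROUP_CONTROL)

    def write(self, expr_path, metadata_path) -> None:
        """Write the matrix as TSV (first column gene id) and metadata as CSV."""
        out = self.values.copy()
        out.index.name = "gene"
        out.to_csv(expr_path, sep="\t")
        meta = pd.DataFrame({"sample_id": self.samples, "group": self.groups.values,
                             "batch": self.batch.values})
        if self.clinical is not None:
            meta = meta.merge(
                self.clinical.reset_index().rename(columns={"index": "sample_id"}),
                on="sample_id", how="left")
        meta.to_csv(metadata_path, index=False)


@dataclass(frozen=True)
class GroupSummary:
    """Per-gene two-arm summary: counts, means and SDs (denominator n-1)."""

    gene: str
    exp_n: int
    exp_mean: float
    exp_sd: float
    ctrl_n: int
    ctrl_mean: float
    ctrl_sd: float


def read_expression_matrix(
    path,
    metadata_path,
    study_id: str | None = None,
    platform_id: str = "unknown",
) -> ExpressionCohort:
    """Load a TSV expression matrix plus CSV metadata into a cohort.

    The TSV has a header row of sample ids and gene ids in the first column;
    the metadata CSV must cover every sample with at least ``sample_id`` and
    ``group`` columns.  Duplicate gene ids are collapsed by their arithmetic
    mean.  Sample order of the matrix is preserved.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", index_col=0)
    for j, col in enumerate(raw.columns):
        numeric = pd.to_numeric(raw[col], errors="coerce")
        if numeric.isna().values.any() and not raw[col].isna().values.any():
            row = raw.index[numeric.isna().values.argmax()]
            raise CohortError(f"{path.name}: non-numeric value at gene {row!r}, sample {col!r}")
        raw[col] = numeric
    if raw.index.duplicated().any():
        raw = raw.groupby(level=0, sort=False).mean()
    meta = pd.read_csv(metadata_path, dtype={"sample_id": str})
    meta = meta.set_index("sample_id")
    missing = [s for s in raw.columns if s not in meta.index]
    if missing:
        raise CohortError(f"{path.name}: sample {missing[0]!r} absent from metadata")
    meta = meta.loc[raw.columns]
    batch = meta["batch"] if "batch" in meta else None
    clinical_cols = [c for c in meta.columns if c not in ("group", "batch")]
    clinical = meta[clinical_cols] if clinical_cols else None
    return ExpressionCohort(
        study_id=study_id or path.stem,
        platform_id=platform_id,
        values=raw,
        groups=meta["group"],
        batch=batch,
        clinical=clinical,
    )


def merge_same_platform(cohorts: list[ExpressionCohort]) -> ExpressionCohort:
    """Combine >=2 same-platform cohorts on the intersection of their genes.

    Each sample keeps its tumor/control label; the batch label becomes the
    source study id so that :func:`adjust_batch_location_scale` can remove
    the study-to-study shift afterwards.
    """
    if len(cohorts) < 2:
        raise CohortError("merge requires at least two cohorts")
    platforms = {c.platform_id for c in cohorts}
    if len(platforms) > 1:
        raise CohortError(f"cannot merge mixed platforms: {sorted(platforms)}")
    genes = cohorts[0].genes
    for c in cohorts[1:]:
        genes = genes.intersection(c.genes)
    if len(genes) == 0:
        raise CohortError("empty gene intersection across cohorts")
    genes = genes.sort_values()

    # disambiguate sample ids only when they collide across studies
    all_ids = [s for c in cohorts for s in c.samples]
    collide = len(set(all_ids)) < len(all_ids)

    blocks, groups, batches, clin = [], [], [], []
    for c in cohorts:
        vals = c.values.loc[genes]
        grp = c.groups.copy()
        bat = pd.Series(c.study_id, index=c.samples)
        cl = c.clinical.copy() if c.clinical is not None else None
        if collide:
            mapper = {s: f"{c.study_id}.{s}" for s in c.samples}
            vals = vals.rename(columns=mapper)
            grp = grp.rename(index=mapper)
            bat = bat.rename(index=mapper)
            if cl is not None:
                cl = cl.rename(index=mapper)
        blocks.append(vals)
        groups.append(grp)
        batches.append(bat)
        clin.append(cl)
    clinical = None
    if all(c is not None for c in clin):
        clinical = pd.concat(clin)
    return ExpressionCohort(
        study_id="+".join(c.study_id for c in cohorts),
        platform_id=cohorts[0].platform_id,
        values=pd.concat(blocks, axis=1),
        groups=pd.concat(groups),
        batch=pd.concat(batches),
        clinical=clinical,
    )


def adjust_batch_location_scale(
    merged: ExpressionCohort, eps: float = VARIANCE_FLOOR
) -> ExpressionCohort:
    """Remove per-batch location and scale gene-wise.

    Per gene and batch the values are centered and scaled by the batch SD
    (floored at ``eps``), then mapped back to the gene's pooled mean and SD
    computed over all samples before adjustment.  A single-batch input is
    returned unchanged; a batch with fewer than two samples is an error.
    Group labels are untouched.
    """
    labels = merged.batch
    uniq = labels.unique()
    if len(uniq) == 1:
        return merged
    counts = labels.value_counts()
    if (counts < 2).any():
        bad = counts.index[counts < 2][0]
        raise CohortError(f"batch {bad!r} has a single sample; cannot estimate scale")
    X = merged.values.to_numpy(dtype=float)
    pooled_mean = X.mean(axis=1, keepdims=True)
    pooled_sd = np.maximum(X.std(axis=1, ddof=1, keepdims=True), eps)
    out = np.empty_like(X)
    for b in uniq:
        mask = (labels.values == b)
        Xb = X[:, mask]
        mb = Xb.mean(axis=1, keepdims=True)
        sb = np.maximum(Xb.std(axis=1, ddof=1, keepdims=True), eps)
        out[:, mask] = (Xb - mb) / sb * pooled_sd + pooled_mean
    return replace(
        merged,
        values=pd.DataFrame(out, index=merged.genes, columns=merged.samples),
    )


def summarize_groups(cohort: ExpressionCohort, gene: str) -> GroupSummary:
    """Two-arm counts, means and sample SDs for one gene.

    Each arm needs at least two samples so that the SD (denominator n-1)
    is defined.
    """
    if gene not in cohort.genes:
        raise CohortError(f"gene {gene!r} not present in cohort {cohort.study_id}")
    row = cohort.values.loc[gene]
    exp = row[cohort.tumor_samples].to_numpy(dtype=float)
    ctrl = row[cohort.control_samples].to_numpy(dtype=float)
    if len(exp) < 2 or len(ctrl) < 2:
        raise CohortError(
            f"gene {gene!r} in {cohort.study_id}: both arms need >=2 samples "
            f"(got {len(exp)} tumor, {len(ctrl)} control)"
        )
    return GroupSummary(
        gene=gene,
        exp_n=len(exp),
        exp_mean=float(exp.mean()),
        exp_sd=float(exp.std(ddof=1)),
        ctrl_n=len(ctrl),
        ctrl_mean=float(ctrl.mean()),
        ctrl_sd=float(ctrl.std(ddof=1)),
    )


def choose_location_test(a, b, normality_alpha: float = 0.05):
    """Compare two samples with Welch t or Wilcoxon rank-sum, chosen by normality.

    Shapiro-Wilk is run on each sample; when both reach p > ``normality_alpha``
    the comparison uses Welch's t test, otherwise the Wilcoxon rank-sum
    (Mann-Whitney) test.  Returns ``(test_name, p_value)`` with
    ``test_name`` in ``{"t_test", "wilcoxon"}``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise CohortError("both samples need >= 3 observations")

    def _normal(x):
        if np.ptp(x) == 0:  # constant sample: Shapiro undefined, treat as non-normal
            return False
        return stats.shapiro(x).pvalue > normality_alpha

    if _normal(a) and _normal(b):
        t = stats.ttest_ind(a, b, equal_var=False)
        p = float(t.pvalue)
        if np.isnan(p):  # both arms constant and equal
            p = 1.0
        return "t_test", p
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return "wilcoxon", float(res.pvalue)
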
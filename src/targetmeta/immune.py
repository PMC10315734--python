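"""Immune-cell fraction estimation and target-gene / cell-type correlation.

Per-sample cell-type fractions are estimated from bulk expression on a
marker-gene signature basis by non-negative least squares, then renormalized
to the simplex.  The target gene's expression is Pearson-correlated with
each estimated cell-type fraction among tumor samples; a cell type is
classified positively (negatively) related when r > 0 (r < 0) with p < 0.05.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import nnls

logger = logging.getLogger(__name__)


class ImmuneError(ValueError):
    pass


@dataclass
class SignatureMatrix:
    """Marker genes x cell types basis of non-negative expression values."""

    basis: pd.DataFrame

    def __post_init__(self):
        if self.basis.shape[1] < 2:
            raise ImmuneError("signature needs >= 2 cell types")
        if self.basis.shape[0] < self.basis.shape[1]:
            raise ImmuneError("signature needs at least as many marker genes as cell types")
        if (self.basis.to_numpy(dtype=float) < 0).any():
            raise ImmuneError("signature basis values must be non-negative")

    @property
    def cell_types(self) -> list[str]:
        return list(self.basis.columns)

    @property
    def markers(self) -> pd.Index:
        return self.basis.index

    @classmethod
    def read_tsv(cls, path) -> "SignatureMatrix":
        return cls(pd.read_csv(path, sep="\t", index_col=0))

    def write_tsv(self, path) -> None:
        out = self.basis.copy()
        out.index.name = "gene"
        out.to_csv(path, sep="\t")


@dataclass(frozen=True)
class FractionEstimate:
    sample_id: str
    fractions: pd.Series  # indexed by cell type, >= 0, sums to 1
    residual: float


@dataclass(frozen=True)
class CellCorrRecord:
    cell_type: str
    r: float
    p: float
    direction: str  # "positive" | "negative" | "none"


def nnls_deconvolve(sample_expression: pd.Series, signature: SignatureMatrix,
                    sample_id: str = "sample") -> FractionEstimate:
    """Estimate one sample's cell-type fractions by non-negative least squares.

    Markers absent from the sample are imputed as 0 with a warning; the
    overlap must still reach the number of cell types.  Coefficients are
    renormalized to sum to 1; the reported residual is the NNLS objective
    at the unnormalized solution.
    """
    A = signature.basis.to_numpy(dtype=float)
    markers = signature.markers
    overlap = np.asarray(markers.isin(sample_expression.index))
    if int(overlap.sum()) < len(signature.cell_types):
        raise ImmuneError(
            f"sample {sample_id}: marker overlap {int(overlap.sum())} below "
            f"{len(signature.cell_types)} cell types"
        )
    if not overlap.all():
        logger.warning("sample %s: %d signature markers missing, imputed as 0",
                       sample_id, int((~overlap).sum()))
    y = np.zeros(len(markers))
    present = markers[overlap]
    y[overlap] = sample_expression.loc[present].to_numpy(dtype=float)
    if not np.any(y != 0):
        raise ImmuneError(f"sample {sample_id}: all-zero expression on markers")
    coef, resid = nnls(A, y)
    total = coef.sum()
    if total <= 0:
        raise ImmuneError(f"sample {sample_id}: degenerate all-zero NNLS solution")
    fractions = pd.Series(coef / total, index=signature.cell_types)
    return FractionEstimate(sample_id, fractions, float(resid))


def deconvolve_samples(expression: pd.DataFrame,
                       signature: SignatureMatrix) -> pd.DataFrame:
    """Deconvolve every column (sample) of a genes x samples matrix.

    Returns a samples x cell types fraction table (rows sum to 1).
    """
    rows = {}
    for sample in expression.columns:
        est = nnls_deconvolve(expression[sample], signature, sample_id=str(sample))
        rows[sample] = est.fractions
    return pd.DataFrame(rows).T


def correlate_gene_cells(target_expression: pd.Series,
                         fractions: pd.DataFrame,
                         alpha: float = 0.05) -> list[CellCorrRecord]:
    """Pearson r of the target gene against each cell-type fraction.

    Only samples shared between the two inputs are used (callers pass tumor
    samples).  A constant fraction vector yields r = nan, p = 1, direction
    "none".
    """
    shared = target_expression.index.intersection(fractions.index)
    if len(shared) < 3:
        raise ImmuneError("correlation needs >= 3 shared samples")
    y = target_expression.loc[shared].to_numpy(dtype=float)
    records = []
    for ct in fractions.columns:
        x = fractions.loc[shared, ct].to_numpy(dtype=float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            records.append(CellCorrRecord(str(ct), float("nan"), 1.0, "none"))
            continue
        r, p = stats.pearsonr(x, y)
        if p < alpha and r > 0:
            direction = "positive"
        elif p < alpha and r < 0:
            direction = "negative"
        else:
            direction = "none"
        records.append(CellCorrRecord(str(ct), float(r), float(p), direction))
    return records
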
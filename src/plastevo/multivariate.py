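"""Correspondence analysis of gene x codon tables.

Classical CA: with P the table divided by its grand total, row masses r
and column masses c, the standardized residual matrix
S = D_r^(-1/2) (P - r c^T) D_c^(-1/2) is decomposed by SVD. Principal
coordinates are the mass-rescaled singular vectors scaled by singular
values; total inertia (the sum of squared singular values) equals the
chi-square statistic of the table divided by its grand total.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger("plastevo.multivariate")

__all__ = ["COAResult", "coa", "rscu_matrix"]

_SV_TOL = 1e-12


@dataclass
class COAResult:
    row_coords: pd.DataFrame  # rows x axes
    col_coords: pd.DataFrame  # columns x axes
    singular_values: np.ndarray
    total_inertia: float
    axis_pct: np.ndarray  # percent of inertia per axis
    pruned_rows: list
    pruned_cols: list

    @property
    def n_axes(self) -> int:
        return len(self.singular_values)


def coa(matrix: pd.DataFrame, n_axes: int | None = None) -> COAResult:
    """Correspondence analysis of a nonnegative table.

    All-zero rows and columns are pruned (and logged) first. Axes are
    sign-fixed so the largest-magnitude column loading on each axis is
    positive, making coordinates deterministic. A rank-0 table (all row
    profiles identical) yields zero inertia and no axes.
    """
    if (matrix.values < 0).any():
        raise ValueError("table must be nonnegative")
    df = matrix.loc[matrix.sum(axis=1) > 0, matrix.sum(axis=0) > 0]
    pruned_rows = [r for r in matrix.index if r not in df.index]
    pruned_cols = [c for c in matrix.columns if c not in df.columns]
    if pruned_rows or pruned_cols:
        logger.info(
            "pruned %d all-zero rows, %d all-zero columns",
            len(pruned_rows),
            len(pruned_cols),
        )
    if df.empty:
        raise ValueError("table is empty after pruning")

    X = df.to_numpy(dtype=float)
    total = X.sum()
    P = X / total
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    U, sv_full, Vt = np.linalg.svd(S, full_matrices=False)
    total_inertia = float(np.sum(sv_full**2))

    keep = sv_full > _SV_TOL
    U, sv, Vt = U[:, keep], sv_full[keep], Vt[keep, :]
    if n_axes is not None:
        U, sv, Vt = U[:, :n_axes], sv[:n_axes], Vt[:n_axes, :]

    if sv.size:
        axis_pct = 100.0 * sv**2 / total_inertia
    else:
        axis_pct = np.array([])

    row_coords = (U * sv) / np.sqrt(r)[:, None] if sv.size else np.zeros((len(r), 0))
    col_coords = (Vt.T * sv) / np.sqrt(c)[:, None] if sv.size else np.zeros((len(c), 0))

    # deterministic sign: largest-|loading| column coordinate positive
    for k in range(sv.size):
        j = int(np.argmax(np.abs(col_coords[:, k])))
        if col_coords[j, k] < 0:
            col_coords[:, k] *= -1
            row_coords[:, k] *= -1

    axes = [f"axis{k + 1}" for k in range(sv.size)]
    return COAResult(
        row_coords=pd.DataFrame(row_coords, index=df.index, columns=axes),
        col_coords=pd.DataFrame(col_coords, index=df.columns, columns=axes),
        singular_values=sv,
        total_inertia=total_inertia,
        axis_pct=axis_pct,
        pruned_rows=pruned_rows,
        pruned_cols=pruned_cols,
    )


def rscu_matrix(per_gene_rscu: dict[str, dict[str, float]]) -> pd.DataFrame:
    """Assemble a genes x 59-codon RSCU table.

    Genes missing a family (unobserved amino acid) get zeros for its
    codons, which is logged once.
    """
    from .genetics import INFORMATIVE_CODONS

    rows = {}
    incomplete = 0
    for gene, values in per_gene_rscu.items():
        if len(values) < len(INFORMATIVE_CODONS):
            incomplete += 1
        rows[gene] = [values.get(c, 0.0) for c in INFORMATIVE_CODONS]
    if incomplete:
        logger.info(
            "%d gene(s) with unobserved families completed with zeros", incomplete
        )
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=list(INFORMATIVE_CODONS)
    ).sort_index()
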
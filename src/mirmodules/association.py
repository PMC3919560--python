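"""Expression correlation and target-prediction integration.

The first stage of the module-discovery pipeline turns matched miRNA and
mRNA expression profiles into an *association matrix* ``A`` (miRNA rows ×
mRNA columns).  Each cell starts life as the Spearman rank correlation
``c_mn`` of one miRNA and one mRNA across the matched samples and is then
reconciled with binary target-site predictions ``t_mn``:

* negative correlation **with** a predicted site — direct repression, kept;
* positive correlation **without** a site — admissible indirect
  (downstream) effect, kept;
* the two remaining combinations contradict the seed-binding model and are
  neutralized to 0.

No correlation-magnitude threshold is applied at this stage; conflicting
cells are zeroed so they contribute nothing to the bicluster objective.

Matrices are plain :class:`pandas.DataFrame` objects throughout: expression
is features × samples, correlation/target/association matrices are
miRNA × mRNA.  Missing correlations (zero-variance features, too few
pairwise-complete samples) are ``NaN`` in the correlation matrix and become
0 in the association matrix.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "validate_expression",
    "compute_correlations",
    "integrate",
    "check_association_invariants",
]


class InvalidInputError(ValueError):
    """Raised when an input matrix violates a precondition."""


def _clean_labels(index: pd.Index, what: str) -> pd.Index:
    labels = index.astype(str).str.strip()
    if labels.duplicated().any():
        dupes = sorted(labels[labels.duplicated()].unique())
        raise InvalidInputError(f"duplicated {what} ids: {dupes[:5]}")
    return labels

def validate_expression(expr: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalize an expression matrix (features × samples).

    Feature and sample identifiers are whitespace-trimmed and matched
    case-sensitively; duplicates raise :class:`InvalidInputError` rather
    than being silently averaged.
    """
    out = expr.copy()
    out.index = _clean_labels(out.index, "feature")
    out.columns = _clean_labels(out.columns, "sample")
    return out.astype(float)


def _rank_rows(values: np.ndarray) -> np.ndarray:
    # average ranks for ties, the standard Spearman convention
    return stats.rankdata(values, axis=1)


def _standardize_rows(ranks: np.ndarray) -> np.ndarray:
    centered = ranks - ranks.mean(axis=1, keepdims=True)
    scale = np.sqrt((centered**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        z = centered / scale[:, None]
    z[scale == 0] = np.nan  # zero-variance feature -> whole row missing
    return z


def compute_correlations(
    mirna_expr: pd.DataFrame,
    mrna_expr: pd.DataFrame,
    method: str = "spearman",
    min_samples: int = 3,
) -> pd.DataFrame:
    """Spearman rank correlation of every miRNA against every mRNA.

    Parameters
    ----------
    mirna_expr, mrna_expr
        Expression matrices (features × samples).  Only the intersection of
        sample ids is used; fewer than ``min_samples`` matched samples is an
        error.
    method
        ``"spearman"`` (rank correlation, default) or ``"pearson"``.
    min_samples
        Minimum number of pairwise-complete samples per (miRNA, mRNA) pair;
        pairs below it are flagged missing (``NaN``).

    Returns
    -------
    pandas.DataFrame
        miRNA × mRNA correlation matrix in [−1, +1]; ``NaN`` marks missing
        cells (zero variance or insufficient complete samples).
    """
    if method not in ("spearman", "pearson"):
        raise InvalidInputError(f"unknown correlation method {method!r}")
    mirna_expr = validate_expression(mirna_expr)
    mrna_expr = validate_expression(mrna_expr)

    shared = mirna_expr.columns.intersection(mrna_expr.columns)
    if len(shared) < min_samples:
        raise InvalidInputError(
            f"need at least {min_samples} matched samples, got {len(shared)} "
            f"(miRNA matrix has {mirna_expr.shape[1]}, "
            f"mRNA matrix has {mrna_expr.shape[1]})"
        )
    x = mirna_expr[shared].to_numpy(float)
    y = mrna_expr[shared].to_numpy(float)

    if not (np.isnan(x).any() or np.isnan(y).any()):
        corr = _complete_corr(x, y, method)
    else:
        corr = _pairwise_corr(x, y, method, min_samples)
    np.clip(corr, -1.0, 1.0, out=corr, where=~np.isnan(corr))
    return pd.DataFrame(corr, index=mirna_expr.index, columns=mrna_expr.index)


def _complete_corr(x: np.ndarray, y: np.ndarray, method: str) -> np.ndarray:
    if method == "spearman":
        x, y = _rank_rows(x), _rank_rows(y)
    return _standardize_rows(x) @ _standardize_rows(y).T


def _pairwise_corr(
    x: np.ndarray, y: np.ndarray, method: str, min_samples: int
) -> np.ndarray:
    """Pairwise-complete correlation; slow path, only taken when NaNs exist."""
    corr = np.full((x.shape[0], y.shape[0]), np.nan)
    for i in range(x.shape[0]):
        xi = x[i]
        ok_i = ~np.isnan(xi)
        for j in range(y.shape[0]):
            yj = y[j]
            ok = ok_i & ~np.isnan(yj)
            if ok.sum() < min_samples:
                continue
            a, b = xi[ok], yj[ok]
            if np.ptp(a) == 0 or np.ptp(b) == 0:
                continue
            if method == "spearman":
                corr[i, j] = stats.spearmanr(a, b).statistic
            else:
                corr[i, j] = stats.pearsonr(a, b).statistic
    return corr


def integrate(corr: pd.DataFrame, targets: pd.DataFrame) -> pd.DataFrame:
    """Reconcile correlations with predicted target sites.

    Keeps negative correlations backed by a predicted site (direct
    repression) and positive correlations without a site (indirect,
    downstream); all conflicting cells, exact zeros and missing values
    become 0.  Labels are intersected first; an empty intersection on
    either axis is an error.

    Returns the association matrix aligned to the intersected labels.
    """
    corr = corr.copy()
    corr.index = _clean_labels(corr.index, "miRNA")
    corr.columns = _clean_labels(corr.columns, "mRNA")
    targets = targets.copy()
    targets.index = _clean_labels(targets.index, "miRNA")
    targets.columns = _clean_labels(targets.columns, "mRNA")

    rows = corr.index.intersection(targets.index)
    cols = corr.columns.intersection(targets.columns)
    if len(rows) == 0 or len(cols) == 0:
        raise InvalidInputError(
            "no shared labels between correlation and target matrices "
            f"({len(rows)} miRNAs, {len(cols)} mRNAs in common)"
        )
    c = corr.loc[rows, cols].to_numpy(float)
    t = targets.loc[rows, cols].to_numpy(bool)

    keep = ((c < 0) & t) | ((c > 0) & ~t)
    a = np.where(keep & ~np.isnan(c), c, 0.0)
    return pd.DataFrame(a, index=rows, columns=cols)


def check_association_invariants(assoc: pd.DataFrame, targets: pd.DataFrame) -> None:
    """Assert the sign/target consistency contract of an association matrix.

    Negative cells must have a predicted site, positive cells must lack one.
    Raises :class:`AssertionError` when violated.
    """
    t = targets.loc[assoc.index, assoc.columns].to_numpy(bool)
    a = assoc.to_numpy(float)
    if not (t | (a >= 0)).all():
        raise AssertionError("negative association without predicted target site")
    if not (~t | (a <= 0)).all():
        raise AssertionError("positive association despite predicted target site")
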
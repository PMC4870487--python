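"""Value transforms, quantile normalization and probe filtering.

Statistical testing downstream runs on M-values (the variance-stabilized
logit of beta); effect-size filtering and clustering stay on the beta
scale. Both directions of the transform live here.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .io import ValidationError


def beta_to_m(beta, epsilon: float = 1e-6):
    """Logit transform: ``M = log2(b / (1 - b))`` with clipping.

    Beta values are clipped into ``[epsilon, 1 - epsilon]`` first so the
    result is always finite. Works elementwise on scalars, arrays and
    DataFrames (NaN propagates).
    """
    if not 0.0 < epsilon < 0.5:
        raise ValueError(f"epsilon={epsilon} must lie in (0, 0.5)")
    if isinstance(beta, pd.DataFrame):
        return pd.DataFrame(beta_to_m(beta.to_numpy(float), epsilon),
                            index=beta.index, columns=beta.columns)
    b = np.clip(np.asarray(beta, dtype=float), epsilon, 1.0 - epsilon)
    b = np.where(np.isnan(np.asarray(beta, dtype=float)), np.nan, b)
    out = np.log2(b / (1.0 - b))
    return out if out.ndim else float(out)


def m_to_beta(m):
    """Inverse of :func:`beta_to_m` (without the clip): ``b = 2^M / (2^M + 1)``."""
    if isinstance(m, pd.DataFrame):
        return pd.DataFrame(m_to_beta(m.to_numpy(float)),
                            index=m.index, columns=m.columns)
    e = np.exp2(np.asarray(m, dtype=float))
    out = e / (1.0 + e)
    return out if out.ndim else float(out)


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every column onto the common reference distribution.

    The reference is the row-mean of the column-wise sorted values; each
    column's values are replaced by the reference value of their rank,
    ties receiving the mean of the reference values they span. Idempotent
    on tie-free inputs.
    """
    if matrix.shape[1] < 2:
        raise ValidationError("quantile normalization needs >= 2 columns")
    X = matrix.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValidationError(
            "quantile normalization requires complete data; impute or drop "
            "missing values first")
    order = np.argsort(X, axis=0, kind="stable")
    ref = np.mean(np.take_along_axis(X, order, axis=0), axis=1)
    out = np.empty_like(X)
    n = X.shape[0]
    for j in range(X.shape[1]):
        col = X[:, j]
        idx = order[:, j]
        vals = ref.copy()
        # average reference values across tied runs of the sorted column
        sorted_col = col[idx]
        start = 0
        for k in range(1, n + 1):
            if k == n or sorted_col[k] != sorted_col[start]:
                if k - start > 1:
                    vals[start:k] = vals[start:k].mean()
                start = k
        out[idx, j] = vals
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def filter_snp_probes(matrix: pd.DataFrame, annotation: pd.DataFrame,
                      unannotated: str = "drop") -> pd.DataFrame:
    """Remove probes whose annotation flags a known SNP in the probe body.

    Probes missing from the annotation are dropped by default (with a
    warning); pass ``unannotated="keep"`` to retain them.
    """
    if unannotated not in ("drop", "keep"):
        raise ValueError("unannotated must be 'drop' or 'keep'")
    known = matrix.index.isin(annotation.index)
    if not known.all():
        n_missing = int((~known).sum())
        warnings.warn(
            f"{n_missing} probe(s) missing from annotation "
            f"({unannotated}ping them)", stacklevel=2)
    snp = pd.Series(False, index=matrix.index)
    covered = matrix.index[known]
    snp.loc[covered] = annotation.loc[covered, "known_snp"].to_numpy()
    keep = ~snp.to_numpy()
    if unannotated == "drop":
        keep &= known
    out = matrix.loc[keep]
    if out.shape[0] == 0:
        warnings.warn("all probes removed by SNP filter", stacklevel=2)
    return out
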
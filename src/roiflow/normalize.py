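"""Between-sample normalization and replicate-based unwanted-variation removal.

``between_lane_normalize`` rescales ROI columns so global signal intensity
is comparable (upper-quartile, full-quantile, or median variants).
``estimate_unwanted_variation`` centers the log matrix within replicate
groups — ROIs that share all biological covariates — and reads nuisance
factors off the SVD of what remains; the factors can be regressed out of
the matrix or passed downstream as design covariates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from roiflow.errors import ConfigurationError
from roiflow.io import RoiCountMatrix

#: Metadata keys whose joint levels define biological replicate groups.
DEFAULT_REPLICATE_KEYS = ("group", "compartment")


@dataclass
class UnwantedFactors:
    """ROI-space nuisance factors: orthonormal columns plus singular values."""

    k: int
    factor_matrix: pd.DataFrame  # ROIs x k
    singular_values: np.ndarray  # length k, non-increasing

    def __post_init__(self) -> None:
        if self.factor_matrix.shape[1] != self.k:
            raise ConfigurationError("factor matrix width disagrees with k")
        if len(self.singular_values) != self.k:
            raise ConfigurationError("need one singular value per factor")


def _column_quantile_scale(x: np.ndarray, q: float) -> np.ndarray:
    n_rois = x.shape[1]
    quantiles = np.empty(n_rois)
    for j in range(n_rois):
        col = x[:, j]
        nz = col[col > 0]
        quantiles[j] = np.percentile(nz, q)
    target = np.exp(np.mean(np.log(quantiles)))
    return target / quantiles


def _full_quantile(x: np.ndarray) -> np.ndarray:
    """Replace each column by the across-column mean order statistics.

    Ties within a column receive the mean of the reference values at the
    tied sort positions, so identical inputs map to identical outputs.
    """
    order = np.argsort(x, axis=0, kind="stable")
    ref = np.take_along_axis(x.astype(float), order, axis=0).mean(axis=1)
    out = np.empty(x.shape, dtype=float)
    for j in range(x.shape[1]):
        assigned = np.empty(x.shape[0])
        assigned[order[:, j]] = ref
        # average the reference values over tied input values
        uniq, inverse = np.unique(x[:, j], return_inverse=True)
        sums = np.bincount(inverse, weights=assigned, minlength=len(uniq))
        cnts = np.bincount(inverse, minlength=len(uniq))
        out[:, j] = (sums / cnts)[inverse]
    return out


def between_lane_normalize(m: RoiCountMatrix, method: str = "upper") -> RoiCountMatrix:
    """Adjust for global differences in signal intensity between ROIs.

    ``upper``/``median``: scale each ROI column so its 75th/50th percentile
    of nonzero values equals the across-column geometric mean of those
    percentiles. ``full``: full-quantile normalization — every column is
    given the across-column mean order statistics (ties averaged). Gene and
    ROI ordering is preserved; output is real-valued.
    """
    x = m.counts.to_numpy()
    zero_cols = np.where((x != 0).sum(axis=0) == 0)[0]
    if len(zero_cols):
        raise ConfigurationError(f"all-zero ROI column: {m.rois[zero_cols[0]]!r}")
    if method == "upper":
        out = x * _column_quantile_scale(x, 75.0)[None, :]
    elif method == "median":
        out = x * _column_quantile_scale(x, 50.0)[None, :]
    elif method == "full":
        out = _full_quantile(x)
    else:
        raise ConfigurationError(f"unknown normalization method {method!r}")
    counts = pd.DataFrame(out, index=m.counts.index, columns=m.counts.columns)
    return RoiCountMatrix(counts, m.metadata.copy())


def replicate_groups_from_metadata(
    metadata: pd.DataFrame, keys: tuple[str, ...] = DEFAULT_REPLICATE_KEYS
) -> list[list[str]]:
    """Partition ROIs into replicate groups by joint metadata levels."""
    grouped = metadata.groupby(list(keys), sort=True, observed=True)
    return [list(idx) for _, idx in grouped.groups.items()]


def estimate_unwanted_variation(
    m: RoiCountMatrix, replicate_groups: list[list[str]], k: int
) -> UnwantedFactors:
    """Estimate k nuisance factors from replicate structure.

    log(x+1)-transform, center each gene within every replicate group
    (which annihilates the biological signal the groups share), then take
    the first k right-singular vectors of the centered matrix as ROI-space
    factors.
    """
    if k < 1:
        raise ConfigurationError("k must be >= 1")
    rois = m.rois
    seen: set[str] = set()
    for group in replicate_groups:
        if len(group) < 2:
            raise ConfigurationError(f"singleton replicate group: {group}")
        seen.update(group)
    missing = set(rois) - seen
    if missing:
        raise ConfigurationError(
            f"ROIs not covered by any replicate group: {sorted(missing)[:5]}"
        )
    if k > min(m.shape):
        raise ConfigurationError(f"k={k} exceeds matrix rank bound {min(m.shape)}")

    log = np.log1p(m.counts.to_numpy(dtype=float))
    col_pos = {r: j for j, r in enumerate(rois)}
    centered = log.copy()
    for group in replicate_groups:
        idx = [col_pos[r] for r in group]
        centered[:, idx] -= centered[:, idx].mean(axis=1, keepdims=True)

    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    factors = pd.DataFrame(
        vt[:k].T, index=rois, columns=[f"W{j + 1}" for j in range(k)]
    )
    return UnwantedFactors(k=k, factor_matrix=factors, singular_values=s[:k])


def remove_unwanted(m: RoiCountMatrix, w: UnwantedFactors | None) -> RoiCountMatrix:
    """Project the estimated factors out of every gene's log profile.

    OLS projection of each log(x+1) row onto the factor columns is
    subtracted; the result is exponentiated back (minus 1) and floored at
    zero. With no factors the matrix passes through unchanged.
    """
    if w is None or w.k == 0:
        return RoiCountMatrix(m.counts.copy(), m.metadata.copy())
    if list(w.factor_matrix.index) != m.rois:
        raise ConfigurationError("factor matrix ROIs disagree with count matrix")
    log = np.log1p(m.counts.to_numpy(dtype=float))
    basis, _ = np.linalg.qr(w.factor_matrix.to_numpy())  # guard orthonormality
    adjusted = log - (log @ basis) @ basis.T
    out = np.maximum(np.expm1(adjusted), 0.0)
    counts = pd.DataFrame(out, index=m.counts.index, columns=m.counts.columns)
    return RoiCountMatrix(counts, m.metadata.copy())
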
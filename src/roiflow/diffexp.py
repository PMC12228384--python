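"""Negative-binomial Wald differential expression between PD and control ROIs.

Median-of-ratios size factors, gene-wise method-of-moments dispersions
shrunk toward a 1/mu trend, an NB log-link regression fitted by IRLS with
the group indicator (and optional covariates) in the design, Wald p-values,
Benjamini-Hochberg adjustment, and the DEG filter (adjusted p < alpha and
|log2FC| > lfc_min).

The implementation is a deliberately simplified NB pipeline: no independent
filtering, no outlier refitting, no fold-change shrinkage.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import norm

from roiflow.errors import ConfigurationError
from roiflow.io import RoiCountMatrix

LN2 = np.log(2.0)

DEG_TABLE_COLUMNS = [
    "base_mean", "log2fc", "se", "wald_stat", "p", "adj_p",
    "is_deg", "direction", "converged",
]


def size_factors(m: RoiCountMatrix) -> pd.Series:
    """Median-of-ratios size factors, normalized to geometric mean 1.

    Each ROI's factor is the median over genes of its count divided by the
    gene's geometric mean across ROIs, using only genes expressed in every
    ROI. When no gene qualifies, geometric means and medians fall back to
    positive counts only.
    """
    x = m.counts.to_numpy(dtype=float)
    if not (x > 0).any():
        raise ConfigurationError("all-zero count matrix")
    with np.errstate(divide="ignore"):
        logx = np.log(x)
    all_pos = np.all(x > 0, axis=1)
    if all_pos.any():
        loggeo = logx[all_pos].mean(axis=1)
        logratios = logx[all_pos] - loggeo[:, None]
        logsf = np.median(logratios, axis=0)
    else:
        # positive-count-only fallback
        any_pos = (x > 0).any(axis=1)
        loggeo = np.where(any_pos,
                          np.where(x > 0, logx, 0.0).sum(axis=1)
                          / np.maximum((x > 0).sum(axis=1), 1), np.nan)
        logsf = np.empty(x.shape[1])
        for j in range(x.shape[1]):
            pos = x[:, j] > 0
            if not pos.any():
                raise ConfigurationError(f"all-zero ROI column: {m.rois[j]!r}")
            logsf[j] = np.median(logx[pos, j] - loggeo[pos])
    logsf -= logsf.mean()
    return pd.Series(np.exp(logsf), index=m.rois, name="size_factor")


def estimate_dispersions(
    m: RoiCountMatrix,
    sf: pd.Series | None = None,
    shrinkage_weight: float = 0.3,
) -> pd.Series:
    """Per-gene NB dispersion alpha (Var = mu + alpha mu^2).

    Gene-wise method-of-moments estimate on size-factor-normalized counts,
    a smooth trend ``a1/mu + a0`` fitted to the positive estimates, and a
    weighted shrinkage of each estimate toward the trend. Zero-variance
    genes keep alpha = 0.
    """
    if m.shape[1] < 2:
        raise ConfigurationError("need >= 2 ROIs to estimate dispersion")
    if not 0 <= shrinkage_weight <= 1:
        raise ConfigurationError("shrinkage_weight must lie in [0, 1]")
    if sf is None:
        sf = size_factors(m)
    norm_counts = m.counts.to_numpy(dtype=float) / sf.to_numpy()[None, :]
    mu = norm_counts.mean(axis=1)
    s2 = norm_counts.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(mu > 0, np.maximum(0.0, (s2 - mu) / mu**2), 0.0)

    fit_mask = (raw > 0) & (mu > 0)
    if fit_mask.sum() >= 2:
        design = np.column_stack([1.0 / mu[fit_mask], np.ones(fit_mask.sum())])
        coef, *_ = np.linalg.lstsq(design, raw[fit_mask], rcond=None)
        a1, a0 = coef
        with np.errstate(divide="ignore"):
            trend = np.where(mu > 0, a1 / mu + a0, 0.0)
        trend = np.maximum(trend, 1e-8)
    else:
        trend = np.full_like(raw, max(float(np.median(raw[raw > 0]))
                                      if (raw > 0).any() else 1e-8, 1e-8))

    alpha = (1 - shrinkage_weight) * raw + shrinkage_weight * trend
    alpha = np.where((s2 == 0) | (mu == 0), 0.0, alpha)
    return pd.Series(alpha, index=m.genes, name="dispersion")


def _check_full_rank(x: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        # name a minimal set of columns involved in the collinearity
        bad = []
        kept: list[int] = []
        for j in range(x.shape[1]):
            trial = x[:, kept + [j]]
            if np.linalg.matrix_rank(trial) == len(kept) + 1:
                kept.append(j)
            else:
                bad.append(names[j])
        raise ConfigurationError(f"rank-deficient design; collinear columns: {bad}")


def nb_wald_test(
    m: RoiCountMatrix,
    group: pd.Series | None = None,
    covariates: pd.DataFrame | None = None,
    dispersions: pd.Series | None = None,
    sf: pd.Series | None = None,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> pd.DataFrame:
    """Per-gene NB log-link regression with a Wald test on the group effect.

    ``group`` defaults to the metadata ``group`` column; PD is coded 1 so a
    positive log2fc means higher expression in PD. Log size factors enter
    as an offset. Genes with all-zero counts get NaN p-values; genes whose
    IRLS does not converge are flagged, not dropped.
    """
    if group is None:
        if "group" not in m.metadata.columns:
            raise ConfigurationError("no group labels available")
        group = m.metadata["group"]
    group = group.loc[m.rois]
    levels = set(group.unique())
    if levels != {"PD", "control"}:
        raise ConfigurationError(f"need both PD and control ROIs, got {sorted(levels)}")

    if sf is None:
        sf = size_factors(m)
    if dispersions is None:
        dispersions = estimate_dispersions(m, sf)

    y = m.counts.to_numpy(dtype=float)
    n_genes, n_obs = y.shape
    g = (group == "PD").to_numpy(dtype=float)

    cols = [np.ones(n_obs), g]
    names = ["intercept", "group_PD"]
    if covariates is not None:
        cov = covariates.loc[m.rois]
        for c in cov.columns:
            cols.append(cov[c].to_numpy(dtype=float))
            names.append(str(c))
    design = np.column_stack(cols)
    _check_full_rank(design, names)
    n_par = design.shape[1]

    offset = np.log(sf.to_numpy())[None, :]
    alpha = dispersions.loc[m.genes].to_numpy()[:, None]

    nonzero = y.sum(axis=1) > 0
    beta = np.zeros((n_genes, n_par))
    beta[:, 0] = np.log(np.maximum(y / np.exp(offset), 1e-8).mean(axis=1))

    converged = np.zeros(n_genes, dtype=bool)
    converged[~nonzero] = True  # nothing to fit
    dev_old = np.full(n_genes, np.inf)
    active = nonzero.copy()
    cov_beta = np.zeros((n_genes, n_par, n_par))

    def deviance(yv, muv, av):
        with np.errstate(divide="ignore", invalid="ignore"):
            term1 = np.where(yv > 0, yv * np.log(yv / muv), 0.0)
            poisson_like = av[:, 0] == 0
            t2 = np.empty_like(muv)
            a = np.where(av > 0, av, 1.0)
            t2_nb = (yv + 1.0 / a) * np.log((1.0 + a * muv) / (1.0 + a * yv))
            t2_pois = muv - yv
            t2 = np.where(poisson_like[:, None], t2_pois, t2_nb)
        return 2.0 * (term1 + t2).sum(axis=1)

    for _ in range(max_iter):
        if not active.any():
            break
        idx = np.where(active)[0]
        eta = beta[idx] @ design.T + offset
        mu = np.exp(np.clip(eta, -30, 30))
        w = mu / (1.0 + alpha[idx] * mu)
        z = (eta - offset) + (y[idx] - mu) / mu
        xtwx = np.einsum("ni,gn,nj->gij", design, w, design)
        xtwz = np.einsum("ni,gn,gn->gi", design, w, z)
        ridge = 1e-10 * np.eye(n_par)[None, :, :]
        beta[idx] = np.linalg.solve(xtwx + ridge, xtwz[..., None])[..., 0]
        cov_beta[idx] = np.linalg.inv(xtwx + ridge)
        dev = deviance(y[idx], np.exp(np.clip(beta[idx] @ design.T + offset, -30, 30)),
                       alpha[idx])
        rel = np.abs(dev - dev_old[idx]) / (np.abs(dev) + 0.1)
        done = rel < tol
        converged[idx[done]] = True
        dev_old[idx] = dev
        active[idx[done]] = False

    se = np.sqrt(np.maximum(cov_beta[:, 1, 1], 0.0))
    wald = np.divide(beta[:, 1], se, out=np.zeros(n_genes), where=se > 0)
    p = 2.0 * norm.sf(np.abs(wald))
    p[~nonzero] = np.nan
    se[~nonzero] = np.nan

    adj_p = bh_adjust(p)
    table = pd.DataFrame(
        {
            "base_mean": (y / np.exp(offset)).mean(axis=1),
            "log2fc": beta[:, 1] / LN2,
            "se": se / LN2,
            "wald_stat": wald,
            "p": p,
            "adj_p": adj_p,
            "is_deg": False,
            "direction": "none",
            "converged": converged,
        },
        index=m.genes,
    )
    return select_degs(table)


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment.

    NaN entries (undefined tests) are excluded from the denominator and
    propagated as NaN. Output is monotone and capped at 1.
    """
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    defined = ~np.isnan(p)
    vals = p[defined]
    if ((vals < 0) | (vals > 1)).any():
        raise ConfigurationError("p-values outside [0, 1]")
    n = len(vals)
    if n == 0:
        return out
    order = np.argsort(vals, kind="stable")
    ranked = vals[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    result = np.empty(n)
    result[order] = adj
    out[defined] = result
    return out


def select_degs(table: pd.DataFrame, alpha: float = 0.05, lfc_min: float = 0.5) -> pd.DataFrame:
    """Apply the DEG filter: adjusted p < alpha and |log2fc| > lfc_min (strict)."""
    table = table.copy()
    sig = (table["adj_p"] < alpha) & (table["log2fc"].abs() > lfc_min)
    sig = sig.fillna(False)
    table["is_deg"] = sig
    table["direction"] = np.where(
        sig & (table["log2fc"] > 0), "up", np.where(sig, "down", "none")
    )
    return table


def deg_genes(table: pd.DataFrame, direction: str | None = None) -> list[str]:
    """Gene ids flagged as DEGs, optionally restricted to 'up' or 'down'."""
    mask = table["is_deg"]
    if direction is not None:
        mask = mask & (table["direction"] == direction)
    return list(table.index[mask])
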
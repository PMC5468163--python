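"""Multivariate divergence-outlier detection by Mahalanobis distance.

Each locus is a point in (F_ST, d_xy, delta_pi) space; its Mahalanobis
distance (MD) from the multivariate centroid, scaled by the sample
covariance of all complete loci, flags loci whose joint differentiation
departs from the genomic background without committing to any single
statistic or demographic model.  delta_pi enters signed: loci at either
diversity extreme can carry high MD.

Outliers exceed the empirical 95th MD quantile, strong outliers the
99th; a retention floor on F_ST (default 0.2) then removes high-MD loci
whose low relative differentiation is better explained by shared
intermediate-frequency alleles (balancing selection) than by divergent
selection.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

logger = logging.getLogger("hybridzone")

DEFAULT_COLUMNS = ("fst", "dxy", "delta_pi")


def mahalanobis_distances(
    stats: pd.DataFrame, columns: tuple[str, ...] = DEFAULT_COLUMNS
) -> pd.Series:
    """Mahalanobis distance of each locus from the multivariate centroid.

    ``md_i = sqrt((x_i - mu)^T S^{-1} (x_i - mu))`` with ``mu`` the column
    means and ``S`` the sample covariance over complete rows.  Rows with
    any missing statistic get NaN.  A near-singular covariance is
    regularised with a ridge of ``1e-8 * trace(S)/dim``; if that fails the
    covariance is genuinely degenerate and an error is raised.
    """
    X = stats.loc[:, list(columns)].to_numpy(dtype=float)
    complete = np.isfinite(X).all(axis=1)
    k = len(columns)
    if complete.sum() < k + 1:
        raise ValueError(f"need at least {k + 1} complete rows, got {int(complete.sum())}")
    Xc = X[complete]
    mu = Xc.mean(axis=0)
    S = np.cov(Xc, rowvar=False)
    S = np.atleast_2d(S)
    try:
        Sinv = np.linalg.inv(S)
    except np.linalg.LinAlgError:
        Sinv = None
    if Sinv is None or np.linalg.cond(S) > 1e12:
        ridge = 1e-8 * np.trace(S) / k
        warnings.warn("near-singular covariance; applying ridge regularisation")
        logger.warning("mahalanobis: applying ridge %.3e to covariance", ridge)
        S = S + ridge * np.eye(k)
        try:
            Sinv = np.linalg.inv(S)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError("covariance singular even after ridge") from exc

    md = np.full(len(stats), np.nan)
    d = X[complete] - mu
    md[complete] = np.sqrt(np.einsum("ij,jk,ik->i", d, Sinv, d))
    return pd.Series(md, index=stats.index, name="md")


def classify_divergence_outliers(
    md: pd.Series,
    stats: pd.DataFrame,
    q_outlier: float = 0.95,
    q_strong: float = 0.99,
    fst_floor: float = 0.2,
) -> pd.DataFrame:
    """Flag outlier loci from MD quantiles and apply the F_ST retention floor.

    Quantiles are empirical (linear-interpolation, type 7) over non-missing
    MD; flags use strict ``>`` ("exceeds").  ``retained`` marks outliers
    that also pass ``fst > fst_floor`` and feed comparative analyses.
    """
    mdv = md.to_numpy(dtype=float)
    finite = np.isfinite(mdv)
    t95 = float(np.quantile(mdv[finite], q_outlier))
    t99 = float(np.quantile(mdv[finite], q_strong))
    is_outlier = finite & (mdv > t95)
    is_strong = finite & (mdv > t99)
    fst = stats["fst"].to_numpy(dtype=float)
    passes_floor = np.isfinite(fst) & (fst > fst_floor)
    out = pd.DataFrame(
        {
            "locus_id": stats["locus_id"].to_numpy(),
            "md": mdv,
            "is_outlier": is_outlier,
            "is_strong": is_strong,
            "passes_fst_floor": passes_floor,
            "retained": is_outlier & passes_floor,
        }
    )
    logger.info(
        "divergence outliers: %d > q%.2f, %d > q%.2f, %d retained after F_ST floor %.2f",
        int(is_outlier.sum()), q_outlier, int(is_strong.sum()), q_strong,
        int(out["retained"].sum()), fst_floor,
    )
    return out
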
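"""Permutation-based expression screen against a quantitative response.

Every gene's expression profile is correlated (Spearman) with a response —
either a strain's minor-allele content or its trait value — and significance
is controlled two ways at once, mirroring the microarray-significance
(SAM-style) recipe:

* a per-gene two-sided p from the rank correlation, and
* a permutation q-value: for each candidate threshold on |rho| the estimated
  FDR is pi0 x (median count of null |rho| exceedances across response
  permutations) / (observed count at that threshold), and a gene's q is the
  lowest estimated FDR at any threshold that calls it.

Defaults follow the screen this package models: 1000 response permutations,
K = 10 nearest-neighbour imputation of missing expression values, and the
dual cutoff q < 0.15, p < 0.05.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import stat_core

logger = logging.getLogger(__name__)


def knn_impute(expr: pd.DataFrame, k: int = 10) -> pd.DataFrame:
    """Impute missing expression cells from the k nearest genes.

    Distance between genes is the mean squared difference over co-observed
    strains (so genes with different missingness patterns remain comparable).
    A missing cell (gene g, strain s) becomes the unweighted mean of the k
    nearest genes that are observed in strain s.  Observed values are never
    altered.  Genes with no observed value are dropped with a warning; if
    fewer than k candidate neighbours exist, all of them are used (logged).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    X = expr.to_numpy(dtype=float)
    obs = np.isfinite(X)
    all_missing = ~obs.any(axis=1)
    if all_missing.any():
        logger.warning(
            "dropping %d gene(s) with no observed expression value",
            int(all_missing.sum()),
        )
        expr = expr.loc[~all_missing]
        X = X[~all_missing]
        obs = obs[~all_missing]
    if obs.all():
        return expr.copy()

    out = X.copy()
    need = np.flatnonzero(~obs.all(axis=1))
    X0 = np.where(obs, X, 0.0)
    for g in need:
        # mean squared difference over strains co-observed with gene g
        shared = obs & obs[g]  # (n_genes, n_strains)
        n_shared = shared.sum(axis=1)
        diff = X0 - X0[g]
        with np.errstate(invalid="ignore", divide="ignore"):
            d2 = np.where(
                n_shared > 0,
                ((diff**2) * shared).sum(axis=1) / np.maximum(n_shared, 1),
                np.inf,
            )
        d2[g] = np.inf  # a gene is not its own neighbour
        for s in np.flatnonzero(~obs[g]):
            cand = np.flatnonzero(obs[:, s] & np.isfinite(d2))
            if cand.size == 0:
                logger.warning(
                    "no neighbour observed in strain %s for gene %s; cell left NaN",
                    expr.columns[s],
                    expr.index[g],
                )
                continue
            if cand.size < k:
                logger.info(
                    "gene %s strain %s: only %d neighbours available (k=%d)",
                    expr.index[g],
                    expr.columns[s],
                    cand.size,
                    k,
                )
            nearest = cand[np.argsort(d2[cand], kind="stable")[:k]]
            out[g, s] = X[nearest, s].mean()
    return pd.DataFrame(out, index=expr.index, columns=expr.columns)


def _sam_pi0(obs_rho: np.ndarray, null_rho: np.ndarray) -> float:
    """Fraction of truly null genes, estimated from the permutation pool.

    The share of observed statistics falling inside the interquartile range
    of the pooled null, divided by 0.5 (the null mass of that interval).
    """
    q25, q75 = np.percentile(null_rho, [25, 75])
    inside = np.mean((obs_rho >= q25) & (obs_rho <= q75))
    return float(min(1.0, max(inside / 0.5, 0.0)))


def sam_screen(
    expr: pd.DataFrame,
    response: np.ndarray | pd.Series,
    response_label: str = "response",
    n_perm: int = 1000,
    seed: int = 0,
    pi0: float | None = None,
) -> pd.DataFrame:
    """Screen every gene for rank correlation with a quantitative response.

    Returns one record per gene: ``gene_id``, ``response_label``, ``rho``,
    ``p_value``, ``q_value``, ``direction`` (``+``/``-``) and ``tested``.
    Constant-expression genes get NaN statistics, ``tested = False``, and are
    excluded from significance.  Identical inputs and seed give identical
    records.
    """
    if isinstance(response, pd.Series):
        response = response.reindex(expr.columns).to_numpy()
    response = np.asarray(response, dtype=float)
    if response.size != expr.shape[1]:
        raise ValueError("response length must equal the number of strains")
    if not np.isfinite(response).all():
        raise ValueError("response contains non-finite values")
    if expr.shape[1] < 5:
        raise ValueError("need >= 5 strains for the permutation screen")

    X = expr.to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("expression has missing values; run knn_impute first")

    rho, p = stat_core.spearman_matrix(X, response)
    tested = np.isfinite(rho)
    if (~tested).any():
        logger.warning(
            "%d constant-expression gene(s) excluded from significance",
            int((~tested).sum()),
        )

    # Permutation null, equivalent to rank-correlating each gene against each
    # permuted response but with gene ranks computed once: with Z the
    # row-standardised gene ranks and z_b the standardised permuted response
    # ranks, rho_null[b] = Z @ z_b.
    from scipy.stats import rankdata

    n = response.size
    rX = rankdata(X[tested], axis=1)
    Z = rX - rX.mean(axis=1, keepdims=True)
    Z /= np.sqrt((Z**2).sum(axis=1, keepdims=True))
    ry = rankdata(response)
    rng = np.random.default_rng(seed)
    perms = rng.permuted(np.tile(ry, (n_perm, 1)), axis=1)
    zp = perms - perms.mean(axis=1, keepdims=True)
    zp /= np.sqrt((zp**2).sum(axis=1, keepdims=True))
    null_rho = (Z @ zp.T).T  # (n_perm, n_tested)

    q = np.full(rho.size, np.nan)
    q[tested] = _sam_qvalues(rho[tested], null_rho, pi0=pi0)

    direction = np.where(rho >= 0, "+", "-").astype(object)
    direction[~tested] = None
    return pd.DataFrame(
        {
            "gene_id": expr.index.astype(str),
            "response_label": response_label,
            "rho": rho,
            "p_value": p,
            "q_value": q,
            "direction": direction,
            "tested": tested,
        }
    )


def _sam_qvalues(
    obs_rho: np.ndarray, null_rho: np.ndarray, pi0: float | None = None
) -> np.ndarray:
    """Permutation q-values over the exhaustive grid of observed |rho|.

    For threshold t: R(t) = #{|rho_obs| >= t}, V_b(t) = #{|rho_null_b| >= t}
    per permutation b; FDR(t) = pi0 * median_b V_b(t) / R(t).  A gene with
    |rho| = t gets q = min FDR over all thresholds <= t, clipped to [0, 1].
    """
    if pi0 is None:
        pi0 = _sam_pi0(obs_rho, null_rho.ravel())
    abs_obs = np.abs(obs_rho)
    order = np.argsort(-abs_obs, kind="mergesort")  # descending |rho|
    thresholds = abs_obs[order]
    sorted_abs = np.sort(abs_obs)
    # observed exceedance count at each threshold (ties counted together)
    R = abs_obs.size - np.searchsorted(sorted_abs, thresholds, side="left")
    null_sorted = np.sort(np.abs(null_rho), axis=1)
    # (n_perm, n_thresholds) exceedance counts via searchsorted per permutation
    V = null_rho.shape[1] - np.stack(
        [np.searchsorted(row, thresholds, side="left") for row in null_sorted]
    )
    med_V = np.median(V, axis=0)
    fdr = pi0 * med_V / np.maximum(R, 1)
    # q at threshold i = min FDR over thresholds j >= i (i.e. less extreme cuts
    # that still call the gene); running min from the least extreme end
    q_sorted = np.minimum.accumulate(fdr[::-1])[::-1]
    q = np.empty_like(q_sorted)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    return q


def select_significant(
    records: pd.DataFrame, q_max: float = 0.15, p_max: float = 0.05
) -> dict[str, set[str]]:
    """Split genes passing the dual cutoff by correlation direction."""
    ok = (
        records["tested"]
        & (records["q_value"] < q_max)
        & (records["p_value"] < p_max)
    )
    hit = records[ok]
    return {
        "+": set(hit.loc[hit["direction"] == "+", "gene_id"]),
        "-": set(hit.loc[hit["direction"] == "-", "gene_id"]),
    }
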
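"""Single-marker quantitative trait association across the panel.

Each marker is tested by simple linear regression of the trait on genotype
coded {P1: 0, P2: 1} — on a binary predictor this is algebraically identical
to the pooled two-sample t-test between the two carrier groups.  The scan is
used both for the trait itself and, with an allele-content score supplied as
the "trait", for locating loci that track MAC or HAC.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from . import stat_core
from .panel_io import MISSING, P2, GenotypePanel

logger = logging.getLogger(__name__)


def _regress_binary(
    G: np.ndarray, y: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised per-column OLS of ``y`` on binary ``G`` with missing codes.

    Returns (beta, p, n_used); columns that are monomorphic in the joined set
    or have n < 3 get NaN.
    """
    obs = G != MISSING
    x = np.where(obs, G, 0).astype(float)
    n = obs.sum(axis=0).astype(float)
    sx = x.sum(axis=0)
    sy = (y[:, None] * obs).sum(axis=0)
    sxx = (x**2 * obs).sum(axis=0)
    sxy = (x * y[:, None] * obs).sum(axis=0)
    syy = ((y**2)[:, None] * obs).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        sxx_c = sxx - sx**2 / n
        sxy_c = sxy - sx * sy / n
        syy_c = syy - sy**2 / n
        beta = sxy_c / sxx_c
        rss = syy_c - beta * sxy_c
        df = n - 2
        se = np.sqrt(np.maximum(rss, 0) / df / sxx_c)
        t = beta / se
    valid = (n >= 3) & (sxx_c > 0)
    p = np.full(G.shape[1], np.nan)
    p[valid] = 2 * stats.t.sf(
        np.abs(t[valid]), df[valid]
    )
    # zero-residual separation: p underflows to 0 via t = inf, which is fine
    beta = np.where(valid, beta, np.nan)
    return beta, p, obs.sum(axis=0)


def snp_association(
    panel: GenotypePanel,
    trait: pd.DataFrame,
    fdr: str = "storey",
    n_perm: int = 0,
    seed: int = 0,
) -> pd.DataFrame:
    """Regress the trait on each marker's genotype.

    Returns one record per marker: ``marker_id``, ``beta`` (trait units per
    P2 allele), ``p_value``, ``q_value``, ``n_used``, ``status``.  Markers
    monomorphic within the joined strain set, or with fewer than 3 usable
    strains, are reported with ``status`` set and no statistics.  ``fdr`` is
    ``storey`` or ``bh``; ``n_perm > 0`` replaces the asymptotic p by a
    label-permutation p (trait shuffled across strains, seeded).
    """
    tr = trait.set_index("strain_id")["trait_value"]
    strains = [s for s in panel.strain_ids if s in tr.index]
    if not strains:
        raise ValueError("no overlapping strains between panel and trait table")
    sub = panel.subset_strains(strains)
    y = tr.loc[strains].to_numpy(dtype=float)

    beta, p, n_used = _regress_binary(sub.calls, y)
    if n_perm > 0:
        p = _permutation_p(sub.calls, y, n_perm, seed)

    status = np.where(np.isfinite(p), "ok", "monomorphic_or_too_few")
    rec = pd.DataFrame(
        {
            "marker_id": sub.marker_ids,
            "beta": beta,
            "p_value": p,
            "q_value": np.nan,
            "n_used": n_used,
            "status": status,
        }
    )
    ok = rec["status"] == "ok"
    if ok.any():
        pv = rec.loc[ok, "p_value"].to_numpy()
        if fdr == "storey":
            rec.loc[ok, "q_value"] = stat_core.storey_qvalues(pv)
        elif fdr == "bh":
            rec.loc[ok, "q_value"] = stat_core.bh_adjust(pv)
        else:
            raise ValueError(f"unknown fdr procedure {fdr!r}")
    n_skip = int((~ok).sum())
    if n_skip:
        logger.info("%d marker(s) skipped (monomorphic or n < 3)", n_skip)
    return rec


def _permutation_p(G: np.ndarray, y: np.ndarray, n_perm: int, seed: int) -> np.ndarray:
    """Per-marker label-permutation p on |beta| (trait permuted across strains)."""
    rng = np.random.default_rng(seed)
    beta_obs = _regress_binary(G, y)[0]
    exceed = np.zeros(G.shape[1])
    for _ in range(n_perm):
        beta_b = _regress_binary(G, y[rng.permutation(y.size)])[0]
        exceed += np.abs(beta_b) >= np.abs(beta_obs) - 1e-12
    p = (exceed + 1) / (n_perm + 1)
    p[~np.isfinite(beta_obs)] = np.nan
    return p


def qtl_filter(
    records: pd.DataFrame, p_max: float, q_max: float | None = None
) -> set[str]:
    """Markers passing the p cutoff and, when given, the q (FDR) cutoff."""
    ok = (records["status"] == "ok") & (records["p_value"] < p_max)
    if q_max is not None:
        ok &= records["q_value"] < q_max
    return set(records.loc[ok, "marker_id"])
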
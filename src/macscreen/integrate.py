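"""Double-correlation candidate genes: intersection, enrichment, nearest SNPs.

The headline procedure: a gene is a candidate for the trait when its
expression is significantly correlated with *both* the panel's minor-allele
content and the trait itself.  This module intersects the two screens,
quantifies how far the observed overlap exceeds the independence expectation
n_total x (n_a/n_total) x (n_b/n_total), assigns each candidate its nearest
genotyped SNP, and tests per-SNP allelic effects on the trait.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import stat_core
from .panel_io import MISSING, P1, P2, GenotypePanel

logger = logging.getLogger(__name__)

#: sentinel distance for a marker inside the gene interval
IN_GENE = "in_gene"


@dataclass
class OverlapStats:
    n_total: int
    n_set_a: int
    n_set_b: int
    n_observed: int
    n_expected: float
    enrichment_p: float

    def as_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "n_set_a": self.n_set_a,
            "n_set_b": self.n_set_b,
            "n_observed": self.n_observed,
            "n_expected": self.n_expected,
            "enrichment_p": self.enrichment_p,
        }


def double_correlation(
    records_mac: pd.DataFrame,
    records_trait: pd.DataFrame,
    q_max: float = 0.15,
    p_max: float = 0.05,
) -> pd.DataFrame:
    """Genes significant in both screens, with per-response directions.

    Both screens must cover the same gene universe.  Candidates with
    discordant directions are retained and flagged (``concordant = False``)
    rather than dropped: direction disagreement is information, not noise.
    """
    ua = set(records_mac["gene_id"])
    ub = set(records_trait["gene_id"])
    if ua != ub:
        diff = sorted(ua ^ ub)
        raise ValueError(
            f"screens cover different gene universes; {len(diff)} gene(s) "
            f"differ, e.g. {diff[:5]}"
        )
    from .expression_screen import select_significant

    sig_a = select_significant(records_mac, q_max=q_max, p_max=p_max)
    sig_b = select_significant(records_trait, q_max=q_max, p_max=p_max)
    hits_a = sig_a["+"] | sig_a["-"]
    hits_b = sig_b["+"] | sig_b["-"]
    both = sorted(hits_a & hits_b)

    a = records_mac.set_index("gene_id")
    b = records_trait.set_index("gene_id")
    out = pd.DataFrame(
        {
            "gene_id": both,
            "rho_mac": a.loc[both, "rho"].to_numpy(),
            "rho_trait": b.loc[both, "rho"].to_numpy(),
            "direction_mac": a.loc[both, "direction"].to_numpy(),
            "direction_trait": b.loc[both, "direction"].to_numpy(),
        }
    )
    out["concordant"] = out["direction_mac"] == out["direction_trait"]
    n_disc = int((~out["concordant"]).sum())
    if n_disc:
        logger.warning("%d candidate(s) have discordant directions", n_disc)
    return out


def expected_overlap(n_total: int, n_a: int, n_b: int) -> float:
    """Expected size of the intersection of two independent gene sets."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not (0 <= n_a <= n_total and 0 <= n_b <= n_total):
        raise ValueError("set sizes must lie in [0, n_total]")
    return n_total * (n_a / n_total) * (n_b / n_total)


def overlap_enrichment(
    n_total: int,
    n_a: int,
    n_b: int,
    n_observed: int,
    method: str = "fisher_one_tailed",
) -> float:
    """Upper-tail p for observing >= n_observed genes in both sets.

    ``fisher_one_tailed`` uses the hypergeometric tail (draw n_a genes from
    n_total of which n_b are "successes"); ``binomial`` treats each of the
    n_a genes as an independent Bernoulli(n_b / n_total) trial.
    """
    if n_observed > min(n_a, n_b):
        raise ValueError("observed overlap exceeds the smaller set")
    if n_observed < 0:
        raise ValueError("n_observed must be non-negative")
    expected_overlap(n_total, n_a, n_b)  # validates counts
    if method == "fisher_one_tailed":
        return float(stats.hypergeom.sf(n_observed - 1, n_total, n_b, n_a))
    if method == "binomial":
        return float(stats.binom.sf(n_observed - 1, n_a, n_b / n_total))
    raise ValueError(f"unknown method {method!r}")


def overlap_stats(
    n_total: int, n_a: int, n_b: int, n_observed: int, method: str = "fisher_one_tailed"
) -> OverlapStats:
    return OverlapStats(
        n_total=n_total,
        n_set_a=n_a,
        n_set_b=n_b,
        n_observed=n_observed,
        n_expected=expected_overlap(n_total, n_a, n_b),
        enrichment_p=overlap_enrichment(n_total, n_a, n_b, n_observed, method),
    )


def nearest_snp(
    gene: pd.Series | dict, marker_map: pd.DataFrame
) -> tuple[str, int | str]:
    """Closest marker to a gene interval, with a strand-aware signed distance.

    Distance is measured from the nearer gene boundary.  A marker inside
    [start, end] returns the ``IN_GENE`` sentinel.  The sign is positive when
    the marker lies on the gene's 5' side (upstream of the first codon for a
    + strand gene, downstream of ``end`` for a - strand gene) and negative on
    the 3' side.  Equidistant ties break toward the 5' side.
    """
    chrom = str(gene["chromosome"])
    start, end = int(gene["start"]), int(gene["end"])
    strand = str(gene.get("strand", "+") if isinstance(gene, dict) else gene["strand"])
    on_chrom = marker_map[marker_map["chromosome"].astype(str) == chrom]
    if on_chrom.empty:
        raise ValueError(f"no marker on chromosome {chrom!r}")
    pos = on_chrom["position"].to_numpy()
    dist = np.where(
        pos < start, start - pos, np.where(pos > end, pos - end, 0)
    )
    # 5' side: lower coordinates for + strand, higher for - strand
    five_prime = (pos < start) if strand == "+" else (pos > end)
    order = np.lexsort((~five_prime, dist))  # min distance, ties favour 5'
    best = order[0]
    marker_id = str(on_chrom["marker_id"].iloc[best])
    if dist[best] == 0:
        return marker_id, IN_GENE
    signed = int(dist[best]) if five_prime[best] else -int(dist[best])
    return marker_id, signed


def allelic_effect_test(
    panel: GenotypePanel, trait: pd.DataFrame, marker_id: str
) -> dict:
    """Two-group trait comparison between P2 (HW) and P1 (N2) carriers.

    Pooled two-sided t-test over the joined strains; reports per-group mean,
    SEM and n.  When either carrier group has n < 2 the result is
    ``status="na"`` (not applicable), matching how single-strain groups are
    reported in practice.
    """
    tr = trait.set_index("strain_id")["trait_value"]
    strains = [s for s in panel.strain_ids if s in tr.index]
    if not strains:
        raise ValueError("no overlapping strains between panel and trait table")
    sub = panel.subset_strains(strains)
    g = sub.calls[:, sub.marker_index(marker_id)]
    y = tr.loc[strains].to_numpy(dtype=float)
    y_p2 = y[g == P2]
    y_p1 = y[g == P1]

    def _grp(v: np.ndarray) -> dict:
        return {
            "n": int(v.size),
            "mean": float(np.mean(v)) if v.size else np.nan,
            "sem": float(stats.sem(v)) if v.size >= 2 else np.nan,
        }

    out = {"marker_id": marker_id, "p2": _grp(y_p2), "p1": _grp(y_p1)}
    if y_p2.size < 2 or y_p1.size < 2:
        out.update(status="na", t=np.nan, p_value=np.nan)
        return out
    if np.var(y_p2, ddof=1) == 0 and np.var(y_p1, ddof=1) == 0:
        # identical-values degenerate case: no evidence of a difference
        same = float(np.mean(y_p2) == np.mean(y_p1))
        out.update(status="ok", t=0.0 if same else np.inf, p_value=1.0 if same else 0.0)
        return out
    res = stat_core.student_t_two_sample(y_p2, y_p1, tails=2)
    out.update(status="ok", t=res.statistic, p_value=res.p_value)
    return out


def success_rate_contrast(k1: int, n1: int, k2: int, n2: int) -> float:
    """One-tailed Fisher exact p that rate k1/n1 exceeds rate k2/n2."""
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2):
        raise ValueError("need 0 <= k <= n in both groups")
    return stat_core.fisher_exact_2x2(
        k1, n1 - k1, k2, n2 - k2, tail="one_greater"
    ).p_value


def annotate_candidates(
    candidates: pd.DataFrame,
    annotation: pd.DataFrame,
    marker_map: pd.DataFrame,
    panel: GenotypePanel | None = None,
    trait: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Attach nearest-SNP assignment (and allelic effects, if panel+trait given)."""
    ann = annotation.set_index("gene_id")
    rows = []
    for gene_id in candidates["gene_id"]:
        if gene_id not in ann.index:
            rows.append((gene_id, None, None, np.nan, np.nan))
            continue
        marker, distance = nearest_snp(ann.loc[gene_id], marker_map)
        t = p = np.nan
        if panel is not None and trait is not None:
            eff = allelic_effect_test(panel, trait, marker)
            if eff["status"] == "ok":
                t, p = eff["t"], eff["p_value"]
        rows.append((gene_id, marker, distance, t, p))
    extra = pd.DataFrame(
        rows,
        columns=["gene_id", "nearest_marker_id", "signed_distance", "allelic_t", "allelic_p"],
    )
    return candidates.merge(extra, on="gene_id", how="left")
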
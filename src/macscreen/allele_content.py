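"""Per-marker allele frequencies and per-strain allele-content scores.

The minor-allele content (MAC) of a strain is the fraction of scanned SNPs at
which the strain carries the panel-minor allele.  The minor-allele (MA) set is
built per marker from within-panel frequencies; markers with MAF exactly 0 or
0.5 carry no information about which allele is minor and are excluded.  The MA
set is the genotype of an imagined strain homozygous for every minor allele,
and a strain's MAC numerator is the number of markers at which its genotype
matches that imagined strain.

Three scores share one scoring engine:

* ``mac``  — minor alleles over the informative (MAF not in {0, 0.5}) markers;
* ``mac2`` — minor alleles over the subset of markers whose MAF departs from
  0.5 significantly (chi-square goodness of fit, default alpha 0.05);
* ``hac``  — alternative-parent (Hawaii) alleles over the informative markers.

Under missing calls the denominator is the per-strain count of non-missing
calls within the relevant marker set, which keeps every score in [0, 1] and
comparable across strains; numerator and denominator are both reported.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .panel_io import MISSING, P1, P2, GenotypePanel

logger = logging.getLogger(__name__)

_ALLELE_NAME = {P1: "P1", P2: "P2"}
_NAME_ALLELE = {"P1": P1, "P2": P2}


def compute_allele_frequencies(panel: GenotypePanel) -> pd.DataFrame:
    """Per-marker counts, minor-allele frequency and informativeness.

    Returns a DataFrame indexed by ``marker_id`` with columns ``count_p1``,
    ``count_p2``, ``n_nonmissing``, ``maf``, ``minor_allele`` (``P1``/``P2``/
    ``None``) and ``informative``.  Markers whose calls are all missing get
    ``maf = NaN`` and ``informative = False``; exact 50/50 ties have a
    defined ``maf = 0.5`` but no minor allele.
    """
    if panel.n_strains == 0 or panel.n_markers == 0:
        raise ValueError("empty panel")
    calls = panel.calls
    count_p1 = (calls == P1).sum(axis=0)
    count_p2 = (calls == P2).sum(axis=0)
    n = count_p1 + count_p2
    with np.errstate(invalid="ignore", divide="ignore"):
        maf = np.where(n > 0, np.minimum(count_p1, count_p2) / np.maximum(n, 1), np.nan)
    minor = np.where(count_p1 < count_p2, "P1", "P2").astype(object)
    tie_or_mono = (count_p1 == count_p2) | (np.minimum(count_p1, count_p2) == 0)
    minor[tie_or_mono | (n == 0)] = None
    informative = (n > 0) & ~tie_or_mono
    return pd.DataFrame(
        {
            "count_p1": count_p1,
            "count_p2": count_p2,
            "n_nonmissing": n,
            "maf": np.where(n > 0, maf, np.nan),
            "minor_allele": minor,
            "informative": informative,
        },
        index=pd.Index(panel.marker_ids, name="marker_id"),
    )


def build_minor_allele_set(freqs: pd.DataFrame) -> dict[str, int]:
    """The MA set: each informative marker paired with its minor allele code."""
    inf = freqs[freqs["informative"]]
    if inf.empty:
        logger.info("minor-allele set is empty (no informative markers)")
    return {m: _NAME_ALLELE[a] for m, a in inf["minor_allele"].items()}


def maf_departure_test(
    count_minor: int, n_nonmissing: int, exact: bool = False
) -> float:
    """P-value for the departure of a marker's MAF from 0.5.

    Chi-square goodness of fit of observed allele counts
    ``(count_minor, n - count_minor)`` against an even split, df = 1, no
    continuity correction.  ``exact=True`` uses the two-sided binomial test
    instead.
    """
    n = int(n_nonmissing)
    k = int(count_minor)
    if n < 1:
        raise ValueError("n_nonmissing must be >= 1")
    if not 0 <= k <= n - k:
        raise ValueError(f"count_minor={k} is not a minor count for n={n}")
    if exact:
        return float(stats.binomtest(k, n, 0.5).pvalue)
    stat = (2 * k - n) ** 2 / n  # sum over both cells of (obs-exp)^2/exp
    return float(stats.chi2.sf(stat, df=1))


def build_mac2_set(freqs: pd.DataFrame, alpha: float = 0.05) -> dict[str, int]:
    """MA-set subset with MAF significantly below 0.5 (chi-square p < alpha)."""
    ma_set = build_minor_allele_set(freqs)
    out: dict[str, int] = {}
    for marker, allele in ma_set.items():
        row = freqs.loc[marker]
        k = int(min(row["count_p1"], row["count_p2"]))
        if maf_departure_test(k, int(row["n_nonmissing"])) < alpha:
            out[marker] = allele
    return out


def build_hac_set(freqs: pd.DataFrame) -> dict[str, int]:
    """Every informative marker paired with the Hawaii-parent allele (P2)."""
    return {m: P2 for m in freqs.index[freqs["informative"]]}


def compute_content(
    panel: GenotypePanel,
    allele_set: Mapping[str, int],
    mode: str = "MAC",
) -> pd.DataFrame:
    """Score each strain against an allele set.

    For every strain: ``numerator`` = non-missing calls matching the set's
    allele, ``denominator`` = set markers with a non-missing call in that
    strain, ``score`` = numerator / denominator.  A strain with no
    non-missing call over the set gets ``score = NaN`` and ``defined=False``.
    """
    cols = [panel.marker_index(m) for m in allele_set]
    want = np.fromiter(allele_set.values(), dtype=np.int8, count=len(allele_set))
    sub = panel.calls[:, cols]
    observed = sub != MISSING
    numer = ((sub == want[None, :]) & observed).sum(axis=1)
    denom = observed.sum(axis=1)
    undefined = denom == 0
    if undefined.any():
        logger.warning(
            "%d strain(s) have no non-missing call over the %s set",
            int(undefined.sum()),
            mode,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        score = np.where(denom > 0, numer / np.maximum(denom, 1), np.nan)
    return pd.DataFrame(
        {
            "strain_id": panel.strain_ids,
            "mode": mode,
            "score": score,
            "numerator": numer,
            "denominator": denom,
            "defined": ~undefined,
        }
    )


def content_scores(
    panel: GenotypePanel, mode: str = "mac", alpha: float = 0.05
) -> pd.DataFrame:
    """Convenience wrapper: build the allele set for ``mode`` and score it.

    ``mode`` is one of ``mac``, ``mac2``, ``hac``.
    """
    freqs = compute_allele_frequencies(panel)
    mode_l = mode.lower()
    if mode_l == "mac":
        allele_set = build_minor_allele_set(freqs)
    elif mode_l == "mac2":
        allele_set = build_mac2_set(freqs, alpha=alpha)
    elif mode_l == "hac":
        allele_set = build_hac_set(freqs)
    else:
        raise ValueError(f"unknown content mode {mode!r}")
    return compute_content(panel, allele_set, mode=mode_l.upper())


def all_content_scores(panel: GenotypePanel, alpha: float = 0.05) -> pd.DataFrame:
    """MAC, MAC2 and HAC in one wide table (one row per strain)."""
    freqs = compute_allele_frequencies(panel)
    wide = pd.DataFrame({"strain_id": panel.strain_ids})
    for mode, aset in (
        ("mac", build_minor_allele_set(freqs)),
        ("mac2", build_mac2_set(freqs, alpha=alpha)),
        ("hac", build_hac_set(freqs)),
    ):
        sc = compute_content(panel, aset, mode=mode.upper())
        wide[mode] = sc["score"].to_numpy()
        wide[f"{mode}_numerator"] = sc["numerator"].to_numpy()
        wide[f"{mode}_denominator"] = sc["denominator"].to_numpy()
    return wide
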
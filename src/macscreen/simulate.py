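"""Synthetic recombinant-inbred panels with planted, recoverable structure.

The generator emulates the statistical shape of a biparental RIAIL panel
derived from N2 x CB4856 *C. elegans* crosses, at the published scale: 237
strains, 1454 nuclear SNP markers over the six chromosomes.  Genomes are
mosaics of parental blocks produced by a two-state Markov chain along each
chromosome (switch probability ``recomb_prob`` between adjacent markers);
selection during panel construction is modelled phenomenologically by biasing
each marker's realised allele frequency toward a target P2 frequency of
``0.5 - skew``.  The trait is an additive function of the strain's computed
minor-allele content plus an optional major-effect locus (with an
``npr-1``-like background-restriction flag) and Gaussian noise; the
expression matrix contains planted genes loaded on standardised MAC with
either sign, the rest pure noise.  Every dataset ships with its ground-truth
labels so recovery can be scored.

All outputs are reproducible from ``SimConfig.seed`` alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .allele_content import content_scores
from .panel_io import MISSING, P1, P2, GenotypePanel

#: marker counts per chromosome, totalling 1454
DEFAULT_CHROM_MARKERS: dict[str, int] = {
    "I": 242,
    "II": 243,
    "III": 242,
    "IV": 243,
    "V": 242,
    "X": 242,
}

#: synthetic inter-marker spacing in bp (~15 Mb chromosomes / ~242 markers)
MARKER_SPACING = 10_000


@dataclass
class MajorLocus:
    """A single large-effect locus added to the trait model."""

    marker_id: str
    effect: float
    #: when True the MAC effect on the trait applies only to P2 carriers here,
    #: emulating a background-restricted (npr-1-like) interaction
    background_restricted: bool = False


@dataclass
class SimConfig:
    n_strains: int = 237
    chrom_markers: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CHROM_MARKERS)
    )
    #: parental-switch probability between adjacent markers; ~0.02 gives a
    #: handful of recombination blocks per chromosome, as in an advanced
    #: intercross panel
    recomb_prob: float = 0.02
    #: per-marker selection skew: target P2 frequency is 0.5 - skew; a scalar
    #: applies to every marker.  0.05 reproduces a panel where roughly a third
    #: of markers have MAF significantly below 0.5 at n = 237.
    skew: float | np.ndarray = 0.05
    genotype_missing_rate: float = 0.0
    # trait model: intercept + beta_mac * MAC + major-locus effect + noise
    intercept: float = 0.1
    beta_mac: float = 1.0
    major_locus: MajorLocus | None = None
    #: trait noise SD, calibrated by sweep so that with beta_mac = 1 the
    #: population rank correlation between MAC and trait is ~0.4
    noise_sd: float = 0.18
    # expression model
    n_genes: int = 2000
    n_planted_pos: int = 20
    n_planted_neg: int = 10
    #: loading of planted genes on standardised MAC (noise SD is expr_noise_sd)
    gamma: float = 1.0
    expr_noise_sd: float = 1.0
    expr_missing_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        skew = np.asarray(self.skew, dtype=float)
        if (0.5 - skew < 0).any() or (0.5 - skew > 1).any():
            raise ValueError("target P2 frequency 0.5 - skew must lie in [0, 1]")
        if not 0 <= self.recomb_prob <= 1:
            raise ValueError("recomb_prob must lie in [0, 1]")
        for rate in (self.genotype_missing_rate, self.expr_missing_rate):
            if not 0 <= rate < 1:
                raise ValueError("missing rates must lie in [0, 1)")
        if self.n_planted_pos + self.n_planted_neg > self.n_genes:
            raise ValueError("planted gene counts exceed n_genes")
        if self.n_strains < 2 or not self.chrom_markers:
            raise ValueError("need >= 2 strains and >= 1 chromosome")


def _marker_map(config: SimConfig) -> pd.DataFrame:
    rows = []
    for chrom, m in config.chrom_markers.items():
        for i in range(m):
            rows.append((f"S{chrom}_{i + 1:04d}", chrom, (i + 1) * MARKER_SPACING))
    return pd.DataFrame(rows, columns=["marker_id", "chromosome", "position"])


def simulate_panel(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[GenotypePanel, pd.DataFrame, pd.DataFrame]:
    """Generate genotypes: Markov parental blocks, then frequency skew.

    Returns ``(panel, marker_map, marker_truth)``; ``marker_truth`` records
    the skew applied per marker.
    """
    config.validate()
    rng = np.random.default_rng(config.seed) if rng is None else rng
    markers = _marker_map(config)
    n, r = config.n_strains, config.recomb_prob

    blocks = []
    for _, m in config.chrom_markers.items():
        first = rng.random(n) < 0.5
        switches = rng.random((n, m - 1)) < r if m > 1 else np.empty((n, 0), bool)
        steps = np.concatenate([first[:, None], switches], axis=1)
        blocks.append(np.cumsum(steps, axis=1) % 2)  # cumulative XOR
    calls = np.concatenate(blocks, axis=1).astype(np.int8)

    # phenomenological selection: per-marker flips toward the target frequency
    skew = np.broadcast_to(
        np.asarray(config.skew, dtype=float), (calls.shape[1],)
    ).copy()
    target = 0.5 - skew
    freq = calls.mean(axis=0)
    # zero-skew markers are left untouched: no selection means no resampling,
    # so their frequencies keep their natural drift-scale variation
    for j in np.flatnonzero((skew != 0) & (np.abs(freq - target) > 1e-12)):
        f, t = freq[j], target[j]
        if f > t:  # flip some P2 -> P1
            pr = (f - t) / f
            carriers = np.flatnonzero(calls[:, j] == P2)
            calls[carriers[rng.random(carriers.size) < pr], j] = P1
        elif f < t and f < 1:  # flip some P1 -> P2
            pr = (t - f) / (1 - f)
            carriers = np.flatnonzero(calls[:, j] == P1)
            calls[carriers[rng.random(carriers.size) < pr], j] = P2

    if config.genotype_missing_rate > 0:
        mask = rng.random(calls.shape) < config.genotype_missing_rate
        calls[mask] = MISSING

    strains = [f"RIL{i + 1:03d}" for i in range(n)]
    panel = GenotypePanel(strain_ids=strains, markers=markers, calls=calls)
    truth = pd.DataFrame({"marker_id": markers["marker_id"], "skew": skew})
    return panel, markers, truth


def simulate_trait(
    panel: GenotypePanel,
    config: SimConfig,
    rng: np.random.Generator | None = None,
    mac: np.ndarray | None = None,
) -> pd.DataFrame:
    """Trait = intercept + beta_mac * MAC (+ major locus) + Gaussian noise.

    With a background-restricted major locus the MAC term applies only to
    strains carrying P2 there, and the returned table carries a ``stratum``
    column (``HW``/``N2``) so stratified analyses can reproduce the design.
    """
    rng = (
        np.random.default_rng(np.random.default_rng(config.seed).integers(2**31) + 1)
        if rng is None
        else rng
    )
    if mac is None:
        mac = content_scores(panel, "mac")["score"].to_numpy()
    mac_term = config.beta_mac * mac
    y = np.full(panel.n_strains, config.intercept, dtype=float)
    out = pd.DataFrame({"strain_id": panel.strain_ids})
    if config.major_locus is None:
        y = y + mac_term
    else:
        j = panel.marker_index(config.major_locus.marker_id)  # raises if unknown
        carrier = panel.calls[:, j] == P2
        if config.major_locus.background_restricted:
            # MAC effect only in the P2 (HW-like) background
            y = y + np.where(carrier, mac_term, 0.0)
        else:
            y = y + mac_term
        y = y + config.major_locus.effect * carrier
        out["stratum"] = np.where(carrier, "HW", "N2")
    out["trait_value"] = y + rng.normal(0.0, config.noise_sd, size=len(out))
    return out[
        ["strain_id", "trait_value"] + (["stratum"] if "stratum" in out else [])
    ]


def simulate_expression(
    panel: GenotypePanel,
    trait: pd.DataFrame,
    config: SimConfig,
    rng: np.random.Generator | None = None,
    mac: np.ndarray | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gene x strain expression with planted MAC-loaded genes.

    Planted positive genes are ``+gamma * z(MAC) + noise``, negative genes
    ``-gamma * z(MAC) + noise``, all others pure Gaussian noise; planted
    genes inherit a trait correlation through the MAC-trait coupling.
    Returns the matrix and a gene-level truth table
    (``planted_class`` in {pos, neg, null}).
    """
    config.validate()
    rng = (
        np.random.default_rng(np.random.default_rng(config.seed).integers(2**31) + 2)
        if rng is None
        else rng
    )
    if mac is None:
        mac = content_scores(panel, "mac")["score"].to_numpy()
    z = (mac - mac.mean()) / mac.std()
    g, n = config.n_genes, panel.n_strains
    X = rng.normal(0.0, config.expr_noise_sd, size=(g, n))
    classes = np.array(["null"] * g, dtype=object)
    classes[: config.n_planted_pos] = "pos"
    classes[config.n_planted_pos : config.n_planted_pos + config.n_planted_neg] = "neg"
    X[classes == "pos"] += config.gamma * z
    X[classes == "neg"] -= config.gamma * z
    if config.expr_missing_rate > 0:
        X[rng.random(X.shape) < config.expr_missing_rate] = np.nan
    gene_ids = [f"G{i + 1:05d}" for i in range(g)]
    expr = pd.DataFrame(X, index=pd.Index(gene_ids, name="gene_id"),
                        columns=panel.strain_ids)
    truth = pd.DataFrame({"gene_id": gene_ids, "planted_class": classes})
    return expr, truth


def simulate_dataset(
    config: SimConfig,
) -> dict:
    """One call for the full study: panel, trait, expression and truth tables.

    A single generator seeded from ``config.seed`` drives every stage, so the
    whole dictionary is byte-identical across runs with the same config.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    panel, markers, marker_truth = simulate_panel(config, rng=rng)
    mac = content_scores(panel, "mac")["score"].to_numpy()
    trait = simulate_trait(panel, config, rng=rng, mac=mac)
    expr, gene_truth = simulate_expression(panel, trait, config, rng=rng, mac=mac)
    return {
        "panel": panel,
        "markers": markers,
        "trait": trait,
        "expression": expr,
        "marker_truth": marker_truth,
        "gene_truth": gene_truth,
        "mac": mac,
        "config": config,
    }


def config_to_dict(config: SimConfig) -> dict:
    d = asdict(config)
    if isinstance(d.get("skew"), np.ndarray):
        d["skew"] = d["skew"].tolist()
    return d
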